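"""Hierarchical assembly of block haplotypes.

Each variant starts as its own cluster carrying a trivial one-site
haplotype.  The assembler repeatedly merges the two clusters joined by the
most trustworthy directly-observed variant pair — highest confidence score
first, normal pairs before ambiguous (singleton before low-coverage) ones,
score ties broken by genomic proximity — until a single cluster remains
(n - 1 merges for an n-variant block).

A merge mates haplotype 1 of one cluster with haplotype 1 or 2 of the
other; the choice is score-led via the 2x2 table of read support at the
leading pair, except where the merge looks risky, in which case a local
MEC vote (:mod:`hierphase.local_mec`) decides instead:

* the clusters interleave with >= ``min_junctions`` junctions (embedded
  merging; default threshold 3), or
* the leading pair is ambiguous and there are >= 2 junctions, or
* the two candidate scores tie exactly.
"""

from __future__ import annotations

import heapq
import statistics
from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .fragments import Fragment, VariantBlock
from .local_mec import CandidateSolution, MecChoice, local_mec_select
from .scoring import (
    S1,
    S2,
    PairClass,
    PairObservation,
    PairScore,
    ScoringParams,
    classify_pair,
    pair_cs,
)

__all__ = [
    "AssemblyParams",
    "Cluster",
    "AssemblyState",
    "MergeRecord",
    "PhasedBlock",
    "cluster_score",
    "select_next_merge",
    "count_junctions",
    "merge_clusters",
    "assemble_block",
]


@dataclass(frozen=True)
class AssemblyParams:
    """Tunables of the assembler."""

    scoring: ScoringParams = field(default_factory=ScoringParams)
    min_junctions: int = 3  # embedded-merge threshold for the local MEC vote
    low_cov_threshold: float | None = None  # None -> median pair depth per block


@dataclass
class Cluster:
    """A partially phased group of sites; hap2 is the complement of hap1."""

    sites: list[int]  # sorted (site_index order == genomic order)
    hap: dict[int, int]  # site_index -> hap1 allele
    frag_ids: set[int]  # indices of fragments touching this cluster


@dataclass(frozen=True)
class ScoredPair:
    """One directly observed variant pair with its fixed score and class."""

    i: int
    j: int
    obs: PairObservation
    score: PairScore
    pclass: PairClass
    distance: int  # bp between the two sites

    @property
    def sort_key(self) -> tuple:
        # assembly priority: class, then CS (higher first), then proximity,
        # then leftmost position / indices for determinism
        return (self.pclass.rank, -self.score.cs, self.distance, self.i, self.j)


@dataclass
class MergeRecord:
    """Audit record of one merge decision."""

    pair: tuple[int, int]
    cs1: float
    cs2: float
    junctions: int
    mechanism: str  # "cs" | "mec_embedded" | "mec_ambiguous" | "mec_tie" | "cs_fallback"
    chosen: int  # S1 or S2
    pair_class: str
    low_confidence: bool = False

    def as_tsv(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                f"{self.pair[0]}-{self.pair[1]}",
                f"{self.cs1:.4f}",
                f"{self.cs2:.4f}",
                self.junctions,
                self.mechanism,
                f"S{self.chosen}",
                self.pair_class,
                int(self.low_confidence),
            )
        )


@dataclass
class PhasedBlock:
    """Final two complementary haplotypes over a block's sites."""

    site_indices: list[int]
    positions: list[int]
    hap1: str
    hap2: str
    phased: list[bool]
    merge_log: list[MergeRecord] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)

    def hap_map(self) -> dict[int, int]:
        return {s: int(a) for s, a in zip(self.site_indices, self.hap1)}


@dataclass
class AssemblyState:
    """Mutable assembler state for one block."""

    clusters: dict[int, Cluster]  # cluster id -> cluster
    cluster_of: dict[int, int]  # site_index -> cluster id
    pair_scores: dict[tuple[int, int], ScoredPair]
    fragments: list[Fragment]
    max_coverage: int
    params: AssemblyParams
    merge_log: list[MergeRecord] = field(default_factory=list)
    _heap: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Pair observation / state construction

def collect_pair_observations(fragments: Sequence[Fragment]) -> dict[tuple[int, int], list[int]]:
    """2x2 read-count tables for every directly observed variant pair."""
    counts: dict[tuple[int, int], list[int]] = {}
    for frag in fragments:
        idxs = sorted(frag.alleles)
        for a_pos in range(len(idxs)):
            i = idxs[a_pos]
            ai = frag.alleles[i]
            for b_pos in range(a_pos + 1, len(idxs)):
                j = idxs[b_pos]
                cell = (int(ai) << 1) | int(frag.alleles[j])
                tbl = counts.get((i, j))
                if tbl is None:
                    tbl = counts[(i, j)] = [0, 0, 0, 0]
                tbl[cell] += 1
    return counts


def init_state(block: VariantBlock, params: AssemblyParams | None = None) -> AssemblyState:
    """Score every observed pair and set up the initial one-site clusters."""
    params = params or AssemblyParams()
    positions = block.positions
    raw = collect_pair_observations(block.fragments)
    if not raw:
        raise ValueError("block has no directly observed variant pairs")
    depths = [sum(t) for t in raw.values()]
    max_coverage = max(depths)
    threshold = (
        params.low_cov_threshold
        if params.low_cov_threshold is not None
        else statistics.median(depths)
    )
    pair_scores: dict[tuple[int, int], ScoredPair] = {}
    for (i, j), tbl in raw.items():
        obs = PairObservation(*tbl)
        pair_scores[(i, j)] = ScoredPair(
            i=i,
            j=j,
            obs=obs,
            score=pair_cs(obs, max_coverage, params.scoring),
            pclass=classify_pair(obs, threshold),
            distance=positions[j] - positions[i],
        )

    clusters = {}
    cluster_of = {}
    site_frags: dict[int, set[int]] = {s.site_index: set() for s in block.sites}
    for fid, frag in enumerate(block.fragments):
        for idx in frag.alleles:
            if idx in site_frags:
                site_frags[idx].add(fid)
    for cid, site in enumerate(block.site_indices):
        clusters[cid] = Cluster(sites=[site], hap={site: 0}, frag_ids=site_frags[site])
        cluster_of[site] = cid

    state = AssemblyState(
        clusters=clusters,
        cluster_of=cluster_of,
        pair_scores=pair_scores,
        fragments=list(block.fragments),
        max_coverage=max_coverage,
        params=params,
    )
    for sp in pair_scores.values():
        heapq.heappush(state._heap, (*sp.sort_key,))
    return state


# ---------------------------------------------------------------------------
# Spec operations

def cluster_score(
    x: Cluster, y: Cluster, pair_scores: dict[tuple[int, int], ScoredPair]
) -> tuple[float | None, tuple[int, int] | None]:
    """Single-linkage score between two clusters.

    S(X, Y) = max CS over directly observed cross pairs (normal pairs
    preferred over ambiguous ones); ``(None, None)`` if no direct pair
    exists.
    """
    best: ScoredPair | None = None
    xs, ys = set(x.sites), set(y.sites)
    for (i, j), sp in pair_scores.items():
        if (i in xs and j in ys) or (i in ys and j in xs):
            if best is None or sp.sort_key < best.sort_key:
                best = sp
    if best is None:
        return None, None
    return best.score.cs, (best.i, best.j)


def select_next_merge(state: AssemblyState) -> ScoredPair:
    """Pop the best remaining cross-cluster pair (lazy-deletion heap).

    Pair scores are immutable, so under single-linkage the globally best
    pair whose endpoints lie in different clusters is always the next merge.
    """
    while state._heap:
        entry = heapq.heappop(state._heap)
        i, j = entry[-2], entry[-1]
        if state.cluster_of[i] != state.cluster_of[j]:
            return state.pair_scores[(i, j)]
    raise AssertionError("no cross-cluster pair left in a connected block")


def count_junctions(x_sites: Sequence[int], y_sites: Sequence[int]) -> int:
    """Boundaries between adjacent sites from different clusters.

    Counted over the position-sorted union of the two clusters' sites.
    """
    merged = sorted((s, 0) for s in x_sites)
    merged += sorted((s, 1) for s in y_sites)
    merged.sort()
    return sum(1 for a, b in zip(merged, merged[1:]) if a[1] != b[1])


def _candidates(x: Cluster, y: Cluster) -> tuple[CandidateSolution, CandidateSolution]:
    s1 = dict(x.hap)
    s1.update(y.hap)
    s2 = dict(x.hap)
    s2.update({k: 1 - v for k, v in y.hap.items()})
    return CandidateSolution(id=S1, haps=s1), CandidateSolution(id=S2, haps=s2)


def merge_table(x: Cluster, y: Cluster, sp: ScoredPair) -> PairObservation:
    """Relabel the leading pair's read counts by cluster-haplotype support.

    A fragment showing alleles (a, b) at the pair supports row
    ``a XOR hap1_X`` and column ``b XOR hap1_Y`` — cell (0, 0) means
    "matches hap1 of X and hap1 of Y".
    """
    fi = x.hap[sp.i] if sp.i in x.hap else y.hap[sp.i]
    fj = y.hap[sp.j] if sp.j in y.hap else x.hap[sp.j]
    tbl = [sp.obs.rc00, sp.obs.rc01, sp.obs.rc10, sp.obs.rc11]
    out = [0, 0, 0, 0]
    for cell, count in enumerate(tbl):
        a, b = cell >> 1, cell & 1
        out[((a ^ fi) << 1) | (b ^ fj)] = count
    return PairObservation(*out)


def merge_clusters(state: AssemblyState, sp: ScoredPair) -> MergeRecord:
    """Execute one merge led by pair ``sp`` and record the decision."""
    params = state.params
    cx = state.cluster_of[sp.i]
    cy = state.cluster_of[sp.j]
    x, y = state.clusters[cx], state.clusters[cy]
    if sp.i not in x.hap:  # orient so that sp.i lies in X
        x, y = y, x
        cx, cy = cy, cx
    junctions = count_junctions(x.sites, y.sites)
    cand1, cand2 = _candidates(x, y)

    obs = merge_table(x, y, sp)
    score = pair_cs(obs, state.max_coverage, params.scoring)
    mechanism = "cs"
    chosen = score.winner
    low_confidence = False

    mec: MecChoice | None = None
    if junctions >= params.min_junctions:
        scope = [state.fragments[fid] for fid in sorted(x.frag_ids & y.frag_ids)]
        mec = local_mec_select(cand1, cand2, scope)
        mechanism = "mec_embedded"
    elif sp.pclass.ambiguous and junctions >= 2:
        scope = [state.fragments[fid] for fid in sorted(x.frag_ids | y.frag_ids)]
        mec = local_mec_select(cand1, cand2, scope)
        mechanism = "mec_ambiguous"
    elif score.tied:
        scope = [state.fragments[fid] for fid in sorted(x.frag_ids & y.frag_ids)]
        mec = local_mec_select(cand1, cand2, scope)
        mechanism = "mec_tie"

    if mec is not None:
        if mec.empty_scope:
            mechanism = "cs_fallback"
            chosen = score.winner
            low_confidence = True
        else:
            chosen = mec.candidate.id
            low_confidence = mec.tied

    winner = cand1 if chosen == S1 else cand2
    merged = Cluster(
        sites=sorted(x.sites + y.sites),
        hap=dict(winner.haps),
        frag_ids=x.frag_ids | y.frag_ids,
    )
    state.clusters[cx] = merged
    del state.clusters[cy]
    for site in merged.sites:
        state.cluster_of[site] = cx

    record = MergeRecord(
        pair=(sp.i, sp.j),
        cs1=score.cs1.cs,
        cs2=score.cs2.cs,
        junctions=junctions,
        mechanism=mechanism,
        chosen=chosen,
        pair_class=sp.pclass.value,
        low_confidence=low_confidence,
    )
    state.merge_log.append(record)
    return record


def assemble_block(block: VariantBlock, params: AssemblyParams | None = None) -> PhasedBlock:
    """Phase one variant block: exactly n - 1 score-guided merges."""
    if len(block.sites) < 2:
        raise ValueError("assembly needs a block with at least two sites")
    state = init_state(block, params)
    n = len(block.sites)
    for _ in range(n - 1):
        sp = select_next_merge(state)
        merge_clusters(state, sp)
    (final,) = state.clusters.values()
    hap1 = "".join(str(final.hap[s]) for s in block.site_indices)
    hap2 = "".join(str(1 - final.hap[s]) for s in block.site_indices)
    return PhasedBlock(
        site_indices=list(block.site_indices),
        positions=[s.pos for s in block.sites],
        hap1=hap1,
        hap2=hap2,
        phased=[True] * n,
        merge_log=state.merge_log,
    )


MERGE_LOG_HEADER = "pair\tCS1\tCS2\tjunctions\tmechanism\tchosen\tpair_class\tlow_confidence"


def write_merge_log(phased: PhasedBlock, fh) -> None:
    """Tab-separated audit file, one line per merge."""
    fh.write(MERGE_LOG_HEADER + "\n")
    for rec in phased.merge_log:
        fh.write(rec.as_tsv() + "\n")
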