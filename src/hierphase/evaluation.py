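"""Phasing accuracy metrics: switch/flip errors, error rate, perfect ratio,
quality-adjusted N50 (QAN50), and the error-correction (EC) rate.

A predicted haplotype is compared against the truth at the sites both have
phased.  Because only heterozygous sites are considered, the prediction is
a mosaic of the two true haplotypes; each boundary where the mosaic changes
template is a *switch error*, and two adjacent switches flanking a single
mis-phased site collapse into one *flip error*.  All metrics are invariant
under global complement of either input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fragments import Fragment
from .assembly import PhasedBlock

__all__ = [
    "BlockComparison",
    "count_switch_flip",
    "compare_blocks",
    "phasing_error_rate",
    "perfect_ratio",
    "qan50",
    "ec_rate",
    "truth_block",
]


def truth_block(site_indices: Sequence[int], positions: Sequence[int], hap1: str) -> PhasedBlock:
    """Wrap a truth haplotype string as a fully phased block."""
    hap2 = "".join("1" if c == "0" else "0" for c in hap1)
    return PhasedBlock(
        site_indices=list(site_indices),
        positions=list(positions),
        hap1=hap1,
        hap2=hap2,
        phased=[True] * len(hap1),
    )


@dataclass
class BlockComparison:
    """Per-block evaluation record."""

    switch_error: int
    flip_error: int
    n_sites: int  # sites in the predicted block
    n_common: int  # sites phased by both prediction and truth
    number_of_variants: int  # decisions needed: all sites but the left-most
    number_of_phased: int  # decisions actually made
    positions: list[int] = field(default_factory=list)  # all predicted sites
    phased: list[bool] = field(default_factory=list)  # compared at this site
    switch_sites: list[int] = field(default_factory=list)  # index: switch boundary before it
    uninformative: bool = False

    @property
    def errors(self) -> int:
        return self.switch_error + self.flip_error

    @property
    def error_free(self) -> bool:
        return self.errors == 0


def _decompose(agreement: Sequence[int]) -> tuple[int, int, list[int]]:
    """Minimum-event switch/flip decomposition of an agreement sequence.

    ``agreement[k]`` is 0 where the prediction follows the anchored truth
    haplotype and 1 where it follows the other.  A switch changes the
    template at a boundary, a flip corrects a single site; both cost one
    event.  Dynamic programming finds the decomposition with the fewest
    events (two adjacent template toggles around an isolated site thereby
    collapse into one flip); among equal-cost decompositions the one with
    fewer flips is taken, so an adjacent mis-phased pair stays two
    switches.  Returns (switches, flips, switch boundary indices) where a
    boundary index k means "between sites k-1 and k".
    """
    m = len(agreement)
    if m == 0:
        return 0, 0, []
    INF = (1 << 30, 1 << 30)
    # dp cost = (events, flips), lexicographic; free initial template
    dp = [
        ((0, 0) if agreement[0] == 0 else (1, 1)),
        ((0, 0) if agreement[0] == 1 else (1, 1)),
    ]
    parents: list[list[int]] = []
    for k in range(1, m):
        ndp = [INF, INF]
        parent = [0, 0]
        for t in (0, 1):
            for prev in (0, 1):
                ev, fl = dp[prev]
                if t != prev:
                    ev += 1  # switch at this boundary
                if agreement[k] != t:
                    ev += 1  # flip at this site
                    fl += 1
                if (ev, fl) < ndp[t]:
                    ndp[t] = (ev, fl)
                    parent[t] = prev
        dp = ndp
        parents.append(parent)

    t = 0 if dp[0] <= dp[1] else 1
    _, flips = dp[t]
    boundaries: list[int] = []
    for k in range(m - 1, 0, -1):
        prev = parents[k - 1][t]
        if prev != t:
            boundaries.append(k)
        t = prev
    boundaries.reverse()
    return len(boundaries), flips, boundaries


def count_switch_flip(pred: PhasedBlock, truth: PhasedBlock) -> tuple[int, int]:
    """(switch_error, flip_error) between a predicted and a true phasing."""
    cmp = compare_blocks(pred, truth)
    return cmp.switch_error, cmp.flip_error


def compare_blocks(pred: PhasedBlock, truth: PhasedBlock) -> BlockComparison:
    """Full per-block comparison, retaining what QAN50 needs.

    Only sites phased by both inputs are compared; the predicted haplotype
    is anchored to whichever truth haplotype it matches at the first common
    site, which makes the result complement-invariant.
    """
    pred_map = {
        s: int(a) for s, a, p in zip(pred.site_indices, pred.hap1, pred.phased) if p
    }
    truth_map = {
        s: int(a) for s, a, p in zip(truth.site_indices, truth.hap1, truth.phased) if p
    }
    common = [s for s in pred.site_indices if s in pred_map and s in truth_map]
    n_sites = len(pred.site_indices)
    n_phased = max(0, len(common) - 1)
    base = BlockComparison(
        switch_error=0,
        flip_error=0,
        n_sites=n_sites,
        n_common=len(common),
        number_of_variants=max(0, n_sites - 1),
        number_of_phased=n_phased,
        positions=list(pred.positions),
        phased=[s in pred_map and s in truth_map for s in pred.site_indices],
    )
    if len(common) < 2:
        base.uninformative = True
        return base

    anchor = pred_map[common[0]] ^ truth_map[common[0]]
    agreement = [pred_map[s] ^ truth_map[s] ^ anchor for s in common]
    switches, flips, boundaries = _decompose(agreement)
    base.switch_error = switches
    base.flip_error = flips
    # translate boundary indices from the common-site sequence back to
    # indices into the full predicted site list
    site_pos = {s: k for k, s in enumerate(pred.site_indices)}
    base.switch_sites = [site_pos[common[b]] for b in boundaries]
    return base


def phasing_error_rate(reports: Iterable[BlockComparison]) -> float | None:
    """(total flips + switches) / total phased decisions; None if no decisions."""
    errors = phased = 0
    for rep in reports:
        errors += rep.errors
        phased += rep.number_of_phased
    if phased == 0:
        return None
    return errors / phased


def perfect_ratio(reports: Iterable[BlockComparison]) -> float | None:
    """Fraction of blocks phased without a single error; None if no blocks."""
    reports = list(reports)
    if not reports:
        return None
    return sum(1 for rep in reports if rep.error_free) / len(reports)


def _n50(values: Sequence[float]) -> float:
    """Largest value whose cumulative (descending) sum reaches half the total."""
    vals = sorted(values, reverse=True)
    total = sum(vals)
    if total <= 0:
        return 0.0
    running = 0.0
    for v in vals:
        running += v
        if running >= total / 2:
            return v
    return vals[-1]


def qan50(reports: Iterable[BlockComparison]) -> float:
    """Quality-adjusted N50 of switch-error-free sub-block spans.

    Each block is split at its switch errors; a sub-block's span (first to
    last phased site, in bp) is weighted by the proportion of phased
    variants it contains, and the N50 of the weighted spans is returned.
    """
    adjusted: list[float] = []
    for rep in reports:
        if not rep.positions:
            continue
        cuts = [0] + sorted(rep.switch_sites) + [len(rep.positions)]
        for lo, hi in zip(cuts, cuts[1:]):
            if hi <= lo:
                continue
            phased_pos = [
                rep.positions[k] for k in range(lo, hi) if rep.phased[k]
            ]
            if not phased_pos:
                continue
            span = phased_pos[-1] - phased_pos[0]
            proportion = len(phased_pos) / (hi - lo)
            adjusted.append(span * proportion)
    return _n50(adjusted) if adjusted else 0.0


def ec_rate(fragments: Iterable[Fragment], solution: Mapping[int, int] | PhasedBlock) -> float | None:
    """Error corrections per fragment character.

    Numerator: per fragment, the minimum mismatches against either
    haplotype of the solution.  Denominator: all called fragment characters
    at the solution's sites.  None when no characters overlap.
    """
    if isinstance(solution, PhasedBlock):
        haps = solution.hap_map()
    else:
        haps = dict(solution)
    corrections = characters = 0
    for frag in fragments:
        m1 = m2 = 0
        for idx, sym in frag.alleles.items():
            h = haps.get(idx)
            if h is None:
                continue
            characters += 1
            if int(sym) != h:
                m1 += 1
            else:
                m2 += 1
        corrections += min(m1, m2)
    if characters == 0:
        return None
    return corrections / characters
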