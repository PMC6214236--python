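"""Local minimum-error-correction (MEC) voting between two merge candidates.

When two partially phased clusters are joined there are only two possible
outcomes under the heterozygous assumption: mate haplotype 1 of cluster X
with haplotype 1 of cluster Y (S1), or with haplotype 2 (S2).  The local
MEC vote recruits the reads overlapping the merge region, charges each read
the minimum number of allele corrections needed to make it consistent with
either haplotype of a candidate, and picks the candidate with the lower
total penalty.

``brute_force_mec`` is an exhaustive whole-block MEC solver; it exists as
an independent oracle for tests and is not on the phasing path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .fragments import Fragment

__all__ = [
    "CandidateSolution",
    "candidate_penalty",
    "local_mec_select",
    "brute_force_mec",
]


@dataclass(frozen=True)
class CandidateSolution:
    """One of the two candidate joins over the union of two clusters.

    ``haps`` maps site_index -> hap1 allele (0/1); hap2 is the complement.
    """

    id: int  # 1 (S1) or 2 (S2)
    haps: Mapping[int, int]


def candidate_penalty(fragments: Iterable[Fragment], candidate: CandidateSolution) -> int:
    """Total corrections needed to reconcile the fragments with a candidate.

    Per fragment: min(mismatches vs hap1, mismatches vs hap2) over its
    called sites that fall inside the candidate; fragments with no overlap
    contribute nothing.
    """
    haps = candidate.haps
    total = 0
    for frag in fragments:
        m1 = m2 = 0
        seen = False
        for idx, sym in frag.alleles.items():
            h = haps.get(idx)
            if h is None:
                continue
            seen = True
            a = int(sym)
            if a != h:
                m1 += 1
            else:
                m2 += 1  # mismatch vs the complementary haplotype
        if seen:
            total += min(m1, m2)
    return total


@dataclass(frozen=True)
class MecChoice:
    candidate: CandidateSolution
    penalties: tuple[int, int]  # (S1, S2)
    tied: bool
    empty_scope: bool = False


def local_mec_select(
    s1: CandidateSolution,
    s2: CandidateSolution,
    fragments: Sequence[Fragment],
) -> MecChoice:
    """Vote between the two candidate joins by MEC penalty.

    ``fragments`` is the recruited scope (junction-spanning reads, or the
    whole block's reads depending on the trigger).  Ties go to S1 with a
    low-confidence flag; an empty scope also falls back to S1, flagged, so
    the caller can use the score-led choice instead.
    """
    frags = [f for f in fragments if any(i in s1.haps for i in f.alleles)]
    if not frags:
        return MecChoice(candidate=s1, penalties=(0, 0), tied=True, empty_scope=True)
    p1 = candidate_penalty(frags, s1)
    p2 = candidate_penalty(frags, s2)
    if p2 < p1:
        return MecChoice(candidate=s2, penalties=(p1, p2), tied=False)
    return MecChoice(candidate=s1, penalties=(p1, p2), tied=p1 == p2)


def brute_force_mec(
    fragments: Sequence[Fragment],
    site_indices: Sequence[int],
    max_sites: int = 16,
) -> tuple[dict[int, int], int]:
    """Exhaustive MEC over a block: the correction-minimizing haplotypes.

    Enumerates all 2^(n-1) assignments (first site fixed to 0; the
    complement is equivalent) and returns ``(hap1 mapping, min_corrections)``.
    Test oracle only — exponential in block size.
    """
    sites = sorted(site_indices)
    n = len(sites)
    if n > max_sites:
        raise ValueError(f"block of {n} sites exceeds oracle limit {max_sites}")
    if n == 0:
        return {}, 0
    pos_of = {s: k for k, s in enumerate(sites)}
    # precompute per-fragment (bitmask of covered sites, bitmask of alt alleles)
    frag_bits = []
    for frag in fragments:
        cover = alts = 0
        for idx, sym in frag.alleles.items():
            k = pos_of.get(idx)
            if k is None:
                continue
            cover |= 1 << k
            if sym == "1":
                alts |= 1 << k
        if cover:
            frag_bits.append((cover, alts))

    best_cost = None
    best_assign = 0
    for bits in range(1 << (n - 1)):
        hap = bits << 1  # site[0] fixed to allele 0
        cost = 0
        for cover, alts in frag_bits:
            d = (alts ^ hap) & cover
            m1 = d.bit_count()
            cost += min(m1, cover.bit_count() - m1)
            if best_cost is not None and cost >= best_cost:
                break
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best_assign = hap
    hap1 = {s: (best_assign >> k) & 1 for s, k in pos_of.items()}
    return hap1, int(best_cost)
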