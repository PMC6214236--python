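"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hierphase.fragments import Fragment, VariantBlock, VariantSite


# ---------------------------------------------------------------------------
# Builders

def make_sites(positions, chrom="chr1"):
    return [
        VariantSite(chrom=chrom, pos=int(p), ref_allele="A", alt_allele="C", site_index=k)
        for k, p in enumerate(positions)
    ]


def make_fragment(name, alleles):
    """alleles: dict site_index -> '0'/'1', or a (first_index, string) pair."""
    if isinstance(alleles, tuple):
        first, s = alleles
        alleles = {first + k: c for k, c in enumerate(s) if c in "01"}
    return Fragment(name=name, alleles=dict(alleles))


def make_block(positions, fragment_specs, chrom="chr1"):
    """fragment_specs: iterable of (count, alleles) or (name, alleles)."""
    sites = make_sites(positions, chrom)
    frags = []
    k = 0
    for spec in fragment_specs:
        head, alleles = spec
        if isinstance(head, int):
            for _ in range(head):
                frags.append(make_fragment(f"f{k}", alleles))
                k += 1
        else:
            frags.append(make_fragment(head, alleles))
    return VariantBlock(sites=sites, fragments=frags)


def random_clean_block(rng, n_sites, coverage=20, spacing=80, frag_sites=4):
    """A connected, conflict-free block: fragments copied from a random truth.

    Independent of the simulator: fragments are sliding windows of
    ``frag_sites`` consecutive sites, ``coverage`` of them per window start,
    each copied verbatim from one of the two true haplotypes.
    """
    positions = np.cumsum(rng.integers(1, 2 * spacing, size=n_sites))
    sites = make_sites(positions)
    truth = "".join(str(int(b)) for b in rng.integers(0, 2, size=n_sites))
    frags = []
    k = 0
    for start in range(0, n_sites - 1):
        width = min(frag_sites, n_sites - start)
        for _ in range(max(1, coverage // frag_sites)):
            hap = int(rng.integers(0, 2))
            alleles = {}
            for off in range(width):
                a = int(truth[start + off])
                alleles[start + off] = str(a if hap == 0 else 1 - a)
            frags.append(Fragment(name=f"r{k}", alleles=alleles))
            k += 1
    return VariantBlock(sites=sites, fragments=frags), truth


def same_phasing(hap1: str, truth: str) -> bool:
    comp = "".join("1" if c == "0" else "0" for c in truth)
    return hap1 == truth or hap1 == comp


# ---------------------------------------------------------------------------
# Independent oracles

def switch_flip_oracle(agreement):
    """Minimum-event switch/flip decomposition by dynamic programming.

    A switch toggles the template at a boundary (cost 1); a flip corrects a
    single site (cost 1).  Returns the minimum total number of events
    needed to explain the agreement sequence.  Independent of the
    closed-form run decomposition it checks.
    """
    m = len(agreement)
    if m == 0:
        return 0
    INF = float("inf")
    # dp[t] = min cost with current template parity t; free initial parity
    dp = [0 + (agreement[0] != 0), 0 + (agreement[0] != 1)]
    for k in range(1, m):
        ndp = [INF, INF]
        for t in (0, 1):
            for prev in (0, 1):
                cost = dp[prev] + (t != prev) + (agreement[k] != t)
                if cost < ndp[t]:
                    ndp[t] = cost
        dp = ndp
    return min(dp)


def two_candidate_mec_oracle(fragments, cand1, cand2):
    """Brute-force penalty comparison over exactly the two candidates."""

    def penalty(haps):
        total = 0
        for frag in fragments:
            m1 = m2 = 0
            hit = False
            for idx, sym in frag.alleles.items():
                if idx not in haps:
                    continue
                hit = True
                if int(sym) != haps[idx]:
                    m1 += 1
                else:
                    m2 += 1
            if hit:
                total += min(m1, m2)
        return total

    p1, p2 = penalty(dict(cand1.haps)), penalty(dict(cand2.haps))
    return (1 if p1 <= p2 else 2), (p1, p2)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
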