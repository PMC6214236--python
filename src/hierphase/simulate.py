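"""Synthetic diploid fragment simulator.

Emulates paired-end short-read sequencing over simulated variant blocks
directly at the fragment level: variant positions are placed uniformly over
a genomic span, a truth haplotype pair is drawn, and read pairs are sampled
with a normally distributed insert size, a haplotype of origin (optionally
skewed), and per-site sequencing errors.  Alignment is not simulated, so
the generated data carry sequencing error but no mapping error.

Default sequencing geometry: 2 x 250 bp reads, insert 850 +/- 50 bp.  The
study grids are coverages {20, 30, 40}, per-base error rates
{0.002, 0.01, 0.03}, block sizes {30, 50, 100, 200, 500} (10 blocks each),
and haplotype-sampling skews 50/50 down to 10/90.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

from .fragments import Fragment, VariantSite

__all__ = [
    "SimConfig",
    "SimulatedBlock",
    "simulate_truth",
    "simulate_fragments",
    "simulate_block",
    "simulate_dataset",
    "scenario_grid",
    "COVERAGE_GRID",
    "ERROR_GRID",
    "SKEW_GRID",
]

COVERAGE_GRID = (20, 30, 40)
ERROR_GRID = (0.002, 0.01, 0.03)
SKEW_GRID = (0.5, 0.4, 0.3, 0.2, 0.1)  # hap1 sampling probability; 0.5 = 50/50
BLOCK_SIZE_GRID = (30, 50, 100, 200, 500)


@dataclass(frozen=True)
class SimConfig:
    """Simulation condition.

    ``coverage`` is mean sequencing depth (bases per position);
    ``seq_error`` the per-site probability that a read's allele is
    corrupted; ``skew`` the probability a read pair originates from
    haplotype 1 (0.5 = balanced, 0.1 = 10/90).  ``region_span`` of None
    places ``mean_site_spacing`` bp per variant.
    """

    block_sizes: tuple[int, ...] = BLOCK_SIZE_GRID
    blocks_per_size: int = 10
    region_span: int | None = None
    mean_site_spacing: int = 80
    coverage: float = 30.0
    seq_error: float = 0.01
    skew: float = 0.5
    read_len: int = 250
    insert_mean: float = 850.0
    insert_sd: float = 50.0
    error_to_other: bool = False  # corrupt to '-' instead of the opposite allele
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.skew <= 0.5:
            raise ValueError("skew is the minor haplotype probability in (0, 0.5]")
        if not 0.0 <= self.seq_error <= 1.0:
            raise ValueError("seq_error must be a probability")

    def span_for(self, n_sites: int) -> int:
        if self.region_span is not None:
            return self.region_span
        return n_sites * self.mean_site_spacing


@dataclass
class SimulatedBlock:
    """One simulated variant block with its truth and fragments."""

    sites: list[VariantSite]
    truth_hap1: str
    fragments: list[Fragment]

    @property
    def site_indices(self) -> list[int]:
        return [s.site_index for s in self.sites]


def simulate_truth(
    n_sites: int, config: SimConfig, rng: np.random.Generator, chrom: str = "sim"
) -> tuple[list[VariantSite], str]:
    """Sample variant positions and a truth haplotype pair.

    Positions are drawn uniformly without replacement over the block span;
    hap1 alleles are uniform over {0, 1} and hap2 is the complement.
    """
    span = config.span_for(n_sites)
    if n_sites > span:
        raise ValueError(f"cannot place {n_sites} variants in a {span} bp span")
    positions = np.sort(rng.choice(span, size=n_sites, replace=False)) + 1
    sites = [
        VariantSite(chrom=chrom, pos=int(p), ref_allele="A", alt_allele="C", site_index=k)
        for k, p in enumerate(positions)
    ]
    hap1 = "".join(str(int(a)) for a in rng.integers(0, 2, size=n_sites))
    return sites, hap1


def simulate_fragments(
    sites: Sequence[VariantSite],
    truth_hap1: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[Fragment]:
    """Sample paired-end fragments over the block's variants.

    The number of read pairs is chosen so mean base depth matches
    ``config.coverage``.  Each pair originates from haplotype 1 with
    probability ``config.skew``; every covered site copies the origin
    allele and is corrupted with probability ``config.seq_error`` — by
    default flipped to the opposite allele (the worst case for phasing),
    or dropped to '-' when ``error_to_other`` is set.  Pairs covering
    fewer than two sites are discarded.
    """
    span = config.span_for(len(sites))
    positions = np.array([s.pos for s in sites])
    hap1 = np.array([int(c) for c in truth_hap1])
    n_pairs = max(1, int(round(config.coverage * span / (2.0 * config.read_len))))

    inserts = np.maximum(
        rng.normal(config.insert_mean, config.insert_sd, size=n_pairs),
        2.0 * config.read_len,
    ).astype(np.int64)
    starts = rng.integers(-config.read_len, span, size=n_pairs)
    origins = rng.random(n_pairs) < config.skew  # True -> haplotype 1

    fragments: list[Fragment] = []
    for k in range(n_pairs):
        s, ins = int(starts[k]), int(inserts[k])
        # two mate windows: [s, s+read_len) and [s+ins-read_len, s+ins)
        m1 = (positions >= s) & (positions < s + config.read_len)
        m2 = (positions >= s + ins - config.read_len) & (positions < s + ins)
        covered = np.flatnonzero(m1 | m2)
        if covered.size < 2:
            continue
        alleles_arr = hap1[covered] if origins[k] else 1 - hap1[covered]
        errs = rng.random(covered.size) < config.seq_error
        alleles: dict[int, str] = {}
        for idx, allele, err in zip(covered, alleles_arr, errs):
            if err and config.error_to_other:
                continue  # '-' entries are not stored
            a = 1 - allele if err else allele
            alleles[int(idx)] = str(int(a))
        if len(alleles) >= 2:
            fragments.append(Fragment(name=f"sim_{k}", alleles=alleles))
    return fragments


def simulate_block(
    n_sites: int,
    config: SimConfig,
    rng: np.random.Generator,
    chrom: str = "sim",
) -> SimulatedBlock:
    sites, hap1 = simulate_truth(n_sites, config, rng, chrom=chrom)
    frags = simulate_fragments(sites, hap1, config, rng)
    return SimulatedBlock(sites=sites, truth_hap1=hap1, fragments=frags)


def simulate_dataset(config: SimConfig) -> list[SimulatedBlock]:
    """All blocks of one simulation replicate, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    blocks = []
    for size in config.block_sizes:
        for b in range(config.blocks_per_size):
            blocks.append(simulate_block(size, config, rng, chrom=f"sim_{size}_{b}"))
    return blocks


def scenario_grid(
    base: SimConfig,
    coverages: Sequence[float] = COVERAGE_GRID,
    errors: Sequence[float] = ERROR_GRID,
    skews: Sequence[float] = (0.5,),
    replicates: int = 1,
    seed: int = 0,
) -> Iterator[tuple[SimConfig, list[SimulatedBlock]]]:
    """Iterate reproducible datasets over the condition grid.

    The full study grid (3 coverages x 3 error rates x 5 skews) yields 45
    conditions; the skewless grid yields 9.  Per-run seeds are derived from
    the master seed, so two calls with the same seed produce identical
    datasets.
    """
    ss = np.random.SeedSequence(seed)
    for coverage in coverages:
        for err in errors:
            for skew in skews:
                for rep in range(replicates):
                    (child,) = ss.spawn(1)
                    run_seed = int(child.generate_state(1)[0] % (2**31))
                    cfg = replace(
                        base,
                        coverage=coverage,
                        seq_error=err,
                        skew=skew,
                        seed=run_seed,
                    )
                    yield cfg, simulate_dataset(cfg)
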