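"""Adjusted multinomial confidence score (CS) for variant pairs.

A variant pair in a diploid sample should be covered by reads from exactly
two haplotypes in roughly equal proportion.  The confidence score measures
how well the observed 2x2 table of allele-combination read counts fits that
model: reads are assigned to the two expected haplotype cells of a candidate
solution (counts ``n1``, ``n2``) or to the unexpected cells (``n3``), and the
multinomial log-likelihood of that assignment, normalized for depth and
adjusted for local coverage, ranks pairs from most to least trustworthy.

Scores are log2-scaled and always non-positive; values closer to zero mean
higher confidence.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "ScoringParams",
    "PairObservation",
    "ScoreBreakdown",
    "PairClass",
    "multinomial_score",
    "normalizing_factor",
    "coverage_sigmoid",
    "confidence_score",
    "pair_cs",
    "classify_pair",
    "NEG_INF",
]

#: Sentinel for an impossible outcome (some P_i = 0 with n_i > 0).
NEG_INF = float("-inf")

LOG2E = math.log2(math.e)


@dataclass(frozen=True)
class ScoringParams:
    """Cell likelihoods of the multinomial model.

    ``p1``/``p2`` are the likelihoods of observing each of the two
    haplotypes; ``p3`` absorbs unexpected observations caused by sequencing
    or alignment error.  Defaults are p1 = p2 = 0.49, p3 = 0.02.
    """

    p1: float = 0.49
    p2: float = 0.49
    p3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p3 is None:
            object.__setattr__(self, "p3", 1.0 - self.p1 - self.p2)
        total = self.p1 + self.p2 + self.p3
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"cell likelihoods must sum to 1, got {total}")
        for p in (self.p1, self.p2, self.p3):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"likelihood {p} outside [0, 1]")


@dataclass(frozen=True)
class PairObservation:
    """Read counts of the four allele combinations at a variant pair.

    ``rc00`` counts fragments showing (0, 0) at the pair, and so on.
    """

    rc00: int
    rc01: int
    rc10: int
    rc11: int

    def __post_init__(self) -> None:
        if min(self.rc00, self.rc01, self.rc10, self.rc11) < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def n(self) -> int:
        return self.rc00 + self.rc01 + self.rc10 + self.rc11


@dataclass(frozen=True)
class ScoreBreakdown:
    """Every intermediate of a confidence-score evaluation."""

    n1: int
    n2: int
    n3: int
    ms: float  # multinomial log2 score
    f: float  # depth-normalizing factor
    ns: float  # ms - f
    c: float  # local / max coverage
    cs: float  # log2(sigmoid(c)) + ns

    @property
    def n(self) -> int:
        return self.n1 + self.n2 + self.n3


class PairClass(enum.Enum):
    """Reliability class of a variant pair.

    Singleton and low-coverage pairs are "ambiguous": their scores cannot be
    trusted to guide assembly, so they are deferred until no normal pair
    remains across any cluster boundary.
    """

    NORMAL = "normal"
    SINGLETON = "singleton"
    LOW_COVERAGE = "low_coverage"

    @property
    def ambiguous(self) -> bool:
        return self is not PairClass.NORMAL

    @property
    def rank(self) -> int:
        # assembly preference order: normal, then singleton, then low-coverage
        return {"normal": 0, "singleton": 1, "low_coverage": 2}[self.value]


def _log2_binom(n: float, k: float) -> float:
    """log2 C(n, k) via log-gamma; well-defined for non-integer arguments."""
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)) * LOG2E


def multinomial_score(n1: int, n2: int, n3: int, params: ScoringParams = ScoringParams()) -> float:
    """Multinomial log2 score of an (n1, n2, n3) outcome.

    MS = log2[ C(N, n1) C(N - n1, n2) p1^n1 p2^n2 p3^n3 ].  Returns ``-inf``
    when an outcome with zero likelihood was observed.
    """
    if min(n1, n2, n3) < 0:
        raise ValueError("counts must be non-negative")
    n = n1 + n2 + n3
    score = _log2_binom(n, n1) + _log2_binom(n - n1, n2)
    for ni, pi in ((n1, params.p1), (n2, params.p2), (n3, params.p3)):
        if ni > 0:
            if pi == 0.0:
                return NEG_INF
            score += ni * math.log2(pi)
    return score


def normalizing_factor(n: int | float, params: ScoringParams = ScoringParams()) -> float:
    """Depth-normalizing factor F at total read count ``n``.

    F = log2[ C(N, N/2)^2 p1^(N/2) p2^(N/2) ] — the score assigned to the
    ideal balanced outcome, evaluated continuously (log-gamma) so odd N is
    well-defined.  Subtracting F removes most of the dependence of MS on N.
    """
    if n < 0:
        raise ValueError("N must be non-negative")
    if n == 0:
        return 0.0
    half = n / 2.0
    f = 2.0 * _log2_binom(n, half)
    if params.p1 > 0.0:
        f += half * math.log2(params.p1)
    if params.p2 > 0.0:
        f += half * math.log2(params.p2)
    return f


def coverage_sigmoid(local_coverage: float, max_coverage: float) -> tuple[float, float]:
    """Coverage ratio ``c`` and its sigmoid weight ``s = 1/(1+e^-(c-0.5))``.

    Pairs observed at depths far below the block's maximum get down-weighted.
    """
    if max_coverage <= 0:
        raise ValueError("max_coverage must be positive (degenerate block)")
    if not 0 <= local_coverage <= max_coverage:
        raise ValueError("local coverage must lie in [0, max_coverage]")
    c = local_coverage / max_coverage
    s = 1.0 / (1.0 + math.exp(-(c - 0.5)))
    return c, s


class UnscorablePair(ValueError):
    """Raised when a pair has no informative reads (N = 0)."""


# the two preferred solutions under the heterozygous assumption
S1 = 1  # cis pairing: (0-0, 1-1)
S2 = 2  # trans pairing: (0-1, 1-0)


def confidence_score(
    obs: PairObservation,
    solution_id: int,
    max_coverage: float,
    params: ScoringParams = ScoringParams(),
) -> ScoreBreakdown:
    """Confidence score of one preferred solution for a variant pair.

    For the cis solution S1 the expected cells are (0,0) and (1,1); for the
    trans solution S2 they are (0,1) and (1,0); the remaining two cells are
    unexpected.  CS = log2(sigmoid(c)) + (MS - F).
    """
    if obs.n == 0:
        raise UnscorablePair("pair has no informative reads")
    if solution_id == S1:
        n1, n2, n3 = obs.rc00, obs.rc11, obs.rc01 + obs.rc10
    elif solution_id == S2:
        n1, n2, n3 = obs.rc01, obs.rc10, obs.rc00 + obs.rc11
    else:
        raise ValueError(f"solution_id must be {S1} or {S2}")
    ms = multinomial_score(n1, n2, n3, params)
    f = normalizing_factor(obs.n, params)
    ns = ms - f
    c, s = coverage_sigmoid(obs.n, max_coverage)
    cs = math.log2(s) + ns
    return ScoreBreakdown(n1=n1, n2=n2, n3=n3, ms=ms, f=f, ns=ns, c=c, cs=cs)


@dataclass(frozen=True)
class PairScore:
    """Both candidate scores for a pair plus the winning solution."""

    cs1: ScoreBreakdown
    cs2: ScoreBreakdown
    winner: int  # S1 or S2; S1 on exact tie
    tied: bool

    @property
    def cs(self) -> float:
        return max(self.cs1.cs, self.cs2.cs)


def pair_cs(
    obs: PairObservation,
    max_coverage: float,
    params: ScoringParams = ScoringParams(),
) -> PairScore:
    """Score both preferred solutions and pick the higher one.

    An exact tie keeps S1 but sets the ``tied`` flag so the caller can
    arbitrate (the assembler falls back to a local MEC vote).
    """
    b1 = confidence_score(obs, S1, max_coverage, params)
    b2 = confidence_score(obs, S2, max_coverage, params)
    tied = b1.cs == b2.cs
    winner = S1 if b1.cs >= b2.cs else S2
    return PairScore(cs1=b1, cs2=b2, winner=winner, tied=tied)


def classify_pair(obs: PairObservation, low_cov_threshold: float) -> PairClass:
    """Classify a pair as normal, singleton, or low-coverage.

    A singleton pair has all its reads in a single cell of the 2x2 table —
    only one haplotype was ever observed, so neither preferred solution can
    be ranked reliably.  Low-coverage pairs fall below the block's median
    pair depth.  Singleton takes precedence.
    """
    cells = (obs.rc00, obs.rc01, obs.rc10, obs.rc11)
    if sum(1 for c in cells if c > 0) == 1:
        return PairClass.SINGLETON
    if obs.n < low_cov_threshold:
        return PairClass.LOW_COVERAGE
    return PairClass.NORMAL
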