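"""Conserved non-coding sequence (CNS) detection by phylogenetic footprinting.

Non-coding columns of a multi-species alignment are scored under a
two-rate log-odds model: a neutral per-column mismatch probability
``p_neutral`` estimated from the alignment itself, against a constrained
(slowly evolving) probability ``p_constrained`` < ``p_neutral``.  Identical
columns score ``log[(1-p_c)/(1-p_n)] > 0``, mismatching columns score
``log[p_c/p_n] < 0``, so maximal-scoring segments (Ruzzo–Tompa
decomposition) are candidate constrained elements.  Segment scores are
converted to P-values with Karlin–Altschul extreme-value statistics
(``P = 1 - exp(-K m e^{-lambda*score})``), and a segment is called a CNS
when its conservation score ``-log10(P)`` exceeds ``-log10(0.05)``.

This is a deliberate simplification of tree-aware footprinting (no
phylogenetic weighting of the LOD scores); it keeps the statistical
skeleton — neutral-rate estimation, constrained-segment LOD,
Karlin–Altschul P, -log10 threshold — in a form that can be calibrated
and tested end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import AlignmentError, ConfigError, EstimationError

__all__ = [
    "AlignmentBlock",
    "ScoreScheme",
    "ConservedSegment",
    "estimate_neutral_rate",
    "build_scheme",
    "column_scores",
    "maximal_segments",
    "solve_lambda",
    "calibrate_karlin_altschul",
    "call_cns",
    "CNS_SCORE_THRESHOLD",
]

CNS_SCORE_THRESHOLD = -math.log10(0.05)  # conservation score must exceed this


@dataclass(frozen=True)
class AlignmentBlock:
    """>=2 aligned rows with an optional mask of excluded (coding) columns."""

    rows: tuple[str, ...]
    ids: tuple[str, ...] = ()
    mask: np.ndarray | None = None  # True = masked (excluded) column

    def __post_init__(self):
        if len(self.rows) < 2:
            raise AlignmentError("need at least two aligned rows")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise AlignmentError("aligned rows differ in length")
        if not self.ids:
            object.__setattr__(
                self, "ids", tuple(f"row{i}" for i in range(len(self.rows)))
            )
        m = self.mask
        if m is None:
            m = np.zeros(L, dtype=bool)
        else:
            m = np.asarray(m, dtype=bool)
            if m.shape != (L,):
                raise AlignmentError("mask length must equal alignment length")
        object.__setattr__(self, "mask", m)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def identity_columns(self) -> np.ndarray:
        """Boolean per column: all rows identical (case-insensitive)."""
        arr = np.array([np.frombuffer(r.upper().encode(), dtype=np.uint8)
                        for r in self.rows])
        return np.all(arr == arr[0], axis=0)

    def unmasked_index(self) -> np.ndarray:
        return np.flatnonzero(~self.mask)


@dataclass(frozen=True)
class ScoreScheme:
    """Two-rate column model with optional Karlin–Altschul calibration."""

    p_neutral: float
    p_constrained: float
    lam: float | None = None
    K: float | None = None

    def __post_init__(self):
        if not 0.0 < self.p_constrained < self.p_neutral < 1.0:
            raise ConfigError(
                "require 0 < p_constrained < p_neutral < 1 "
                f"(got {self.p_constrained}, {self.p_neutral})"
            )

    @property
    def s_match(self) -> float:
        return math.log((1.0 - self.p_constrained) / (1.0 - self.p_neutral))

    @property
    def s_mismatch(self) -> float:
        return math.log(self.p_constrained / self.p_neutral)

    @property
    def calibrated(self) -> bool:
        return self.lam is not None and self.K is not None


@dataclass(frozen=True)
class ConservedSegment:
    """Maximal-scoring segment in original alignment-column coordinates."""

    start: int
    end: int
    score: float
    p_value: float
    conservation_score: float
    is_cns: bool


# ---------------------------------------------------------------------------
# Neutral rate and column scores
# ---------------------------------------------------------------------------

def estimate_neutral_rate(block: AlignmentBlock, min_columns: int = 100) -> float:
    """Fraction of unmasked columns that are not identical across rows,
    clipped to [0.01, 0.99]."""
    idx = block.unmasked_index()
    if idx.size < min_columns:
        raise EstimationError(
            f"need >= {min_columns} unmasked columns to estimate the "
            f"neutral rate (have {idx.size})"
        )
    ident = block.identity_columns()[idx]
    return float(np.clip(1.0 - ident.mean(), 0.01, 0.99))


def build_scheme(block: AlignmentBlock, p_constrained: float | None = None,
                 constrained_fraction: float = 0.2) -> ScoreScheme:
    """Estimate the neutral rate and pick the constrained rate.

    By default the constrained mismatch probability is a fifth of the
    neutral one (``constrained_fraction = 0.2``); pass ``p_constrained``
    to override.
    """
    p_n = estimate_neutral_rate(block)
    if p_constrained is None:
        p_constrained = constrained_fraction * p_n
    return ScoreScheme(p_neutral=p_n, p_constrained=p_constrained)


def column_scores(block: AlignmentBlock, scheme: ScoreScheme) -> np.ndarray:
    """Log-odds score per unmasked column (match vs mismatch)."""
    idx = block.unmasked_index()
    ident = block.identity_columns()[idx]
    return np.where(ident, scheme.s_match, scheme.s_mismatch)


# ---------------------------------------------------------------------------
# Ruzzo–Tompa maximal-scoring subsequences
# ---------------------------------------------------------------------------

def maximal_segments(scores) -> list[tuple[int, int, float]]:
    """All disjoint maximal-scoring subsequences with positive score.

    Linear-time Ruzzo–Tompa decomposition; returns (start, end, score)
    triples, 0-based half-open, in coordinate order.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ConfigError("scores must be finite")
    # stack entries: [start, end, L, R] with L/R cumulative-score bounds
    stack: list[list[float]] = []
    cum = 0.0
    for i, x in enumerate(scores):
        left = cum
        cum += x
        if x <= 0:
            continue
        entry = [i, i + 1, left, cum]
        while True:
            # rightmost j with L_j < entry.L
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= entry[2]:
                j -= 1
            if j < 0 or stack[j][3] >= entry[3]:
                # no dominated predecessor: entry is a new candidate
                stack.append(entry)
                break
            # stack[j] is dominated: extend entry left over it and retry
            entry = [stack[j][0], entry[1], stack[j][2], entry[3]]
            del stack[j:]
    return [(int(s), int(e), float(r - l)) for s, e, l, r in stack]


def _brute_maximal_segments(scores) -> list[tuple[int, int, float]]:
    """Exhaustive reference implementation of the maximal-subsequence
    definition (quadratic; for cross-checks on short vectors only).

    A subsequence is maximal when every proper contained prefix/suffix has
    lower score than it does, and it is not contained in any longer such
    subsequence with that property.  Implemented by recursive splitting on
    the best-scoring subsequence; exact score ties take the minimal segment
    (latest start, earliest end), matching the zero-extension convention of
    the linear-time decomposition.
    """
    scores = np.asarray(scores, dtype=float)

    def best(lo, hi):
        b = None
        for i in range(lo, hi):
            tot = 0.0
            for j in range(i, hi):
                tot += scores[j]
                if tot <= 0:
                    continue
                if (
                    b is None
                    or tot > b[2] + 1e-12
                    or (
                        abs(tot - b[2]) <= 1e-12
                        and (i > b[0] or (i == b[0] and j + 1 < b[1]))
                    )
                ):
                    b = (i, j + 1, tot)
        return b

    out = []

    def rec(lo, hi):
        b = best(lo, hi)
        if b is None:
            return
        rec(lo, b[0])
        out.append((b[0], b[1], float(b[2])))
        rec(b[1], hi)

    rec(0, len(scores))
    return out


# ---------------------------------------------------------------------------
# Karlin–Altschul calibration and CNS calls
# ---------------------------------------------------------------------------

def solve_lambda(scores, probs, tol: float = 1e-12) -> float:
    """Unique positive root of E[e^{lambda * score}] = 1 for a discrete
    score distribution (Karlin–Altschul lambda; bisection to |f| < tol).

    Requires a negative mean score with some positive outcome; for the
    classic two-outcome case +s (prob p) / -s (prob 1-p) the root is
    ``log((1-p)/p)/s``.  Note the log-odds scores of a two-rate scheme
    always give lambda = 1 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    probs = np.asarray(probs, dtype=float)
    if scores @ probs >= 0 or scores.max() <= 0:
        raise EstimationError(
            "Karlin-Altschul regime requires a negative expected score and "
            "a positive top score"
        )

    def f(lam):
        return float(probs @ np.exp(lam * scores)) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise EstimationError("failed to bracket lambda")
    lam = brentq(f, 1e-12, hi, xtol=tol)
    if abs(f(lam)) > 1e-9:
        raise EstimationError("lambda root did not converge")
    return float(lam)


def _solve_lambda(scheme: ScoreScheme, tol: float = 1e-12) -> float:
    return solve_lambda(
        [scheme.s_match, scheme.s_mismatch],
        [1.0 - scheme.p_neutral, scheme.p_neutral],
        tol,
    )


def _null_max_scores(scheme: ScoreScheme, m: int, reps: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Maximal segment score of `reps` neutral blocks of m columns
    (vectorized Kadane over the block axis)."""
    sm, sx = scheme.s_match, scheme.s_mismatch
    best = np.zeros(reps)
    run = np.zeros(reps)
    for _ in range(m):
        x = np.where(rng.random(reps) < scheme.p_neutral, sx, sm)
        run = np.maximum(run + x, 0.0)
        np.maximum(best, run, out=best)
    return best


def calibrate_karlin_altschul(scheme: ScoreScheme, m: int = 500,
                              reps: int = 10000, seed: int = 0,
                              K: float | None = None) -> ScoreScheme:
    """Attach (lambda, K) to a scheme.

    lambda solves the classic transcendental equation for the neutral
    column-score distribution (bisection to |f| < 1e-12).  K is estimated
    by simulating `reps` null blocks of `m` columns and anchoring the
    extreme-value tail ``P(M > s) = 1 - exp(-K m e^{-lambda s})`` at the
    empirical upper-5% point of the simulated maxima; pass ``K`` to skip
    the simulation.
    """
    lam = _solve_lambda(scheme)
    if K is None:
        rng = np.random.default_rng(seed)
        maxima = _null_max_scores(scheme, m, reps, rng)
        q95 = float(np.quantile(maxima, 0.95))
        if q95 <= 0:
            q95 = float(np.max(maxima))
        if q95 <= 0:
            raise EstimationError("null maxima are all zero; cannot set K")
        K = -math.log(0.95) * math.exp(lam * q95) / m
    return replace(scheme, lam=lam, K=float(K))


def segment_p_value(score: float, scheme: ScoreScheme, m: int) -> float:
    """P-value of a maximal segment score in a block of m unmasked columns."""
    if not scheme.calibrated:
        raise EstimationError("scheme lacks Karlin-Altschul calibration")
    return float(-math.expm1(-scheme.K * m * math.exp(-scheme.lam * score)))


def call_cns(block: AlignmentBlock, scheme: ScoreScheme,
             alpha: float = 0.05) -> list[ConservedSegment]:
    """Maximal-scoring segments with Karlin–Altschul P-values and CNS flags.

    Coordinates are original alignment columns (masked columns are skipped
    when scoring, so calls are invariant to inserting masked columns).
    A segment is a CNS when conservation score > -log10(alpha), strictly.
    """
    if not scheme.calibrated:
        raise EstimationError("calibrate the scheme before calling CNSs")
    idx = block.unmasked_index()
    scores = column_scores(block, scheme)
    m = int(idx.size)
    thr = -math.log10(alpha)
    out = []
    for s, e, sc in maximal_segments(scores):
        p = segment_p_value(sc, scheme, m)
        cs = -math.log10(p) if p > 0 else math.inf
        out.append(
            ConservedSegment(
                start=int(idx[s]),
                end=int(idx[e - 1]) + 1,
                score=sc,
                p_value=p,
                conservation_score=cs,
                is_cns=cs > thr,
            )
        )
    return out
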