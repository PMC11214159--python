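"""Polarized site-frequency-spectrum estimators and sweep statistics.

Sweep footprints distort the derived-allele frequency spectrum of a sample
of haplotypes: an excess of high-frequency derived alleles (hitch-hiking)
and of rare alleles (post-sweep recovery).  Three standardized contrasts of
SFS-weighted theta estimators pick these distortions up:

* Tajima's D   = (theta_pi - theta_W) / sd  — low with excess rare alleles,
* Fay & Wu's H = (theta_pi - theta_L) / sd  — low with excess high-frequency
  derived alleles (standardized form of Zeng et al. 2006),
* Zeng's E     = (theta_L - theta_W) / sd   — high with excess high-frequency
  derived alleles.

Polarization against an outgroup/ancestral sequence assigns each segregating
site its derived-allele count i (1..n-1); the per-window spectrum S_i feeds
all estimators.  Statistics are computed over sliding windows along a locus
and the extreme windows (max E, min H, min D) are the sweep candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigError, EstimationError, InputError

__all__ = [
    "HaplotypeWindow",
    "DerivedSFS",
    "ThetaSet",
    "WindowStats",
    "harmonic_numbers",
    "polarize",
    "theta_estimators",
    "tajimas_d",
    "fay_wu_h_std",
    "zengs_e",
    "stats_from_sfs",
    "sliding_scan",
    "find_peaks",
]

_VALID = frozenset(b"ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeWindow:
    """Aligned haploid sample sequences plus one ancestral sequence.

    Coordinates are 0-based half-open locus positions; ``end - start`` must
    equal the alignment length.
    """

    sequences: tuple[str, ...]
    ancestral: str
    start: int = 0
    end: int = 0

    def __post_init__(self):
        if len(self.sequences) < 2:
            raise InputError("need at least 2 sample haplotypes")
        L = len(self.ancestral)
        if any(len(s) != L for s in self.sequences):
            raise AlignmentError("sample/ancestral sequence lengths differ")
        if self.end == 0 and self.start == 0:
            object.__setattr__(self, "end", L)
        if self.end - self.start != L:
            raise AlignmentError(
                f"coordinates span {self.end - self.start} bp but alignment "
                f"is {L} bp"
            )

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.ancestral)

    def slice(self, start: int, end: int) -> "HaplotypeWindow":
        """Sub-window in locus coordinates (0-based half-open)."""
        a, b = start - self.start, end - self.start
        return HaplotypeWindow(
            tuple(s[a:b] for s in self.sequences),
            self.ancestral[a:b],
            start,
            end,
        )


@dataclass(frozen=True)
class DerivedSFS:
    """Unfolded site frequency spectrum: counts[i-1] = S_i for i in 1..n-1."""

    n: int
    counts: tuple[int, ...]

    def __post_init__(self):
        if self.n < 2:
            raise InputError("sample size must be >= 2")
        if len(self.counts) != self.n - 1:
            raise InputError("SFS must have n-1 frequency classes")
        if any(c < 0 for c in self.counts):
            raise InputError("negative SFS count")

    @property
    def S(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_counts(cls, n: int, counts: Sequence[int]) -> "DerivedSFS":
        return cls(n, tuple(int(c) for c in counts))


@dataclass(frozen=True)
class ThetaSet:
    """The four SFS-weighted theta estimators plus harmonic constants."""

    theta_pi: float
    theta_w: float
    theta_l: float
    theta_h: float
    a_n: float
    b_n: float


@dataclass(frozen=True)
class WindowStats:
    """Per-window sweep statistics; NaN marks an undefined statistic (S=0)."""

    start: int
    end: int
    D: float
    H: float
    E: float
    S: int

    @property
    def defined(self) -> bool:
        return self.S >= 1 and math.isfinite(self.D)


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def _encode(seqs: Sequence[str]) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).upper().encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    code = np.full(arr.shape, 4, dtype=np.int8)
    for k, b in enumerate(b"ACGT"):
        code[arr == b] = k
    return code


def polarize(window: HaplotypeWindow) -> DerivedSFS:
    """Derived-allele SFS of a window, polarized against the ancestral row.

    Site filters (infinite-sites framing): columns with any gap or N in the
    samples or the ancestral row are excluded listwise; columns with more
    than two sample alleles are excluded; columns whose sample alleles do
    not include the ancestral base while being polymorphic are unpolarizable
    and excluded; monomorphic columns and fixed-derived columns (derived
    count 0 or n) do not segregate and contribute nothing.
    """
    n = window.n
    samp = _encode(window.sequences)
    anc = _encode([window.ancestral])[0]

    valid = (anc < 4) & np.all(samp < 4, axis=0)
    # per-column counts of each base among samples
    base_counts = np.stack([(samp == k).sum(axis=0) for k in range(4)])
    n_alleles = (base_counts > 0).sum(axis=0)
    anc_count = base_counts[np.clip(anc, 0, 3), np.arange(samp.shape[1])]
    derived = n - anc_count
    polarizable = valid & (n_alleles == 2) & (anc_count > 0)
    seg = polarizable & (derived > 0) & (derived < n)

    counts = np.bincount(derived[seg], minlength=n)[1:n]
    return DerivedSFS.from_counts(n, counts)


# ---------------------------------------------------------------------------
# Theta estimators
# ---------------------------------------------------------------------------

def harmonic_numbers(n: int) -> tuple[float, float]:
    """a_n = sum_{i=1}^{n-1} 1/i and b_n = sum_{i=1}^{n-1} 1/i**2."""
    i = np.arange(1, n, dtype=float)
    return float(np.sum(1.0 / i)), float(np.sum(1.0 / i**2))


def theta_estimators(sfs: DerivedSFS) -> ThetaSet:
    """Watterson, pairwise, high-frequency (theta_H) and linear (theta_L)
    estimators from the unfolded spectrum.

    theta_pi = sum 2 i (n-i) S_i / (n(n-1));  theta_W = S / a_n;
    theta_L  = sum i S_i / (n-1);             theta_H = sum 2 i^2 S_i / (n(n-1)).
    The algebraic identity theta_pi + theta_H = 2 theta_L holds exactly.
    """
    n = sfs.n
    a_n, b_n = harmonic_numbers(n)
    i = np.arange(1, n, dtype=float)
    s = np.asarray(sfs.counts, dtype=float)
    theta_pi = float(np.sum(2.0 * i * (n - i) * s) / (n * (n - 1)))
    theta_w = float(sfs.S / a_n)
    theta_l = float(np.sum(i * s) / (n - 1))
    theta_h = float(np.sum(2.0 * i**2 * s) / (n * (n - 1)))
    return ThetaSet(theta_pi, theta_w, theta_l, theta_h, a_n, b_n)


# ---------------------------------------------------------------------------
# Standardized statistics
# ---------------------------------------------------------------------------

def tajimas_d(sfs: DerivedSFS) -> float:
    """Tajima's D; NaN when no site segregates (undefined, never 0)."""
    S = sfs.S
    if S < 1:
        return math.nan
    n = sfs.n
    t = theta_estimators(sfs)
    a1, a2 = t.a_n, t.b_n
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    num = t.theta_pi - t.theta_w
    if var <= 0:
        return 0.0 if num == 0 else math.nan  # n=2: numerator and variance both vanish
    return num / math.sqrt(var)


def _theta_moments(sfs: DerivedSFS) -> tuple[float, float, float, float]:
    """(theta_hat, theta_sq_hat, a_n, b_n) with Watterson-based moments
    theta = S/a_n and theta^2 = S(S-1)/(a_n^2 + b_n)."""
    a_n, b_n = harmonic_numbers(sfs.n)
    S = sfs.S
    return S / a_n, S * (S - 1) / (a_n**2 + b_n), a_n, b_n


def fay_wu_h_std(sfs: DerivedSFS) -> float:
    """Standardized Fay & Wu's H = (theta_pi - theta_L)/sd (Zeng et al. form).

    Low values signal an excess of high-frequency derived alleles, the
    hallmark of hitch-hiking around a recently fixed beneficial mutation.
    """
    S = sfs.S
    if S < 1:
        return math.nan
    n = sfs.n
    t = theta_estimators(sfs)
    th, th2, a_n, b_n = _theta_moments(sfs)
    bn1 = b_n + 1.0 / n**2  # sum_{i=1}^{n} 1/i^2
    var = (n - 2) / (6.0 * (n - 1)) * th + (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2) * th2
    num = t.theta_pi - t.theta_l
    if var <= 0:
        return 0.0 if num == 0 else math.nan
    return num / math.sqrt(var)


def zengs_e(sfs: DerivedSFS) -> float:
    """Zeng's E = (theta_L - theta_W)/sd; high with excess high-frequency
    derived alleles."""
    S = sfs.S
    if S < 1:
        return math.nan
    n = sfs.n
    t = theta_estimators(sfs)
    th, th2, a_n, b_n = _theta_moments(sfs)
    var = (n / (2.0 * (n - 1.0)) - 1.0 / a_n) * th + (
        b_n / a_n**2
        + 2.0 * (n / (n - 1.0)) ** 2 * b_n
        - 2.0 * (n * b_n - n + 1.0) / ((n - 1.0) * a_n)
        - (3.0 * n + 1.0) / (n - 1.0)
    ) * th2
    num = t.theta_l - t.theta_w
    if var <= 0:
        return 0.0 if num == 0 else math.nan
    return num / math.sqrt(var)


def stats_from_sfs(sfs: DerivedSFS, start: int = 0, end: int = 0) -> WindowStats:
    """Bundle D/H/E for one window; undefined statistics become NaN."""
    return WindowStats(
        start=start,
        end=end,
        D=tajimas_d(sfs),
        H=fay_wu_h_std(sfs),
        E=zengs_e(sfs),
        S=sfs.S,
    )


# ---------------------------------------------------------------------------
# Sliding windows and peaks
# ---------------------------------------------------------------------------

def sliding_scan(
    locus: HaplotypeWindow, window_bp: int = 2000, step_bp: int = 100
) -> list[WindowStats]:
    """Sweep statistics in sliding windows along an aligned locus.

    Windows start at ``locus.start`` and advance by ``step_bp``; only full
    windows (``start + window_bp <= locus.end``) are evaluated.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ConfigError("window and step must be positive")
    if window_bp > locus.length:
        raise ConfigError(
            f"window ({window_bp} bp) exceeds locus length ({locus.length} bp)"
        )
    out = []
    for start in range(locus.start, locus.end - window_bp + 1, step_bp):
        sub = locus.slice(start, start + window_bp)
        out.append(stats_from_sfs(polarize(sub), start, start + window_bp))
    return out


def find_peaks(track: Sequence[WindowStats]) -> dict[str, WindowStats]:
    """Candidate sweep windows: highest E, lowest H, lowest D.

    Ties are broken toward the smallest start coordinate; windows with
    undefined statistics are ignored.
    """
    defined = [w for w in track if w.defined]
    if not defined:
        raise EstimationError("no window has defined statistics (all S = 0)")
    e_peak = max(defined, key=lambda w: (w.E, -w.start))
    h_peak = min(defined, key=lambda w: (w.H, w.start))
    d_peak = min(defined, key=lambda w: (w.D, w.start))
    return {"E_peak": e_peak, "H_peak": h_peak, "D_peak": d_peak}
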