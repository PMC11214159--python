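"""Single-QTL genome scan for a backcross with a covariate trait.

A BC1 cross segregates 1:1 between recurrent-parent homozygotes ("b") and
heterozygotes ("h").  Markers violating 1:1 segregation are filtered by a
1-df chi-square test.  The scan regresses a log-scale trait on the
probability of being heterozygous at each grid position (Haley–Knott
regression on genotype probabilities), optionally with a second,
correlated trait as covariate:

    LOD(x) = (n/2) * log10( RSS[trait ~ covariate]
                            / RSS[trait ~ covariate + P(h at x)] )

Genotype probabilities condition on the nearest flanking non-missing
markers with recombination fractions from the inverse Kosambi (or
Haldane) map function and Markov-chain combination across the interval.
Genome-wide significance comes from permuting the (trait, covariate)
rows jointly against the genotypes; QTL location uncertainty from a
Bayesian credible interval over the normalized 10^LOD profile; and the
variance explained from 1 - 10^(-2*LOD/n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DegenerateModelError, EstimationError, InputError

__all__ = [
    "CrossData",
    "LodCurve",
    "filter_markers",
    "kosambi_r",
    "kosambi_d",
    "haldane_r",
    "genotype_probabilities",
    "scan_lod",
    "permutation_threshold",
    "bayes_interval",
    "variance_explained",
    "map_density",
]

_GENO_CODES = {"b": 0.0, "h": 1.0, "-": np.nan, "": np.nan}


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class CrossData:
    """BC1 genotypes, marker map and phenotype table.

    genotypes: individuals x markers, float codes 0.0 ("b", recurrent
    homozygote), 1.0 ("h", heterozygote), NaN (missing).
    map: indexed by marker with columns ``lg`` and ``cM``, positions
    non-decreasing within each linkage group.
    phenotypes: individuals x named (log-scale) traits.
    """

    genotypes: pd.DataFrame
    map: pd.DataFrame
    phenotypes: pd.DataFrame

    def __post_init__(self):
        if self.genotypes.dtypes.eq(object).any():
            self.genotypes = self.genotypes.apply(
                lambda c: c.map(lambda v: _GENO_CODES.get(str(v).strip(), np.nan)
                                if isinstance(v, str) else float(v))
            )
        if list(self.genotypes.columns) != list(self.map.index):
            missing = set(self.genotypes.columns) ^ set(self.map.index)
            if missing:
                raise InputError(f"genotype/map marker mismatch: {sorted(missing)[:5]}")
            self.genotypes = self.genotypes[self.map.index]
        for lg, sub in self.map.groupby("lg", sort=False):
            if not sub["cM"].is_monotonic_increasing:
                raise InputError(f"marker positions decrease within LG {lg}")
        if not self.genotypes.index.equals(self.phenotypes.index):
            raise InputError("genotype and phenotype tables index different individuals")

    @property
    def n_individuals(self) -> int:
        return len(self.genotypes)

    @property
    def linkage_groups(self) -> list:
        return list(dict.fromkeys(self.map["lg"]))


@dataclass(frozen=True)
class LodCurve:
    """LOD profile on a grid of (linkage group, cM) positions."""

    lg: np.ndarray
    cM: np.ndarray
    lod: np.ndarray
    covariate_used: str | None = None

    def max(self) -> tuple[float, object, float]:
        """(max LOD, lg, cM) with ties broken to the first grid position."""
        i = int(np.argmax(self.lod))
        return float(self.lod[i]), self.lg[i], float(self.cM[i])

    def restrict(self, lg) -> "LodCurve":
        sel = self.lg == lg
        if not sel.any():
            raise InputError(f"no grid positions on linkage group {lg!r}")
        return LodCurve(self.lg[sel], self.cM[sel], self.lod[sel],
                        self.covariate_used)


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

def filter_markers(cross: CrossData, alpha: float = 0.05) -> CrossData:
    """Drop markers deviating from 1:1 segregation (chi-square, 1 df).

    Missing genotypes are excluded from the counts; a marker is retained
    when its P-value is >= alpha.
    """
    G = cross.genotypes
    nh = (G == 1.0).sum(axis=0).to_numpy(float)
    nb = (G == 0.0).sum(axis=0).to_numpy(float)
    tot = nh + nb
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(tot > 0, (nb - nh) ** 2 / np.where(tot > 0, tot, 1), np.inf)
    p = sps.chi2.sf(chi2, df=1)
    keep = p >= alpha
    if not keep.any():
        raise InputError("all markers removed by the segregation filter")
    markers = G.columns[keep]
    return CrossData(
        genotypes=G[markers].copy(),
        map=cross.map.loc[markers].copy(),
        phenotypes=cross.phenotypes,
    )


# ---------------------------------------------------------------------------
# Map functions and genotype probabilities
# ---------------------------------------------------------------------------

def kosambi_r(d_cM):
    """Recombination fraction from Kosambi map distance (cM)."""
    return 0.5 * np.tanh(2.0 * np.asarray(d_cM, dtype=float) / 100.0)


def kosambi_d(r):
    """Kosambi map distance (cM) from recombination fraction."""
    return 50.0 * np.arctanh(2.0 * np.asarray(r, dtype=float))


def haldane_r(d_cM):
    """Recombination fraction from Haldane map distance (cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


_MAPF = {"kosambi": kosambi_r, "haldane": haldane_r}


def _trans(g, h_state, r):
    """Markov transition probability between BC1 genotype states.

    g, h_state in {0, 1}; r = recombination fraction over the interval.
    """
    same = g == h_state
    return np.where(same, 1.0 - r, r)


def build_grid(cross_map: pd.DataFrame, grid_step: float = 1.0
               ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation grid: every `grid_step` cM within each LG plus each
    terminal marker position."""
    if grid_step <= 0:
        raise ConfigError("grid step must be positive")
    lgs, pos = [], []
    for lg, sub in cross_map.groupby("lg", sort=False):
        lo, hi = float(sub["cM"].iloc[0]), float(sub["cM"].iloc[-1])
        g = np.arange(lo, hi, grid_step)
        g = np.append(g, hi)
        lgs.append(np.full(g.size, lg, dtype=object))
        pos.append(g)
    return np.concatenate(lgs), np.concatenate(pos)


def genotype_probabilities(cross: CrossData, grid_step: float = 1.0,
                           map_function: str = "kosambi"
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(heterozygous) at grid positions given flanking non-missing markers.

    Returns (lg, cM, P) with P of shape (individuals, grid positions).
    Conditioning uses the nearest non-missing marker on each side and a
    two-state Markov chain with interval recombination fractions from the
    chosen map function; at a typed marker the probability is the 0/1
    genotype indicator.  Individuals untyped over a whole LG get 0.5.
    """
    rfun = _MAPF.get(map_function)
    if rfun is None:
        raise ConfigError(f"unknown map function {map_function!r}")
    glg, gpos = build_grid(cross.map, grid_step)
    n = cross.n_individuals
    P = np.full((n, gpos.size), 0.5)
    G = cross.genotypes.to_numpy(float)
    for lg in cross.linkage_groups:
        msel = (cross.map["lg"] == lg).to_numpy()
        mpos = cross.map["cM"].to_numpy(float)[msel]
        gsel = np.flatnonzero(glg == lg)
        x = gpos[gsel]
        Glg = G[:, msel]
        for i in range(n):
            typed = np.flatnonzero(~np.isnan(Glg[i]))
            if typed.size == 0:
                continue
            tp = mpos[typed]
            tg = Glg[i, typed]
            ridx = np.searchsorted(tp, x, side="left")
            has_l = ridx > 0
            has_r = ridx < tp.size
            li = np.clip(ridx - 1, 0, tp.size - 1)
            ri = np.clip(ridx, 0, tp.size - 1)
            dl = x - tp[li]
            dr = tp[ri] - x
            rl = rfun(np.abs(dl))
            rr = rfun(np.abs(dr))
            gl = tg[li]
            gr = tg[ri]
            # both flanks
            num = _trans(gl, 1, rl) * _trans(1, gr, rr)
            r_ab = rl * (1 - rr) + rr * (1 - rl)
            den = _trans(gl, gr, r_ab)
            both = num / np.where(den > 0, den, 1.0)
            left_only = gl * (1 - rl) + (1 - gl) * rl
            right_only = gr * (1 - rr) + (1 - gr) * rr
            p = np.where(has_l & has_r, both,
                         np.where(has_l, left_only,
                                  np.where(has_r, right_only, 0.5)))
            P[i, gsel] = p
    return glg, gpos, P


# ---------------------------------------------------------------------------
# Haley-Knott scan
# ---------------------------------------------------------------------------

def _design(cross: CrossData, trait: str, covariate: str | None
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rows, y, Q) with Q an orthonormal basis of the null design."""
    ph = cross.phenotypes
    cols = [trait] + ([covariate] if covariate else [])
    for c in cols:
        if c not in ph.columns:
            raise InputError(f"phenotype {c!r} not found")
    sub = ph[cols].dropna()
    rows = cross.phenotypes.index.get_indexer(sub.index)
    y = sub[trait].to_numpy(float)
    X0 = np.ones((len(sub), 1))
    if covariate:
        X0 = np.column_stack([X0, sub[covariate].to_numpy(float)])
    Q, R = np.linalg.qr(X0)
    if np.abs(np.diag(R)).min() < 1e-10 * max(1.0, np.abs(R).max()):
        raise DegenerateModelError("covariate is collinear with the intercept")
    return rows, y, Q

_DEN_TOL = 1e-12


def _lod_from_parts(rss0, num, den, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(den > _DEN_TOL, num**2 / np.where(den > _DEN_TOL, den, 1.0), 0.0)
    rss1 = np.maximum(rss0 - gain, np.finfo(float).tiny)
    return (n / 2.0) * np.log10(rss0 / rss1)


def scan_lod(cross: CrossData, trait: str, covariate: str | None = None,
             grid_step: float = 1.0, map_function: str = "kosambi",
             genoprob: tuple | None = None) -> LodCurve:
    """LOD profile of `trait` (with optional covariate) across the genome.

    ``genoprob`` may carry a precomputed ``genotype_probabilities`` result
    to reuse across traits and permutations.
    """
    glg, gpos, P = genoprob if genoprob is not None else genotype_probabilities(
        cross, grid_step, map_function)
    rows, y, Q = _design(cross, trait, covariate)
    Pm = P[rows]
    n = y.size
    e_y = y - Q @ (Q.T @ y)
    rss0 = float(e_y @ e_y)
    if rss0 <= _DEN_TOL * max(1.0, float(y @ y)):
        raise DegenerateModelError(
            "null model leaves no residual variance (trait duplicates the "
            "covariate?)"
        )
    B = Q.T @ Pm
    num = e_y @ Pm
    den = (Pm * Pm).sum(axis=0) - (B * B).sum(axis=0)
    lod = _lod_from_parts(rss0, num, den, n)
    return LodCurve(glg, gpos, np.maximum(lod, 0.0), covariate)


def permutation_threshold(cross: CrossData, trait: str,
                          covariate: str | None = None,
                          n_perm: int = 10000, alpha: float = 0.05,
                          seed: int = 0, grid_step: float = 1.0,
                          map_function: str = "kosambi",
                          genoprob: tuple | None = None,
                          chunk: int = 512) -> float:
    """Genome-wide LOD threshold from joint (trait, covariate) permutations.

    Rows of the phenotype pair are permuted together against the genotype
    rows (preserving the trait-covariate correlation); the threshold is
    the (1 - alpha) quantile of the permuted genome-wide maximum LOD.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    glg, gpos, P = genoprob if genoprob is not None else genotype_probabilities(
        cross, grid_step, map_function)
    rows, y, Q = _design(cross, trait, covariate)
    Pm = P[rows]
    n = y.size
    e_y = y - Q @ (Q.T @ y)
    rss0 = float(e_y @ e_y)
    if rss0 <= _DEN_TOL * max(1.0, float(y @ y)):
        raise DegenerateModelError("null model leaves no residual variance")
    colP2 = (Pm * Pm).sum(axis=0)
    b1 = Q[:, 0] @ Pm  # constant column: permutation-invariant
    q2 = Q[:, 1] if Q.shape[1] > 1 else None
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.argsort(rng.random((m, n)), axis=1)
        E = e_y[perms]
        num = E @ Pm
        den = colP2 - b1**2
        if q2 is not None:
            B2 = q2[perms] @ Pm
            den = den - B2**2
        lod = _lod_from_parts(rss0, num, den, n)
        maxima[done:done + m] = lod.max(axis=1)
        done += m
    return float(np.quantile(maxima, 1.0 - alpha))


# ---------------------------------------------------------------------------
# Credible interval and effect size
# ---------------------------------------------------------------------------

def bayes_interval(curve: LodCurve, prob: float = 0.95
                   ) -> tuple[object, float, float]:
    """Bayesian credible interval for QTL location on one linkage group.

    10^LOD is normalized to a density over the grid; the smallest
    contiguous run of grid cells containing the peak whose mass reaches
    `prob` gives (lg, start cM, end cM).
    """
    lgs = set(curve.lg.tolist())
    if len(lgs) != 1:
        raise InputError("bayes_interval needs a single-linkage-group curve; "
                         "use curve.restrict(lg)")
    if not 0 < prob <= 1:
        raise ConfigError("prob must be in (0, 1]")
    lod = curve.lod
    if np.max(lod) <= 0:
        raise EstimationError("flat zero LOD curve: interval undefined")
    w = np.power(10.0, lod - np.max(lod))
    w = w / w.sum()
    peak = int(np.argmax(lod))
    i = j = peak
    mass = w[peak]
    while mass < prob and (i > 0 or j < w.size - 1):
        left = w[i - 1] if i > 0 else -1.0
        right = w[j + 1] if j < w.size - 1 else -1.0
        if left >= right:
            i -= 1
            mass += left
        else:
            j += 1
            mass += right
    return curve.lg[peak], float(curve.cM[i]), float(curve.cM[j])


def variance_explained(lod_at_peak: float, n: int) -> float:
    """Proportion of phenotypic variance explained: 1 - 10^(-2*LOD/n)."""
    if n < 2:
        raise ConfigError("need n >= 2")
    if lod_at_peak < 0:
        raise ConfigError("LOD must be non-negative")
    return 1.0 - 10.0 ** (-2.0 * lod_at_peak / n)


def map_density(n_markers: int, length_cM: float) -> float:
    """Markers per cM of the genetic map."""
    if n_markers < 1 or length_cM <= 0:
        raise ConfigError("need positive marker count and map length")
    return n_markers / length_cM
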