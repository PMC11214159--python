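"""Neutral coalescent null model with recombination for sweep statistics.

Simulates samples of n haplotypes over a window of L sites under the
standard neutral coalescent with crossover recombination (exact
ancestral-recombination-graph construction, no sequential-Markov
approximation — the locus is small).  Mutations follow the infinite-sites
model: Poisson on branches, uniform positions, ancestral state known by
construction, so every polymorphism is perfectly polarized.

Scaling conventions: time in units of 2N generations, theta = 4*N*mu and
rho = 4*N*r per site, multiplied by the window length L to give locus
rates.  Pairwise coalescence rate is 1 per 2N generations; a lineage
recombines at rate rho_locus/2 per unit of the span between the ends of
its ancestral material.  Only rate ratios matter for the statistics.

The simulated D/H/E values form empirical null distributions; observed
peak values get one-sided empirical probabilities P(Sim <= Obs), and a
window is called significant when P >= 0.95 for Zeng's E or P < 0.05 for
standardized Fay & Wu's H and Tajima's D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigError, EstimationError
from .popgen import DerivedSFS, stats_from_sfs

__all__ = [
    "NullModel",
    "NullDistribution",
    "SweepCall",
    "derive_parameters",
    "simulate_replicate",
    "simulate_sfs",
    "build_null",
    "null_from_sfs",
    "empirical_p",
    "call_significance",
]

MU_SITE_DEFAULT = 2.9e-9


# ---------------------------------------------------------------------------
# Parameter derivation
# ---------------------------------------------------------------------------

def derive_parameters(
    map_length_morgans: float,
    genome_size_bp: float,
    theta_site: float = 7.6e-3,
    mu_site: float = MU_SITE_DEFAULT,
) -> dict[str, float]:
    """Per-site recombination rate and population recombination parameter.

    recomb_rate = genetic map length (Morgans) / genome size (bp);
    rho_site = theta_site * recomb_rate / mu_site, i.e. theta scaled by the
    ratio of per-site crossover to per-site mutation rates.
    """
    if min(map_length_morgans, genome_size_bp, theta_site, mu_site) <= 0:
        raise ConfigError("all parameter-derivation inputs must be positive")
    recomb_rate = map_length_morgans / genome_size_bp
    return {
        "recomb_rate": recomb_rate,
        "rho_site": theta_site * recomb_rate / mu_site,
    }


# ---------------------------------------------------------------------------
# Model / result types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModel:
    """Configuration of the neutral null.

    ``theta_site``/``rho_site`` are per-site by default (multiplied by L);
    set ``per_locus=True`` to interpret them as whole-locus values.
    """

    n: int = 22
    theta_site: float = 7.6e-3
    rho_site: float = 2.5e-1
    L: int = 2000
    reps: int = 10000
    seed: int = 0
    per_locus: bool = False

    def __post_init__(self):
        if self.n < 2 or self.n > 62:
            raise ConfigError("sample size must be in [2, 62]")
        if self.theta_site < 0 or self.rho_site < 0:
            raise ConfigError("theta and rho must be non-negative")
        if self.L < 1 or self.reps < 1:
            raise ConfigError("L and reps must be >= 1")

    @property
    def theta_locus(self) -> float:
        return self.theta_site if self.per_locus else self.theta_site * self.L

    @property
    def rho_locus(self) -> float:
        return self.rho_site if self.per_locus else self.rho_site * self.L


@dataclass(frozen=True)
class NullDistribution:
    """Sorted simulated values of one statistic plus definedness bookkeeping."""

    statistic_name: str
    values: np.ndarray  # sorted ascending, defined replicates only
    reps: int

    @property
    def n_defined(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class SweepCall:
    p_E: float
    p_H: float
    p_D: float
    significant_E: bool
    significant_H: bool
    significant_D: bool


# ---------------------------------------------------------------------------
# ARG kernel (numba)
# ---------------------------------------------------------------------------
# Lineages carry sorted disjoint segments of ancestral material on [0, 1);
# each segment maps to the bitmask of sample leaves it is ancestral to.
# Material whose mask reaches all n samples has found its local MRCA and is
# dropped.  Branch mutations are sampled lazily when a lineage is retired
# (its segments are immutable over its lifetime).

@njit(cache=True)
def _emit(seg_l, seg_r, seg_m, sp, new_off, l, r, m, full):
    if r <= l or m == full:
        return sp
    if sp > new_off and seg_m[sp - 1] == m and seg_r[sp - 1] == l:
        seg_r[sp - 1] = r
    else:
        seg_l[sp] = l
        seg_r[sp] = r
        seg_m[sp] = m
        sp += 1
    return sp


@njit(cache=True)
def _retire(lid, t, lin_off, lin_cnt, lin_birth, seg_l, seg_r, seg_m,
            half_theta, mut_pos, mut_mask, mp):
    """Drop Poisson mutations on a dying lineage; returns new mp or -1."""
    dt = t - lin_birth[lid]
    if dt <= 0.0 or half_theta <= 0.0:
        return mp
    off = lin_off[lid]
    for si in range(off, off + lin_cnt[lid]):
        seg_len = seg_r[si] - seg_l[si]
        nm = np.random.poisson(half_theta * dt * seg_len)
        for _ in range(nm):
            if mp >= mut_pos.shape[0]:
                return -1
            mut_pos[mp] = seg_l[si] + np.random.random() * seg_len
            mut_mask[mp] = seg_m[si]
            mp += 1
    return mp


@njit(cache=True)
def _arg_kernel(n, theta, rho, seed,
                seg_l, seg_r, seg_m,
                lin_off, lin_cnt, lin_birth,
                act, mut_pos, mut_mask):
    """One replicate; returns (status, n_mutations).

    status: 0 ok; 1/2/3 segment/lineage/mutation workspace overflow
    (caller enlarges and re-runs with the same seed); 4 internal
    inconsistency (should never happen).
    """
    np.random.seed(seed)
    SEGCAP = seg_l.shape[0]
    LINCAP = lin_off.shape[0]
    full = (np.int64(1) << n) - np.int64(1)
    half_theta = 0.5 * theta
    sp = 0
    lp = 0
    mp = 0
    k = 0
    total_span = 0.0
    for i in range(n):
        seg_l[sp] = 0.0
        seg_r[sp] = 1.0
        seg_m[sp] = np.int64(1) << i
        lin_off[lp] = sp
        lin_cnt[lp] = 1
        lin_birth[lp] = 0.0
        act[k] = lp
        sp += 1
        lp += 1
        k += 1
        total_span += 1.0
    t = 0.0
    while k >= 2:
        rate_c = 0.5 * k * (k - 1)
        rate_r = 0.5 * rho * total_span
        total = rate_c + rate_r
        t += np.random.exponential(1.0 / total)
        if np.random.random() * total < rate_c:
            # --- coalescence of two uniformly chosen lineages
            ia = np.random.randint(0, k)
            ib = np.random.randint(0, k - 1)
            if ib >= ia:
                ib += 1
            la = act[ia]
            lb = act[ib]
            if ia < ib:
                ia, ib = ib, ia
            act[ia] = act[k - 1]
            k -= 1
            act[ib] = act[k - 1]
            k -= 1
            oa, ca = lin_off[la], lin_cnt[la]
            ob, cb = lin_off[lb], lin_cnt[lb]
            total_span -= seg_r[oa + ca - 1] - seg_l[oa]
            total_span -= seg_r[ob + cb - 1] - seg_l[ob]
            mp = _retire(la, t, lin_off, lin_cnt, lin_birth,
                         seg_l, seg_r, seg_m, half_theta, mut_pos, mut_mask, mp)
            if mp < 0:
                return 3, 0
            mp = _retire(lb, t, lin_off, lin_cnt, lin_birth,
                         seg_l, seg_r, seg_m, half_theta, mut_pos, mut_mask, mp)
            if mp < 0:
                return 3, 0
            if sp + ca + cb + 2 > SEGCAP:
                return 1, 0
            if lp + 1 > LINCAP:
                return 2, 0
            # merge the two sorted segment lists, OR-ing masks on overlap
            new_off = sp
            i = 0
            j = 0
            al = ar = bl = br = 0.0
            am = bm = np.int64(0)
            have_a = i < ca
            if have_a:
                al, ar, am = seg_l[oa], seg_r[oa], seg_m[oa]
            have_b = j < cb
            if have_b:
                bl, br, bm = seg_l[ob], seg_r[ob], seg_m[ob]
            while have_a and have_b:
                if ar <= bl:
                    sp = _emit(seg_l, seg_r, seg_m, sp, new_off, al, ar, am, full)
                    i += 1
                    have_a = i < ca
                    if have_a:
                        al, ar, am = seg_l[oa + i], seg_r[oa + i], seg_m[oa + i]
                elif br <= al:
                    sp = _emit(seg_l, seg_r, seg_m, sp, new_off, bl, br, bm, full)
                    j += 1
                    have_b = j < cb
                    if have_b:
                        bl, br, bm = seg_l[ob + j], seg_r[ob + j], seg_m[ob + j]
                elif al < bl:
                    sp = _emit(seg_l, seg_r, seg_m, sp, new_off, al, bl, am, full)
                    al = bl
                elif bl < al:
                    sp = _emit(seg_l, seg_r, seg_m, sp, new_off, bl, al, bm, full)
                    bl = al
                else:
                    e = min(ar, br)
                    sp = _emit(seg_l, seg_r, seg_m, sp, new_off, al, e, am | bm, full)
                    al = e
                    bl = e
                    if al >= ar:
                        i += 1
                        have_a = i < ca
                        if have_a:
                            al, ar, am = seg_l[oa + i], seg_r[oa + i], seg_m[oa + i]
                    if bl >= br:
                        j += 1
                        have_b = j < cb
                        if have_b:
                            bl, br, bm = seg_l[ob + j], seg_r[ob + j], seg_m[ob + j]
            while have_a:
                sp = _emit(seg_l, seg_r, seg_m, sp, new_off, al, ar, am, full)
                i += 1
                have_a = i < ca
                if have_a:
                    al, ar, am = seg_l[oa + i], seg_r[oa + i], seg_m[oa + i]
            while have_b:
                sp = _emit(seg_l, seg_r, seg_m, sp, new_off, bl, br, bm, full)
                j += 1
                have_b = j < cb
                if have_b:
                    bl, br, bm = seg_l[ob + j], seg_r[ob + j], seg_m[ob + j]
            if sp > new_off:
                lin_off[lp] = new_off
                lin_cnt[lp] = sp - new_off
                lin_birth[lp] = t
                act[k] = lp
                k += 1
                lp += 1
                total_span += seg_r[sp - 1] - seg_l[new_off]
        else:
            # --- recombination within the span of a lineage
            u = np.random.random() * total_span
            acc = 0.0
            ci = k - 1
            for idx in range(k):
                lid0 = act[idx]
                off0 = lin_off[lid0]
                acc += seg_r[off0 + lin_cnt[lid0] - 1] - seg_l[off0]
                if u < acc:
                    ci = idx
                    break
            lid = act[ci]
            off = lin_off[lid]
            c = lin_cnt[lid]
            lo = seg_l[off]
            hi = seg_r[off + c - 1]
            x = lo + np.random.random() * (hi - lo)
            if x <= lo or x >= hi:
                continue  # measure-zero draw; no material changes sides
            act[ci] = act[k - 1]
            k -= 1
            total_span -= hi - lo
            mp = _retire(lid, t, lin_off, lin_cnt, lin_birth,
                         seg_l, seg_r, seg_m, half_theta, mut_pos, mut_mask, mp)
            if mp < 0:
                return 3, 0
            if sp + c + 1 > SEGCAP:
                return 1, 0
            if lp + 2 > LINCAP:
                return 2, 0
            left_off = sp
            si = 0
            while si < c and seg_l[off + si] < x:
                l0 = seg_l[off + si]
                r0 = min(seg_r[off + si], x)
                seg_l[sp] = l0
                seg_r[sp] = r0
                seg_m[sp] = seg_m[off + si]
                sp += 1
                if seg_r[off + si] > x:
                    break
                si += 1
            left_cnt = sp - left_off
            right_off = sp
            while si < c:
                l0 = max(seg_l[off + si], x)
                r0 = seg_r[off + si]
                if r0 > l0:
                    seg_l[sp] = l0
                    seg_r[sp] = r0
                    seg_m[sp] = seg_m[off + si]
                    sp += 1
                si += 1
            right_cnt = sp - right_off
            if left_cnt == 0 or right_cnt == 0:
                return 4, 0
            lin_off[lp] = left_off
            lin_cnt[lp] = left_cnt
            lin_birth[lp] = t
            act[k] = lp
            k += 1
            lp += 1
            lin_off[lp] = right_off
            lin_cnt[lp] = right_cnt
            lin_birth[lp] = t
            act[k] = lp
            k += 1
            lp += 1
            total_span += (seg_r[left_off + left_cnt - 1] - seg_l[left_off])
            total_span += (seg_r[right_off + right_cnt - 1] - seg_l[right_off])
    if k != 0:
        return 4, 0
    return 0, mp


class _Workspace:
    """Reusable kernel buffers; grown on overflow and retried."""

    def __init__(self, segcap=1 << 17, lincap=1 << 15, mutcap=1 << 14):
        self.alloc(segcap, lincap, mutcap)

    def alloc(self, segcap, lincap, mutcap):
        self.seg_l = np.empty(segcap)
        self.seg_r = np.empty(segcap)
        self.seg_m = np.empty(segcap, dtype=np.int64)
        self.lin_off = np.empty(lincap, dtype=np.int64)
        self.lin_cnt = np.empty(lincap, dtype=np.int64)
        self.lin_birth = np.empty(lincap)
        self.act = np.empty(lincap, dtype=np.int64)
        self.mut_pos = np.empty(mutcap)
        self.mut_mask = np.empty(mutcap, dtype=np.int64)

    def grow(self, status):
        segcap = self.seg_l.shape[0] * (2 if status == 1 else 1)
        lincap = self.lin_off.shape[0] * (2 if status == 2 else 1)
        mutcap = self.mut_pos.shape[0] * (2 if status == 3 else 1)
        self.alloc(segcap, lincap, mutcap)


_WS: _Workspace | None = None


def _workspace() -> _Workspace:
    global _WS
    if _WS is None:
        _WS = _Workspace()
    return _WS


def simulate_replicate(
    n: int, theta_locus: float, rho_locus: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One neutral ARG replicate.

    Returns (positions, masks): mutation positions in [0, 1) along the
    locus and int64 bitmasks of the samples carrying the derived allele
    (bit i = sample i).  Every mutation segregates (0 < carriers < n).
    """
    if n < 2 or n > 62:
        raise ConfigError("sample size must be in [2, 62]")
    ws = _workspace()
    for _ in range(20):
        status, nm = _arg_kernel(
            n, theta_locus, rho_locus, int(seed) & 0x7FFFFFFF,
            ws.seg_l, ws.seg_r, ws.seg_m,
            ws.lin_off, ws.lin_cnt, ws.lin_birth,
            ws.act, ws.mut_pos, ws.mut_mask,
        )
        if status == 0:
            return ws.mut_pos[:nm].copy(), ws.mut_mask[:nm].copy()
        if status == 4:
            raise RuntimeError("ARG bookkeeping inconsistency")
        ws.grow(status)
    raise RuntimeError("ARG workspace kept overflowing")


def _rep_seeds(seed: int, reps: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(reps).astype(np.int64)


def sfs_from_masks(n: int, masks: np.ndarray) -> DerivedSFS:
    """Fold derived-carrier bitmasks into an unfolded SFS."""
    if masks.size == 0:
        return DerivedSFS.from_counts(n, [0] * (n - 1))
    freq = np.bitwise_count(masks.astype(np.uint64)).astype(np.int64)
    counts = np.bincount(freq, minlength=n)[1:n]
    return DerivedSFS.from_counts(n, counts)


def simulate_sfs(model: NullModel) -> list[DerivedSFS]:
    """Independent per-window SFS replicates under the null model."""
    seeds = _rep_seeds(model.seed, model.reps)
    out = []
    for s in seeds:
        _, masks = simulate_replicate(
            model.n, model.theta_locus, model.rho_locus, int(s)
        )
        out.append(sfs_from_masks(model.n, masks))
    return out


def null_from_sfs(replicates, reps: int | None = None
                  ) -> dict[str, NullDistribution]:
    """Null distributions of D, H, E from simulated per-window SFS
    replicates (those with S = 0 are dropped, not imputed)."""
    replicates = list(replicates)
    vals = {"D": [], "H": [], "E": []}
    for sfs in replicates:
        if sfs.S < 1:
            continue
        w = stats_from_sfs(sfs)
        vals["D"].append(w.D)
        vals["H"].append(w.H)
        vals["E"].append(w.E)
    total = len(replicates) if reps is None else reps
    return {
        name: NullDistribution(name, np.sort(np.asarray(v)), total)
        for name, v in vals.items()
    }


def build_null(model: NullModel) -> dict[str, NullDistribution]:
    """Simulate the model and collect null distributions of D, H, E."""
    return null_from_sfs(simulate_sfs(model), model.reps)


# ---------------------------------------------------------------------------
# Empirical probabilities and the significance rule
# ---------------------------------------------------------------------------

def empirical_p(null: NullDistribution, observed: float,
                pseudocount: bool = False) -> float:
    """P(Sim <= Obs) over defined replicates, ties counted.

    ``pseudocount=True`` switches to (k+1)/(n_defined+1); the raw
    proportion is the default (it can reach exactly 0 and 1).
    """
    if null.n_defined < 1:
        raise EstimationError("null distribution has no defined replicates")
    k = int(np.searchsorted(null.values, observed, side="right"))
    if pseudocount:
        return (k + 1) / (null.n_defined + 1)
    return k / null.n_defined


def call_significance(p_E: float, p_H: float, p_D: float,
                      alpha: float = 0.05) -> SweepCall:
    """One-tailed calls: E significant when P(Sim <= Obs) >= 1 - alpha
    (high tail); H and D significant when P(Sim <= Obs) < alpha (low tail,
    strict)."""
    for p in (p_E, p_H, p_D):
        if not 0.0 <= p <= 1.0:
            raise ConfigError("probabilities must lie in [0, 1]")
    return SweepCall(
        p_E=p_E, p_H=p_H, p_D=p_D,
        significant_E=p_E >= 1.0 - alpha,
        significant_H=p_H < alpha,
        significant_D=p_D < alpha,
    )
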