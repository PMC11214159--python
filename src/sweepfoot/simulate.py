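"""Synthetic data generators for every pipeline stage.

Each generator is deterministic given its seed and produces data with the
statistical structure the corresponding analysis stage assumes: neutral
or sweep-distorted haplotype loci, BC1 crosses with a planted QTL and a
correlated covariate, multi-species alignments with embedded slowly
evolving blocks, log-scale allometric morphometric tables, and random
position frequency matrices.  Defaults mirror the study conditions the
pipeline targets: n = 22 haplotypes over a 2,000-bp window with
theta = 7.6e-3 and rho = 2.5e-1 per site; 132 BC1 individuals, 1,533
markers on 14 linkage groups spanning 1,790 cM, four log-scale traits.

The sweep generator applies an explicit genealogical distortion rather
than a forward selection simulation: a fraction f of the sampled
lineages is collapsed onto one founder haplotype around the sweep
position, with exponentially distributed escape (recombination)
distances, reproducing the excess of high-frequency derived alleles that
the sweep statistics test for, with tunable strength.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .coalescent import simulate_replicate
from .errors import ConfigError
from .morpho import MorphoMatrix
from .qtl import CrossData, kosambi_r
from .tfbs import PFM

__all__ = [
    "LocusConfig",
    "BC1Config",
    "AlignmentConfig",
    "MorphoConfig",
    "gen_neutral_locus",
    "gen_sweep_locus",
    "gen_bc1",
    "gen_alignment",
    "gen_morpho",
    "gen_pfm",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Haplotype loci
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusConfig:
    n: int = 22
    L: int = 2000
    theta_site: float = 7.6e-3
    rho_site: float = 2.5e-1
    seed: int = 0

    def __post_init__(self):
        if self.theta_site < 0 or self.rho_site < 0 or self.L < 1:
            raise ConfigError("rates must be >= 0 and L >= 1")

    @property
    def params(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Locus:
    """Generated haplotype alignment plus its perfect ancestral sequence."""

    sequences: tuple[str, ...]
    ancestral: str
    ids: tuple[str, ...]
    params: dict


def _assign_sites(positions: np.ndarray, L: int) -> np.ndarray:
    """Distinct integer sites for sorted continuous positions in [0, 1)."""
    sites = np.floor(positions * L).astype(np.int64)
    for i in range(1, sites.size):
        if sites[i] <= sites[i - 1]:
            sites[i] = sites[i - 1] + 1
    overflow = sites >= L
    if overflow.any():  # push colliding tail back into range
        sites[-1] = min(sites[-1], L - 1)
        for i in range(sites.size - 2, -1, -1):
            if sites[i] >= sites[i + 1]:
                sites[i] = sites[i + 1] - 1
        if sites[0] < 0:
            raise ConfigError("more segregating sites than alignment columns")
    return sites


def _sequences_from_mutations(n, L, positions, masks, rng) -> tuple[list[str], str]:
    anc = rng.integers(0, 4, L)
    hap = np.tile(anc, (n, 1))
    order = np.argsort(positions, kind="stable")
    sites = _assign_sites(positions[order], L)
    for site, mask in zip(sites, masks[order].astype(np.int64)):
        derived = (anc[site] + rng.integers(1, 4)) % 4
        carriers = [i for i in range(n) if (int(mask) >> i) & 1]
        hap[carriers, site] = derived
    decode = np.array(list("ACGT"))
    return (["".join(decode[r]) for r in hap], "".join(decode[anc]))


def gen_neutral_locus(config: LocusConfig = LocusConfig()) -> Locus:
    """Neutral coalescent haplotypes with a perfect ancestral record."""
    rng = np.random.default_rng(config.seed)
    pos, masks = simulate_replicate(
        config.n, config.theta_site * config.L, config.rho_site * config.L,
        int(rng.integers(0, 2**31 - 1)),
    )
    seqs, anc = _sequences_from_mutations(config.n, config.L, pos, masks, rng)
    return Locus(
        sequences=tuple(seqs),
        ancestral=anc,
        ids=tuple(f"hap{i:02d}" for i in range(config.n)),
        params={**config.params, "scenario": "neutral"},
    )


def sweep_distort(positions: np.ndarray, masks: np.ndarray, n: int,
                  sweep_position: float, f: float, escape_scale: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Collapse a fraction f of lineages onto a founder around a sweep.

    ``sweep_position`` and ``escape_scale`` are in locus units ([0, 1]).
    Each swept lineage copies the founder's allelic state at every
    position closer to the sweep than its exponentially distributed
    escape distances (left and right drawn independently).  Mutations
    rendered monomorphic or fixed are dropped.
    """
    if not 0.0 <= f <= 1.0:
        raise ConfigError("sweep strength f must be in [0, 1]")
    m = int(round(f * n))
    if m < 2 or positions.size == 0:
        return positions, masks
    swept = rng.choice(n, size=m, replace=False)
    founder = int(swept[0])
    masks = masks.astype(np.int64).copy()
    full = (1 << n) - 1
    for i in swept[1:]:
        left = rng.exponential(escape_scale)
        right = rng.exponential(escape_scale)
        linked = (positions > sweep_position - left) & (
            positions < sweep_position + right)
        fbit = (masks[linked] >> founder) & 1
        masks[linked] = np.where(
            fbit == 1,
            masks[linked] | (1 << int(i)),
            masks[linked] & ~(1 << int(i)),
        )
    keep = (masks != 0) & (masks != full)
    return positions[keep], masks[keep]


def gen_sweep_locus(config: LocusConfig = LocusConfig(),
                    sweep_position: float | None = None,
                    sweep_strength: float = 0.9,
                    escape_scale_bp: float = 10000.0) -> Locus:
    """Haplotypes carrying the SFS footprint of a recent sweep.

    ``sweep_position`` is in bp along the locus (default: center);
    ``sweep_strength`` is the fraction f of lineages collapsed onto the
    founder; f = 0 reproduces the neutral generator draw for draw.
    ``escape_scale_bp`` is the mean recombination-escape distance,
    1/(r*T) for per-bp crossover rate r and sweep duration T; with
    r = 9.5e-8 and T = (2/s) ln(2N) this is roughly 7-40 kb for
    selection coefficients 0.02-0.1, so the 10-kb default corresponds to
    a strong recent sweep whose footprint decays over several kb.
    """
    rng = np.random.default_rng(config.seed)
    pos, masks = simulate_replicate(
        config.n, config.theta_site * config.L, config.rho_site * config.L,
        int(rng.integers(0, 2**31 - 1)),
    )
    x0 = 0.5 if sweep_position is None else sweep_position / config.L
    pos, masks = sweep_distort(
        pos, masks, config.n, x0, sweep_strength,
        escape_scale_bp / config.L, rng,
    )
    seqs, anc = _sequences_from_mutations(config.n, config.L, pos, masks, rng)
    return Locus(
        sequences=tuple(seqs),
        ancestral=anc,
        ids=tuple(f"hap{i:02d}" for i in range(config.n)),
        params={**config.params, "scenario": "sweep", "f": sweep_strength,
                "sweep_position": x0 * config.L,
                "escape_scale_bp": escape_scale_bp},
    )


# ---------------------------------------------------------------------------
# BC1 cross
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BC1Config:
    n_individuals: int = 132
    n_markers: int = 1533
    n_lg: int = 14
    total_cM: float = 1790.0
    qtl_lg: int = 6
    qtl_cM: float = 60.0
    effect: float = 0.0  # additive effect of "h", in residual-SD units
    covariate_effect: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    @property
    def params(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BC1Result:
    cross: CrossData
    qtl_lg: int
    qtl_cM: float
    qtl_genotype: np.ndarray  # planted 0/1 genotype per individual
    params: dict


def gen_bc1(config: BC1Config = BC1Config()) -> BC1Result:
    """BC1 genotypes, marker map and four correlated log-scale traits.

    Genotypes follow a two-state Markov chain along each linkage group
    with interval recombination fractions from the Kosambi map function,
    so markers segregate 1:1 and the map is Kosambi-consistent.  The
    trait pair (head_width, head_length) carries the planted QTL plus a
    shared dependence on thorax_width, which is itself genetically
    independent of the QTL; effect = 0 plants no QTL.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    per_lg = np.full(cfg.n_lg, cfg.n_markers // cfg.n_lg)
    per_lg[: cfg.n_markers % cfg.n_lg] += 1
    lg_len = cfg.total_cM / cfg.n_lg
    names, lgs, pos = [], [], []
    for lg in range(1, cfg.n_lg + 1):
        k = per_lg[lg - 1]
        p = np.linspace(0.0, lg_len, k)
        names += [f"m{lg:02d}_{j:03d}" for j in range(k)]
        lgs += [lg] * k
        pos.append(p)
    cmap = pd.DataFrame({"lg": lgs, "cM": np.concatenate(pos)},
                        index=pd.Index(names, name="marker"))

    n = cfg.n_individuals
    geno = np.empty((n, cfg.n_markers))
    qtl_geno = np.zeros(n)
    col = 0
    for lg in range(1, cfg.n_lg + 1):
        p = cmap.loc[cmap["lg"] == lg, "cM"].to_numpy()
        sim_pos = p
        qtl_idx = None
        if lg == cfg.qtl_lg:
            sim_pos = np.sort(np.append(p, cfg.qtl_cM))
            qtl_idx = int(np.searchsorted(sim_pos, cfg.qtl_cM))
        r = kosambi_r(np.diff(sim_pos))
        states = np.empty((n, sim_pos.size))
        states[:, 0] = rng.random(n) < 0.5
        for j, rj in enumerate(r, start=1):
            flip = rng.random(n) < rj
            states[:, j] = np.where(flip, 1 - states[:, j - 1], states[:, j - 1])
        if qtl_idx is not None:
            qtl_geno = states[:, qtl_idx].copy()
            states = np.delete(states, qtl_idx, axis=1)
        geno[:, col:col + states.shape[1]] = states
        col += states.shape[1]

    ind = pd.Index([f"ind{i:03d}" for i in range(n)], name="id")
    thorax_width = rng.normal(0.0, 1.0, n)
    thorax_length = 0.8 * thorax_width + rng.normal(0.0, 0.6, n)
    a = cfg.effect * cfg.noise_sd
    g = cfg.covariate_effect
    head_width = a * qtl_geno + g * thorax_width + rng.normal(0, cfg.noise_sd, n)
    head_length = a * qtl_geno + g * thorax_width + rng.normal(0, cfg.noise_sd, n)
    pheno = pd.DataFrame(
        {
            "head_width": head_width,
            "head_length": head_length,
            "thorax_width": thorax_width,
            "thorax_length": thorax_length,
        },
        index=ind,
    )
    cross = CrossData(
        genotypes=pd.DataFrame(geno, index=ind, columns=cmap.index),
        map=cmap,
        phenotypes=pheno,
    )
    return BC1Result(cross, cfg.qtl_lg, cfg.qtl_cM, qtl_geno, cfg.params)


# ---------------------------------------------------------------------------
# Alignments with constrained blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentConfig:
    n_rows: int = 4
    length: int = 300
    p_neutral: float = 0.3
    blocks: tuple[tuple[int, int, float], ...] = ()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.p_neutral < 1.0:
            raise ConfigError("p_neutral must be in (0, 1)")
        taken = np.zeros(self.length, dtype=bool)
        for s, e, pc in self.blocks:
            if not (0 <= s < e <= self.length):
                raise ConfigError(f"block ({s}, {e}) outside alignment")
            if not 0.0 <= pc < 1.0:
                raise ConfigError("block rate must be in [0, 1)")
            if taken[s:e].any():
                raise ConfigError("constrained blocks overlap")
            taken[s:e] = True

    @property
    def params(self) -> dict:
        d = asdict(self)
        d["blocks"] = list(map(list, self.blocks))
        return d


def gen_alignment(config: AlignmentConfig = AlignmentConfig()
                  ) -> tuple[tuple[str, ...], dict]:
    """Aligned rows mutated from a common reference.

    Each column differs across rows with the per-column substitution
    probability of its region (``p_neutral`` outside blocks, the block's
    ``p_constrained`` inside); a differing column substitutes one random
    row with a random different base, so the induced column mismatch
    probability equals the configured rate exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rate = np.full(cfg.length, cfg.p_neutral)
    for s, e, pc in cfg.blocks:
        rate[s:e] = pc
    ref = rng.integers(0, 4, cfg.length)
    rows = np.tile(ref, (cfg.n_rows, 1))
    hit = rng.random(cfg.length) < rate
    which = rng.integers(0, cfg.n_rows, cfg.length)
    shift = rng.integers(1, 4, cfg.length)
    for j in np.flatnonzero(hit):
        rows[which[j], j] = (ref[j] + shift[j]) % 4
    decode = np.array(list("ACGT"))
    return tuple("".join(decode[r]) for r in rows), cfg.params


# ---------------------------------------------------------------------------
# Morphometric tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphoConfig:
    groups: tuple[str, ...] = ("control", "knockdown")
    n_per_group: int = 20
    p: int = 4
    group_shape_offsets: tuple[tuple[float, ...], ...] | None = None
    size_sd: float = 0.1
    noise_sd: float = 0.03
    baseline_log_mm: tuple[float, ...] = (1.2, 1.0, 1.6, 1.7)
    seed: int = 0

    @property
    def params(self) -> dict:
        return asdict(self)


def gen_morpho(config: MorphoConfig = MorphoConfig()) -> MorphoMatrix:
    """Log-normal measurement table with a common size factor per specimen.

    log x_ij = mu_j + s_i + delta_{group(i), j} + eps_ij with
    s_i ~ N(0, size_sd^2) shared across the p measurements, so the
    isometric Burnaby adjustment removes s_i exactly when the group shape
    offsets are size-orthogonal (sum to zero).
    """
    cfg = config
    if cfg.p < 2:
        raise ConfigError("need p >= 2 measurements")
    rng = np.random.default_rng(cfg.seed)
    mu = np.asarray(cfg.baseline_log_mm[: cfg.p], dtype=float)
    if mu.size < cfg.p:
        mu = np.resize(mu, cfg.p)
    offsets = cfg.group_shape_offsets
    if offsets is None:
        offsets = tuple(tuple(0.0 for _ in range(cfg.p)) for _ in cfg.groups)
    rows, labels = [], []
    for g, grp in enumerate(cfg.groups):
        delta = np.asarray(offsets[g], dtype=float)
        for _ in range(cfg.n_per_group):
            s = rng.normal(0.0, cfg.size_sd)
            eps = rng.normal(0.0, cfg.noise_sd, cfg.p)
            rows.append(np.exp(mu + s + delta + eps))
            labels.append(grp)
    idx = pd.Index([f"sp{i:03d}" for i in range(len(rows))], name="specimen")
    cols = [f"dim{j}" for j in range(cfg.p)] if cfg.p != 4 else [
        "head_width", "head_length", "thorax_width", "thorax_length"]
    values = pd.DataFrame(np.array(rows), index=idx, columns=cols)
    return MorphoMatrix(values=values, group=pd.Series(labels, index=idx, name="group"))


# ---------------------------------------------------------------------------
# Random motifs
# ---------------------------------------------------------------------------

def gen_pfm(width: int = 8, total: int = 100, concentration: float = 0.5,
            seed: int = 0, motif_id: str = "SYN0001", name: str = "synthetic"
            ) -> PFM:
    """Random Dirichlet-column PFM (low concentration = sharp motif)."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(np.full(4, concentration), size=width).T
    counts = np.round(probs * total)
    counts[:, counts.sum(axis=0) == 0] = 1.0
    return PFM(id=motif_id, name=name, counts=counts)
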