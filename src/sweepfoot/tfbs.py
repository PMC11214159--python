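"""Position-weight-matrix scanning with SNP/binding-site intersection.

A position frequency matrix (PFM) of base counts becomes a log-odds PWM
after adding a per-cell pseudocount and normalizing against a background
base distribution.  A site's relative score rescales its summed log-odds
between the matrix's attainable minimum and maximum,

    rel = (score - min_score) / (max_score - min_score)  in [0, 1],

so the consensus word scores exactly 1.  Both strands are scanned (minus
strand via the reverse complement) and sites at or above the relative
score threshold are reported; SNPs are then intersected with the
half-open site intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, InputError

__all__ = ["PFM", "PWM", "BindingSite", "pfm_to_pwm", "scan", "snp_overlap"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: 4 x w non-negative counts (rows A,C,G,T)."""

    id: str
    name: str
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2 or c.shape[0] != 4 or c.shape[1] < 1:
            raise InputError("PFM counts must be a 4 x w matrix with w >= 1")
        if (c < 0).any():
            raise InputError("PFM counts must be non-negative")
        if (c.sum(axis=0) <= 0).any():
            raise InputError("every PFM column needs a positive count sum")
        object.__setattr__(self, "counts", c)

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PWM:
    """Log-odds matrix with attainable score bounds."""

    id: str
    name: str
    logodds: np.ndarray  # 4 x w
    min_score: float
    max_score: float

    @property
    def width(self) -> int:
        return self.logodds.shape[1]


@dataclass
class BindingSite:
    """Predicted site, 0-based half-open on the scanned (+) sequence."""

    motif_id: str
    start: int
    end: int
    strand: str
    relative_score: float
    snp_hits: tuple[int, ...] = ()


def pfm_to_pwm(pfm: PFM, pseudocount: float = 0.1,
               background: np.ndarray | None = None) -> PWM:
    """Log-odds PWM from counts with per-cell pseudocount.

    Column probabilities are (counts + pseudocount) normalized; log-odds
    are taken against the background (uniform by default).  min/max
    attainable scores are the column-wise minima/maxima sums.
    """
    if pseudocount < 0:
        raise ConfigError("pseudocount must be >= 0")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ConfigError("background must be 4 positive frequencies")
    bg = bg / bg.sum()
    probs = pfm.counts + pseudocount
    probs = probs / probs.sum(axis=0)
    if (probs <= 0).any():
        raise ConfigError("zero probability cell; use a positive pseudocount")
    lo = np.log2(probs / bg[:, None])
    return PWM(
        id=pfm.id,
        name=pfm.name,
        logodds=lo,
        min_score=float(lo.min(axis=0).sum()),
        max_score=float(lo.max(axis=0).sum()),
    )


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in seq.upper()], dtype=np.int64)


def _window_scores(codes: np.ndarray, pwm: PWM) -> np.ndarray:
    """Summed log-odds at every start position; NaN where a window has N."""
    w = pwm.width
    L = codes.size
    if L < w:
        return np.empty(0)
    out = np.zeros(L - w + 1)
    ok = np.ones(L - w + 1, dtype=bool)
    for j in range(w):
        c = codes[j:L - w + 1 + j]
        valid = c >= 0
        ok &= valid
        out += np.where(valid, pwm.logodds[np.clip(c, 0, 3), j], 0.0)
    out[~ok] = np.nan
    return out


def scan(sequence: str, pwm: PWM, threshold: float = 0.95,
         width_filter: tuple[int, int] | None = None) -> list[BindingSite]:
    """Binding sites with relative score >= threshold on both strands.

    Windows containing N are skipped; a sequence shorter than the motif
    yields an empty list.  ``width_filter=(5, 12)`` restricts reporting to
    motifs of 5-12 bp (inclusive), the typical insect TF site range.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigError("threshold must be in [0, 1]")
    if width_filter is not None:
        lo, hi = width_filter
        if not lo <= pwm.width <= hi:
            return []
    span = pwm.max_score - pwm.min_score
    if span <= 0:
        # degenerate motif: every word attains the same score
        span = np.inf
    sites: list[BindingSite] = []
    seq = sequence.upper()
    L = len(seq)
    w = pwm.width
    for strand in "+-":
        s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
        scores = _window_scores(_encode(s), pwm)
        rel = (scores - pwm.min_score) / span
        for i in np.flatnonzero(rel >= threshold):
            start = int(i) if strand == "+" else L - int(i) - w
            sites.append(
                BindingSite(
                    motif_id=pwm.id,
                    start=start,
                    end=start + w,
                    strand=strand,
                    relative_score=float(rel[i]),
                )
            )
    sites.sort(key=lambda b: (b.start, b.strand, b.motif_id))
    return sites


def snp_overlap(sites: list[BindingSite], snp_positions) -> dict:
    """Annotate sites with the SNPs inside their half-open intervals.

    Returns {"sites": annotated list, "n_sites": ..., "n_with_snp": ...}.
    """
    snps = np.sort(np.asarray(list(snp_positions), dtype=np.int64))
    n_with = 0
    for site in sites:
        lo = int(np.searchsorted(snps, site.start, side="left"))
        hi = int(np.searchsorted(snps, site.end, side="left"))
        site.snp_hits = tuple(int(p) for p in snps[lo:hi])
        n_with += bool(site.snp_hits)
    return {"sites": sites, "n_sites": len(sites), "n_with_snp": n_with}
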