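"""Geometric-mean body size and Burnaby size correction.

Body size of a specimen with p positive measurements is their geometric
mean.  On the natural-log scale the isometric size axis is
g = (1,...,1)/sqrt(p); Burnaby's procedure projects each log-measurement
vector into the space orthogonal to the size axis and back-projects so
every adjusted specimen has log body size exactly zero (geometric mean
one), removing size while preserving shape contrasts between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["MorphoMatrix", "body_size", "burnaby_adjust"]


@dataclass
class MorphoMatrix:
    """Specimens x measurements table (original units) with group labels."""

    values: pd.DataFrame  # numeric measurement columns only
    group: pd.Series

    def __post_init__(self):
        if self.values.shape[1] < 2:
            raise InputError("need at least two measurement columns")
        if (self.values.to_numpy(float) <= 0).any():
            raise InputError("all measurements must be positive")
        if not self.values.index.equals(self.group.index):
            raise InputError("group labels index different specimens")

    @property
    def log_values(self) -> np.ndarray:
        return np.log(self.values.to_numpy(float))


def body_size(row) -> float:
    """Geometric mean of one specimen's measurements."""
    x = np.asarray(row, dtype=float)
    if (x <= 0).any():
        raise InputError("measurements must be positive")
    return float(np.exp(np.mean(np.log(x))))


def _size_axis(logx: np.ndarray, axis: str, groups: np.ndarray | None) -> np.ndarray:
    p = logx.shape[1]
    if axis == "isometric":
        return np.ones(p) / np.sqrt(p)
    if axis == "pc1":
        if groups is None:
            centered = logx - logx.mean(axis=0)
        else:
            centered = logx.copy()
            for g in np.unique(groups):
                sel = groups == g
                centered[sel] -= logx[sel].mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        a = vt[0]
        return a if a.sum() >= 0 else -a  # orient toward increasing size
    raise InputError(f"unknown size axis {axis!r}")


def burnaby_adjust(matrix: MorphoMatrix, axis: str = "isometric",
                   per_group: bool = False) -> MorphoMatrix:
    """Size-corrected measurement table (original units).

    Each log row x is replaced by its projection off the size axis a,
    x' = x - (x.a)a, then back-projected along a so the adjusted specimen
    has log body size exactly zero: x'' = x' - mean(x') * sqrt(p) * ...
    collapses to x'' = x' - (sum(x')/sum(a)) a.  With the default
    isometric axis the projection alone already zeroes the log size.
    The operation is idempotent and invariant to isometric rescaling of a
    specimen.  ``axis='pc1'`` uses the pooled (or per-group) first
    principal component of the log data as the size axis instead.
    """
    logx = matrix.log_values
    groups = matrix.group.to_numpy()
    a = _size_axis(logx, axis, groups if per_group else None)
    proj = logx - np.outer(logx @ a, a)
    s = a.sum()
    if abs(s) < 1e-12:
        raise InputError("size axis orthogonal to the isometric direction; "
                         "log size cannot be zeroed along it")
    adj = proj - np.outer(proj.sum(axis=1) / s, a)
    out = pd.DataFrame(np.exp(adj), index=matrix.values.index,
                       columns=matrix.values.columns)
    return MorphoMatrix(values=out, group=matrix.group)
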