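"""Per-gene association strengths from binned signal.

TF association strength (TFAS) weights the 100 binned signal values by a
normalized Gaussian kernel of the bin-midpoint distance to the TSS,

    a_i = sum_j N_ij * F(d_j),   F(d) = exp(-d^2 / 2h^2) / (h * sqrt(2*pi)),

with the bandwidth h from Silverman's rule of thumb on the pooled tag-to-TSS
distances. HM/DNase association strength (HMAS) is the plain sum of the 20
bins. Both are then log2(x + pseudocount)-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import BinnedSignal, BinScheme
from .core import DEFAULT_PSEUDOCOUNT, TagTrack
from .errors import AlignmentError, ConfigError, DegenerateSampleError


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel evaluated at a scheme's bin midpoints."""

    bandwidth: float
    weights: np.ndarray


def gaussian_kernel(d: np.ndarray, bandwidth: float) -> np.ndarray:
    """Normalized (unit-area in d) Gaussian density with sd = bandwidth."""
    d = np.asarray(d, dtype=float)
    return np.exp(-(d ** 2) / (2.0 * bandwidth ** 2)) / (bandwidth * np.sqrt(2.0 * np.pi))


def make_kernel(scheme: BinScheme, bandwidth: float) -> KernelSpec:
    if bandwidth <= 0:
        raise ConfigError("bandwidth must be positive")
    return KernelSpec(bandwidth, gaussian_kernel(np.asarray(scheme.midpoints), bandwidth))


def tag_tss_distances(track: TagTrack, genes: pd.DataFrame, scheme: BinScheme) -> np.ndarray:
    """Signed strand-oriented distances of in-window tags to their gene's TSS.

    Each tag is assigned to the nearest TSS; tags farther than the window
    bounds (5' side: -window_upstream, 3' side: +window_downstream) from every
    TSS are dropped.
    """
    tss = genes["tss"].to_numpy(dtype=np.int64)
    order = np.argsort(tss)
    tss_sorted = tss[order]
    minus = (genes["strand"] == "-").to_numpy()[order]
    pos = track.positions
    idx = np.searchsorted(tss_sorted, pos)
    idx = np.clip(idx, 1, len(tss_sorted) - 1) if len(tss_sorted) > 1 else np.zeros_like(idx)
    left = np.maximum(idx - 1, 0)
    use_left = np.abs(pos - tss_sorted[left]) <= np.abs(pos - tss_sorted[idx])
    nearest = np.where(use_left, left, idx)
    d = pos - tss_sorted[nearest]
    d = np.where(minus[nearest], -d, d)  # 5'->3' orientation
    keep = (d >= -scheme.window_upstream) & (d < scheme.window_downstream)
    return d[keep].astype(float)


def rule_of_thumb_bandwidth(track: TagTrack, genes: pd.DataFrame, scheme: BinScheme) -> float:
    """Silverman's rule-of-thumb bandwidth on pooled tag-TSS distances:

    h = 0.9 * min(sd, IQR/1.34) * n^(-1/5).
    """
    d = tag_tss_distances(track, genes, scheme)
    if np.unique(d).size < 2:
        raise DegenerateSampleError(
            f"track {track.factor_name!r}: need >= 2 distinct in-window tag-TSS distances"
        )
    sd = float(np.std(d, ddof=1))
    q75, q25 = np.percentile(d, [75, 25])
    iqr = float(q75 - q25)
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * d.size ** (-1.0 / 5.0)
    if h <= 0:
        raise DegenerateSampleError("bandwidth collapsed to zero")
    return h


@dataclass
class AssociationColumn:
    """One factor's per-gene association strength (raw and logged)."""

    factor_name: str
    factor_class: str
    gene_ids: list
    raw: np.ndarray
    logged: np.ndarray
    pseudocount: float
    bandwidth: float | None = None


def _log_transform(raw: np.ndarray, pseudocount: float) -> np.ndarray:
    if pseudocount <= 0 and np.any(raw + pseudocount <= 0):
        raise ConfigError("pseudocount must keep raw + sigma positive for log2")
    return np.log2(raw + pseudocount)


def tfas(
    binned: BinnedSignal, kernel: KernelSpec, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> AssociationColumn:
    """TF association strength: kernel-weighted bin sum, then log2(x + sigma)."""
    if binned.matrix.shape[1] != kernel.weights.size:
        raise AlignmentError(
            f"kernel has {kernel.weights.size} weights but signal has "
            f"{binned.matrix.shape[1]} bins"
        )
    raw = binned.matrix @ kernel.weights
    return AssociationColumn(
        binned.factor_name,
        binned.factor_class,
        list(binned.gene_ids),
        raw,
        _log_transform(raw, pseudocount),
        pseudocount,
        bandwidth=kernel.bandwidth,
    )


def hmas(binned: BinnedSignal, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> AssociationColumn:
    """HM/DNase association strength: plain bin sum, then log2(x + sigma)."""
    raw = binned.matrix.sum(axis=1)
    return AssociationColumn(
        binned.factor_name,
        binned.factor_class,
        list(binned.gene_ids),
        raw,
        _log_transform(raw, pseudocount),
        pseudocount,
    )


@dataclass
class AssociationMatrix:
    """Genes x factors association strengths.

    ``logged`` (log2(raw + sigma)) is the feature matrix every downstream
    model consumes; ``raw`` is kept for inspection.
    """

    gene_ids: list
    factor_names: list
    factor_classes: dict
    raw: pd.DataFrame
    logged: pd.DataFrame
    pseudocounts: dict
    bandwidths: dict = field(default_factory=dict)

    def subset(self, names) -> pd.DataFrame:
        """Logged feature columns for the given factor names, in given order."""
        missing = [n for n in names if n not in self.logged.columns]
        if missing:
            raise AlignmentError(f"unknown factors: {missing}")
        return self.logged[list(names)]

    def names_of_class(self, *classes) -> list:
        return [n for n in self.factor_names if self.factor_classes[n] in classes]


def assemble(columns) -> AssociationMatrix:
    """Stack per-factor association columns into a genes x factors matrix."""
    columns = list(columns)
    if not columns:
        raise AlignmentError("no association columns to assemble")
    gene_ids = columns[0].gene_ids
    for c in columns[1:]:
        if c.gene_ids != gene_ids:
            raise AlignmentError(f"gene ids of {c.factor_name!r} do not match")
    names = [c.factor_name for c in columns]
    if len(set(names)) != len(names):
        raise AlignmentError("duplicate factor names")
    raw = pd.DataFrame({c.factor_name: c.raw for c in columns}, index=gene_ids)
    logged = pd.DataFrame({c.factor_name: c.logged for c in columns}, index=gene_ids)
    return AssociationMatrix(
        gene_ids=list(gene_ids),
        factor_names=names,
        factor_classes={c.factor_name: c.factor_class for c in columns},
        raw=raw,
        logged=logged,
        pseudocounts={c.factor_name: c.pseudocount for c in columns},
        bandwidths={c.factor_name: c.bandwidth for c in columns if c.bandwidth is not None},
    )
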