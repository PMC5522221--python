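"""Binned, depth-normalized signal matrices around transcription start sites.

TF binding signal is aggregated over a +/-10 kb window split into 100 bins of
200 bp; HM and DNase signal over +/-2 kb split into 20 bins of 200 bp. The raw
tag count n_ij of factor k in bin j of gene i is normalized to

    N_ij = n_ij * 1e9 / (n_tag * bin_width)

where n_tag is the factor's total tag count — a tags-per-billion-per-bp rate
that puts ChIP-seq signal on a scale commensurate with RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TagTrack, validate_genes
from .errors import ConfigError, NormalizationError

NORMALIZATION_SCALE = 1e9

#: (upstream bp, downstream bp, bin width bp) per factor class
WINDOWS = {
    "TF": (10_000, 10_000, 200),
    "HM": (2_000, 2_000, 200),
    "DNase": (2_000, 2_000, 200),
}


@dataclass(frozen=True)
class BinScheme:
    """Fixed-width binning of a TSS-flanking window.

    Bins run 5'->3' along the gene; ``midpoints[j]`` is the signed offset
    (bp, negative = upstream) of bin j's midpoint from the TSS.
    """

    window_upstream: int
    window_downstream: int
    bin_width: int
    n_bins: int
    midpoints: tuple

    def __post_init__(self) -> None:
        span = self.window_upstream + self.window_downstream
        if span != self.n_bins * self.bin_width:
            raise ConfigError(
                f"window span {span} != n_bins*bin_width {self.n_bins * self.bin_width}"
            )


def make_scheme(factor_class: str) -> BinScheme:
    """The binning scheme for a factor class: TF -> 100 bins over +/-10 kb,
    HM/DNase -> 20 bins over +/-2 kb, all 200 bp wide."""
    if factor_class not in WINDOWS:
        raise ConfigError(f"unknown factor class {factor_class!r}")
    up, down, width = WINDOWS[factor_class]
    n_bins = (up + down) // width
    midpoints = tuple(-up + (j + 0.5) * width for j in range(n_bins))
    return BinScheme(up, down, width, n_bins, midpoints)


@dataclass
class BinnedSignal:
    """Genes x bins normalized-signal matrix for one factor."""

    factor_name: str
    factor_class: str
    scheme: BinScheme
    matrix: np.ndarray
    gene_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{m:+.0f}" for m in self.scheme.midpoints]
        return pd.DataFrame(self.matrix, index=self.gene_ids, columns=cols)


def _raw_counts(track: TagTrack, genes: pd.DataFrame, scheme: BinScheme) -> np.ndarray:
    """Integer tag counts per (gene, bin), bins ordered 5'->3'.

    A tag at position p falls in forward-axis bin floor((p - window_start)/w),
    left-closed ([start, end) in 0-based coordinates); for minus-strand genes
    the bin order is then reversed so bin 0 is always the most 5' (upstream)
    bin. A tag inside several gene windows is counted for each of them.
    """
    pos = np.sort(track.positions)
    n_bins = scheme.n_bins
    width = scheme.bin_width
    counts = np.zeros((len(genes), n_bins), dtype=np.int64)
    tss = genes["tss"].to_numpy(dtype=np.int64)
    minus = (genes["strand"] == "-").to_numpy()
    # genomic window start: strand decides which side is "upstream"
    starts = np.where(minus, tss - scheme.window_downstream, tss - scheme.window_upstream)
    ends = starts + n_bins * width
    lo = np.searchsorted(pos, starts, side="left")
    hi = np.searchsorted(pos, ends, side="left")
    for i in range(len(genes)):
        if hi[i] == lo[i]:
            continue
        idx = (pos[lo[i]:hi[i]] - starts[i]) // width
        row = np.bincount(idx, minlength=n_bins)
        counts[i] = row[::-1] if minus[i] else row
    return counts


def bin_track(track: TagTrack, genes: pd.DataFrame, scheme: BinScheme) -> BinnedSignal:
    """Bin one factor's tags around every TSS and depth-normalize.

    Entry (i, j) = raw count * 1e9 / (total_tags * bin_width). Tags outside
    every window are ignored.
    """
    validate_genes(genes)
    if len(genes) == 0:
        raise ConfigError("empty gene table")
    if track.total_tags == 0:
        raise NormalizationError(
            f"track {track.factor_name!r} has zero total tags; normalization undefined"
        )
    raw = _raw_counts(track, genes, scheme)
    norm = raw * (NORMALIZATION_SCALE / (track.total_tags * scheme.bin_width))
    return BinnedSignal(
        factor_name=track.factor_name,
        factor_class=track.factor_class,
        scheme=scheme,
        matrix=norm,
        gene_ids=list(genes["id"]),
    )
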