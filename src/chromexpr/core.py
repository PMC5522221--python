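"""Shared containers: gene tables and tag tracks.

A gene table is a :class:`pandas.DataFrame` with columns ``id``, ``chrom``,
``strand`` (``+``/``-``), ``tss`` (0-based bp) and ``rpkm``; one row per gene,
unique ids. A tag track holds the single-bp positions (aligned-read midpoints)
of one factor — a transcription factor (TF), a histone modification (HM) or
DNase-I hypersensitivity — on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

GENE_COLUMNS = ("id", "chrom", "strand", "tss", "rpkm")

FACTOR_CLASSES = ("TF", "HM", "DNase")

#: default pseudocount sigma used in every log2(x + sigma) transform
DEFAULT_PSEUDOCOUNT = 1.0


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    """Check a gene table's schema and invariants; return it unchanged."""
    missing = [c for c in GENE_COLUMNS if c not in genes.columns]
    if missing:
        raise ConfigError(f"gene table missing columns: {missing}")
    if genes["id"].duplicated().any():
        dup = genes.loc[genes["id"].duplicated(), "id"].iloc[0]
        raise ConfigError(f"duplicate gene id: {dup!r}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ConfigError("strand must be '+' or '-'")
    if (genes["rpkm"] < 0).any():
        raise ConfigError("rpkm must be non-negative")
    return genes


def log_expression(genes: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """log2(RPKM + sigma), the response every model in the package predicts."""
    return np.log2(genes["rpkm"].to_numpy(dtype=float) + pseudocount)


@dataclass
class TagTrack:
    """Aligned-tag positions of one factor on one chromosome.

    ``positions`` are 0-based single-bp coordinates (read midpoints);
    ``total_tags`` always equals ``len(positions)``. ``ground_truth`` is
    populated by the synthetic generator (per-gene log2 intensities, the
    generating effect weight, spatial profile, redundancy partner) and is
    empty for tracks read from disk without a sidecar.
    """

    factor_name: str
    factor_class: str
    positions: np.ndarray
    chrom: str = "chrSim"
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factor_class not in FACTOR_CLASSES:
            raise ConfigError(
                f"factor_class must be one of {FACTOR_CLASSES}, got {self.factor_class!r}"
            )
        self.positions = np.asarray(self.positions, dtype=np.int64)

    @property
    def total_tags(self) -> int:
        return int(self.positions.size)
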