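"""Plain-text readers and writers (TSV, BED, JSON sidecars).

Conventions: BED intervals are 0-based half-open; tags are 1-bp intervals
(read midpoints); the gene BED6 represents each TSS as a 1-bp interval with
the score column holding min(1000, round(rpkm)).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .association import AssociationColumn, AssociationMatrix, assemble
from .binning import BinnedSignal, make_scheme
from .core import TagTrack, validate_genes
from .errors import ConfigError


def write_genes_tsv(genes: pd.DataFrame, path) -> None:
    validate_genes(genes)
    genes.to_csv(path, sep="\t", index=False)


def read_genes_tsv(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str, "strand": str})
    return validate_genes(genes)


def write_genes_bed6(genes: pd.DataFrame, path) -> None:
    validate_genes(genes)
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["tss"],
            "end": genes["tss"] + 1,
            "name": genes["id"],
            "score": np.minimum(1000, np.round(genes["rpkm"]).astype(int)),
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def _json_safe(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    return value


def write_track(track: TagTrack, bed_path, sidecar_path=None) -> None:
    """BED3 of 1-bp tag intervals plus a JSON sidecar with the metadata and
    any ground-truth parameters."""
    bed_path = Path(bed_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bed_path.with_suffix(".json")
    pos = track.positions
    pd.DataFrame({"chrom": track.chrom, "start": pos, "end": pos + 1}).to_csv(
        bed_path, sep="\t", index=False, header=False
    )
    meta = {
        "factor_name": track.factor_name,
        "factor_class": track.factor_class,
        "total_tags": track.total_tags,
        "chrom": track.chrom,
        "ground_truth": {k: _json_safe(v) for k, v in track.ground_truth.items()},
    }
    sidecar_path.write_text(json.dumps(meta, indent=1))


def read_track(bed_path, sidecar_path=None, factor_name=None, factor_class=None) -> TagTrack:
    """Read a BED3 tag track; metadata from the sidecar or the arguments."""
    bed_path = Path(bed_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else bed_path.with_suffix(".json")
    bed = pd.read_csv(bed_path, sep="\t", header=None, usecols=[0, 1, 2],
                      names=["chrom", "start", "end"])
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    name = factor_name or meta.get("factor_name")
    klass = factor_class or meta.get("factor_class")
    if name is None or klass is None:
        raise ConfigError("factor name/class not in sidecar and not supplied")
    gt = meta.get("ground_truth", {})
    if "log_intensity" in gt:
        gt["log_intensity"] = np.asarray(gt["log_intensity"], dtype=float)
    return TagTrack(
        factor_name=name,
        factor_class=klass,
        positions=bed["start"].to_numpy(np.int64),
        chrom=str(bed["chrom"].iloc[0]) if len(bed) else meta.get("chrom", "chrSim"),
        ground_truth=gt,
    )


def write_binned(binned: BinnedSignal, tsv_path, header_path=None) -> None:
    tsv_path = Path(tsv_path)
    header_path = Path(header_path) if header_path else tsv_path.with_suffix(".json")
    binned.to_frame().to_csv(tsv_path, sep="\t", index_label="gene_id")
    header_path.write_text(
        json.dumps(
            {
                "factor_name": binned.factor_name,
                "factor_class": binned.factor_class,
                "window_upstream": binned.scheme.window_upstream,
                "window_downstream": binned.scheme.window_downstream,
                "bin_width": binned.scheme.bin_width,
                "n_bins": binned.scheme.n_bins,
            },
            indent=1,
        )
    )


def read_binned(tsv_path, header_path=None) -> BinnedSignal:
    tsv_path = Path(tsv_path)
    header_path = Path(header_path) if header_path else tsv_path.with_suffix(".json")
    meta = json.loads(header_path.read_text())
    frame = pd.read_csv(tsv_path, sep="\t", index_col="gene_id")
    return BinnedSignal(
        factor_name=meta["factor_name"],
        factor_class=meta["factor_class"],
        scheme=make_scheme(meta["factor_class"]),
        matrix=frame.to_numpy(dtype=float),
        gene_ids=list(frame.index.astype(str)),
    )


def write_association(assoc: AssociationMatrix, tsv_path, meta_path=None) -> None:
    tsv_path = Path(tsv_path)
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(".json")
    assoc.logged.to_csv(tsv_path, sep="\t", index_label="gene_id")
    meta_path.write_text(
        json.dumps(
            {
                "factor_classes": assoc.factor_classes,
                "pseudocounts": assoc.pseudocounts,
                "bandwidths": assoc.bandwidths,
            },
            indent=1,
        )
    )


def read_association(tsv_path, meta_path=None) -> AssociationMatrix:
    """Rebuild an AssociationMatrix from its logged TSV + metadata.

    Raw values are back-computed as 2^logged - pseudocount.
    """
    tsv_path = Path(tsv_path)
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    logged = pd.read_csv(tsv_path, sep="\t", index_col="gene_id")
    logged.index = logged.index.astype(str)
    cols = []
    for name in logged.columns:
        sigma = meta["pseudocounts"].get(name, 1.0)
        lg = logged[name].to_numpy(dtype=float)
        cols.append(
            AssociationColumn(
                factor_name=name,
                factor_class=meta["factor_classes"][name],
                gene_ids=list(logged.index),
                raw=np.maximum(np.exp2(lg) - sigma, 0.0),
                logged=lg,
                pseudocount=sigma,
                bandwidth=meta.get("bandwidths", {}).get(name),
            )
        )
    return assemble(cols)


def write_gene_sets(sets: dict, path) -> None:
    """Two-column TSV: set_id <tab> gene_id."""
    rows = [(sid, g) for sid, members in sets.items() for g in members]
    pd.DataFrame(rows, columns=["set_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_gene_sets(path) -> dict:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if list(frame.columns) != ["set_id", "gene_id"]:
        raise ConfigError("gene-set TSV must have columns set_id, gene_id")
    out: dict = {}
    for sid, grp in frame.groupby("set_id", sort=True):
        out[sid] = sorted(grp["gene_id"])
    return out
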