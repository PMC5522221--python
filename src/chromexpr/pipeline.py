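"""End-to-end orchestration from one YAML config.

Stages run in dependency order — simulate -> bin -> assoc -> [select] ->
fit / modes / network / genesets — and a manifest JSON records package and
library versions, seeds, stage parameters and SHA-256 checksums of every
output file, so two runs of the same config are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import assemble, hmas, make_kernel, rule_of_thumb_bandwidth, tfas
from .binning import bin_track, make_scheme
from .core import log_expression
from .errors import ConfigError
from .genesets import band_counts, evaluate_gene_sets, results_frame, select_high_expressed
from .models import ModelConfig, fit_log_linear, fit_svr
from .modes import best_mode_at, enumerate_modes, evaluate_modes, summarize_modes
from .network import attach_expression, network_robustness, partial_correlation_network
from .simulate import SimulationConfig, simulate_gene_sets, simulate_genes, simulate_tracks
from .stepwise import stepwise_select

log = logging.getLogger("chromexpr")

DEFAULT_CONFIG = {
    "schema_version": 1,
    "seed": 1,
    "pseudocount": 1.0,
    "simulate": {"enabled": True},
    "select": {"enabled": True, "cap": 15, "criterion": "aic"},
    "fit": {"enabled": True, "folds": 10, "svr_c": 1.0, "svr_epsilon": 0.1},
    "modes": {
        "enabled": True,
        "classes": ["HM", "TF"],
        "cardinality": 4,
        "threshold_fraction": 0.95,
        "hm_only_summary": False,
    },
    "network": {"enabled": True, "n_edges": 20, "n_reps": 50, "n_remove": 200},
    "genesets": {
        "enabled": True,
        "n_sets": 9,
        "size_min": 60,
        "size_max": 100,
        "high_fraction": 0.15,
        "min_size": 30,
        "alpha": 0.05,
    },
    "write_binned": False,
}

_KNOWN_SECTIONS = set(DEFAULT_CONFIG) | {"inputs", "log_level"}


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_config(user)


def merge_config(user: dict) -> dict:
    unknown = set(user) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            bad = set(val) - set(cfg[key]) - set(
                f.name for f in SimulationConfig.__dataclass_fields__.values()
            )
            if bad:
                raise ConfigError(f"unknown fields in config section {key!r}: {sorted(bad)}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    if "inputs" in user:
        cfg["inputs"] = user["inputs"]
        cfg["simulate"]["enabled"] = False
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, frozenset):
        return sorted(x)
    return str(x)


def _load_inputs(cfg: dict):
    inputs = cfg.get("inputs")
    if not inputs:
        raise ConfigError("simulate disabled and no 'inputs' section given")
    genes_path = Path(inputs.get("genes", ""))
    if not genes_path.is_file():
        raise ConfigError(f"input gene table not found: {genes_path}")
    genes = io.read_genes_tsv(genes_path)
    tracks = []
    for bed in inputs.get("tracks", []):
        bed = Path(bed)
        if not bed.is_file():
            raise ConfigError(f"input track not found: {bed}")
        tracks.append(io.read_track(bed))
    if not tracks:
        raise ConfigError("no input tracks given")
    return genes, tracks


def run_pipeline(cfg: dict, outdir) -> dict:
    """Execute the configured stages; return (and write) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    sigma = float(cfg["pseudocount"])
    manifest: dict = {
        "versions": _versions(),
        "seed": seed,
        "config": cfg,
        "stages": {},
        "outputs": {},
    }
    outputs: list = []

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    # --- simulate / load -------------------------------------------------
    tracks_gt = None
    if cfg["simulate"]["enabled"]:
        sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
        sim_kwargs.setdefault("seed", seed)
        sim_kwargs["redundant_pairs"] = [
            tuple(p) for p in sim_kwargs.get("redundant_pairs", [("TF02", "TF03", 0.9)])
        ]
        sim = SimulationConfig(**sim_kwargs)
        genes = simulate_genes(sim)
        tracks = simulate_tracks(genes, sim)
        tracks_gt = tracks
        io.write_genes_tsv(genes, outdir / "genes.tsv")
        io.write_genes_bed6(genes, outdir / "genes.bed")
        outputs += [outdir / "genes.tsv", outdir / "genes.bed"]
        tdir = outdir / "tracks"
        tdir.mkdir(exist_ok=True)
        for t in tracks:
            io.write_track(t, tdir / f"{t.factor_name}.bed")
            outputs += [tdir / f"{t.factor_name}.bed", tdir / f"{t.factor_name}.json"]
        record("simulate", n_genes=len(genes), factors=[t.factor_name for t in tracks],
               sim_config={k: _coerce_cfg(v) for k, v in asdict(sim).items()})
    else:
        genes, tracks = _load_inputs(cfg)
        record("load", n_genes=len(genes), factors=[t.factor_name for t in tracks])

    y = log_expression(genes, sigma)

    # --- bin + association ----------------------------------------------
    columns = []
    bandwidths = {}
    for t in tracks:
        scheme = make_scheme(t.factor_class)
        binned = bin_track(t, genes, scheme)
        if cfg["write_binned"]:
            io.write_binned(binned, outdir / f"binned_{t.factor_name}.tsv")
            outputs += [outdir / f"binned_{t.factor_name}.tsv",
                        outdir / f"binned_{t.factor_name}.json"]
        if t.factor_class == "TF":
            h = rule_of_thumb_bandwidth(t, genes, scheme)
            bandwidths[t.factor_name] = h
            columns.append(tfas(binned, make_kernel(scheme, h), sigma))
        else:
            columns.append(hmas(binned, sigma))
    assoc = assemble(columns)
    io.write_association(assoc, outdir / "assoc.tsv")
    outputs += [outdir / "assoc.tsv", outdir / "assoc.json"]
    record("association", factors=assoc.factor_names, bandwidths=bandwidths)

    tf_names = assoc.names_of_class("TF")
    hm_names = assoc.names_of_class("HM", "DNase")
    mc = ModelConfig(folds=int(cfg["fit"]["folds"]), svr_c=float(cfg["fit"]["svr_c"]),
                     svr_epsilon=float(cfg["fit"]["svr_epsilon"]))

    # --- stepwise selection ----------------------------------------------
    if cfg["select"]["enabled"] and tf_names:
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            sel = stepwise_select(assoc.subset(tf_names), y, cap=int(cfg["select"]["cap"]),
                                  criterion=cfg["select"]["criterion"])
        tf_names = sel.selected or tf_names
        _write_json({"ranked": sel.ranked_factors, "criterion": sel.criterion_kind},
                    outdir / "selection.json")
        outputs.append(outdir / "selection.json")
        record("select", selected=tf_names, criterion=sel.criterion_kind)

    # --- genome-wide models ----------------------------------------------
    reports = {}
    if cfg["fit"]["enabled"]:
        feature_sets = {"TF": tf_names, "HM": hm_names, "all": tf_names + hm_names}
        fit_summary = {}
        for label, names in feature_sets.items():
            if not names:
                continue
            X = assoc.subset(names)
            lin = fit_log_linear(X, y, folds=mc.folds, seed=seed)
            svr = fit_svr(X, y, folds=mc.folds, seed=seed, kernel_cfg=mc)
            reports[label] = {"log_linear": lin, "svr": svr}
            fit_summary[label] = {
                kind: {
                    "r2": rep.r2,
                    "cv_r2": rep.cv_r2,
                    "pcc": rep.pcc,
                    "stability_rmse": rep.stability_rmse,
                }
                for kind, rep in reports[label].items()
            }
        from .network import cross_model_pcc

        if "TF" in reports and "HM" in reports:
            fit_summary["cross_model_pcc"] = cross_model_pcc(
                reports["TF"]["svr"], reports["HM"]["svr"]
            )
        _write_json(fit_summary, outdir / "models.json")
        outputs.append(outdir / "models.json")
        preds = pd.DataFrame({"gene_id": genes["id"], "observed": y})
        for label, pair in reports.items():
            preds[f"{label}_svr_oof"] = pair["svr"].predictions_oof
        preds.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
        outputs.append(outdir / "predictions.tsv")
        record("fit", **{k: v for k, v in fit_summary.items()})

    # --- combination modes -----------------------------------------------
    if cfg["modes"]["enabled"]:
        mcfg = cfg["modes"]
        mode_summaries = {}
        for klass in mcfg["classes"]:
            names = tf_names if klass == "TF" else hm_names
            if len(names) < 2:
                continue
            subsets = enumerate_modes(names)
            results = evaluate_modes(subsets, assoc, y, model_cfg=mc, seed=seed)
            restrict = None
            if klass == "HM" and mcfg.get("hm_only_summary"):
                restrict = [n for n in names if assoc.factor_classes[n] == "HM"]
            card = min(int(mcfg["cardinality"]), len(names))
            summary = summarize_modes(results, cardinality=card,
                                      threshold_fraction=float(mcfg["threshold_fraction"]),
                                      restrict_to=restrict)
            frame = pd.DataFrame(
                [{"subset": "+".join(r.subset), "cardinality": r.cardinality, "pcc": r.pcc}
                 for r in results]
            )
            frame.to_csv(outdir / f"modes_{klass}.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(summary.max_curve.items()), columns=["cardinality", "max_pcc"]
            ).to_csv(outdir / f"max_curve_{klass}.tsv", sep="\t", index=False)
            pd.DataFrame(
                [(f, c, frac) for f, (c, frac) in summary.factor_frequency.items()],
                columns=["factor", "count", "fraction"],
            ).to_csv(outdir / f"frequency_{klass}.tsv", sep="\t", index=False)
            outputs += [outdir / f"modes_{klass}.tsv", outdir / f"max_curve_{klass}.tsv",
                        outdir / f"frequency_{klass}.tsv"]
            best = best_mode_at(results, card)
            mode_summaries[klass] = {
                "n_modes": len(results),
                "all_factor_pcc": summary.all_factor_pcc,
                "n_top_modes": len(summary.top_modes),
                "best_mode": {"subset": list(best.subset), "pcc": best.pcc},
            }
        record("modes", **mode_summaries)

    # --- partial-correlation network --------------------------------------
    if cfg["network"]["enabled"]:
        ncfg = cfg["network"]
        data = attach_expression(assoc, genes, sigma)
        net = partial_correlation_network(data, n_edges=int(ncfg["n_edges"]))
        pd.DataFrame(
            net.edges, columns=["node1", "node2", "pcor", "rank", "sign"]
        ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
        outputs.append(outdir / "network_edges.tsv")
        rb = network_robustness(data, n_edges=int(ncfg["n_edges"]),
                                n_reps=int(ncfg["n_reps"]),
                                n_remove=int(ncfg["n_remove"]), seed=seed)
        _write_json(
            {
                "shrinkage_intensity": net.shrinkage_intensity,
                "n_edges": net.n_edges_selected,
                "mean_jaccard": rb.mean_jaccard,
                "edge_frequency": {"+".join(sorted(e)): f for e, f in rb.edge_frequency.items()},
            },
            outdir / "network.json",
        )
        outputs.append(outdir / "network.json")
        record("network", n_edges=net.n_edges_selected,
               shrinkage_intensity=net.shrinkage_intensity, mean_jaccard=rb.mean_jaccard)

    # --- gene-set ratio ---------------------------------------------------
    if cfg["genesets"]["enabled"]:
        gcfg = cfg["genesets"]
        if tracks_gt is None:
            record("genesets", skipped="requires simulated tracks with ground truth")
        else:
            high = select_high_expressed(genes, float(gcfg["high_fraction"]))
            bias = [["TF-favoured", "HM-favoured", "neutral"][i % 3]
                    for i in range(int(gcfg["n_sets"]))]
            coll = simulate_gene_sets(
                genes, int(gcfg["n_sets"]), (int(gcfg["size_min"]), int(gcfg["size_max"])),
                bias, seed, tracks=tracks_gt, within=set(high["id"]),
            )
            io.write_gene_sets(coll.sets, outdir / "gene_sets.tsv")
            results = evaluate_gene_sets(
                coll.sets, assoc, genes, high_expressed=high, model_cfg=mc, seed=seed,
                min_size=int(gcfg["min_size"]), alpha=float(gcfg["alpha"]),
            )
            frame = results_frame(results)
            if len(frame):
                frame["true_bias"] = [coll.labels[s] for s in frame["set_id"]]
            frame.to_csv(outdir / "gene_set_results.tsv", sep="\t", index=False)
            counts = band_counts(results)
            _write_json({"band_counts": counts, "n_sets_evaluated": len(results)},
                        outdir / "gene_set_summary.json")
            outputs += [outdir / "gene_sets.tsv", outdir / "gene_set_results.tsv",
                        outdir / "gene_set_summary.json"]
            record("genesets", n_sets_evaluated=len(results), band_counts=counts)

    manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))}
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _coerce_cfg(v):
    if isinstance(v, dict):
        return {k: _coerce_cfg(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_coerce_cfg(x) for x in v]
    return _coerce(v) if isinstance(v, (np.generic, np.ndarray)) else v


def _versions() -> dict:
    import sklearn
    import scipy

    return {
        "chromexpr": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }
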