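"""Gene-set-level comparison of TF-only vs HM-only predictive power.

For the high-expressed genes (top 15% by RPKM), each gene set is scored with
two SVR models — TF features only and HM(+DNase) features only. Sets smaller
than 30 genes after intersecting with the high-expressed subset are dropped;
per model a Pearson-correlation t-test p-value (out-of-fold predictions vs
observed log-expression) is Benjamini–Hochberg adjusted across sets, and a
set is retained only if both adjusted values are below 0.05. The TF/HM PCC
ratio then classifies each set: < 0.90 HM-superior, 0.90–1.10 similar
(boundaries inclusive), > 1.10 TF-superior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .association import AssociationMatrix
from .core import log_expression, validate_genes
from .errors import ConfigError
from .models import ModelConfig, fit_svr

MIN_SET_SIZE = 30
HIGH_EXPRESSED_FRACTION = 0.15
ALPHA = 0.05
RATIO_LOW, RATIO_HIGH = 0.90, 1.10

BAND_HM = "HM-superior"
BAND_SIMILAR = "similar"
BAND_TF = "TF-superior"


def classify_ratio(ratio: float) -> str:
    """Band a TF/HM PCC ratio; 0.90 and 1.10 fall in the 'similar' band."""
    if not np.isfinite(ratio) or ratio <= 0:
        raise ConfigError(f"ratio must be finite and positive, got {ratio}")
    if ratio < RATIO_LOW:
        return BAND_HM
    if ratio <= RATIO_HIGH:
        return BAND_SIMILAR
    return BAND_TF


def select_high_expressed(genes: pd.DataFrame, fraction: float = HIGH_EXPRESSED_FRACTION) -> pd.DataFrame:
    """Top ``fraction`` of genes by RPKM (ceil count); ties at the cutoff are
    broken by gene id so the selection is deterministic."""
    validate_genes(genes)
    if len(genes) == 0:
        raise ConfigError("empty gene table")
    if not 0 < fraction <= 1:
        raise ConfigError("fraction must be in (0, 1]")
    k = ceil(fraction * len(genes))
    ranked = genes.sort_values(["rpkm", "id"], ascending=[False, True], kind="mergesort")
    if len(genes) > k and ranked["rpkm"].iloc[k - 1] == ranked["rpkm"].iloc[k]:
        warnings.warn("RPKM ties at the selection cutoff; broken by gene id", stacklevel=2)
    return ranked.head(k).sort_index()


@dataclass
class GeneSetResult:
    """Per-set TF-vs-HM comparison."""

    set_id: str
    set_size: int
    tf_pcc: float
    hm_pcc: float
    tf_p: float
    hm_p: float
    tf_q: float = np.nan
    hm_q: float = np.nan
    ratio: float = np.nan
    band: str | None = None
    significant: bool = False
    undefined_ratio: bool = False


def _correlation_p(pred: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(pred, y).pvalue)


def evaluate_gene_sets(
    sets: dict,
    assoc: AssociationMatrix,
    genes: pd.DataFrame,
    high_expressed: pd.DataFrame | None = None,
    model_cfg: ModelConfig | None = None,
    seed: int = 0,
    min_size: int = MIN_SET_SIZE,
    alpha: float = ALPHA,
) -> list:
    """Score every gene set with TF-only and HM(+DNase)-only SVR models.

    ``high_expressed`` defaults to the top 15% of ``genes`` by RPKM; each set
    is intersected with it before the ``min_size`` filter. Returns one
    GeneSetResult per surviving set with BH-adjusted p-values, the PCC ratio
    and its band; ``significant`` marks sets with both q-values < alpha, and
    a non-positive HM PCC flags the ratio as undefined (excluded from
    banding).
    """
    cfg = model_cfg or ModelConfig()
    if high_expressed is None:
        high_expressed = select_high_expressed(genes)
    known = set(genes["id"])
    tf_names = assoc.names_of_class("TF")
    hm_names = assoc.names_of_class("HM", "DNase")
    if not tf_names or not hm_names:
        raise ConfigError("need at least one TF and one HM/DNase factor")
    y_all = pd.Series(log_expression(genes), index=list(genes["id"]))
    high_ids = set(high_expressed["id"])

    results = []
    for set_id, members in sets.items():
        unknown = [g for g in members if g not in known]
        if unknown:
            raise ConfigError(f"set {set_id!r} references unknown genes: {unknown[:5]}")
        kept = sorted(set(members) & high_ids)
        if len(kept) < min_size:
            continue
        y = y_all.loc[kept].to_numpy()
        folds = cfg.folds
        if folds > len(kept):
            warnings.warn(
                f"set {set_id!r}: reducing folds to its size {len(kept)}", stacklevel=2
            )
            folds = len(kept)
        tf_rep = fit_svr(assoc.subset(tf_names).loc[kept], y, folds=folds, seed=seed, kernel_cfg=cfg)
        hm_rep = fit_svr(assoc.subset(hm_names).loc[kept], y, folds=folds, seed=seed, kernel_cfg=cfg)
        results.append(
            GeneSetResult(
                set_id=set_id,
                set_size=len(kept),
                tf_pcc=tf_rep.pcc,
                hm_pcc=hm_rep.pcc,
                tf_p=_correlation_p(tf_rep.predictions_oof, y),
                hm_p=_correlation_p(hm_rep.predictions_oof, y),
            )
        )

    if not results:
        return results
    tf_q = multipletests([r.tf_p for r in results], method="fdr_bh")[1]
    hm_q = multipletests([r.hm_p for r in results], method="fdr_bh")[1]
    for r, tq, hq in zip(results, tf_q, hm_q):
        r.tf_q, r.hm_q = float(tq), float(hq)
        r.significant = tq < alpha and hq < alpha
        if r.hm_pcc <= 0:
            r.undefined_ratio = True
            continue
        r.ratio = r.tf_pcc / r.hm_pcc
        if r.ratio > 0:
            r.band = classify_ratio(r.ratio)
    return results


def band_counts(results, significant_only: bool = True) -> dict:
    """How many retained sets fall in each ratio band."""
    counts = {BAND_HM: 0, BAND_SIMILAR: 0, BAND_TF: 0}
    for r in results:
        if significant_only and not r.significant:
            continue
        if r.band is not None:
            counts[r.band] += 1
    return counts


def results_frame(results) -> pd.DataFrame:
    """Tabular view with the conventional columns (set, size, TF_PCC, HM_PCC,
    Ratio, band, p/q-values)."""
    return pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "set_size": r.set_size,
                "TF_PCC": r.tf_pcc,
                "HM_PCC": r.hm_pcc,
                "Ratio": r.ratio,
                "band": r.band,
                "TF_p": r.tf_p,
                "HM_p": r.hm_p,
                "TF_q": r.tf_q,
                "HM_q": r.hm_q,
                "significant": r.significant,
            }
            for r in results
        ]
    )
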