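"""High-expression selection, gene-set scoring and TF/HM ratio banding."""

import numpy as np
import pandas as pd
import pytest

from chromexpr import (
    assemble,
    bin_track,
    classify_ratio,
    evaluate_gene_sets,
    hmas,
    log_expression,
    make_kernel,
    make_scheme,
    rule_of_thumb_bandwidth,
    select_high_expressed,
    simulate_gene_sets,
    simulate_genes,
    simulate_tracks,
    tfas,
)
from chromexpr.errors import ConfigError
from chromexpr.genesets import BAND_HM, BAND_SIMILAR, BAND_TF, band_counts
from chromexpr.simulate import SimulationConfig


class TestHighExpressed:
    def test_top_fraction_count(self, genes):
        high = select_high_expressed(genes, 0.15)
        assert len(high) == 75  # ceil(0.15 * 500)
        assert high["rpkm"].min() >= genes["rpkm"].quantile(0.84)

    def test_fraction_one_returns_all(self, genes):
        assert len(select_high_expressed(genes, 1.0)) == len(genes)

    def test_ties_broken_by_id_deterministically(self):
        genes = pd.DataFrame(
            {"id": ["g3", "g1", "g2", "g0"], "chrom": "c", "strand": "+",
             "tss": [1, 2, 3, 4], "rpkm": [5.0, 5.0, 5.0, 5.0]}
        )
        with pytest.warns(UserWarning, match="ties"):
            high = select_high_expressed(genes, 0.5)
        assert sorted(high["id"]) == ["g0", "g1"]

    def test_invalid_inputs_rejected(self, genes):
        with pytest.raises(ConfigError):
            select_high_expressed(genes, 0.0)
        with pytest.raises(ConfigError):
            select_high_expressed(genes.iloc[:0], 0.15)


class TestClassifyRatio:
    @pytest.mark.parametrize(
        "tf,hm,band",
        [
            (0.591, 0.897, BAND_HM),     # printed example: ratio 0.659
            (0.845, 0.429, BAND_TF),     # printed example: ratio 1.970
            (0.890, 0.926, BAND_SIMILAR),
        ],
    )
    def test_printed_rows_band_correctly(self, tf, hm, band):
        assert classify_ratio(tf / hm) == band

    def test_boundaries_belong_to_similar(self):
        assert classify_ratio(0.90) == BAND_SIMILAR
        assert classify_ratio(1.10) == BAND_SIMILAR
        assert classify_ratio(1.0) == BAND_SIMILAR
        assert classify_ratio(0.8999) == BAND_HM
        assert classify_ratio(1.1001) == BAND_TF

    def test_nonpositive_or_infinite_ratio_rejected(self):
        for bad in (0.0, -0.5, np.inf, np.nan):
            with pytest.raises(ConfigError):
                classify_ratio(bad)


def tiny_study(seed):
    cfg = SimulationConfig(
        n_genes=400, n_tf=3, n_hm=3, include_dnase=False,
        chrom_length=15_000_000, tags_per_factor=60_000, seed=seed,
        effect_weights={"TF01": 1.2, "TF02": 1.0, "TF03": 0.8,
                        "HM01": 1.2, "HM02": 1.0, "HM03": 0.8},
    )
    genes = simulate_genes(cfg)
    tracks = simulate_tracks(genes, cfg)
    cols = []
    for t in tracks:
        scheme = make_scheme(t.factor_class)
        binned = bin_track(t, genes, scheme)
        if t.factor_class == "TF":
            h = rule_of_thumb_bandwidth(t, genes, scheme)
            cols.append(tfas(binned, make_kernel(scheme, h)))
        else:
            cols.append(hmas(binned))
    return genes, tracks, assemble(cols)


class TestEvaluateGeneSets:
    def test_undersized_set_discarded(self, genes, assoc):
        members = list(genes["id"].iloc[:29])
        results = evaluate_gene_sets(
            {"small": members, "ok": list(genes["id"].iloc[:60])},
            assoc, genes, high_expressed=genes,
        )
        assert [r.set_id for r in results] == ["ok"]

    def test_unknown_gene_rejected(self, genes, assoc):
        with pytest.raises(ConfigError):
            evaluate_gene_sets({"s": ["not-a-gene"] * 30}, assoc, genes,
                               high_expressed=genes)

    def test_ratio_and_bands_consistent(self, genes, assoc):
        sets = {f"s{i}": list(genes["id"].iloc[i * 60:(i + 1) * 60]) for i in range(4)}
        results = evaluate_gene_sets(sets, assoc, genes, high_expressed=genes, seed=2)
        assert len(results) == 4
        for r in results:
            assert r.ratio == pytest.approx(r.tf_pcc / r.hm_pcc)
            assert r.band == classify_ratio(r.ratio)
        counts = band_counts(results, significant_only=False)
        assert sum(counts.values()) == sum(r.band is not None for r in results)

    def test_bh_adjustment_monotone_in_raw_p(self, genes, assoc):
        sets = {f"s{i}": list(genes["id"].iloc[i * 50:(i + 1) * 50 + 10]) for i in range(6)}
        results = evaluate_gene_sets(sets, assoc, genes, high_expressed=genes, seed=3)
        by_p = sorted(results, key=lambda r: r.tf_p)
        qs = [r.tf_q for r in by_p]
        assert qs == sorted(qs)
        for r in results:
            assert r.tf_q >= r.tf_p

    def test_fold_count_reduced_for_tiny_sets_with_warning(self, genes, assoc):
        # min_size lowered so an 8-gene set is evaluated with 8 folds
        sets = {"tiny": list(genes["id"].iloc[:8])}
        with pytest.warns(UserWarning, match="folds"):
            results = evaluate_gene_sets(sets, assoc, genes, high_expressed=genes,
                                         min_size=5, seed=4)
        assert len(results) == 1


@pytest.mark.parametrize("seeds", [tuple(range(10))])
def test_bias_labels_order_the_tf_hm_ratio(seeds):
    """End-to-end paired comparison: within the same study, the engineered
    HM-favoured set scores a lower TF/HM PCC ratio than the TF-favoured set.
    Pairing cancels the per-study noise that dominates a 60-gene set's PCC,
    so the ordering is the reliable signature of the generator's bias."""
    hm_ratios, tf_ratios, ordered = [], [], 0
    for seed in seeds:
        genes, tracks, assoc = tiny_study(seed)
        coll = simulate_gene_sets(genes, 2, (60, 60),
                                  ["HM-favoured", "TF-favoured"],
                                  seed=seed, tracks=tracks)
        results = {r.set_id: r.ratio for r in evaluate_gene_sets(
            coll.sets, assoc, genes, high_expressed=genes, seed=seed)}
        assert len(results) == 2
        hm_ratios.append(results["set000"])
        tf_ratios.append(results["set001"])
        ordered += results["set000"] < results["set001"]
    assert ordered >= len(seeds) - 1
    assert np.mean(hm_ratios) < 0.95
    assert np.mean(tf_ratios) > 1.00
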