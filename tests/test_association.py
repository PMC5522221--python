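"""Kernel-weighted TFAS, summed HMAS, and the rule-of-thumb bandwidth."""

import numpy as np
import pandas as pd
import pytest

from chromexpr import (
    TagTrack,
    assemble,
    hmas,
    make_kernel,
    make_scheme,
    rule_of_thumb_bandwidth,
    tfas,
)
from chromexpr.association import AssociationColumn, gaussian_kernel
from chromexpr.binning import BinnedSignal, BinScheme
from chromexpr.errors import AlignmentError, ConfigError, DegenerateSampleError


def signal(matrix, factor_class="HM", scheme=None):
    matrix = np.asarray(matrix, dtype=float)
    scheme = scheme or make_scheme(factor_class)
    return BinnedSignal("f", factor_class, scheme,
                        matrix, [f"g{i}" for i in range(matrix.shape[0])])


def one_gene(tss=500_000, strand="+"):
    return pd.DataFrame(
        {"id": ["g0"], "chrom": ["chrSim"], "strand": [strand], "tss": [tss], "rpkm": [1.0]}
    )


class TestBandwidth:
    def test_matches_silverman_closed_form_on_normal_sample(self):
        rng = np.random.default_rng(0)
        n = 10_000
        d = np.rint(rng.normal(0, 1000, n)).astype(int)
        track = TagTrack("t", "TF", 500_000 + d)
        h = rule_of_thumb_bandwidth(track, one_gene(), make_scheme("TF"))
        assert h == pytest.approx(0.9 * 1000 * n ** (-0.2), rel=0.05)

    def test_degenerate_sample_raises(self):
        track = TagTrack("t", "TF", np.array([500_100]))
        with pytest.raises(DegenerateSampleError):
            rule_of_thumb_bandwidth(track, one_gene(), make_scheme("TF"))

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        d = np.rint(rng.normal(0, 400, 5000)).astype(int)
        scheme = make_scheme("TF")
        h1 = rule_of_thumb_bandwidth(TagTrack("t", "TF", 500_000 + d), one_gene(), scheme)
        h2 = rule_of_thumb_bandwidth(TagTrack("t", "TF", 500_000 + 2 * d), one_gene(), scheme)
        assert h2 == pytest.approx(2 * h1, rel=1e-9)

    def test_minus_strand_orientation_flips_sign(self):
        d = np.array([100, 200, 300, 1000])
        scheme = make_scheme("TF")
        from chromexpr.association import tag_tss_distances

        plus = tag_tss_distances(TagTrack("t", "TF", 500_000 + d), one_gene(500_000, "+"), scheme)
        minus = tag_tss_distances(TagTrack("t", "TF", 500_000 + d), one_gene(500_000, "-"), scheme)
        np.testing.assert_array_equal(np.sort(plus), np.sort(-minus))


class TestKernel:
    def test_symmetric_and_maximal_at_zero(self):
        d = np.linspace(-10_000, 10_000, 101)
        f = gaussian_kernel(d, 700.0)
        np.testing.assert_allclose(f, f[::-1])
        assert f.argmax() == 50

    def test_single_bin_at_tss_hand_value(self):
        # one 200-bp bin centred exactly on the TSS, signal 10, h = 1000
        scheme = BinScheme(100, 100, 200, 1, (0.0,))
        kern = make_kernel(scheme, 1000.0)
        col = tfas(signal([[10.0]], "TF", scheme), kern, pseudocount=1.0)
        assert col.raw[0] == pytest.approx(10.0 / (1000.0 * np.sqrt(2 * np.pi)), rel=1e-9)
        assert col.raw[0] == pytest.approx(3.989e-3, rel=1e-3)

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ConfigError):
            make_kernel(make_scheme("TF"), 0.0)


class TestTfasHmas:
    def test_hmas_hand_sum(self):
        col = hmas(signal([np.ones(20)]), pseudocount=1.0)
        assert col.raw[0] == pytest.approx(20.0)
        assert col.logged[0] == pytest.approx(np.log2(21.0))

    def test_all_zero_row_maps_to_zero_feature(self):
        scheme = make_scheme("TF")
        kern = make_kernel(scheme, 500.0)
        col = tfas(signal(np.zeros((1, 100)), "TF"), kern, pseudocount=1.0)
        assert col.raw[0] == 0.0 and col.logged[0] == 0.0
        assert hmas(signal(np.zeros((1, 20)))).logged[0] == 0.0

    def test_hmas_invariant_to_bin_permutation(self):
        rng = np.random.default_rng(2)
        row = rng.random(20)
        a = hmas(signal([row])).raw[0]
        b = hmas(signal([rng.permutation(row)])).raw[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_identical_rows_get_identical_tfas(self):
        row = np.linspace(0, 5, 100)
        kern = make_kernel(make_scheme("TF"), 800.0)
        col = tfas(signal([row, row], "TF"), kern)
        assert col.raw[0] == col.raw[1]

    def test_matches_naive_double_loop(self):
        """Matrix products equal an explicit double loop to 1e-12."""
        rng = np.random.default_rng(3)
        tf_scheme = make_scheme("TF")
        kern = make_kernel(tf_scheme, 650.0)
        N = rng.random((5, 100)) * 30
        col = tfas(signal(N, "TF"), kern)
        for i in range(5):
            expected = sum(N[i, j] * kern.weights[j] for j in range(100))
            assert col.raw[i] == pytest.approx(expected, rel=1e-12)
        H = rng.random((5, 20)) * 30
        col_h = hmas(signal(H))
        for i in range(5):
            assert col_h.raw[i] == pytest.approx(sum(H[i]), rel=1e-12)

    def test_tfas_strictly_monotone_in_any_bin(self):
        # Bandwidth wide enough that even the outermost bins' kernel weight
        # stays above float64 resolution relative to the total.
        rng = np.random.default_rng(4)
        N = rng.random((1, 100))
        kern = make_kernel(make_scheme("TF"), 3000.0)
        base = tfas(signal(N, "TF"), kern).raw[0]
        for j in (0, 50, 99):
            bumped = N.copy()
            bumped[0, j] += 1.0
            assert tfas(signal(bumped, "TF"), kern).raw[0] > base

    def test_nonpositive_pseudocount_with_zero_raw_rejected(self):
        with pytest.raises(ConfigError):
            hmas(signal(np.zeros((1, 20))), pseudocount=0.0)


class TestAssemble:
    @staticmethod
    def col(name, gene_ids, klass="TF"):
        raw = np.arange(len(gene_ids), dtype=float)
        return AssociationColumn(name, klass, list(gene_ids), raw, np.log2(raw + 1), 1.0)

    def test_genome_wide_matrix_shape(self):
        ids = [f"g{i}" for i in range(19120)]
        tf = assemble([self.col(f"TF{k:02d}", ids) for k in range(15)])
        assert tf.logged.shape == (19120, 15)
        hm = assemble(
            [self.col(f"HM{k:02d}", ids, "HM") for k in range(10)]
            + [self.col("DNase", ids, "DNase")]
        )
        assert hm.logged.shape == (19120, 11)

    def test_gene_id_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            assemble([self.col("a", ["g0", "g1"]), self.col("b", ["g0", "gX"])])

    def test_empty_column_list_raises(self):
        with pytest.raises(AlignmentError):
            assemble([])

    def test_logged_is_log2_of_raw_plus_pseudocount(self, assoc):
        for name in assoc.factor_names:
            np.testing.assert_allclose(
                assoc.logged[name],
                np.log2(assoc.raw[name] + assoc.pseudocounts[name]),
                rtol=1e-12,
            )
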