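import numpy as np
import pytest

from chromexpr import (
    assemble,
    bin_track,
    hmas,
    log_expression,
    make_kernel,
    make_scheme,
    rule_of_thumb_bandwidth,
    simulate_genes,
    simulate_tracks,
    tfas,
)
from chromexpr.simulate import SimulationConfig


@pytest.fixture(scope="session")
def sim_cfg():
    """Small but statistically meaningful study: 500 genes, 5 TFs, 4 HMs +
    DNase, one engineered 0.9-correlated TF pair."""
    return SimulationConfig(
        n_genes=500,
        chrom_length=20_000_000,
        seed=3,
        redundant_pairs=[("TF02", "TF03", 0.9)],
    )


@pytest.fixture(scope="session")
def genes(sim_cfg):
    return simulate_genes(sim_cfg)


@pytest.fixture(scope="session")
def tracks(genes, sim_cfg):
    return simulate_tracks(genes, sim_cfg)


@pytest.fixture(scope="session")
def assoc(genes, tracks):
    cols = []
    for t in tracks:
        scheme = make_scheme(t.factor_class)
        binned = bin_track(t, genes, scheme)
        if t.factor_class == "TF":
            h = rule_of_thumb_bandwidth(t, genes, scheme)
            cols.append(tfas(binned, make_kernel(scheme, h)))
        else:
            cols.append(hmas(binned))
    return assemble(cols)


@pytest.fixture(scope="session")
def y(genes):
    return log_expression(genes)


def naive_bin_counts(track, genes, scheme):
    """Per-tag reference implementation of window binning."""
    n = scheme.n_bins
    counts = np.zeros((len(genes), n), dtype=int)
    for i, (_, g) in enumerate(genes.iterrows()):
        for p in track.positions:
            if g["strand"] == "+":
                b = (p - (g["tss"] - scheme.window_upstream)) // scheme.bin_width
            else:
                b = (p - (g["tss"] - scheme.window_downstream)) // scheme.bin_width
                b = n - 1 - b if 0 <= b < n else -1
            if 0 <= b < n:
                counts[i, b] += 1
    return counts
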