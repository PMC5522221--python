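"""Synthetic chromosome with expression-coupled factor tracks.

The generator emulates the statistical structure the analysis assumes:

* genes on one chromosome with TSSs spaced > 24 kb apart (so the +/-10 kb and
  +/-2 kb windows never collide), log2(RPKM + sigma) drawn from a normal law;
* per factor, a latent per-gene log2 tag intensity coupled linearly to
  log-expression with a known effect weight plus Gaussian noise — so TF and
  HM intensities share the expression signal, the redundancy the analysis is
  built to detect;
* tags placed around each TSS at a factor-specific strand-oriented offset
  with Gaussian spread, plus a uniform background fraction;
* engineered redundant factor pairs whose latent intensities hit a target
  correlation exactly in-sample (Gram-Schmidt remixing);
* gene sets whose members are biased toward genes where one factor class
  tracks expression more faithfully than the other.

All ground truth (latent intensities, weights, profiles) is recorded on the
tracks for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_PSEUDOCOUNT, TagTrack, log_expression
from .errors import ConfigError, SizingError

#: minimum TSS separation, bp; > 24 kb so that TF windows never overlap
MIN_TSS_SPACING = 25_000
_EDGE_MARGIN = 12_000

GENE_SET_BIASES = ("TF-favoured", "HM-favoured", "neutral")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic chromosome.

    ``effect_weights`` maps factor name -> true linear coefficient of the
    factor's latent log2 intensity on standardized log-expression;
    ``spatial_profile`` maps factor name -> (strand-oriented offset bp from
    the TSS, Gaussian spread bp) of its tag placement. ``noise_sd`` is the
    per-factor intensity noise on the log2 scale; ``redundant_pairs`` lists
    (factor_a, factor_b, target correlation) to engineer.
    """

    n_genes: int = 2000
    n_tf: int = 5
    n_hm: int = 4
    include_dnase: bool = True
    chrom_length: int = 70_000_000
    expression_log_mean: float = 2.0
    expression_log_sd: float = 2.0
    effect_weights: dict = field(default_factory=dict)
    spatial_profile: dict = field(default_factory=dict)
    tags_per_factor: int = 200_000
    noise_sd: float = 0.5
    background_fraction: float = 0.1
    redundant_pairs: list = field(default_factory=list)
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    seed: int = 0
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ConfigError("n_genes must be >= 10")
        for name, val in (("n_tf", self.n_tf), ("n_hm", self.n_hm),
                          ("tags_per_factor", self.tags_per_factor),
                          ("chrom_length", self.chrom_length)):
            if val <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.background_fraction < 1:
            raise ConfigError("background_fraction must be in [0, 1)")
        if self.expression_log_sd <= 0 or self.noise_sd < 0:
            raise ConfigError("expression_log_sd must be > 0 and noise_sd >= 0")
        if not self.effect_weights:
            self.effect_weights = self._default_weights()
        if not self.spatial_profile:
            self.spatial_profile = self._default_profiles()
        names = set(self.factor_names())
        missing = names - set(self.effect_weights)
        if missing:
            raise ConfigError(f"effect_weights missing factors: {sorted(missing)}")
        for name, (offset, spread) in self.spatial_profile.items():
            if spread <= 0:
                raise ConfigError(f"spatial spread must be > 0 for {name!r}")
        for a, b, rho in self.redundant_pairs:
            if a not in names or b not in names:
                raise ConfigError(f"redundant pair ({a!r}, {b!r}) names unknown factor")
            if not -1 < rho < 1:
                raise ConfigError("target correlation must be in (-1, 1)")

    def factor_names(self) -> list:
        names = [f"TF{i + 1:02d}" for i in range(self.n_tf)]
        names += [f"HM{i + 1:02d}" for i in range(self.n_hm)]
        if self.include_dnase:
            names.append("DNase")
        return names

    def factor_class(self, name: str) -> str:
        if name.startswith("TF"):
            return "TF"
        if name.startswith("HM"):
            return "HM"
        return "DNase"

    def _default_weights(self) -> dict:
        tf_w = [1.2, 1.0, 0.8, 0.7, 0.5]
        hm_w = [1.3, 1.0, 0.8, 0.6]
        weights = {}
        for i in range(self.n_tf):
            weights[f"TF{i + 1:02d}"] = tf_w[i % len(tf_w)]
        for i in range(self.n_hm):
            weights[f"HM{i + 1:02d}"] = hm_w[i % len(hm_w)]
        if self.include_dnase:
            weights["DNase"] = 0.9
        return weights

    def _default_profiles(self) -> dict:
        tf_spread = [300, 500, 400, 600, 800]
        hm = [(300, 600), (-200, 700), (500, 500), (0, 800)]
        prof = {}
        for i in range(self.n_tf):
            prof[f"TF{i + 1:02d}"] = (0, tf_spread[i % len(tf_spread)])
        for i in range(self.n_hm):
            prof[f"HM{i + 1:02d}"] = hm[i % len(hm)]
        if self.include_dnase:
            prof["DNase"] = (0, 200)
        return prof


def simulate_genes(cfg: SimulationConfig) -> pd.DataFrame:
    """Gene table with spaced TSSs and lognormal-style expression.

    log2(RPKM + sigma) is drawn from N(expression_log_mean,
    expression_log_sd^2); RPKM is floored at 0, which leaves a realistic
    point mass of silent genes.
    """
    step = (cfg.chrom_length - 2 * _EDGE_MARGIN) / cfg.n_genes
    if step < MIN_TSS_SPACING:
        raise SizingError(
            f"chrom_length {cfg.chrom_length} too short for {cfg.n_genes} genes "
            f"at >= {MIN_TSS_SPACING} bp spacing"
        )
    rng = np.random.default_rng([cfg.seed, 0])
    jitter = rng.uniform(0.0, step - MIN_TSS_SPACING, cfg.n_genes)
    tss = (_EDGE_MARGIN + step * np.arange(cfg.n_genes) + jitter).astype(np.int64)
    strand = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    ylog = rng.normal(cfg.expression_log_mean, cfg.expression_log_sd, cfg.n_genes)
    rpkm = np.maximum(np.exp2(ylog) - cfg.pseudocount, 0.0)
    width = len(str(cfg.n_genes))
    return pd.DataFrame(
        {
            "id": [f"gene{i:0{width}d}" for i in range(cfg.n_genes)],
            "chrom": cfg.chrom,
            "strand": strand,
            "tss": tss,
            "rpkm": rpkm,
        }
    )


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def simulate_tracks(genes: pd.DataFrame, cfg: SimulationConfig) -> list:
    """One TagTrack per configured factor, coupled to expression.

    Latent per-gene log2 intensity: u_k = w_k * z + noise_sd * eps, with z the
    standardized log-expression. For each redundant pair (a, b, rho), u_b is
    remixed as rho * z_a + sqrt(1 - rho^2) * r with r the standardized
    residual of u_b on z_a, so corr(u_a, u_b) = rho exactly in-sample.
    Foreground tags are multinomial across genes with probability
    proportional to 2^u, placed at TSS + offset (strand-oriented) with
    Gaussian spread; the background fraction is uniform on the chromosome.
    """
    z = _standardize(log_expression(genes, cfg.pseudocount))
    names = cfg.factor_names()
    latent = {}
    for f, name in enumerate(names):
        rng = np.random.default_rng([cfg.seed, 1, f])
        w = cfg.effect_weights[name]
        latent[name] = w * z + cfg.noise_sd * rng.standard_normal(cfg.n_genes)

    partner = {}
    for a, b, rho in cfg.redundant_pairs:
        za = _standardize(latent[a])
        zb = _standardize(latent[b])
        c = float(np.mean(za * zb))
        resid = zb - c * za
        resid = _standardize(resid)
        latent[b] = rho * za + np.sqrt(1.0 - rho ** 2) * resid
        partner[b] = (a, rho)

    tss = genes["tss"].to_numpy(dtype=np.int64)
    sign = np.where(genes["strand"].to_numpy() == "+", 1, -1)
    tracks = []
    for f, name in enumerate(names):
        rng = np.random.default_rng([cfg.seed, 2, f])
        u = latent[name]
        p = np.exp2(u - u.max())
        p /= p.sum()
        n_bg = int(round(cfg.background_fraction * cfg.tags_per_factor))
        n_fg = cfg.tags_per_factor - n_bg
        counts = rng.multinomial(n_fg, p)
        offset, spread = cfg.spatial_profile[name]
        gene_idx = np.repeat(np.arange(cfg.n_genes), counts)
        d = offset + spread * rng.standard_normal(n_fg)
        fg = tss[gene_idx] + sign[gene_idx] * np.rint(d).astype(np.int64)
        bg = rng.integers(0, cfg.chrom_length, n_bg)
        pos = np.clip(np.concatenate([fg, bg]), 0, cfg.chrom_length - 1)
        tracks.append(
            TagTrack(
                factor_name=name,
                factor_class=cfg.factor_class(name),
                positions=pos,
                chrom=cfg.chrom,
                ground_truth={
                    "log_intensity": u,
                    "effect_weight": cfg.effect_weights[name],
                    "offset": offset,
                    "spread": spread,
                    "noise_sd": cfg.noise_sd,
                    "redundant_with": partner.get(name, (None, None))[0],
                    "target_correlation": partner.get(name, (None, None))[1],
                    "n_background": n_bg,
                },
            )
        )
    return tracks


@dataclass
class GeneSetCollection:
    """Synthetic gene sets with their ground-truth bias labels."""

    sets: dict
    labels: dict


def _class_noise_scores(genes: pd.DataFrame, tracks, pseudocount: float):
    """Per-gene mean standardized |residual| of each class's latent
    intensities after regressing out log-expression — large means the class
    tracks expression poorly for that gene."""
    z = _standardize(log_expression(genes, pseudocount))
    by_class = {"TF": [], "HM": []}
    for t in tracks:
        u = t.ground_truth["log_intensity"]
        b = float(np.mean(_standardize(u) * z))
        resid = _standardize(u) - b * z
        score = np.abs(resid) / resid.std()
        by_class["TF" if t.factor_class == "TF" else "HM"].append(score)
    return {k: np.mean(v, axis=0) for k, v in by_class.items() if v}


def simulate_gene_sets(
    genes: pd.DataFrame,
    n_sets: int,
    size_range: tuple,
    bias,
    seed: int,
    tracks=None,
    sharpness: float = 8.0,
    within=None,
) -> GeneSetCollection:
    """Gene sets biased toward genes better explained by one factor class.

    ``bias`` gives one label per set from ``GENE_SET_BIASES``. TF-favoured
    sets preferentially contain genes whose TF latent intensities track
    expression tightly while the HM intensities do not (and symmetrically);
    neutral sets are uniform samples. Selection uses Gumbel top-k on the
    bias score so sets vary across seeds. ``within`` restricts members to
    the given gene ids (e.g. the high-expressed subset).
    """
    lo, hi = size_range
    if lo > hi:
        raise ConfigError(f"size_range inverted: {size_range}")
    eligible = (
        genes["id"].isin(set(within)).to_numpy()
        if within is not None
        else np.ones(len(genes), dtype=bool)
    )
    if hi > int(eligible.sum()):
        raise ConfigError("max set size exceeds number of eligible genes")
    bias = list(bias)
    if len(bias) != n_sets:
        raise ConfigError(f"need {n_sets} bias labels, got {len(bias)}")
    for b in bias:
        if b not in GENE_SET_BIASES:
            raise ConfigError(f"unknown bias label {b!r}")
    if n_sets == 0:
        return GeneSetCollection({}, {})
    if tracks is None and any(b != "neutral" for b in bias):
        raise ConfigError("biased gene sets require the simulated tracks")

    scores = _class_noise_scores(genes, tracks, DEFAULT_PSEUDOCOUNT) if tracks else {}
    ids = genes["id"].to_numpy()
    rng = np.random.default_rng([seed, 4])
    sets, labels = {}, {}
    for j in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        if bias[j] == "TF-favoured":
            score = scores["HM"] - scores["TF"]
        elif bias[j] == "HM-favoured":
            score = scores["TF"] - scores["HM"]
        else:
            score = np.zeros(len(genes))
        key = sharpness * score + rng.gumbel(size=len(genes))
        key[~eligible] = -np.inf
        members = ids[np.argsort(-key)[:size]]
        set_id = f"set{j:03d}"
        sets[set_id] = sorted(members)
        labels[set_id] = bias[j]
    return GeneSetCollection(sets, labels)
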