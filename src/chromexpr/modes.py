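"""Exhaustive factor-subset ("combination mode") analysis.

Every non-empty subset of a factor class is a combination mode; an SVR model
is fit per mode with a shared cross-validation fold assignment so that PCC
differences between modes reflect the feature sets, not fold noise. The
summary reproduces the analysis style of the redundancy study: per-cardinality
maximum-PCC curve, the modes at a fixed cardinality reaching a fraction
(default 95%) of the all-factor PCC, and per-factor frequency / pairwise
co-occurrence among those top modes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np

from .association import AssociationMatrix
from .errors import ChromexprError, ConfigError, SizingError
from .models import ModelConfig, fit_svr

MAX_ENUMERABLE_FACTORS = 20


@dataclass(frozen=True)
class ModeResult:
    """CV PCC of one factor subset."""

    subset: tuple  # sorted factor names
    cardinality: int
    pcc: float


@dataclass
class ModeSummary:
    max_curve: dict  # cardinality -> max pcc
    all_factor_pcc: float
    top_modes: list  # ModeResult at the summary cardinality passing threshold
    factor_frequency: dict  # name -> (count, fraction of top modes)
    cooccurrence: dict  # frozenset({a, b}) -> joint count; {a} -> frequency
    cardinality: int = 4
    threshold_fraction: float = 0.95

    def cooccurrence_count(self, a: str, b: str) -> int:
        """Joint top-mode count of factors a and b; a == b gives a's frequency."""
        return self.cooccurrence.get(frozenset((a, b)), 0)


def enumerate_modes(factor_names) -> list:
    """All 2^n - 1 non-empty subsets, ordered by (cardinality, lexicographic)."""
    names = sorted(factor_names)
    if len(set(names)) != len(names):
        raise ConfigError("duplicate factor names")
    if not 1 <= len(names) <= MAX_ENUMERABLE_FACTORS:
        raise SizingError(
            f"can enumerate 1..{MAX_ENUMERABLE_FACTORS} factors, got {len(names)}"
        )
    out = []
    for c in range(1, len(names) + 1):
        out.extend(combinations(names, c))
    return out


def evaluate_modes(subsets, assoc: AssociationMatrix, y, model_cfg: ModelConfig | None = None,
                   seed: int = 0) -> list:
    """One cross-validated SVR PCC per subset, shared folds across subsets."""
    cfg = model_cfg or ModelConfig()
    seen = set()
    unique = []
    for s in subsets:
        key = tuple(sorted(s))
        if key in seen:
            warnings.warn(f"duplicate subset {key} dropped", stacklevel=2)
            continue
        seen.add(key)
        unique.append(key)
    results = []
    y = np.asarray(y, dtype=float)
    for key in unique:
        try:
            report = fit_svr(assoc.subset(key), y, folds=cfg.folds, seed=seed, kernel_cfg=cfg)
        except ChromexprError as exc:
            raise type(exc)(f"mode {key}: {exc}") from exc
        results.append(ModeResult(subset=key, cardinality=len(key), pcc=report.pcc))
    return results


def _check_full(results, n_factors: int) -> None:
    expected = 2 ** n_factors - 1
    if len(results) != expected:
        raise ConfigError(
            f"results cover {len(results)} subsets; full enumeration of "
            f"{n_factors} factors has {expected}"
        )
    by_card = {}
    for r in results:
        by_card[r.cardinality] = by_card.get(r.cardinality, 0) + 1
    for c, n in by_card.items():
        if n != comb(n_factors, c):
            raise ConfigError(f"cardinality {c}: {n} subsets, expected {comb(n_factors, c)}")


def summarize_modes(results, cardinality: int = 4, threshold_fraction: float = 0.95,
                    restrict_to=None) -> ModeSummary:
    """Max-PCC curve plus over-representation counts among top modes.

    ``restrict_to``, if given, limits the top-mode pool to subsets drawn from
    that factor list (e.g. HMs only, excluding DNase) without touching the
    max curve or the all-factor reference.
    """
    results = list(results)
    all_factors = sorted({f for r in results for f in r.subset})
    _check_full(results, len(all_factors))
    max_curve = {}
    for r in results:
        if r.cardinality not in max_curve or r.pcc > max_curve[r.cardinality]:
            max_curve[r.cardinality] = r.pcc
    (full,) = [r for r in results if r.cardinality == len(all_factors)]
    pool = [r for r in results if r.cardinality == cardinality]
    if restrict_to is not None:
        allowed = set(restrict_to)
        pool = [r for r in pool if set(r.subset) <= allowed]
    if not pool:
        warnings.warn(f"no subsets at cardinality {cardinality}", stacklevel=2)
    top = sorted(
        (r for r in pool if r.pcc >= threshold_fraction * full.pcc),
        key=lambda r: (-r.pcc, r.subset),
    )
    freq = {f: 0 for f in all_factors}
    cooc: dict = {}
    for r in top:
        for f in r.subset:
            freq[f] += 1
        for a, b in combinations(r.subset, 2):
            key = frozenset((a, b))
            cooc[key] = cooc.get(key, 0) + 1
    for f, n in freq.items():
        cooc[frozenset((f,))] = n
    n_top = len(top)
    return ModeSummary(
        max_curve=dict(sorted(max_curve.items())),
        all_factor_pcc=full.pcc,
        top_modes=top,
        factor_frequency={f: (n, n / n_top if n_top else 0.0) for f, n in freq.items()},
        cooccurrence=cooc,
        cardinality=cardinality,
        threshold_fraction=threshold_fraction,
    )


def best_mode_at(results, cardinality: int) -> ModeResult:
    """Highest-PCC subset of the given size; ties broken lexicographically."""
    pool = sorted(
        (r for r in results if r.cardinality == cardinality),
        key=lambda r: (-r.pcc, r.subset),
    )
    if not pool:
        raise ConfigError(f"no subsets of cardinality {cardinality}")
    if len(pool) > 1 and pool[1].pcc == pool[0].pcc:
        warnings.warn(
            f"tie at cardinality {cardinality}: {pool[0].subset} vs {pool[1].subset}",
            stacklevel=2,
        )
    return pool[0]
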