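"""Stepwise selection of the most predictive TFs.

Bidirectional (forward with backward pruning) stepwise OLS regression of
log-expression on candidate association columns, capped at 15 factors by
default. The entry/removal criterion is AIC by default; a classical
partial-F-test variant (p_enter = 0.05, p_remove = 0.10) is available. Ties
are broken lexicographically by factor name so the result is independent of
candidate column order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DegenerateSampleError

_TOL = 1e-10


@dataclass
class SelectionReport:
    """Ordered record of the stepwise path."""

    ranked_factors: list  # (step, factor_name, criterion value at entry)
    cap: int
    criterion_kind: str

    @property
    def selected(self) -> list:
        return [name for _, name, _ in self.ranked_factors]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    return float(r @ r)


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * (k + 1)


def stepwise_select(X, y, cap: int = 15, criterion: str = "aic",
                    p_enter: float = 0.05, p_remove: float = 0.10) -> SelectionReport:
    """Select up to ``cap`` factors by bidirectional stepwise regression.

    Stops when no candidate improves the criterion (AIC decrease, or
    partial-F entry test) or the cap is reached; after each addition a
    backward pass drops any included factor whose removal improves the
    criterion.
    """
    if criterion not in ("aic", "f_test"):
        raise ConfigError(f"unknown criterion {criterion!r}")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{j}" for j in X.columns]
    y = np.asarray(y, dtype=float)
    names = sorted(X.columns)
    n = len(y)
    if n <= cap + 1:
        raise DegenerateSampleError("need n_genes > cap + 1")
    if cap > len(names):
        warnings.warn(
            f"cap {cap} exceeds candidate count {len(names)}; selecting from all",
            stacklevel=2,
        )

    def cols(sel):
        return X[sel].to_numpy(dtype=float) if sel else np.empty((n, 0))

    selected: list = []
    entry: list = []
    current_rss = _rss(cols(selected), y)
    while len(selected) < cap:
        best_name, best_val, best_rss = None, None, None
        for name in names:
            if name in selected:
                continue
            rss = _rss(cols(selected + [name]), y)
            if criterion == "aic":
                val = _aic(rss, n, len(selected) + 1)
                cur = _aic(current_rss, n, len(selected))
                better = val < cur - _TOL
            else:
                df2 = n - len(selected) - 2
                f = (current_rss - rss) / max(rss / df2, 1e-300)
                val = float(stats.f.sf(f, 1, df2))
                better = val < p_enter
            if better and (best_val is None or val < best_val - _TOL):
                best_name, best_val, best_rss = name, val, rss
        if best_name is None:
            break
        selected.append(best_name)
        entry.append((len(entry) + 1, best_name, float(best_val)))
        current_rss = best_rss

        # backward pass: drop anything whose removal now improves the criterion
        changed = True
        while changed and len(selected) > 1:
            changed = False
            for name in sorted(selected):
                if name == best_name:
                    continue
                rest = [s for s in selected if s != name]
                rss = _rss(cols(rest), y)
                if criterion == "aic":
                    drop = _aic(rss, n, len(rest)) < _aic(current_rss, n, len(selected)) - _TOL
                else:
                    df2 = n - len(selected) - 1
                    f = (rss - current_rss) / max(current_rss / df2, 1e-300)
                    drop = float(stats.f.sf(f, 1, df2)) > p_remove
                if drop:
                    selected = rest
                    entry = [e for e in entry if e[1] != name]
                    current_rss = rss
                    changed = True
                    break

    return SelectionReport(ranked_factors=entry, cap=cap, criterion_kind=criterion)
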