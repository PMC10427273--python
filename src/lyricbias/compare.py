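"""WAIC computation and model-comparison tables.

WAIC is computed from the pointwise posterior log-likelihood matrix:
lppd = sum_i log mean_s exp(ll_si) (stable log-sum-exp), the effective
parameter count p_waic = sum_i var_s(ll_si), and
waic = -2 (lppd - p_waic).  Comparison reports per-model deltas against
the best model, standard errors of the deltas from the pointwise
contributions, and Akaike-style weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

__all__ = ["WaicResult", "ComparisonTable", "waic", "compare", "TIME_SERIES_CAVEAT"]

TIME_SERIES_CAVEAT = (
    "Model comparison by information criteria is less robust for "
    "time-series-structured data; interpret full-model coefficients rather "
    "than relying on WAIC ranking alone."
)


@dataclass(frozen=True)
class WaicResult:
    lppd: float
    p_waic: float
    waic: float
    se: float
    pointwise: np.ndarray  # per-row -2*(lppd_i - p_i)

    @property
    def n_rows(self) -> int:
        return self.pointwise.size


def waic(pointwise_loglik: np.ndarray) -> WaicResult:
    """WAIC from a (draws x rows) pointwise log-likelihood matrix."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim != 2:
        raise ValueError("expected a draws x rows matrix")
    n_draws, n_rows = ll.shape
    if n_draws < 2 or n_rows < 1:
        raise ValueError("need at least 2 draws and 1 row")
    finite = np.isfinite(ll).all(axis=0)
    if not finite.all():
        bad = int(np.flatnonzero(~finite)[0])
        raise ValueError(f"non-finite log-likelihood entries at row {bad}")
    lppd_i = logsumexp(ll, axis=0) - np.log(n_draws)
    p_i = np.var(ll, axis=0, ddof=1)
    pointwise = -2.0 * (lppd_i - p_i)
    lppd = float(np.sum(lppd_i))
    p_waic = float(np.sum(p_i))
    total = float(np.sum(pointwise))
    se = float(np.sqrt(n_rows * np.var(pointwise, ddof=1))) if n_rows > 1 else 0.0
    return WaicResult(lppd=lppd, p_waic=p_waic, waic=total, se=se, pointwise=pointwise)


@dataclass
class ComparisonTable:
    labels: list[str]
    waic: np.ndarray
    se: np.ndarray
    d_waic: np.ndarray
    d_se: np.ndarray
    weight: np.ndarray
    caveat: str = TIME_SERIES_CAVEAT

    @property
    def best(self) -> str:
        return self.labels[int(np.argmin(self.waic))]

    def to_frame(self):
        import pandas as pd

        order = np.argsort(self.waic)
        return pd.DataFrame(
            {
                "model": [self.labels[i] for i in order],
                "waic": self.waic[order],
                "se": self.se[order],
                "d_waic": self.d_waic[order],
                "d_se": self.d_se[order],
                "weight": self.weight[order],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def compare(results: list[WaicResult], labels: list[str] | None = None) -> ComparisonTable:
    """Rank models by WAIC; all results must share the same row set."""
    if not results:
        raise ValueError("no models to compare")
    labels = labels or [f"model{i}" for i in range(len(results))]
    if len(labels) != len(results):
        raise ValueError("labels/results length mismatch")
    n_rows = results[0].n_rows
    if any(r.n_rows != n_rows for r in results):
        raise ValueError("mismatched row counts between models")
    waics = np.array([r.waic for r in results])
    ses = np.array([r.se for r in results])
    best = int(np.argmin(waics))
    d_waic = waics - waics[best]
    d_se = np.empty(len(results))
    for i, r in enumerate(results):
        diff = r.pointwise - results[best].pointwise
        d_se[i] = (
            float(np.sqrt(n_rows * np.var(diff, ddof=1)))
            if (i != best and n_rows > 1)
            else 0.0
        )
    rel = np.exp(-0.5 * (d_waic - d_waic.min()))
    weight = rel / rel.sum()
    warnings.warn(TIME_SERIES_CAVEAT, UserWarning, stacklevel=2)
    return ComparisonTable(
        labels=list(labels), waic=waics, se=ses, d_waic=d_waic, d_se=d_se, weight=weight
    )
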