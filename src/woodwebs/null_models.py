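"""Fixed-marginal (Patefield) null models and significance machinery.

The null hypothesis for every network metric is conditional
independence of hosts and beetles given the observed marginal totals:
random contingency tables with exactly the observed row and column
sums, distributed as the multiple hypergeometric distribution.  Tables
are drawn with Patefield's algorithm (``scipy.stats.random_table``).

Significance: add-one empirical p-values (never zero) for WNODF, H2'
and niche overlap; a z-score against the null mean/SD for modularity,
with z >= 2 read as a significantly modular network.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import InteractionMatrix
from . import network_metrics as nm

logger = logging.getLogger(__name__)

__all__ = ["NullEnsemble", "patefield_sample", "null_test", "METRICS"]


def patefield_sample(
    row_totals: np.ndarray,
    col_totals: np.ndarray,
    seed: int | np.random.Generator | None = None,
    size: int = 1,
) -> np.ndarray:
    """Random contingency table(s) with exactly the given marginals.

    Draws from the multiple hypergeometric distribution via Patefield's
    algorithm.  Returns shape ``(n_rows, n_cols)`` for ``size=1``, else
    ``(size, n_rows, n_cols)``.
    """
    r = np.asarray(row_totals, dtype=np.int64)
    c = np.asarray(col_totals, dtype=np.int64)
    if (r < 0).any() or (c < 0).any():
        raise ValueError("marginal totals must be non-negative")
    if r.sum() != c.sum():
        raise ValueError(
            f"marginal totals disagree: sum(rows)={r.sum()} != sum(cols)={c.sum()}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = stats.random_table(r, c)
    out = dist.rvs(size, method="patefield", random_state=rng).astype(np.int64)
    return out[0] if size == 1 else out


def _metric_wnodf(mat: InteractionMatrix, **kw) -> float:
    return nm.wnodf(mat)


def _metric_h2(mat: InteractionMatrix, **kw) -> float:
    return nm.h2_prime(mat)


def _metric_overlap_host(mat: InteractionMatrix, **kw) -> float:
    return nm.niche_overlap(mat, "host")


def _metric_overlap_beetle(mat: InteractionMatrix, **kw) -> float:
    return nm.niche_overlap(mat, "beetle")


def _metric_modularity(mat: InteractionMatrix, *, n_trials=20, seed=None) -> float:
    return nm.modularity_lp(mat, n_trials=n_trials, seed=seed)[1]


METRICS: dict[str, Callable] = {
    "wnodf": _metric_wnodf,
    "h2": _metric_h2,
    "niche_overlap_host": _metric_overlap_host,
    "niche_overlap_beetle": _metric_overlap_beetle,
    "modularity": _metric_modularity,
}


@dataclass
class NullEnsemble:
    """Observed metric, its fixed-marginal null distribution, and the
    derived p-value and z-score."""

    metric: str
    observed: float
    null_values: np.ndarray
    p_value: float
    z_score: float
    tail: str
    n_rand: int
    seed: int | None

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    def significant(self, alpha: float = 0.01, z_threshold: float = 2.0) -> bool:
        if self.metric == "modularity":
            return self.z_score >= z_threshold
        return self.p_value < alpha


def null_test(
    matrix: InteractionMatrix,
    metric: str,
    n_rand: int = 1000,
    tail: str = "auto",
    seed: int | None = None,
    *,
    n_trials_null: int = 5,
    n_trials_obs: int = 20,
) -> NullEnsemble:
    """Test one network metric against the Patefield null.

    p = (1 + #{null >= obs}) / (1 + n_rand) for the upper tail (the
    lower tail is mirrored; ``tail='auto'`` picks the direction from
    the sign of obs - null mean).  z = (obs - mean(null)) / sd(null),
    sample SD.  Modularity nulls are re-optimized per draw with
    ``n_trials_null`` restarts.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if tail not in ("auto", "upper", "lower"):
        raise ValueError(f"tail must be auto/upper/lower, got {tail!r}")
    rng = np.random.default_rng(seed)
    fn = METRICS[metric]
    obs_kwargs = {"n_trials": n_trials_obs, "seed": rng} if metric == "modularity" else {}
    observed = fn(matrix, **obs_kwargs)
    null_vals = np.empty(n_rand)
    for k in range(n_rand):
        for attempt in range(2):
            table = patefield_sample(matrix.row_totals, matrix.col_totals, rng)
            null_mat = InteractionMatrix(matrix.hosts, matrix.beetles, table)
            kw = {"n_trials": n_trials_null, "seed": rng} if metric == "modularity" else {}
            try:
                null_vals[k] = fn(null_mat, **kw)
                break
            except Exception:
                if attempt == 1:
                    raise
                logger.warning("metric %s failed on a null draw; resampling once", metric)
    mean = null_vals.mean()
    sd = null_vals.std(ddof=1)
    if tail == "auto":
        tail = "upper" if observed >= mean else "lower"
    if tail == "upper":
        p = (1 + int((null_vals >= observed).sum())) / (1 + n_rand)
    else:
        p = (1 + int((null_vals <= observed).sum())) / (1 + n_rand)
    if sd > 0:
        z = (observed - mean) / sd
    else:
        warnings.warn(f"null distribution of {metric} is degenerate; z reported as 0")
        z = 0.0
    return NullEnsemble(
        metric=metric,
        observed=float(observed),
        null_values=null_vals,
        p_value=float(p),
        z_score=float(z),
        tail=tail,
        n_rand=n_rand,
        seed=seed,
    )


def null_report(
    matrix: InteractionMatrix,
    metrics: tuple[str, ...] = tuple(METRICS),
    n_rand: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run ``null_test`` for several metrics; one row per metric."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for metric, child in zip(metrics, ss.spawn(len(metrics))):
        ens = null_test(
            matrix, metric, n_rand=n_rand,
            seed=int(child.generate_state(1)[0] % (2**31)), **kwargs,
        )
        rows.append(
            {
                "metric": metric,
                "observed": ens.observed,
                "null_mean": ens.null_mean,
                "null_sd": ens.null_sd,
                "p": ens.p_value,
                "z": ens.z_score,
                "significant": ens.significant(),
            }
        )
    return pd.DataFrame(rows)
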