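"""Entropy and irreversibility metrics for gait time series.

Four per-cycle, per-series scalars:

* **Shannon entropy (SE)** — uncertainty of the value distribution,
  ``E = -sum_i p(i) ln p(i)`` over ``B = round(sqrt(N))`` equal-width bins
  spanning the series range.  Zero for a constant series; at most ``ln B``.
* **Permutation entropy (PE)** — Shannon entropy of the distribution of
  ordinal patterns: each length-``D`` sub-window is mapped to the
  permutation that sorts its values, ``PE = -sum_i p(pi_i) ln p(pi_i)``.
  ``D = 4`` by default (short per-cycle series), delay 1.
* **Weighted permutation entropy (WPE)** — permutation entropy with each
  window weighted by its variance ``w = (1/D) sum_k (x_k - xbar)^2``, so
  that low-amplitude (noise-dominated) patterns contribute little.  The
  weighted probabilities are normalised to sum to one.
* **BDS statistic** — the Brock-Dechert-Scheinkman z-statistic
  ``W = sqrt(M) (C_m(eps) - C_1(eps)^m) / sigma_m(eps)`` comparing the
  m-dimensional correlation integral with its i.i.d. expectation;
  asymptotically standard normal under independence, and increasingly
  negative/positive for dynamics with memory.  Here ``C_1`` is estimated
  on the full sample, which makes the statistic exactly invariant under
  time reversal.

All entropies use the natural logarithm (nats).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .data import Cohort

__all__ = [
    "UndefinedMetricError",
    "OrdinalDistribution",
    "shannon_entropy",
    "ordinal_patterns",
    "permutation_entropy",
    "weighted_permutation_entropy",
    "correlation_integral",
    "bds_statistic",
    "compute_features",
    "features_to_wide",
    "METRICS",
]

METRICS = ("SE", "PE", "WPE", "BDS")


class UndefinedMetricError(ValueError):
    """A metric has no defined value for this input (e.g. WPE of a constant)."""


def _check_series(series, min_len: int) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"series must be 1-d, got shape {x.shape}")
    if x.size < min_len:
        raise ValueError(f"series needs >= {min_len} samples, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


def shannon_entropy(series) -> float:
    """Shannon entropy (nats) of the binned value distribution.

    Bin count is ``round(sqrt(N))``; bins are equal-width over
    ``[min, max]`` of this series.  A constant series has entropy 0.
    """
    x = _check_series(series, 4)
    lo, hi = x.min(), x.max()
    if lo == hi:
        return 0.0
    n_bins = int(np.round(np.sqrt(x.size)))
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-np.sum(p * np.log(p)))


@dataclass
class OrdinalDistribution:
    """Counts and summed variance-weights of ordinal patterns.

    Keys are permutation tuples (positions of the ascending sort, ties
    broken towards the earlier sample).
    """

    D: int
    tau: int
    counts: dict[tuple[int, ...], int] = field(default_factory=dict)
    weights: dict[tuple[int, ...], float] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return sum(self.counts.values())

    @property
    def total_weight(self) -> float:
        return sum(self.weights.values())


def _ordinal_windows(x: np.ndarray, D: int, tau: int) -> np.ndarray:
    span = (D - 1) * tau + 1
    return sliding_window_view(x, span)[:, ::tau]


def ordinal_patterns(series, D: int = 4, tau: int = 1) -> OrdinalDistribution:
    """Tally the ordinal patterns of all delay-embedded sub-windows.

    Each window of ``D`` samples (delay ``tau``) is mapped to the
    permutation that sorts it ascending; per-symbol counts and summed
    window variances are recorded.
    """
    if D < 2:
        raise ValueError("embedding dimension D must be >= 2")
    if tau < 1:
        raise ValueError("embedding delay tau must be >= 1")
    x = _check_series(series, (D - 1) * tau + 1)
    windows = _ordinal_windows(x, D, tau)
    n_win = windows.shape[0]
    if n_win < 2 * D:
        warnings.warn(
            f"only {n_win} ordinal windows for D={D}, tau={tau}; "
            "pattern frequencies are poorly determined",
            stacklevel=2,
        )
    perms = np.argsort(windows, axis=1, kind="stable")
    var = windows.var(axis=1)
    dist = OrdinalDistribution(D=D, tau=tau)
    # encode permutations as base-D integers for a vectorised tally
    codes = perms @ (D ** np.arange(D))
    order = np.argsort(codes, kind="stable")
    codes_sorted = codes[order]
    boundaries = np.flatnonzero(np.diff(codes_sorted)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n_win]))
    var_sorted = var[order]
    cumvar = np.concatenate(([0.0], np.cumsum(var_sorted)))
    for s, e in zip(starts, ends):
        symbol = tuple(int(v) for v in perms[order[s]])
        dist.counts[symbol] = int(e - s)
        dist.weights[symbol] = float(cumvar[e] - cumvar[s])
    return dist


def _entropy_of(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def permutation_entropy(series, D: int = 4, tau: int = 1) -> float:
    """Permutation entropy (nats); 0 for monotone series, at most ln(D!)."""
    dist = ordinal_patterns(series, D, tau)
    counts = np.array(list(dist.counts.values()), dtype=float)
    return _entropy_of(counts / counts.sum())


def weighted_permutation_entropy(series, D: int = 4, tau: int = 1) -> float:
    """Variance-weighted permutation entropy (nats).

    Raises :class:`UndefinedMetricError` when every window has zero
    variance (constant series), since the weighted distribution is then
    undefined.
    """
    dist = ordinal_patterns(series, D, tau)
    total = dist.total_weight
    if total == 0:
        raise UndefinedMetricError(
            "weighted permutation entropy undefined: all windows have zero variance"
        )
    w = np.array(list(dist.weights.values()), dtype=float)
    return _entropy_of(w / total)


def correlation_integral(series, m: int, eps: float) -> float:
    """Fraction of distinct pairs of m-dim delay vectors closer than eps.

    Distance is the max-norm (Chebyshev); the inequality is strict.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    x = _check_series(series, m + 1)
    emb = sliding_window_view(x, m)
    n_vec = emb.shape[0]
    if n_vec < 2:
        raise ValueError("need at least 2 embedding vectors")
    dist = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    iu = np.triu_indices(n_vec, 1)
    return float(np.mean(dist[iu] < eps))


def bds_statistic(series, m: int = 2, eps: float | None = None) -> float:
    """Brock-Dechert-Scheinkman z-statistic for serial independence.

    ``eps`` defaults to ``0.5 * sd(series)`` (sample sd).  Uses the
    published asymptotic variance; the full-sample estimate of ``C_1``
    makes the value exactly invariant under time reversal.
    """
    x = _check_series(series, 20)
    if m < 2:
        raise ValueError("m must be >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise UndefinedMetricError("BDS undefined for a zero-variance series")
    if eps is None:
        eps = 0.5 * sd
    if eps <= 0:
        raise ValueError("eps must be positive")

    n = x.size
    h = (np.abs(x[:, None] - x[None, :]) < eps)
    np.fill_diagonal(h, False)
    hf = h.astype(np.float64)

    c1 = hf.sum() / (n * (n - 1))

    n_vec = n - m + 1
    joint = h[m - 1:, m - 1:].copy()
    for d in range(m - 1):
        joint &= h[d : d + n_vec, d : d + n_vec]
    # joint is symmetric with a False diagonal
    c_m = float(joint.sum()) / (n_vec * (n_vec - 1))

    r = hf.sum(axis=1)
    k = float(np.sum(r**2 - r)) / (n * (n - 1) * (n - 2))

    j = np.arange(1, m)
    var = 4.0 * (
        k**m
        + 2.0 * np.sum(k ** (m - j) * c1 ** (2 * j))
        + (m - 1) ** 2 * c1 ** (2 * m)
        - m**2 * k * c1 ** (2 * m - 2)
    )
    if var <= 0:
        raise UndefinedMetricError("degenerate BDS variance estimate")
    return float(np.sqrt(n_vec) * (c_m - c1**m) / np.sqrt(var))


def _cycle_features(samples, D, tau, bds_m, bds_eps_factor, bds_increments):
    out = {}
    out["SE"] = shannon_entropy(samples)
    dist = ordinal_patterns(samples, D, tau)  # shared by PE and WPE
    counts = np.array(list(dist.counts.values()), dtype=float)
    out["PE"] = _entropy_of(counts / counts.sum())
    total = dist.total_weight
    if total > 0:
        w = np.array(list(dist.weights.values()), dtype=float)
        out["WPE"] = _entropy_of(w / total)
    else:
        out["WPE"] = np.nan
    bx = np.diff(np.asarray(samples, dtype=float)) if bds_increments else np.asarray(
        samples, dtype=float
    )
    if bx.size < 20:  # too short for the asymptotic statistic
        out["BDS"] = np.nan
        return out
    try:
        sd = bx.std(ddof=1)
        out["BDS"] = bds_statistic(bx, m=bds_m, eps=bds_eps_factor * sd)
    except UndefinedMetricError:
        out["BDS"] = np.nan
    return out


def compute_features(
    cohort: Cohort,
    D: int = 4,
    tau: int = 1,
    bds_m: int = 2,
    bds_eps_factor: float = 0.5,
    bds_increments: bool = False,
) -> pd.DataFrame:
    """One row of SE/PE/WPE/BDS per (subject, side, cycle, series).

    Metrics that are undefined for a particular cycle (e.g. WPE of a
    constant series) are recorded as NaN, never dropped.  Hard errors are
    re-raised with the offending cycle's identity attached.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cyc in cohort.cycles:
            rec = cohort.subjects[cyc.subject_id]
            try:
                feats = _cycle_features(cyc.samples, D, tau, bds_m,
                                        bds_eps_factor, bds_increments)
            except Exception as exc:
                raise ValueError(f"metric failure on cycle {cyc.key()}: {exc}") from exc
            rows.append(
                {
                    "subject_id": cyc.subject_id,
                    "group": rec.group,
                    "side": cyc.side,
                    "cycle": cyc.cycle_index,
                    "series": cyc.series_name,
                    **feats,
                }
            )
    return pd.DataFrame(rows)


def features_to_wide(features: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-cycle features to one row per (subject, side, cycle).

    Feature columns are named ``<series>__<metric>``; identity columns
    ``subject_id``, ``group``, ``side``, ``cycle`` are retained.
    """
    wide = (
        features.set_index(["subject_id", "group", "side", "cycle", "series"])[
            list(METRICS)
        ]
        .unstack("series")
    )
    wide.columns = [f"{series}__{metric}" for metric, series in wide.columns]
    return wide.sort_index(axis=1).reset_index()
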