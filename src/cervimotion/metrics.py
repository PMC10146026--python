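"""Repeatability and rank-agreement metrics.

Repeatability of the angle pipeline is measured by running the same
recording n times and taking, per frame, the sample standard deviation

    s = sqrt( sum_i (x_i - xbar)^2 / (n - 1) )

of the estimated angle across runs; the mean of s over frames summarizes
one axis.  Agreement between a benchmark scoring (e.g. physician
assessment) and predicted scores is measured by RMSE, MAE and the
coefficient of determination R^2 (which can go negative when predictions
are worse than the benchmark mean), and on the rank scale by Kendall's
tau-a and rank-biased overlap (RBO).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "framewise_std",
    "regression_metrics",
    "kendall_tau",
    "rbo",
    "ranking_from_scores",
]


def framewise_std(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-frame sample std across repeated runs, and its mean over frames.

    ``values`` is rectangular, shape ``(n_runs, n_frames)`` with
    ``n_runs >= 2``; the divisor is ``n_runs - 1``.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ValueError(f"expected (runs, frames) matrix, got shape {m.shape}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 runs")
    stds = m.std(axis=0, ddof=1)
    return stds, float(stds.mean())


def regression_metrics(benchmark, predicted) -> tuple[float, float, float]:
    """RMSE, MAE and R^2 of predictions against a benchmark.

    ``r2 = 1 - SS_res/SS_tot`` with ``SS_tot`` about the benchmark mean;
    it is negative when predictions underperform the constant-mean
    predictor.  A constant benchmark leaves R^2 undefined.
    """
    b = np.asarray(benchmark, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if b.shape != p.shape or b.ndim != 1:
        raise ValueError("benchmark and predicted must be 1-D and equal length")
    if len(b) < 2:
        raise ValueError("need at least 2 pairs")
    resid = b - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((b - b.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant benchmark: R^2 undefined")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return rmse, mae, r2


def kendall_tau(benchmark, predicted) -> float:
    """Kendall's tau-a: (concordant - discordant) / (n(n-1)/2).

    Tied pairs (in either list) count as neither concordant nor
    discordant; the denominator is not tie-corrected.
    """
    b = np.asarray(benchmark, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if b.shape != p.shape or b.ndim != 1 or len(b) < 2:
        raise ValueError("need two equal-length 1-D arrays with n >= 2")
    n = len(b)
    db = np.sign(b[:, None] - b[None, :])
    dp = np.sign(p[:, None] - p[None, :])
    prod = np.triu(db * dp, k=1)
    concordant = int((prod > 0).sum())
    discordant = int((prod < 0).sum())
    return (concordant - discordant) / (n * (n - 1) / 2)


def ranking_from_scores(scores, ids=None) -> list:
    """Item identifiers sorted by descending score; ties broken by identifier.

    Deterministic tie handling keeps rank-based metrics reproducible.
    """
    scores = list(scores)
    if ids is None:
        ids = list(range(len(scores)))
    ids = list(ids)
    if len(ids) != len(scores):
        raise ValueError("ids and scores must have equal length")
    return [i for _, i in sorted(zip(scores, ids), key=lambda t: (-t[0], t[1]))]


def rbo(ranking_a, ranking_b, persistence: float = 0.9) -> float:
    """Extrapolated rank-biased overlap of two equal-length rankings.

    With overlap ``X_d = |A[:d] & B[:d]|`` and agreement ``X_d / d``, the
    extrapolated RBO at full depth n is::

        RBO = (X_n / n) * p^n + (1 - p)/p * sum_{d=1..n} (X_d / d) * p^d

    where ``p`` (the persistence) weights agreement toward the top of the
    rankings.  Identical rankings give 1; rankings over disjoint item sets
    give 0.
    """
    if not 0.0 < persistence < 1.0:
        raise ValueError("persistence must be in (0, 1)")
    a, b = list(ranking_a), list(ranking_b)
    if len(a) != len(b) or not a:
        raise ValueError("rankings must be non-empty and equal length")
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("rankings must not repeat items")
    n = len(a)
    p = persistence
    seen_a: set = set()
    seen_b: set = set()
    x = 0  # running overlap |A[:d] & B[:d]|
    acc = 0.0
    for d in range(1, n + 1):
        ia, ib = a[d - 1], b[d - 1]
        if ia == ib:
            x += 1
        else:
            x += (ia in seen_b) + (ib in seen_a)
        seen_a.add(ia)
        seen_b.add(ib)
        acc += (x / d) * p**d
    return (x / n) * p**n + (1 - p) / p * acc
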