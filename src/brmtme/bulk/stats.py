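"""Correlation with bootstrap CIs and Kaplan–Meier / log-rank survival tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as ss


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p: float
    ci_low: float
    ci_high: float
    n: int


def correlate_bootstrap(
    x, y, n_boot: int = 1000, seed: int | None = None
) -> CorrelationResult:
    """Pearson correlation with a patient-level percentile bootstrap CI.

    Pairs (x_i, y_i) are resampled with replacement ``n_boot`` times; the CI
    is the 2.5/97.5 percentile interval of the resampled correlations.
    Resamples with zero variance in either coordinate are redrawn implicitly
    by being skipped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    r, p = ss.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    n = x.size
    while len(boots) < n_boot:
        idx = rng.integers(0, n, size=n)
        bx, by = x[idx], y[idx]
        if np.std(bx) == 0 or np.std(by) == 0:
            continue
        boots.append(ss.pearsonr(bx, by)[0])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(
        r=float(r), r2=float(r * r), p=float(p), ci_low=float(lo), ci_high=float(hi), n=n
    )


@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # stratum -> KM survival function
    chi2: float
    p: float
    n_events: int


def km_logrank(surv: pd.DataFrame, strata: pd.Series | dict) -> KMResult:
    """Product-limit curves per stratum and the log-rank test between them.

    Parameters
    ----------
    surv : DataFrame with columns ``patient``, ``time``, ``event`` (1 = death).
    strata : patient -> group label; patients without a label are dropped.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test, multivariate_logrank_test

    if isinstance(strata, dict):
        strata = pd.Series(strata)
    df = surv.copy()
    df["stratum"] = df["patient"].map(strata)
    df = df.dropna(subset=["stratum"])
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise ValueError("no events in survival table")
    groups = df["stratum"].unique()
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 strata")

    curves = {}
    for g, sub in df.groupby("stratum"):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"], label=str(g))
        curves[str(g)] = kmf.survival_function_

    if len(groups) == 2:
        a = df[df["stratum"] == groups[0]]
        b = df[df["stratum"] == groups[1]]
        res = logrank_test(a["time"], b["time"], a["event"], b["event"])
    else:
        res = multivariate_logrank_test(df["time"], df["stratum"], df["event"])
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        p=float(res.p_value),
        n_events=n_events,
    )
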