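"""Shared numerical helpers: seeded substreams, geometric means, exact tests."""

from __future__ import annotations

import hashlib
import itertools
import logging
from math import comb

import numpy as np

logger = logging.getLogger("brmtme")


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-stage RNG derived from one global integer seed.

    The stage name is hashed so adding a stage never perturbs the streams of
    existing stages.
    """
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng([int(seed), h])


def geomean(x) -> float:
    """Geometric mean; 0 if any entry is 0 (counts are non-negative)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("geometric mean of empty array")
    if np.any(x < 0):
        raise ValueError("geometric mean requires non-negative values")
    if np.any(x == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(x))))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of all label assignments.

    Feasible for group sizes <= ~9. Handles ties correctly because the
    permutation distribution is built on the observed pooled values.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    nx = len(x)
    u_obs = _u_stat(x, y)
    n = len(pooled)
    total = comb(n, nx)
    # two-sided: count assignments whose U is at least as extreme (by distance
    # from the null mean nx*ny/2) as the observed one
    mid = nx * (n - nx) / 2.0
    d_obs = abs(u_obs - mid)
    count = 0
    idx = set(range(n))
    for xs in itertools.combinations(range(n), nx):
        xv = [pooled[i] for i in xs]
        yv = [pooled[i] for i in idx - set(xs)]
        if abs(_u_stat(xv, yv) - mid) >= d_obs - 1e-12:
            count += 1
    return count / total


def _u_stat(x, y) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact Wilcoxon signed-rank p by enumerating all 2^n sign flips.

    Zero differences are dropped (Wilcoxon convention); ties among |d| are
    mid-ranked. Feasible for n <= ~16.
    """
    import scipy.stats as ss

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    ranks = ss.rankdata(np.abs(d))
    w_obs = float(ranks[d > 0].sum())
    mid = n * (n + 1) / 4.0
    d_obs = abs(w_obs - mid)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = float(sum(r for s, r in zip(signs, ranks) if s))
        if abs(w - mid) >= d_obs - 1e-12:
            count += 1
    return count / 2**n


def benjamini_hochberg(p) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, clipped at 1)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
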