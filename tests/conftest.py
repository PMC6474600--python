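"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use sorting and explicit Python loops — no
vectorized shortcuts — so they stay independent of the implementation
paths they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from petrim import PhantomSpec, make_phantom


# --------------------------------------------------------------------------
# Brute-force oracles


def bf_quantile(sorted_vals: list[float], p: float) -> float:
    """Linear interpolation between order statistics."""
    n = len(sorted_vals)
    h = (n - 1) * p
    lo = int(math.floor(h))
    if lo >= n - 1:
        return sorted_vals[n - 1]
    frac = h - lo
    return sorted_vals[lo] + frac * (sorted_vals[lo + 1] - sorted_vals[lo])


def bf_statistics(values) -> dict[str, float]:
    """Loop-based boxplot/moment statistics."""
    s = sorted(float(v) for v in values)
    n = len(s)
    mean = sum(s) / n
    var = sum((x - mean) ** 2 for x in s) / n
    q1 = bf_quantile(s, 0.25)
    med = bf_quantile(s, 0.50)
    q3 = bf_quantile(s, 0.75)
    fence = q3 + 1.5 * (q3 - q1)
    upper_adjacent = max(x for x in s if x <= fence)
    return {
        "Max": s[-1],
        "Min": s[0],
        "Mean": mean,
        "Std": math.sqrt(var),
        "RMS": math.sqrt(sum(x * x for x in s) / n),
        "1st Quartile": q1,
        "Median": med,
        "3rd Quartile": q3,
        "Upper Adjacent": upper_adjacent,
    }


def bf_quarter_bins(values) -> list[list[float]]:
    """Assign each value to its grayscale quarter by explicit comparison."""
    vals = [float(v) for v in values]
    lo, hi = min(vals), max(vals)
    r = hi - lo
    bins: list[list[float]] = [[], [], [], []]
    for v in vals:
        if r == 0:
            bins[0].append(v)
            continue
        placed = False
        for k in range(3):
            if lo + k * r / 4 <= v < lo + (k + 1) * r / 4:
                bins[k].append(v)
                placed = True
                break
        if not placed:  # last quarter is closed at the top
            bins[3].append(v)
    return bins


def bf_rim(lesion: np.ndarray, width: int) -> np.ndarray:
    """Voxels at city-block distance 1..width from the lesion."""
    coords = [tuple(c) for c in np.argwhere(lesion)]
    out = np.zeros_like(lesion, dtype=bool)
    for v in np.ndindex(lesion.shape):
        if lesion[v]:
            continue
        d = min(
            abs(v[0] - c[0]) + abs(v[1] - c[1]) + abs(v[2] - c[2])
            for c in coords
        )
        if d <= width:
            out[v] = True
    return out


def bf_concordance(risk, time, event) -> float:
    """All-pairs Harrell concordance; risk ties count 1/2.

    A pair is usable when the shorter observed time is an event; the
    higher-risk member should have the shorter survival.
    """
    risk = [float(r) for r in risk]
    time = [float(t) for t in time]
    event = [int(e) for e in event]
    n = len(risk)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            short, long_ = (i, j) if time[i] < time[j] else (j, i)
            if not event[short]:
                continue
            den += 1
            if risk[short] > risk[long_]:
                num += 1.0
            elif risk[short] == risk[long_]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def bf_km(times, events) -> dict[float, float]:
    """Product-limit estimate by explicit risk-set counting."""
    order = sorted(set(t for t, e in zip(times, events) if e))
    s = 1.0
    curve = {}
    for t in order:
        at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei)
        s *= 1.0 - d / at_risk
        curve[t] = s
    return curve


# --------------------------------------------------------------------------
# Fixtures


@pytest.fixture(scope="session")
def uniform_phantom():
    """Hard-edged uniform lesion (SUV 8) on background 1, liver 2."""
    return make_phantom(PhantomSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_censored_cohort(rng, n, censor_frac=0.3):
    """Continuous times (no ties) with roughly the asked censoring."""
    risk = rng.standard_normal(n)
    time = rng.exponential(10.0, n) + 1e-3
    event = (rng.uniform(size=n) > censor_frac).astype(int)
    if event.sum() == 0:
        event[int(np.argmin(time))] = 1
    return risk, time, event
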