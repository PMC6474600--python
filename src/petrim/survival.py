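"""Univariate survival screening of imaging features.

Each feature is standardized (divided by the cohort sample SD) and fitted
individually against disease-free survival with a Cox proportional-hazards
model, so hazard ratios are reported per one-SD increase.  Discrimination
is summarized with Harrell's c index, multiplicity across the feature
family with Benjamini–Hochberg FDR, and group-wise survival with
Kaplan–Meier curves over feature tertiles.

The screening itself follows the Model/Results pattern:
``FeatureScreen(data, features).fit()`` returns a :class:`ScreenResults`
whose ``table`` holds one row per feature (HR, 95% CI, p, FDR, c index),
sorted by p-value, with ``summary()`` producing the formatted table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index as _lifelines_concordance
from statsmodels.stats.multitest import multipletests

from .io import CohortTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class UnivariateResult:
    """One row of the screening table: a single feature's Cox fit."""

    feature: str
    hr: float                   # hazard ratio per 1 SD
    ci_low: float               # 95% Wald CI on the HR scale
    ci_high: float
    p: float                    # two-sided Wald p
    c_index: float              # Harrell's concordance
    n: int
    n_events: int
    coef: float = float("nan")  # log-hazard per SD
    se: float = float("nan")
    fdr: float | None = None    # filled in by the screen

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval does not bracket the HR")
        if not (0.0 <= self.c_index <= 1.0):
            raise ValueError("c index outside [0, 1]")


def _validate_outcomes(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicators must be 0 or 1")
    return time, event.astype(int)


def cox_univariate(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    name: str = "feature",
) -> UnivariateResult:
    """Fit a single-covariate Cox model with a per-SD hazard ratio.

    The feature is divided by its sample standard deviation (n−1
    denominator) over the supplied subjects before fitting; ties in event
    times are handled with the Efron approximation.  Returns the hazard
    ratio per one-SD increase with its 95% Wald CI, the two-sided Wald
    p-value and Harrell's c index of the fitted risk score.
    """
    x = np.asarray(values, dtype=float)
    time, event = _validate_outcomes(time, event)
    if x.shape != time.shape:
        raise ValueError("feature values and outcomes must have equal length")
    if np.any(~np.isfinite(x)):
        raise ValueError(f"feature '{name}' contains non-finite values")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(
            f"need >= 2 events to fit a Cox model, got {n_events}"
        )
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"feature '{name}' has zero variance")
    z = x / sd

    df = pd.DataFrame({"z": z, "time": time, "event": event})
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood etc. — report, never clip
        raise RuntimeError(
            f"Cox fit failed for feature '{name}': {exc}"
        ) from exc
    row = cph.summary.loc["z"]
    coef = float(row["coef"])
    se = float(row["se(coef)"])
    risk = coef * z
    return UnivariateResult(
        feature=name,
        hr=float(np.exp(coef)),
        ci_low=float(row["exp(coef) lower 95%"]),
        ci_high=float(row["exp(coef) upper 95%"]),
        p=float(row["p"]),
        c_index=c_index(risk, time, event),
        n=len(z),
        n_events=n_events,
        coef=coef,
        se=se,
    )


def c_index(
    risk_scores: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
) -> float:
    """Harrell's concordance index of a risk score against survival.

    The probability that, of two comparable subjects, the one with the
    lower risk score survives longer; risk ties count 1/2.  A pair is
    comparable when the shorter observed time is an event.
    """
    risk = np.asarray(risk_scores, dtype=float)
    time, event = _validate_outcomes(time, event)
    # lifelines scores "higher prediction ↔ longer survival"; negate risk.
    try:
        return float(_lifelines_concordance(time, -risk, event))
    except ZeroDivisionError:
        raise ValueError("no comparable pairs under this censoring") from None


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tertile_groups(values: Sequence[float]) -> np.ndarray:
    """Assign 0/1/2 group labels at the 33.3/66.7 feature percentiles.

    Subjects exactly at a cut point go to the lower group.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects to form tertiles")
    c1, c2 = np.percentile(x, [100.0 / 3.0, 200.0 / 3.0])
    return np.where(x <= c1, 0, np.where(x <= c2, 1, 2))


def km_tertile_curves(
    values: Sequence[float],
    time: Sequence[float],
    event: Sequence[int],
    feature_name: str = "feature",
    plot_path: str | Path | None = None,
):
    """Kaplan–Meier survival per low/intermediate/high feature tertile.

    Returns a dict mapping group label ("low", "intermediate", "high") to a
    fitted :class:`lifelines.KaplanMeierFitter`; when ``plot_path`` is set,
    the three curves (with censoring marks) are written to that file.
    """
    time, event = _validate_outcomes(time, event)
    groups = tertile_groups(values)
    labels = {0: "low", 1: "intermediate", 2: "high"}
    fitters: dict[str, KaplanMeierFitter] = {}
    for g, label in labels.items():
        sel = groups == g
        if not sel.any():
            continue
        kmf = KaplanMeierFitter(label=f"{feature_name} {label}")
        kmf.fit(time[sel], event_observed=event[sel])
        fitters[label] = kmf
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for kmf in fitters.values():
            kmf.plot_survival_function(ax=ax, show_censors=True)
        ax.set_xlabel("Disease-free survival (months)")
        ax.set_ylabel("Survival probability")
        ax.set_ylim(0, 1.05)
        ax.set_title(feature_name)
        fig.tight_layout()
        fig.savefig(plot_path)
        plt.close(fig)
    return fitters


class FeatureScreen:
    """Univariate Cox screen of a feature family against survival.

    Parameters
    ----------
    data : DataFrame
        One row per subject with ``time`` and ``event`` columns plus the
        feature columns.  Rows with a missing value for a given feature are
        excluded from that feature's fit only (complete-case per feature).
    features : sequence of str
        Columns to screen; the BH FDR family is exactly this set.
    fdr_threshold : float
        Significance threshold on the adjusted values (default 10% FDR).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Sequence[str],
        time_col: str = "time",
        event_col: str = "event",
        fdr_threshold: float = 0.10,
    ) -> None:
        if not 0 < fdr_threshold < 1:
            raise ValueError("FDR threshold must lie in (0, 1)")
        missing = [f for f in features if f not in data.columns]
        if missing:
            raise ValueError(f"feature column(s) not in data: {', '.join(missing)}")
        for col in (time_col, event_col):
            if col not in data.columns:
                raise ValueError(f"missing column '{col}'")
        self.data = data
        self.features = list(features)
        self.time_col = time_col
        self.event_col = event_col
        self.fdr_threshold = fdr_threshold

    @classmethod
    def from_cohort(
        cls,
        cohort: CohortTable,
        which: str = "baseline",
        fdr_threshold: float = 0.10,
    ) -> "FeatureScreen":
        """Build a screen from a :class:`CohortTable`.

        ``which`` selects the ``"baseline"`` feature columns over all
        subjects or the ``"delta"`` (pre-minus-post change) columns over
        the residual-lesion subset.
        """
        if which == "baseline":
            return cls(cohort.data, cohort.baseline_features,
                       fdr_threshold=fdr_threshold)
        if which == "delta":
            return cls(cohort.delta_subset(), cohort.delta_features,
                       fdr_threshold=fdr_threshold)
        raise ValueError(f"which must be 'baseline' or 'delta', got {which!r}")

    def fit(self) -> "ScreenResults":
        """Fit every per-feature Cox model and adjust across the family."""
        results: list[UnivariateResult] = []
        for name in self.features:
            sub = self.data[[name, self.time_col, self.event_col]].dropna()
            res = cox_univariate(
                sub[name], sub[self.time_col], sub[self.event_col], name=name
            )
            results.append(res)
        fdr = bh_fdr([r.p for r in results])
        results = [
            UnivariateResult(**{**r.__dict__, "fdr": float(q)})
            for r, q in zip(results, fdr)
        ]
        results.sort(key=lambda r: r.p)
        return ScreenResults(results, self.fdr_threshold)


@dataclass
class ScreenResults:
    """Fitted screening table with formatting and plotting helpers."""

    results: list[UnivariateResult]
    fdr_threshold: float = 0.10

    @property
    def table(self) -> pd.DataFrame:
        """One row per feature, sorted by p: HR, CI, p, FDR, c index."""
        return pd.DataFrame(
            {
                "Feature": [r.feature for r in self.results],
                "HR": [r.hr for r in self.results],
                "CI low": [r.ci_low for r in self.results],
                "CI high": [r.ci_high for r in self.results],
                "p-value": [r.p for r in self.results],
                "FDR": [r.fdr for r in self.results],
                "c Index": [r.c_index for r in self.results],
                "significant": [r.fdr < self.fdr_threshold
                                for r in self.results],
            }
        )

    @property
    def significant_features(self) -> list[str]:
        return [r.feature for r in self.results
                if r.fdr is not None and r.fdr < self.fdr_threshold]

    def __getitem__(self, feature: str) -> UnivariateResult:
        for r in self.results:
            if r.feature == feature:
                return r
        raise KeyError(feature)

    def summary(self) -> pd.DataFrame:
        """Formatted table: 'HR (95% CI)' to 2 decimals, p/FDR/c to 3."""
        return pd.DataFrame(
            {
                "Feature": [r.feature for r in self.results],
                "HR (95% CI)": [
                    f"{r.hr:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"
                    for r in self.results
                ],
                "p-value": [f"{r.p:.3f}" for r in self.results],
                "FDR": [f"{r.fdr:.3f}" for r in self.results],
                "c Index": [f"{r.c_index:.3f}" for r in self.results],
            }
        )

    def to_csv(self, path: str | Path, formatted: bool = True) -> None:
        (self.summary() if formatted else self.table).to_csv(path, index=False)


def screen_features(
    data: pd.DataFrame | CohortTable,
    features: Sequence[str] | None = None,
    which: str = "baseline",
    time_col: str = "time",
    event_col: str = "event",
    fdr_threshold: float = 0.10,
) -> ScreenResults:
    """Convenience wrapper: build a :class:`FeatureScreen` and fit it."""
    if isinstance(data, CohortTable):
        screen = FeatureScreen.from_cohort(data, which=which,
                                           fdr_threshold=fdr_threshold)
    else:
        if features is None:
            raise ValueError("features must be given with a plain DataFrame")
        screen = FeatureScreen(data, features, time_col=time_col,
                               event_col=event_col,
                               fdr_threshold=fdr_threshold)
    return screen.fit()
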