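"""Group comparisons and vehicle-normalized drug-screen portfolios.

The screening convention: each treatment arm is compared against the
drug-free vehicle arm.  Two-condition comparisons use the unpaired
two-tailed Student's t-test (pooled variance); multi-arm screens use
one-way ANOVA followed by Fisher's LSD against the vehicle — pairwise
comparisons sharing the ANOVA's pooled error, two-tailed and uncorrected,
as the LSD convention prescribes.  Effects are reported as per-fly percent
change from the vehicle mean, so potency can be ranked within each sleep
parameter, with the usual star annotation
(* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .errors import (
    ConfigurationError,
    DegenerateVarianceError,
    InsufficientGroupError,
    NormalizationError,
)
from .sleep_metrics import PARAMETER_NAMES

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class LsdComparison:
    label: str
    mean_diff: float
    t: float
    p: float


@dataclass(frozen=True)
class AnovaLsdResult:
    f: float
    p_overall: float
    df_between: int
    df_within: int
    mse: float
    comparisons: tuple[LsdComparison, ...]

    def p_vs_reference(self, label: str) -> float:
        for c in self.comparisons:
            if c.label == label:
                return c.p
        raise KeyError(label)


@dataclass
class GroupSummary:
    """Per-group mean +/- SEM for each sleep parameter."""

    label: str
    n: int
    means: dict
    sems: dict


@dataclass
class ScreenPortfolio:
    """Vehicle-normalized drug-effect table for one protocol.

    ``table`` has one row per (window, treatment, parameter) with the
    per-fly percent-change mean and SEM, the test p-value and its star
    annotation; within each (window, parameter) the rows are ordered by
    effect size so treatments are ranked by potency.
    """

    reference: str
    mode: str
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def _clean(sample) -> np.ndarray:
    a = np.asarray(sample, dtype=float)
    return a[~np.isnan(a)]


def t_test_unpaired(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Classical unpaired two-tailed Student's t-test with pooled variance.

    df = n_a + n_b - 2.  With zero pooled variance, equal means give the
    p = 1 convention; unequal means are a degenerate-variance error.
    """
    a, b = _clean(a), _clean(b)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise InsufficientGroupError("each sample needs n >= 2 finite values")
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(t=0.0, df=df, p=1.0)
        raise DegenerateVarianceError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / na + 1 / nb))
    return TTestResult(t=float(t), df=df, p=float(2 * _st.t.sf(abs(t), df)))


def anova_lsd(groups: Mapping[str, Sequence[float]], reference: str) -> AnovaLsdResult:
    """One-way ANOVA plus Fisher's LSD comparisons of each group vs the reference.

    The LSD t statistics share the ANOVA mean-square error and its
    within-groups df; p-values are two-tailed and uncorrected.  With two
    groups the LSD p equals the pooled-variance t-test p exactly.
    """
    if reference not in groups:
        raise ConfigurationError(f"reference group {reference!r} not among groups")
    labels = list(groups)
    arrays = {k: _clean(v) for k, v in groups.items()}
    for k, arr in arrays.items():
        if len(arr) < 2:
            raise InsufficientGroupError(f"group {k!r} has fewer than 2 finite values")
    if len(labels) < 2:
        raise ConfigurationError("need at least two groups")

    ns = {k: len(v) for k, v in arrays.items()}
    means = {k: v.mean() for k, v in arrays.items()}
    n_total = sum(ns.values())
    grand = sum(v.sum() for v in arrays.values()) / n_total
    ss_between = sum(ns[k] * (means[k] - grand) ** 2 for k in labels)
    ss_within = sum(((arrays[k] - means[k]) ** 2).sum() for k in labels)
    df_b = len(labels) - 1
    df_w = n_total - len(labels)
    msw = ss_within / df_w

    if msw == 0:
        if ss_between == 0:
            f_stat, p_overall = 0.0, 1.0
            comps = tuple(
                LsdComparison(k, means[k] - means[reference], 0.0, 1.0)
                for k in labels if k != reference
            )
            return AnovaLsdResult(f_stat, p_overall, df_b, df_w, 0.0, comps)
        raise DegenerateVarianceError("zero within-group variance with unequal means")

    f_stat = (ss_between / df_b) / msw
    p_overall = float(_st.f.sf(f_stat, df_b, df_w))
    comps = []
    for k in labels:
        if k == reference:
            continue
        se = np.sqrt(msw * (1 / ns[k] + 1 / ns[reference]))
        t = (means[k] - means[reference]) / se
        comps.append(LsdComparison(k, float(means[k] - means[reference]), float(t),
                                   float(2 * _st.t.sf(abs(t), df_w))))
    return AnovaLsdResult(float(f_stat), p_overall, df_b, df_w, float(msw), tuple(comps))


def percent_change(sample: Sequence[float], reference_mean: float) -> np.ndarray:
    """Per-fly percent change from the reference (vehicle) mean.

    The group mean of the returned values equals the percent change of the
    group mean itself (linearity); SEM over them is the plotted error bar.
    """
    if reference_mean == 0:
        raise NormalizationError("reference mean is zero; report raw differences instead")
    a = np.asarray(sample, dtype=float)
    return 100.0 * (a - reference_mean) / reference_mean


def stars(p: float) -> str:
    """Star annotation for a p-value: ns, *, **, *** or ****."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p >= 0.05:
        return "ns"
    for threshold, symbol in STAR_THRESHOLDS:
        if p < threshold:
            return symbol
    return "*"


def group_summaries(parameter_table: pd.DataFrame, by: str = "treatment",
                    parameters: Sequence[str] = PARAMETER_NAMES) -> list[GroupSummary]:
    """Mean +/- SEM of each parameter per group (NaNs dropped per parameter)."""
    out = []
    for label, sub in parameter_table.groupby(by, sort=False):
        means, sems = {}, {}
        for p in parameters:
            vals = _clean(sub[p])
            means[p] = float(vals.mean()) if len(vals) else float("nan")
            sems[p] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append(GroupSummary(str(label), int(sub["fly_id"].nunique()), means, sems))
    return out


def _sem(values: np.ndarray) -> float:
    return float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0


def build_portfolio(parameter_table: pd.DataFrame, reference: str,
                    mode: str = "anova_lsd",
                    parameters: Sequence[str] = PARAMETER_NAMES,
                    sem_method: str = "per_fly") -> ScreenPortfolio:
    """Vehicle-normalized screen portfolio over a per-fly parameter table.

    ``parameter_table`` is the output of
    :func:`damsleep.sleep_metrics.sleep_parameter_table` (one protocol at a
    time); ``reference`` names the vehicle treatment.  ``mode`` selects the
    test: ``"pairwise_t"`` (independent Student's t per treatment, the
    two-condition convention) or ``"anova_lsd"`` (one shared ANOVA error per
    (window, parameter), the multi-arm screen convention).

    ``sem_method="per_fly"`` computes the error bar as the SEM of the
    per-fly normalized values; ``"delta"`` propagates the group SEM of the
    raw means instead (SEM(x)/|ref mean|).
    """
    if mode not in ("pairwise_t", "anova_lsd"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    if sem_method not in ("per_fly", "delta"):
        raise ConfigurationError(f"unknown sem_method {sem_method!r}")
    if reference not in set(parameter_table["treatment"]):
        raise ConfigurationError(f"reference treatment {reference!r} absent from table")

    rows = []
    for window, wsub in parameter_table.groupby("window", sort=False):
        for param in parameters:
            groups: dict[str, np.ndarray] = {}
            for label, gsub in wsub.groupby("treatment", sort=False):
                vals = _clean(gsub[param])
                if len(vals) < 2:
                    raise InsufficientGroupError(
                        f"group {label!r} has fewer than 2 flies with finite "
                        f"{param} in window {window}"
                    )
                groups[str(label)] = vals
            ref_vals = groups[reference]
            ref_mean = float(ref_vals.mean())

            if mode == "anova_lsd" and len(groups) > 2:
                res = anova_lsd(groups, reference)
                pvals = {c.label: c.p for c in res.comparisons}
            else:
                pvals = {}
                for label, vals in groups.items():
                    if label == reference:
                        continue
                    pvals[label] = t_test_unpaired(vals, ref_vals).p

            for label, vals in groups.items():
                try:
                    pct = percent_change(vals, ref_mean)
                    units = "percent"
                except NormalizationError:
                    pct = vals - ref_mean
                    units = "raw_difference"
                if sem_method == "per_fly":
                    sem = _sem(pct)
                else:
                    scale = 100.0 / abs(ref_mean) if units == "percent" else 1.0
                    sem = _sem(vals) * scale
                p = 1.0 if label == reference else pvals[label]
                rows.append({
                    "window": window,
                    "treatment": label,
                    "parameter": param,
                    "n": len(vals),
                    "pct_change_mean": 0.0 if label == reference else float(pct.mean()),
                    "pct_change_sem": sem,
                    "units": units,
                    "p": p,
                    "stars": "ns" if label == reference else stars(p),
                    "is_reference": label == reference,
                })

    table = pd.DataFrame(rows)
    # rank potency: within each (window, parameter), largest effects first,
    # reference pinned last
    table = (table
             .sort_values(["window", "parameter", "is_reference", "pct_change_mean"],
                          ascending=[True, True, True, False],
                          kind="mergesort")
             .reset_index(drop=True))
    return ScreenPortfolio(reference=reference, mode=mode, table=table)
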