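"""Signature-level survival and correlation analysis.

A gene signature is scored per subject as the mean of per-gene
z-standardized expression; subjects are split at the median score (ties to
the low group) and the two Kaplan-Meier curves are compared with the
two-group log-rank test.  The hazard ratio (high vs low) is estimated from
the log-rank observed/expected totals,

    HR = (O_high / E_high) / (O_low / E_low),

with a log-scale confidence interval using SE(log HR) ~ sqrt(1/E_h + 1/E_l)
— fully determined by the risk-set tables the test already computes, which
is adequate for a two-group median split.  Spearman rank correlation (with
exact permutation p at very small n) covers expression-vs-infiltration
analyses.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .exceptions import DegenerateDataError, ValidationError

logger = logging.getLogger(__name__)


def signature_score(cohort: pd.DataFrame, gene_set) -> pd.Series:
    """Mean z-standardized expression of the signature genes, per subject.

    Genes absent from the cohort's expression columns are reported and
    skipped; zero-variance genes are dropped with a warning.  Raises if no
    usable gene remains.
    """
    gene_set = list(dict.fromkeys(gene_set))
    present = [g for g in gene_set if g in cohort.columns]
    missing = sorted(set(gene_set) - set(present))
    if missing:
        logger.warning("signature genes absent from cohort: %s", missing[:10])
    if not present:
        raise ValidationError("no signature gene present in the cohort")
    cols = []
    for g in present:
        x = cohort[g].to_numpy(float)
        sd = x.std(ddof=0)
        if sd == 0.0:
            logger.warning("signature gene %s has zero variance; dropped", g)
            continue
        cols.append((x - x.mean()) / sd)
    if not cols:
        raise DegenerateDataError("every signature gene has zero variance")
    return pd.Series(
        np.mean(cols, axis=0), index=cohort["subject"], name="score"
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Label subjects 'high' (score > median) or 'low' (score <= median)."""
    if len(scores) < 4:
        raise ValidationError("median split needs >= 4 subjects")
    values = scores.to_numpy(float)
    if np.ptp(values) == 0.0:
        raise DegenerateDataError("all scores identical; split is degenerate")
    med = float(np.median(values))
    return pd.Series(
        np.where(values > med, "high", "low"), index=scores.index,
        name="group",
    )


@dataclass
class SurvivalResult:
    """Two-group survival comparison.

    ``km`` maps group -> step-function DataFrame (columns ``time``,
    ``survival``); ``observed``/``expected`` are the log-rank O/E totals.
    """

    groups: pd.Series
    km: dict
    statistic: float
    p_value: float
    hr: float
    hr_ci: tuple
    observed: dict
    expected: dict

    def summary(self) -> str:
        n = self.groups.value_counts()
        lines = [
            "Median-split survival analysis",
            "=" * 52,
            f"subjects: high {int(n.get('high', 0))}, low {int(n.get('low', 0))}",
            f"events:   high {self.observed['high']:g}, "
            f"low {self.observed['low']:g}",
            f"log-rank chi2(1) = {self.statistic:.4g}, p = {self.p_value:.3g}",
            f"HR (high vs low) = {self.hr:.4g} "
            f"[95% CI {self.hr_ci[0]:.4g}, {self.hr_ci[1]:.4g}]",
            "=" * 52,
        ]
        return "\n".join(lines)


def logrank_and_hr(cohort: pd.DataFrame, groups: pd.Series) -> SurvivalResult:
    """Two-group log-rank test with O/E hazard ratio and KM curves.

    ``groups`` labels each subject 'high' or 'low' (index = subject).  At
    each distinct event time t_j with d_j events and n_j subjects at risk,
    the high group's expected events are d_j * n_hj / n_j; the chi-square
    statistic is (O_h - E_h)^2 / V with the usual hypergeometric variance.
    """
    df = cohort.set_index("subject").loc[groups.index]
    time = df["time"].to_numpy(float)
    event = df["event"].to_numpy(int)
    is_high = (groups == "high").to_numpy()
    if is_high.all() or (~is_high).all():
        raise ValidationError("both groups must be non-empty")
    if event.sum() == 0:
        raise ValidationError("no events in the cohort")

    event_times = np.unique(time[event == 1])
    O_h = float(event[is_high].sum())
    O_l = float(event[~is_high].sum())
    E_h = 0.0
    V = 0.0
    for t in event_times:
        at_risk = time >= t
        n_j = float(at_risk.sum())
        n_hj = float((at_risk & is_high).sum())
        d_j = float(((time == t) & (event == 1)).sum())
        E_h += d_j * n_hj / n_j
        if n_j > 1:
            V += d_j * (n_hj / n_j) * (1 - n_hj / n_j) * (n_j - d_j) / (n_j - 1)
    E_l = (O_h + O_l) - E_h
    statistic = (O_h - E_h) ** 2 / V if V > 0 else 0.0
    p_value = float(stats.chi2.sf(statistic, df=1)) if V > 0 else 1.0

    if E_h > 0 and E_l > 0 and O_h > 0 and O_l > 0:
        hr = (O_h / E_h) / (O_l / E_l)
        se = math.sqrt(1.0 / E_h + 1.0 / E_l)
        hr_ci = (hr * math.exp(-1.96 * se), hr * math.exp(1.96 * se))
    else:
        hr, hr_ci = float("nan"), (float("nan"), float("nan"))

    km = {}
    for label, mask in (("high", is_high), ("low", ~is_high)):
        fitter = KaplanMeierFitter()
        fitter.fit(time[mask], event[mask], label=label)
        sf = fitter.survival_function_
        km[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf[label].to_numpy()}
        )
    return SurvivalResult(
        groups=groups,
        km=km,
        statistic=float(statistic),
        p_value=p_value,
        hr=float(hr),
        hr_ci=hr_ci,
        observed={"high": O_h, "low": O_l},
        expected={"high": E_h, "low": E_l},
    )


class MedianSplitSurvival:
    """Model object: cohort + signature -> median-split survival comparison."""

    def __init__(self, cohort: pd.DataFrame, signature_genes):
        for col in ("subject", "time", "event"):
            if col not in cohort.columns:
                raise ValidationError(f"cohort lacks column {col!r}")
        self.cohort = cohort
        self.signature_genes = list(signature_genes)

    def fit(self) -> SurvivalResult:
        scores = signature_score(self.cohort, self.signature_genes)
        groups = median_split(scores)
        return logrank_and_hr(self.cohort, groups)


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its p-value and sample size."""

    rho: float
    p_value: float
    n: int
    method: str

    def summary(self) -> str:
        return (
            f"Spearman rho = {self.rho:.4g}, p = {self.p_value:.3g} "
            f"(n = {self.n}, {self.method})"
        )


def spearman_corr(x, y) -> CorrelationResult:
    """Spearman correlation on mid-ranks.

    The p-value uses the large-sample t approximation, except at n <= 9
    where the exact permutation distribution (all n! rank orderings,
    two-sided on |rho|) is enumerated.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    n = len(x)
    if n < 5:
        raise ValidationError("need n >= 5")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("zero variance in x or y")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= 9:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))))
        ry_perm = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc @ rxc) * (ryc * ryc).sum(axis=1))
        rho_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return CorrelationResult(rho, p, n, "exact permutation")
    p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(rho, p, n, "t approximation")
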