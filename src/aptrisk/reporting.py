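"""Downstream clinical reports: cross-tabulations with association tests,
multivariate Cox adjustment, and disease-free-survival summaries.

These reproduce, from pipeline outputs, the shapes of the study's clinical
tables: covariate-by-risk-group contingency tables with chi-square or
Fisher's exact tests, a multivariate Cox model of recurrence adjusting the
risk label for clinical covariates, and Kaplan-Meier 5-year DFS rates per
risk group (optionally crossed with a stratifying covariate such as age).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival import (KMCurve, SurvivalOutcome, cox_fit, km_estimate,
                       logrank_test)

_log = logging.getLogger(__name__)

__all__ = ["CrosstabReport", "crosstab", "multivariate_report", "dfs_report",
           "plot_km"]

# covariates of the standard clinical table and their reference levels
CLINICAL_COVARIATES = {
    "age_group": ">=60",
    "sex": "female",
    "differentiation": "moderately",
    "lvi": "positive",
    "nodes_group": "<12",
    "chemo": "yes",
    "cea_group": ">5",
    "clinical_risk": "yes",
}


@dataclass
class CrosstabReport:
    """2 x k contingency table with row percentages and an association test."""

    covariate: str
    table: pd.DataFrame        # rows: covariate levels; cols: group counts + %
    test_used: str             # 'chi-square' | 'fisher'
    statistic: float | None
    p_value: float
    group_sizes: dict

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"{self.covariate}: {self.test_used} p = {self.p_value:.3g}\n"
                f"{self.table}")


def _percent(x: float) -> float:
    return round(100.0 * x, 1)


def crosstab(clinical: pd.DataFrame, labels, covariate: str,
             group_col_values=("low", "high"), yates: bool = False
             ) -> CrosstabReport:
    """Cross-tabulate a clinical covariate against the risk labels.

    Rows with a missing covariate are excluded listwise.  Fisher's exact
    test is used when any expected cell count is below 5 (2x2 tables),
    otherwise the Pearson chi-square (no continuity correction unless
    `yates`).  Percentages are row-wise.
    """
    if covariate not in clinical.columns:
        raise KeyError(f"covariate {covariate!r} not in clinical table")
    labels = np.asarray(labels)
    cov = clinical[covariate].to_numpy(dtype=object)
    keep = pd.notna(cov)
    n_excl = int((~keep).sum())
    if n_excl:
        _log.info("crosstab(%s): excluding %d sample(s) with missing value",
                  covariate, n_excl)
    cov, lab = cov[keep], labels[keep]
    levels = [lv for lv in pd.unique(cov)]
    counts = np.array([[np.sum((cov == lv) & (lab == gv))
                        for gv in group_col_values] for lv in levels],
                      dtype=float)
    nonempty = counts.sum(axis=1) > 0
    if not nonempty.all():
        dropped = [lv for lv, ok in zip(levels, nonempty) if not ok]
        _log.warning("crosstab(%s): dropping empty level(s) %s", covariate, dropped)
        levels = [lv for lv, ok in zip(levels, nonempty) if ok]
        counts = counts[nonempty]
    if counts.shape[0] < 2:
        raise ValueError(f"covariate {covariate!r} has < 2 nonempty levels")

    row_tot = counts.sum(axis=1, keepdims=True)
    expected = counts.sum(axis=1, keepdims=True) * counts.sum(axis=0) / counts.sum()
    use_fisher = (expected < 5).any() and counts.shape == (2, 2)
    if use_fisher:
        _, p = stats.fisher_exact(counts.astype(int))
        test_used, statistic = "fisher", None
    else:
        chi2, p, _, _ = stats.chi2_contingency(counts, correction=yates)
        test_used, statistic = "chi-square", float(chi2)

    data = {}
    for j, gv in enumerate(group_col_values):
        data[f"n_{gv}"] = counts[:, j].astype(int)
        data[f"pct_{gv}"] = [_percent(c / t) for c, t in
                             zip(counts[:, j], row_tot[:, 0])]
    table = pd.DataFrame(data, index=pd.Index(levels, name=covariate))
    sizes = {gv: int(counts[:, j].sum()) for j, gv in enumerate(group_col_values)}
    return CrosstabReport(covariate=covariate, table=table, test_used=test_used,
                          statistic=statistic, p_value=float(p),
                          group_sizes=sizes)


def _binary_design(clinical: pd.DataFrame, labels, covariates: list[str]
                   ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """0/1 design matrix (risk label last), dropping rows with missing values."""
    cols, names = [], []
    keep = np.ones(len(clinical), dtype=bool)
    for cov in covariates:
        vals = clinical[cov].to_numpy(dtype=object)
        keep &= pd.notna(vals)
    for cov in covariates:
        vals = clinical[cov].to_numpy(dtype=object)[keep]
        ref = CLINICAL_COVARIATES.get(cov)
        lv = pd.unique(vals)
        if len(lv) < 2:
            _log.warning("multivariate_report: covariate %r has a single "
                         "level after exclusions; dropped", cov)
            continue
        pos = ref if ref in lv else lv[-1]
        cols.append((vals == pos).astype(float))
        names.append(f"{cov}={pos}")
    lab = (np.asarray(labels)[keep] == "high").astype(float)
    cols.append(lab)
    names.append("risk=high")
    return np.column_stack(cols), names, keep


def multivariate_report(clinical: pd.DataFrame, labels,
                        covariates: list[str] | None = None) -> pd.DataFrame:
    """Multivariate Cox model of recurrence: risk label plus clinical factors.

    Returns a table of hazard ratios with 95% CIs and Wald p-values.
    Covariates default to age group, sex, chemotherapy, clinical risk and
    CEA group; inestimable covariates (a single level) are dropped.
    """
    if covariates is None:
        covariates = ["age_group", "sex", "chemo", "clinical_risk", "cea_group"]
    x, names, keep = _binary_design(clinical, labels, covariates)
    outcome = SurvivalOutcome(
        clinical["time_months"].to_numpy(dtype=float)[keep],
        clinical["event"].to_numpy()[keep])
    fit = cox_fit(x, outcome, names=names)
    tbl = fit.summary()
    tbl.index.name = "covariate"
    return tbl


def dfs_report(clinical: pd.DataFrame, labels, horizon_months: float = 60.0,
               strata: str | None = None) -> dict:
    """Kaplan-Meier DFS summary per risk group (optionally crossed with a
    stratifying covariate, e.g. age group -> 4 curves).

    Returns a dict with per-group KMCurve objects, survival at the horizon
    (the "5-year rate" when horizon_months = 60), group sizes and the
    log-rank comparison across all groups.
    """
    labels = np.asarray(labels)
    outcome = SurvivalOutcome(clinical["time_months"].to_numpy(dtype=float),
                              clinical["event"].to_numpy())
    if strata is None:
        groups = labels.astype(object)
    else:
        sv = clinical[strata].to_numpy(dtype=object)
        keep = pd.notna(sv)
        if not keep.all():
            _log.warning("dfs_report: excluding %d sample(s) with missing %s",
                         int((~keep).sum()), strata)
            outcome = outcome.subset(np.flatnonzero(keep))
            labels, sv = labels[keep], sv[keep]
        groups = np.array([f"{s}/{l}" for s, l in zip(sv, labels)], dtype=object)
    uniq = pd.unique(groups)
    curves = km_estimate(outcome, groups)
    rates = {str(g): float(curves[g].survival_at(horizon_months)) for g in uniq}
    sizes = {str(g): int(np.sum(groups == g)) for g in uniq}
    if uniq.size >= 2:
        lr = logrank_test(outcome, groups)
        logrank_p, logrank_chi = lr.p_value, lr.chi_square
    else:
        logrank_p = logrank_chi = float("nan")
    return {
        "curves": {str(g): curves[g] for g in uniq},
        "survival_at_horizon": rates,
        "horizon_months": horizon_months,
        "group_sizes": sizes,
        "logrank_chi": logrank_chi,
        "logrank_p": logrank_p,
    }


def plot_km(report: dict, path=None, title: str = "Disease-free survival"):
    """Step plot of the KM curves in a dfs_report (SVG-friendly)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, curve in report["curves"].items():
        t = np.r_[0.0, np.repeat(curve.event_times, 2)]
        s = np.r_[1.0, 1.0, np.repeat(curve.surv, 2)[:-1]]
        ax.plot(t, s, drawstyle="default",
                label=f"{name} (n={report['group_sizes'][name]})")
    ax.set_xlabel("months")
    ax.set_ylabel("DFS probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{title} (log-rank p = {report['logrank_p']:.3g})")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
        return None
    return fig
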