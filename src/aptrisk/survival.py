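"""Survival-analysis primitives.

This module implements the building blocks the prognostic pipeline rests on:

* the Cox proportional-hazards partial likelihood (Breslow and Efron tie
  corrections) with analytic gradient and observed information, organised
  around a precomputed risk-set structure (:class:`CoxData`) so that the
  likelihood can be evaluated cheaply many times at different coefficient
  vectors — the access pattern of the L1-constrained solver;
* Newton--Raphson maximum partial-likelihood fitting (:func:`cox_fit`);
* per-feature univariate Cox screening with Wald p-values, vectorized across
  features (:func:`univariate_screen`);
* the Kaplan--Meier product-limit estimator (:func:`km_estimate`) and the
  unweighted k-sample log-rank test (:func:`logrank_test`).

Conventions: time is in months and strictly positive; ``event`` is 1 for an
observed event (recurrence) and 0 for censoring.  A subject censored at the
same time as an event is still at risk for that event (risk sets are
``{j : t_j >= t_i}``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

_log = logging.getLogger(__name__)

__all__ = [
    "SurvivalOutcome",
    "CoxData",
    "CoxFit",
    "ScreenResult",
    "KMCurve",
    "LogrankResult",
    "cox_partial_loglik",
    "cox_fit",
    "univariate_screen",
    "km_estimate",
    "logrank_test",
]


def _revcumsum(a: np.ndarray, axis: int = 0) -> np.ndarray:
    """Cumulative sum from the end of `axis` toward the start."""
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(None, None, -1)
    sl = tuple(sl)
    return a[sl].cumsum(axis=axis)[sl]


# ---------------------------------------------------------------------------
# Outcome container
# ---------------------------------------------------------------------------


@dataclass
class SurvivalOutcome:
    """Aligned follow-up times (months) and event indicators for a cohort."""

    time: np.ndarray
    event: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        if self.time.ndim != 1 or self.event.shape != self.time.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("times must be finite and strictly positive")
        ev = np.asarray(self.event, dtype=float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        self.event = ev.astype(np.int8)
        if self.sample_ids is not None:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != self.time.size:
                raise ValueError("sample_ids length mismatch")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_clinical(cls, clinical: pd.DataFrame) -> "SurvivalOutcome":
        """Build from a clinical table with sample_id / time_months / event."""
        return cls(
            time=clinical["time_months"].to_numpy(dtype=float),
            event=clinical["event"].to_numpy(),
            sample_ids=list(clinical["sample_id"].astype(str)),
        )

    def subset(self, idx: np.ndarray) -> "SurvivalOutcome":
        ids = [self.sample_ids[i] for i in np.atleast_1d(idx)] if self.sample_ids else None
        return SurvivalOutcome(self.time[idx], self.event[idx], ids)


# ---------------------------------------------------------------------------
# Risk-set structure and partial likelihood
# ---------------------------------------------------------------------------


class CoxData:
    """Precomputed risk-set bookkeeping for partial-likelihood evaluation.

    Sorting, tie grouping and Efron weights are computed once; `loglik`,
    `grad` and `info` then run in a handful of vectorized passes.  All
    evaluation methods operate in *sorted* (ascending-time) order; use
    `sort_rows` to bring a covariate matrix into that order.
    """

    def __init__(self, outcome: SurvivalOutcome, ties: str = "efron") -> None:
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.n = outcome.n
        self.order = np.argsort(outcome.time, kind="stable")
        self.time = outcome.time[self.order]
        self.event = outcome.event[self.order]
        t = self.time
        n = self.n
        # first index of each run of tied times (risk set at t starts there)
        new_run = np.r_[True, t[1:] > t[:-1]]
        run_first = np.where(new_run, np.arange(n), 0)
        self.first_idx = np.maximum.accumulate(run_first)
        self.n_at_risk = n - self.first_idx

        self.ev_idx = np.flatnonzero(self.event == 1)
        m = self.ev_idx.size
        self.n_events = m
        if m:
            ev_t = t[self.ev_idx]
            g_new = np.r_[True, ev_t[1:] > ev_t[:-1]]
            self.g_start = np.flatnonzero(g_new)              # starts into ev_idx
            self.d = np.diff(np.r_[self.g_start, m])          # events per tied group
            self.risk_start = self.first_idx[self.ev_idx[self.g_start]]
            # Efron expansion: one row per (group, l) with l = 0..d-1
            self.g_rep = np.repeat(np.arange(self.g_start.size), self.d)
            within = np.arange(m) - np.repeat(self.g_start, self.d)
            self.l_frac = within / self.d[self.g_rep]
            self.has_ties = bool((self.d > 1).any())
        else:
            self.g_start = np.empty(0, dtype=int)
            self.d = np.empty(0, dtype=int)
            self.risk_start = np.empty(0, dtype=int)
            self.g_rep = np.empty(0, dtype=int)
            self.l_frac = np.empty(0)
            self.has_ties = False

    # -- helpers ----------------------------------------------------------

    def sort_rows(self, x: np.ndarray) -> np.ndarray:
        """Reorder sample rows of `x` into ascending-time order."""
        return np.asarray(x, dtype=float)[self.order]

    def _use_efron(self) -> bool:
        return self.ties == "efron" and self.has_ties

    @property
    def _amask(self) -> np.ndarray:
        # risk-set membership, one row per tied event group; risk sums then
        # become small matmuls (rows ~ number of events) instead of full
        # cumulative passes over n
        mask = getattr(self, "_amask_cache", None)
        if mask is None:
            mask = (np.arange(self.n)[None, :] >= self.risk_start[:, None]
                    ).astype(float)
            self._amask_cache = mask
        return mask

    # -- partial likelihood ----------------------------------------------

    def loglik(self, eta: np.ndarray) -> float:
        """Partial log-likelihood at linear predictor `eta` (sorted order)."""
        if self.n_events == 0:
            return 0.0
        c = float(np.max(eta))
        w = np.exp(eta - c)
        if not self._use_efron():
            r0 = self._amask @ w
            return float(eta[self.ev_idx].sum()
                         - (self.d * (np.log(r0) + c)).sum())
        r0 = _revcumsum(w)[self.risk_start]
        s_eta = np.add.reduceat(eta[self.ev_idx], self.g_start)
        d0 = np.add.reduceat(w[self.ev_idx], self.g_start)
        denom = r0[self.g_rep] - self.l_frac * d0[self.g_rep]
        return float(s_eta.sum() - (np.log(denom) + c).sum())

    def dirderiv(self, eta: np.ndarray, deta: np.ndarray) -> float:
        """Directional derivative of the partial log-likelihood at `eta`
        along `deta` (both in sorted order).

        Used by exact line searches: unlike differences of log-likelihood
        values, the derivative keeps full floating-point resolution near an
        optimum.
        """
        if self.n_events == 0:
            return 0.0
        c = float(np.max(eta))
        w = np.exp(eta - c)
        wd = w * deta
        if not self._use_efron():
            r0 = self._amask @ w
            r1 = self._amask @ wd
            return float(deta[self.ev_idx].sum() - (self.d * r1 / r0).sum())
        r0 = _revcumsum(w)[self.risk_start]
        r1 = _revcumsum(wd)[self.risk_start]
        s_d = np.add.reduceat(deta[self.ev_idx], self.g_start)
        d0 = np.add.reduceat(w[self.ev_idx], self.g_start)
        d1 = np.add.reduceat(wd[self.ev_idx], self.g_start)
        den = r0[self.g_rep] - self.l_frac * d0[self.g_rep]
        num = r1[self.g_rep] - self.l_frac * d1[self.g_rep]
        return float(s_d.sum() - (num / den).sum())

    def loglik_grad(self, xs: np.ndarray, beta: np.ndarray,
                    eta: np.ndarray | None = None) -> tuple[float, np.ndarray]:
        """Partial log-likelihood and gradient w.r.t. `beta`.

        `xs` must be in sorted order; `eta` may be passed to reuse
        ``xs @ beta``.
        """
        if eta is None:
            eta = xs @ beta
        k = xs.shape[1]
        if self.n_events == 0:
            return 0.0, np.zeros(k)
        c = float(np.max(eta))
        w = np.exp(eta - c)
        if not self._use_efron():
            r0 = self._amask @ w
            r1 = self._amask @ (w[:, None] * xs)
            ll = eta[self.ev_idx].sum() - (self.d * (np.log(r0) + c)).sum()
            g = (xs[self.ev_idx].sum(axis=0)
                 - (self.d[:, None] * r1 / r0[:, None]).sum(axis=0))
            return float(ll), g
        wx = w[:, None] * xs
        r0 = _revcumsum(w)[self.risk_start]
        r1 = _revcumsum(wx, axis=0)[self.risk_start]
        s_eta = np.add.reduceat(eta[self.ev_idx], self.g_start)
        s_x = np.add.reduceat(xs[self.ev_idx], self.g_start, axis=0)
        d0 = np.add.reduceat(w[self.ev_idx], self.g_start)
        d1 = np.add.reduceat(wx[self.ev_idx], self.g_start, axis=0)
        den = r0[self.g_rep] - self.l_frac * d0[self.g_rep]
        num = r1[self.g_rep] - self.l_frac[:, None] * d1[self.g_rep]
        ll = s_eta.sum() - (np.log(den) + c).sum()
        g = s_x.sum(axis=0) - (num / den[:, None]).sum(axis=0)
        return float(ll), g

    def loglik_grad_info(self, xs: np.ndarray, beta: np.ndarray
                         ) -> tuple[float, np.ndarray, np.ndarray]:
        """Log-likelihood, gradient and observed information matrix."""
        eta = xs @ beta
        k = xs.shape[1]
        if self.n_events == 0:
            return 0.0, np.zeros(k), np.zeros((k, k))
        c = float(np.max(eta))
        w = np.exp(eta - c)
        wx = w[:, None] * xs
        wxx = np.einsum("i,ij,il->ijl", w, xs, xs)
        r0 = _revcumsum(w)[self.risk_start]
        r1 = _revcumsum(wx, axis=0)[self.risk_start]
        r2 = _revcumsum(wxx, axis=0)[self.risk_start]
        s_eta = np.add.reduceat(eta[self.ev_idx], self.g_start)
        s_x = np.add.reduceat(xs[self.ev_idx], self.g_start, axis=0)
        if not self._use_efron():
            ll = s_eta.sum() - (self.d * (np.log(r0) + c)).sum()
            mu = r1 / r0[:, None]
            g = s_x.sum(axis=0) - (self.d[:, None] * mu).sum(axis=0)
            v = r2 / r0[:, None, None] - np.einsum("gj,gl->gjl", mu, mu)
            info = (self.d[:, None, None] * v).sum(axis=0)
            return float(ll), g, info
        d0 = np.add.reduceat(w[self.ev_idx], self.g_start)
        d1 = np.add.reduceat(wx[self.ev_idx], self.g_start, axis=0)
        d2 = np.add.reduceat(wxx[self.ev_idx], self.g_start, axis=0)
        den = r0[self.g_rep] - self.l_frac * d0[self.g_rep]
        num1 = r1[self.g_rep] - self.l_frac[:, None] * d1[self.g_rep]
        num2 = r2[self.g_rep] - self.l_frac[:, None, None] * d2[self.g_rep]
        ll = s_eta.sum() - (np.log(den) + c).sum()
        mu = num1 / den[:, None]
        g = s_x.sum(axis=0) - mu.sum(axis=0)
        v = num2 / den[:, None, None] - np.einsum("gj,gl->gjl", mu, mu)
        info = v.sum(axis=0)
        return float(ll), g, info


def cox_partial_loglik(x: np.ndarray, beta: np.ndarray,
                       outcome: SurvivalOutcome, ties: str = "efron") -> float:
    """Cox partial log-likelihood at coefficients `beta`.

    `x` is samples x covariates in the outcome's sample order.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != outcome.n:
        raise ValueError("covariate rows must match outcome length")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariates")
    cd = CoxData(outcome, ties=ties)
    xs = cd.sort_rows(x)
    return cd.loglik(xs @ np.asarray(beta, dtype=float))


# ---------------------------------------------------------------------------
# Newton-Raphson fitting
# ---------------------------------------------------------------------------


@dataclass
class CoxFit:
    """Maximum partial-likelihood fit with Wald inference."""

    coefficients: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    hr_ci_lower: np.ndarray
    hr_ci_upper: np.ndarray
    p_values: np.ndarray
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    names: list[str] | None = None

    def summary(self) -> pd.DataFrame:
        idx = self.names if self.names is not None else list(range(self.coefficients.size))
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.se,
                "hr": self.hr,
                "hr_ci_lower": self.hr_ci_lower,
                "hr_ci_upper": self.hr_ci_upper,
                "p": self.p_values,
            },
            index=idx,
        )


def cox_fit(x: np.ndarray, outcome: SurvivalOutcome, ties: str = "efron",
            tol: float = 1e-8, max_iter: int = 100,
            names: list[str] | None = None) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton--Raphson.

    Convergence when the gradient sup-norm drops below `tol` or the
    log-likelihood improvement falls below 1e-10.  Standard errors come from
    the inverse observed information.  Monotone-likelihood (perfect
    separation) is flagged via ``converged=False`` with a warning rather than
    raised, matching common practice.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, k = x.shape
    if n != outcome.n:
        raise ValueError("covariate rows must match outcome length")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite covariates")
    if outcome.n_events == 0:
        raise ValueError("at least one event is required to fit a Cox model")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant covariate(s) at position(s) %s" %
                         np.flatnonzero(sd == 0).tolist())
    if outcome.n_events < k:
        warnings.warn(
            f"fewer events ({outcome.n_events}) than covariates ({k}); "
            "estimates may be unstable", stacklevel=2)

    cd = CoxData(outcome, ties=ties)
    xs = cd.sort_rows(x)
    beta = np.zeros(k)
    ll, g, info = cd.loglik_grad_info(xs, beta)
    ll_null = ll
    converged = False
    diverged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, g)
        except np.linalg.LinAlgError as err:
            if it == 1 and np.max(np.abs(beta)) < 1.0:
                raise np.linalg.LinAlgError(
                    "singular information matrix in cox_fit") from err
            # information degenerates along a monotone-likelihood path
            diverged = True
            break
        # step halving keeps the likelihood monotone
        new_beta, new_ll = beta, ll
        for h in range(31):
            cand = beta + step / (2.0 ** h)
            cll = cd.loglik(xs @ cand)
            if cll >= ll - 1e-13:
                new_beta, new_ll = cand, cll
                break
        if new_ll - ll < 1e-10 and np.max(np.abs(g)) < 1e-5:
            beta = new_beta
            ll, g, info = cd.loglik_grad_info(xs, beta)
            converged = True
            break
        beta, ll = new_beta, new_ll
        ll, g, info = cd.loglik_grad_info(xs, beta)
        if np.max(np.abs(beta)) > 80:
            diverged = True
            break
    if diverged or (not converged and it >= max_iter):
        warnings.warn(
            "cox_fit did not converge (possible monotone likelihood / "
            "perfect separation); coefficients reported as-is", stacklevel=2)
        converged = False
    elif converged and np.max(np.abs(beta)) > 10:
        # gradient criterion met but at an implausible coefficient: the
        # likelihood is monotone (Hauck-Donner regime)
        warnings.warn(
            "cox_fit: coefficient magnitude exceeds 10 (possible monotone "
            "likelihood / perfect separation)", stacklevel=2)
        converged = False
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
        p = 2.0 * stats.norm.sf(np.abs(z))
        hr = np.exp(beta)
        ci_lo = np.exp(beta - 1.96 * se)
        ci_hi = np.exp(beta + 1.96 * se)
    return CoxFit(
        coefficients=beta,
        se=se,
        hr=hr,
        hr_ci_lower=ci_lo,
        hr_ci_upper=ci_hi,
        p_values=p,
        loglik=float(ll),
        loglik_null=float(ll_null),
        n_iter=it,
        converged=converged and not diverged,
        names=names,
    )


# ---------------------------------------------------------------------------
# Univariate screening (vectorized across features)
# ---------------------------------------------------------------------------


@dataclass
class ScreenResult:
    """Per-feature univariate Cox screen with a strict p < alpha selection."""

    table: pd.DataFrame       # feature_id, coef, se, p, selected
    alpha: float

    @property
    def selected_ids(self) -> list:
        return list(self.table.index[self.table["selected"]])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature_id")


def _screen_newton(xs: np.ndarray, cd: CoxData, beta0: np.ndarray | None = None,
                   tol: float = 1e-8, max_iter: int = 40
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-covariate Newton fits for every column of `xs` simultaneously.

    Returns (beta, info, p, ok) arrays of length p.  Columns whose fit fails
    (zero information or non-convergence) get p = 1, beta = 0, ok = False.
    Handles Efron/Breslow ties through the expanded (group, l) arrays.
    """
    n, p = xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    ev = cd.ev_idx
    use_efron = cd._use_efron()
    x_ev_sum = xs[ev].sum(axis=0)
    failed = np.zeros(p, dtype=bool)
    conv = np.zeros(p, dtype=bool)
    info = np.zeros(p)

    def stats_at(b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        eta = xs * b[None, :]
        eta -= eta.max(axis=0, keepdims=True)
        w = np.exp(eta)
        wx = w * xs
        wxx = wx * xs
        r0 = _revcumsum(w)[cd.risk_start]
        r1 = _revcumsum(wx)[cd.risk_start]
        r2 = _revcumsum(wxx)[cd.risk_start]
        if use_efron:
            d0 = np.add.reduceat(w[ev], cd.g_start, axis=0)
            d1 = np.add.reduceat(wx[ev], cd.g_start, axis=0)
            d2 = np.add.reduceat(wxx[ev], cd.g_start, axis=0)
            lf = cd.l_frac[:, None]
            den = r0[cd.g_rep] - lf * d0[cd.g_rep]
            num1 = r1[cd.g_rep] - lf * d1[cd.g_rep]
            num2 = r2[cd.g_rep] - lf * d2[cd.g_rep]
        else:
            den, num1, num2 = r0, r1, r2
        mu = num1 / den
        if (not use_efron) and cd.has_ties:
            grad = x_ev_sum - (cd.d[:, None] * mu).sum(axis=0)
            inf = (cd.d[:, None] * (num2 / den - mu * mu)).sum(axis=0)
        else:
            grad = x_ev_sum - mu.sum(axis=0)
            inf = (num2 / den - mu * mu).sum(axis=0)
        return grad, inf

    grad, info = stats_at(beta)
    for _ in range(max_iter):
        conv = np.abs(grad) < tol
        live = ~conv & ~failed
        if not live.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(info > 1e-12, grad / np.where(info > 1e-12, info, 1.0), 0.0)
        failed |= live & (info <= 1e-12) & (np.abs(grad) > 1e-8)
        step = np.clip(step, -2.0, 2.0)
        beta = np.where(live, beta + step, beta)
        failed |= np.abs(beta) > 40
        grad, info = stats_at(beta)
    conv = np.abs(grad) < np.maximum(tol, 1e-6)
    failed |= ~conv
    ok = ~failed & (info > 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        z2 = np.where(ok, beta * beta * info, 0.0)
    p_vals = np.where(ok, stats.chi2.sf(z2, 1), 1.0)
    beta = np.where(ok, beta, 0.0)
    return beta, info, p_vals, ok


def univariate_screen(mat: pd.DataFrame, outcome: SurvivalOutcome,
                      alpha: float = 0.01, ties: str = "efron") -> ScreenResult:
    """Screen features by one-covariate Cox Wald p-values (strict p < alpha).

    `mat` is features x samples, complete (post-imputation), with columns
    aligned to (or reindexable by) the outcome's sample ids.
    """
    mat = align_matrix(mat, outcome)
    values = mat.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("expression matrix contains missing values; impute first")
    cd = CoxData(outcome, ties=ties)
    xs = values.T[cd.order]
    beta, info, p, ok = _screen_newton(xs, cd)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(info > 0, 1.0 / np.sqrt(np.where(info > 0, info, 1.0)), np.inf)
    n_failed = int((~ok).sum())
    if n_failed:
        _log.info("univariate_screen: %d feature fit(s) failed; assigned p=1", n_failed)
    table = pd.DataFrame(
        {"coef": beta, "se": se, "p": p, "selected": p < alpha},
        index=mat.index,
    )
    return ScreenResult(table=table, alpha=alpha)


def align_matrix(mat: pd.DataFrame, outcome: SurvivalOutcome) -> pd.DataFrame:
    """Align the sample columns of `mat` to the outcome's sample order."""
    if outcome.sample_ids is None:
        if mat.shape[1] != outcome.n:
            raise ValueError("matrix has %d samples, outcome has %d"
                             % (mat.shape[1], outcome.n))
        return mat
    missing = set(outcome.sample_ids) - set(map(str, mat.columns))
    if missing:
        raise ValueError(f"samples missing from matrix: {sorted(missing)[:5]} ...")
    return mat.reindex(columns=[str(s) for s in outcome.sample_ids]) \
        if list(map(str, mat.columns)) != list(map(str, outcome.sample_ids)) else mat


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate with right-continuous step convention."""

    event_times: np.ndarray   # distinct times with >= 1 event, ascending
    surv: np.ndarray          # S(t) just after each event time
    at_risk: np.ndarray       # risk-set size at each event time
    n_events: np.ndarray      # events at each event time
    label: str | None = None

    def survival_at(self, t) -> np.ndarray | float:
        """S(t) with S(0) = 1 and right-continuous steps."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.r_[1.0, self.surv]
        out = s[idx]
        return float(out) if out.ndim == 0 else out


def km_estimate(outcome: SurvivalOutcome,
                group_labels: np.ndarray | None = None
                ) -> KMCurve | dict[object, KMCurve]:
    """Kaplan-Meier estimate, overall or per group."""
    if group_labels is None:
        return _km_one(outcome.time, outcome.event)
    labels = np.asarray(group_labels)
    if labels.shape[0] != outcome.n:
        raise ValueError("group labels must align with the outcome")
    out: dict[object, KMCurve] = {}
    for lab in pd.unique(labels):
        m = labels == lab
        if not m.any():
            raise ValueError(f"empty group {lab!r}")
        out[lab] = _km_one(outcome.time[m], outcome.event[m], label=str(lab))
    return out


def _km_one(time: np.ndarray, event: np.ndarray, label: str | None = None) -> KMCurve:
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    uniq, first = np.unique(t, return_index=True)
    at_risk_all = n - first
    d = np.zeros(uniq.size)
    np.add.at(d, np.searchsorted(uniq, t[e == 1]), 1)
    has_ev = d > 0
    et, dd, rr = uniq[has_ev], d[has_ev], at_risk_all[has_ev].astype(float)
    surv = np.cumprod(1.0 - dd / rr)
    return KMCurve(event_times=et, surv=surv, at_risk=rr.astype(int),
                   n_events=dd.astype(int), label=label)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogrankResult:
    chi_square: float
    p_value: float
    df: int
    observed: np.ndarray = field(default=None)
    expected: np.ndarray = field(default=None)


def logrank_test(outcome: SurvivalOutcome, group_labels) -> LogrankResult:
    """Unweighted k-sample log-rank test (chi-squared with k-1 df).

    With zero events overall the statistic is 0 and p = 1 by convention.
    """
    labels = np.asarray(group_labels)
    if labels.shape[0] != outcome.n:
        raise ValueError("group labels must align with the outcome")
    uniq_labels = pd.unique(labels)
    k = uniq_labels.size
    if k < 2:
        raise ValueError("at least two nonempty groups required")
    if outcome.n_events == 0:
        _log.info("logrank_test: zero events; returning p = 1")
        return LogrankResult(0.0, 1.0, k - 1)

    order = np.argsort(outcome.time, kind="stable")
    t = outcome.time[order]
    e = outcome.event[order]
    # recode group labels to 0..k-1 preserving first-appearance order
    lab_to_idx = {lab: i for i, lab in enumerate(uniq_labels)}
    g = np.fromiter((lab_to_idx[x] for x in labels[order]), dtype=int, count=t.size)

    uniq_t, first = np.unique(t, return_index=True)
    # events per (time, group)
    ev_rows = e == 1
    ti = np.searchsorted(uniq_t, t)
    d_tg = np.zeros((uniq_t.size, k))
    np.add.at(d_tg, (ti[ev_rows], g[ev_rows]), 1.0)
    # at-risk per (time, group): reverse cumulative count of members
    memb = np.zeros((t.size, k))
    memb[np.arange(t.size), g] = 1.0
    n_tg = _revcumsum(memb, axis=0)[first]
    n_t = n_tg.sum(axis=1)
    d_t = d_tg.sum(axis=1)
    has_ev = d_t > 0
    d_tg, n_tg, n_t, d_t = d_tg[has_ev], n_tg[has_ev], n_t[has_ev], d_t[has_ev]

    observed = d_tg.sum(axis=0)
    expected = (d_t[:, None] * n_tg / n_t[:, None]).sum(axis=0)
    # hypergeometric covariance, groups 0..k-2
    with np.errstate(divide="ignore", invalid="ignore"):
        mult = np.where(n_t > 1, d_t * (n_t - d_t) / (n_t - 1), 0.0)
    pi = n_tg / n_t[:, None]
    v = np.einsum("t,tj,tl->jl", mult, pi, -pi)
    v[np.arange(k), np.arange(k)] += (mult[:, None] * pi * 1.0).sum(axis=0)
    oe = (observed - expected)[: k - 1]
    vsub = v[: k - 1, : k - 1]
    try:
        chi = float(oe @ np.linalg.solve(vsub, oe))
    except np.linalg.LinAlgError:
        vpinv = np.linalg.pinv(vsub)
        chi = float(oe @ vpinv @ oe)
    if not np.isfinite(chi) or chi < 0:
        chi = 0.0
    p = float(stats.chi2.sf(chi, k - 1))
    return LogrankResult(chi, p, k - 1, observed=observed, expected=expected)
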