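"""L1-constrained Cox partial-likelihood maximization by the gradient lasso.

The fitting problem is

    maximize  l(beta)   subject to  ||beta||_1 <= s,

where ``l`` is the Cox partial log-likelihood.  The solver is a
coordinate-wise gradient (Frank--Wolfe style) scheme over the L1 ball, whose
vertices are ``+/- s e_k``:

* *addition step* — pick the coordinate with the largest absolute gradient,
  move toward the corresponding signed vertex with an exact 1-d line search
  (the objective is concave along the segment);
* *deletion step* — when an active coefficient's sign opposes its gradient,
  try shrinking that coordinate toward zero, again with an exact line search.
  This is the "away"/drop move that lets the iterate leave a bad vertex and
  restores fast convergence near sparse solutions.

Both moves keep the iterate inside the L1 ball and never decrease the
objective, so the partial log-likelihood is monotone across iterations.  The
stopping rule is the constrained-optimality (Frank--Wolfe duality) gap

    gap = s * ||g||_inf - g . beta  >= l(beta*) - l(beta),

which is zero exactly at a KKT point of the constrained problem.

The constraint (bound) form is the primary parameterization; the penalty form
``lambda * ||beta||_1`` corresponds through the KKT identity
``lambda = ||g(beta_hat)||_inf`` at the solution, exposed via
:func:`penalty_equivalent`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .survival import CoxData, SurvivalOutcome

_log = logging.getLogger(__name__)

__all__ = ["LassoFit", "gradient_lasso_cox", "lasso_path", "select_bound",
           "penalty_equivalent"]


@dataclass
class LassoFit:
    """Sparse Cox coefficients under an L1 bound, with fit diagnostics."""

    bound_s: float
    coefficients: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    gap: float
    names: list | None = None
    path: list[tuple[float, float, int]] | None = None  # (s, loglik, n_active)

    @property
    def active_idx(self) -> np.ndarray:
        return np.flatnonzero(self.coefficients != 0.0)

    @property
    def active_ids(self) -> list:
        idx = self.active_idx
        if self.names is None:
            return idx.tolist()
        return [self.names[i] for i in idx]

    @property
    def n_active(self) -> int:
        return int((self.coefficients != 0.0).sum())


def _line_search(cd: CoxData, eta: np.ndarray, deta: np.ndarray,
                 hi: float) -> float:
    """Exact maximizer of the concave ``gamma -> l(eta + gamma * deta)``
    on [0, hi], located by root-finding on the directional derivative.

    Working with the derivative rather than log-likelihood differences keeps
    full floating-point resolution near the optimum (differences of nearly
    equal log-likelihoods bottom out at ~1e-13).
    """
    if hi <= 0:
        return 0.0
    d0 = cd.dirderiv(eta, deta)
    if d0 <= 0:
        return 0.0
    d_hi = cd.dirderiv(eta + hi * deta, deta)
    if d_hi >= 0:
        return hi
    return float(optimize.brentq(
        lambda g: cd.dirderiv(eta + g * deta, deta), 0.0, hi,
        xtol=1e-15 * max(1.0, hi), rtol=8.9e-16, maxiter=200))


def _fit_sorted(cd: CoxData, xs: np.ndarray, s: float, tol: float,
                max_iter: int, deletion: bool, beta0: np.ndarray | None = None
                ) -> tuple[np.ndarray, float, int, bool, float]:
    """Core solver; `xs` already in the CoxData's sorted row order.

    Each iteration picks the coordinate with the largest absolute gradient
    (the addition target) and moves toward its signed vertex.  With
    ``deletion=True`` the step is *pairwise*: the mass comes out of the
    worst active coordinate — the one whose sign most opposes its gradient —
    or out of the unused part of the L1 budget when that is worse still, so
    sign-opposed coefficients are shrunk (and can hit exactly zero) in the
    same move.  With ``deletion=False`` the plain convex-combination step
    ``(1 - a) beta + a vertex`` is used.  Both variants use an exact 1-d
    line search, so the partial log-likelihood never decreases.
    """
    n, k = xs.shape
    if s < 0:
        raise ValueError("L1 bound s must be nonnegative")
    if s == 0 or k == 0:
        beta = np.zeros(k)
        return beta, cd.loglik(np.zeros(n)), 0, True, 0.0

    beta = np.zeros(k) if beta0 is None else beta0.copy()
    eta = xs @ beta
    ll, g = cd.loglik_grad(xs, beta, eta=eta)
    gap = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        gap = s * float(np.max(np.abs(g))) - float(g @ beta)
        if gap < tol:
            return beta, ll, it - 1, True, gap
        j = int(np.argmax(np.abs(g)))
        sgn_j = 1.0 if g[j] >= 0 else -1.0

        if deletion:
            # away atom: worst active signed vertex, or the slack (origin)
            slack = 1.0 - float(np.abs(beta).sum()) / s
            away_coord = -1
            away_score = 0.0 if slack > 1e-15 else np.inf
            active = np.flatnonzero(beta != 0.0)
            if active.size:
                scores = s * np.sign(beta[active]) * g[active]
                worst = int(np.argmin(scores))
                if scores[worst] < away_score:
                    away_coord = int(active[worst])
                    away_score = float(scores[worst])
            d_eta = (s * sgn_j) * xs[:, j]
            if away_coord >= 0:
                sgn_a = np.sign(beta[away_coord])
                d_eta = d_eta - (s * sgn_a) * xs[:, away_coord]
                gamma_max = float(abs(beta[away_coord])) / s
            else:
                gamma_max = slack
            g_star = _line_search(cd, eta, d_eta, gamma_max)
            if g_star > 0:
                beta[j] += g_star * s * sgn_j
                if away_coord >= 0:
                    beta[away_coord] -= g_star * s * sgn_a
                    if abs(beta[away_coord]) < 1e-12:
                        beta[away_coord] = 0.0
        else:
            eta_v = (s * sgn_j) * xs[:, j]
            a_star = _line_search(cd, eta, eta_v - eta, 1.0)
            if a_star > 0:
                beta = (1.0 - a_star) * beta
                beta[j] += a_star * s * sgn_j
        beta[np.abs(beta) < 1e-14] = 0.0
        eta = xs @ beta
        new_ll, g = cd.loglik_grad(xs, beta, eta=eta)
        if new_ll < ll - 1e-9:  # guard: exact line search cannot go downhill
            _log.warning("line search regression (%.3g); keeping new iterate",
                         ll - new_ll)
        ll = new_ll
    gap = s * float(np.max(np.abs(g))) - float(g @ beta)
    return beta, ll, it, gap < tol, gap


def gradient_lasso_cox(x: np.ndarray, outcome: SurvivalOutcome, s: float,
                       tol: float = 1e-7, max_iter: int = 5000,
                       deletion: bool = True, ties: str = "efron",
                       names: list | None = None,
                       check_standardized: bool = True) -> LassoFit:
    """Maximize the Cox partial likelihood subject to ``||beta||_1 <= s``.

    Parameters
    ----------
    x : (n_samples, n_features) array, complete and column-standardized.
    s : nonnegative L1 constraint radius; ``s = 0`` returns the null model.
    tol : tolerance on the constrained-optimality gap (log-likelihood units).
    deletion : include the shrink-toward-zero move (recommended; switch off
        for the plain coordinate-addition algorithm).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != outcome.n:
        raise ValueError("covariate rows must match outcome length")
    if check_standardized and x.shape[1]:
        sd = x.std(axis=0, ddof=1)
        if np.any(np.abs(sd - 1.0) > 0.01):
            warnings.warn("covariates do not look standardized (sd != 1); "
                          "the L1 bound mixes scales", stacklevel=2)
    cd = CoxData(outcome, ties=ties)
    xs = cd.sort_rows(x)
    beta, ll, n_iter, conv, gap = _fit_sorted(cd, xs, float(s), tol, max_iter, deletion)
    if not conv:
        _log.warning("gradient_lasso_cox: gap %.3g above tol after %d iterations",
                     gap, n_iter)
    return LassoFit(bound_s=float(s), coefficients=beta, loglik=ll,
                    n_iter=n_iter, converged=conv, gap=gap, names=names)


def lasso_path(x: np.ndarray, outcome: SurvivalOutcome, s_grid,
               ties: str = "efron", tol: float = 1e-7, max_iter: int = 5000,
               deletion: bool = True, names: list | None = None) -> list[LassoFit]:
    """Fit a warm-started sequence of bounds (s_grid must be increasing)."""
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s_grid) < 0):
        raise ValueError("s_grid must be nondecreasing")
    x = np.asarray(x, dtype=float)
    cd = CoxData(outcome, ties=ties)
    xs = cd.sort_rows(x)
    fits: list[LassoFit] = []
    beta0 = None
    trace: list[tuple[float, float, int]] = []
    for s in s_grid:
        beta, ll, n_iter, conv, gap = _fit_sorted(
            cd, xs, float(s), tol, max_iter, deletion, beta0=beta0)
        beta0 = beta
        trace.append((float(s), ll, int((beta != 0).sum())))
        fits.append(LassoFit(bound_s=float(s), coefficients=beta.copy(),
                             loglik=ll, n_iter=n_iter, converged=conv,
                             gap=gap, names=names, path=list(trace)))
    return fits


def penalty_equivalent(fit: LassoFit, x: np.ndarray,
                       outcome: SurvivalOutcome, ties: str = "efron") -> float:
    """KKT-equivalent penalty weight lambda for a bound-form solution."""
    cd = CoxData(outcome, ties=ties)
    xs = cd.sort_rows(np.asarray(x, dtype=float))
    _, g = cd.loglik_grad(xs, fit.coefficients)
    return float(np.max(np.abs(g)))


def select_bound(x: np.ndarray, outcome: SurvivalOutcome, s_grid,
                 n_folds: int = 5, seed: int = 0, ties: str = "efron",
                 one_se: bool = True, tol: float = 1e-7,
                 max_iter: int = 5000):
    """Choose the L1 bound by k-fold cross-validated partial likelihood.

    Uses the van Houwelingen form: each fold contributes
    ``l_all(beta_-k) - l_train(beta_-k)``, evaluated on the full-data and
    training-data partial likelihoods.  Under the one-standard-error rule the
    smallest bound whose mean CV likelihood is within one SE of the best is
    returned (preferring sparser models); otherwise the argmax.

    Returns ``(s_opt, cv_trace)`` with cv_trace a DataFrame indexed by s.
    """
    import pandas as pd

    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.size == 0:
        raise ValueError("empty s_grid")
    if np.any(np.diff(s_grid) < 0):
        raise ValueError("s_grid must be increasing")
    if s_grid.size == 1:
        return float(s_grid[0]), pd.DataFrame({"mean_cvl": [np.nan]}, index=s_grid)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    x = np.asarray(x, dtype=float)
    n = outcome.n
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(fold_of)

    cd_all = CoxData(outcome, ties=ties)
    xs_all = cd_all.sort_rows(x)
    cvl = np.full((n_folds, s_grid.size), np.nan)
    for fold in range(n_folds):
        tr = np.flatnonzero(fold_of != fold)
        out_tr = outcome.subset(tr)
        if out_tr.n_events < 2:
            _log.warning("select_bound: fold %d has < 2 events; skipped", fold)
            continue
        cd_tr = CoxData(out_tr, ties=ties)
        xs_tr = cd_tr.sort_rows(x[tr])
        beta0 = None
        for si, s in enumerate(s_grid):
            try:
                beta, ll_tr, _, _, _ = _fit_sorted(
                    cd_tr, xs_tr, float(s), tol, max_iter, True, beta0=beta0)
            except Exception as err:  # pragma: no cover - defensive
                _log.warning("select_bound: fit failed at s=%.3g (%s)", s, err)
                continue
            beta0 = beta
            ll_all = cd_all.loglik(xs_all @ beta)
            cvl[fold, si] = ll_all - ll_tr
    valid = ~np.all(np.isnan(cvl), axis=0)
    if not valid.any():
        raise RuntimeError("all cross-validation fits failed")
    dropped = np.flatnonzero(~valid)
    if dropped.size:
        _log.warning("select_bound: dropping grid points %s (all folds failed)",
                     s_grid[dropped])
    mean_cvl = np.nanmean(cvl, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se_cvl = np.nanstd(cvl, axis=0, ddof=1) / np.sqrt(
            np.sum(~np.isnan(cvl), axis=0))
    mean_masked = np.where(valid, mean_cvl, -np.inf)
    best = int(np.argmax(mean_masked))
    if one_se:
        threshold = mean_cvl[best] - se_cvl[best]
        ok = np.flatnonzero(valid & (mean_cvl >= threshold))
        choice = int(ok[0]) if ok.size else best
    else:
        choice = best
    trace = pd.DataFrame({"mean_cvl": mean_cvl, "se_cvl": se_cvl,
                          "n_folds": np.sum(~np.isnan(cvl), axis=0)},
                         index=pd.Index(s_grid, name="s"))
    return float(s_grid[choice]), trace
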