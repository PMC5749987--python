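"""Beta-regression GAM for hourly activity, with AICc all-subsets selection.

The response is mean hourly acoustic activity (MAA) normalized to [0, 1]
and squeezed off the boundary; it is modelled as Beta(mu * phi,
(1 - mu) * phi) with a logit link on the mean and a common precision phi.
Continuous predictors (hour of day, hours since explosion, cumulative
hours) enter as penalized cubic B-spline smooths with a second-order
difference penalty; categorical predictors as unpenalized dummies;
ordinal predictors linearly.  The smoothing parameter is chosen by
minimizing AICc over a log-spaced grid, with the effective number of
parameters taken as the trace of the penalized influence approximation
plus one for phi — the same criterion used to rank predictor subsets, so
smoothness selection and model selection agree on what "complexity" is.

The estimator follows scikit-learn conventions: ``BetaGAM(terms).fit(X, y)``
with fitted attributes carrying a trailing underscore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "boundary_transform",
    "inverse_boundary_transform",
    "BetaGAM",
    "fit_beta_gam",
    "all_subsets_selection",
    "deviance_by_predictor",
    "residual_autocorrelation",
]


def boundary_transform(y, n: int | None = None) -> np.ndarray:
    """Squeeze values in [0, 1] strictly inside (0, 1).

    ``y' = (y (n - 1) + 1/2) / n`` with n the sample size; 0.5 is a fixed
    point for every n.  The beta likelihood is undefined at the boundary
    and zero-activity hours are common, so this is applied once, globally,
    before any fit.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("values must lie in [0, 1]")
    if n is None:
        n = len(y)
    return (y * (n - 1) + 0.5) / n


def inverse_boundary_transform(y_prime, n: int) -> np.ndarray:
    y_prime = np.asarray(y_prime, dtype=float)
    return (y_prime * n - 0.5) / (n - 1)


# ---------------------------------------------------------------- basis ----

def _bspline_basis(x: np.ndarray, knots: np.ndarray, k: int) -> np.ndarray:
    """Cubic B-spline design matrix with clamped knot vector; x is clipped
    to the knot range so prediction slightly outside the training range is
    defined."""
    from scipy.interpolate import BSpline

    x = np.clip(x, knots[0], knots[-1])
    t = np.concatenate([[knots[0]] * 3, knots, [knots[-1]] * 3])
    # nudge the right edge inside so the last basis function is evaluated
    xe = np.minimum(x, knots[-1] - 1e-10 * max(1.0, abs(knots[-1])))
    return BSpline.design_matrix(xe, t, 3).toarray()


@dataclass
class _Block:
    """One design-matrix block: its columns, penalty and metadata."""

    name: str
    kind: str                 # "intercept" | "smooth" | "linear" | "factor"
    sl: slice
    penalty: np.ndarray | None = None     # in block coordinates, or None
    knots: np.ndarray | None = None
    constraint: np.ndarray | None = None  # k x (k-1) centering transform
    levels: list | None = None


class _Design:
    """Build and re-apply the model design matrix for a term list."""

    def __init__(self, terms: list[tuple[str, str]], n_splines: int = 10):
        self.terms = list(terms)
        self.n_splines = n_splines
        self.blocks: list[_Block] = []

    def fit_build(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(X), 1))]
        self.blocks = [_Block("(intercept)", "intercept", slice(0, 1))]
        pos = 1
        for kind, name in self.terms:
            x = X[name]
            if kind == "s":
                k = self.n_splines
                xv = x.to_numpy(dtype=float)
                lo, hi = float(np.min(xv)), float(np.max(xv))
                if hi <= lo:
                    raise ValueError(f"smooth term {name!r} has no variation")
                knots = np.linspace(lo, hi, k - 2)
                B = _bspline_basis(xv, knots, k)
                # sum-to-zero constraint removes confounding with the intercept
                c = B.sum(axis=0, keepdims=True)
                Z = _null_space(c)
                Bc = B @ Z
                D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
                S = Z.T @ D.T @ D @ Z
                self.blocks.append(
                    _Block(name, "smooth", slice(pos, pos + Bc.shape[1]),
                           penalty=S, knots=knots, constraint=Z)
                )
                cols.append(Bc)
                pos += Bc.shape[1]
            elif kind == "linear":
                v = x.to_numpy(dtype=float)[:, None]
                self.blocks.append(_Block(name, "linear", slice(pos, pos + 1)))
                cols.append(v)
                pos += 1
            elif kind == "factor":
                levels = sorted(pd.unique(x.astype(str)))
                dummies = np.column_stack(
                    [(x.astype(str) == lv).to_numpy(float) for lv in levels[1:]]
                ) if len(levels) > 1 else np.zeros((len(X), 0))
                self.blocks.append(
                    _Block(name, "factor", slice(pos, pos + dummies.shape[1]),
                           levels=levels)
                )
                cols.append(dummies)
                pos += dummies.shape[1]
            else:
                raise ValueError(f"unknown term kind {kind!r}")
        self.p = pos
        return np.hstack(cols)

    def build(self, X: pd.DataFrame) -> np.ndarray:
        cols = [np.ones((len(X), 1))]
        for b in self.blocks[1:]:
            x = X[b.name]
            if b.kind == "smooth":
                B = _bspline_basis(x.to_numpy(float), b.knots, self.n_splines)
                cols.append(B @ b.constraint)
            elif b.kind == "linear":
                cols.append(x.to_numpy(float)[:, None])
            elif b.kind == "factor":
                cols.append(
                    np.column_stack(
                        [(x.astype(str) == lv).to_numpy(float) for lv in b.levels[1:]]
                    ) if len(b.levels) > 1 else np.zeros((len(X), 0))
                )
        return np.hstack(cols)

    def penalty_matrix(self, lam: float) -> np.ndarray:
        S = np.zeros((self.p, self.p))
        for b in self.blocks:
            if b.penalty is not None:
                S[b.sl, b.sl] = lam * b.penalty
        return S

    @property
    def has_smooth(self) -> bool:
        return any(b.kind == "smooth" for b in self.blocks)


def _null_space(c: np.ndarray) -> np.ndarray:
    from scipy.linalg import null_space

    return null_space(c)


# ------------------------------------------------------------ likelihood ----

def _beta_loglik(y, mu, phi) -> float:
    a = mu * phi
    b = (1.0 - mu) * phi
    return float(
        np.sum(
            special.gammaln(phi)
            - special.gammaln(a)
            - special.gammaln(b)
            + (a - 1.0) * np.log(y)
            + (b - 1.0) * np.log1p(-y)
        )
    )


def _saturated_loglik(y, phi) -> float:
    return _beta_loglik(y, y, phi)


_MU_EPS = 1e-10


def _mu(eta):
    return np.clip(special.expit(eta), _MU_EPS, 1.0 - _MU_EPS)


class BetaGAM(RegressorMixin, BaseEstimator):
    """Penalized-spline beta-regression GAM with logit link.

    Parameters
    ----------
    terms : list of (kind, column) tuples
        ``("s", col)`` penalized smooth, ``("linear", col)`` linear,
        ``("factor", col)`` categorical.  The intercept is always included.
    n_splines : int
        Basis functions per smooth (before the centering constraint).
    lambda_grid : array-like
        Candidate smoothing parameters (shared across smooths); the one
        minimizing AICc wins.  Ignored for models without smooths.
    max_iter, tol : fitting control for the Fisher-scoring iterations.

    Attributes
    ----------
    coef_, phi_, edf_, edf_by_term_, loglik_, aicc_, deviance_,
    null_deviance_, deviance_explained_, r2_, loglik_trace_, lambda_
    """

    def __init__(
        self,
        terms: list[tuple[str, str]] = (),
        n_splines: int = 10,
        lambda_grid=(0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 1e4, 1e6, 1e8),
        max_iter: int = 200,
        tol: float = 1e-9,
    ):
        self.terms = terms
        self.n_splines = n_splines
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter
        self.tol = tol

    # -- core penalized fit at fixed lambda ---------------------------------
    def _fit_lambda(self, Xm, y, S):
        n, p = Xm.shape
        ystar = np.log(y) - np.log1p(-y)
        ridge = S + 1e-8 * np.eye(p)
        beta = np.linalg.solve(Xm.T @ Xm + ridge, Xm.T @ ystar)
        mu = _mu(Xm @ beta)
        resid_var = max(float(np.var(y - mu)), 1e-8)
        phi = float(np.clip(np.mean(mu * (1 - mu)) / resid_var - 1.0, 2.0, 500.0))

        def penalized(beta, phi):
            return _beta_loglik(y, _mu(Xm @ beta), phi) - 0.5 * beta @ S @ beta

        obj = penalized(beta, phi)
        trace = [obj]
        for _ in range(self.max_iter):
            mu = _mu(Xm @ beta)
            a, b = mu * phi, (1 - mu) * phi
            mustar = special.digamma(a) - special.digamma(b)
            T = mu * (1 - mu)
            w = phi**2 * (special.polygamma(1, a) + special.polygamma(1, b)) * T**2
            score = phi * Xm.T @ (T * (ystar - mustar)) - S @ beta
            H = (Xm * w[:, None]).T @ Xm + S
            try:
                step = np.linalg.solve(H + 1e-10 * np.eye(p), score)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, score, rcond=None)[0]
            new_obj, scale = obj, 1.0
            for _ in range(30):
                cand = beta + scale * step
                cand_obj = penalized(cand, phi)
                if np.isfinite(cand_obj) and cand_obj >= obj - 1e-12:
                    beta, new_obj = cand, cand_obj
                    break
                scale *= 0.5

            # phi Newton step on the log scale, with step halving
            mu = _mu(Xm @ beta)
            a, b = mu * phi, (1 - mu) * phi
            mustar = special.digamma(a) - special.digamma(b)
            s_phi = float(
                np.sum(mu * (ystar - mustar) + np.log1p(-y) - special.digamma(b)
                       + special.digamma(phi))
            )
            i_phi = float(
                np.sum(special.polygamma(1, a) * mu**2
                       + special.polygamma(1, b) * (1 - mu) ** 2
                       - special.polygamma(1, phi))
            )
            dlog = s_phi * phi / max(i_phi * phi**2, 1e-8)
            dlog = float(np.clip(dlog, -2.0, 2.0))
            scale = 1.0
            for _ in range(30):
                cand_phi = float(np.clip(phi * np.exp(scale * dlog), 1e-2, 1e6))
                cand_obj = penalized(beta, cand_phi)
                if np.isfinite(cand_obj) and cand_obj >= new_obj - 1e-12:
                    phi, new_obj = cand_phi, cand_obj
                    break
                scale *= 0.5

            trace.append(new_obj)
            if abs(new_obj - obj) < self.tol * (abs(obj) + 1.0):
                obj = new_obj
                break
            obj = new_obj

        mu = _mu(Xm @ beta)
        a, b = mu * phi, (1 - mu) * phi
        T = mu * (1 - mu)
        w = phi**2 * (special.polygamma(1, a) + special.polygamma(1, b)) * T**2
        XtWX = (Xm * w[:, None]).T @ Xm
        F = np.linalg.solve(XtWX + S + 1e-10 * np.eye(p), XtWX)
        edf_diag = np.diag(F)
        ll = _beta_loglik(y, mu, phi)
        return beta, phi, ll, edf_diag, trace

    @staticmethod
    def _aicc(ll: float, k: float, n: int) -> float:
        aic = -2.0 * ll + 2.0 * k
        if n - k - 1 <= 0:
            return np.inf
        return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=float)
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError(
                "response must lie strictly in (0, 1); apply boundary_transform first"
            )
        self.design_ = _Design(list(self.terms), self.n_splines)
        Xm = self.design_.fit_build(pd.DataFrame(X))
        n = len(y)

        grid = list(self.lambda_grid) if self.design_.has_smooth else [0.0]
        best = None
        for lam in grid:
            S = self.design_.penalty_matrix(lam)
            beta, phi, ll, edf_diag, trace = self._fit_lambda(Xm, y, S)
            k = float(edf_diag.sum()) + 1.0
            aicc = self._aicc(ll, k, n)
            if best is None or aicc < best[0]:
                best = (aicc, lam, beta, phi, ll, edf_diag, trace)

        aicc, lam, beta, phi, ll, edf_diag, trace = best
        self.lambda_ = lam
        self.coef_ = beta
        self.phi_ = phi
        self.loglik_ = ll
        self.loglik_trace_ = trace
        self.edf_ = float(edf_diag.sum())
        self.edf_by_term_ = {
            b.name: float(edf_diag[b.sl].sum()) for b in self.design_.blocks
        }
        self.aicc_ = aicc
        self.n_obs_ = n

        mu = _mu(Xm @ beta)
        self.fitted_ = mu
        self.residuals_ = y - mu
        self.deviance_ = 2.0 * (_saturated_loglik(y, phi) - ll)
        self.null_deviance_ = self._null_deviance(y, phi)
        self.deviance_explained_ = (
            1.0 - self.deviance_ / self.null_deviance_
            if self.null_deviance_ > 0
            else 0.0
        )
        ssr = float(np.sum((y - mu) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ssr / sst if sst > 0 else 0.0
        return self

    @staticmethod
    def _null_deviance(y, phi) -> float:
        """Deviance of the best constant-mean beta model at precision phi."""
        ystar_bar = float(np.mean(np.log(y) - np.log1p(-y)))

        def score(eta):
            m = _mu(np.array([eta]))[0]
            return special.digamma(m * phi) - special.digamma((1 - m) * phi) - ystar_bar

        eta0 = optimize.brentq(score, -30.0, 30.0)
        mu0 = _mu(np.full_like(y, eta0))
        return 2.0 * (_saturated_loglik(y, phi) - _beta_loglik(y, mu0, phi))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xm = self.design_.build(pd.DataFrame(X))
        return _mu(Xm @ self.coef_)

    def smooth_component(self, name: str, x: np.ndarray) -> np.ndarray:
        """Centered fitted smooth f(x) on the linear-predictor scale."""
        for b in self.design_.blocks:
            if b.name == name and b.kind == "smooth":
                B = _bspline_basis(np.asarray(x, float), b.knots, self.n_splines)
                return (B @ b.constraint) @ self.coef_[b.sl]
        raise KeyError(f"no smooth term named {name!r}")


def fit_beta_gam(X: pd.DataFrame, y, terms, **kwargs) -> BetaGAM:
    """Functional wrapper: fit a :class:`BetaGAM` and return it."""
    return BetaGAM(terms=list(terms), **kwargs).fit(X, y)


# -------------------------------------------------------------- selection ----

def _term_names(terms) -> str:
    return " + ".join(name for _, name in terms) if terms else "(intercept)"


def all_subsets_selection(
    X: pd.DataFrame,
    y,
    candidate_terms: list[tuple[str, str]],
    always_terms: list[tuple[str, str]] = (),
    **gam_kwargs,
) -> pd.DataFrame:
    """Fit every subset of the candidate predictors and rank by AICc.

    The intercept (and any ``always_terms``) is in every model.  Returns a
    table sorted by AICc with columns ``predictors``, ``r2``,
    ``deviance_explained``, ``edf``, ``aicc``, ``delta_aicc``,
    ``n_predictors`` and ``selected``.  The minimum-AICc model is selected;
    if several models tie to 2 d.p. within the delta <= 2 set, the one
    with fewest predictors wins.
    """
    if len(candidate_terms) > 12:
        raise ValueError("more than 12 candidate predictors (2^k fits) refused")
    from itertools import combinations

    rows = []
    n = len(np.asarray(y))
    for r in range(len(candidate_terms) + 1):
        for subset in combinations(candidate_terms, r):
            terms = list(always_terms) + list(subset)
            model = BetaGAM(terms=terms, **gam_kwargs)
            try:
                model.fit(X, y)
            except Exception as exc:  # noqa: BLE001 - skipped subsets are logged
                rows.append(
                    {"predictors": _term_names(terms), "r2": np.nan,
                     "deviance_explained": np.nan, "edf": np.nan, "aicc": np.nan,
                     "n_predictors": len(subset), "error": str(exc)}
                )
                continue
            if n <= model.edf_ + 2:
                continue
            rows.append(
                {
                    "predictors": _term_names(terms),
                    "r2": model.r2_,
                    "deviance_explained": model.deviance_explained_,
                    "edf": model.edf_,
                    "aicc": model.aicc_,
                    "n_predictors": len(subset),
                    "error": "",
                }
            )
    table = pd.DataFrame(rows).dropna(subset=["aicc"]).sort_values("aicc")
    table = table.reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    best_rounded = round(float(table["aicc"].iloc[0]), 2)
    tied = table[(table["delta_aicc"] <= 2.0) & (table["aicc"].round(2) == best_rounded)]
    chosen = tied.sort_values(["n_predictors", "aicc"]).index[0]
    table["selected"] = False
    table.loc[chosen, "selected"] = True
    return table


def deviance_by_predictor(
    X: pd.DataFrame,
    y,
    terms: list[tuple[str, str]],
    **gam_kwargs,
) -> pd.DataFrame:
    """Per-predictor explained-deviance contributions by leave-one-out refit.

    Contribution of a predictor = DE(full) - DE(full without it); the
    contributions are reported individually and need not sum to DE(full).
    """
    full = BetaGAM(terms=list(terms), **gam_kwargs).fit(X, y)
    rows = [
        {"predictor": "(whole model)", "deviance_explained_without": np.nan,
         "contribution": full.deviance_explained_}
    ]
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        try:
            reduced = BetaGAM(terms=reduced_terms, **gam_kwargs).fit(X, y)
            de = reduced.deviance_explained_
            contrib = full.deviance_explained_ - de
        except Exception:  # noqa: BLE001 - refit failure -> missing
            de, contrib = np.nan, np.nan
        rows.append(
            {"predictor": term[1], "deviance_explained_without": de,
             "contribution": contrib}
        )
    out = pd.DataFrame(rows)
    body = out.iloc[1:].sort_values("contribution", ascending=False)
    return pd.concat([out.iloc[:1], body], ignore_index=True)


# ------------------------------------------------------------- diagnostics ----

def residual_autocorrelation(
    residuals: np.ndarray,
    nlags: int = 48,
    n_permutations: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, float, float]:
    """ACF, Durbin-Watson statistic and a permutation p-value.

    Residuals must be ordered in time.  DW = sum((e_t - e_{t-1})^2) /
    sum(e_t^2); its null distribution under exchangeability is obtained by
    permuting the residual order (the classical DW bounds assume an
    ordinary linear regression, which this is not).  The p-value is the
    two-sided tail fraction of |DW - 2| under permutation.
    """
    from statsmodels.stats.stattools import durbin_watson
    from statsmodels.tsa.stattools import acf

    e = np.asarray(residuals, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 residuals")
    lags = min(nlags, len(e) - 1)
    acf_vals = acf(e, nlags=lags, fft=True)
    dw = float(durbin_watson(e))
    rng = np.random.default_rng(seed)
    stat = abs(dw - 2.0)
    hits = 1  # the observed ordering counts as one permutation
    for _ in range(n_permutations):
        perm = rng.permutation(e)
        if abs(durbin_watson(perm) - 2.0) >= stat:
            hits += 1
    p = hits / (n_permutations + 1)
    return acf_vals, dw, float(p)
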