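"""Penalized-smooth regression engine (the GAMM layer).

P-spline generalized additive models for the gamma (log link) and
binomial (logit link) families: cubic B-spline bases on equally spaced
knots with second-difference penalties, a cyclic variant that wraps at a
stated period (24 h for time of day), and random intercepts implemented
as ridge-penalized dummy blocks.  Smoothing parameters are chosen by GCV
(deterministic), effective degrees of freedom come from the trace of the
influence decomposition, and model comparison uses a deviance-based AIC
with the total EDF as the parameter count.

This is a self-contained penalized-IRLS implementation in the classic
P-spline style (Eilers & Marx), not a re-implementation of any specific
GAMM package; random effects are ridge blocks rather than full mixed
model machinery, which is adequate for the intercept-only groupings used
here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline


class SmoothConvergenceError(RuntimeError):
    pass


@dataclass
class SmoothSpec:
    """Declaration of one smooth model term.

    kind: 'cs' (cubic spline), 'cc' (cyclic cubic spline, needs
    ``period``), or 're' (random intercept on a categorical column).
    ``k`` is the basis dimension for spline terms.
    """

    name: str
    kind: str = "cs"
    k: int = 10
    period: float | None = None


@dataclass
class _TermBasis:
    spec: SmoothSpec
    knots: np.ndarray | None  # spline knot vector (None for 're')
    levels: np.ndarray | None  # category levels (None for splines)
    col_means: np.ndarray  # centering applied to the basis block
    S: np.ndarray  # penalty matrix
    sl: slice  # columns of this term in the model matrix
    xmin: float = 0.0
    xmax: float = 0.0


def build_basis(x, kind: str = "cs", k: int = 10, period: float | None = None):
    """Spline basis and penalty for a covariate vector.

    Returns ``(B, S, knots)``: the (n, k) design block, the (k, k)
    second-difference penalty, and the knot vector.  'cs' uses clamped
    cubic B-splines on equally spaced knots (rows sum to one; the penalty
    annihilates linear functions).  'cc' wraps the basis and penalty at
    ``period`` so fit and derivatives match at the two ends.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    if k < 4:
        raise ValueError("basis dimension k must be >= 4 for cubic splines")
    if len(np.unique(x)) < k:
        raise ValueError(
            f"basis dimension k={k} exceeds the {len(np.unique(x))} distinct values"
        )
    if kind == "cs":
        knots = _cs_knots(x.min(), x.max(), k)
        B = _cs_design(x, knots)
        D = np.diff(np.eye(k), n=2, axis=0)
        return B, D.T @ D, knots
    if kind == "cc":
        if period is None or period <= 0:
            raise ValueError("cyclic basis requires a positive period")
        knots = _cc_knots(period, k)
        B = _cc_design(x, knots, k, period)
        D = _cyclic_diff2(k)
        return B, D.T @ D, knots
    raise ValueError(f"unknown basis kind '{kind}'")


def _cs_knots(lo: float, hi: float, k: int) -> np.ndarray:
    # uniform (unclamped) knots: equally spaced Greville sites keep
    # linear-in-x functions exactly in the difference-penalty null space
    span = hi - lo if hi > lo else 1.0
    h = span / (k - 3)
    return lo + (np.arange(k + 4) - 3.0) * h


def _cs_design(x, knots) -> np.ndarray:
    lo, hi = knots[3], knots[-4]
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, knots, 3).toarray()


def _cc_knots(period: float, k: int) -> np.ndarray:
    h = period / k
    return np.arange(-3, k + 4) * h


def _cc_design(x, knots, k: int, period: float) -> np.ndarray:
    xw = np.mod(x, period)
    Bext = BSpline.design_matrix(xw, knots, 3, extrapolate=True).toarray()
    B = Bext[:, :k].copy()
    B[:, :3] += Bext[:, k : k + 3]
    return B


def _cyclic_diff2(k: int) -> np.ndarray:
    D = np.zeros((k, k))
    for i in range(k):
        D[i, i] = 1.0
        D[i, (i + 1) % k] = -2.0
        D[i, (i + 2) % k] = 1.0
    return D


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------

def _family_funcs(family: str):
    if family == "gamma":
        def inv(eta):
            return np.exp(np.clip(eta, -300, 300))

        mu_eta = inv

        def weights(mu):
            return np.ones_like(mu)  # (dmu/deta)^2 / V = mu^2 / mu^2

        def working(y, mu, eta, offset):
            return eta - offset + (y - mu) / mu

        def deviance(y, mu):
            return float(2.0 * np.sum((y - mu) / mu - np.log(y / mu)))

        def init_mu(y):
            return np.maximum(y, 1e-8)

    elif family == "binomial":
        def inv(eta):
            return 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))

        mu_eta = inv

        def weights(mu):
            return np.clip(mu * (1.0 - mu), 1e-10, None)

        def working(y, mu, eta, offset):
            return eta - offset + (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)

        def deviance(y, mu):
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

        def init_mu(y):
            return (y + 0.5) / 2.0

    else:
        raise ValueError(f"unsupported family '{family}'")
    return inv, mu_eta, weights, working, deviance, init_mu


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class GamFit:
    """Fitted penalized additive model."""

    coef: np.ndarray
    family: str
    terms: list[_TermBasis]
    linear_terms: list[str]
    offset_cols: list[str]
    lambdas: np.ndarray
    edf_by_term: dict[str, float]
    edf_total: float
    deviance: float
    aic: float
    phi: float  # dispersion (1 for binomial; Pearson estimate for gamma)
    Vb: np.ndarray  # Bayesian posterior covariance of coef
    pvalues: dict[str, float]
    n_obs: int
    response: str = ""

    def linear_predictor(self, data: pd.DataFrame, include_offset: bool = True):
        X = _model_matrix_for(self, data)
        eta = X @ self.coef
        if include_offset:
            eta = eta + _offset_vector(self.offset_cols, data)
        return X, eta

    def predict(self, data: pd.DataFrame, include_offset: bool = True) -> np.ndarray:
        inv = _family_funcs(self.family)[0]
        _, eta = self.linear_predictor(data, include_offset)
        return inv(eta)

    def predict_with_ci(
        self, data: pd.DataFrame, alpha: float = 0.05, include_offset: bool = True
    ) -> pd.DataFrame:
        """Response-scale predictions with a normal CI on the linear predictor."""
        inv = _family_funcs(self.family)[0]
        X, eta = self.linear_predictor(data, include_offset)
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.Vb, X), 0.0))
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {
                "fit": inv(eta),
                "lower": inv(eta - z * se),
                "upper": inv(eta + z * se),
            },
            index=data.index,
        )

    def term_summary(self) -> pd.DataFrame:
        rows = [
            {"term": name, "edf": self.edf_by_term[name],
             "p": self.pvalues.get(name, np.nan)}
            for name in self.edf_by_term
        ]
        return pd.DataFrame(rows)


def _offset_vector(offset_cols, data: pd.DataFrame) -> np.ndarray:
    off = np.zeros(len(data))
    for col in offset_cols:
        if col in data.columns:
            off = off + data[col].to_numpy(dtype=float)
    return off


def _assemble(
    data: pd.DataFrame,
    smooth_specs: list[SmoothSpec],
    linear_terms: list[str],
):
    """Build the model matrix: intercept | linear | smooth blocks."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    col = 1 + len(linear_terms)
    if linear_terms:
        blocks.append(data[list(linear_terms)].to_numpy(dtype=float))
    terms: list[_TermBasis] = []
    penalties: list[tuple[slice, np.ndarray]] = []
    for spec in smooth_specs:
        if spec.kind == "re":
            codes, levels = pd.factorize(data[spec.name])
            if (codes < 0).any():
                raise ValueError(f"missing values in grouping '{spec.name}'")
            m = len(levels)
            B = np.zeros((n, m))
            B[np.arange(n), codes] = 1.0
            S = np.eye(m)
            tb = _TermBasis(spec, None, levels, np.zeros(m), S, slice(col, col + m))
        else:
            x = data[spec.name].to_numpy(dtype=float)
            B, S, knots = build_basis(x, spec.kind, spec.k, spec.period)
            means = B.mean(axis=0)
            B = B - means  # sum-to-zero centering; intercept carries the level
            tb = _TermBasis(
                spec, knots, None, means, S, slice(col, col + B.shape[1]),
                xmin=float(x.min()), xmax=float(x.max()),
            )
        blocks.append(B)
        penalties.append((tb.sl, tb.S))
        terms.append(tb)
        col += B.shape[1]
    X = np.hstack(blocks)
    return X, terms, penalties


def _model_matrix_for(fit: GamFit, data: pd.DataFrame) -> np.ndarray:
    n = len(data)
    blocks = [np.ones((n, 1))]
    for name in fit.linear_terms:
        if name not in data.columns:
            raise ValueError(f"unknown covariate '{name}' in newdata")
        blocks.append(data[[name]].to_numpy(dtype=float))
    for tb in fit.terms:
        spec = tb.spec
        if spec.kind == "re":
            codes = pd.Categorical(data[spec.name], categories=tb.levels).codes
            m = len(tb.levels)
            B = np.zeros((n, m))
            seen = codes >= 0  # unseen levels predict at the population mean
            B[np.arange(n)[seen], codes[seen]] = 1.0
        else:
            if spec.name not in data.columns:
                raise ValueError(f"unknown covariate '{spec.name}' in newdata")
            x = data[spec.name].to_numpy(dtype=float)
            if spec.kind == "cs":
                if x.min() < tb.xmin - 1e-9 or x.max() > tb.xmax + 1e-9:
                    warnings.warn(
                        f"extrapolating smooth '{spec.name}' outside fitted range"
                    )
                B = _cs_design(x, tb.knots)
            else:
                B = _cc_design(x, tb.knots, spec.k, spec.period)
            B = B - tb.col_means
        blocks.append(B)
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# Penalized IRLS and smoothing-parameter selection
# ---------------------------------------------------------------------------

def _pirls(X, y, offset, penalties, lambdas, family, max_iter=200, tol=1e-9,
           use_lstsq=False):
    inv, mu_eta, weights, working, deviance, init_mu = _family_funcs(family)
    n, p = X.shape
    S_lam = np.zeros((p, p))
    for lam, (sl, S) in zip(lambdas, penalties):
        S_lam[sl, sl] += lam * S

    R_aug = None
    if use_lstsq:
        # square-root penalty rows: the augmented least-squares solve stays
        # accurate even when a smoothing parameter is pushed to extremes
        rows = []
        for lam, (sl, S) in zip(lambdas, penalties):
            evals, evecs = np.linalg.eigh(S)
            R = np.sqrt(np.clip(evals, 0.0, None))[:, None] * evecs.T
            block = np.zeros((R.shape[0], p))
            block[:, sl] = np.sqrt(lam) * R
            rows.append(block)
        R_aug = np.vstack(rows) if rows else np.zeros((0, p))

    def ridge(XtWX):
        # tiny relative ridge bounds the condition number when the data
        # barely constrain a penalty null-space direction
        scale = np.trace(XtWX) / p
        return (1e-8 * max(scale, 1e-12)) * np.eye(p)
    mu = init_mu(y)
    eta = np.log(mu) if family == "gamma" else np.log(mu / (1 - mu))
    dev_old = np.inf
    beta = np.zeros(p)
    beta_old = None
    for it in range(max_iter):
        w = weights(mu)
        z = working(y, mu, eta, offset)
        if use_lstsq:
            sw = np.sqrt(w)
            A = np.vstack([X * sw[:, None], R_aug])
            b = np.r_[z * sw, np.zeros(R_aug.shape[0])]
            beta = np.linalg.lstsq(A, b, rcond=None)[0]
        else:
            Xw = X * w[:, None]
            XtWX_it = Xw.T @ X
            H = XtWX_it + S_lam + ridge(XtWX_it)
            beta = np.linalg.solve(H, Xw.T @ z)

        def pdev_at(b):
            e = X @ b + offset
            m = inv(e)
            return deviance(y, m) + float(b @ S_lam @ b), e, m

        pdev, eta, mu = pdev_at(beta)
        if beta_old is not None and not (pdev <= dev_old + 1e-10):
            # step-halving keeps the iteration monotone in the penalized deviance
            for _ in range(30):
                beta = 0.5 * (beta + beta_old)
                pdev, eta, mu = pdev_at(beta)
                if pdev <= dev_old + 1e-10:
                    break
        if np.isfinite(dev_old) and abs(dev_old - pdev) < tol * (abs(pdev) + 0.1):
            dev_old = pdev
            break
        dev_old = pdev
        beta_old = beta
    else:
        raise SmoothConvergenceError(
            f"penalized IRLS did not converge in {max_iter} iterations "
            f"(deviance trace ended at {dev_old:.6g})"
        )
    dev = deviance(y, mu)  # raw (unpenalized) deviance for GCV / AIC
    w = weights(mu)
    Xw = X * w[:, None]
    XtWX = Xw.T @ X
    H = XtWX + S_lam + ridge(XtWX)
    Hinv = np.linalg.inv(H)
    F = np.linalg.solve(H, XtWX)  # influence decomposition; trace = model EDF
    edf = float(np.trace(F))
    return beta, mu, dev, edf, F, Hinv, XtWX


def fit_pgam(
    data: pd.DataFrame,
    response: str,
    smooth_terms: list[SmoothSpec],
    linear_terms: list[str] = (),
    offset_cols: list[str] = (),
    family: str = "gamma",
    lambdas: np.ndarray | None = None,
    optimize_lambda: bool = True,
) -> GamFit:
    """Fit a penalized additive model.

    ``offset_cols`` name data columns already on the linear-predictor
    scale (e.g. log ring area); they are summed and added to the linear
    predictor.  Smoothing parameters (one per smooth / random-effect
    term) are selected by minimising GCV ``n * deviance / (n - edf)^2``
    over log-lambdas with Nelder-Mead unless fixed via ``lambdas``.
    """
    y = data[response].to_numpy(dtype=float)
    if family == "gamma" and np.any(y <= 0):
        raise ValueError("gamma family requires strictly positive response")
    if family == "binomial" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial family requires a 0/1 response")
    offset = _offset_vector(list(offset_cols), data)
    X, terms, penalties = _assemble(data, list(smooth_terms), list(linear_terms))
    n = len(y)
    nterm = len(penalties)

    if nterm == 0:
        lam = np.array([])
    elif lambdas is not None:
        lam = np.asarray(lambdas, dtype=float)
    elif not optimize_lambda:
        lam = np.ones(nterm)
    else:
        def gcv(loglam):
            # GCV for the gamma family (unknown dispersion); UBRE-style
            # deviance + 2*EDF for binomial, where the scale is known
            ll = np.clip(loglam, -4.0, 10.0)
            try:
                _, _, dev, edf, *_ = _pirls(
                    X, y, offset, penalties, 10.0**ll, family, max_iter=100, tol=1e-7
                )
            except (SmoothConvergenceError, np.linalg.LinAlgError):
                return np.inf
            if family == "binomial":
                return dev + 2.0 * edf
            denom = max(n - edf, 1e-3)
            return n * dev / denom**2

        x0 = np.zeros(nterm)
        res = optimize.minimize(
            gcv, x0, method="Nelder-Mead",
            options={"maxiter": 80 * max(nterm, 1), "xatol": 0.05, "fatol": 1e-8},
        )
        lam = 10.0 ** np.clip(res.x, -4.0, 10.0)

    beta, mu, dev, edf_total, F, Hinv, XtWX = _pirls(
        X, y, offset, penalties, lam, family, use_lstsq=True
    )

    # dispersion: fixed at 1 for binomial, Pearson estimate for gamma
    if family == "gamma":
        phi = float(np.sum((y - mu) ** 2 / mu**2) / max(n - edf_total, 1.0))
    else:
        phi = 1.0
    Vb = Hinv * phi  # Bayesian posterior covariance

    edf_by_term: dict[str, float] = {}
    pvalues: dict[str, float] = {}
    diagF = np.diag(F)
    for tb in terms:
        name = f"{tb.spec.kind}({tb.spec.name})"
        edf_term = float(diagF[tb.sl].sum())
        edf_by_term[name] = edf_term
        b = beta[tb.sl]
        V = Vb[tb.sl, tb.sl]
        # Wald-type test on the penalized block; df = EDF (approximate)
        try:
            chi2 = float(b @ np.linalg.pinv(V, rcond=1e-10) @ b)
            df = max(edf_term, 0.5)
            pvalues[name] = float(stats.chi2.sf(chi2, df))
        except np.linalg.LinAlgError:
            pvalues[name] = np.nan
    for j, name in enumerate(linear_terms, start=1):
        se = np.sqrt(Vb[j, j])
        zval = beta[j] / se if se > 0 else np.nan
        edf_by_term[name] = 1.0
        pvalues[name] = float(2 * stats.norm.sf(abs(zval)))

    aic = dev + 2.0 * edf_total
    return GamFit(
        coef=beta,
        family=family,
        terms=terms,
        linear_terms=list(linear_terms),
        offset_cols=list(offset_cols),
        lambdas=lam,
        edf_by_term=edf_by_term,
        edf_total=edf_total,
        deviance=dev,
        aic=aic,
        phi=phi,
        Vb=Vb,
        pvalues=pvalues,
        n_obs=n,
        response=response,
    )


def backwards_aic(
    data: pd.DataFrame,
    response: str,
    smooth_terms: list[SmoothSpec],
    linear_terms: list[str],
    removable: list[str],
    offset_cols: list[str] = (),
    family: str = "gamma",
) -> tuple[GamFit, pd.DataFrame]:
    """Backwards stepwise elimination by AIC.

    ``removable`` names linear terms or smooth covariates that may be
    dropped.  At each round the removal that most decreases AIC is
    applied; elimination stops when every removal would increase AIC.
    Returns the reduced fit and a log of each round's ΔAIC (positive =
    the removal improved AIC by that much).
    """
    smooths = list(smooth_terms)
    linears = list(linear_terms)
    current = fit_pgam(data, response, smooths, linears, offset_cols, family)
    log_rows = []
    pool = list(removable)
    while pool:
        best_name, best_fit, best_aic = None, None, current.aic
        for name in pool:
            s_try = [s for s in smooths if s.name != name]
            l_try = [l for l in linears if l != name]
            if len(s_try) == len(smooths) and len(l_try) == len(linears):
                continue  # name not in the model
            try:
                fit_try = fit_pgam(data, response, s_try, l_try, offset_cols, family)
            except (SmoothConvergenceError, np.linalg.LinAlgError, ValueError):
                continue
            if fit_try.aic < best_aic:
                best_name, best_fit, best_aic = name, fit_try, fit_try.aic
        if best_name is None:
            break
        log_rows.append(
            {"removed": best_name, "delta_aic": current.aic - best_aic}
        )
        smooths = [s for s in smooths if s.name != best_name]
        linears = [l for l in linears if l != best_name]
        pool.remove(best_name)
        current = best_fit
    return current, pd.DataFrame(log_rows, columns=["removed", "delta_aic"])
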