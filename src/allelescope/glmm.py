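"""Fragment-level mixed-effect logistic models of allele-specific accessibility.

The response is the presence of the alternate allele in a single
allele-informative ATAC fragment; the predictor of interest is the linked
gene's imputed expression in the fragment's cell, min-max normalized to
[0, 100].  A random intercept per sample (library) absorbs between-donor
variation and guards against pseudo-replication of fragments within donors:

    logit P(y_ij = 1) = beta0 + beta_expr * x_ij [+ beta_dia * d_j]
                        [+ beta_int * x_ij * d_j] + u_j,   u_j ~ N(0, sigma_u^2)

Three nested fixed-effect structures are exposed: ``base`` (expression only),
``m2`` (adds the disease indicator), ``m3`` (adds the disease x expression
interaction).  The marginal likelihood integrates the random intercept by
adaptive Gauss-Hermite quadrature (9 nodes by default; 1 node is the Laplace
approximation), and inference on the fixed effects is Wald: z = beta / SE
from the observed information, two-sided normal p, CI = beta +/- 1.96 SE.

:class:`MixedLogisticRegression` is a scikit-learn style estimator; the
module-level functions (``fit_glmm``, ``fit_per_donor``, ...) are thin
wrappers shaped around peak-gene design tables.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit, logsumexp
from scipy.stats import norm
from sklearn.base import BaseEstimator

MODELS = ("base", "m2", "m3")
_LOG_SIGMA_MIN = np.log(1e-6)
_LOG_SIGMA_MAX = np.log(50.0)


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # numerically stable: log sigmoid(eta)*y + log sigmoid(-eta)*(1-y)
    return -np.logaddexp(0.0, np.where(y > 0, -eta, eta))


class MixedLogisticRegression(BaseEstimator):
    """Logistic regression with a Gaussian random intercept per group.

    Parameters
    ----------
    n_quad : int
        Adaptive Gauss-Hermite nodes for the marginal likelihood; 1 gives
        the Laplace approximation.
    fit_intercept : bool
        Prepend a fixed intercept column.
    max_iter, tol, gtol : optimizer controls (relative log-likelihood change
        and gradient max-norm).

    Attributes (after fit)
    ----------------------
    intercept_, coef_ : fixed-effect estimates (log-odds).
    bse_ : standard errors, intercept first.
    sigma_u_ : random-intercept SD estimate.
    random_effects_ : posterior modes of u per group.
    loglik_ : maximized marginal log-likelihood.
    converged_, separation_ : fit diagnostics.
    """

    def __init__(self, n_quad: int = 9, fit_intercept: bool = True,
                 max_iter: int = 200, tol: float = 1e-8, gtol: float = 1e-5,
                 fix_sigma: float | None = None):
        self.n_quad = n_quad
        self.fit_intercept = fit_intercept
        self.max_iter = max_iter
        self.tol = tol
        self.gtol = gtol
        self.fix_sigma = fix_sigma

    # -- marginal likelihood machinery ------------------------------------

    def _inner_modes(self, eta0, y, gidx, n_groups, sigma, u0):
        """Posterior mode and curvature of u per group (vectorized Newton).

        The per-group joint log-density is strictly concave in u, so Newton
        with a capped step converges; tolerance is tight (1e-11) to keep the
        outer finite-difference gradient smooth.
        """
        u = u0.copy()
        inv_s2 = 1.0 / (sigma * sigma)
        for _ in range(100):
            eta = eta0 + u[gidx]
            p = expit(eta)
            grad = np.bincount(gidx, weights=y - p, minlength=n_groups) - u * inv_s2
            hess = -np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) - inv_s2
            step = -grad / hess
            np.clip(step, -5.0, 5.0, out=step)
            u += step
            if np.max(np.abs(step)) < 1e-11:
                break
        eta = eta0 + u[gidx]
        p = expit(eta)
        curv = np.bincount(gidx, weights=p * (1 - p), minlength=n_groups) + inv_s2
        return u, curv

    def _marginal_loglik(self, theta, X, y, gidx, n_groups, nodes, weights,
                         with_grad=False):
        """AGQ marginal log-likelihood; optionally its gradient.

        The gradient uses Fisher's identity (posterior expectation of the
        joint score) with the same quadrature nodes; the small terms from
        the nodes' dependence on theta are omitted, so the final Newton
        polish works on the objective itself.
        """
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta0 = X @ beta
        u_hat, curv = self._inner_modes(
            eta0, y, gidx, n_groups, sigma, np.zeros(n_groups)
        )
        tau = 1.0 / np.sqrt(curv)

        log_prior_const = -np.log(sigma) - 0.5 * np.log(2 * np.pi)
        inv_2s2 = 0.5 / (sigma * sigma)
        p_fix = X.shape[1]
        # log integrand h_g(u) at each scaled node, all groups at once
        a = np.empty((len(nodes), n_groups))
        score_beta = np.empty((len(nodes), n_groups, p_fix)) if with_grad else None
        score_sig = np.empty((len(nodes), n_groups)) if with_grad else None
        for j, (z, w) in enumerate(zip(nodes, weights)):
            u_j = u_hat + np.sqrt(2.0) * tau * z
            eta = eta0 + u_j[gidx]
            ll = np.bincount(
                gidx, weights=_bernoulli_loglik(eta, y), minlength=n_groups
            )
            h = ll + log_prior_const - u_j * u_j * inv_2s2
            a[j] = np.log(w) + z * z + h
            if with_grad:
                resid = y - expit(eta)
                for k in range(p_fix):
                    score_beta[j, :, k] = np.bincount(
                        gidx, weights=X[:, k] * resid, minlength=n_groups
                    )
                score_sig[j] = u_j * u_j / (sigma * sigma) - 1.0
        log_lg = 0.5 * np.log(2.0) + np.log(tau) + logsumexp(a, axis=0)
        total = float(np.sum(log_lg))
        if not with_grad:
            return total
        # posterior node weights per group
        amax = a.max(axis=0)
        wgt = np.exp(a - amax)
        wgt /= wgt.sum(axis=0)
        g_beta = np.einsum("jg,jgk->k", wgt, score_beta)
        g_sig = float(np.sum(wgt * score_sig))
        return total, np.append(g_beta, g_sig)

    def _polish(self, theta, nll, free, max_steps=4):
        """Newton polish over the free coordinates after L-BFGS-B.

        The sigma profile is nearly flat, so quasi-Newton can stop slightly
        off the ridge; a few damped Newton steps with exact (numeric)
        curvature pin the MLE down.
        """
        k = len(theta)
        lo = np.array([-np.inf] * (k - 1) + [_LOG_SIGMA_MIN])
        hi = np.array([np.inf] * (k - 1) + [_LOG_SIGMA_MAX])
        f0 = nll(theta)
        free = np.asarray(free)
        for _ in range(max_steps):
            g = _numeric_grad(nll, theta)[free]
            if np.max(np.abs(g)) < self.gtol * 0.1:
                break
            H = _numeric_hessian(nll, theta, list(free))
            try:
                step = np.linalg.solve(H, -g)
            except np.linalg.LinAlgError:
                break
            t, fc, cand = 1.0, f0, theta
            for _ in range(8):
                cand = theta.copy()
                cand[free] = theta[free] + t * step
                cand = np.clip(cand, lo, hi)
                fc = nll(cand)
                if fc <= f0:
                    break
                t *= 0.5
            if fc > f0:
                break
            moved = np.max(np.abs(cand - theta))
            theta, f0 = cand, fc
            if moved < 1e-10:
                break
        return theta, f0

    def _finish_plain(self, Xd, y, beta, n_groups, uniques):
        """sigma_u = 0 endpoint: ordinary logistic MLE with observed-info SEs."""
        p = Xd.shape[1]
        eta = Xd @ beta
        pr = expit(eta)
        self.loglik_ = float(np.sum(_bernoulli_loglik(eta, y)))
        H = (Xd * (pr * (1 - pr))[:, None]).T @ Xd
        cov = _safe_inverse(H)
        self.bse_ = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        self.sigma_u_ = 0.0
        self.se_log_sigma_ = np.nan
        self.sigma_at_boundary_ = True
        self.converged_ = True
        self.n_iter_ = 0
        self.n_obs_ = int(len(y))
        self.n_groups_ = int(n_groups)
        self.group_index_ = pd.Index(uniques)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self._beta_full = beta
        self.random_effects_ = np.zeros(n_groups)
        self.separation_ = bool(np.max(np.abs(beta)) > 15)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y, groups):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("degenerate outcome: y is constant")
        codes, uniques = pd.factorize(np.asarray(groups), sort=True)
        n_groups = len(uniques)
        if n_groups < 2 and self.fix_sigma is None:
            raise ValueError("mixed fit needs >= 2 groups")
        if self.fit_intercept:
            Xd = np.column_stack([np.ones(len(X)), X])
        else:
            Xd = X
        p = Xd.shape[1]

        nodes, weights = hermgauss(self.n_quad)

        beta0 = _irls_logistic(Xd, y)

        if self.fix_sigma is not None and self.fix_sigma <= 1e-12:
            # sigma pinned to 0: the marginal model IS plain logistic
            return self._finish_plain(Xd, y, beta0, n_groups, uniques)

        theta0 = np.append(beta0, np.log(0.3))
        if self.fix_sigma is not None:
            theta0[-1] = np.log(self.fix_sigma)

        def nll(theta):
            return -self._marginal_loglik(theta, Xd, y, codes, n_groups, nodes, weights)

        def nll_grad(theta):
            f, g = self._marginal_loglik(
                theta, Xd, y, codes, n_groups, nodes, weights, with_grad=True
            )
            return -f, -g

        if self.fix_sigma is not None:
            sig_bounds = (float(theta0[-1]), float(theta0[-1]))
        else:
            sig_bounds = (_LOG_SIGMA_MIN, _LOG_SIGMA_MAX)
        bounds = [(None, None)] * p + [sig_bounds]
        res = scipy.optimize.minimize(
            nll_grad, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={
                "maxiter": self.max_iter,
                "ftol": self.tol * 1e-4,  # the sigma profile is flat; stop on gradient
                "gtol": self.gtol,
                "maxfun": 20000,
            },
        )
        sigma_fixed = self.fix_sigma is not None
        free0 = list(range(p)) if sigma_fixed else list(range(p + 1))
        theta, fval = self._polish(res.x, nll, free0)
        self.loglik_ = -float(fval)
        self.sigma_u_ = float(np.exp(theta[-1]))
        self.n_iter_ = int(res.nit)
        self.converged_ = bool(res.success)
        beta = theta[:p]
        self.n_obs_ = int(len(y))
        self.n_groups_ = int(n_groups)
        self.group_index_ = pd.Index(uniques)

        at_boundary = theta[-1] <= _LOG_SIGMA_MIN + 1e-6
        self.sigma_at_boundary_ = bool(at_boundary)
        free = list(range(p)) if (at_boundary or sigma_fixed) else list(range(p + 1))
        H = _numeric_hessian(nll, theta, free)
        cov = _safe_inverse(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
        bse = np.full(p + 1, np.nan)
        bse[free] = se
        self.bse_ = bse[:p]
        self.se_log_sigma_ = float(bse[p]) if not at_boundary else np.nan

        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self._beta_full = beta
        eta0 = Xd @ beta
        self.random_effects_, _ = self._inner_modes(
            eta0, y, codes, n_groups, max(self.sigma_u_, 1e-6), np.zeros(n_groups)
        )
        self.separation_ = bool(np.max(np.abs(beta)) > 15)
        return self

    def predict_proba(self, X):
        """P(y=1) at the population level (random intercept at 0)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        p1 = expit(eta)
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def wald_table(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-coefficient Wald z, two-sided p and 95% CI (intercept first)."""
        beta = self._beta_full
        if names is None:
            names = ["beta0"] + [f"x{i}" for i in range(len(beta) - 1)]
        se = self.bse_.copy()  # intercept first, matching _beta_full
        se[se <= 0] = np.nan  # degenerate curvature: no Wald inference
        z = beta / se
        pvals = 2 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "term": list(names),
                "estimate": beta,
                "se": se,
                "wald_z": z,
                "wald_p": pvals,
                "ci_lo": beta - 1.96 * se,
                "ci_hi": beta + 1.96 * se,
            }
        )


def _irls_logistic(X, y, max_iter=25, tol=1e-10, ridge=1e-8):
    """Plain logistic MLE by damped Newton (start values and sigma=0 path)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        W = p * (1 - p)
        grad = X.T @ (y - p)
        H = (X * W[:, None]).T @ X + ridge * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        nstep = np.linalg.norm(step)
        if nstep > 10:
            step *= 10 / nstep
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _numeric_grad(f, theta, h=1e-6):
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        hi = h * (1 + abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += hi
        tm[i] -= hi
        g[i] = (f(tp) - f(tm)) / (2 * hi)
    return g


def _numeric_hessian(f, theta, free, h=1e-4):
    """Central-difference Hessian of f over the ``free`` coordinates."""
    k = len(free)
    H = np.zeros((k, k))
    steps = [h * (1 + abs(theta[i])) for i in free]
    f0 = f(theta)
    for a in range(k):
        i, hi = free[a], steps[a]
        tp, tm = theta.copy(), theta.copy()
        tp[i] += hi
        tm[i] -= hi
        H[a, a] = (f(tp) - 2 * f0 + f(tm)) / (hi * hi)
        for b in range(a + 1, k):
            j, hj = free[b], steps[b]
            tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
            tpp[i] += hi; tpp[j] += hj
            tpm[i] += hi; tpm[j] -= hj
            tmp[i] -= hi; tmp[j] += hj
            tmm[i] -= hi; tmm[j] -= hj
            H[a, b] = H[b, a] = (f(tpp) - f(tpm) - f(tmp) + f(tmm)) / (4 * hi * hj)
    return H


def _safe_inverse(H):
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


# ---------------------------------------------------------------------------
# expression normalization and design construction

MODEL_TERMS = {
    "base": ["beta0", "beta_expr"],
    "m2": ["beta0", "beta_expr", "beta_dia"],
    "m3": ["beta0", "beta_expr", "beta_dia", "beta_int"],
}


def normalize_expression(values) -> np.ndarray:
    """Min-max scale one gene's per-cell values to [0, 100].

    Raises on negative input; a constant vector has zero range and the gene
    must be dropped by the caller (signalled with ValueError).
    """
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("negative expression values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise ValueError("constant expression vector (zero range); drop gene")
    return (v - lo) / (hi - lo) * 100.0


def normalize_expression_matrix(expr, barcodes=None):
    """Min-max normalize every gene to [0, 100] over the analysis cell set.

    Returns ``(normalized ExpressionMatrix, dropped_genes)``; genes with zero
    range over the selected cells are dropped.
    """
    from .io import ExpressionMatrix

    if barcodes is not None:
        expr = expr.subset_barcodes(barcodes)
    dense = expr.matrix.toarray().astype(float)
    lo = dense.min(axis=0)
    hi = dense.max(axis=0)
    keep = hi > lo
    dropped = list(expr.genes[~keep])
    dense = dense[:, keep]
    scaled = (dense - lo[keep]) / (hi[keep] - lo[keep]) * 100.0
    return ExpressionMatrix(scaled, expr.barcodes, expr.genes[keep]), dropped


def build_design(assigned_calls: pd.DataFrame, links: pd.DataFrame,
                 expr_norm, meta: pd.DataFrame, *,
                 peak_ids=None) -> pd.DataFrame:
    """Fragment-level design rows for every (peak, gene) combination.

    Parameters
    ----------
    assigned_calls
        Fragment calls with a ``peak_id`` column (one row per
        fragment-peak assignment); only ref/alt calls are used.
    links
        Peak-gene pairs (``peak_id``, ``gene_id``); a peak with two linked
        genes yields two designs sharing y but differing x_expr.
    expr_norm
        ExpressionMatrix already normalized to [0, 100].
    meta
        Cell metadata (condition in {control, disease}).
    peak_ids
        Optional restriction (e.g. peaks passing the count filter).

    Returns a long DataFrame with columns peak_id, gene_id, y, x_expr, dia,
    sample_id, barcode; rows whose barcode is missing from the metadata or
    the expression matrix are dropped (counted nowhere here — upstream QC
    already tallies unknown barcodes).
    """
    frags = assigned_calls[assigned_calls["call"].isin(["ref", "alt"])]
    if peak_ids is not None:
        frags = frags[frags["peak_id"].isin(set(peak_ids))]
        links = links[links["peak_id"].isin(set(peak_ids))]
    links = links[links["gene_id"].isin(set(expr_norm.genes))]
    merged = frags.merge(links[["peak_id", "gene_id"]], on="peak_id", how="inner")
    meta_idx = meta.set_index("barcode")
    known = merged["barcode"].isin(meta_idx.index) & merged["barcode"].isin(
        expr_norm.barcodes
    )
    merged = merged[known].reset_index(drop=True)
    if merged.empty:
        return pd.DataFrame(
            columns=["peak_id", "gene_id", "y", "x_expr", "dia", "sample_id", "barcode"]
        )
    rows = expr_norm.barcodes.get_indexer(merged["barcode"])
    cols = expr_norm.genes.get_indexer(merged["gene_id"])
    x = np.asarray(expr_norm.matrix[rows, cols]).ravel()
    sub = meta_idx.loc[merged["barcode"]]
    out = pd.DataFrame(
        {
            "peak_id": merged["peak_id"].to_numpy(),
            "gene_id": merged["gene_id"].to_numpy(),
            "y": (merged["call"] == "alt").astype(int).to_numpy(),
            "x_expr": x,
            "dia": (sub["condition"] == "disease").astype(int).to_numpy(),
            "sample_id": sub["sample_id"].to_numpy(),
            "barcode": merged["barcode"].to_numpy(),
        }
    )
    return out.sort_values(["peak_id", "gene_id", "sample_id", "barcode"],
                           kind="mergesort").reset_index(drop=True)


def _design_matrix(design: pd.DataFrame, model_id: str) -> np.ndarray:
    x = design["x_expr"].to_numpy(float)
    d = design["dia"].to_numpy(float)
    if model_id == "base":
        return x[:, None]
    if model_id == "m2":
        return np.column_stack([x, d])
    if model_id == "m3":
        return np.column_stack([x, d, x * d])
    raise ValueError(f"unknown model_id {model_id!r}; choose from {MODELS}")


@dataclasses.dataclass
class GlmmFit:
    """One fitted peak-gene combination under one model."""

    model_id: str
    peak_id: str
    gene_id: str
    terms: tuple
    estimate: dict
    se: dict
    wald_z: dict
    wald_p: dict
    ci_lo: dict
    ci_hi: dict
    sigma_u: float
    loglik: float
    converged: bool
    separation: bool
    n_obs: int
    n_samples: int

    def to_row(self) -> dict:
        row = {
            "model_id": self.model_id,
            "peak_id": self.peak_id,
            "gene_id": self.gene_id,
        }
        for t in self.terms:
            row[t] = self.estimate[t]
            row[f"se_{t}"] = self.se[t]
            row[f"wald_z_{t}"] = self.wald_z[t]
            row[f"wald_p_{t}"] = self.wald_p[t]
            row[f"ci_lo_{t}"] = self.ci_lo[t]
            row[f"ci_hi_{t}"] = self.ci_hi[t]
        row.update(
            sigma_u=self.sigma_u, loglik=self.loglik, converged=self.converged,
            separation=self.separation, n_obs=self.n_obs, n_samples=self.n_samples,
        )
        return row


def fit_glmm(design: pd.DataFrame, model_id: str = "base", n_quad: int = 9,
             peak_id: str = "", gene_id: str = "") -> GlmmFit:
    """Fit one mixed-effect logistic model to one peak-gene design."""
    terms = MODEL_TERMS[model_id]
    X = _design_matrix(design, model_id)
    est = MixedLogisticRegression(n_quad=n_quad).fit(
        X, design["y"].to_numpy(), design["sample_id"].to_numpy()
    )
    tab = est.wald_table(names=terms)
    get = lambda col: dict(zip(tab["term"], tab[col]))
    return GlmmFit(
        model_id=model_id,
        peak_id=peak_id or str(design["peak_id"].iloc[0]),
        gene_id=gene_id or str(design["gene_id"].iloc[0]),
        terms=tuple(terms),
        estimate=get("estimate"), se=get("se"), wald_z=get("wald_z"),
        wald_p=get("wald_p"), ci_lo=get("ci_lo"), ci_hi=get("ci_hi"),
        sigma_u=est.sigma_u_, loglik=est.loglik_, converged=est.converged_,
        separation=est.separation_, n_obs=est.n_obs_, n_samples=est.n_groups_,
    )


def fit_all_glmm(design: pd.DataFrame, model_id: str = "base",
                 n_quad: int = 9) -> pd.DataFrame:
    """Fit every (peak, gene) combination in a long design table."""
    rows = []
    for (pk, gn), sub in design.groupby(["peak_id", "gene_id"], sort=True):
        if sub["y"].nunique() < 2 or sub["sample_id"].nunique() < 2:
            continue
        try:
            fit = fit_glmm(sub, model_id, n_quad=n_quad, peak_id=pk, gene_id=gn)
        except (ValueError, np.linalg.LinAlgError):
            continue
        rows.append(fit.to_row())
    return pd.DataFrame(rows)


@dataclasses.dataclass
class DonorFit:
    """Per-donor plain logistic fit (base model, no random effect)."""

    sample_id: str
    peak_id: str
    gene_id: str
    beta0: float
    beta_expr: float
    se: float
    wald_p: float
    separation: bool
    n_obs: int

    def to_row(self) -> dict:
        return dataclasses.asdict(self)


def fit_per_donor(design: pd.DataFrame, peak_id: str = "",
                  gene_id: str = "") -> DonorFit:
    """Plain-ML logistic fit of the base model on a single donor's fragments."""
    import statsmodels.api as sm

    samples = design["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("fit_per_donor expects a single-sample design")
    y = design["y"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: y is constant for this donor")
    X = sm.add_constant(design["x_expr"].to_numpy(float))
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception:
            separation = True
            res = sm.Logit(y, X).fit(disp=False, maxiter=200, method="bfgs")
    beta = np.asarray(res.params, float)
    se = np.asarray(res.bse, float)
    separation = separation or bool(np.max(np.abs(beta)) > 15)
    z = beta[1] / se[1]
    return DonorFit(
        sample_id=str(samples[0]),
        peak_id=peak_id or str(design["peak_id"].iloc[0]),
        gene_id=gene_id or str(design["gene_id"].iloc[0]),
        beta0=float(beta[0]), beta_expr=float(beta[1]), se=float(se[1]),
        wald_p=float(2 * norm.sf(abs(z))), separation=separation,
        n_obs=int(len(y)),
    )


def fit_all_donors(design: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (pk, gn, s), sub in design.groupby(["peak_id", "gene_id", "sample_id"],
                                           sort=True):
        if sub["y"].nunique() < 2:
            continue
        try:
            rows.append(fit_per_donor(sub, peak_id=pk, gene_id=gn).to_row())
        except (ValueError, np.linalg.LinAlgError):
            continue
    return pd.DataFrame(rows)


def donor_concordance(donor_fits: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Cross-donor replication of per-donor expression effects.

    A combination is 'nominal' in a donor when that donor's Wald p < alpha;
    among combinations nominal in >= 2 donors, sign-concordant means every
    nominal donor shares the sign of beta_expr.
    """
    if donor_fits.empty:
        return {
            "n_combinations": 0, "n_nominal_any": 0, "n_nominal_multi": 0,
            "n_sign_concordant": 0, "frac_sign_concordant": np.nan,
        }
    nominal = donor_fits[donor_fits["wald_p"] < alpha]
    per_combo = nominal.groupby(["peak_id", "gene_id"])["beta_expr"].agg(
        n_donors="size",
        all_pos=lambda s: bool((s > 0).all()),
        all_neg=lambda s: bool((s < 0).all()),
    )
    multi = per_combo[per_combo["n_donors"] >= 2]
    n_conc = int((multi["all_pos"] | multi["all_neg"]).sum())
    return {
        "n_combinations": int(
            donor_fits.groupby(["peak_id", "gene_id"]).ngroups
        ),
        "n_nominal_any": int(len(per_combo)),
        "n_nominal_multi": int(len(multi)),
        "n_sign_concordant": n_conc,
        "frac_sign_concordant": n_conc / len(multi) if len(multi) else np.nan,
    }


def multiple_testing_summary(fits: pd.DataFrame, term: str = "beta_expr",
                             alpha: float = 0.05) -> dict:
    """Counts and fractions at nominal p < alpha and BH-adjusted p < alpha."""
    from .asca import bh_adjust

    if fits.empty:
        return {
            "n_total": 0, "n_nominal": 0, "frac_nominal": np.nan,
            "n_adjusted": 0, "frac_adjusted": np.nan,
        }
    fits = fits[fits["converged"]] if "converged" in fits.columns else fits
    p = fits[f"wald_p_{term}"].to_numpy(float)
    p = p[np.isfinite(p)]  # degenerate-curvature fits carry no Wald p
    if p.size == 0:
        return {
            "n_total": 0, "n_nominal": 0, "frac_nominal": np.nan,
            "n_adjusted": 0, "frac_adjusted": np.nan,
        }
    padj = bh_adjust(p)
    n = len(p)
    return {
        "n_total": n,
        "n_nominal": int((p < alpha).sum()),
        "frac_nominal": float((p < alpha).mean()),
        "n_adjusted": int((padj < alpha).sum()),
        "frac_adjusted": float((padj < alpha).mean()),
    }


def odds_multiplier(beta_expr: float, delta_expr: float = 10.0) -> float:
    """Odds multiplier implied by a log-odds slope over an expression change.

    A slope of 0.01 log-odds per 1% expression gives exp(0.1) ~ 1.10 for a
    10% increase.
    """
    return float(np.exp(beta_expr * delta_expr))
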