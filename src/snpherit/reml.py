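"""Variance-component estimation by restricted maximum likelihood (AI-REML).

The model is the linear mixed model on the observed 0/1 disease scale,

    y = X b + sum_r g_r + e,   g_r ~ N(0, sigma2_g[r] * A_r),   e ~ N(0, sigma2_e * I),

with A_r the genetic relationship matrices (one per SNP set).  Fitting
maximizes the restricted log-likelihood

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],
    V   = sum_r sigma2_g[r] A_r + sigma2_e I,
    P   = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1,

by average-information (AI) updates after a single EM warm-up step, with
step halving whenever a proposed update decreases the likelihood and an EM
fallback when the AI matrix is singular.  With the default constraint,
variance components are clamped at a small positive floor so the observed-
scale heritability lies in [0, 1]; estimates stuck at the floor are flagged
as boundary estimates and their standard errors marked unreliable.

Dense linear algebra throughout: every analysis this package targets has at
most a few thousand individuals, where Cholesky factorizations of V are
cheap and the code stays transparent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .containers import GRM, CovariateMatrix, PhenotypeVector, align_samples

log = logging.getLogger(__name__)

#: Variance floor, as a fraction of the phenotypic variance (constrained fits).
_FLOOR_FRACTION = 1e-6


@dataclass
class RemlOptions:
    max_iter: int = 100
    loglik_tol: float = 1e-8
    algorithm: str = "ai"  # "ai" (EM first step then AI) or "em"
    constrain: bool = True

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.loglik_tol <= 0:
            raise ValueError("loglik_tol must be > 0")
        if self.algorithm not in ("ai", "em"):
            raise ValueError("algorithm must be 'ai' or 'em'")


@dataclass
class VarianceComponentFit:
    """REML estimates for one or more genetic components plus the residual."""

    sigma2_g: np.ndarray          # per-component genetic variance
    sigma2_e: float
    beta: np.ndarray              # fixed effects (intercept first)
    se: np.ndarray                # SEs of [sigma2_g..., sigma2_e] from inv(AI)
    loglik: float
    h2_obs: np.ndarray            # per-component observed-scale h2
    h2_obs_total: float
    h2_se: np.ndarray             # delta-method SEs, per component
    h2_se_total: float
    converged: bool
    n_iter: int
    boundary: np.ndarray          # per-[g..., e] flag: estimate at constraint
    ai_covariance: np.ndarray = field(repr=False, default=None)

    @property
    def total_variance(self) -> float:
        return float(np.sum(self.sigma2_g) + self.sigma2_e)


# ---------------------------------------------------------------------------
# Restricted likelihood (public so independent oracles can maximize it)
# ---------------------------------------------------------------------------

def _as_arrays(y, X, grms):
    """Coerce containers to aligned numpy arrays; X gains an intercept column."""
    if isinstance(grms, (GRM, np.ndarray)):
        grms = [grms]
    if isinstance(y, PhenotypeVector):
        ids = y.sample_ids
        y_arr = y.values.astype(np.float64)
        mats = []
        for g in grms:
            if isinstance(g, GRM):
                idx = align_samples(ids, g.sample_ids, allow_subset=True, what="GRM vs phenotype")
                mats.append(g.values[np.ix_(idx, idx)])
            else:
                mats.append(np.asarray(g, dtype=np.float64))
        if isinstance(X, CovariateMatrix):
            idx = align_samples(ids, X.sample_ids, allow_subset=True,
                                what="covariates vs phenotype")
            X_arr = X.values[idx]
        else:
            X_arr = None if X is None else np.asarray(X, dtype=np.float64)
    else:
        y_arr = np.asarray(y, dtype=np.float64).ravel()
        mats = [g.values if isinstance(g, GRM) else np.asarray(g, dtype=np.float64)
                for g in grms]
        X_arr = None if X is None else np.asarray(X, dtype=np.float64)
        if isinstance(X, CovariateMatrix):
            X_arr = X.values

    n = y_arr.shape[0]
    intercept = np.ones((n, 1))
    X_full = intercept if X_arr is None or X_arr.size == 0 else np.hstack([intercept, X_arr])
    for g in mats:
        if g.shape != (n, n):
            raise ValueError(f"GRM shape {g.shape} does not match n={n}")
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    return y_arr, X_full, mats


def _reml_pieces(y, X, mats, theta):
    """Cholesky-based evaluation of l_R and the projection quantities."""
    n = y.shape[0]
    V = theta[-1] * np.eye(n)
    for sg, A in zip(theta[:-1], mats):
        V += sg * A
    L, low = linalg.cho_factor(V, lower=True, check_finite=False)
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Vinv = linalg.cho_solve((L, low), np.eye(n), check_finite=False)
    VinvX = Vinv @ X
    XtVinvX = X.T @ VinvX
    Lx = linalg.cho_factor(XtVinvX)
    logdet_X = 2.0 * np.sum(np.log(np.diag(Lx[0])))
    XtVinvX_inv = linalg.cho_solve(Lx, np.eye(X.shape[1]))
    P = Vinv - VinvX @ XtVinvX_inv @ VinvX.T
    Py = P @ y
    loglik = -0.5 * (logdet_V + logdet_X + float(y @ Py))
    beta = XtVinvX_inv @ (VinvX.T @ y)
    return loglik, P, Py, beta


class _DenseEngine:
    """Generic multi-component likelihood machinery (O(n^3) per evaluation)."""

    def __init__(self, y, X, mats):
        self.y, self.X = y, X
        self.mats_all = mats + [np.eye(y.shape[0])]
        self.mats = mats
        self.n = y.shape[0]

    def evaluate(self, theta):
        loglik, P, Py, beta = _reml_pieces(self.y, self.X, self.mats, theta)
        return loglik, {"P": P, "Py": Py, "beta": beta}

    def beta(self, state):
        return state["beta"]

    def traces_and_quads(self, state):
        P, Py = state["P"], state["Py"]
        tr = np.array([float(np.sum(P * A)) for A in self.mats_all])
        APy = [A @ Py for A in self.mats_all]
        quad = np.array([float(Py @ v) for v in APy])
        q = len(self.mats_all)
        ai = np.empty((q, q))
        PAPy = [P @ v for v in APy]
        for i in range(q):
            for j in range(i, q):
                ai[i, j] = ai[j, i] = 0.5 * float(APy[i] @ PAPy[j])
        return tr, quad, ai


class _SpectralEngine:
    """Single-GRM likelihood machinery via one eigendecomposition.

    With A = U diag(lam) U', V = sigma2_g A + sigma2_e I is diagonal in the
    eigenbasis, so after rotating y and X once every likelihood evaluation,
    gradient, EM step and AI matrix costs O(n p^2) instead of O(n^3).
    Numerically identical to the dense path (same model, exact algebra).
    """

    def __init__(self, y, X, A):
        self.n = y.shape[0]
        lam, U = linalg.eigh(A)
        self.lam = lam
        self.yt = U.T @ y
        self.Xt = U.T @ X

    def evaluate(self, theta):
        d = theta[0] * self.lam + theta[1]
        if d.min() <= 0:
            raise linalg.LinAlgError("V not positive definite")
        Xd = self.Xt / d[:, None]
        B = self.Xt.T @ Xd
        Lb = linalg.cho_factor(B)
        logdet_B = 2.0 * np.sum(np.log(np.diag(Lb[0])))
        beta = linalg.cho_solve(Lb, Xd.T @ self.yt)
        r = self.yt / d - Xd @ beta          # rotated P y
        loglik = -0.5 * (float(np.sum(np.log(d))) + logdet_B + float(self.yt @ r))
        return loglik, {"d": d, "Xd": Xd, "Lb": Lb, "r": r, "beta": beta}

    def beta(self, state):
        return state["beta"]

    def _project(self, v, state):
        """Rotated P applied to a rotated vector."""
        d, Xd, Lb = state["d"], state["Xd"], state["Lb"]
        return v / d - Xd @ linalg.cho_solve(Lb, Xd.T @ v)

    def traces_and_quads(self, state):
        d, Xd, Lb, r = state["d"], state["Xd"], state["Lb"], state["r"]
        Binv = linalg.cho_solve(Lb, np.eye(Xd.shape[1]))

        def tr_P_diag(w):  # trace of P @ diag(w) in the eigenbasis
            M = self.Xt.T @ (self.Xt * (w / d**2)[:, None])
            return float(np.sum(w / d)) - float(np.sum(Binv * M.T))

        tr = np.array([tr_P_diag(self.lam), tr_P_diag(np.ones(self.n))])
        quad = np.array([float(np.sum(self.lam * r * r)), float(r @ r)])
        APy = [self.lam * r, r]
        ai = np.empty((2, 2))
        PAPy = [self._project(v, state) for v in APy]
        for i in range(2):
            for j in range(i, 2):
                ai[i, j] = ai[j, i] = 0.5 * float(APy[i] @ PAPy[j])
        return tr, quad, ai


def restricted_log_likelihood(y, X, grms, sigma2_g, sigma2_e) -> float:
    """Restricted log-likelihood of the mixed model at given variances.

    ``y`` may be a :class:`PhenotypeVector` or array; ``X`` a
    :class:`CovariateMatrix`, array or None (an intercept is always added);
    ``grms`` one or more :class:`GRM`/arrays.  Raises on a singular V or a
    rank-deficient design.
    """
    y_arr, X_full, mats = _as_arrays(y, X, grms)
    theta = np.append(np.atleast_1d(np.asarray(sigma2_g, dtype=np.float64)),
                      float(sigma2_e))
    try:
        loglik, *_ = _reml_pieces(y_arr, X_full, mats, theta)
    except linalg.LinAlgError as exc:
        raise ValueError(f"V is not positive definite at the given variances ({exc})")
    return loglik


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def fit_reml(y, grms, X=None, options: RemlOptions | None = None) -> VarianceComponentFit:
    """Fit the mixed model by REML and return variance-component estimates.

    Starting values split Var(y) evenly across the genetic components and
    the residual.  The first update is an EM step; subsequent updates use
    the average-information matrix, clamped to the constraint set when
    ``options.constrain`` and step-halved whenever the restricted likelihood
    would decrease.  Convergence is declared when successive log-likelihoods
    differ by less than ``options.loglik_tol``.
    """
    options = options or RemlOptions()
    y_arr, X_full, mats = _as_arrays(y, X, grms)
    n = y_arr.shape[0]
    n_comp = len(mats)
    if n <= X_full.shape[1] + n_comp:
        raise ValueError("too few individuals for the number of fixed effects/components")

    vp = float(np.var(y_arr, ddof=1))
    if vp == 0:
        raise ValueError("phenotype has zero variance")
    floor = _FLOOR_FRACTION * vp

    def clamp(theta):
        t = theta.copy()
        if options.constrain:
            t = np.maximum(t, floor)
        else:
            t[-1] = max(t[-1], floor)  # residual variance stays positive regardless
        return t

    engine = (_SpectralEngine(y_arr, X_full, mats[0]) if n_comp == 1
              else _DenseEngine(y_arr, X_full, mats))
    theta = np.full(n_comp + 1, vp / (n_comp + 1))
    loglik, state = engine.evaluate(theta)

    converged = False
    n_iter = 0
    delta_ll = np.inf
    for n_iter in range(1, options.max_iter + 1):
        tr, quad, ai = engine.traces_and_quads(state)
        grad = -0.5 * (tr - quad)
        em_proposal = clamp(theta + theta**2 * (quad - tr) / n)
        use_em = options.algorithm == "em" or n_iter == 1
        if use_em:
            proposal = em_proposal
        else:
            try:
                delta = linalg.solve(ai, grad, assume_a="sym")
            except linalg.LinAlgError:
                delta = None
            if delta is None or not np.isfinite(delta).all():
                log.debug("AI matrix singular at iteration %d; EM fallback", n_iter)
                proposal = em_proposal
            else:
                proposal = clamp(theta + delta)

        # Step-halve toward the current point until the likelihood improves
        # and V stays positive definite; plain EM is the fallback.  If no
        # improving move exists inside the constraint set, the current point
        # is the (possibly boundary) optimum.
        accepted = None
        n_halvings = 0
        trial = proposal
        while n_halvings < 30 and not np.allclose(trial, theta, rtol=0, atol=1e-14):
            try:
                candidate = engine.evaluate(trial)
            except linalg.LinAlgError:
                pass
            else:
                if candidate[0] >= loglik - 1e-12:
                    accepted = (trial, candidate)
                    break
            trial = clamp(theta + 0.5 * (trial - theta))
            n_halvings += 1
        if accepted is None and not use_em and \
                not np.allclose(em_proposal, theta, rtol=0, atol=1e-14):
            try:
                candidate = engine.evaluate(em_proposal)
            except linalg.LinAlgError as exc:
                raise RuntimeError(f"V became indefinite and step-halving failed ({exc})")
            if candidate[0] >= loglik - 1e-12:
                accepted = (em_proposal, candidate)
        if accepted is None:
            converged = True  # no admissible ascent direction remains
            delta_ll = 0.0
            break

        new_theta, (new_loglik, state) = accepted
        delta_ll = new_loglik - loglik
        theta, loglik = new_theta, new_loglik
        if abs(delta_ll) < options.loglik_tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"REML did not converge in {options.max_iter} iterations "
                      f"(last delta logL = {delta_ll:.3e})", RuntimeWarning)

    beta = engine.beta(state)
    tr, quad, ai = engine.traces_and_quads(state)
    grad = -0.5 * (tr - quad)
    try:
        ai_cov = linalg.inv(ai)
        se = np.sqrt(np.maximum(np.diag(ai_cov), 0.0))
    except linalg.LinAlgError:
        ai_cov = np.full((n_comp + 1, n_comp + 1), np.nan)
        se = np.full(n_comp + 1, np.nan)

    at_floor = theta <= floor * (1 + 1e-9)
    boundary = at_floor & (grad < 0) if options.constrain else np.zeros_like(at_floor)
    if options.constrain and boundary.any():
        log.info("REML: components %s at the lower constraint boundary; their SEs "
                 "are unreliable", np.flatnonzero(boundary).tolist())

    h2, h2_total, h2_se, h2_se_total = _h2_from_theta(theta, ai_cov)
    return VarianceComponentFit(
        sigma2_g=theta[:-1].copy(), sigma2_e=float(theta[-1]), beta=beta,
        se=se, loglik=loglik, h2_obs=h2, h2_obs_total=h2_total,
        h2_se=h2_se, h2_se_total=h2_se_total, converged=converged,
        n_iter=n_iter, boundary=boundary, ai_covariance=ai_cov,
    )


def _h2_from_theta(theta, ai_cov):
    total = float(theta.sum())
    if total <= 0:
        raise ValueError("total phenotypic variance is zero")
    q = len(theta)
    h2 = theta[:-1] / total
    h2_total = float(theta[:-1].sum() / total)

    def delta_se(weight_vec):
        if not np.isfinite(ai_cov).all():
            return np.nan
        return float(np.sqrt(max(weight_vec @ ai_cov @ weight_vec, 0.0)))

    h2_se = np.empty(q - 1)
    for r in range(q - 1):
        grad = np.full(q, -theta[r] / total**2)
        grad[r] += 1.0 / total
        h2_se[r] = delta_se(grad)
    sg = float(theta[:-1].sum())
    grad_tot = np.full(q, -sg / total**2)
    grad_tot[:-1] += 1.0 / total
    return h2, h2_total, h2_se, delta_se(grad_tot)


def h2_observed(fit: VarianceComponentFit):
    """Observed-scale heritability per component and in total, with SEs.

    Ratios of the fitted variance components; standard errors by the delta
    method on the inverse-AI covariance of the variance estimates.  Returns
    ``(h2_per_component, h2_total, se_per_component, se_total)``.
    """
    theta = np.append(fit.sigma2_g, fit.sigma2_e)
    return _h2_from_theta(theta, fit.ai_covariance)


def format_fit_report(fit: VarianceComponentFit, component_names=None,
                      liability=None, n_cases=None, n_controls=None) -> str:
    """Key-value text report shaped like a GCTA ``.hsq`` file."""
    names = component_names or [f"G{i + 1}" for i in range(len(fit.sigma2_g))]
    lines = ["Source\tVariance\tSE"]
    for name, v, s in zip(names, fit.sigma2_g, fit.se[:-1]):
        lines.append(f"V({name})\t{v:.6f}\t{s:.6f}")
    lines.append(f"V(e)\t{fit.sigma2_e:.6f}\t{fit.se[-1]:.6f}")
    lines.append(f"Vp\t{fit.total_variance:.6f}\t")
    for name, h, s in zip(names, fit.h2_obs, fit.h2_se):
        lines.append(f"V({name})/Vp\t{h:.6f}\t{s:.6f}")
    if len(fit.sigma2_g) > 1:
        lines.append(f"Sum V(G)/Vp\t{fit.h2_obs_total:.6f}\t{fit.h2_se_total:.6f}")
    if liability is not None:
        lines.append(f"V(G)/Vp_L\t{liability.h2_liability:.6f}\t{liability.se_liability:.6f}")
        lines.append(f"Prevalence\t{liability.K:g}\t")
    lines.append(f"logL\t{fit.loglik:.4f}\t")
    if n_cases is not None:
        lines.append(f"n_cases\t{n_cases}\t")
    if n_controls is not None:
        lines.append(f"n_controls\t{n_controls}\t")
    lines.append(f"converged\t{fit.converged}\t(iterations {fit.n_iter})")
    if fit.boundary.any():
        lines.append("note\testimates at the constraint boundary; SEs unreliable\t")
    return "\n".join(lines) + "\n"
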