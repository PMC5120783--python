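"""Inverse-Gaussian and Gaussian mixed models with Laplace approximation.

The response model is a GLMM: outcome score y > 0 (inverse Gaussian with
log link) or unrestricted (Gaussian with identity link), fixed effects
for severity group and a (possibly group-specific) lagged-state slope,
and random effects for person (intercept + slope, unstructured 2x2
covariance) nested in family (intercept).  The marginal likelihood
integrates the random effects out by a Laplace approximation: penalized
IRLS finds the joint mode of (fixed effects, random effects), and the
log-determinant of the penalized information over the random-effect
block supplies the Gaussian-integral correction.  The outer quasi-Newton
optimization runs over the log-Cholesky random-effect parameters and the
log dispersion, with the fixed effects profiled at the conditional mode
(the strategy of the standard mixed-model software this mirrors).

Independent clusters factorize the likelihood, so all cluster-level
solves are batched; an adaptive Gauss-Hermite oracle for the
single-random-intercept case is provided for validation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "IGParams",
    "GlmmSpec",
    "GlmmFit",
    "GlmFit",
    "InteractionTest",
    "ScoreRatio",
    "ig_logpdf",
    "ig_sample",
    "fit_ig_glm",
    "fit_glmm",
    "marginal_loglik_agq",
    "lrt",
    "score_ratio",
    "center_predictor",
    "shift_outcome",
]

_ETA_CLIP = 30.0


# ---------------------------------------------------------------------------
# inverse-Gaussian distribution utilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IGParams:
    """Inverse-Gaussian parameters: mean mu > 0, precision lam > 0.

    Variance is mu**3 / lam; skewness 3*sqrt(mu/lam), so the
    distribution approaches normality as lam/mu grows.
    """

    mu: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.lam > 0):
            raise ValueError("IGParams requires mu > 0 and lam > 0")

    @property
    def variance(self) -> float:
        return self.mu**3 / self.lam


def ig_logpdf(y, mu, lam):
    """Log-density of the inverse-Gaussian distribution (vectorized).

    log f = 0.5*log(lam / (2 pi y^3)) - lam (y - mu)^2 / (2 mu^2 y).
    Raises on any non-positive y: the support is strictly positive,
    which is why shifted outcome scales may be needed.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.any(y <= 0):
        raise ValueError("inverse-Gaussian support is y > 0")
    if np.any(mu <= 0) or np.any(np.asarray(lam) <= 0):
        raise ValueError("mu and lam must be positive")
    return 0.5 * (np.log(lam) - np.log(2.0 * np.pi) - 3.0 * np.log(y)) - lam * (
        y - mu
    ) ** 2 / (2.0 * mu**2 * y)


def ig_sample(params: IGParams, n: int, seed) -> np.ndarray:
    """Exact inverse-Gaussian sample of size n (scipy's IG sampler)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return stats.invgauss.rvs(
        params.mu / params.lam, scale=params.lam, size=n, random_state=rng
    )


# ---------------------------------------------------------------------------
# rescaling protocol
# ---------------------------------------------------------------------------

def center_predictor(x) -> tuple[np.ndarray, float]:
    """Subtract the grand mean (over all persons and measurements)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty predictor")
    grand_mean = float(np.mean(x))
    return x - grand_mean, grand_mean


def shift_outcome(y, shift: float = 0.5) -> np.ndarray:
    """Shift the outcome scale upward (1-7 becomes 1.5-7.5 for +0.5)."""
    return np.asarray(y, dtype=float) + shift


@dataclass(frozen=True)
class ScoreRatio:
    """exp(B) under the log link: multiplicative change per predictor unit."""

    coefficient: float
    ratio: float
    percent_change: float


def score_ratio(coefficient: float) -> ScoreRatio:
    """Score ratio exp(B) and the corresponding percent change."""
    ratio = float(np.exp(coefficient))
    return ScoreRatio(
        coefficient=float(coefficient),
        ratio=ratio,
        percent_change=100.0 * (ratio - 1.0),
    )


# ---------------------------------------------------------------------------
# fixed-effects GLM (statsmodels-backed)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmFit:
    params: np.ndarray
    cov_params: np.ndarray
    dispersion: float  # ML estimate (deviance/n for IG, RSS/n for Gaussian)
    log_likelihood: float
    fitted: np.ndarray
    family: str


def fit_ig_glm(y, design_matrix, family: str = "ig") -> GlmFit:
    """Maximum-likelihood fixed-effects GLM (IG/log or Gaussian/identity).

    Coefficients come from IRLS (statsmodels); the dispersion is the ML
    estimate, and the reported log-likelihood uses it.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = np.asarray(design_matrix, dtype=float)
    if family == "ig":
        if np.any(y <= 0):
            raise ValueError("inverse-Gaussian outcome must be strictly positive")
        fam = sm.families.InverseGaussian(link=sm.families.links.Log())
    elif family == "gaussian":
        fam = sm.families.Gaussian(link=sm.families.links.Identity())
    else:
        raise ValueError("family must be 'ig' or 'gaussian'")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    res = sm.GLM(y, X, family=fam).fit()
    mu = np.asarray(res.fittedvalues)
    n = y.size
    if family == "ig":
        phi = float(np.sum((y - mu) ** 2 / (mu**2 * y)) / n)
        ll = float(np.sum(ig_logpdf(y, mu, 1.0 / phi)))
    else:
        phi = float(np.sum((y - mu) ** 2) / n)
        ll = float(-0.5 * n * np.log(2.0 * np.pi * phi) - 0.5 * n)
    return GlmFit(
        params=np.asarray(res.params),
        cov_params=np.asarray(res.cov_params()) * phi / res.scale,
        dispersion=phi,
        log_likelihood=ll,
        fitted=mu,
        family=family,
    )


# ---------------------------------------------------------------------------
# model specification and fit containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlmmSpec:
    """Description of one cross-lagged mixed model.

    ``outcome`` / ``predictor`` name columns of the lagged-pair table.
    ``severity_role``: 'none' (single slope, no severity terms),
    'covariate' (severity-group main effects + common slope) or
    'moderator' (severity-group main effects + one slope per group).
    ``random_effects``: 'person_slope_family' (person intercept+slope,
    family intercept; the default three-level structure),
    'person_intercept_family', 'person_intercept', or 'none'.
    """

    outcome: str
    predictor: str | None  # None fits an intercept(-plus-severity)-only model
    response_family: str = "ig"  # 'ig' (log link) | 'gaussian' (identity)
    severity_role: str = "moderator"
    random_effects: str = "person_slope_family"
    rescale_outcome_shift: float = 0.0
    rescale_predictor_center: bool = False

    def __post_init__(self) -> None:
        if self.response_family not in ("ig", "gaussian"):
            raise ValueError("response_family must be 'ig' or 'gaussian'")
        if self.severity_role not in ("none", "covariate", "moderator"):
            raise ValueError("invalid severity_role")
        if self.random_effects not in (
            "person_slope_family",
            "person_intercept_family",
            "person_intercept",
            "none",
        ):
            raise ValueError("invalid random_effects structure")
        if self.predictor is None and (
            self.random_effects == "person_slope_family"
            or self.severity_role == "moderator"
        ):
            raise ValueError("slope terms require a predictor")

    @property
    def link(self) -> str:
        return "log" if self.response_family == "ig" else "identity"


@dataclass
class GlmmFit:
    spec: GlmmSpec
    coefficients: pd.DataFrame  # index term; columns estimate, se, ci_low, ci_high
    person_cov: np.ndarray | None
    family_var: float | None
    dispersion: float
    log_likelihood: float
    n_obs: int
    n_params: int
    converged: bool
    rescaling: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def group_slopes(self) -> pd.Series:
        rows = [t for t in self.coefficients.index if t.startswith("slope_g")]
        return self.coefficients.loc[rows, "estimate"]


@dataclass(frozen=True)
class InteractionTest:
    chi_sq: float
    df: int
    p_value: float


def lrt(full: GlmmFit, reduced: GlmmFit) -> InteractionTest:
    """Likelihood-ratio test of nested ML fits on the same data."""
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits use different numbers of observations")
    df = full.n_params - reduced.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than reduced")
    chi = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    return InteractionTest(
        chi_sq=chi, df=df, p_value=float(stats.chi2.sf(chi, df))
    )


# ---------------------------------------------------------------------------
# Laplace machinery
# ---------------------------------------------------------------------------

class _Family:
    """Link/variance bundle for the two response families."""

    def __init__(self, name: str):
        self.name = name

    def mu(self, eta):
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)) if self.name == "ig" else eta

    def weights_and_working(self, y, eta, phi):
        """Fisher-scoring weights and working response."""
        if self.name == "ig":
            mu = self.mu(eta)
            w = 1.0 / (phi * mu)  # (dmu/deta)^2 / (phi * mu^3) with dmu/deta = mu
            z = eta + (y - mu) / mu
        else:
            w = np.full_like(y, 1.0 / phi)
            z = y
        return w, z

    def loglik(self, y, eta, phi):
        mu = self.mu(eta)
        if self.name == "ig":
            return float(np.sum(ig_logpdf(y, mu, 1.0 / phi)))
        n = y.size
        return float(-0.5 * n * np.log(2.0 * np.pi * phi) - np.sum((y - mu) ** 2) / (2.0 * phi))

    def observed_curvature(self, y, eta, phi):
        """Per-observation -d2 loglik / d eta2 (the joint-Hessian weights)."""
        if self.name == "gaussian":
            return np.full_like(y, 1.0 / phi)
        mu = self.mu(eta)
        r = y / mu
        return (2.0 * r**2 - r) / (phi * y)


class _LaplaceProblem:
    """Preprocessed cluster structure for one model's data.

    Rows must be grouped person-within-cluster; clusters are families
    when a family intercept is present, otherwise persons.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        x_slope: np.ndarray,
        person_ids: np.ndarray,
        family_ids: np.ndarray,
        family: str,
        person_slope: bool,
        family_re: bool,
    ):
        self.fam = _Family(family)
        self.person_slope = person_slope
        self.family_re = family_re
        cluster_ids = family_ids if family_re else person_ids
        order = np.lexsort((person_ids, cluster_ids))
        self.y = np.ascontiguousarray(y[order])
        self.X = np.ascontiguousarray(X[order])
        self.x = np.ascontiguousarray(x_slope[order])
        pid = person_ids[order]
        cid = cluster_ids[order]
        # person segmentation (contiguous after the sort)
        new_p = np.concatenate([[True], (pid[1:] != pid[:-1]) | (cid[1:] != cid[:-1])])
        self.p_starts = np.flatnonzero(new_p)
        self.n_pers = self.p_starts.size
        pclust = cid[self.p_starts]
        new_c = np.concatenate([[True], pclust[1:] != pclust[:-1]])
        self.c_pstarts = np.flatnonzero(new_c)  # cluster starts in person space
        self.n_clust = self.c_pstarts.size
        # person -> cluster row, person slot within cluster
        self.p_cluster = np.cumsum(new_c) - 1
        rank = np.arange(self.n_pers) - self.c_pstarts[self.p_cluster]
        self.dp = 2 if person_slope else 1
        c0 = 1 if family_re else 0
        self.c0 = c0
        self.p_slot = c0 + self.dp * rank
        members = np.diff(np.append(self.c_pstarts, self.n_pers))
        self.d_max = int(c0 + self.dp * members.max())
        # per-obs flat indices into b.reshape(-1)
        obs_person = np.cumsum(new_p) - 1
        self.obs_cluster = self.p_cluster[obs_person]
        base = self.obs_cluster * self.d_max
        self.idx_p0 = base + self.p_slot[obs_person]
        self.idx_p1 = self.idx_p0 + 1 if person_slope else None
        self.idx_c0 = base if family_re else None
        self.n = self.y.size
        self.p = X.shape[1]

    # -- random-effect covariance ------------------------------------------
    def unpack(self, theta: np.ndarray):
        """theta -> (person precision block, family var, phi, logdetG)."""
        i = 0
        if self.person_slope:
            a, b, c = theta[i], theta[i + 1], theta[i + 2]
            i += 3
            L = np.array([[np.exp(a), 0.0], [c, np.exp(b)]])
            sigma_p = L @ L.T
            prec_p = np.linalg.inv(sigma_p + 1e-12 * np.eye(2))
            logdet_p = 2.0 * (a + b)
        else:
            sp2 = np.exp(2.0 * theta[i])
            i += 1
            sigma_p = np.array([[sp2]])
            prec_p = np.array([[1.0 / sp2]])
            logdet_p = float(np.log(sp2))
        if self.family_re:
            sf2 = np.exp(2.0 * theta[i])
            i += 1
        else:
            sf2 = None
        phi = np.exp(theta[i])
        logdetG = self.n_pers * logdet_p + (
            self.n_clust * np.log(sf2) if self.family_re else 0.0
        )
        return sigma_p, prec_p, sf2, phi, logdetG

    def n_theta(self) -> int:
        return (3 if self.person_slope else 1) + (1 if self.family_re else 0) + 1

    def _g_inv(self, prec_p, sf2):
        d = self.d_max
        G = np.zeros((self.n_clust, d, d))
        G[:, np.arange(d), np.arange(d)] = 1.0  # padding
        pc, sl = self.p_cluster, self.p_slot
        G[pc, sl, sl] = prec_p[0, 0]
        if self.person_slope:
            G[pc, sl, sl + 1] = prec_p[0, 1]
            G[pc, sl + 1, sl] = prec_p[1, 0]
            G[pc, sl + 1, sl + 1] = prec_p[1, 1]
        if self.family_re:
            G[:, 0, 0] = 1.0 / sf2
        return G

    # -- one penalized weighted least-squares solve ------------------------
    def _pwls(self, w, z, G_inv, offset=None):
        """Solve the penalized WLS system for (beta, b).

        With ``offset`` given, beta is skipped (fixed-effects part held
        at the offset) and only the random-effect block is solved.
        """
        n_c, d, dp, p = self.n_clust, self.d_max, self.dp, self.p
        pc, sl, c0 = self.p_cluster, self.p_slot, self.c0
        X, x = self.X, self.x
        resp = z if offset is None else z - offset
        # per-person moment sums
        cols = [w, w * resp]
        if self.person_slope:
            cols += [w * x, w * x * x, w * resp * x]
        stack = np.column_stack(cols)
        psums = np.add.reduceat(stack, self.p_starts, axis=0)
        pw, pwz = psums[:, 0], psums[:, 1]
        if self.person_slope:
            pwx, pwxx, pwzx = psums[:, 2], psums[:, 3], psums[:, 4]
        S = np.zeros((n_c, d, d))
        S[pc, sl, sl] = pw
        if self.person_slope:
            S[pc, sl, sl + 1] = S[pc, sl + 1, sl] = pwx
            S[pc, sl + 1, sl + 1] = pwxx
        r = np.zeros((n_c, d))
        r[pc, sl] = pwz
        if self.person_slope:
            r[pc, sl + 1] = pwzx
        if self.family_re:
            csum = lambda a: np.add.reduceat(a, self.c_pstarts, axis=0)
            S[:, 0, 0] = csum(pw)
            S[pc, 0, sl] = S[pc, sl, 0] = pw
            if self.person_slope:
                S[pc, 0, sl + 1] = S[pc, sl + 1, 0] = pwx
            r[:, 0] = csum(pwz)
        S_pen = S + G_inv
        if offset is None:
            wX = w[:, None] * X
            pwX = np.add.reduceat(wX, self.p_starts, axis=0)
            U = np.zeros((n_c, d, p))
            U[pc, sl, :] = pwX
            if self.person_slope:
                pwxX = np.add.reduceat(wX * x[:, None], self.p_starts, axis=0)
                U[pc, sl + 1, :] = pwxX
            if self.family_re:
                U[:, 0, :] = np.add.reduceat(pwX, self.c_pstarts, axis=0)
            rhs = np.concatenate([U, r[:, :, None]], axis=2)
            sol = np.linalg.solve(S_pen, rhs)
            A, c = sol[:, :, :p], sol[:, :, p]
            M = (wX.T @ X) - np.einsum("cdi,cdj->ij", U, A)
            v = X.T @ (w * resp) - np.einsum("cdi,cd->i", U, c)
            beta = np.linalg.solve(M, v)
            b = c - np.einsum("cdp,p->cd", A, beta)
            return beta, b, S_pen, M
        b = np.linalg.solve(S_pen, r[:, :, None])[:, :, 0]
        return None, b, S_pen, None

    def _eta_from(self, beta, b, offset=None):
        bflat = b.reshape(-1)
        eta = (self.X @ beta) if offset is None else offset.copy()
        eta += bflat[self.idx_p0]
        if self.person_slope:
            eta += bflat[self.idx_p1] * self.x
        if self.family_re:
            eta += bflat[self.idx_c0]
        return eta

    def _pen_obj(self, eta, b, G_inv, phi):
        return self.fam.loglik(self.y, eta, phi) - 0.5 * float(
            np.einsum("cd,cde,ce->", b, G_inv, b)
        )

    def pirls(
        self,
        theta: np.ndarray,
        start: tuple[np.ndarray, np.ndarray] | None = None,
        offset: np.ndarray | None = None,
        max_iter: int = 80,
        tol: float = 1e-10,
    ):
        """Penalized IRLS to the joint (beta, b) mode; Laplace log-likelihood.

        Fisher-scoring steps with step-halving on the penalized
        log-likelihood; the Gaussian-identity case is a single exact
        solve.  The Laplace correction uses the log-determinant of the
        negative joint Hessian over the random-effect block (observed
        curvature, falling back to Fisher curvature if the observed one
        is not positive definite at the mode).

        Returns (loglik, beta, b, M, (beta, b), ok).
        """
        sigma_p, prec_p, sf2, phi, logdetG = self.unpack(theta)
        G_inv = self._g_inv(prec_p, sf2)
        y = self.y
        p = self.p
        if start is not None:
            beta = start[0].copy() if start[0] is not None else None
            b = start[1].copy()
        else:
            beta = None
            b = np.zeros((self.n_clust, self.d_max))
        if offset is None and beta is None:
            beta = np.zeros(p)
            beta[0] = np.log(np.mean(y)) if self.fam.name == "ig" else np.mean(y)
        eta = self._eta_from(beta, b, offset=offset)
        pen = self._pen_obj(eta, b, G_inv, phi)
        if not np.isfinite(pen):
            b = np.zeros_like(b)
            if offset is None:
                beta = np.zeros(p)
                beta[0] = np.log(np.mean(y)) if self.fam.name == "ig" else np.mean(y)
            eta = self._eta_from(beta, b, offset=offset)
            pen = self._pen_obj(eta, b, G_inv, phi)
        ok = False
        M = None
        for _ in range(1 if self.fam.name == "gaussian" else max_iter):
            w, z = self.fam.weights_and_working(y, eta, phi)
            beta_new, b_new, _, M = self._pwls(w, z, G_inv, offset=offset)
            step = 1.0
            for _half in range(12):
                beta_try = (
                    None if offset is not None
                    else beta + step * (beta_new - beta)
                )
                b_try = b + step * (b_new - b)
                eta_try = self._eta_from(beta_try, b_try, offset=offset)
                pen_try = self._pen_obj(eta_try, b_try, G_inv, phi)
                if np.isfinite(pen_try) and (
                    pen_try >= pen - 1e-10 * max(1.0, abs(pen))
                ):
                    break
                step *= 0.5
            else:
                return -np.inf, beta, b, M, (beta, b), False
            delta = np.max(np.abs(eta_try - eta))
            beta = beta_try if offset is None else beta
            b, eta, pen = b_try, eta_try, pen_try
            if delta < max(tol, 1e-9 * max(1.0, np.max(np.abs(eta)))):
                ok = True
                break
        if self.fam.name == "gaussian":
            ok = True
        if not np.all(np.isfinite(eta)):
            return -np.inf, beta, b, M, (beta, b), False
        # Laplace correction at the mode
        w_obs = self.fam.observed_curvature(y, eta, phi)
        S_pen = self._s_pen_only(w_obs, G_inv)
        try:
            chol = np.linalg.cholesky(S_pen)
        except np.linalg.LinAlgError:
            w_fis, _ = self.fam.weights_and_working(y, eta, phi)
            chol = np.linalg.cholesky(self._s_pen_only(w_fis, G_inv))
        logdetS = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)))
        ll = pen - 0.5 * (logdetG + logdetS)
        return float(ll), beta, b, M, (beta, b), ok

    def _s_pen_only(self, w, G_inv):
        n_c, d = self.n_clust, self.d_max
        pc, sl = self.p_cluster, self.p_slot
        x = self.x
        cols = [w]
        if self.person_slope:
            cols += [w * x, w * x * x]
        psums = np.add.reduceat(np.column_stack(cols), self.p_starts, axis=0)
        pw = psums[:, 0]
        S = np.zeros((n_c, d, d))
        S[pc, sl, sl] = pw
        if self.person_slope:
            pwx, pwxx = psums[:, 1], psums[:, 2]
            S[pc, sl, sl + 1] = S[pc, sl + 1, sl] = pwx
            S[pc, sl + 1, sl + 1] = pwxx
        if self.family_re:
            S[:, 0, 0] = np.add.reduceat(pw, self.c_pstarts)
            S[pc, 0, sl] = S[pc, sl, 0] = pw
            if self.person_slope:
                S[pc, 0, sl + 1] = S[pc, sl + 1, 0] = pwx
        return S + G_inv


def _design(frame: pd.DataFrame, spec: GlmmSpec):
    """Design matrix, slope covariate, outcome, and term names for a spec."""
    y = frame[spec.outcome].to_numpy(dtype=float)
    n = y.size
    x = (
        frame[spec.predictor].to_numpy(dtype=float)
        if spec.predictor is not None
        else np.zeros(n)
    )
    rescaling = {"outcome_shift": spec.rescale_outcome_shift,
                 "predictor_centered": spec.rescale_predictor_center}
    if spec.rescale_outcome_shift:
        y = shift_outcome(y, spec.rescale_outcome_shift)
    if spec.rescale_predictor_center and spec.predictor is not None:
        x, gm = center_predictor(x)
        rescaling["predictor_grand_mean"] = gm
    if spec.severity_role == "none":
        if spec.predictor is None:
            X = np.ones((n, 1))
            names = ["intercept"]
        else:
            X = np.column_stack([np.ones(n), x])
            names = ["intercept", "slope"]
    else:
        g = frame["severity_group"].to_numpy(dtype=int)
        levels = np.unique(g)
        dummies = [(g == lv).astype(float) for lv in levels[1:]]
        if spec.severity_role == "covariate":
            if spec.predictor is None:
                X = np.column_stack([np.ones(n), *dummies])
                names = ["intercept"] + [f"severity_g{lv}" for lv in levels[1:]]
            else:
                X = np.column_stack([np.ones(n), *dummies, x])
                names = ["intercept"] + [f"severity_g{lv}" for lv in levels[1:]] + ["slope"]
        else:
            slopes = [x * (g == lv) for lv in levels]
            X = np.column_stack([np.ones(n), *dummies, *slopes])
            names = (
                ["intercept"]
                + [f"severity_g{lv}" for lv in levels[1:]]
                + [f"slope_g{lv}" for lv in levels]
            )
    return y, x, X, names, rescaling


def fit_glmm(
    spec: GlmmSpec,
    pairs: pd.DataFrame,
    start_theta: np.ndarray | None = None,
    fix_theta: np.ndarray | None = None,
    max_iter: int = 500,
    gtol: float = 1e-3,
    ftol: float = 1e-8,
    fd_step: float = 1e-6,
) -> GlmmFit:
    """Fit one cross-lagged mixed model by Laplace-approximated ML.

    ``pairs`` must carry person_id, family_id, the outcome column at
    time t, the predictor column at t-1 and (unless severity_role is
    'none') a severity_group column.  Rows with a missing outcome or
    predictor are dropped (per-model pairwise deletion).  The fit is
    deterministic given data and starting values: fixed effects start at
    the fixed-effects GLM solution and random-effect standard deviations
    at 10% of the outcome's scale SD.  ``fix_theta`` pins the
    variance/dispersion parameters (no outer optimization), which is how
    the zero-variance degeneracy to the plain GLM can be exercised.
    """
    cols = [spec.outcome] + ([spec.predictor] if spec.predictor is not None else [])
    data = pairs.dropna(subset=cols)
    if data.empty:
        raise ValueError("no complete outcome/predictor pairs")
    y, x, X, names, rescaling = _design(data, spec)
    if spec.response_family == "ig" and np.any(y <= 0):
        raise ValueError(
            "inverse-Gaussian outcome must be strictly positive "
            "(consider the +0.5 outcome shift)"
        )

    if spec.random_effects == "none":
        glm = fit_ig_glm(y, X, family=spec.response_family)
        se = np.sqrt(np.diag(glm.cov_params))
        coef = pd.DataFrame(
            {
                "estimate": glm.params,
                "se": se,
                "ci_low": glm.params - 1.959963984540054 * se,
                "ci_high": glm.params + 1.959963984540054 * se,
            },
            index=names,
        )
        return GlmmFit(
            spec=spec, coefficients=coef, person_cov=None, family_var=None,
            dispersion=glm.dispersion, log_likelihood=glm.log_likelihood,
            n_obs=y.size, n_params=X.shape[1] + 1, converged=True,
            rescaling=rescaling, diagnostics={"method": "glm"},
        )

    person_slope = spec.random_effects == "person_slope_family"
    family_re = spec.random_effects in ("person_slope_family", "person_intercept_family")
    prob = _LaplaceProblem(
        y=y, X=X, x_slope=x,
        person_ids=data["person_id"].to_numpy(),
        family_ids=data["family_id"].to_numpy()
        if "family_id" in data else data["person_id"].to_numpy(),
        family=spec.response_family,
        person_slope=person_slope, family_re=family_re,
    )

    # starting values: fixed effects at the GLM solution; person-intercept
    # SD from the person-level spread of link-scale residuals (a moment
    # estimate that lands the outer search close to the optimum)
    glm0 = fit_ig_glm(y, X, family=spec.response_family)
    resid = (np.log(y) if spec.response_family == "ig" else y) - (
        np.log(glm0.fitted) if spec.response_family == "ig" else glm0.fitted
    )
    person_means = pd.Series(resid).groupby(data["person_id"].to_numpy()).mean()
    sd_int = float(max(np.std(person_means), 0.02 * max(np.std(resid), 1e-3)))
    theta0 = []
    if person_slope:
        theta0 += [np.log(sd_int), np.log(0.25 * sd_int), 0.0]
    else:
        theta0 += [np.log(sd_int)]
    if family_re:
        theta0 += [np.log(0.5 * sd_int)]
    theta0 += [float(np.log(glm0.dispersion))]
    theta0 = np.asarray(theta0)
    if start_theta is not None:
        theta0 = np.asarray(start_theta, dtype=float)

    state = {"warm": (glm0.params.copy(), np.zeros((prob.n_clust, prob.d_max)))}

    def objective(theta):
        ll, beta, b, M, warm, ok = prob.pirls(theta, start=state["warm"])
        if not np.isfinite(ll):
            return 1e10
        state["warm"] = warm
        return -ll

    if fix_theta is not None:
        theta_hat = np.asarray(fix_theta, dtype=float)
        opt_ok = True
        n_outer = 0
        ll_start = None
    else:
        ll_start = -objective(theta0)
        bounds = [(-12.0, 8.0)] * theta0.size
        res = optimize.minimize(
            objective, theta0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol, "eps": fd_step},
        )
        theta_hat = res.x
        opt_ok = bool(res.success)
        n_outer = int(res.nit)

    ll, beta, b, M, _, pirls_ok = prob.pirls(theta_hat, start=state["warm"])
    sigma_p, _, sf2, phi, _ = prob.unpack(theta_hat)
    cov_beta = np.linalg.inv(M)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    zq = 1.959963984540054
    coef = pd.DataFrame(
        {
            "estimate": beta,
            "se": se,
            "ci_low": beta - zq * se,
            "ci_high": beta + zq * se,
        },
        index=names,
    )
    converged = bool(pirls_ok and (fix_theta is not None or opt_ok) and np.isfinite(ll))
    return GlmmFit(
        spec=spec,
        coefficients=coef,
        person_cov=sigma_p if person_slope else sigma_p[:1, :1],
        family_var=float(sf2) if family_re else None,
        dispersion=float(phi),
        log_likelihood=float(ll),
        n_obs=y.size,
        n_params=X.shape[1] + prob.n_theta(),
        converged=converged,
        rescaling=rescaling,
        diagnostics={"method": "laplace", "outer_iterations": n_outer,
                     "theta": theta_hat.tolist(), "pirls_converged": bool(pirls_ok),
                     "ll_start": ll_start},
    )


def laplace_loglik_fixed_beta(
    spec: GlmmSpec, pairs: pd.DataFrame, beta: np.ndarray, theta: np.ndarray
) -> float:
    """Laplace marginal log-likelihood at fixed parameters (mode over b only).

    Companion to :func:`marginal_loglik_agq` for validation at matched
    parameter values.
    """
    data = pairs.dropna(
        subset=[spec.outcome] + ([spec.predictor] if spec.predictor is not None else [])
    )
    y, x, X, _, _ = _design(data, spec)
    person_slope = spec.random_effects == "person_slope_family"
    family_re = spec.random_effects in ("person_slope_family", "person_intercept_family")
    prob = _LaplaceProblem(
        y=y, X=X, x_slope=x,
        person_ids=data["person_id"].to_numpy(),
        family_ids=data["family_id"].to_numpy()
        if "family_id" in data else data["person_id"].to_numpy(),
        family=spec.response_family,
        person_slope=person_slope, family_re=family_re,
    )
    offset = prob.X @ np.asarray(beta, dtype=float)
    ll, *_ = prob.pirls(
        np.asarray(theta, dtype=float),
        start=(None, np.zeros((prob.n_clust, prob.d_max))),
        offset=offset,
    )
    return float(ll)


def marginal_loglik_agq(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    cluster_ids: np.ndarray,
    sigma_b: float,
    phi: float,
    family: str = "ig",
    n_nodes: int = 15,
) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood, single random intercept.

    Validation oracle only: per cluster, centers the quadrature at the
    random-intercept mode with curvature-matched scaling and integrates
    the joint likelihood exactly up to quadrature error.
    """
    y = np.asarray(y, dtype=float)
    eta_fix = np.asarray(X, dtype=float) @ np.asarray(beta, dtype=float)
    nodes, weights = special.roots_hermite(n_nodes)
    fam = _Family(family)
    total = 0.0
    for cl in np.unique(cluster_ids):
        m = cluster_ids == cl
        yc, oc = y[m], eta_fix[m]

        def joint(b):
            eta = oc + b
            return fam.loglik(yc, eta, phi) + float(
                stats.norm.logpdf(b, scale=sigma_b)
            )

        b_hat = optimize.minimize_scalar(
            lambda b: -joint(b), bounds=(-8 * sigma_b, 8 * sigma_b), method="bounded",
            options={"xatol": 1e-10},
        ).x
        h = 1e-4 * max(1.0, abs(b_hat))
        curv = -(joint(b_hat + h) - 2.0 * joint(b_hat) + joint(b_hat - h)) / h**2
        scale = 1.0 / np.sqrt(max(curv, 1e-8))
        pts = b_hat + np.sqrt(2.0) * scale * nodes
        vals = np.array([joint(b) for b in pts]) + nodes**2
        mx = vals.max()
        integral = np.sqrt(2.0) * scale * np.sum(weights * np.exp(vals - mx))
        total += mx + np.log(integral)
    return float(total)
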