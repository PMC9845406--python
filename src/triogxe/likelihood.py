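"""Conditional likelihood for G'xE inference from case-parent trios.

The disease-risk model is log-linear in genotype relative risks (GRRs) at the
test locus, with the log-GRR for genotype level g' a linear function of the
exposure e and an adjustment covariate vector x:

    log GRR_{g'}(e, x) = beta_{g'} + beta_{g'X}' x + beta_{g'E} e
                         + beta_{g'EX}' x * e,      g' = 1, 2.

Conditioning on the affected child's parents removes both the environmental
main effect (the baseline risk eta(e) cancels) and confounding of the genetic
main effects by population structure. The per-trio likelihood contribution is

    P(G'_c = g | G'_p, E = e, X = x, D = 1)
        = m(g) prod_{i<=g} GRR_i(e, x) / sum_g* m(g*) prod_{i<=g*} GRR_i(e, x)

with m(.) the Mendelian transmission distribution and GRR_0 = 1. A
likelihood-ratio test of beta_{g'E} = beta_{g'EX} = 0 (g' = 1, 2) detects
G'xE; with K covariates its degrees of freedom are 2(K+1) under the
codominant model and K+1 under the additive model (which ties the two
genotype levels to a single per-allele parameter set).

The negative log-likelihood is convex in the parameters (a conditional
multinomial-logit form), so a damped Newton iteration with analytic gradient
and Hessian is used for fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .core import TrioDataset, TrioRecord

_MODELS = ("codominant", "additive")


@dataclass(frozen=True)
class GRRModelSpec:
    """Shape of the log-GRR model: genetic model, covariate count, and
    whether exposure-slope (interaction) terms are present."""

    genetic_model: str = "codominant"
    k_covariates: int = 0
    with_interaction: bool = True

    def __post_init__(self) -> None:
        if self.genetic_model not in _MODELS:
            raise ValueError(f"genetic_model must be one of {_MODELS}")
        if self.k_covariates < 0:
            raise ValueError("k_covariates must be >= 0")

    @property
    def n_levels(self) -> int:
        """Distinct parameter sets over genotype levels: 2 codominant, 1 additive."""
        return 2 if self.genetic_model == "codominant" else 1

    @property
    def d_per_level(self) -> int:
        """Free parameters per level: intercept + K mains (+ slope + K products)."""
        k = self.k_covariates
        return (2 + 2 * k) if self.with_interaction else (1 + k)

    @property
    def n_params(self) -> int:
        return self.n_levels * self.d_per_level

    @property
    def df_interaction(self) -> int:
        """Degrees of freedom of the G'xE LRT: (exposure slope + K products) per level."""
        return self.n_levels * (self.k_covariates + 1)

    def null(self) -> "GRRModelSpec":
        return dataclasses.replace(self, with_interaction=False)


@dataclass
class GRRParams:
    """Log-GRR coefficients, one row per genotype level (a single shared row
    under the additive model)."""

    beta: np.ndarray        # (L,)
    beta_x: np.ndarray      # (L, K)
    beta_e: np.ndarray      # (L,)
    beta_ex: np.ndarray     # (L, K)

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        self.beta_e = np.atleast_1d(np.asarray(self.beta_e, float))
        self.beta_x = np.asarray(self.beta_x, float)
        self.beta_ex = np.asarray(self.beta_ex, float)
        L = self.beta.shape[0]
        for name in ("beta_x", "beta_ex"):
            v = getattr(self, name)
            if v.ndim == 1:
                v = v.reshape(L, -1) if v.size else v.reshape(L, 0)
                setattr(self, name, v)
        if not (self.beta_e.shape[0] == self.beta_x.shape[0]
                == self.beta_ex.shape[0] == L):
            raise ValueError("parameter blocks disagree on the number of levels")
        if self.beta_x.shape != self.beta_ex.shape:
            raise ValueError("beta_x and beta_ex must have the same shape")

    @property
    def n_levels(self) -> int:
        return int(self.beta.shape[0])

    @property
    def k_covariates(self) -> int:
        return int(self.beta_x.shape[1])

    @classmethod
    def zeros(cls, spec: GRRModelSpec) -> "GRRParams":
        L, K = spec.n_levels, spec.k_covariates
        return cls(np.zeros(L), np.zeros((L, K)), np.zeros(L), np.zeros((L, K)))

    def to_vector(self, spec: GRRModelSpec) -> np.ndarray:
        self._check_spec(spec)
        rows = []
        for l in range(spec.n_levels):
            row = [self.beta[l], *self.beta_x[l]]
            if spec.with_interaction:
                row += [self.beta_e[l], *self.beta_ex[l]]
            rows.append(row)
        return np.concatenate([np.asarray(r, float) for r in rows])

    @classmethod
    def from_vector(cls, vec: np.ndarray, spec: GRRModelSpec) -> "GRRParams":
        vec = np.asarray(vec, float)
        if vec.shape != (spec.n_params,):
            raise ValueError(f"expected {spec.n_params} parameters, got {vec.shape}")
        L, K, d = spec.n_levels, spec.k_covariates, spec.d_per_level
        p = cls.zeros(spec)
        for l in range(L):
            row = vec[l * d:(l + 1) * d]
            p.beta[l] = row[0]
            p.beta_x[l] = row[1:1 + K]
            if spec.with_interaction:
                p.beta_e[l] = row[1 + K]
                p.beta_ex[l] = row[2 + K:]
        return p

    def _check_spec(self, spec: GRRModelSpec) -> None:
        if self.n_levels != spec.n_levels or self.k_covariates != spec.k_covariates:
            raise ValueError("parameter shape does not match the model spec")
        if not spec.with_interaction and (
            np.any(self.beta_e != 0.0) or np.any(self.beta_ex != 0.0)
        ):
            raise ValueError("null-model spec but nonzero interaction parameters")


def log_grr(
    g_prime: int,
    e: float,
    x: np.ndarray,
    params: GRRParams,
    spec: GRRModelSpec,
) -> float:
    """Evaluate log GRR_{g'}(e, x) for a single genotype level g' in {1, 2}."""
    if g_prime not in (1, 2):
        raise ValueError("g_prime must be 1 or 2")
    x = np.atleast_1d(np.asarray(x, float))
    if x.shape[0] != spec.k_covariates:
        raise ValueError(
            f"covariate vector has length {x.shape[0]}, spec says {spec.k_covariates}"
        )
    params._check_spec(spec)
    l = 0 if spec.n_levels == 1 else g_prime - 1
    return float(
        params.beta[l]
        + params.beta_x[l] @ x
        + params.beta_e[l] * e
        + (params.beta_ex[l] @ x) * e
    )


# ---------------------------------------------------------------------------
# vectorized likelihood internals
# ---------------------------------------------------------------------------

# cumulative level multiplicities: c_g = sum_l U[g, l] * (z' beta_l)
_U_CODOMINANT = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
_U_ADDITIVE = np.array([[0.0], [1.0], [2.0]])


def _level_matrix(spec: GRRModelSpec) -> np.ndarray:
    return _U_CODOMINANT if spec.genetic_model == "codominant" else _U_ADDITIVE


def _design(data: TrioDataset, spec: GRRModelSpec) -> np.ndarray:
    """Per-trio covariate row z: [1, x] or [1, x, e, x*e]."""
    if data.k_covariates != spec.k_covariates:
        raise ValueError(
            f"dataset has {data.k_covariates} covariates, spec says {spec.k_covariates}"
        )
    n = len(data)
    ones = np.ones((n, 1))
    if spec.with_interaction:
        e = data.exposure[:, None]
        return np.hstack([ones, data.covariates, e, data.covariates * e])
    return np.hstack([ones, data.covariates])


def _mendel_matrix(data: TrioDataset) -> np.ndarray:
    from .core import _MENDEL

    return _MENDEL[data.g_mother, data.g_father]


def _child_prob_matrix(theta: np.ndarray, Z: np.ndarray, U: np.ndarray,
                       M: np.ndarray) -> np.ndarray:
    """n x 3 matrix of P(child genotype | parents, e, x, affected)."""
    d = Z.shape[1]
    L = U.shape[1]
    B = theta.reshape(L, d)
    eta = Z @ B.T            # (n, L): z' beta_l
    C = eta @ U.T            # (n, 3): cumulative log-GRR sums
    C = C - C.max(axis=1, keepdims=True)
    W = M * np.exp(C)
    return W / W.sum(axis=1, keepdims=True)


def child_genotype_probs(
    record: TrioRecord, params: GRRParams, spec: GRRModelSpec
) -> np.ndarray:
    """P(child genotype | parents, exposure, covariates, affected) over {0,1,2}.

    The baseline risk eta(e) cancels in this conditional probability, so only
    the GRR parameters enter.
    """
    data = TrioDataset.from_records([record])
    Z = _design(data, spec)
    theta = params.to_vector(spec)
    return _child_prob_matrix(theta, Z, _level_matrix(spec), _mendel_matrix(data))[0]


def _nll_parts(theta, Z, U, M, g_child, order=2):
    """Negative log-likelihood and (optionally) analytic gradient/Hessian."""
    n, d = Z.shape
    L = U.shape[1]
    B = theta.reshape(L, d)
    C = (Z @ B.T) @ U.T
    cmax = C.max(axis=1, keepdims=True)
    W = M * np.exp(C - cmax)
    S = W.sum(axis=1)
    P = W / S[:, None]
    rows = np.arange(n)
    obs_m = M[rows, g_child]
    nll = float(np.sum(np.log(S) + cmax[:, 0] - (C[rows, g_child] - 0.0)
                       - np.log(obs_m)))
    if order == 0:
        return nll, None, None
    # E_l = E_p[u_l], observed u at the child's genotype
    Eu = P @ U                      # (n, L)
    Uobs = U[g_child]               # (n, L)
    R = Eu - Uobs                   # residual multiplicities
    grad = np.concatenate([Z.T @ R[:, l] for l in range(L)])
    if order == 1:
        return nll, grad, None
    # Hessian blocks: z' diag(w_{ll'}) z with w = E[u_l u_l'] - E[u_l]E[u_l']
    H = np.zeros((L * d, L * d))
    for l in range(L):
        for lp in range(l, L):
            m2 = P @ (U[:, l] * U[:, lp])          # (n,)
            w = m2 - Eu[:, l] * Eu[:, lp]
            blk = (Z * w[:, None]).T @ Z
            H[l * d:(l + 1) * d, lp * d:(lp + 1) * d] = blk
            if lp != l:
                H[lp * d:(lp + 1) * d, l * d:(l + 1) * d] = blk.T
    return nll, grad, H


def total_loglik(data: TrioDataset, params: GRRParams, spec: GRRModelSpec) -> float:
    """Sum over trios of the log conditional child-genotype probability."""
    if len(data) == 0:
        return 0.0
    theta = params.to_vector(spec)
    Z = _design(data, spec)
    nll, _, _ = _nll_parts(
        theta, Z, _level_matrix(spec), _mendel_matrix(data), data.g_child, order=0
    )
    return -nll


@dataclass
class FitResult:
    """Maximum-likelihood fit of the log-GRR model."""

    params: GRRParams
    spec: GRRModelSpec
    loglik: float
    covariance: np.ndarray
    converged: bool
    n_informative: int
    n_iter: int
    message: str = ""

    @property
    def theta(self) -> np.ndarray:
        return self.params.to_vector(self.spec)


class SeparationError(RuntimeError):
    """Monotone likelihood: the MLE diverges (complete separation)."""


def fit(
    data: TrioDataset,
    spec: GRRModelSpec,
    start: GRRParams | None = None,
    gtol: float = 1e-6,
    max_iter: int = 200,
) -> FitResult:
    """Maximize the conditional trio likelihood by damped Newton iteration.

    The objective is convex; iterations start at zero (the null) unless a
    warm start is given. Non-convergence is flagged on the result, not
    raised; the covariance is the inverse observed information at the
    optimum.
    """
    mask = data.informative
    n_inf = int(mask.sum())
    if n_inf == 0:
        raise ValueError("no informative trios (need at least one heterozygous parent)")
    sub = TrioDataset(
        data.g_child[mask], data.g_mother[mask], data.g_father[mask],
        data.exposure[mask], data.covariates[mask],
        None if data.stratum is None else data.stratum[mask],
        data.exposure_type,
    )
    Z = _design(sub, spec)
    U = _level_matrix(spec)
    M = _mendel_matrix(sub)
    g = sub.g_child
    theta = (start.to_vector(spec) if start is not None
             else np.zeros(spec.n_params))

    nll, grad, H = _nll_parts(theta, Z, U, M, g)
    converged = False
    message = ""
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) <= gtol:
            converged = True
            break
        ridge = 0.0
        for _ in range(8):
            try:
                step = linalg.solve(
                    H + ridge * np.eye(H.shape[0]), -grad, assume_a="pos"
                )
                break
            except linalg.LinAlgError:
                ridge = 10.0 * ridge if ridge else 1e-8
        else:
            message = "Hessian solve failed"
            break
        # stop when the attainable improvement (half the Newton decrement)
        # is below floating-point noise in the objective
        decrement = float(-(grad @ step))
        if decrement <= 1e-12 * (1.0 + abs(nll)):
            converged = True
            break
        # backtracking line search on the convex objective
        t = 1.0
        for _ in range(40):
            cand = theta + t * step
            nll_new, _, _ = _nll_parts(cand, Z, U, M, g, order=0)
            if nll_new <= nll + 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        else:
            message = "line search failed"
            break
        theta = theta + t * step
        nll, grad, H = _nll_parts(theta, Z, U, M, g)
        if np.max(np.abs(theta)) > 50.0:
            message = "parameters diverging: possible complete separation"
            break
    if not converged and not message:
        message = f"gradient sup-norm {np.max(np.abs(grad)):.2e} > {gtol:g} after {it} iterations"

    try:
        cov = linalg.inv(H)
    except linalg.LinAlgError:
        cov = linalg.pinvh(H)
    cov = (cov + cov.T) / 2.0
    return FitResult(
        params=GRRParams.from_vector(theta, spec),
        spec=spec,
        loglik=-nll,
        covariance=cov,
        converged=converged,
        n_informative=n_inf,
        n_iter=it,
        message=message,
    )


@dataclass
class LRTResult:
    """Likelihood-ratio test of no G'xE (all exposure-slope terms zero)."""

    statistic: float
    df: int
    p_value: float
    full_fit: FitResult
    null_fit: FitResult

    def to_frame(self) -> pd.DataFrame:
        spec = self.full_fit.spec
        p = self.full_fit.params
        row: dict[str, object] = {
            "model": spec.genetic_model,
            "k_covariates": spec.k_covariates,
            "n_informative": self.full_fit.n_informative,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
        }
        for l in range(spec.n_levels):
            tag = "" if spec.n_levels == 1 else f"_g{l + 1}"
            row[f"beta{tag}"] = p.beta[l]
            row[f"beta_E{tag}"] = p.beta_e[l]
        return pd.DataFrame([row])

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def lrt_gxe(data: TrioDataset, spec: GRRModelSpec) -> LRTResult:
    """Fit the null and full log-GRR models and test the exposure slopes.

    The statistic 2(l_full - l_null) is clipped at zero (nested models) and
    referred to chi-square with 2(K+1) df (codominant) or K+1 df (additive).
    """
    full_spec = dataclasses.replace(spec, with_interaction=True)
    null_fit = fit(data, full_spec.null())
    # warm-start the full model at the null optimum with zero slopes
    warm = GRRParams.zeros(full_spec)
    warm.beta[:] = null_fit.params.beta
    warm.beta_x[:] = null_fit.params.beta_x
    full_fit = fit(data, full_spec, start=warm)
    statistic = max(0.0, 2.0 * (full_fit.loglik - null_fit.loglik))
    df = full_spec.df_interaction
    p_value = float(stats.chi2.sf(statistic, df))
    return LRTResult(statistic, df, p_value, full_fit, null_fit)


def modifying_effect(
    fit_result: FitResult, x: np.ndarray, level: int = 1, conf: float = 0.95
) -> tuple[float, float, float]:
    """Multiplicative modification of the GRR by one unit of exposure at
    covariate value x: exp(beta_{g'E} + beta_{g'EX}' x), with a Wald CI.

    Under the additive model the single shared level is used regardless of
    ``level``.
    """
    if not fit_result.converged:
        raise RuntimeError("modifying effects require a converged fit")
    spec = fit_result.spec
    if not spec.with_interaction:
        raise ValueError("fit has no interaction terms")
    x = np.atleast_1d(np.asarray(x, float))
    if x.shape[0] != spec.k_covariates:
        raise ValueError("covariate vector length does not match the fit")
    l = 0 if spec.n_levels == 1 else int(level) - 1
    if l not in range(spec.n_levels):
        raise ValueError("level must be 1 or 2")
    d, K = spec.d_per_level, spec.k_covariates
    c = np.zeros(spec.n_params)
    c[l * d + 1 + K] = 1.0          # beta_e
    c[l * d + 2 + K: (l + 1) * d] = x   # beta_ex
    est_log = float(c @ fit_result.theta)
    se = float(np.sqrt(max(0.0, c @ fit_result.covariance @ c)))
    z = stats.norm.ppf(0.5 + conf / 2.0)
    return (
        float(np.exp(est_log)),
        float(np.exp(est_log - z * se)),
        float(np.exp(est_log + z * se)),
    )


def modifying_effect_table(
    fit_result: FitResult, contrasts: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Modifying-effect estimates with CIs at named covariate values, one row
    per (contrast, genotype level)."""
    rows = []
    for name, x in contrasts.items():
        for level in range(1, fit_result.spec.n_levels + 1):
            est, lo, hi = modifying_effect(fit_result, x, level=level)
            rows.append(
                {"contrast": name, "level": level,
                 "estimate": est, "lower95": lo, "upper95": hi}
            )
    return pd.DataFrame(rows)
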