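"""Variance-component heritability estimation for a binary trait.

The 0/1 case–control phenotype is analysed as quantitative on the observed
scale under the linear mixed model

    y ~ N(Xβ, σ_v² A + σ_e² I),

where A is a genomic relationship matrix. (σ_v², σ_e²) are estimated by
restricted maximum likelihood — one EM step from the initialisation
followed by average-information (AI) updates with step-halving — and the
observed-scale SNP heritability is h² = σ_v² / (σ_v² + σ_e²) with a
delta-method standard error from the inverse AI matrix.

Case–control ascertainment (sample case proportion P exceeding the
population prevalence K) inflates observed-scale h²; under the
liability-threshold model the estimate transforms to the liability scale
by the constant factor

    h²_liab = h²_obs · [K(1−K)/z²] · [K(1−K)/(P(1−P))],

with t = Φ⁻¹(1−K) the liability threshold and z = φ(t) the standard
normal density there. The SE transforms by the same factor.

Covariate models follow the convention of SNP-heritability studies of
admixed cohorts: Model 1 has no covariates (intercept only), Model 2 adds
ancestry PCs 1–4 from the GRM, Model 3 adds age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import norm

from .io_formats import GenotypeMatrix, KinshipMatrix
from .kinship import (
    LDWeights,
    compute_grm_gcta,
    compute_grm_ldak,
    compute_ld_weights,
    compute_pcs,
)

__all__ = [
    "ModelSpec",
    "RemlFit",
    "RemlError",
    "HeritabilityEstimate",
    "fit_reml",
    "h2_observed",
    "liability_factor",
    "estimate_h2",
    "MODEL1",
    "MODEL2",
    "MODEL3",
]

#: Variance-component floor, as a fraction of var(y).
_VC_FLOOR_FRAC = 1e-6
_MAX_ITER = 100
_LOGL_TOL = 1e-8
_PARAM_TOL = 1e-6


class RemlError(RuntimeError):
    """REML failed (non-PSD kinship, unidentifiable model, or no convergence)."""

    def __init__(self, message: str, trace: list[float] | None = None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class ModelSpec:
    """Named covariate model: which fixed effects accompany the GRM."""

    label: str
    covariates: tuple[str, ...]


MODEL1 = ModelSpec("model1", ("intercept",))
MODEL2 = ModelSpec("model2", ("intercept", "PC1", "PC2", "PC3", "PC4"))
MODEL3 = ModelSpec("model3", ("intercept", "PC1", "PC2", "PC3", "PC4", "age", "sex"))
MODELS = {"model1": MODEL1, "model2": MODEL2, "model3": MODEL3,
          "1": MODEL1, "2": MODEL2, "3": MODEL3}


@dataclass
class RemlFit:
    """REML solution: variance components, their covariance, and the trace."""

    sigma2_v: float
    sigma2_e: float
    vcov: np.ndarray
    loglik_trace: list[float] = field(repr=False, default_factory=list)
    converged: bool = False
    n_iter: int = 0
    at_boundary: bool = False
    n_samples: int = 0


@dataclass
class HeritabilityEstimate:
    """h² on the observed and liability scales with (K, P) provenance."""

    h2_obs: float
    se_obs: float
    h2_liab: float
    se_liab: float
    k_prevalence: float
    p_sample: float
    model: ModelSpec
    method_tag: str
    n_cases: int = 0
    n_controls: int = 0
    fit: RemlFit | None = field(repr=False, default=None)


def _reml_parts(d, yt, xt, sv, se):
    """Pieces of the restricted log-likelihood in the eigenbasis of A.

    d: eigenvalues of A; yt, xt: rotated phenotype/design.
    Returns (logL, Py, C_inv_factor, D) where Py is P·y in the eigenbasis.
    """
    big_d = sv * d + se
    if np.any(big_d <= 0):
        return None
    xd = xt / big_d[:, None]
    c = xt.T @ xd
    try:
        c_cho = scipy.linalg.cho_factor(c)
    except scipy.linalg.LinAlgError:
        return None
    yd = yt / big_d
    xty = xt.T @ yd
    beta = scipy.linalg.cho_solve(c_cho, xty)
    py = yd - xd @ beta
    sign, logdet_c = np.linalg.slogdet(c)
    if sign <= 0:
        return None
    logl = -0.5 * (np.sum(np.log(big_d)) + logdet_c + float(yt @ py))
    return logl, py, (xd, c_cho), big_d


def _apply_p(vec, big_d, proj):
    """P·v in the eigenbasis, given the cached projection pieces."""
    xd, c_cho = proj
    vd = vec / big_d
    return vd - xd @ scipy.linalg.cho_solve(c_cho, xd.T @ vec)


def fit_reml(
    k: KinshipMatrix,
    phenotype: np.ndarray,
    covariates: np.ndarray,
    max_iter: int = _MAX_ITER,
    eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> RemlFit:
    """AI-REML for y ~ N(Xβ, σ_v² A + σ_e² I).

    Starts from σ_v² = σ_e² = var(y)/2, takes one EM-REML step, then AI
    updates with step-halving so the restricted log-likelihood never
    decreases. Components are clamped to ≥ 1e-6·var(y) (boundary flagged).
    Convergence: relative logL change < 1e-8 and parameter change < 1e-6.
    """
    y = np.asarray(phenotype, dtype=np.float64)
    x = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n = y.shape[0]
    if k.n_samples != n or x.shape[0] != n:
        raise ValueError("kinship, phenotype and covariates are not aligned")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix is rank deficient")

    d, u = scipy.linalg.eigh(k.values) if eig is None else eig
    if d.min() < -1e-8:
        raise RemlError(f"kinship matrix not PSD (min eigenvalue {d.min():.3e})")
    d = np.maximum(d, 0.0)
    if np.ptp(d) < 1e-10 * max(1.0, d.max()):
        raise RemlError(
            "kinship matrix is (a multiple of) the identity: "
            "σ_v² and σ_e² are not separately identifiable"
        )
    yt = u.T @ y
    xt = u.T @ x

    var_y = float(np.var(y, ddof=1))
    floor = _VC_FLOOR_FRAC * var_y
    theta = np.array([var_y / 2.0, var_y / 2.0])

    parts = _reml_parts(d, yt, xt, *theta)
    if parts is None:
        raise RemlError("restricted likelihood undefined at initialisation")
    logl, py, proj, big_d = parts
    trace = [logl]

    def _score_ai(py, proj, big_d):
        u_v = d * py          # A·Py in eigenbasis
        u_e = py
        # traces tr(P·A), tr(P) via diag of P in eigenbasis
        xd, c_cho = proj
        # diag(P)_i = 1/D_i - x_i' C^{-1} x_i / D_i^2
        sol = scipy.linalg.cho_solve(c_cho, xd.T)   # p x n
        quad = np.einsum("ij,ji->i", xd, sol)
        diag_p = 1.0 / big_d - quad
        tr_pa = float(d @ diag_p)
        tr_p = float(diag_p.sum())
        score = np.array([
            -0.5 * (tr_pa - float(py @ u_v)),
            -0.5 * (tr_p - float(py @ u_e)),
        ])
        p_uv = _apply_p(u_v, big_d, proj)
        p_ue = _apply_p(u_e, big_d, proj)
        ai = 0.5 * np.array([
            [float(u_v @ p_uv), float(u_v @ p_ue)],
            [float(u_e @ p_uv), float(u_e @ p_ue)],
        ])
        return score, ai, (float(py @ u_v), float(py @ u_e), tr_pa, tr_p)

    converged = False
    n_iter = 0
    ai = np.eye(2)
    for it in range(max_iter):
        n_iter = it + 1
        score, ai, (ypapy, yppy, tr_pa, tr_p) = _score_ai(py, proj, big_d)
        if it == 0:
            # EM-REML step: globally stable from the initialisation
            new_theta = np.array([
                theta[0] + theta[0] ** 2 * (ypapy - tr_pa) / n,
                theta[1] + theta[1] ** 2 * (yppy - tr_p) / n,
            ])
            step = new_theta - theta
        else:
            # active set: a component clamped at the floor whose score points
            # further down stays fixed; the AI step is solved on the rest
            free = (theta > floor * (1 + 1e-9)) | (score > 0)
            if not free.any():
                converged = True
                break
            step = np.zeros(2)
            try:
                if free.all():
                    if np.linalg.cond(ai) > 1e12:
                        raise RemlError("AI matrix numerically singular",
                                        trace=trace)
                    step = np.linalg.solve(ai, score)
                else:
                    idx = np.flatnonzero(free)
                    sub = ai[np.ix_(idx, idx)]
                    step[idx] = np.linalg.solve(sub, score[idx])
            except np.linalg.LinAlgError as exc:
                raise RemlError("AI matrix singular (model unidentifiable)",
                                trace=trace) from exc

        # step-halving: never accept a decrease in the restricted logL
        accepted = None
        for _ in range(30):
            cand = np.maximum(theta + step, floor)
            parts = _reml_parts(d, yt, xt, *cand)
            if parts is not None and parts[0] >= logl - 1e-12:
                accepted = (cand, parts)
                break
            step *= 0.5
        if accepted is None:
            converged = True  # no uphill move remains
            break
        new_theta, (new_logl, py, proj, big_d) = accepted
        param_change = float(np.max(np.abs(new_theta - theta))) / max(var_y, 1e-30)
        rel_dl = abs(new_logl - logl) / max(abs(logl), 1.0)
        theta, logl = new_theta, new_logl
        trace.append(logl)
        if it > 0 and rel_dl < _LOGL_TOL and param_change < _PARAM_TOL:
            converged = True
            break

    if not converged:
        raise RemlError(f"AI-REML did not converge in {max_iter} iterations",
                        trace=trace)

    score, ai, _ = _score_ai(py, proj, big_d)
    try:
        vcov = np.linalg.inv(ai)
    except np.linalg.LinAlgError as exc:
        raise RemlError("AI matrix singular at optimum", trace=trace) from exc
    at_boundary = bool(np.any(theta <= floor * (1 + 1e-9)))
    return RemlFit(
        sigma2_v=float(theta[0]),
        sigma2_e=float(theta[1]),
        vcov=vcov,
        loglik_trace=trace,
        converged=True,
        n_iter=n_iter,
        at_boundary=at_boundary,
        n_samples=n,
    )


def h2_observed(fit: RemlFit) -> tuple[float, float]:
    """Observed-scale h² = σ_v²/(σ_v²+σ_e²) and its delta-method SE."""
    if not fit.converged:
        raise ValueError("REML fit did not converge")
    total = fit.sigma2_v + fit.sigma2_e
    if total <= 0:
        raise ValueError("total variance is zero")
    h2 = fit.sigma2_v / total
    grad = np.array([fit.sigma2_e, -fit.sigma2_v]) / total ** 2
    se = float(np.sqrt(grad @ fit.vcov @ grad))
    return float(h2), se


def liability_factor(K: float, P: float) -> float:
    """Observed→liability multiplier [K(1−K)/z²]·[K(1−K)/(P(1−P))].

    K is the population prevalence, P the sample case proportion, and
    z = φ(Φ⁻¹(1−K)) the normal density at the liability threshold.
    """
    if not (0.0 < K < 1.0):
        raise ValueError(f"prevalence K must be in (0, 1), got {K}")
    if not (0.0 < P < 1.0):
        raise ValueError(f"case proportion P must be in (0, 1), got {P}")
    t = norm.isf(K)
    z = norm.pdf(t)
    return float(K * (1 - K) / z ** 2 * (K * (1 - K)) / (P * (1 - P)))


def _design_matrix(
    model: ModelSpec,
    n: int,
    pcs: np.ndarray | None,
    covar: pd.DataFrame | None,
    sample_keys: list[tuple[str, str]],
) -> np.ndarray:
    cols = [np.ones(n)]
    for name in model.covariates:
        if name == "intercept":
            continue
        if name.startswith("PC"):
            if pcs is None:
                raise ValueError(f"{model.label} requires ancestry PCs")
            idx = int(name[2:]) - 1
            cols.append(pcs[:, idx])
        else:
            if covar is None or name not in {c.lower() for c in covar.columns}:
                raise ValueError(
                    f"{model.label} requires covariate {name!r}; not found in table"
                )
            colname = next(c for c in covar.columns if c.lower() == name)
            lookup = {(f, i): v for f, i, v in
                      zip(covar["FID"], covar["IID"], covar[colname])}
            try:
                vals = np.array([lookup[key] for key in sample_keys], dtype=np.float64)
            except KeyError as exc:
                raise ValueError(f"covariate table missing sample {exc.args[0]}") from exc
            if np.any(np.isnan(vals)):
                raise ValueError(f"covariate {name!r} has missing values")
            cols.append(vals)
    return np.column_stack(cols)


def estimate_h2(
    g: GenotypeMatrix,
    phenotype: np.ndarray,
    covariate_table: pd.DataFrame | None,
    model: ModelSpec | str,
    method: str,
    K: float,
    ld_weights: LDWeights | None = None,
    alpha: float = -0.25,
    ld_window: int = 50,
    grm: KinshipMatrix | None = None,
    pcs: np.ndarray | None = None,
) -> HeritabilityEstimate:
    """End-to-end estimate for one (method, model) cell.

    Builds the requested GRM (unless a precomputed one is supplied),
    computes ancestry PCs from the allele-sharing GRM when the model needs
    them, fits REML, and reports observed- and liability-scale h² with the
    sample case proportion P taken from the analysed sample. Inputs are
    expected to be QC'd and relatedness-pruned.
    """
    if isinstance(model, str):
        model = MODELS[model]
    if method not in ("gcta", "ldak"):
        raise ValueError(f"method must be 'gcta' or 'ldak', got {method!r}")
    y = np.asarray(phenotype, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("phenotype must be coded 0/1")

    if grm is None:
        if method == "gcta":
            grm = compute_grm_gcta(g)
        else:
            if ld_weights is None:
                ld_weights = compute_ld_weights(g, window_size=ld_window, alpha=alpha)
            grm = compute_grm_ldak(g, ld_weights)

    needs_pcs = any(c.startswith("PC") for c in model.covariates)
    if needs_pcs and pcs is None:
        base = grm if grm.method_tag == "gcta" else compute_grm_gcta(g)
        pcs = compute_pcs(base, n_components=4).components

    x = _design_matrix(model, len(y), pcs, covariate_table,
                       [s.key for s in g.samples] if g is not None else grm.sample_ids)
    fit = fit_reml(grm, y, x)
    h2o, seo = h2_observed(fit)
    n_cases = int(np.sum(y == 1))
    n_controls = int(np.sum(y == 0))
    p_sample = n_cases / len(y)
    factor = liability_factor(K, p_sample)
    return HeritabilityEstimate(
        h2_obs=h2o,
        se_obs=seo,
        h2_liab=h2o * factor,
        se_liab=seo * factor,
        k_prevalence=K,
        p_sample=p_sample,
        model=model,
        method_tag=method,
        n_cases=n_cases,
        n_controls=n_controls,
        fit=fit,
    )
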