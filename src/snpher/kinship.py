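"""Genomic relationship matrices, LD weights, relatedness pruning, and PCs.

Two GRM constructions are provided:

* the allele-sharing GRM of GREML analyses,
  ``A_ij = (1/m) Σ_k (x_ik − 2p_k)(x_jk − 2p_k) / (2 p_k (1 − p_k))``,
  which standardizes each variant to unit variance (the α = −1 convention,
  equal expected heritability per variant regardless of MAF); and

* an LD-weighted GRM in which variant j contributes proportionally to
  ``[2 f_j (1 − f_j)]^(1+α) · ϖ_j · r_j`` relative to the unit-variance
  baseline, where ϖ_j is a local-LD weight (small in high-LD regions, ≈1
  for variants tagging nothing else), r_j ∈ [0,1] an imputation-certainty
  info score, and α the assumed MAF–heritability scaling (−0.25 default
  for the LD-weighted model). The GRM is normalized by the sum of
  effective weights so the expected diagonal is 1; with unit weights,
  unit info and α = −1 it reduces exactly to the allele-sharing GRM.

Missing genotypes are mean-imputed to 2p_k before standardization (the
practical behaviour of the GREML ecosystem; keeps the GRM positive
semidefinite); strict pairwise deletion is available via a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .io_formats import MISSING, GenotypeMatrix, KinshipMatrix

__all__ = [
    "LDWeights",
    "PCResult",
    "compute_grm_gcta",
    "compute_ld_weights",
    "compute_grm_ldak",
    "prune_related",
    "compute_pcs",
]

#: Relatedness threshold above which one member of a pair is removed.
DEFAULT_RELATEDNESS_CUTOFF = 0.025

#: Tikhonov ridge added to each window's NNLS system; ties (e.g. perfect LD)
#: resolve to the minimum-norm non-negative solution.
_NNLS_RIDGE = 1e-6


@dataclass
class LDWeights:
    """Per-variant LD weights ϖ_j with info scores and MAF-scaling exponent."""

    weights: np.ndarray
    alpha: float
    info_scores: np.ndarray
    window_size: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.info_scores = np.asarray(self.info_scores, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("LD weights must be finite and non-negative")
        if not np.any(self.weights > 0):
            raise ValueError("at least one LD weight must be positive")
        if np.any(self.info_scores < 0) or np.any(self.info_scores > 1):
            raise ValueError("info scores must lie in [0, 1]")

    @classmethod
    def unit(cls, m: int, alpha: float = -1.0) -> "LDWeights":
        """Unit weights and info scores (the GRM-equivalence limit at α=−1)."""
        return cls(weights=np.ones(m), alpha=alpha, info_scores=np.ones(m), window_size=0)


@dataclass
class PCResult:
    """Ancestry principal components: n×k sample scores and eigenvalues."""

    components: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")


def _standardized(g: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Z mean-imputed standardized, observed mask, counted-allele freq p)."""
    d = g.dosages
    obs = d != MISSING
    p = g.allele_frequencies()
    if np.any(np.isnan(p)) or np.any((p <= 0) | (p >= 1)):
        bad = [g.variants[j].id for j in
               np.flatnonzero(np.isnan(p) | (p <= 0) | (p >= 1))[:5]]
        raise ValueError(f"monomorphic or all-missing variants present (e.g. {bad}); run QC first")
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (np.where(obs, d, 0).astype(np.float64) - 2.0 * p) / denom
    z[~obs] = 0.0  # mean imputation: zero contribution after centering
    return z, obs, p


def compute_grm_gcta(g: GenotypeMatrix, pairwise_missing: bool = False) -> KinshipMatrix:
    """Allele-sharing GRM from standardized genotypes.

    With ``pairwise_missing=False`` (default) missing calls are mean-imputed
    and every pair is normalized by the full variant count m; with
    ``pairwise_missing=True`` each pair is normalized by the number of
    variants non-missing in both members (classical pairwise deletion,
    not guaranteed positive semidefinite).
    """
    z, obs, _ = _standardized(g)
    m = g.m_variants
    if pairwise_missing:
        counts = obs.astype(np.float64) @ obs.T.astype(np.float64)
        if np.any(counts == 0):
            i, j = np.argwhere(counts == 0)[0]
            raise ValueError(
                f"samples ({g.samples[i].fid},{g.samples[i].iid}) and "
                f"({g.samples[j].fid},{g.samples[j].iid}) share no non-missing variants"
            )
        values = (z @ z.T) / counts
    else:
        counts = np.full((g.n_samples, g.n_samples), float(m))
        values = (z @ z.T) / m
    values = (values + values.T) / 2.0
    return KinshipMatrix(
        values=values,
        sample_ids=[s.key for s in g.samples],
        n_variants_used=counts,
        method_tag="gcta",
    )


def compute_ld_weights(
    g: GenotypeMatrix, window_size: int, alpha: float = -0.25
) -> LDWeights:
    """Solve for non-negative per-variant LD weights ϖ_j.

    Within sliding windows of ``window_size`` variants the weights minimise
    ``Σ_j (Σ_k r²_jk ϖ_k − 1)²`` subject to ϖ ≥ 0, where r² is the squared
    genotype correlation; overlapping window solutions are averaged. An
    isolated variant gets weight ≈ 1, a set of mutually redundant variants
    shares weight (two in perfect LD get ½ each), so per-variant expected
    tagged signal is equalised across LD regimes.
    """
    if window_size < 2:
        raise ValueError(f"window_size must be >= 2, got {window_size}")
    z, _, _ = _standardized(g)
    m = g.m_variants
    # correlation of mean-imputed standardized dosages
    zc = z - z.mean(axis=0)
    sd = zc.std(axis=0)
    sd[sd == 0] = 1.0
    zc /= sd

    w = min(window_size, m)
    stride = max(1, w // 2)
    starts = list(range(0, max(m - w, 0) + 1, stride))
    if starts[-1] != m - w:
        starts.append(m - w)

    acc = np.zeros(m)
    cnt = np.zeros(m)
    n = g.n_samples
    ridge = np.sqrt(_NNLS_RIDGE) * np.eye(w)
    target = np.concatenate([np.ones(w), np.zeros(w)])
    for s in starts:
        block = zc[:, s:s + w]
        r2 = (block.T @ block / n) ** 2
        np.fill_diagonal(r2, 1.0)
        sol, _ = scipy.optimize.nnls(np.vstack([r2, ridge]), target)
        acc[s:s + w] += sol
        cnt[s:s + w] += 1.0
    weights = acc / cnt
    return LDWeights(
        weights=weights,
        alpha=alpha,
        info_scores=np.array([v.info_score for v in g.variants], dtype=np.float64),
        window_size=window_size,
    )


def compute_grm_ldak(g: GenotypeMatrix, w: LDWeights) -> KinshipMatrix:
    """LD-weighted GRM: Z diag(s) Z' / Σ s with effective weight
    ``s_j = [2 p_j (1 − p_j)]^(1+α) · ϖ_j · r_j`` on unit-variance
    standardized genotypes Z (so the expected diagonal is 1)."""
    if len(w.weights) != g.m_variants or len(w.info_scores) != g.m_variants:
        raise ValueError("LD weights not aligned with variants")
    z, _, p = _standardized(g)
    het = 2.0 * p * (1.0 - p)
    s = het ** (1.0 + w.alpha) * w.weights * w.info_scores
    s_sum = s.sum()
    if s_sum <= 0:
        raise ValueError("all effective LDAK weights are zero")
    values = (z * s) @ z.T / s_sum
    values = (values + values.T) / 2.0
    n = g.n_samples
    return KinshipMatrix(
        values=values,
        sample_ids=[s_.key for s_ in g.samples],
        n_variants_used=np.full((n, n), float(np.count_nonzero(s))),
        method_tag="ldak",
    )


def prune_related(
    k: KinshipMatrix, cutoff: float = DEFAULT_RELATEDNESS_CUTOFF
) -> np.ndarray:
    """Greedy relatedness pruning: indices of samples retained.

    While any retained off-diagonal relatedness exceeds ``cutoff`` (strict),
    remove the sample involved in the most violating pairs (ties broken by
    lower sample index). Exactly one member of each isolated pair is removed.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be > 0, got {cutoff}")
    a = k.values.copy()
    np.fill_diagonal(a, -np.inf)
    viol = a > cutoff
    alive = np.ones(k.n_samples, dtype=bool)
    while True:
        deg = (viol & alive[None, :] & alive[:, None]).sum(axis=1)
        deg[~alive] = 0
        if deg.max() == 0:
            break
        alive[int(np.argmax(deg))] = False
    return np.flatnonzero(alive)


def compute_pcs(k: KinshipMatrix, n_components: int = 4) -> PCResult:
    """Top principal components of the double-centered kinship matrix.

    Scores are eigenvectors scaled by √eigenvalue; the sign convention
    (largest-magnitude loading positive) makes repeated runs bit-identical.
    """
    n = k.n_samples
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds n={n}")
    a = k.values
    row_mean = a.mean(axis=0)
    b = a - row_mean[None, :] - row_mean[:, None] + row_mean.mean()
    evals, evecs = scipy.linalg.eigh(b)  # ascending, deterministic dense solver
    order = np.argsort(evals, kind="stable")[::-1][:n_components]
    evals = evals[order]
    evecs = evecs[:, order]
    scores = evecs * np.sqrt(np.maximum(evals, 0.0))[None, :]
    for c in range(scores.shape[1]):
        col = scores[:, c] if np.any(scores[:, c]) else evecs[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, c] *= -1.0
            evecs[:, c] *= -1.0
    return PCResult(components=scores, eigenvalues=evals)
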