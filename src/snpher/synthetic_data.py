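"""Synthetic admixed case–control cohorts with known truth.

The generator emulates the statistical structure of the admixed
case–control cohorts this pipeline targets, with every quantity the
pipeline later estimates known by construction:

* two-way admixture: each sample draws an ancestry fraction
  q ~ Beta(a, b); subpopulation allele frequencies follow the
  Balding–Nichols model, Beta with mean π_j and variance
  Fst·π_j(1−π_j) around an ancestral frequency π_j;
* LD in blocks: haplotype alleles follow a first-order Markov chain with
  correlation ``ld_rho`` between adjacent variants inside a block, blocks
  independent;
* a liability-threshold phenotype: standardized effects at ``n_causal``
  variants plus Gaussian noise; case iff liability exceeds Φ⁻¹(1−K);
* case ascertainment: all cases kept (controls subsampled) until the
  retained sample hits the target case proportion P;
* optional age/sex/ancestry shifts on the liability so covariate and
  structure adjustment can be exercised.

All randomness derives from one seed via named substreams, so a fixed
seed reproduces the cohort bit-for-bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import GenotypeMatrix, SampleInfo, VariantInfo

__all__ = [
    "CohortConfig",
    "TruthRecord",
    "AscertainmentError",
    "simulate_ancestral_freqs",
    "simulate_genotypes",
    "simulate_liability_phenotype",
    "ascertain_cases",
    "match_by_decile",
    "generate_cohort",
    "covariate_frame",
]

logger = logging.getLogger(__name__)

_SUBSTREAMS = ("freqs", "genotypes", "phenotype", "ascertainment", "matching")


class AscertainmentError(ValueError):
    """Not enough cases (or controls) to reach the target case proportion."""

    def __init__(self, message: str, max_feasible_n: int):
        super().__init__(message)
        self.max_feasible_n = max_feasible_n


@dataclass
class CohortConfig:
    """Generation parameters; defaults are the package's reference study
    conditions (a two-way admixed cohort of 2,000 at case proportion 0.50
    ascertained from prevalence 0.125, polygenic liability h² = 0.25)."""

    n_samples: int = 2000
    m_variants: int = 5000
    #: None -> one causal variant per 10 (500 at the reference m of 5000)
    n_causal: int | None = None
    h2_liability_true: float = 0.25
    prevalence_k: float = 0.125
    case_proportion_p: float = 0.50
    fst: float = 0.1
    admixture_beta: tuple[float, float] = (8.0, 2.0)
    ld_block_size: int = 20
    ld_rho: float = 0.7
    maf_floor: float = 0.05
    seed: int = 0
    #: standardized-liability shift per SD of age / for female sex / per SD
    #: of ancestry fraction; all zero by default (no confounding).
    age_liability_beta: float = 0.0
    sex_liability_beta: float = 0.0
    ancestry_liability_beta: float = 0.0
    age_mean: float = 60.0
    age_sd: float = 10.0

    def __post_init__(self) -> None:
        if self.n_causal is None:
            self.n_causal = max(1, self.m_variants // 10)
        if not (0 <= self.n_causal <= self.m_variants):
            raise ValueError("n_causal must be in [0, m_variants]")
        if not (0.0 <= self.h2_liability_true < 1.0):
            raise ValueError("h2_liability_true must be in [0, 1)")
        for name in ("prevalence_k", "case_proportion_p"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")
        if not (0.0 <= self.fst < 1.0):
            raise ValueError("fst must be in [0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in (0, 0.5)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")

    def substream(self, name: str) -> np.random.Generator:
        """Named, independent RNG substream derived from the master seed."""
        if name not in _SUBSTREAMS:
            raise ValueError(f"unknown substream {name!r}")
        idx = _SUBSTREAMS.index(name)
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(idx,)))
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthRecord:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    causal_ids: list[str]
    effect_sizes: np.ndarray
    ancestry_proportions: np.ndarray
    liabilities: np.ndarray
    h2_realized: float
    realized_prevalence: float = float("nan")
    realized_case_proportion: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"causal_id": self.causal_ids,
                             "effect_size": self.effect_sizes})


def simulate_ancestral_freqs(
    cfg: CohortConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Balding–Nichols subpopulation frequencies (p1, p2) per variant.

    Ancestral π_j ~ Uniform(maf_floor, 1−maf_floor); each subpopulation
    draws Beta(π(1−Fst)/Fst, (1−π)(1−Fst)/Fst), i.e. mean π and variance
    Fst·π(1−π); results clipped to [0.01, 0.99]. Fst = 0 degenerates to
    p1 = p2 = π.
    """
    rng = cfg.substream("freqs") if rng is None else rng
    m = cfg.m_variants
    pi = rng.uniform(cfg.maf_floor, 1.0 - cfg.maf_floor, size=m)
    if cfg.fst == 0.0:
        p1 = pi.copy()
        p2 = pi.copy()
    else:
        a = pi * (1.0 - cfg.fst) / cfg.fst
        b = (1.0 - pi) * (1.0 - cfg.fst) / cfg.fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    return np.clip(p1, 0.01, 0.99), np.clip(p2, 0.01, 0.99)


def simulate_genotypes(
    cfg: CohortConfig,
    freqs: tuple[np.ndarray, np.ndarray],
    rng: np.random.Generator | None = None,
    n_samples: int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw admixed genotypes with block-Markov LD.

    Each sample has ancestry fraction q ~ Beta(admixture_beta) and two
    haplotypes; within an LD block the allele at variant j is Bernoulli
    with the sample's mixed frequency f_j = q·p1_j + (1−q)·p2_j,
    correlated ``ld_rho`` with the allele at variant j−1; blocks are
    independent. Dosage is the haplotype sum (no missingness).
    """
    rng = cfg.substream("genotypes") if rng is None else rng
    n = cfg.n_samples if n_samples is None else n_samples
    p1, p2 = freqs
    m = p1.shape[0]
    a, b = cfg.admixture_beta
    q = rng.beta(a, b, size=n)

    # All blocks share the same Markov structure, so the chain runs over the
    # ld_block_size within-block positions with every block advanced at once
    # (arrays of shape n x n_blocks); variant j lives in block j // bs at
    # within-block offset j % bs.
    bs = cfg.ld_block_size
    n_blocks = (m + bs - 1) // bs
    m_pad = n_blocks * bs
    pp1 = np.full(m_pad, 0.5)
    pp2 = np.full(m_pad, 0.5)
    pp1[:m], pp2[:m] = p1, p2
    pp1 = pp1.reshape(n_blocks, bs)
    pp2 = pp2.reshape(n_blocks, bs)

    rho = cfg.ld_rho
    dosages = np.zeros((n, n_blocks, bs), dtype=np.int8)
    hap_prev = [np.empty((n, n_blocks)), np.empty((n, n_blocks))]
    f_prev = np.empty((n, n_blocks))
    for t in range(bs):
        f_t = q[:, None] * pp1[None, :, t] + (1.0 - q[:, None]) * pp2[None, :, t]
        if t == 0 or rho == 0.0:
            scale_dev = None
        else:
            # cap the pairwise correlation so both conditional probabilities
            # stay in [0,1]; the marginal frequency is then preserved exactly
            s = np.sqrt(f_t * (1.0 - f_t) / (f_prev * (1.0 - f_prev)))
            r_eff = np.minimum(rho, (1.0 - f_t) / (s * (1.0 - f_prev)))
            r_eff = np.minimum(r_eff, f_t / (s * f_prev))
            scale_dev = r_eff * s
        for h in range(2):
            if scale_dev is None:
                prob = f_t
            else:
                prob = f_t + scale_dev * (hap_prev[h] - f_prev)
            allele = rng.random((n, n_blocks)) < prob
            hap_prev[h] = allele.astype(np.float64)
            dosages[:, :, t] += allele
        f_prev = f_t
    dosages = dosages.reshape(n, m_pad)[:, :m]

    variants = [
        VariantInfo(chrom="1", pos=j + 1, id=f"snp{j + 1}", allele_a1="A", allele_a2="C")
        for j in range(m)
    ]
    samples = [SampleInfo(fid=f"F{i + 1}", iid=f"I{i + 1}") for i in range(n)]
    return GenotypeMatrix(dosages=dosages, samples=samples, variants=variants), q


def simulate_liability_phenotype(
    g: GenotypeMatrix,
    cfg: CohortConfig,
    ancestry: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, TruthRecord]:
    """Liability-threshold phenotype with known genetic architecture.

    ``n_causal`` variants are chosen uniformly; effects on standardized
    dosages are drawn N(0, h²/n_causal) and the genetic values rescaled so
    their sample variance equals h² exactly; environmental noise is
    N(0, 1−h²). Optional age/sex/ancestry terms shift the liability.
    Case iff liability > Φ⁻¹(1−K). Also fills age and sex on the samples.
    """
    rng = cfg.substream("phenotype") if rng is None else rng
    n, m = g.n_samples, g.m_variants
    h2 = cfg.h2_liability_true

    causal_idx = np.sort(rng.choice(m, size=cfg.n_causal, replace=False))
    betas = (rng.normal(0.0, np.sqrt(h2 / max(cfg.n_causal, 1)), size=cfg.n_causal)
             if h2 > 0 else np.zeros(cfg.n_causal))

    if h2 > 0 and cfg.n_causal > 0:
        d = g.dosages[:, causal_idx].astype(np.float64)
        mu = d.mean(axis=0)
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        z = (d - mu) / sd
        genetic = z @ betas
        gv = genetic.var()
        if gv > 0:
            rescale = np.sqrt(h2 / gv)
            genetic *= rescale
            betas = betas * rescale
    else:
        genetic = np.zeros(n)

    env = rng.normal(0.0, np.sqrt(1.0 - h2), size=n)

    age = rng.normal(cfg.age_mean, cfg.age_sd, size=n)
    sex = rng.integers(1, 3, size=n)  # 1=male, 2=female
    liability = genetic + env
    liability += cfg.age_liability_beta * (age - cfg.age_mean) / cfg.age_sd
    liability += cfg.sex_liability_beta * (sex - 1.5)
    if cfg.ancestry_liability_beta != 0.0:
        if ancestry is None:
            raise ValueError("ancestry_liability_beta set but no ancestry given")
        qc_ = (ancestry - ancestry.mean()) / max(ancestry.std(), 1e-12)
        liability += cfg.ancestry_liability_beta * qc_

    threshold = norm.isf(cfg.prevalence_k)
    phenotypes = (liability > threshold).astype(np.int8)
    for i, s in enumerate(g.samples):
        s.age = float(age[i])
        s.sex = int(sex[i])
        s.phenotype = int(phenotypes[i])

    lv = liability.var()
    truth = TruthRecord(
        causal_ids=[g.variants[j].id for j in causal_idx],
        effect_sizes=betas,
        ancestry_proportions=(ancestry if ancestry is not None else np.full(n, np.nan)),
        liabilities=liability,
        h2_realized=float(genetic.var() / lv) if lv > 0 else 0.0,
        realized_prevalence=float(phenotypes.mean()),
    )
    return phenotypes, truth


def ascertain_cases(
    phenotypes: np.ndarray,
    cfg: CohortConfig,
    rng: np.random.Generator | None = None,
    n_retained: int | None = None,
) -> tuple[np.ndarray, float]:
    """Case-enriched subsample hitting the target case proportion P.

    Cases are kept (subsampled only if a smaller ``n_retained`` demands it)
    and controls are randomly subsampled so the retained sample has case
    proportion P (±1 sample). Returns (sorted indices, realized P).
    """
    rng = cfg.substream("ascertainment") if rng is None else rng
    p = cfg.case_proportion_p
    phenotypes = np.asarray(phenotypes)
    case_idx = np.flatnonzero(phenotypes == 1)
    ctrl_idx = np.flatnonzero(phenotypes == 0)

    if n_retained is None:
        n_cases_keep = len(case_idx)
        n_ctrl_keep = round(n_cases_keep * (1.0 - p) / p)
    else:
        n_cases_keep = round(n_retained * p)
        n_ctrl_keep = n_retained - n_cases_keep
    if n_cases_keep > len(case_idx):
        max_n = int(len(case_idx) / p)
        raise AscertainmentError(
            f"need {n_cases_keep} cases but only {len(case_idx)} available; "
            f"maximum feasible n at P={p} is {max_n}", max_feasible_n=max_n)
    if n_ctrl_keep > len(ctrl_idx):
        max_n = int(len(ctrl_idx) / (1.0 - p))
        raise AscertainmentError(
            f"need {n_ctrl_keep} controls but only {len(ctrl_idx)} available; "
            f"maximum feasible n at P={p} is {max_n}", max_feasible_n=max_n)

    keep_cases = (case_idx if n_cases_keep == len(case_idx)
                  else rng.choice(case_idx, size=n_cases_keep, replace=False))
    keep_ctrls = (ctrl_idx if n_ctrl_keep == len(ctrl_idx)
                  else rng.choice(ctrl_idx, size=n_ctrl_keep, replace=False))
    keep = np.sort(np.concatenate([keep_cases, keep_ctrls]))
    realized_p = n_cases_keep / (n_cases_keep + n_ctrl_keep)
    return keep, float(realized_p)


def match_by_decile(
    samples: list[SampleInfo],
    age_range: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Age-decile case/control matching: indices of retained samples.

    Samples outside ``age_range`` are excluded, age deciles are computed on
    the retained pooled sample, and within each decile both classes are
    randomly downsampled to min(n_cases, n_controls). A decile with zero
    of one class contributes no samples (warning logged).
    """
    rng = np.random.default_rng(0) if rng is None else rng
    lo, hi = age_range
    ages = np.array([s.age if s.age is not None else np.nan for s in samples])
    if np.any(np.isnan(ages)):
        raise ValueError("all samples must have an age for decile matching")
    status = np.array([s.phenotype for s in samples])
    in_range = (ages >= lo) & (ages <= hi)
    pool = np.flatnonzero(in_range)

    edges = np.quantile(ages[pool], np.linspace(0.0, 1.0, 11))
    edges[-1] = np.nextafter(edges[-1], np.inf)
    decile = np.digitize(ages[pool], edges[1:-1])

    kept: list[np.ndarray] = []
    for dec in range(10):
        members = pool[decile == dec]
        cases = members[status[members] == 1]
        ctrls = members[status[members] == 0]
        k = min(len(cases), len(ctrls))
        if k == 0:
            if len(cases) or len(ctrls):
                logger.warning(
                    "age decile %d has %d cases / %d controls; dropped",
                    dec + 1, len(cases), len(ctrls))
            continue
        keep_c = cases if len(cases) == k else rng.choice(cases, size=k, replace=False)
        keep_t = ctrls if len(ctrls) == k else rng.choice(ctrls, size=k, replace=False)
        kept.append(np.concatenate([keep_c, keep_t]))
    if not kept:
        return np.array([], dtype=int)
    return np.sort(np.concatenate(kept))


def covariate_frame(g: GenotypeMatrix) -> pd.DataFrame:
    """FID/IID-keyed age+sex covariate table for the samples of *g*."""
    return pd.DataFrame({
        "FID": [s.fid for s in g.samples],
        "IID": [s.iid for s in g.samples],
        "age": [s.age for s in g.samples],
        "sex": [float(s.sex) for s in g.samples],
    })


def generate_cohort(
    cfg: CohortConfig,
    ascertain: bool = True,
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame, TruthRecord]:
    """Full generation: super-population → phenotype → ascertained cohort.

    Simulates a super-population large enough that ascertainment to
    ``cfg.n_samples`` at case proportion P from prevalence K succeeds with
    margin, then returns (genotypes, 0/1 phenotypes, covariate table,
    truth). With ``ascertain=False`` the first ``n_samples`` draws are
    returned unascertained (a population sample).
    """
    k, p = cfg.prevalence_k, cfg.case_proportion_p
    if ascertain:
        n_super = int(np.ceil(cfg.n_samples * max(p / k, (1 - p) / (1 - k)) * 1.3))
        n_super = max(n_super, cfg.n_samples)
    else:
        n_super = cfg.n_samples

    freqs = simulate_ancestral_freqs(cfg)
    g, q = simulate_genotypes(cfg, freqs, n_samples=n_super)
    phenotypes, truth = simulate_liability_phenotype(g, cfg, ancestry=q)

    if ascertain:
        keep, realized_p = ascertain_cases(phenotypes, cfg, n_retained=cfg.n_samples)
        g = g.subset(sample_idx=keep)
        phenotypes = phenotypes[keep]
        truth.ancestry_proportions = truth.ancestry_proportions[keep]
        truth.liabilities = truth.liabilities[keep]
        truth.realized_case_proportion = realized_p
    else:
        truth.realized_case_proportion = float(np.mean(phenotypes))
    return g, phenotypes.astype(np.int8), covariate_frame(g), truth
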