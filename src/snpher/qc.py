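"""Variant-level quality control and cross-cohort variant harmonization.

Filters follow array-QC convention for admixed case–control cohorts:
autosomal, biallelic, per-variant missing rate ≤ 10%, MAF ≥ 5% (strict
``MAF < threshold`` removal), and a Hardy–Weinberg exact test at a
cohort-specific p-value threshold (1e-5 or 1e-12 are the usual choices).
Filters are applied in a fixed declared order so removal counts are
deterministic; each variant is charged to the first filter it fails.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

__all__ = [
    "QCConfig",
    "QCReport",
    "QCError",
    "hwe_exact_test",
    "filter_variants",
    "intersect_variants",
]

logger = logging.getLogger(__name__)

#: Filter application order; QCReport counts follow it.
FILTER_ORDER = ("autosome", "biallelic", "missing_rate", "maf", "hwe")

_AUTOSOMES = {str(c) for c in range(1, 23)}
_AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})


class QCError(ValueError):
    """QC could not produce a usable variant set."""

    def __init__(self, message: str, report: "QCReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class QCConfig:
    """Thresholds for variant-level QC.

    ``maf_min`` and ``missing_max`` default to the 5% / 10% array-QC
    convention; ``hwe_p_min`` is cohort-specific (1e-5 default, 1e-12 for
    very large imputed cohorts). ``hwe_controls_only`` restricts the HWE
    test to controls when case status is available.
    """

    maf_min: float = 0.05
    missing_max: float = 0.10
    hwe_p_min: float = 1e-5
    autosomes_only: bool = True
    biallelic_only: bool = True
    hwe_controls_only: bool = False

    def __post_init__(self) -> None:
        for name in ("maf_min", "missing_max", "hwe_p_min"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass
class QCReport:
    """Per-filter removal accounting; totals are conserved."""

    n_input_variants: int
    n_removed_by_filter: dict[str, int]
    n_output_variants: int
    fail_flags: list[str | None] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        total_removed = sum(self.n_removed_by_filter.values())
        if self.n_input_variants != self.n_output_variants + total_removed:
            raise ValueError("QCReport counts do not conserve totals")

    def to_text(self) -> str:
        lines = ["filter\tn_removed"]
        lines += [f"{name}\t{n}" for name, n in self.n_removed_by_filter.items()]
        lines.append(f"input\t{self.n_input_variants}")
        lines.append(f"output\t{self.n_output_variants}")
        return "\n".join(lines) + "\n"


def hwe_exact_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Two-sided Hardy–Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote configuration whose conditional probability does not
    exceed that of the observed one. Monomorphic input returns 1.0.
    """
    if min(n_hom_minor, n_het, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        raise ValueError("total genotype count must be > 0")
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # counts given with major/minor swapped; symmetric test
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
        n_minor = 2 * n_hom_minor + n_het
    if n_minor == 0:
        return 1.0

    # log P(het = h | allele counts) up to a shared constant
    lf = math.lgamma
    hets = range(n_minor % 2, n_minor + 1, 2)
    logps = []
    for h in hets:
        hom_r = (n_minor - h) // 2
        hom_c = n - hom_r - h
        if hom_c < 0:
            continue
        logps.append(
            h * math.log(2.0)
            - lf(hom_r + 1) - lf(h + 1) - lf(hom_c + 1)
        )
    logps = np.array(logps)
    logps -= logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    obs_idx = (n_het - n_minor % 2) // 2
    p_obs = probs[obs_idx]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-variant (hom-a1, het, hom-a2) counts over non-missing calls."""
    n2 = (dosages == 2).sum(axis=0)
    n1 = (dosages == 1).sum(axis=0)
    n0 = (dosages == 0).sum(axis=0)
    return n2, n1, n0


def filter_variants(g: GenotypeMatrix, cfg: QCConfig) -> tuple[GenotypeMatrix, QCReport]:
    """Apply variant filters in the fixed order autosome → biallelic →
    missing-rate → MAF → HWE; the sample set is unchanged.

    MAF is computed on non-missing calls; removal thresholds follow the
    conventional strict inequalities (removed iff MAF < maf_min, missing
    rate > missing_max, or HWE p < hwe_p_min).
    """
    m = g.m_variants
    fail: list[str | None] = [None] * m
    removed = {name: 0 for name in FILTER_ORDER}
    d = g.dosages
    obs = d != MISSING

    if cfg.hwe_controls_only:
        ctrl = np.array([s.phenotype == 0 for s in g.samples])
        d_hwe = d[ctrl] if ctrl.any() else d
    else:
        d_hwe = d

    miss_rate = 1.0 - obs.sum(axis=0) / g.n_samples
    freqs = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freqs, 1.0 - freqs)

    n2, n1, n0 = _genotype_counts(d_hwe)

    for j, v in enumerate(g.variants):
        if cfg.autosomes_only and v.chrom not in _AUTOSOMES:
            fail[j] = "autosome"
        elif cfg.biallelic_only and (
            v.allele_a1 in ("0", ".") or v.allele_a2 in ("0", ".")
        ):
            fail[j] = "biallelic"
        elif miss_rate[j] > cfg.missing_max:
            fail[j] = "missing_rate"
        elif np.isnan(maf[j]) or maf[j] < cfg.maf_min:
            fail[j] = "maf"
        elif hwe_exact_test(int(n2[j]), int(n1[j]), int(n0[j])) < cfg.hwe_p_min:
            fail[j] = "hwe"
        if fail[j] is not None:
            removed[fail[j]] += 1

    keep = [j for j in range(m) if fail[j] is None]
    report = QCReport(
        n_input_variants=m,
        n_removed_by_filter=removed,
        n_output_variants=len(keep),
        fail_flags=fail,
    )
    if not keep:
        raise QCError("no variants survive QC", report=report)

    out = g.subset(variant_idx=keep)
    freqs_out = out.allele_frequencies()
    for j, v in enumerate(out.variants):
        v.freq_a1 = float(freqs_out[j])
    return out, report


def intersect_variants(cohorts: list[GenotypeMatrix]) -> list[GenotypeMatrix]:
    """Harmonize ≥2 cohorts to their shared variants.

    Variant identity is (chrom, pos, unordered allele pair). The counted
    allele is aligned to the first cohort's allele-1 by flipping dosages
    d → 2−d where orientation differs. Strand-ambiguous A/T or C/G pairs
    whose counted-allele frequencies disagree by more than 0.2 across any
    cohort pair are excluded with a warning. Output variant order is the
    first cohort's order, identical across cohorts.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to intersect")

    keymaps: list[dict] = []
    for c_idx, g in enumerate(cohorts):
        km: dict = {}
        for j, v in enumerate(g.variants):
            if v.key in km:
                raise ValueError(
                    f"cohort {c_idx}: duplicate variant key {v.key} "
                    f"(ids {g.variants[km[v.key]].id!r}, {v.id!r})"
                )
            km[v.key] = j
        keymaps.append(km)

    shared = [k for k in keymaps[0] if all(k in km for km in keymaps[1:])]

    ref = cohorts[0]
    freqs = [g.allele_frequencies() for g in cohorts]
    kept_keys = []
    for key in shared:
        j0 = keymaps[0][key]
        v0 = ref.variants[j0]
        pair = {v0.allele_a1, v0.allele_a2}
        if pair in _AMBIGUOUS_PAIRS:
            f_aligned = []
            for km, g, fq in zip(keymaps, cohorts, freqs):
                j = km[key]
                f = fq[j]
                if g.variants[j].allele_a1 != v0.allele_a1:
                    f = 1.0 - f
                f_aligned.append(f)
            if np.nanmax(f_aligned) - np.nanmin(f_aligned) > 0.2:
                logger.warning(
                    "excluding strand-ambiguous variant %s (%s/%s): "
                    "aligned frequencies %s differ by > 0.2",
                    v0.id, v0.allele_a1, v0.allele_a2,
                    [round(float(f), 3) for f in f_aligned],
                )
                continue
        kept_keys.append(key)

    out: list[GenotypeMatrix] = []
    for km, g in zip(keymaps, cohorts):
        idx = [km[key] for key in kept_keys]
        sub = g.subset(variant_idx=idx)
        for j, key in enumerate(kept_keys):
            v_ref = ref.variants[keymaps[0][key]]
            v = sub.variants[j]
            if v.allele_a1 != v_ref.allele_a1:
                col = sub.dosages[:, j]
                nonmiss = col != MISSING
                col[nonmiss] = 2 - col[nonmiss]
                v.allele_a1, v.allele_a2 = v.allele_a2, v.allele_a1
                if v.freq_a1 is not None:
                    v.freq_a1 = 1.0 - v.freq_a1
        out.append(sub)
    return out
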