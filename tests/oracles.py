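"""Independent brute-force / closed-form oracles used by the test suite.

Each oracle is written from the definition of the quantity it checks and
shares no code path with the implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hwe_pvalue_exact(n_hom_minor: int, n_het: int, n_hom_major: int) -> Fraction:
    """HWE exact p by full enumeration with exact rational arithmetic.

    P(het = h | allele counts) = C(n, r) C(n−r, h) 2^h / C(2n, nA) with
    r = (nA − h)/2 homozygotes for the rarer allele; the two-sided p-value
    sums the probabilities of configurations no more probable than observed.
    """
    n = n_hom_minor + n_het + n_hom_major
    na = 2 * n_hom_minor + n_het
    if na > n:
        na = 2 * n - na
    if na == 0:
        return Fraction(1)
    denom = math.comb(2 * n, na)
    probs = {}
    for h in range(na % 2, na + 1, 2):
        r = (na - h) // 2
        probs[h] = Fraction(math.comb(n, r) * math.comb(n - r, h) * 2 ** h, denom)
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs)


def grm_entry(x: np.ndarray, freqs: np.ndarray, i: int, j: int) -> float:
    """Naive per-pair allele-sharing GRM entry (double loop over variants)."""
    total = 0.0
    m = 0
    for k in range(x.shape[1]):
        p = freqs[k]
        if x[i, k] < 0 or x[j, k] < 0:
            continue
        total += (x[i, k] - 2 * p) * (x[j, k] - 2 * p) / (2 * p * (1 - p))
        m += 1
    return total / m


def grm_naive(x: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Full naive GRM with mean imputation (missing contributes 0, /m)."""
    n, m = x.shape
    a = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            total = 0.0
            for k in range(m):
                p = freqs[k]
                xi = x[i, k]
                xj = x[j, k]
                zi = 0.0 if xi < 0 else (xi - 2 * p) / math.sqrt(2 * p * (1 - p))
                zj = 0.0 if xj < 0 else (xj - 2 * p) / math.sqrt(2 * p * (1 - p))
                total += zi * zj
            a[i, j] = a[j, i] = total / m
    return a


def reml_loglik(sigma_v: float, sigma_e: float, a: np.ndarray, y: np.ndarray,
                x: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ N(Xβ, σv A + σe I), dense formula."""
    n = len(y)
    v = sigma_v * a + sigma_e * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(v)
    if sign <= 0:
        return -np.inf
    vi = np.linalg.inv(v)
    xtvx = x.T @ vi @ x
    sign2, logdet_x = np.linalg.slogdet(xtvx)
    if sign2 <= 0:
        return -np.inf
    beta = np.linalg.solve(xtvx, x.T @ vi @ y)
    r = y - x @ beta
    return -0.5 * (logdet_v + logdet_x + float(r @ vi @ r))


# --- standard normal quantile, rational approximation + Halley refinement ---

_ACKLAM_A = [-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
             1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00]
_ACKLAM_B = [-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
             6.680131188771972e+01, -1.328068155288572e+01]
_ACKLAM_C = [-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
             -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00]
_ACKLAM_D = [7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
             3.754408661907416e+00]


def _erf_series(x: float) -> float:
    """erf by its Maclaurin series (converges fast for |x| ≲ 3)."""
    total = 0.0
    term = x
    k = 0
    while abs(term) > 1e-18 * max(1.0, abs(total)):
        total += term / (2 * k + 1)
        k += 1
        term *= -x * x / k
    return 2.0 / math.sqrt(math.pi) * total


def _phi_cdf(x: float) -> float:
    return 0.5 * (1.0 + _erf_series(x / math.sqrt(2.0)))


def norm_quantile(p: float) -> float:
    """Φ⁻¹(p): Acklam's rational approximation plus one Halley step."""
    a, b, c, d = _ACKLAM_A, _ACKLAM_B, _ACKLAM_C, _ACKLAM_D
    p_low, p_high = 0.02425, 1 - 0.02425
    if p < p_low:
        q = math.sqrt(-2 * math.log(p))
        x = ((((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5])
             / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1))
    elif p <= p_high:
        q = p - 0.5
        r = q * q
        x = ((((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q
             / (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1))
    else:
        q = math.sqrt(-2 * math.log(1 - p))
        x = -((((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5])
              / ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1))
    # one Halley refinement using the series-based CDF
    e = _phi_cdf(x) - p
    u = e * math.sqrt(2 * math.pi) * math.exp(x * x / 2.0)
    return x - u / (1.0 + x * u / 2.0)


def liability_factor_oracle(k: float, p: float) -> float:
    t = norm_quantile(1.0 - k)
    z = math.exp(-t * t / 2.0) / math.sqrt(2.0 * math.pi)
    return k * (1 - k) / z ** 2 * (k * (1 - k)) / (p * (1 - p))


def max_independent_set_size(adj: np.ndarray) -> int:
    """Exact maximum independent set size by subset enumeration (n ≤ ~16)."""
    n = adj.shape[0]
    nbr = [int(sum(1 << j for j in range(n) if adj[i, j] and j != i))
           for i in range(n)]
    best = 0
    for mask in range(1 << n):
        if mask.bit_count() <= best:
            continue
        ok = True
        mm = mask
        while mm:
            i = (mm & -mm).bit_length() - 1
            if nbr[i] & mask:
                ok = False
                break
            mm &= mm - 1
        if ok:
            best = mask.bit_count()
    return best
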