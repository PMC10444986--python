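"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, for the studentized range,
the library routines) they are used to check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm


def shannon_loop(proportions) -> float:
    """H' by explicit loop over -p ln p terms."""
    h = 0.0
    for p in proportions:
        if p > 0:
            h -= p * math.log(p)
    return h


def studentized_range_sf(q: float, k: int, df: int, n_outer: int = 240,
                         n_inner: int = 240) -> float:
    """P(Q >= q) for the studentized range by direct double quadrature.

    Uses the classical representation

        P(Q < q) = ∫ f_s(s) · k ∫ φ(z) [Φ(z) − Φ(z − q·s)]^{k−1} dz ds

    with s = S/σ following a chi/√df law, evaluated on Gauss–Legendre grids.
    Independent of scipy.stats.studentized_range.
    """
    if q <= 0:
        return 1.0
    # outer grid over s: the chi/sqrt(df) density is concentrated near 1
    s_hi = 1.0 + 10.0 / math.sqrt(df)
    xs, ws = np.polynomial.legendre.leggauss(n_outer)
    s = 0.5 * s_hi * (xs + 1.0)
    w_s = 0.5 * s_hi * ws
    log_c = (df / 2.0) * math.log(df) - gammaln(df / 2.0) - (df / 2.0 - 1.0) * math.log(2.0)
    f_s = np.exp(log_c + (df - 1.0) * np.log(s) - df * s * s / 2.0)

    zs, wz = np.polynomial.legendre.leggauss(n_inner)
    z_lo, z_hi = -9.0, 9.0
    z = 0.5 * (z_hi - z_lo) * (zs + 1.0) + z_lo
    w_z = 0.5 * (z_hi - z_lo) * wz

    phi_z = norm.pdf(z)
    cdf_z = norm.cdf(z)
    # inner[j] = k ∫ φ(z) (Φ(z) − Φ(z − q s_j))^{k−1} dz  for each outer node
    inner = np.empty_like(s)
    for j, sj in enumerate(s):
        diff = cdf_z - norm.cdf(z - q * sj)
        inner[j] = k * np.sum(w_z * phi_z * np.power(diff, k - 1))
    cdf = float(np.sum(w_s * f_s * inner))
    return min(max(1.0 - cdf, 0.0), 1.0)


def tukey_pairwise_oracle(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Adjusted Tukey p-values computed from first principles."""
    names = sorted(groups)
    k = len(names)
    n_total = sum(len(v) for v in groups.values())
    df = n_total - k
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = math.sqrt(mse / 2.0 * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            q = abs(groups[a].mean() - groups[b].mean()) / se if se > 0 else math.inf
            out[(a, b)] = studentized_range_sf(q, k, df) if math.isfinite(q) else 0.0
    return out
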