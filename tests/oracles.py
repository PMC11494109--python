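"""Independent reference computations used to check the implementation.

These deliberately use different routes than the library: an exact Fourier
series for rectangular-duct flow, O(n²) pair counting for Kendall's tau-b,
and closed-form probability results.
"""

from __future__ import annotations

import math

import numpy as np


def duct_wall_shear_rate(flow_rate_ul_min: float, width_um: float,
                         height_um: float, n_terms: int = 400) -> float:
    """Exact wall shear rate (1/s) at the centre of the wide wall of a
    rectangular duct, from the Fourier-series Poiseuille solution.

    Geometry: height 2a across y, width 2b across z, b >= a. For pressure
    gradient G the velocity is

        u(y, z) = (16 a² G / (mu pi³)) * sum_{n odd} (-1)^((n-1)/2)
                  [1 - cosh(n pi z / 2a)/cosh(n pi b / 2a)] cos(n pi y / 2a)/n³

    giving Q = (4 b a³ G / 3 mu) [1 - (192 a / pi⁵ b) sum tanh(n pi b/2a)/n⁵]
    and wall shear rate at (y=a, z=0)

        gamma = (8 a G / mu pi²) * sum_{n odd} [1 - sech(n pi b / 2a)] / n².
    """
    q = flow_rate_ul_min * 1e-9 / 60.0  # m³/s
    a = height_um * 1e-6 / 2.0
    b = width_um * 1e-6 / 2.0
    s_q = 0.0
    s_g = 0.0
    for i in range(n_terms):
        n = 2 * i + 1
        arg = n * math.pi * b / (2.0 * a)
        if arg > 350.0:  # tanh -> 1, sech -> 0 beyond double-precision range
            s_q += 1.0 / n**5
            s_g += 1.0 / n**2
        else:
            s_q += math.tanh(arg) / n**5
            s_g += (1.0 - 1.0 / math.cosh(arg)) / n**2
    q_per_g_over_mu = (4.0 * b * a**3 / 3.0) * (1.0 - (192.0 * a / (math.pi**5 * b)) * s_q)
    g_over_mu = q / q_per_g_over_mu  # G / mu, 1/(m s)
    return (8.0 * a / math.pi**2) * g_over_mu * s_g


def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b by exhaustive concordant/discordant pair counting."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = x.size
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    n0 = n * (n - 1) // 2
    ties_x = _tie_pairs(x)
    ties_y = _tie_pairs(y)
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return math.nan
    return (concordant - discordant) / denom


def _tie_pairs(v) -> int:
    _, counts = np.unique(v, return_counts=True)
    return int(sum(c * (c - 1) // 2 for c in counts))


def catch_slip_peak_force(k_c0: float, f_c: float, k_s0: float, f_s: float) -> float:
    """Analytic minimiser of k(F) = k_c0 e^(-F/f_c) + k_s0 e^(F/f_s)."""
    return math.log(k_c0 * f_s / (k_s0 * f_c)) / (1.0 / f_c + 1.0 / f_s)
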