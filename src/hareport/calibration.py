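"""Statistical calibration checks for the estimators in this package.

These routines measure, by seeded simulation, properties the estimators
should have: the kernel home-range area should converge to the analytic
95% region of a known utilisation distribution as the number of
relocations grows, and the Kruskal–Wallis test should hold its nominal
type-I error under the null.
"""

from __future__ import annotations

import numpy as np

from .home_range import contour_home_range, href_bandwidth, kernel_ud
from .rank_stats import kruskal_wallis

#: chi-square 0.95 quantile with 2 df — the analytic 95% region of an
#: isotropic bivariate normal has area pi * sigma^2 * this
CHI2_2DF_95 = 5.991464547107979


def analytic_95_area_ha(sigma_m: float) -> float:
    return np.pi * sigma_m**2 * CHI2_2DF_95 / 1e4


def kud_recovery_curve(
    seed: int,
    sigma_m: float = 100.0,
    ns: tuple[int, ...] = (200, 1000, 5000),
    reps: tuple[int, ...] = (80, 40, 10),
) -> dict:
    """Mean 95% KUD area and relative error vs sample size.

    Draws ``reps[i]`` independent samples of ``ns[i]`` relocations from an
    isotropic bivariate normal (sd ``sigma_m``), estimates each 95% kernel
    home range with the reference bandwidth, and averages the areas. The
    relative error of the mean area against the analytic region shrinks
    with n (the kernel's h² inflation fades as h_ref → 0).
    """
    target = analytic_95_area_ha(sigma_m)
    mean_areas, rel_errors = [], []
    for n, r in zip(ns, reps):
        areas = []
        for i in range(r):
            rng = np.random.default_rng([seed, n, i])
            pts = rng.normal(0.0, sigma_m, size=(n, 2))
            hr = contour_home_range(kernel_ud(pts, href_bandwidth(pts)), 0.95)
            areas.append(hr.area_ha)
        mean_areas.append(float(np.mean(areas)))
        rel_errors.append(abs(mean_areas[-1] - target) / target)
    return {
        "ns": list(ns),
        "analytic_area_ha": target,
        "mean_areas_ha": mean_areas,
        "relative_errors": rel_errors,
    }


def kw_type_i_error(
    seed: int,
    n_sims: int = 2000,
    k: int = 3,
    n_per_group: int = 15,
    alpha: float = 0.05,
) -> float:
    """Empirical rejection rate of Kruskal–Wallis under the null.

    All groups iid standard normal; the fraction of simulations with
    p < alpha estimates the achieved type-I error.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = rng.standard_normal((k, n_per_group))
        if kruskal_wallis(list(groups)).p < alpha:
            rejections += 1
    return rejections / n_sims
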