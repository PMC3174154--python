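"""Monomer-dimer equilibrium model for concentration-dependent size data.

For total monomer-equivalent concentration ``c = [M] + 2[D]`` and
dissociation constant ``K_D = [M]^2 / [D]`` the free-monomer concentration
has the closed form

    [M] = (-K_D + sqrt(K_D^2 + 8 K_D c)) / 4,

and the observed hydrodynamic radius is modelled as the weight-fraction
average  R_s(c) = f_M R_M + (1 - f_M) R_D  with f_M = [M]/c.  Fitting is
ordinary least squares over (K_D, R_M, R_D) with a deterministic multi-start
over log-spaced K_D initialisations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Isotherm", "EquilibriumFit", "monomer_fraction", "predicted_rs", "fit_kd"]


@dataclass
class Isotherm:
    """Concentration series (uM, monomer-equivalent) with observed radii."""

    c_total: np.ndarray
    rs_observed: np.ndarray
    noise_sd: float | None = None

    def __post_init__(self) -> None:
        self.c_total = np.asarray(self.c_total, dtype=float)
        self.rs_observed = np.asarray(self.rs_observed, dtype=float)
        if self.c_total.shape != self.rs_observed.shape or self.c_total.ndim != 1:
            raise ValueError("c_total and rs_observed must be matching 1-d arrays")
        if np.any(self.c_total <= 0) or np.any(self.rs_observed <= 0):
            raise ValueError("concentrations and radii must be positive")


def monomer_fraction(c_total, k_d):
    """Weight fraction of monomer at total concentration ``c_total``.

    Both arguments in the same concentration unit; scalar or array.
    """
    c = np.asarray(c_total, dtype=float)
    if np.any(c <= 0) or k_d <= 0:
        raise ValueError("c_total and k_d must be positive")
    m = (-k_d + np.sqrt(k_d * k_d + 8.0 * k_d * c)) / 4.0
    frac = m / c
    return float(frac) if np.isscalar(c_total) else frac


def predicted_rs(c_total, k_d, rs_m, rs_d):
    """Weight-average hydrodynamic radius under the monomer-dimer model."""
    if rs_m <= 0 or rs_d <= 0:
        raise ValueError("radii must be positive")
    f = monomer_fraction(c_total, k_d)
    return f * rs_m + (1.0 - f) * rs_d


@dataclass
class EquilibriumFit:
    k_d: float
    rs_monomer: float
    rs_dimer: float
    residual_sse: float
    converged: bool

    def predict(self, c_total):
        return predicted_rs(c_total, self.k_d, self.rs_monomer, self.rs_dimer)


def fit_kd(
    isotherm: Isotherm,
    n_starts: int = 5,
    kd_bounds: tuple[float, float] = (1e-6, 1e6),
) -> EquilibriumFit:
    """Least-squares fit of (K_D, R_M, R_D) to an isotherm.

    K_D is optimised on a log scale; ``n_starts`` initial values are spaced
    log-uniformly over the observed concentration range (extended one decade
    each way), which makes the fit deterministic with no RNG.  A flat
    isotherm is flagged non-identifiable via ``converged=False``.
    """
    c = isotherm.c_total
    rs = isotherm.rs_observed
    if len(c) < 4:
        raise ValueError("need at least 4 points")
    if c.max() / c.min() < 10.0:
        raise ValueError("concentrations must span at least 10-fold")
    span = rs.max() - rs.min()
    scale = max(span, 1e-12)

    def residuals(theta):
        log_kd, rs_m, rs_d = theta
        return predicted_rs(c, math.exp(log_kd), rs_m, rs_d) - rs

    lo = np.log(max(kd_bounds[0], c.min() / 10.0))
    hi = np.log(min(kd_bounds[1], c.max() * 10.0))
    starts = np.linspace(lo, hi, n_starts)
    # endpoint guesses: low-c plateau ~ monomer, high-c plateau ~ dimer
    order = np.argsort(c)
    rs_m0 = float(rs[order[:2]].mean())
    rs_d0 = float(rs[order[-2:]].mean())

    best = None
    for s in starts:
        try:
            res = least_squares(
                residuals,
                x0=[s, rs_m0, rs_d0],
                bounds=([math.log(kd_bounds[0]), 1e-9, 1e-9],
                        [math.log(kd_bounds[1]), np.inf, np.inf]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
        except ValueError:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        raise RuntimeError("all fit starts failed")
    sse, res = best
    log_kd, rs_m, rs_d = res.x
    # enforce the monomer < dimer ordering of the reported endpoints
    if rs_d < rs_m:
        rs_m, rs_d = rs_d, rs_m
    identifiable = span > 1e-9 * max(abs(rs).max(), 1.0)
    return EquilibriumFit(
        k_d=float(math.exp(log_kd)),
        rs_monomer=float(rs_m),
        rs_dimer=float(rs_d),
        residual_sse=sse,
        converged=bool(res.success and identifiable),
    )
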