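"""Ripple-driven pore-water exchange in permeable sediments.

Converts tidal bed stress into an advective enhancement of the within-bed
diffusivity through a chain of closed forms:

1. log-law near-bed reference velocity ``U`` from the bed stress,
2. ripple pressure difference ``dP = a1 rho U^2 (h/L)``,
3. Darcy pore-water velocity ``w0 = k dP / (rho nu L)``,
4. advective diffusivity ``K_adv = a2 w0 min(h, D1)``,
5. effective diffusivity ``K_eff = (K0 + K_adv) I_bio``.

The enhancement applies only within the oxic (top) layer of the bed; deeper
layers keep ``K0 * I_bio``. Setting the permeability to zero recovers the
unmodified (muddy) model exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import VON_KARMAN


@dataclass(frozen=True)
class RippleGeometry:
    """Ripple and roughness geometry. ``z0`` defaults to h/7."""

    h: float = 0.03            # ripple height, m
    L_ripple: float = 0.2      # ripple wavelength, m
    z0: float | None = None    # bed roughness length, m; default h/7
    z_r: float = 0.1           # reference height for U, m

    def __post_init__(self) -> None:
        if not (0.0 < self.h < self.L_ripple):
            raise ValueError("need 0 < ripple height < wavelength")
        z0 = self.h / 7.0 if self.z0 is None else self.z0
        object.__setattr__(self, "z0", z0)
        if not (0.0 < z0 < self.z_r):
            raise ValueError("need 0 < z0 < z_r")


@dataclass(frozen=True)
class PermeableParams:
    """Constants of the exchange chain.

    ``log_law_form`` selects how the von Karman constant enters the
    reference-velocity law: ``"divide"`` (standard log law, the default) or
    ``"multiply"`` (kappa as a plain multiplier), retained as a sensitivity
    switch.
    """

    k_perm: float = 5.0e-11    # permeability, m^2
    a1: float = 1.0            # empirical pressure constant
    a2: float = 4.0            # diffusivity scaling constant
    rho: float = 1010.0        # water density, kg m^-3
    nu: float = 1.0e-6         # kinematic viscosity, m^2 s^-1
    kappa: float = VON_KARMAN
    log_law_form: str = "divide"

    def __post_init__(self) -> None:
        for name in ("a1", "a2", "rho", "nu", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_perm < 0:
            raise ValueError("permeability must be >= 0")
        if self.log_law_form not in ("divide", "multiply"):
            raise ValueError("log_law_form must be 'divide' or 'multiply'")


@dataclass(frozen=True)
class ExchangeCoefficients:
    """One evaluation of the exchange chain with its intermediate quantities."""

    U: float          # near-bed reference velocity, m s^-1
    deltaP: float     # ripple pressure difference, Pa
    w0: float         # Darcy pore-water velocity, m s^-1
    K_adv: float      # advective diffusivity, m^2 s^-1
    K0: float         # background (molecular) diffusivity, m^2 s^-1
    I_bio: float      # bio-irrigation factor, dimensionless
    K_eff: float      # effective oxic-layer diffusivity, m^2 s^-1


def log_law_velocity(
    tau_b: float, geom: RippleGeometry, params: PermeableParams
) -> float:
    """Near-bed reference velocity from bed stress via the log law.

    ``U = (u*/kappa) ln(z_r/z0)`` with ``u* = sqrt(tau_b/rho)``.
    """
    tau_b = np.asarray(tau_b, dtype=float)
    if np.any(tau_b < 0):
        raise ValueError("bed stress must be >= 0")
    u_star = np.sqrt(tau_b / params.rho)
    log_term = np.log(geom.z_r / geom.z0)
    if params.log_law_form == "divide":
        u = u_star / params.kappa * log_term
    else:
        u = u_star * params.kappa * log_term
    return float(u) if np.isscalar(tau_b) or tau_b.ndim == 0 else u


def ripple_pressure(U, geom: RippleGeometry, params: PermeableParams):
    """Pressure difference across a ripple: ``dP = a1 rho U^2 (h/L)``."""
    U = np.asarray(U, dtype=float)
    dp = params.a1 * params.rho * U**2 * (geom.h / geom.L_ripple)
    return float(dp) if dp.ndim == 0 else dp


def darcy_velocity(deltaP, geom: RippleGeometry, params: PermeableParams):
    """Darcy pore-water velocity: ``w0 = k dP / (rho nu L)``."""
    deltaP = np.asarray(deltaP, dtype=float)
    w0 = params.k_perm * deltaP / (params.rho * params.nu * geom.L_ripple)
    return float(w0) if w0.ndim == 0 else w0


def advective_diffusivity(w0, D1, geom: RippleGeometry, params: PermeableParams):
    """``K_adv = a2 w0 min(h, D1)``: velocity scale times a length scale.

    The length scale is the lesser of the ripple height and the oxic-layer
    depth, since pore-water flow only ventilates to about a ripple height.
    """
    w0 = np.asarray(w0, dtype=float)
    length = np.minimum(geom.h, np.asarray(D1, dtype=float))
    k_adv = params.a2 * w0 * length
    return float(k_adv) if k_adv.ndim == 0 else k_adv


def effective_diffusivity(K0, K_adv, I_bio):
    """``K_eff = (K0 + K_adv) I_bio``."""
    k = (np.asarray(K0, float) + np.asarray(K_adv, float)) * np.asarray(I_bio, float)
    return float(k) if k.ndim == 0 else k


def exchange_from_stress(
    tau_b: float,
    D1: float,
    K0: float,
    I_bio: float,
    geom: RippleGeometry | None = None,
    params: PermeableParams | None = None,
) -> ExchangeCoefficients:
    """Evaluate the full chain stress -> U -> dP -> w0 -> K_adv -> K_eff."""
    geom = geom or RippleGeometry()
    params = params or PermeableParams()
    u = log_law_velocity(tau_b, geom, params)
    dp = ripple_pressure(u, geom, params)
    w0 = darcy_velocity(dp, geom, params)
    k_adv = advective_diffusivity(w0, D1, geom, params)
    k_eff = effective_diffusivity(K0, k_adv, I_bio)
    return ExchangeCoefficients(
        U=u, deltaP=dp, w0=w0, K_adv=k_adv, K0=K0, I_bio=I_bio, K_eff=k_eff
    )


def exchange_table(
    tau_series: np.ndarray,
    D1: float,
    K0: float,
    I_bio: float,
    geom: RippleGeometry | None = None,
    params: PermeableParams | None = None,
):
    """Vectorised chain over a stress series; returns a DataFrame.

    Columns carry units in their names; used by the standalone CLI.
    """
    import pandas as pd

    geom = geom or RippleGeometry()
    params = params or PermeableParams()
    tau = np.asarray(tau_series, dtype=float)
    u = log_law_velocity(tau, geom, params)
    dp = ripple_pressure(u, geom, params)
    w0 = darcy_velocity(dp, geom, params)
    k_adv = advective_diffusivity(w0, D1, geom, params)
    k_eff = effective_diffusivity(K0, k_adv, I_bio)
    return pd.DataFrame(
        {
            "bed_stress_Pa": tau,
            "U_m_s-1": u,
            "deltaP_Pa": dp,
            "w0_m_s-1": w0,
            "K_adv_m2_s-1": k_adv,
            "K_eff_m2_s-1": k_eff,
        }
    )
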