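"""First-order POM mass-balance box model and its budget analyses.

A single stock ``Q`` (g C m^-2) receives an input flux ``p(t)``
(g C m^-2 yr^-1) and loses mass by first-order remineralisation
``l = lambda Q``. Time is in YEARS throughout this module; a helper
converts to the simulator's day unit.

The integrator is the exponential (exact) step for piecewise-constant
input, so the trajectory matches the analytic solution for constant
forcing to machine precision and annual budgets close exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import DAYS_PER_YEAR


class StepSizeError(RuntimeError):
    pass


@dataclass
class BoxTrajectory:
    """Output of :func:`simulate_box`: stock and loss-rate series."""

    time: np.ndarray      # years, length n+1 (includes t=0)
    Q: np.ndarray         # g C m^-2, stock at the time points
    p: np.ndarray         # g C m^-2 yr^-1, input over each step (length n)
    l: np.ndarray         # g C m^-2 yr^-1, instantaneous loss lambda*Q at time points
    lambda_rate: float
    dt: float


@dataclass
class AnnualBudget:
    """Per-year integrals of the box model: ``deltaQ = P - L`` exactly."""

    year: int
    P: float        # annual input, g C m^-2 yr^-1
    L: float        # annual loss
    deltaQ: float   # annual stock change
    near_equilibrium: bool


def days_to_years(t_days: np.ndarray) -> np.ndarray:
    """Convert the simulator's day axis to this module's year unit."""
    return np.asarray(t_days, float) / DAYS_PER_YEAR


def simulate_box(
    p_series: np.ndarray, lambda_rate: float, Q0: float, dt: float
) -> BoxTrajectory:
    """Integrate ``dQ/dt = p - lambda Q`` with the exponential step.

    ``p_series`` holds the (piecewise-constant) input over each step of
    length ``dt`` years. The step
    ``Q_{n+1} = Q_n e^{-lambda dt} + p_n (1 - e^{-lambda dt})/lambda``
    is exact, so no discretisation error enters the trajectory.
    """
    if lambda_rate < 0 or Q0 < 0 or dt <= 0:
        raise ValueError("need lambda >= 0, Q0 >= 0, dt > 0")
    if lambda_rate * dt >= 0.5:
        raise StepSizeError(
            f"lambda*dt = {lambda_rate * dt:.3g} >= 0.5; reduce dt"
        )
    p = np.asarray(p_series, dtype=float)
    n = len(p)
    q = np.empty(n + 1)
    q[0] = Q0
    lam = lambda_rate
    if lam > 0:
        decay = np.exp(-lam * dt)
        gain = (1.0 - decay) / lam
        for i in range(n):
            q[i + 1] = q[i] * decay + p[i] * gain
    else:
        for i in range(n):
            q[i + 1] = q[i] + p[i] * dt
    time = np.arange(n + 1) * dt
    return BoxTrajectory(time=time, Q=q, p=p, l=lam * q, lambda_rate=lam, dt=dt)


def analytic_constant_forcing(
    t: np.ndarray, p: float, lambda_rate: float, Q0: float
) -> np.ndarray:
    """Closed form ``Q(t) = P/lambda + (Q0 - P/lambda) e^{-lambda t}``."""
    t = np.asarray(t, float)
    if lambda_rate == 0:
        return Q0 + p * t
    q_eq = p / lambda_rate
    return q_eq + (Q0 - q_eq) * np.exp(-lambda_rate * t)


def annual_budget(
    traj: BoxTrajectory, equilibrium_tolerance: float = 0.05
) -> list[AnnualBudget]:
    """Per-year input, loss and stock change; ``deltaQ = P - L`` by construction.

    ``L`` is diagnosed from the budget closure (P minus the stock change),
    which for the exact integrator equals the true integral of
    ``lambda Q(t)`` over the year. Partial trailing years are an error.
    """
    steps_per_year = round(1.0 / traj.dt)
    if abs(steps_per_year * traj.dt - 1.0) > 1e-9:
        raise ValueError("dt must divide one year evenly")
    n = len(traj.p)
    if n == 0 or n % steps_per_year != 0:
        raise ValueError("series must cover whole years")
    budgets = []
    for y in range(n // steps_per_year):
        lo, hi = y * steps_per_year, (y + 1) * steps_per_year
        P = float(traj.p[lo:hi].sum() * traj.dt)
        dq = float(traj.Q[hi] - traj.Q[lo])
        L = P - dq
        near = bool(P > 0 and abs(dq) / P < equilibrium_tolerance)
        budgets.append(AnnualBudget(year=y, P=P, L=L, deltaQ=dq, near_equilibrium=near))
    return budgets


def seasonal_response(
    lambda_rate: float,
    mean_input: float = 20.0,
    rel_amplitude: float = 0.5,
    dt: float = 1.0 / 3650.0,
) -> tuple[float, float]:
    """Measured gain and phase lag of ``l`` relative to a sinusoidal ``p``.

    Drives the box with ``p = P0 (1 + a cos(2 pi t))`` (one-year period),
    starts on the periodic attractor, and fits sinusoids to one full cycle.
    For a first-order filter the gain is ``lambda / sqrt(lambda^2 + w^2)``
    with ``w = 2 pi yr^-1``; phase lag is ``atan(w / lambda)``. Small
    discretisation residue only, since the integrator is exact per step.

    Returns ``(amplitude_ratio, phase_lag_radians)``.
    """
    if lambda_rate <= 0:
        raise ValueError("lambda must be > 0 to define a response")
    omega = 2.0 * np.pi
    n = round(1.0 / dt)
    t_mid = (np.arange(n) + 0.5) * dt
    p = mean_input * (1.0 + rel_amplitude * np.cos(omega * t_mid))
    # analytic periodic initial condition so no spin-up is needed
    amp = mean_input * rel_amplitude / np.hypot(lambda_rate, omega)
    phase = np.arctan2(omega, lambda_rate)
    q0 = mean_input / lambda_rate + amp * np.cos(-phase)
    traj = simulate_box(p, lambda_rate, q0, dt)
    t = traj.time[:-1]

    def _fit(series: np.ndarray, tt: np.ndarray) -> tuple[float, float]:
        basis = np.column_stack(
            [np.ones_like(tt), np.cos(omega * tt), np.sin(omega * tt)]
        )
        coef, *_ = np.linalg.lstsq(basis, series, rcond=None)
        # series = A cos(w t - phi) -> coef = (mean, A cos(phi), A sin(phi))
        return float(np.hypot(coef[1], coef[2])), float(np.arctan2(coef[2], coef[1]))

    amp_l, ph_l = _fit(traj.l[:-1], t)
    amp_p, ph_p = _fit(p, t_mid)
    gain = amp_l / amp_p
    lag = (ph_l - ph_p) % (2.0 * np.pi)
    if lag > np.pi:
        lag -= 2.0 * np.pi
    return gain, float(lag)


def first_order_gain(lambda_rate: float, omega: float = 2.0 * np.pi) -> float:
    """Closed-form filter gain ``lambda / sqrt(lambda^2 + omega^2)``."""
    return lambda_rate / np.hypot(lambda_rate, omega)


def fit_lambda(Q_series: np.ndarray, l_series: np.ndarray) -> float:
    """Least-squares slope of ``l`` on ``Q`` through the origin.

    Recovers the turnover rate from paired stock/loss series; degenerate
    (identically-zero) stocks raise.
    """
    q = np.asarray(Q_series, float)
    l = np.asarray(l_series, float)
    if q.shape != l.shape or q.size < 2:
        raise ValueError("need matched series of length >= 2")
    denom = float(np.dot(q, q))
    if denom == 0.0:
        raise ValueError("stock series is identically zero")
    return float(np.dot(q, l) / denom)


def burial_accumulation_time(target_stock: float, burial_rate: float) -> float:
    """Years to accumulate ``target_stock`` at a constant burial rate.

    Linear accumulation of an inert pool: ``years = stock / rate``.
    """
    if burial_rate <= 0:
        raise ValueError("burial rate must be > 0")
    if target_stock < 0:
        raise ValueError("target stock must be >= 0")
    return target_stock / burial_rate
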