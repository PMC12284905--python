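"""Deterministic companion models: coupled infection-frequency recursions and
closed-form persistence thresholds for sex-allocation distortion.

The recursions track the infection frequency among females (f) and males (m)
across discrete, non-overlapping host generations in an infinite population.
One generation corresponds to 11 days of the individual-based model,
following *T. urticae* developmental biology.

Rescue scope.  With imperfect transmission, an infected mother lays a
fraction mu of uninfected eggs.  Under the default ``female_level`` scope
these eggs are protected from CI by their mother's infection; under
``egg_level`` they are exposed to CI whenever the sperm is infected.  The
female-level recursion has the fixed point f* = 0.9813 under the Beis
parameters (complete CI, mu = 1.8%) and reduces exactly to the
sigma_total = 0 fixed-point relation used for the Sd threshold algebra.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RecursionState",
    "RecursionParams",
    "recursion_step",
    "iterate_recursions",
    "days_to_generations",
    "sd_threshold",
    "stable_infection_freq",
    "invasion_surface_recursion",
    "GENERATION_DAYS",
]

GENERATION_DAYS = 11


@dataclass(frozen=True)
class RecursionState:
    """Female (f) and male (m) infection frequencies at one generation."""

    f: float
    m: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0 and 0.0 <= self.m <= 1.0):
            raise ValueError("infection frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class RecursionParams:
    """Parameters of the deterministic recursions (symbols as in ModelParams)."""

    F: float = 0.0
    alpha: float = 0.0
    lam: float = 0.8
    mu: float = 0.0
    sigma_total: float = 0.0
    sigma_md: float = 0.0
    rescue_scope: str = "female_level"

    def __post_init__(self) -> None:
        for name in ("F", "alpha", "lam", "mu", "sigma_total", "sigma_md"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if self.sigma_md > self.sigma_total + 1e-12:
            raise ValueError("sigma_md cannot exceed sigma_total")
        if self.rescue_scope not in ("female_level", "egg_level"):
            raise ValueError("rescue_scope must be 'female_level' or 'egg_level'")


def recursion_step(state: RecursionState, p: RecursionParams) -> RecursionState:
    """One host generation of the coupled female/male infection recursions.

    Daughters of infected mothers number f(1+F)(1+alpha(1-lam)) relative to
    the (1-sigma_total*m) surviving daughters of uninfected mothers, and a
    fraction 1-mu of them inherit the infection; sons arise from unfertilized
    eggs, plus — in uninfected mothers — from fertilized eggs converted by
    male-development CI at rate sigma_md*m.
    """
    f, m = state.f, state.m
    fk = f * (1.0 + p.F) * (1.0 + p.alpha * (1.0 - p.lam))
    if p.rescue_scope == "egg_level":
        denom_f = fk * (1.0 - p.mu * p.sigma_total * m) + (1.0 - f) * (1.0 - p.sigma_total * m)
    else:
        denom_f = fk + (1.0 - f) * (1.0 - p.sigma_total * m)
    if denom_f <= 0.0:
        return RecursionState(0.0, 0.0)
    f_next = fk * (1.0 - p.mu) / denom_f

    sons_inf = f * (1.0 + p.F) * (1.0 - p.mu) * (1.0 - p.lam) * (1.0 - p.alpha)
    if p.rescue_scope == "egg_level":
        from_inf = f * (1.0 + p.F) * (
            (1.0 - p.lam) - p.alpha * (1.0 - p.lam) * (1.0 - p.mu * p.sigma_md * m)
        )
    else:
        from_inf = f * (1.0 + p.F) * (1.0 - p.lam) * (1.0 - p.alpha)
    denom_m = from_inf + (1.0 - f) * ((1.0 - p.lam) + p.lam * p.sigma_md * m)
    m_next = sons_inf / denom_m if denom_m > 0.0 else 0.0
    return RecursionState(min(max(f_next, 0.0), 1.0), min(max(m_next, 0.0), 1.0))


def iterate_recursions(
    f0: float, m0: float, p: RecursionParams, n: int
) -> list[RecursionState]:
    """Trajectory of n generations, including the initial state."""
    if n < 0:
        raise ValueError("n must be >= 0")
    traj = [RecursionState(f0, m0)]
    for _ in range(n):
        traj.append(recursion_step(traj[-1], p))
    return traj


def days_to_generations(days: float) -> int:
    """Map simulated days to whole recursion generations: floor(days / 11).

    Remainder days are not fractionally iterated.
    """
    if days < 0:
        raise ValueError("days must be >= 0")
    return int(days // GENERATION_DAYS)


def sd_threshold(mu: float, omega0: float) -> float:
    """Minimum Sd keeping infection frequency omega0 stationary after CI loss.

    Solves the sigma_total = 0, F = 0 fixed-point relation
    omega0 = omega0 (1+Sd)(1-mu) / (omega0 (1+Sd) + 1 - omega0)
    for Sd, giving Sd = mu / (1 - mu - omega0); defined only for
    mu + omega0 < 1.
    """
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    if not 0.0 < omega0 <= 1.0:
        raise ValueError("omega0 must lie in (0, 1]")
    if mu + omega0 >= 1.0:
        raise ValueError("sd_threshold requires mu + omega0 < 1")
    return mu / (1.0 - mu - omega0)


def stable_infection_freq(Sd: float, mu: float) -> float:
    """Stable polymorphic infection frequency maintained by Sd upon CI loss.

    omega = (Sd - mu(1+Sd)) / Sd.  A non-positive raw value means the
    infection cannot be maintained and 0.0 is returned; values above 1 are
    capped at 1.
    """
    if Sd <= 0.0:
        raise ValueError("stable_infection_freq requires Sd > 0")
    if not 0.0 <= mu < 1.0:
        raise ValueError("mu must lie in [0, 1)")
    omega = (Sd - mu * (1.0 + Sd)) / Sd
    return min(max(omega, 0.0), 1.0)


def invasion_surface_recursion(
    p: RecursionParams,
    sigma_grid,
    omega_grid,
    n: int,
) -> np.ndarray:
    """Final female infection frequency over a (sigma_total, omega0) grid.

    The FM:MD proportions of ``p`` are held fixed while sigma_total varies;
    returns a matrix indexed [i_sigma, j_omega].
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any((sigma_grid < 0) | (sigma_grid > 1)) or np.any((omega_grid < 0) | (omega_grid > 1)):
        raise ValueError("grids must lie within [0, 1]")
    md_ratio = p.sigma_md / p.sigma_total if p.sigma_total > 0 else 0.0
    out = np.empty((sigma_grid.size, omega_grid.size))
    for (i, sigma), (j, omega) in itertools.product(
        enumerate(sigma_grid), enumerate(omega_grid)
    ):
        pij = RecursionParams(
            F=p.F,
            alpha=p.alpha,
            lam=p.lam,
            mu=p.mu,
            sigma_total=sigma,
            sigma_md=md_ratio * sigma,
            rescue_scope=p.rescue_scope,
        )
        out[i, j] = iterate_recursions(omega, omega, pij, n)[-1].f
    return out
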