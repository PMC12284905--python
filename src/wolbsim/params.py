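"""Model parameters for the haplodiploid *Wolbachia* individual-based model.

The parameter set mirrors the life history of *Tetranychus urticae* spider
mites: overlapping generations on a daily time step, arrhenotokous
haplodiploidy (a fraction ``lam`` of eggs is fertilized and becomes diploid
females; the rest develop into haploid males), logistic density-dependent
mortality toward a carrying capacity ``K``, and *Wolbachia*-mediated
reproductive phenotypes — female-mortality CI (``sigma_fm``), male-development
CI (``sigma_md``), sex-allocation distortion (``Sd``), imperfect maternal
transmission (``mu``) and a relative fecundity benefit (``F``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

__all__ = ["ModelParams", "scale_total_ci", "beis_params"]

_PROB_FIELDS = (
    "lam",
    "mu",
    "sigma_fm",
    "sigma_md",
    "sigma_total",
    "F",
    "Sd",
    "omega0",
    "suppressor_init_freq",
)

_RESCUE_SCOPES = ("female_level", "egg_level")


@dataclass(frozen=True)
class ModelParams:
    """All tunable constants of the individual-based model.

    Defaults are the *T. urticae* reference values: a 150-day reproductive
    season, carrying capacity 5000, 50 founding adult females, death age 20 d,
    female/male maturity 11/10 d, oviposition peak at 16 d rising from 1 to
    10 eggs per day, per-individual trait dispersion 0.5 d, and a fertilized
    egg proportion lam = 0.8.
    """

    T: int = 150
    K: int = 5000
    P0: int = 50
    D_mean: float = 20.0
    M_female_mean: float = 11.0
    M_male_mean: float = 10.0
    Mp_mean: float = 16.0
    eggsM_mean: float = 1.0
    eggsMp_mean: float = 10.0
    trait_sd: float = 0.5
    lam: float = 0.8
    mu: float = 0.0
    L: int = 5
    sigma_fm: float = 0.0
    sigma_md: float = 0.0
    sigma_total: float = 0.0
    F: float = 0.0
    Sd: float = 0.0
    omega0: float = 0.0
    suppressor_init_freq: float = 0.0
    r_half_day: float = 60.0
    ci_rescue_scope: str = "female_level"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} must lie in [0, 1]")
        if abs(self.sigma_fm + self.sigma_md - self.sigma_total) > 1e-9:
            raise ValueError(
                "sigma_fm + sigma_md must equal sigma_total "
                f"(got {self.sigma_fm} + {self.sigma_md} != {self.sigma_total})"
            )
        if self.lam >= 1.0 and self.Sd > 0:
            raise ValueError("Sd requires lam < 1 (no unfertilized eggs to distort)")
        if self.Sd > 1.0 - self.lam + 1e-12:
            raise ValueError(
                f"Sd={self.Sd} exceeds its maximum 1 - lam = {1.0 - self.lam:.3g}; "
                "the per-egg fertilization boost alpha = Sd/(1-lam) would exceed 1"
            )
        if self.T <= 0:
            raise ValueError(f"T={self.T} must be a positive number of days")
        if self.K <= 0:
            raise ValueError(f"K={self.K} must be positive")
        if self.P0 <= 0:
            raise ValueError(f"P0={self.P0} must be positive")
        if self.P0 > self.K:
            raise ValueError(f"P0={self.P0} cannot exceed the carrying capacity K={self.K}")
        if self.L <= 0:
            raise ValueError(f"L={self.L} must be a positive number of loci")
        if self.r_half_day <= 0:
            raise ValueError(f"r_half_day={self.r_half_day} must be positive")
        for name in ("D_mean", "M_female_mean", "M_male_mean", "Mp_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.M_female_mean < self.Mp_mean < self.D_mean:
            raise ValueError("age means must satisfy M_female < Mp < D")
        if self.trait_sd < 0:
            raise ValueError(f"trait_sd={self.trait_sd} must be non-negative")
        if self.ci_rescue_scope not in _RESCUE_SCOPES:
            raise ValueError(
                f"ci_rescue_scope={self.ci_rescue_scope!r} must be one of {_RESCUE_SCOPES}"
            )

    @property
    def alpha(self) -> float:
        """Per-egg extra fertilization probability implied by Sd: alpha = Sd/(1-lam)."""
        if self.Sd == 0.0:
            return 0.0
        return self.Sd / (1.0 - self.lam)

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (revalidated)."""
        return dataclasses.replace(self, **changes)

    def logistic_constants(self, p0_season: int | None = None) -> tuple[float, float]:
        """Logistic constants (A, r) for a season starting at ``p0_season`` individuals.

        A = (K - P0)/P0 and r = ln(A)/r_half_day, so the logistic target
        K/(1 + A e^(-r t)) passes through K/2 at day ``r_half_day``.  When the
        season starts at or above K/2 (A <= 1) the midpoint calibration is
        ill-posed; the caller should retain r from the run's first season
        (the target is then ~K regardless of r).
        """
        p0 = self.P0 if p0_season is None else p0_season
        if p0 <= 0:
            raise ValueError("season starting size must be positive")
        if p0 >= self.K:
            return 0.0, float("nan")
        A = (self.K - p0) / p0
        r = math.log(A) / self.r_half_day if A > 1.0 else float("nan")
        return A, r


def scale_total_ci(params: ModelParams, sigma_total: float) -> ModelParams:
    """Rescale total CI strength while keeping the FM:MD proportions fixed.

    E.g. moving sigma_total from 1 to 0.5 with sigma_fm = 0.9 yields
    sigma_fm' = 0.45 and sigma_md' = 0.05.
    """
    if not 0.0 <= sigma_total <= 1.0:
        raise ValueError(f"sigma_total={sigma_total} must lie in [0, 1]")
    if params.sigma_total == 0.0:
        if sigma_total == 0.0:
            return params
        raise ValueError(
            "cannot rescale from sigma_total=0: the FM:MD proportions are undefined"
        )
    ratio_fm = params.sigma_fm / params.sigma_total
    return params.replace(
        sigma_fm=ratio_fm * sigma_total,
        sigma_md=(1.0 - ratio_fm) * sigma_total,
        sigma_total=sigma_total,
    )


def beis_params(**overrides) -> ModelParams:
    """Reference parametrization of the Beis *T. urticae* line.

    Complete CI dominated by female mortality (sigma_fm = 0.98,
    sigma_md = 0.02), imperfect maternal transmission mu = 1.8%, and a 50%
    initial female infection frequency.
    """
    base = dict(
        sigma_fm=0.98,
        sigma_md=0.02,
        sigma_total=1.0,
        mu=0.018,
        omega0=0.5,
    )
    base.update(overrides)
    return ModelParams(**base)
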