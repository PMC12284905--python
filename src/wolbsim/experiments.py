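"""Campaign harness: replicated simulations and derived analyses.

Wraps the daily engine in seeded multi-replicate campaigns — single-season
invasions, (sigma_total, omega0) response surfaces, CI-type contrasts,
multi-year suppressor/infection coevolution, persistence-time analysis with
gamma fits, fecundity-threshold estimation and model-vs-data error — and
compares them against the deterministic recursions.

Seed discipline: replicate ``i`` of a campaign runs on ``base_seed + i`` (grid
campaigns offset by cell), so identical campaigns are bit-reproducible and
paired designs can share seeds across arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .analytic import (
    RecursionParams,
    days_to_generations,
    invasion_surface_recursion,
    stable_infection_freq,
)
from .engine import (
    init_population,
    new_season,
    records_to_frame,
    run_replicate,
    run_season,
)
from .params import ModelParams, scale_total_ci

__all__ = [
    "Campaign",
    "YearlyRecord",
    "GammaFit",
    "ContrastResult",
    "run_one_year",
    "summarize_daily",
    "final_frequency_surface",
    "ibm_vs_recursion_bias",
    "ci_type_contrast",
    "run_multi_year",
    "persistence_times",
    "fit_gamma_mle",
    "fecundity_threshold",
    "fc_from_samples",
    "sd_stability_check",
    "relative_rmse",
]


@dataclass(frozen=True)
class Campaign:
    """A replicated simulation experiment built around one parameter set."""

    params: ModelParams
    replicates: int = 100
    years: int = 1
    carryover: str = "full"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        if self.carryover not in ("full", "subsample"):
            raise ValueError("carryover must be 'full' or 'subsample'")


@dataclass(frozen=True)
class YearlyRecord:
    """End-of-year observables of one replicate."""

    replicate: int
    year: int
    inf_freq_female: float
    inf_freq_all: float
    suppressor_freq: float
    pop_size: int


@dataclass(frozen=True)
class GammaFit:
    """Maximum-likelihood gamma fit of persistence times."""

    shape: float
    scale: float
    mean: float
    loglik: float
    n: int


@dataclass(frozen=True)
class ContrastResult:
    """Paired FM-CI vs MD-CI comparison."""

    diff_matrix: np.ndarray | None  # MD minus FM mean final frequency
    sigma_grid: np.ndarray | None
    omega_grid: np.ndarray | None
    focal_fm: pd.DataFrame
    focal_md: pd.DataFrame
    focal_final_fm: float
    focal_final_md: float


def run_one_year(campaign: Campaign) -> pd.DataFrame:
    """Replicated single-season trajectories, one row per (replicate, day)."""
    frames = []
    for rep in range(campaign.replicates):
        _, df = run_replicate(campaign.params, seed=campaign.base_seed + rep)
        df.insert(0, "replicate", rep)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def summarize_daily(daily: pd.DataFrame) -> pd.DataFrame:
    """Per-day mean and standard deviation across replicates."""
    cols = [c for c in daily.columns if c not in ("replicate", "day", "year")]
    g = daily.groupby("day")[cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=1).add_suffix("_sd")
    return pd.concat([mean, sd], axis=1).reset_index()


def _surface(campaign: Campaign, sigma_grid, omega_grid) -> np.ndarray:
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    omega_grid = np.asarray(omega_grid, dtype=float)
    out = np.empty((sigma_grid.size, omega_grid.size))
    cell = 0
    for i, sigma in enumerate(sigma_grid):
        for j, omega in enumerate(omega_grid):
            p = scale_total_ci(campaign.params, sigma).replace(omega0=omega)
            finals = []
            for rep in range(campaign.replicates):
                seed = campaign.base_seed + cell * campaign.replicates + rep
                _, df = run_replicate(p, seed=seed)
                finals.append(df["inf_freq_female"].iloc[-1])
            out[i, j] = float(np.mean(finals))
            cell += 1
    return out


def final_frequency_surface(campaign: Campaign, sigma_grid, omega_grid) -> np.ndarray:
    """Mean end-of-season female infection frequency per (sigma_total, omega0).

    The FM:MD proportions of the campaign's parameters are held fixed while
    sigma_total varies along the grid.
    """
    if campaign.params.sigma_total <= 0:
        raise ValueError(
            "final_frequency_surface needs sigma_total > 0 in the base parameters "
            "to define the FM:MD proportions"
        )
    return _surface(campaign, sigma_grid, omega_grid)


def ibm_vs_recursion_bias(
    campaign: Campaign, sigma_grid, omega_grid, n_generations: int | None = None
) -> tuple[float, np.ndarray]:
    """Recursion-minus-IBM final infection frequency over a shared grid.

    Returns the grid-mean difference and the per-cell matrix.  Positive values
    mean the deterministic recursions overestimate the drive of CI relative to
    the finite-population simulation.
    """
    p = campaign.params
    if n_generations is None:
        n_generations = days_to_generations(p.T)
    ibm = final_frequency_surface(campaign, sigma_grid, omega_grid)
    rp = RecursionParams(
        F=p.F,
        alpha=p.alpha,
        lam=p.lam,
        mu=p.mu,
        sigma_total=p.sigma_total,
        sigma_md=p.sigma_md,
    )
    rec = invasion_surface_recursion(rp, sigma_grid, omega_grid, n_generations)
    diff = rec - ibm
    return float(diff.mean()), diff


def ci_type_contrast(
    campaign: Campaign,
    sigma_grid=None,
    omega_grid=None,
    focal: tuple[float, float] = (0.25, 1.0),
) -> ContrastResult:
    """Strict FM-CI vs strict MD-CI regimes with identical seeds per cell.

    Always runs the focal cell (omega0, sigma_total) with full daily
    diagnostics; optionally also a (sigma_total, omega0) grid of end-of-season
    differences (MD minus FM).
    """
    omega_f, sigma_f = focal

    def arm(fm_fraction: float, omega: float, sigma: float) -> Campaign:
        p = campaign.params.replace(
            sigma_fm=fm_fraction * sigma,
            sigma_md=(1.0 - fm_fraction) * sigma,
            sigma_total=sigma,
            omega0=omega,
        )
        return Campaign(
            params=p,
            replicates=campaign.replicates,
            base_seed=campaign.base_seed,
        )

    fm_daily = run_one_year(arm(1.0, omega_f, sigma_f))
    md_daily = run_one_year(arm(0.0, omega_f, sigma_f))
    last = fm_daily["day"].max()
    final_fm = float(fm_daily.loc[fm_daily.day == last, "inf_freq_female"].mean())
    final_md = float(md_daily.loc[md_daily.day == last, "inf_freq_female"].mean())

    diff = sg = og = None
    if sigma_grid is not None and omega_grid is not None:
        sg = np.asarray(sigma_grid, dtype=float)
        og = np.asarray(omega_grid, dtype=float)
        diff = np.empty((sg.size, og.size))
        for i, sigma in enumerate(sg):
            for j, omega in enumerate(og):
                cell_seed = campaign.base_seed + (i * og.size + j) * campaign.replicates
                finals = {}
                for name, frac in (("fm", 1.0), ("md", 0.0)):
                    c = arm(frac, omega, sigma)
                    vals = [
                        run_replicate(c.params, seed=cell_seed + rep)[1][
                            "inf_freq_female"
                        ].iloc[-1]
                        for rep in range(campaign.replicates)
                    ]
                    finals[name] = float(np.mean(vals))
                diff[i, j] = finals["md"] - finals["fm"]
    return ContrastResult(
        diff_matrix=diff,
        sigma_grid=sg,
        omega_grid=og,
        focal_fm=fm_daily,
        focal_md=md_daily,
        focal_final_fm=final_fm,
        focal_final_md=final_md,
    )


def _run_years(
    params: ModelParams, seed: int, years: int, carryover: str
) -> list[tuple[int, float, float, float, int]]:
    p = params.replace(seed=seed)
    state = init_population(p)
    out = []
    for year in range(1, years + 1):
        records = run_season(state, p)
        end = records[-1]
        out.append(
            (year, end.inf_freq_female, end.inf_freq_all, end.suppressor_freq, end.pop_size)
        )
        if state.pop.size == 0:
            break
        if year < years:
            new_season(state, p, carryover)
    return out


def run_multi_year(campaign: Campaign) -> pd.DataFrame:
    """Chained seasons per replicate; one row per (replicate, year)."""
    rows = []
    for rep in range(campaign.replicates):
        for year, ff, fa, sf, n in _run_years(
            campaign.params, campaign.base_seed + rep, campaign.years, campaign.carryover
        ):
            rows.append(YearlyRecord(rep, year, ff, fa, sf, n))
    return pd.DataFrame([r.__dict__ for r in rows])


def persistence_times(
    campaign: Campaign, max_years: int
) -> tuple[np.ndarray, np.ndarray]:
    """Years until infection loss per replicate, censored at ``max_years``.

    Loss is scored at season ends: the first year whose final population
    contains zero infected individuals.  Returns ``(times, censored)``; a
    censored replicate reports ``max_years`` with its flag set.
    """
    times = np.empty(campaign.replicates, dtype=float)
    censored = np.zeros(campaign.replicates, dtype=bool)
    for rep in range(campaign.replicates):
        p = campaign.params.replace(seed=campaign.base_seed + rep)
        state = init_population(p)
        if not state.pop.infected.any():
            times[rep] = 0.0
            continue
        lost_at = None
        for year in range(1, max_years + 1):
            records = run_season(state, p)
            if records[-1].inf_freq_all == 0.0 or state.pop.size == 0:
                lost_at = year
                break
            if year < max_years:
                new_season(state, p, campaign.carryover)
        if lost_at is None:
            times[rep] = max_years
            censored[rep] = True
        else:
            times[rep] = lost_at
    return times, censored


def fit_gamma_mle(times, censored=None) -> GammaFit:
    """ML gamma fit (shape, scale) of uncensored persistence times.

    Censored observations are excluded.  A constant sample is reported as the
    degenerate limit (shape -> infinity at the observed mean), not an error.
    """
    times = np.asarray(times, dtype=float)
    if censored is not None:
        censored = np.asarray(censored, dtype=bool)
        times = times[~censored]
    if times.size < 2:
        raise ValueError("need at least two uncensored observations")
    if np.any(times <= 0):
        raise ValueError("persistence times must be positive")
    if np.ptp(times) == 0.0:
        return GammaFit(
            shape=math.inf, scale=0.0, mean=float(times[0]), loglik=math.nan, n=times.size
        )
    shape, _, scale = scipy.stats.gamma.fit(times, floc=0)
    loglik = float(np.sum(scipy.stats.gamma.logpdf(times, shape, scale=scale)))
    return GammaFit(
        shape=float(shape), scale=float(scale), mean=float(shape * scale),
        loglik=loglik, n=times.size,
    )


def fc_from_samples(F_values, final_freqs, omega0: float, window: int = 10):
    """Fecundity threshold from (F, final frequency) samples.

    Samples are ordered by non-decreasing F and a trailing moving average of
    the final infection frequencies (lag ``window``) is scanned; Fc is the F
    closing the first window whose moving average reaches ``omega0``.  When
    the very first window already satisfies the condition the smallest
    sampled F is returned (no fecundity benefit required); ``None`` means the
    condition is never satisfied.
    """
    F_values = np.asarray(F_values, dtype=float)
    final_freqs = np.asarray(final_freqs, dtype=float)
    if F_values.size != final_freqs.size:
        raise ValueError("F_values and final_freqs must have equal length")
    if F_values.size < window:
        raise ValueError(f"need at least window={window} samples")
    order = np.argsort(F_values, kind="stable")
    Fs = F_values[order]
    freqs = final_freqs[order]
    moving = np.convolve(freqs, np.ones(window) / window, mode="valid")
    hit = np.flatnonzero(moving >= omega0)
    if hit.size == 0:
        return None
    idx = int(hit[0])
    if idx == 0:
        return float(Fs[0])
    return float(Fs[idx + window - 1])


def fecundity_threshold(
    campaign: Campaign,
    n_samples: int,
    years: int,
    window: int = 10,
    f_max: float = 0.10,
):
    """Minimal fecundity benefit Fc for stable infection after CI loss.

    Samples F uniformly from [0, f_max], runs each sample for ``years`` years
    and applies :func:`fc_from_samples` to the end-of-horizon female infection
    frequencies.  Returns ``(fc, samples)`` where ``samples`` is a DataFrame
    of the (F, final frequency) pairs.
    """
    if n_samples < window:
        raise ValueError("n_samples must be >= window")
    rng = np.random.default_rng(campaign.base_seed)
    Fs = np.sort(rng.uniform(0.0, f_max, n_samples))
    finals = np.empty(n_samples)
    for i, F in enumerate(Fs):
        p = campaign.params.replace(F=float(F))
        rows = _run_years(p, campaign.base_seed + 1 + i, years, campaign.carryover)
        finals[i] = rows[-1][1] if rows[-1][0] == years else 0.0
    fc = fc_from_samples(Fs, finals, campaign.params.omega0, window)
    samples = pd.DataFrame({"F": Fs, "final_freq": finals})
    return fc, samples


def sd_stability_check(campaign: Campaign, sd_grid, years: int) -> pd.DataFrame:
    """Simulated long-run infection frequency vs the closed-form prediction.

    For each Sd on the grid (with sigma_total = 0) the campaign is run for
    ``years`` years and the mean end-of-horizon frequency across replicates is
    tabulated next to the fixed-point prediction (Sd - mu(1+Sd))/Sd.
    """
    if campaign.params.sigma_total != 0.0:
        raise ValueError("sd_stability_check requires sigma_total = 0")
    rows = []
    for k, sd in enumerate(np.asarray(sd_grid, dtype=float)):
        p = campaign.params.replace(Sd=float(sd))
        finals = []
        for rep in range(campaign.replicates):
            seed = campaign.base_seed + k * campaign.replicates + rep
            run = _run_years(p, seed, years, campaign.carryover)
            finals.append(run[-1][1] if run[-1][0] == years else 0.0)
        predicted = stable_infection_freq(sd, p.mu) if sd > 0 else 0.0
        finals = np.asarray(finals)
        rows.append(
            {
                "Sd": sd,
                "predicted_freq": predicted,
                "simulated_freq": float(finals.mean()),
                "simulated_sem": float(finals.std(ddof=1) / np.sqrt(finals.size))
                if finals.size > 1
                else 0.0,
                "n_lost": int((finals == 0.0).sum()),
            }
        )
    return pd.DataFrame(rows)


def relative_rmse(
    sim_days, sim_freqs, obs_days, obs_freqs, normalizer: str = "mean"
) -> float:
    """Relative root-mean-squared error of a simulated trajectory vs data, in %.

    The simulated day-indexed mean trajectory is linearly interpolated to the
    observation days; the RMSE over observation points is normalized by the
    mean of the observed frequencies (alternatives: ``range``, ``final``).
    """
    sim_days = np.asarray(sim_days, dtype=float)
    sim_freqs = np.asarray(sim_freqs, dtype=float)
    obs_days = np.asarray(obs_days, dtype=float)
    obs_freqs = np.asarray(obs_freqs, dtype=float)
    if obs_days.size == 0:
        raise ValueError("observation table is empty")
    if obs_days.min() < sim_days.min() or obs_days.max() > sim_days.max():
        raise ValueError("observed days fall outside the simulated range")
    order = np.argsort(sim_days)
    interp = np.interp(obs_days, sim_days[order], sim_freqs[order])
    rmse = float(np.sqrt(np.mean((interp - obs_freqs) ** 2)))
    if normalizer == "mean":
        denom = float(np.mean(obs_freqs))
    elif normalizer == "range":
        denom = float(np.ptp(obs_freqs))
    elif normalizer == "final":
        denom = float(obs_freqs[-1])
    else:
        raise ValueError("normalizer must be 'mean', 'range' or 'final'")
    if denom == 0.0:
        raise ValueError("normalizer value is zero")
    return 100.0 * rmse / denom
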