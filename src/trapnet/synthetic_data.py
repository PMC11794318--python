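"""Synthetic trap-dataset generator from the growth model's own generative
process, emulating the study schedule (21 sites, 4 years with 6/7/10/11
weeks, one absent site-year, one flagged-missing site-week)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.linalg import cholesky

from .growth_model import logistic_mean
from .trap_data import SiteRegistry, TrapDataset

__all__ = ["SimScenario", "sample_sites", "sample_growth_field", "generate_dataset"]


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth configuration for one simulated monitoring study.

    Defaults emulate the reference schedule: 21 sites in a 30x30 km box
    observed over 2020-2023 with 6/7/10/11 weekly collections, site 3
    absent in 2020, and site 13's week-2 record of 2023 flagged missing.
    Truth parameter magnitudes are generator choices tuned so trajectories
    span tens of (hundred-)counts early and thousands late in the season.
    """

    L: int = 21
    region_km: tuple[float, float] = (30.0, 30.0)
    weeks_per_year: Mapping[int, int] = field(
        default_factory=lambda: {2020: 6, 2021: 7, 2022: 10, 2023: 11}
    )
    absent_site_years: frozenset[tuple[int, int]] = frozenset({(3, 2020)})
    missing_site_weeks: frozenset[tuple[int, int, int]] = frozenset({(2023, 13, 2)})
    mu_beta: float = 15.0
    mu_gamma: float = 6.0
    k: float = 1.5
    sigma2: float = 0.25
    sigma2_beta: float = 16.0
    sigma2_gamma: float = 1.0
    rho_beta: float = 10.0
    rho_gamma: float = 10.0
    seed: int = 0
    allow_nonmonotone: bool = False

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("need at least 2 sites")
        for name in ("k", "sigma2_beta", "sigma2_gamma", "rho_beta", "rho_gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if any(w < 3 for w in self.weeks_per_year.values()):
            raise ValueError("each year needs at least 3 weeks")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.weeks_per_year))


def sample_sites(scenario: SimScenario, rng: np.random.Generator | None = None) -> SiteRegistry:
    """Place L sites uniformly in the region with a minimum separation of
    1% of the region diagonal (rejection sampling)."""
    rng = rng or np.random.default_rng(scenario.seed)
    wx, wy = scenario.region_km
    min_sep = 0.01 * float(np.hypot(wx, wy))
    coords: list[np.ndarray] = []
    attempts = 0
    while len(coords) < scenario.L:
        p = rng.random(2) * np.array([wx, wy])
        if all(np.linalg.norm(p - q) >= min_sep for q in coords):
            coords.append(p)
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError(
                "could not place sites with the minimum separation; enlarge the region"
            )
    return SiteRegistry(tuple(range(1, scenario.L + 1)), np.stack(coords))


def sample_growth_field(
    scenario: SimScenario,
    registry: SiteRegistry,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray | float]:
    """Draw true (beta, gamma) fields from the exponential-correlation GP.

    Site asymptotes are redrawn (up to 100 attempts) until all are
    positive; the growth scale k is fixed at the scenario value.
    """
    rng = rng or np.random.default_rng(scenario.seed + 1)
    D = registry.distances()
    jitter = 1e-10 * np.eye(len(D))

    Lb = cholesky(scenario.sigma2_beta * np.exp(-D / scenario.rho_beta) + jitter, lower=True)
    for _attempt in range(100):
        beta = scenario.mu_beta + Lb @ rng.standard_normal(len(D))
        if np.all(beta > 0):
            break
    else:
        raise RuntimeError(
            "could not draw an all-positive asymptote field; increase mu_beta"
        )
    Lg = cholesky(scenario.sigma2_gamma * np.exp(-D / scenario.rho_gamma) + jitter, lower=True)
    gamma = scenario.mu_gamma + Lg @ rng.standard_normal(len(D))
    return {
        "beta": beta,
        "gamma": gamma,
        "k": scenario.k,
        "sigma2": scenario.sigma2,
        "mu_beta": scenario.mu_beta,
        "mu_gamma": scenario.mu_gamma,
        "sigma2_beta": scenario.sigma2_beta,
        "sigma2_gamma": scenario.sigma2_gamma,
        "rho_beta": scenario.rho_beta,
        "rho_gamma": scenario.rho_gamma,
    }


def generate_dataset(
    scenario: SimScenario,
) -> tuple[TrapDataset, dict]:
    """Generate a trap dataset plus its ground-truth record.

    Cumulative paths are the logistic mean plus iid Normal noise; unless
    ``allow_nonmonotone`` is set, a running maximum (clipped at zero) is
    applied so emitted cumulative series honour their definitional
    monotonicity, and weekly counts are the successive differences.
    Missingness is applied afterwards: absent site-years are dropped
    entirely, missing site-weeks flagged NA.
    """
    rng = np.random.default_rng(scenario.seed)
    registry = sample_sites(scenario, rng)
    truth = sample_growth_field(scenario, registry, rng)
    beta, gamma, k = truth["beta"], truth["gamma"], truth["k"]
    sigma = float(np.sqrt(scenario.sigma2))

    rows = []
    for year in scenario.years:
        n_weeks = scenario.weeks_per_year[year]
        weeks = np.arange(1, n_weeks + 1, dtype=float)
        for i, site in enumerate(registry.site_ids):
            if (site, year) in scenario.absent_site_years:
                continue
            mean_path = logistic_mean(weeks, beta[i], gamma[i], k)
            path = mean_path + sigma * rng.standard_normal(n_weeks)
            if not scenario.allow_nonmonotone:
                path = np.maximum.accumulate(np.maximum(path, 0.0))
            weekly = np.diff(path, prepend=0.0)
            if not scenario.allow_nonmonotone:
                weekly = np.maximum(weekly, 0.0)
            for w, z in zip(range(1, n_weeks + 1), weekly):
                missing = (year, site, w) in scenario.missing_site_weeks
                rows.append(
                    {
                        "year": year,
                        "site_id": site,
                        "week": w,
                        "count": np.nan if missing else float(z),
                    }
                )
    ds = TrapDataset(
        registry, pd.DataFrame(rows), allow_negative=scenario.allow_nonmonotone
    )
    truth_record = {
        "scenario": {
            "L": scenario.L,
            "region_km": list(scenario.region_km),
            "weeks_per_year": {str(y): int(w) for y, w in scenario.weeks_per_year.items()},
            "seed": scenario.seed,
        },
        "params": {
            name: (val.tolist() if isinstance(val, np.ndarray) else float(val))
            for name, val in truth.items()
        },
        "site_ids": list(registry.site_ids),
    }
    return ds, truth_record


def write_outputs(ds: TrapDataset, truth: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.to_csv(out / "counts.csv")
    ds.registry.to_csv(out / "sites.csv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
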