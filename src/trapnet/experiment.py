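"""Monte-Carlo K-sweep harness: surrogate-guided subset search per K and
repetition, random-subset baseline, final test-year evaluation, inclusion
proportions and the tile table of top sites."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bayes_opt import Design, bo_loop
from .growth_model import MCMCConfig
from .loss_functions import SiteSubset, holdout_loss
from .trap_data import TrapDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "run_sweep",
    "inclusion_proportions",
    "tile_table",
]


@dataclass(frozen=True)
class ExperimentConfig:
    K_values: tuple[int, ...] = tuple(range(5, 15))
    n_mc: int = 50
    N0: int = 20
    B: int = 30
    seed: int = 0
    test_year: int = 2023
    fit_window: str = "all"  # "all": fit final model on every year; "test_only": test year alone
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    equal_budget_random: bool = False
    acquisition_mode: str = "mean"

    def __post_init__(self) -> None:
        if self.n_mc < 1:
            raise ValueError("n_mc must be at least 1")
        if self.fit_window not in ("all", "test_only"):
            raise ValueError("fit_window must be 'all' or 'test_only'")


@dataclass
class ExperimentSummary:
    mean_mle: pd.DataFrame        # columns: K, method, mean_mle, sd, n_reps
    inclusion_prop: pd.DataFrame  # columns: K, site_id, proportion
    avg_inclusion: pd.DataFrame   # columns: site_id, proportion
    tiles: pd.DataFrame           # columns: K, site_id, selected
    best_sets: dict[tuple[int, int], SiteSubset]
    losses: pd.DataFrame          # per-rep detail: K, rep, method, test_mle

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.mean_mle.to_csv(out / "summary.csv", index=False)
        self.inclusion_prop.to_csv(out / "inclusion.csv", index=False)
        self.avg_inclusion.to_csv(out / "avg_inclusion.csv", index=False)
        self.tiles.to_csv(out / "tiles.csv", index=False)
        self.losses.to_csv(out / "losses.csv", index=False)


def _rep_seed(ss_child: np.random.SeedSequence) -> int:
    return int(ss_child.generate_state(1, dtype=np.uint32)[0])


def run_sweep(ds: TrapDataset, cfg: ExperimentConfig) -> ExperimentSummary:
    """For each K and MC repetition, search subsets on the pre-test-year
    objective, evaluate the winner (and a random baseline) on the test
    year, and aggregate losses, inclusion proportions and the tile table.

    Per-rep seeds derive from the master seed via SeedSequence spawning so
    repetitions are independent and individually replayable.  A failed
    model fit is retried once with a jittered seed, then recorded missing.
    """
    site_order = tuple(ds.registry.site_ids)
    L = len(site_order)
    all_years = set(ds.years)
    if cfg.test_year not in all_years:
        raise ValueError(f"test year {cfg.test_year} not present in dataset")
    pre_years = sorted(all_years - {cfg.test_year})
    if not pre_years:
        raise ValueError("no training years before the test year")
    fit_years_final = (
        sorted(all_years) if cfg.fit_window == "all" else [cfg.test_year]
    )
    for K in cfg.K_values:
        if not 1 <= K < L:
            raise ValueError(f"K={K} out of range for L={L}")

    loss_rows = []
    best_sets: dict[tuple[int, int], SiteSubset] = {}

    for K in cfg.K_values:
        for rep in range(cfg.n_mc):
            # stable per-(K, rep) children regardless of loop order
            kids = np.random.SeedSequence(
                entropy=cfg.seed, spawn_key=(int(K), int(rep))
            ).spawn(3)
            bo_ss, rand_ss, eval_ss = kids

            def objective(design: Design, _ss=bo_ss) -> float:
                subset = SiteSubset.from_binary(design.x, site_order)
                key = 0
                for m in subset.members:  # stable across processes, unlike hash()
                    key = (key * 1000003 + m) % (2**31 - 1)
                fit_seed = int(
                    np.random.SeedSequence(
                        entropy=_ss.entropy,
                        spawn_key=_ss.spawn_key + (key,),
                    ).generate_state(1, dtype=np.uint32)[0]
                )
                report = holdout_loss(
                    ds, subset, eval_years=pre_years, fit_years=pre_years,
                    mcmc_config=cfg.mcmc.with_seed(fit_seed),
                )
                return report.value

            try:
                state = _run_bo_with_retry(objective, L, K, cfg, bo_ss)
            except Exception as exc:  # pragma: no cover - defensive
                warnings.warn(f"BO rep (K={K}, rep={rep}) failed: {exc}", RuntimeWarning)
                continue
            best_subset = SiteSubset.from_binary(state.best.x, site_order)
            best_sets[(K, rep)] = best_subset

            eval_seed = _rep_seed(eval_ss)
            bo_test = _final_eval(
                ds, best_subset, cfg, fit_years_final, eval_seed, K, rep, "bo"
            )
            if bo_test is not None:
                loss_rows.append(
                    {"K": K, "rep": rep, "method": "bo", "test_mle": bo_test}
                )

            rand_rng = np.random.default_rng(rand_ss)
            if cfg.equal_budget_random:
                budget = cfg.N0 + cfg.B
                cands = [
                    tuple(site_order[j] for j in sorted(rand_rng.choice(L, K, replace=False)))
                    for _ in range(budget)
                ]
                best_rand, best_val = None, np.inf
                for members in cands:
                    subset = SiteSubset(members, site_order)
                    report = holdout_loss(
                        ds, subset, eval_years=pre_years, fit_years=pre_years,
                        mcmc_config=cfg.mcmc.with_seed(_rep_seed(rand_ss)),
                    )
                    if report.value < best_val:
                        best_rand, best_val = subset, report.value
                rand_subset = best_rand
            else:
                members = tuple(
                    site_order[j] for j in sorted(rand_rng.choice(L, K, replace=False))
                )
                rand_subset = SiteSubset(members, site_order)
            rand_test = _final_eval(
                ds, rand_subset, cfg, fit_years_final, eval_seed + 1, K, rep, "random"
            )
            if rand_test is not None:
                loss_rows.append(
                    {"K": K, "rep": rep, "method": "random", "test_mle": rand_test}
                )

    losses = pd.DataFrame(loss_rows)
    mean_mle = (
        losses.groupby(["K", "method"])["test_mle"]
        .agg(mean_mle="mean", sd="std", n_reps="count")
        .reset_index()
    )
    inclusion_prop, avg_inclusion = inclusion_proportions(best_sets)
    tiles = tile_table(inclusion_prop, cfg.K_values)
    return ExperimentSummary(
        mean_mle=mean_mle,
        inclusion_prop=inclusion_prop,
        avg_inclusion=avg_inclusion,
        tiles=tiles,
        best_sets=best_sets,
        losses=losses,
    )


def _run_bo_with_retry(objective, L, K, cfg, bo_ss):
    seed = _rep_seed(bo_ss)
    try:
        return bo_loop(objective, L, K, N0=cfg.N0, B=cfg.B, seed=seed,
                       acquisition_mode=cfg.acquisition_mode)
    except Exception as exc:
        warnings.warn(
            f"BO run failed ({exc}); retrying once with jittered seed", RuntimeWarning
        )
        return bo_loop(objective, L, K, N0=cfg.N0, B=cfg.B, seed=seed + 1,
                       acquisition_mode=cfg.acquisition_mode)


def _final_eval(ds, subset, cfg, fit_years, seed, K, rep, method):
    for attempt, s in enumerate((seed, seed + 7919)):
        try:
            report = holdout_loss(
                ds, subset, eval_years=[cfg.test_year], fit_years=fit_years,
                mcmc_config=cfg.mcmc.with_seed(s),
            )
            return report.value
        except Exception as exc:
            if attempt == 1:
                warnings.warn(
                    f"final evaluation failed twice (K={K}, rep={rep}, {method}): {exc}",
                    RuntimeWarning,
                )
                return None
            warnings.warn(
                f"final evaluation failed (K={K}, rep={rep}, {method}); retrying: {exc}",
                RuntimeWarning,
            )
    return None


def inclusion_proportions(
    best_sets: Mapping[tuple[int, int], SiteSubset],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(K, site) fraction of repetitions whose best set contains the
    site, plus the unweighted average over K."""
    if not best_sets:
        raise ValueError("no best sets provided")
    site_order = next(iter(best_sets.values())).site_order
    Ks = sorted({K for K, _ in best_sets})
    rows = []
    for K in Ks:
        reps = [subset for (k, _), subset in best_sets.items() if k == K]
        for site in site_order:
            prop = float(np.mean([site in s.members for s in reps]))
            rows.append({"K": K, "site_id": site, "proportion": prop})
    inclusion = pd.DataFrame(rows)
    avg = (
        inclusion.groupby("site_id")["proportion"].mean().reset_index()
        .rename(columns={"proportion": "proportion"})
    )
    return inclusion, avg


def tile_table(inclusion_prop: pd.DataFrame, K_values: Sequence[int]) -> pd.DataFrame:
    """Mark, for each K, every site whose inclusion proportion reaches the
    Kth largest; ties at the threshold all get marked, so a row may hold
    more than K marks."""
    rows = []
    for K in K_values:
        block = inclusion_prop[inclusion_prop["K"] == K]
        if block.empty:
            continue
        props = block["proportion"].to_numpy()
        threshold = np.sort(props)[::-1][K - 1]
        for _, row in block.iterrows():
            rows.append(
                {
                    "K": int(K),
                    "site_id": int(row["site_id"]),
                    "selected": bool(row["proportion"] >= threshold),
                }
            )
    return pd.DataFrame(rows)


def nesting_fraction(tiles: pd.DataFrame) -> float:
    """Fraction of sites marked at K that are also marked at the next K."""
    Ks = sorted(tiles["K"].unique())
    hits = total = 0
    for K, K_next in zip(Ks, Ks[1:]):
        cur = set(tiles[(tiles["K"] == K) & tiles["selected"]]["site_id"])
        nxt = set(tiles[(tiles["K"] == K_next) & tiles["selected"]]["site_id"])
        hits += len(cur & nxt)
        total += len(cur)
    return hits / total if total else float("nan")
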