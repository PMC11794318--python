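"""Mean-log-error loss on held-out sites, and the cost-penalized variant.

The loss for a candidate subset is the mean over evaluation cells of
``log(|Y - Yhat| + 1)`` (natural log, counts in hundreds of pests), where
predictions at held-out sites come from the growth model fit on the subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .growth_model import MCMCConfig, fit_growth_model, predict_cumulative
from .trap_data import TrapDataset, cumulative_table

__all__ = [
    "SiteSubset",
    "LossReport",
    "mean_log_error",
    "holdout_loss",
    "cost_penalized_loss",
    "implied_abs_error",
]

Cell = tuple[int, int, int]  # (year, site_id, week)


@dataclass(frozen=True)
class SiteSubset:
    """An ordered size-K subset of candidate sites.

    ``site_order`` is the full ordered candidate list; ``as_binary`` is the
    matching 0/1 inclusion vector with row sum K.
    """

    members: tuple[int, ...]
    site_order: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(int(m) for m in self.members)
        order = tuple(int(s) for s in self.site_order)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "site_order", order)
        if len(set(members)) != len(members):
            raise ValueError("subset members must be distinct")
        if not set(members) <= set(order):
            raise ValueError("subset members must come from the candidate list")
        if not 1 <= len(members) < len(order):
            raise ValueError("need 1 <= K < L")

    @property
    def k(self) -> int:
        return len(self.members)

    @property
    def as_binary(self) -> np.ndarray:
        x = np.zeros(len(self.site_order), dtype=np.uint8)
        member_set = set(self.members)
        for j, s in enumerate(self.site_order):
            if s in member_set:
                x[j] = 1
        return x

    @classmethod
    def from_binary(cls, x: np.ndarray, site_order: Iterable[int]) -> "SiteSubset":
        order = tuple(int(s) for s in site_order)
        x = np.asarray(x)
        if x.shape != (len(order),) or not set(np.unique(x)) <= {0, 1}:
            raise ValueError("binary vector must be 0/1 of length L")
        members = tuple(order[j] for j in range(len(order)) if x[j])
        return cls(members, order)

    def complement(self) -> tuple[int, ...]:
        member_set = set(self.members)
        return tuple(s for s in self.site_order if s not in member_set)


@dataclass
class LossReport:
    value: float
    terms: dict[Cell, float]
    n_cells: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"year": y, "site_id": s, "week": w, "term": t}
            for (y, s, w), t in sorted(self.terms.items())
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def mean_log_error(
    obs: Mapping[Cell, float],
    pred: Mapping[Cell, float],
    cells: Iterable[Cell],
) -> LossReport:
    """Mean of ``log(|Y - Yhat| + 1)`` over the given cells (natural log)."""
    cells = list(cells)
    if not cells:
        raise ValueError("empty cell set")
    terms: dict[Cell, float] = {}
    for cell in cells:
        y, yhat = float(obs[cell]), float(pred[cell])
        if not math.isfinite(yhat):
            raise ValueError(f"non-finite prediction at cell {cell}")
        terms[cell] = math.log(abs(y - yhat) + 1.0)
    value = float(np.mean(list(terms.values())))
    return LossReport(value=value, terms=terms, n_cells=len(cells))


def holdout_loss(
    ds: TrapDataset,
    subset: SiteSubset,
    eval_years: Iterable[int],
    fit_years: Iterable[int],
    mcmc_config: MCMCConfig | None = None,
    *,
    clip_negative: bool = True,
    max_kriging_draws: int = 400,
) -> LossReport:
    """Fit on the subset's sites, predict at the held-out sites, score.

    Fits the growth model on ``subset`` over ``fit_years``, kriges to every
    site not in the subset, and returns the mean log error over all
    observed cells at held-out sites in ``eval_years``.  For the training
    objective both year sets are the pre-test years; for final evaluation
    the eval cells are the test year.
    """
    eval_years = set(int(y) for y in eval_years)
    fit_years = set(int(y) for y in fit_years)
    held_out = subset.complement()
    if not held_out:
        raise ValueError("subset covers all sites; no held-out cells")

    obs = cumulative_table(ds)
    held_set = set(held_out)
    cells = [
        (y, s, w) for (y, s, w) in obs if y in eval_years and s in held_set
    ]
    if not cells:
        raise ValueError("no evaluation cells at held-out sites in eval years")

    post = fit_growth_model(ds, subset.members, fit_years, mcmc_config)
    post = post.thin(max_kriging_draws)
    targets = ds.registry.subset(held_out)
    weeks = sorted({w for (_, _, w) in cells})
    prediction = predict_cumulative(post, targets, weeks)
    pred = {
        (y, s, w): prediction.value(s, w, clip_zero=clip_negative)
        for (y, s, w) in cells
    }
    return mean_log_error(obs, pred, cells)


def cost_penalized_loss(
    base: LossReport,
    subset: SiteSubset,
    costs: Mapping[int, float] | Callable[[SiteSubset], float],
    lam: float,
) -> float:
    """``base.value + lam * C(subset)``.

    ``costs`` is either a per-site cost map (additive total) or a callable
    computing the subset cost directly (e.g. a tour length).
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if callable(costs):
        total = float(costs(subset))
    else:
        missing = [s for s in subset.members if s not in costs]
        if missing:
            raise ValueError(f"missing cost for sites: {missing}")
        total = float(sum(costs[s] for s in subset.members))
    return base.value + lam * total


def implied_abs_error(mle: float, *, per_hundred: float = 100.0) -> float:
    """Average absolute error in individual pests implied by a mean log error.

    Inverts the per-cell term: ``per_hundred * (exp(mle) - 1)``, since the
    loss is computed on counts in hundreds of pests.
    """
    return per_hundred * (math.exp(mle) - 1.0)
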