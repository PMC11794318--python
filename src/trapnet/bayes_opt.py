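"""Bayesian optimization over binary site-inclusion vectors.

Designs are 0/1 vectors of length L with exactly K ones.  The expensive
objective (a held-out model-fit loss) is approximated by a Bayesian linear
surrogate without intercept; the acquisition rule selects the K sites with
the smallest posterior-mean coefficients, which is the exact minimizer of
the surrogate over the constrained binary cube.  A brute-force enumerator
is provided as an oracle for small instances.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Design",
    "SurrogateFit",
    "BOState",
    "BruteForceResult",
    "init_designs",
    "fit_surrogate",
    "acquire",
    "bo_loop",
    "brute_force",
]


@dataclass
class Design:
    """A binary inclusion vector with fixed row sum, plus its loss once known."""

    x: np.ndarray
    loss: float | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=np.uint8)
        if not set(np.unique(x)) <= {0, 1}:
            raise ValueError("design vector must be binary")
        self.x = x
        if self.loss is not None and not math.isfinite(self.loss):
            raise ValueError("evaluated loss must be finite")

    @property
    def k(self) -> int:
        return int(self.x.sum())

    @property
    def members(self) -> tuple[int, ...]:
        """Zero-based positions of the included sites."""
        return tuple(int(j) for j in np.flatnonzero(self.x))

    def key(self) -> bytes:
        return self.x.tobytes()

    @classmethod
    def from_members(cls, members: Sequence[int], L: int) -> "Design":
        x = np.zeros(L, dtype=np.uint8)
        x[list(members)] = 1
        return cls(x)


@dataclass
class SurrogateFit:
    """Posterior of the no-intercept linear surrogate over inclusion bits."""

    coef_mean: np.ndarray
    coef_cov: np.ndarray
    n_designs: int


@dataclass
class BOState:
    evaluated: list[Design]
    surrogate: SurrogateFit | None
    best: Design
    seed: int
    best_trace: list[float] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        L = len(self.evaluated[0].x)
        rows = []
        for i, d in enumerate(self.evaluated):
            row = {"iteration": i, "loss": d.loss, "seed": self.seed}
            row.update({f"x{j+1}": int(b) for j, b in enumerate(d.x)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "designs.csv", index=False)
        if self.surrogate is not None:
            pd.DataFrame(
                {
                    "site_index": np.arange(1, L + 1),
                    "coef_mean": self.surrogate.coef_mean,
                    "coef_sd": np.sqrt(np.diag(self.surrogate.coef_cov)),
                }
            ).to_csv(out / "surrogate.csv", index=False)
        with open(out / "best.json", "w") as fh:
            json.dump(
                {
                    "members": [int(m) for m in self.best.members],
                    "loss": self.best.loss,
                    "seed": self.seed,
                    "n_evaluated": len(self.evaluated),
                },
                fh,
                indent=2,
            )


def _n_subsets(L: int, K: int) -> int:
    return math.comb(L, K)


def init_designs(L: int, K: int, N0: int, seed: int | np.random.Generator) -> list[Design]:
    """N0 distinct uniform-random K-subsets of L sites."""
    if not 1 <= K < L:
        raise ValueError("need 1 <= K < L")
    if N0 < 1:
        raise ValueError("N0 must be at least 1")
    total = _n_subsets(L, K)
    if N0 > total:
        raise ValueError(f"N0={N0} exceeds the number of K-subsets C({L},{K})={total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if total <= 5000:
        # small space: sample without replacement from the full enumeration
        all_subsets = list(itertools.combinations(range(L), K))
        idx = rng.choice(total, size=N0, replace=False)
        return [Design.from_members(all_subsets[i], L) for i in idx]
    seen: set[bytes] = set()
    designs: list[Design] = []
    while len(designs) < N0:
        members = rng.choice(L, size=K, replace=False)
        d = Design.from_members(members, L)
        if d.key() not in seen:
            seen.add(d.key())
            designs.append(d)
    return designs


def fit_surrogate(designs: Sequence[Design], prior_scale: float = 10.0) -> SurrogateFit:
    """Bayesian linear regression of losses on inclusion bits, no intercept.

    A vague-but-proper Normal(0, tau^2 I) prior keeps the posterior defined
    when there are fewer designs than sites or the design matrix is
    rank-deficient.
    """
    if len(designs) < 2:
        raise ValueError("need at least 2 evaluated designs")
    X = np.stack([d.x for d in designs]).astype(float)
    y = np.array([d.loss for d in designs], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("all designs must be evaluated with finite losses")
    n, L = X.shape

    rank = np.linalg.matrix_rank(X)
    if rank < min(n, L):
        logger.info("surrogate design matrix is rank-deficient (rank %d)", rank)

    # noise-variance estimate from a least-squares pass
    coef_ls, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef_ls) ** 2))
    dof = n - rank
    sigma2 = rss / dof if dof > 0 else max(rss, 1e-8 * max(np.var(y), 1.0))
    sigma2 = max(sigma2, 1e-12)

    scale = max(float(np.var(y)), float(np.mean(y)) ** 2, 1e-6)
    tau2 = prior_scale**2 * scale
    A = X.T @ X + (sigma2 / tau2) * np.eye(L)
    coef_mean = np.linalg.solve(A, X.T @ y)
    coef_cov = sigma2 * np.linalg.inv(A)
    coef_cov = 0.5 * (coef_cov + coef_cov.T)
    return SurrogateFit(coef_mean=coef_mean, coef_cov=coef_cov, n_designs=n)


def acquire(fit: SurrogateFit, K: int, rng: np.random.Generator | None = None,
            thompson: bool = False) -> Design:
    """Select the K sites with smallest surrogate coefficients.

    Ties at the Kth order statistic break by ascending site index, so
    exactly K sites are always chosen; this is the exact argmin of the
    surrogate over row-sum-K binary vectors.  ``thompson=True`` ranks a
    single posterior draw of the coefficients instead of the mean.
    """
    L = len(fit.coef_mean)
    if K >= L:
        raise ValueError("need K < L")
    if thompson:
        if rng is None:
            raise ValueError("thompson acquisition needs an rng")
        jitter = 1e-12 * np.eye(L)
        b = rng.multivariate_normal(fit.coef_mean, fit.coef_cov + jitter)
    else:
        b = fit.coef_mean
    order = np.argsort(b, kind="stable")
    return Design.from_members(order[:K], L)


def bo_loop(
    objective: Callable[[Design], float],
    L: int,
    K: int,
    N0: int = 20,
    B: int = 30,
    seed: int = 0,
    acquisition_mode: str = "mean",
) -> BOState:
    """Run the surrogate-guided optimization loop.

    Evaluates N0 random initial designs, then repeats B times: fit the
    surrogate, take its constrained argmin, evaluate, append.  If the
    proposed design was already evaluated, up to 10 Thompson draws are
    tried, then a uniform-random unseen subset.  Returns the state with the
    best evaluated design over all N0 + B evaluations.
    """
    if acquisition_mode not in ("mean", "thompson"):
        raise ValueError("acquisition_mode must be 'mean' or 'thompson'")
    if B < 0:
        raise ValueError("B must be non-negative")
    rng = np.random.default_rng(seed)

    def evaluate(d: Design) -> Design:
        loss = float(objective(d))
        if not math.isfinite(loss):
            raise ValueError(f"objective returned non-finite loss for design {d.members}")
        d.loss = loss
        return d

    evaluated = [evaluate(d) for d in init_designs(L, K, N0, rng)]
    seen = {d.key() for d in evaluated}
    best = min(evaluated, key=lambda d: d.loss)
    trace = [best.loss]
    fit: SurrogateFit | None = None

    total = _n_subsets(L, K)
    for _ in range(B):
        if len(seen) >= total:
            logger.info("design space exhausted after %d evaluations", len(seen))
            break
        fit = fit_surrogate(evaluated)
        cand = acquire(fit, K, rng, thompson=(acquisition_mode == "thompson"))
        if cand.key() in seen:
            for _attempt in range(10):
                cand = acquire(fit, K, rng, thompson=True)
                if cand.key() not in seen:
                    break
            else:
                logger.info("thompson fallback exhausted; sampling a random subset")
                while True:
                    cand = Design.from_members(rng.choice(L, size=K, replace=False), L)
                    if cand.key() not in seen:
                        break
        evaluate(cand)
        evaluated.append(cand)
        seen.add(cand.key())
        if cand.loss < best.loss:
            best = cand
        trace.append(best.loss)

    return BOState(evaluated=evaluated, surrogate=fit, best=best, seed=seed,
                   best_trace=trace)


@dataclass
class BruteForceResult:
    best: Design
    table: pd.DataFrame  # all designs ranked by loss


def brute_force(
    objective: Callable[[Design], float], L: int, K: int, cap: int = 5000
) -> BruteForceResult:
    """Exhaustively evaluate every K-subset (oracle for small instances)."""
    total = _n_subsets(L, K)
    if total > cap:
        raise ValueError(
            f"C({L},{K})={total} exceeds cap {cap}; use bo_loop instead"
        )
    rows = []
    best: Design | None = None
    for members in itertools.combinations(range(L), K):
        d = Design.from_members(members, L)
        d.loss = float(objective(d))
        rows.append({"members": members, "loss": d.loss})
        if best is None or d.loss < best.loss:
            best = d
    table = pd.DataFrame(rows).sort_values("loss").reset_index(drop=True)
    return BruteForceResult(best=best, table=table)
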