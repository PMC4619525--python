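"""Prediction-error metrics and replicated strategy evaluation.

Two representativeness metrics, both expressed as a percentage of the true
population total of a product:

* hospital-level error: the absolute prediction errors summed over all
  hospitals, ``100 * sum_h |yhat_h - y_h| / sum_h y_h`` — accuracy within
  individual hospitals;
* national-level error: the absolute deviation of the summed estimate,
  ``100 * |sum_h yhat_h - sum_h y_h| / sum_h y_h`` — accuracy of the total,
  always no larger than the hospital-level error because hospital-level
  over- and under-prediction cancel in the sum.

Strategies with a random element are evaluated by Monte Carlo: a sampling
process is replicated (1000 times by default), each replicate fits the three
product models and predicts population-wide; medians, means and 95% centiles
(2.5th/97.5th) of the error distributions are reported. The full experiment
averages the summaries of several independent batches (10 x 1000 by default)
and also tabulates how often each random strategy outperforms each purposive
one (head-to-head win fractions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import strategies as strat
from .errors import MetricUndefinedError, SampleSimError
from .inference import ModelSpec, irls_poisson
from .population import PRODUCT_COLUMNS, PRODUCTS, Population
from .strategies import DETERMINISTIC, SCENARIOS, STRATEGIES, Scenario

METRICS = ("hospital", "national")


# ---------------------------------------------------------------------------
# error metrics


def _percent_errors(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    total = float(np.sum(obs))
    if total <= 0:
        raise MetricUndefinedError("population total is zero; error % undefined")
    hosp = 100.0 * float(np.sum(np.abs(pred - obs))) / total
    nat = 100.0 * abs(float(np.sum(pred)) - total) / total
    return hosp, nat


def hospital_level_error(pred, pop: Population, product: str) -> float:
    """Summed absolute per-hospital error as % of the population total."""
    obs = pop.counts(product).astype(float)
    values = pred.values if hasattr(pred, "values") else np.asarray(pred, dtype=float)
    return _percent_errors(values, obs)[0]


def national_level_error(pred, pop: Population, product: str) -> float:
    """Absolute deviation of the national estimate as % of the true total."""
    obs = pop.counts(product).astype(float)
    values = pred.values if hasattr(pred, "values") else np.asarray(pred, dtype=float)
    return _percent_errors(values, obs)[1]


def summarize_distribution(values: Sequence[float]) -> dict[str, float]:
    """Median, mean and 2.5/97.5 centiles (sorted linear interpolation)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    lo, hi = np.percentile(arr, [2.5, 97.5], method="linear")
    return {
        "median": float(np.median(arr)),
        "mean": float(np.mean(arr)),
        "centile_2.5": float(lo),
        "centile_97.5": float(hi),
    }


def head_to_head_fraction(random_errors: Sequence[float], purposive_error: float) -> float:
    """Percent of replicates strictly below the purposive error (ties lose)."""
    arr = np.asarray(random_errors, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compare an empty error sequence")
    return 100.0 * float(np.mean(arr < purposive_error))


# ---------------------------------------------------------------------------
# replicate machinery


@dataclass(frozen=True)
class ErrorSummary:
    """Both error metrics for one product of one replicate."""

    product: str
    hospital_level_pct: float
    national_level_pct: float


@dataclass
class SimulationResult:
    """Replicated evaluation of one strategy under one scenario."""

    strategy: str
    scenario: Scenario
    products: tuple[str, ...]
    errors: dict[str, np.ndarray]  # product -> (n_ok, 2) [hospital, national]
    failed_replicates: int
    n_replicates: int

    def replicate_errors(self, product: str) -> list[ErrorSummary]:
        return [
            ErrorSummary(product, float(h), float(n))
            for h, n in self.errors[product]
        ]

    def summary(self) -> dict[str, dict[str, dict[str, float]]]:
        out: dict[str, dict[str, dict[str, float]]] = {}
        for p in self.products:
            err = self.errors[p]
            out[p] = {
                "hospital": summarize_distribution(err[:, 0]),
                "national": summarize_distribution(err[:, 1]),
            }
        return out


def derive_rng(seed: int, *parts) -> np.random.Generator:
    """A reproducible substream keyed on (seed, *parts).

    Strings are mapped through CRC-32 so that adding one strategy, batch or
    replicate never perturbs another's draws.
    """
    import zlib

    key = tuple(
        zlib.crc32(p.encode()) if isinstance(p, str) else int(p) for p in parts
    )
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


class _PopArrays:
    """Design matrix and responses for one population, built once."""

    def __init__(self, pop: Population, products: Sequence[str], per_type_slopes=False):
        self.pop = pop
        self.specs = {p: ModelSpec(p, per_type_slopes) for p in products}
        any_spec = next(iter(self.specs.values()))
        self.X = any_spec.design_matrix(pop.df)
        self.y = {
            p: pop.df[PRODUCT_COLUMNS[p]].to_numpy(dtype=float) for p in products
        }
        self.totals = {p: float(self.y[p].sum()) for p in products}
        for p, tot in self.totals.items():
            if tot <= 0:
                raise MetricUndefinedError(f"population total for {p} is zero")

    def evaluate(self, idx: np.ndarray, holdout_only: bool) -> np.ndarray | None:
        """Fit all products on rows ``idx``; return (n_products, 2) errors.

        Returns None when any product's fit fails (rank deficiency or
        non-convergence); the caller records a failed replicate.
        """
        Xs = self.X[idx]
        if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
            return None
        if holdout_only:
            mask = np.ones(len(self.pop), dtype=bool)
            mask[idx] = False
        out = np.empty((len(self.specs), 2))
        for j, p in enumerate(self.specs):
            beta, converged, _, _ = irls_poisson(Xs, self.y[p][idx])
            if not converged:
                return None
            mu = np.exp(np.clip(self.X @ beta, -500, 500))
            obs = self.y[p]
            if holdout_only:
                mu, obs = mu[mask], obs[mask]
            total = float(obs.sum())
            if total <= 0:
                return None
            out[j, 0] = 100.0 * np.abs(mu - obs).sum() / total
            out[j, 1] = 100.0 * abs(mu.sum() - total) / total
        return out


def run_replicates(
    pop: Population,
    strategy: str,
    scenario: Scenario,
    n_reps: int = 1000,
    seed: int = 0,
    products: Sequence[str] = PRODUCTS,
    holdout_only: bool = False,
    per_type_slopes: bool = False,
    pair: tuple[str, str] | None = None,
    _arrays: "_PopArrays | None" = None,
) -> SimulationResult:
    """Replicate one strategy: select, fit all products, predict, score.

    Deterministic strategies (LARG, MAXVAR) are evaluated once and the result
    replicated logically. For 2REG each replicate first draws a region pair
    uniformly from all pairs (unless ``pair`` pins one down). Reproducible
    given ``seed``.
    """
    strategy = strategy.upper()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    arrays = _arrays or _PopArrays(pop, products, per_type_slopes)
    deterministic = strategy in DETERMINISTIC
    n_draws = 1 if deterministic else n_reps

    rows: list[np.ndarray] = []
    failed = 0
    for rep in range(n_draws):
        rng = derive_rng(seed, strategy, rep)
        sel = strat.select(pop, strategy, scenario, rng=rng, pair=pair)
        res = arrays.evaluate(np.asarray(sel.indices), holdout_only)
        if res is None:
            failed += 1
        else:
            rows.append(res)
    if not rows:
        raise SampleSimError(
            f"all {n_draws} replicate(s) of {strategy} failed to fit"
        )
    stacked = np.stack(rows)  # (n_ok, n_products, 2)
    if deterministic and n_reps > 1:
        stacked = np.repeat(stacked, n_reps, axis=0)
        failed *= n_reps
    return SimulationResult(
        strategy=strategy,
        scenario=scenario,
        products=tuple(products),
        errors={p: stacked[:, j, :] for j, p in enumerate(products)},
        failed_replicates=failed,
        n_replicates=n_reps,
    )


# ---------------------------------------------------------------------------
# full experiment (Tables 2 and 3 shape)


@dataclass
class ExperimentReport:
    """Full comparison across scenarios, strategies and products."""

    summary: dict
    replicates: pd.DataFrame  # tidy per-replicate errors
    head_to_head: dict

    def to_json_dict(self) -> dict:
        return {
            "schema": "samplesim-summary-v1",
            "summary": self.summary,
            "head_to_head": self.head_to_head,
        }


def run_experiment(
    pop: Population,
    scenarios: Mapping[str, Scenario] | Iterable[str] = ("A", "B", "C"),
    strategy_names: Sequence[str] = STRATEGIES,
    n_reps: int = 1000,
    n_batches: int = 10,
    seed: int = 0,
    holdout_only: bool = False,
    per_type_slopes: bool = False,
    products: Sequence[str] = PRODUCTS,
) -> ExperimentReport:
    """Evaluate every scenario x strategy x product cell.

    Random strategies run in ``n_batches`` independent batches of ``n_reps``
    replicates; per-batch summary statistics are averaged for the report and
    their between-batch standard deviation is reported alongside.
    Deterministic strategies are evaluated once per scenario.
    """
    if n_reps < 1 or n_batches < 1:
        raise ValueError("n_reps and n_batches must be >= 1")
    if isinstance(scenarios, Mapping):
        scen_map = dict(scenarios)
    else:
        scen_map = {s: SCENARIOS[s] for s in scenarios}
    strategy_names = [s.upper() for s in strategy_names]
    arrays = _PopArrays(pop, products, per_type_slopes)

    summary: dict = {}
    h2h: dict = {}
    tidy_rows: list[dict] = []
    for scen_name, scenario in scen_map.items():
        summary[scen_name] = {}
        pooled: dict[str, dict[str, np.ndarray]] = {}
        for s in strategy_names:
            deterministic = s in DETERMINISTIC
            n_b = 1 if deterministic else n_batches
            batch_sums: list[dict] = []
            batch_errors: list[dict[str, np.ndarray]] = []
            failed = 0
            for b in range(n_b):
                res = run_replicates(
                    pop,
                    s,
                    scenario,
                    n_reps=1 if deterministic else n_reps,
                    seed=int(derive_rng(seed, scen_name, s, b).integers(2**31)),
                    products=products,
                    holdout_only=holdout_only,
                    per_type_slopes=per_type_slopes,
                    _arrays=arrays,
                )
                batch_sums.append(res.summary())
                batch_errors.append(res.errors)
                failed += res.failed_replicates
                for p in products:
                    for r, (he, ne) in enumerate(res.errors[p]):
                        tidy_rows.append(
                            {
                                "scenario": scen_name,
                                "strategy": s,
                                "product": p,
                                "replicate": r,
                                "batch": b,
                                "hospital_error_pct": float(he),
                                "national_error_pct": float(ne),
                            }
                        )
            pooled[s] = {
                p: np.concatenate([be[p] for be in batch_errors]) for p in products
            }
            cell: dict = {"failed_replicates": failed}
            for p in products:
                cell[p] = {}
                for metric_i, metric in enumerate(METRICS):
                    stats = {
                        k: float(np.mean([bs[p][metric][k] for bs in batch_sums]))
                        for k in ("median", "mean", "centile_2.5", "centile_97.5")
                    }
                    stats["batch_sd_median"] = float(
                        np.std([bs[p][metric]["median"] for bs in batch_sums])
                    )
                    cell[p][metric] = stats
            summary[scen_name][s] = cell

        # Table-3 shape: random strategies vs purposive strategies
        h2h[scen_name] = {}
        randoms = [s for s in strategy_names if s not in DETERMINISTIC]
        purposives = [s for s in strategy_names if s in DETERMINISTIC]
        for rs in randoms:
            h2h[scen_name][rs] = {}
            for ps in purposives:
                h2h[scen_name][rs][ps] = {
                    p: {
                        metric: head_to_head_fraction(
                            pooled[rs][p][:, mi], float(pooled[ps][p][0, mi])
                        )
                        for mi, metric in enumerate(METRICS)
                    }
                    for p in products
                }

    return ExperimentReport(
        summary=summary,
        replicates=pd.DataFrame(tidy_rows),
        head_to_head=h2h,
    )
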