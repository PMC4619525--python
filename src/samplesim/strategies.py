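"""The five stratified hospital selection strategies.

All strategies are stratified by hospital type with a 1:1:1 sample size ratio
across strata (scenarios A/B/C request 4/6/2 hospitals per stratum). Two are
purposive and deterministic:

* ``LARG``  — the largest hospitals (most beds) per stratum.
* ``MAXVAR`` — maximum variation sampling: hospitals at both extremes of the
  RBC count distribution, so the sampled range spans the population range.

Three contain a random element:

* ``RAND``  — simple random sampling without replacement per stratum.
* ``REGVAR`` — regional variation: seats filled round-robin over a random
  permutation of the occupied regions, maximizing the number of distinct
  regions represented per stratum.
* ``2REG``  — (nearly) all hospitals from two regions; the academic stratum
  is whatever academic centres those regions hold (two, or three when the
  dual-academic region is included).

Ties on beds or RBC counts break by ascending hospital id, so the purposive
strategies are pure functions of the population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError, InfeasibleScenarioError
from .population import TYPES, Population

STRATEGIES = ("LARG", "MAXVAR", "RAND", "REGVAR", "2REG")

#: Strategies whose selection is a pure function of the population.
DETERMINISTIC = ("LARG", "MAXVAR")


@dataclass(frozen=True)
class Scenario:
    """Per-stratum sample sizes (1:1:1 across the three hospital types)."""

    per_stratum_n: Mapping[str, int]
    name: str = ""

    def __post_init__(self):
        for t, n in self.per_stratum_n.items():
            if t not in TYPES:
                raise ConfigError(f"unknown stratum {t!r} in scenario")
            if n < 1:
                raise ConfigError(f"scenario size for {t!r} must be >= 1")

    def n(self, stratum: str) -> int:
        return int(self.per_stratum_n[stratum])

    @property
    def total(self) -> int:
        return sum(self.per_stratum_n.values())


#: The three sample-size scenarios: 4/6/2 hospitals per stratum
#: (totals 12, 18 and 6).
SCENARIOS = {
    "A": Scenario({t: 4 for t in TYPES}, name="A"),
    "B": Scenario({t: 6 for t in TYPES}, name="B"),
    "C": Scenario({t: 2 for t in TYPES}, name="C"),
}


@dataclass(frozen=True)
class Selection:
    """The outcome of one strategy realization."""

    strategy: str
    hospital_ids: tuple[str, ...]
    indices: tuple[int, ...]  # positions in population order
    region_pair: tuple[str, str] | None = None
    replicate_index: int = 0
    shortfall: int = 0  # unfilled seats (2REG only, both regions exhausted)

    def __len__(self) -> int:
        return len(self.hospital_ids)


def _check_feasible(pop: Population, scenario: Scenario) -> dict[str, np.ndarray]:
    strata = pop.stratum_indices()
    for t in TYPES:
        n = scenario.n(t)
        if n > len(strata[t]):
            raise InfeasibleScenarioError(t, n, len(strata[t]))
    return strata


def _ordered(pop: Population, idx: np.ndarray, key: np.ndarray, descending: bool):
    """Indices sorted by key then ascending id; stable, reproducible."""
    ids = pop.ids[idx]
    order = np.lexsort((ids, -key[idx] if descending else key[idx]))
    return idx[order]


def _finish(pop, strategy, chosen, **kw) -> Selection:
    chosen = np.asarray(chosen, dtype=int)
    return Selection(
        strategy=strategy,
        hospital_ids=tuple(pop.ids[chosen]),
        indices=tuple(int(i) for i in chosen),
        **kw,
    )


def select_largest(pop: Population, scenario: Scenario) -> Selection:
    """Per stratum, the n hospitals with the most beds (LARG)."""
    strata = _check_feasible(pop, scenario)
    beds = pop.beds.astype(float)
    chosen: list[int] = []
    for t in TYPES:
        ranked = _ordered(pop, strata[t], beds, descending=True)
        chosen.extend(ranked[: scenario.n(t)])
    return _finish(pop, "LARG", chosen)


def select_maxvar(
    pop: Population, scenario: Scenario, high_end_extra: bool = True
) -> Selection:
    """Per stratum, hospitals at both extremes of RBC use (MAXVAR).

    For odd n the extra seat goes to the high end by default
    (``high_end_extra=False`` flips it).
    """
    strata = _check_feasible(pop, scenario)
    rbc = pop.counts("RBC").astype(float)
    chosen: list[int] = []
    for t in TYPES:
        n = scenario.n(t)
        n_high = math.ceil(n / 2) if high_end_extra else n // 2
        high = _ordered(pop, strata[t], rbc, descending=True)[:n_high]
        rest = np.setdiff1d(strata[t], high, assume_unique=True)
        low = _ordered(pop, rest, rbc, descending=False)[: n - n_high]
        chosen.extend(high)
        chosen.extend(low)
    return _finish(pop, "MAXVAR", chosen)


def select_random(
    pop: Population, scenario: Scenario, rng: np.random.Generator
) -> Selection:
    """Per stratum, a simple random sample without replacement (RAND)."""
    strata = _check_feasible(pop, scenario)
    chosen: list[int] = []
    for t in TYPES:
        chosen.extend(rng.choice(strata[t], size=scenario.n(t), replace=False))
    return _finish(pop, "RAND", chosen)


def select_regvar(
    pop: Population, scenario: Scenario, rng: np.random.Generator
) -> Selection:
    """Per stratum, spread seats over as many regions as possible (REGVAR).

    Occupied regions are randomly permuted and seats filled round-robin, one
    uniformly random not-yet-selected hospital per region per pass, so the
    number of distinct regions represented equals min(n, occupied regions).
    """
    _check_feasible(pop, scenario)
    by_region = pop.region_stratum_indices()
    chosen: list[int] = []
    for t in TYPES:
        n = scenario.n(t)
        pools = {r: list(rng.permutation(idx)) for r, idx in by_region[t].items()}
        region_order = list(rng.permutation(np.asarray(list(pools), dtype=object)))
        taken = 0
        while taken < n:
            for r in region_order:
                if taken >= n:
                    break
                if pools[r]:
                    chosen.append(int(pools[r].pop()))
                    taken += 1
    return _finish(pop, "REGVAR", chosen)


def enumerate_region_pairs(regions) -> list[tuple[str, str]]:
    """All unordered distinct region pairs, lexicographically canonical."""
    regions = sorted(set(regions))
    if len(regions) < 2:
        raise ConfigError("at least two regions are required to form pairs")
    return [
        (regions[i], regions[j])
        for i in range(len(regions))
        for j in range(i + 1, len(regions))
    ]


def select_two_regions(
    pop: Population,
    scenario: Scenario,
    pair: tuple[str, str],
    rng: np.random.Generator,
) -> Selection:
    """Sample (nearly) all hospitals from two regions (2REG).

    The academic stratum consists of every academic centre located in the two
    regions — its size is fixed by the regional placement of academic centres,
    not by the scenario. For the teaching and general strata the scenario's n
    is split evenly over the two regions (odd seat to a random region);
    within a region hospitals are drawn uniformly without replacement; seats a
    region cannot fill move to the other region; if both regions jointly hold
    fewer than n, all are taken and the shortfall is recorded.
    """
    r1, r2 = pair
    if r1 == r2:
        raise ConfigError(f"2REG needs two distinct regions, got {r1!r} twice")
    for r in pair:
        if r not in pop.regions:
            raise ConfigError(f"region {r!r} not in the population's region set")
    pair = tuple(sorted(pair))
    by_region = pop.region_stratum_indices()
    chosen: list[int] = []
    shortfall = 0

    chosen.extend(by_region["academic"].get(pair[0], ()))
    chosen.extend(by_region["academic"].get(pair[1], ()))

    for t in ("teaching", "general"):
        n = scenario.n(t)
        pools = [list(by_region[t].get(r, ())) for r in pair]
        share = [n // 2, n // 2]
        if n % 2:
            share[rng.integers(2)] += 1
        picked: list[int] = []
        for k in (0, 1):
            take = min(share[k], len(pools[k]))
            if take:
                picked.extend(rng.choice(pools[k], size=take, replace=False))
        # top up from whichever region still has unselected hospitals
        deficit = n - len(picked)
        if deficit > 0:
            leftovers = [
                i for k in (0, 1) for i in pools[k] if i not in set(picked)
            ]
            take = min(deficit, len(leftovers))
            if take:
                picked.extend(
                    rng.choice(np.asarray(leftovers), size=take, replace=False)
                )
            shortfall += n - len(picked)
        chosen.extend(picked)

    return _finish(
        pop, "2REG", chosen, region_pair=(pair[0], pair[1]), shortfall=shortfall
    )


def select(
    pop: Population,
    strategy: str,
    scenario: Scenario,
    rng: np.random.Generator | None = None,
    pair: tuple[str, str] | None = None,
) -> Selection:
    """Dispatch a strategy by name (``LARG|MAXVAR|RAND|REGVAR|2REG``)."""
    strategy = strategy.upper()
    if strategy == "LARG":
        return select_largest(pop, scenario)
    if strategy == "MAXVAR":
        return select_maxvar(pop, scenario)
    if rng is None:
        raise ConfigError(f"strategy {strategy} needs a random generator")
    if strategy == "RAND":
        return select_random(pop, scenario, rng)
    if strategy == "REGVAR":
        return select_regvar(pop, scenario, rng)
    if strategy == "2REG":
        if pair is None:
            pairs = enumerate_region_pairs(pop.regions)
            pair = pairs[rng.integers(len(pairs))]
        return select_two_regions(pop, scenario, pair, rng)
    raise ConfigError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
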