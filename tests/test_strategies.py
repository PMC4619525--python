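"""Selection strategies: purposive determinism, random sampling behaviour."""

import numpy as np
import pytest

from samplesim import (
    GeneratorConfig,
    InfeasibleScenarioError,
    Scenario,
    enumerate_region_pairs,
    generate_population,
    select,
    select_largest,
    select_maxvar,
    select_random,
    select_regvar,
    select_two_regions,
)
from samplesim.errors import ConfigError
from samplesim.population import TYPES

from conftest import build_population, uniform_stratum

REGIONS = ("Leiden", "Noord-Holland", "Utrecht")


def tiny_pop(academic_rows=None, teaching_rows=None, general_rows=None):
    rows = []
    rows += academic_rows or uniform_stratum("academic", "Noord-Holland", 2)
    rows += teaching_rows or uniform_stratum("teaching", "Leiden", 6)
    rows += general_rows or uniform_stratum("general", "Utrecht", 6)
    return build_population(rows, regions=REGIONS)


def scenario(n_acad=1, n_teach=2, n_gen=2):
    return Scenario({"academic": n_acad, "teaching": n_teach, "general": n_gen})


def stratum_ids(selection, pop, t):
    types = dict(zip(pop.ids, pop.df["type"]))
    return sorted(i for i in selection.hospital_ids if types[i] == t)


class TestLargest:
    def test_selects_most_beds(self):
        beds = [50, 100, 150, 200, 250, 300]
        pop = tiny_pop(general_rows=uniform_stratum("general", "Utrecht", 6, beds=beds))
        sel = select_largest(pop, scenario(n_acad=1, n_teach=1, n_gen=2))
        assert stratum_ids(sel, pop, "general") == ["G05", "G06"]

    def test_tie_breaks_by_ascending_id(self):
        beds = [50, 100, 300, 300, 250, 200]
        pop = tiny_pop(general_rows=uniform_stratum("general", "Utrecht", 6, beds=beds))
        sel = select_largest(pop, scenario(n_acad=1, n_teach=1, n_gen=1))
        assert stratum_ids(sel, pop, "general") == ["G03"]

    def test_n_equal_to_stratum_takes_all(self):
        pop = tiny_pop()
        sel = select_largest(pop, scenario(n_acad=2, n_teach=6, n_gen=6))
        assert len(sel) == 14

    def test_infeasible_scenario_names_stratum(self):
        with pytest.raises(InfeasibleScenarioError, match="academic"):
            select_largest(tiny_pop(), scenario(n_acad=3))


class TestMaxvar:
    RBC = [10, 40, 90, 160, 250, 360]

    def pop(self):
        return tiny_pop(general_rows=uniform_stratum("general", "Utrecht", 6, rbc=self.RBC))

    @pytest.mark.parametrize(
        "n, expected",
        [
            (4, ["G01", "G02", "G05", "G06"]),  # two at each extreme
            (3, ["G01", "G05", "G06"]),  # odd n: extra seat to the high end
            (6, ["G01", "G02", "G03", "G04", "G05", "G06"]),
        ],
    )
    def test_extremes_of_rbc(self, n, expected):
        pop = self.pop()
        sel = select_maxvar(pop, scenario(n_acad=1, n_teach=1, n_gen=n))
        assert stratum_ids(sel, pop, "general") == expected

    def test_low_end_extra_flip(self):
        pop = self.pop()
        sel = select_maxvar(
            pop, scenario(n_acad=1, n_teach=1, n_gen=3), high_end_extra=False
        )
        assert stratum_ids(sel, pop, "general") == ["G01", "G02", "G06"]

    def test_keyed_on_rbc_only(self):
        # FFP/PLT orderings differ from RBC's; selection must follow RBC
        rows = [
            ("G01", "general", "Utrecht", 100, 500, 1, 999),
            ("G02", "general", "Utrecht", 100, 10, 999, 1),
            ("G03", "general", "Utrecht", 100, 200, 500, 500),
        ]
        pop = build_population(
            uniform_stratum("academic", "Noord-Holland", 1)
            + uniform_stratum("teaching", "Leiden", 1)
            + rows,
            regions=REGIONS,
        )
        sel = select_maxvar(pop, scenario(n_acad=1, n_teach=1, n_gen=2))
        assert stratum_ids(sel, pop, "general") == ["G01", "G02"]


class TestRandom:
    def test_whole_stratum_when_n_equals_size(self, rng):
        pop = tiny_pop()
        sel = select_random(pop, scenario(n_acad=2, n_teach=6, n_gen=6), rng)
        assert len(sel) == 14

    def test_same_seed_identical(self):
        pop = tiny_pop()
        sels = [
            select_random(pop, scenario(), np.random.default_rng(5)) for _ in range(2)
        ]
        assert sels[0].hospital_ids == sels[1].hospital_ids

    def test_inclusion_probabilities_uniform(self):
        """SRSWOR inclusion probability is n/N per stratum (3-SE check)."""
        pop = tiny_pop()
        n, N, reps = 3, 6, 4000
        rng = np.random.default_rng(77)
        freq = {f"G{i + 1:02d}": 0 for i in range(6)}
        for _ in range(reps):
            sel = select_random(pop, scenario(n_acad=1, n_teach=1, n_gen=n), rng)
            for h in stratum_ids(sel, pop, "general"):
                freq[h] += 1
        p = n / N
        se = np.sqrt(p * (1 - p) / reps)
        for h, c in freq.items():
            assert abs(c / reps - p) < 3 * se


class TestRegvar:
    def test_covers_all_occupied_regions(self, rng):
        pop = tiny_pop(
            general_rows=uniform_stratum(
                "general", ["Leiden", "Leiden", "Utrecht", "Noord-Holland", "Utrecht", "Leiden"], 6
            )
        )
        sel = select_regvar(pop, scenario(n_acad=1, n_teach=1, n_gen=3), rng)
        regions = set(
            pop.df.set_index("hospital_id").loc[
                stratum_ids(sel, pop, "general"), "region"
            ]
        )
        assert regions == {"Leiden", "Utrecht", "Noord-Holland"}

    def test_n_equals_stratum_takes_all(self, rng):
        pop = tiny_pop()
        sel = select_regvar(pop, scenario(n_acad=1, n_teach=1, n_gen=6), rng)
        assert len(stratum_ids(sel, pop, "general")) == 6

    def test_single_region_degenerate(self, rng):
        pop = tiny_pop()  # general stratum entirely in Utrecht
        sel = select_regvar(pop, scenario(n_acad=1, n_teach=1, n_gen=2), rng)
        ids = stratum_ids(sel, pop, "general")
        assert len(ids) == 2

    def test_coverage_equals_min_of_n_and_occupied(self):
        """Distinct regions represented == min(n, occupied regions), any draw."""
        pop = generate_population(GeneratorConfig(), seed=5)
        by_region = pop.region_stratum_indices()
        rng = np.random.default_rng(9)
        for n in (1, 2, 4, 6):
            sel = select_regvar(pop, Scenario({t: n for t in TYPES}), rng)
            lookup = pop.df.set_index("hospital_id")
            for t in TYPES:
                ids = stratum_ids(sel, pop, t)
                got = len(set(lookup.loc[ids, "region"]))
                assert got == min(n, len(by_region[t]))


class TestRegionPairs:
    def test_seven_regions_give_21_pairs(self):
        pairs = enumerate_region_pairs([f"R{i}" for i in range(7)])
        assert len(pairs) == 21

    def test_two_regions_give_one_pair(self):
        assert enumerate_region_pairs(["B", "A"]) == [("A", "B")]

    @pytest.mark.parametrize("k", [2, 3, 5, 8, 12])
    def test_count_matches_brute_force(self, k):
        regions = [f"R{i}" for i in range(k)]
        pairs = enumerate_region_pairs(regions)
        brute = {
            tuple(sorted((a, b))) for a in regions for b in regions if a != b
        }
        assert set(pairs) == brute
        assert len(pairs) == k * (k - 1) // 2

    def test_fewer_than_two_regions_rejected(self):
        with pytest.raises(ConfigError):
            enumerate_region_pairs(["solo"])


class TestTwoRegions:
    def test_academic_count_follows_regional_placement(self, default_pop, rng):
        sc = scenario(n_acad=4, n_teach=4, n_gen=4)
        with_dual = select_two_regions(
            default_pop, sc, ("Noord-Holland", "Utrecht"), rng
        )
        without = select_two_regions(default_pop, sc, ("Leiden", "Utrecht"), rng)
        assert len(stratum_ids(with_dual, default_pop, "academic")) == 3
        assert len(stratum_ids(without, default_pop, "academic")) == 2

    def test_short_region_tops_up_from_the_other(self, rng):
        general = uniform_stratum(
            "general",
            ["Leiden"] + ["Utrecht"] * 10,
            11,
        )
        pop = tiny_pop(general_rows=general)
        sel = select_two_regions(
            pop, scenario(n_acad=1, n_teach=1, n_gen=4), ("Leiden", "Utrecht"), rng
        )
        ids = stratum_ids(sel, pop, "general")
        regions = pop.df.set_index("hospital_id").loc[ids, "region"]
        assert len(ids) == 4
        assert (regions == "Leiden").sum() == 1
        assert (regions == "Utrecht").sum() == 3

    def test_joint_shortfall_recorded(self, rng):
        pop = tiny_pop(general_rows=uniform_stratum("general", "Utrecht", 3))
        sel = select_two_regions(
            pop, scenario(n_acad=1, n_teach=1, n_gen=5), ("Leiden", "Utrecht"), rng
        )
        assert len(stratum_ids(sel, pop, "general")) == 3
        assert sel.shortfall == 2

    def test_identical_regions_rejected(self, default_pop, rng):
        with pytest.raises(ConfigError):
            select_two_regions(default_pop, scenario(), ("Utrecht", "Utrecht"), rng)

    def test_unknown_region_rejected(self, default_pop, rng):
        with pytest.raises(ConfigError):
            select_two_regions(default_pop, scenario(), ("Utrecht", "Atlantis"), rng)


class TestSelectionInvariants:
    """Fuzzed populations: every strategy yields a valid Selection."""

    @pytest.mark.parametrize("fuzz_seed", range(25))
    def test_fuzzed_populations(self, fuzz_seed):
        rng = np.random.default_rng(800 + fuzz_seed)
        cfg = GeneratorConfig(
            stratum_sizes={
                "academic": int(rng.integers(2, 9)),
                "teaching": int(rng.integers(4, 20)),
                "general": int(rng.integers(4, 30)),
            },
            latent_sd=float(rng.uniform(0, 0.5)),
        )
        pop = generate_population(cfg, seed=int(rng.integers(2**31)))
        nmax = min(cfg.stratum_sizes.values())
        n = int(rng.integers(1, nmax + 1))
        sc = Scenario({t: n for t in TYPES})
        lookup = dict(zip(pop.ids, pop.df["type"]))
        for strat in ("LARG", "MAXVAR", "RAND", "REGVAR"):
            sel = select(pop, strat, sc, rng=rng)
            assert set(sel.hospital_ids) <= set(pop.ids)
            assert len(set(sel.hospital_ids)) == len(sel.hospital_ids)
            for t in TYPES:
                assert sum(lookup[i] == t for i in sel.hospital_ids) == n

    def test_purposive_strategies_ignore_rng(self, default_pop):
        sc = scenario(n_acad=4, n_teach=4, n_gen=4)
        for strat, fn in (("LARG", select_largest), ("MAXVAR", select_maxvar)):
            a = fn(default_pop, sc)
            b = fn(default_pop, sc)
            via_dispatch = select(
                default_pop, strat, sc, rng=np.random.default_rng(999)
            )
            assert a.hospital_ids == b.hospital_ids == via_dispatch.hospital_ids
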