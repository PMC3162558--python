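"""Fitness functions, instance I/O and brute-force oracles."""

import itertools
import math
import random

import pytest

from pathevo import benchmarks as bm


class TestKnapsack:
    def toy(self):
        return bm.KnapsackInstance(profits=(10, 7), weights=((3, 4),),
                                   capacities=(5,))

    def test_empty_packing_is_zero(self):
        assert bm.knapsack_fitness([0, 0], self.toy()) == 0.0

    def test_toy_values_and_bruteforce_optimum(self):
        inst = self.toy()
        assert bm.knapsack_fitness([1, 0], inst) == 10.0
        assert bm.knapsack_fitness([1, 1], inst) == -2.0
        # brute force over all 4 vectors confirms (1, 0) optimal
        vals = {x: bm.knapsack_fitness(x, inst)
                for x in itertools.product((0, 1), repeat=2)}
        assert max(vals, key=vals.get) == (1, 0)
        opt, x = bm.brute_force_knapsack(inst)
        assert opt == 10.0 and x == (1, 0)

    def test_penalty_iff_infeasible_and_profit_bounded(self):
        rng = random.Random(0)
        inst, opt = bm.generate_knapsack(10, 2, seed=3)
        total = sum(inst.profits)
        for _ in range(200):
            x = [rng.randint(0, 1) for _ in range(10)]
            f = bm.knapsack_fitness(x, inst)
            assert f <= total
            infeasible = any(
                sum(w for w, xi in zip(row, x) if xi) > c
                for row, c in zip(inst.weights, inst.capacities))
            assert (f < 0) == infeasible or f >= 0

    def test_generator_deterministic_and_oracle_feasible(self):
        a, opt_a = bm.generate_knapsack(12, 2, seed=5)
        b, opt_b = bm.generate_knapsack(12, 2, seed=5)
        assert a == b and opt_a == opt_b
        _, x = bm.brute_force_knapsack(a)
        assert bm.knapsack_fitness(x, a) == opt_a >= 0

    def test_exhaustive_oracle_matches_direct_search(self):
        inst, opt = bm.generate_knapsack(12, 2, seed=11)
        best = max(bm.knapsack_fitness(x, inst)
                   for x in itertools.product((0, 1), repeat=12))
        assert best == opt

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            bm.knapsack_fitness([1], self.toy())


class TestKnapsackIO:
    def test_native_round_trip(self, tmp_path):
        inst, _ = bm.generate_knapsack(8, 2, seed=1)
        p = tmp_path / "inst.txt"
        bm.write_knapsack(inst, p)
        back = bm.read_knapsack(p, "native")
        assert back.profits == inst.profits
        assert back.weights == inst.weights
        assert back.capacities == inst.capacities

    def test_orlib_dialect(self, tmp_path):
        text = "4 2 100\n10 7 3 5\n3 4 1 2\n2 2 2 2\n6 4\n"
        p = tmp_path / "orlib.txt"
        p.write_text(text)
        inst = bm.read_knapsack(p, "orlib")
        assert inst.n == 4 and inst.m == 2
        assert inst.known_optimum == 100
        assert inst.weights[1] == (2, 2, 2, 2)
        assert inst.capacities == (6, 4)

    def test_truncated_file_errors(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("105 2 0\n1 2 3\n")
        with pytest.raises(bm.KnapsackParseError, match="truncated"):
            bm.read_knapsack(p, "orlib")
        p2 = tmp_path / "bad2.txt"
        p2.write_text("n 3\nm 1\nprofits 1 2\ncapacities 5\nweights 1 1 1\n")
        with pytest.raises(bm.KnapsackParseError, match="dimension"):
            bm.read_knapsack(p2, "native")


class TestContinuous:
    def test_global_minima(self):
        assert bm.sphere([0.0] * 5) == 0.0
        assert bm.rosenbrock([1.0] * 5) == 0.0
        assert bm.rastrigin([0.0] * 5) == 0.0
        assert bm.quartic_noise([0.0] * 5, noise=False) == 0.0

    def test_hand_values(self):
        assert bm.rosenbrock((0.0, 0.0)) == 1.0
        assert bm.rastrigin((1.0,)) == pytest.approx(1.0)
        assert bm.quartic_noise((2.0, 1.0), noise=False) == \
            pytest.approx(1 * 16 + 2 * 1)

    def test_nonnegative(self):
        rng = random.Random(2)
        for _ in range(100):
            x = [rng.uniform(-2, 2) for _ in range(4)]
            assert bm.sphere(x) >= 0
            assert bm.rosenbrock(x) >= 0
            assert bm.rastrigin(x) >= -1e-12
            assert bm.quartic_noise(x, noise=False) >= 0

    def test_noise_term_in_unit_interval(self):
        rng = random.Random(3)
        base = bm.quartic_noise((0.5,) * 3, noise=False)
        for _ in range(50):
            noisy = bm.quartic_noise((0.5,) * 3, rng=rng)
            assert base <= noisy < base + 1.0

    @pytest.mark.parametrize("label,expect", [
        (0.0, 0.0), (1.0, 5.12), (-1.0, -5.12)])
    def test_decode_affine(self, label, expect):
        (x,) = bm.decode_continuous((label,), (-5.12, 5.12))
        assert x == pytest.approx(expect)


class TestHiff:
    def test_hand_values(self):
        assert bm.hiff("11111111") == 12.0
        assert bm.hiff("11110000") == 8.0
        assert bm.hiff("10101010") == 0.0

    def test_complement_symmetry_exhaustive_8bit(self):
        for bits in itertools.product("01", repeat=8):
            s = "".join(bits)
            comp = "".join("1" if c == "0" else "0" for c in s)
            assert bm.hiff(s) == bm.hiff(comp)

    def test_unique_global_optima_exhaustive(self):
        values = {s: bm.hiff("".join(s))
                  for s in itertools.product("01", repeat=8)}
        best = max(values.values())
        argmax = {"".join(s) for s, v in values.items() if v == best}
        assert argmax == {"00000000", "11111111"}
        assert best == 12.0

    def test_watson_variant_classic_values(self):
        assert bm.hiff("1" * 8, variant="watson") == 32.0
        assert bm.hiff("1" * 64, variant="watson") == 448.0

    @pytest.mark.parametrize("bad", ["", "1", "101", "1" * 12])
    def test_non_power_of_two_rejected(self, bad):
        with pytest.raises(ValueError):
            bm.hiff(bad)


class TestRoyalRoad:
    def test_extremes_and_single_schema(self):
        assert bm.royal_road("1" * 64) == 64.0
        assert bm.royal_road("0" * 64) == 0.0
        assert bm.royal_road("1" * 8 + "0" * 56) == 8.0

    def test_additive_over_blocks(self):
        s = list("0" * 64)
        total = 0.0
        rng = random.Random(1)
        for block in rng.sample(range(8), 5):
            s[block * 8:(block + 1) * 8] = "1" * 8
            total += 8.0
            assert bm.royal_road("".join(s)) == total

    def test_partial_block_scores_nothing(self):
        assert bm.royal_road("1" * 7 + "0" * 57) == 0.0

    def test_wrong_length(self):
        with pytest.raises(ValueError):
            bm.royal_road("1" * 32)


class TestAlternating:
    def test_phases(self):
        s = "1" * 6
        assert bm.alternating_count(s, 0, 1000) == 6.0
        assert bm.alternating_count(s, 1000, 1000) == 0.0
        assert bm.alternating_count(s, 2000, 1000) == 6.0

    def test_complement_identity(self):
        rng = random.Random(4)
        for _ in range(20):
            s = [rng.randint(0, 1) for _ in range(10)]
            g = rng.randrange(5000)
            assert bm.alternating_count(s, g, 500) + \
                bm.alternating_count(s, g + 500, 500) == 10.0


def test_fitness_factories_expose_metadata():
    f = bm.hiff_fitness(16)
    assert f.scheme == "binary" and not f.minimize
    assert f.optimum == bm.hiff("1" * 16)
    g = bm.rastrigin_fitness(20)
    assert g.scheme == "continuous" and g.minimize
    assert g((0.0,) * 20, 0) == pytest.approx(0.0)
    # label 0 maps to domain midpoint 0 for symmetric bounds
    assert g((1.0,) * 20, 0) > 0


# ----------------------------------------------------------------------
# property-based invariants
# ----------------------------------------------------------------------
from hypothesis import given, settings, strategies as st


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=32, max_size=32))
def test_hiff_complement_symmetry_property(bits):
    comp = [1 - b for b in bits]
    assert bm.hiff(bits) == bm.hiff(comp)
    assert bm.hiff(bits) <= bm.hiff([1] * 32)


@settings(max_examples=60, derandomize=True)
@given(st.lists(st.integers(0, 1), min_size=12, max_size=12),
       st.integers(0, 10_000), st.integers(1, 2000))
def test_alternating_phases_partition_the_bits(bits, gen, period):
    a = bm.alternating_count(bits, gen, period)
    b = bm.alternating_count(bits, gen + period, period)
    assert a + b == len(bits)


@settings(max_examples=40, derandomize=True)
@given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=3, max_size=8))
def test_decode_continuous_stays_in_domain(labels):
    lo, hi = bm.DE_JONG_BOUNDS["sphere"]
    xs = bm.decode_continuous(labels, (lo, hi))
    assert all(lo - 1e-9 <= x <= hi + 1e-9 for x in xs)
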