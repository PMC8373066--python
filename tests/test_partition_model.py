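"""Partition-function predictions, singularity lengths, duplex yield."""

import math

import numpy as np
import pandas as pd
import pytest

from slidebulge.energy_tables import EnergyTable
from slidebulge.motif_model import BASES, BulgeMotif, parse_motif
from slidebulge.partition_model import (
    R,
    duplex_dg_and_yield,
    mean_ddg_summary,
    predict_ddg,
    predict_ddg_enumerated,
    rt,
    singularity_length,
)

RT37 = rt(37.0)


def tables_with(g2: float, gt: float) -> dict:
    """Table set where every two-slide entry is g2 and every triplet gt."""
    grid = [25.0, 67.0]
    two_keys = [
        f"{f5.lower()}{b}{b}{f3.lower()}"
        for b in BASES
        for f5 in BASES
        if f5 != b
        for f3 in BASES
        if f3 != b
    ]
    trip_keys = [f"{b.lower()}{b}{b.lower()}" for b in BASES]
    two = pd.DataFrame([[g2, g2]] * len(two_keys), index=two_keys, columns=grid)
    trip = pd.DataFrame([[gt, gt]] * len(trip_keys), index=trip_keys, columns=grid)
    return {
        "two_slide": EnergyTable("two_slide", two),
        "triplet": EnergyTable("triplet", trip),
    }


class TestPredictDdg:
    def test_constants(self):
        assert R == pytest.approx(1.9872e-3, rel=0, abs=0)
        assert RT37 == pytest.approx(1.9872e-3 * 310.15, abs=1e-12)

    def test_two_slide_is_a_pure_lookup(self, param_set):
        motif = parse_motif("cT2c")
        expected = param_set.two_slide.ddg_at("cTTc", 37.0)
        result = predict_ddg(motif, param_set, 37.0)
        assert result.ddg == expected
        assert result.Z == pytest.approx(math.exp(-expected / RT37), rel=1e-12)

    def test_non_slide_is_a_pure_lookup(self, param_set):
        motif = parse_motif("aTc")
        assert predict_ddg(motif, param_set, 37.0).ddg == param_set.non_slide.ddg_at(
            "aTc", 37.0
        )

    def test_equal_energy_states_reduce_to_g_minus_rt_ln_degeneracy(self):
        g = 2.0
        tables = tables_with(g, g)
        for n in (3, 5, 20):
            result = predict_ddg(parse_motif(f"cT{n}c"), tables, 37.0)
            assert result.ddg == pytest.approx(g - RT37 * math.log(n - 1), abs=1e-12)

    def test_closed_form_value_by_hand(self):
        # g2 = 2.0, gt = 3.0 kcal/mol at 37 degC, n = 10:
        # ddG = -RT ln(exp(-2/RT) + 8 exp(-3/RT)), evaluated independently
        tables = tables_with(2.0, 3.0)
        result = predict_ddg(parse_motif("cT10c"), tables, 37.0)
        assert result.ddg == pytest.approx(1.41603400854568, abs=1e-9)
        assert sum(result.occupancies) == pytest.approx(1.0, abs=1e-12)
        assert result.ddg == pytest.approx(-RT37 * math.log(result.Z), abs=1e-12)

    def test_missing_entry_raises(self, param_set):
        from slidebulge.energy_tables import TableError

        with pytest.raises(TableError):
            predict_ddg(parse_motif("cT10c"), {"two_slide": param_set.two_slide}, 37.0)


class TestEnumeratedOracle:
    def test_single_state_returns_its_energy(self):
        assert predict_ddg_enumerated(
            parse_motif("aTc"), {"aTc": 2.31}, 37.0
        ) == pytest.approx(2.31, abs=1e-12)

    def test_uniform_states(self):
        motif = parse_motif("cT7c")
        got = predict_ddg_enumerated(motif, {"cTt": 1.5, "tTc": 1.5, "tTt": 1.5}, 37.0)
        assert got == pytest.approx(1.5 - RT37 * math.log(7), abs=1e-12)

    def test_agrees_with_closed_form_over_random_draws(self, rng):
        """Closed form vs explicit state enumeration, 1000 random draws."""
        for _ in range(1000):
            n = int(rng.integers(3, 51))
            t = float(rng.uniform(25, 67))
            RT = rt(t)
            e1, e2, gt = rng.uniform(0.2, 5.0, size=3)
            # composite two-slide value implied by the two terminal states
            g2 = -RT * math.log(math.exp(-e1 / RT) + math.exp(-e2 / RT))
            tables = tables_with(g2, gt)
            motif = parse_motif(f"cT{n}c")
            closed = predict_ddg(motif, tables, t).ddg
            enumerated = predict_ddg_enumerated(
                motif, {"cTt": e1, "tTc": e2, "tTt": gt}, t
            )
            assert abs(closed - enumerated) < 1e-9

    def test_numerically_stable_at_extreme_energies(self):
        motif = parse_motif("cT30c")
        for e in (-50.0, 50.0):
            val = predict_ddg_enumerated(motif, {"cTt": e, "tTc": e, "tTt": e}, 37.0)
            assert math.isfinite(val)
        tables = tables_with(-50.0, 50.0)
        assert math.isfinite(predict_ddg(motif, tables, 37.0).ddg)

    def test_missing_state_energy(self):
        from slidebulge.motif_model import MotifError

        with pytest.raises(MotifError):
            predict_ddg_enumerated(parse_motif("cT3c"), {"cTt": 1.0, "tTc": 1.0}, 37.0)


class TestEnsembleProperties:
    def test_strictly_decreasing_in_length(self, rng):
        for _ in range(200):
            g2, gt = rng.uniform(0.2, 5.0, size=2)
            tables = tables_with(g2, gt)
            t = float(rng.uniform(25, 67))
            values = [
                predict_ddg(parse_motif(f"cT{n}c"), tables, t).ddg
                for n in range(2, 12)
            ]
            assert all(a > b for a, b in zip(values, values[1:]))

    def test_two_slide_composite_below_both_state_energies(self, rng):
        for _ in range(200):
            e1, e2 = rng.uniform(0.2, 5.0, size=2)
            t = float(rng.uniform(25, 67))
            RT = rt(t)
            g2 = -RT * math.log(math.exp(-e1 / RT) + math.exp(-e2 / RT))
            assert g2 < min(e1, e2)

    def test_occupancies_are_a_distribution(self, param_set, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            base = rng.choice(list(BASES))
            flanks = [b for b in BASES if b != base]
            motif = BulgeMotif(
                rng.choice(flanks), base, rng.choice(flanks), n
            )
            res = predict_ddg(motif, param_set, float(rng.uniform(25, 67)))
            assert all(o >= 0 for o in res.occupancies)
            assert sum(res.occupancies) == pytest.approx(1.0, abs=1e-12)
            assert res.ddg == pytest.approx(
                -rt(res.temperature_C) * math.log(res.Z), abs=1e-12
            )


class TestSingularity:
    def test_already_stable_two_slide(self):
        tables = tables_with(-0.5, 3.0)
        assert singularity_length("T", "C", "C", tables, 37.0) == 2

    def test_zero_triplet_weight_never_stabilizes(self):
        # approximate an infinite triplet penalty; weight underflows to 0
        tables = tables_with(1.0, 1e4)
        assert singularity_length("T", "C", "C", tables, 37.0, n_max=10**6) is None

    def test_formula_matches_scan_for_moderate_cases(self):
        tables = tables_with(2.0, 3.0)
        by_formula = singularity_length("T", "C", "C", tables, 37.0, n_max=10**5)
        by_scan = singularity_length(
            "T", "C", "C", tables, 37.0, n_max=10**5, method="scan"
        )
        assert by_formula == by_scan is not None

    def test_formula_matches_scan_on_random_draws(self, rng):
        """1000 random parameter draws; the incremental scan is the oracle."""
        agree = 0
        for _ in range(1000):
            g2 = float(rng.uniform(-0.5, 2.0))
            gt = float(rng.uniform(0.0, 2.5))
            t = float(rng.uniform(25, 67))
            tables = tables_with(g2, gt)
            f = singularity_length("T", "C", "C", tables, t, n_max=3000)
            s = singularity_length("T", "C", "C", tables, t, n_max=3000, method="scan")
            assert f == s
            agree += 1
        assert agree == 1000

    def test_exact_zero_counts_as_stable(self):
        # choose gt so that Z reaches exactly 1 at an integer length
        RT = RT37
        w2 = 0.5
        g2 = -RT * math.log(w2)
        wt = 0.125  # (1 - w2)/wt = 4 exactly
        gt = -RT * math.log(wt)
        tables = tables_with(g2, gt)
        assert singularity_length("T", "C", "C", tables, 37.0) == 6


class TestMeanSummary:
    def test_mean_over_nine_flank_contexts(self, param_set):
        got = mean_ddg_summary("A", 10, param_set, 37.0)
        flanks = [b for b in BASES if b != "A"]
        manual = np.mean(
            [
                predict_ddg(BulgeMotif(f5, "A", f3, 10), param_set, 37.0).ddg
                for f5 in flanks
                for f3 in flanks
            ]
        )
        assert got == pytest.approx(manual, abs=1e-12)

    def test_uniform_tables_give_the_common_value(self):
        tables = tables_with(2.0, 3.0)
        expected = predict_ddg(parse_motif("cT10c"), tables, 37.0).ddg
        assert mean_ddg_summary("T", 10, tables, 37.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_n2_is_the_mean_of_table_entries(self, param_set):
        flanks = [b for b in BASES if b != "G"]
        manual = np.mean(
            [
                param_set.two_slide.ddg_at(f"{f5.lower()}GG{f3.lower()}", 37.0)
                for f5 in flanks
                for f3 in flanks
            ]
        )
        assert mean_ddg_summary("G", 2, param_set, 37.0) == pytest.approx(
            manual, abs=1e-12
        )


class TestDuplexYield:
    def test_zero_bulge_penalty_recovers_the_canonical_duplex(self):
        stacks = [-1.2, -1.4, -1.1]
        res = duplex_dg_and_yield(stacks, 1.96, 0.0, 37.0, 1e-7, 1e-7)
        assert res.dg_duplex == pytest.approx(sum(stacks) + 1.96, abs=1e-12)

    def test_strong_binding_limit_saturates_the_limiting_species(self):
        res = duplex_dg_and_yield([-30.0], 0.0, 0.0, 37.0, 20e-9, 40e-9)
        assert res.bound_fraction == pytest.approx(1.0, abs=1e-6)
        assert res.duplex_conc == pytest.approx(20e-9, rel=1e-6)

    def test_quadratic_root_matches_fixed_point_iteration(self):
        # K = 1e9 / M, both totals 20 nM
        RT = RT37
        dg = -RT * math.log(1e9)
        res = duplex_dg_and_yield([dg], 0.0, 0.0, 37.0, 20e-9, 20e-9)
        # convergent rearrangement of x = K (A0 - x)(B0 - x)
        k, a0, b0 = 1e9, 20e-9, 20e-9
        q = k * (a0 + b0) + 1.0
        x = 0.0
        for _ in range(400):
            x = (k * x * x + k * a0 * b0) / q
        assert res.duplex_conc == pytest.approx(x, rel=1e-9)
        assert 0 < res.bound_fraction < 1

    def test_bulge_penalty_lowers_the_yield(self):
        base = duplex_dg_and_yield([-12.0], 0.0, 0.0, 37.0, 20e-9, 20e-9)
        bulged = duplex_dg_and_yield([-12.0], 0.0, 2.0, 37.0, 20e-9, 20e-9)
        assert bulged.dg_duplex == pytest.approx(base.dg_duplex + 2.0, abs=1e-12)
        assert bulged.bound_fraction < base.bound_fraction

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            duplex_dg_and_yield([math.nan], 0.0, 0.0, 37.0, 1e-8, 1e-8)
        with pytest.raises(ValueError):
            duplex_dg_and_yield([-10.0], 0.0, 0.0, 37.0, 0.0, 1e-8)
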