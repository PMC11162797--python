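"""Reaction-network tests: stoichiometric conservation, analytic limits,
quasi-steady-state consistency and the 2AI-suppression calibration."""

import math

import numpy as np
import pytest

from primex.network import (
    RateConstants,
    SpeciesState,
    build_network,
    calibrate_k_rev,
    half_life,
    simulate,
    steady_state_bridged,
)

TIMES_100H = np.linspace(0.0, 100.0, 51)


def nucleotide_unit_vector(names):
    """Left-null-vector weights of the stoichiometric matrix for the
    nucleotide-unit total."""
    w = {"activated_mono": 1, "bridged": 2, "nmp": 1, "two_ai": 0, "primer": 0}
    for n in names:
        if n.startswith("ext"):
            w[n] = int(n[3:])
    return w


class TestBuildNetwork:
    def test_six_reactions_for_single_extension_chain(self):
        rxns = build_network(RateConstants(), n_extended=1)
        assert len(rxns) == 6

    def test_nucleotide_units_conserved_by_every_reaction(self):
        rxns = build_network(RateConstants(), n_extended=3)
        names = ["activated_mono", "bridged", "nmp", "two_ai", "primer"] + [
            f"ext{k}" for k in (1, 2, 3)
        ]
        w = nucleotide_unit_vector(names)
        for r in rxns:
            assert sum(w[s] * d for s, d in r.stoichiometry.items()) == 0, r.name

    def test_ai_units_conserved_by_every_reaction(self):
        w = {"activated_mono": 1, "bridged": 1, "two_ai": 1}
        for r in build_network(RateConstants(), n_extended=2):
            assert sum(w.get(s, 0) * d for s, d in r.stoichiometry.items()) == 0

    def test_negative_constant_rejected(self):
        with pytest.raises(ValueError):
            RateConstants(k_form=-1.0)


class TestSimulate:
    def test_all_zero_rates_freeze_the_state(self):
        rc = RateConstants(0, 0, 0, 0, 0, 0)
        s0 = SpeciesState(activated_mono=5.0, bridged=3.0, nmp=1.0, two_ai=2.0)
        df = simulate(rc, s0, np.linspace(0, 50, 11))
        for col, v0 in [("activated_mono", 5.0), ("bridged", 3.0), ("nmp", 1.0)]:
            assert np.allclose(df[col], v0, rtol=0, atol=1e-12)

    def test_pure_bridged_hydrolysis_matches_analytic_exponential(self):
        k = 0.105
        rc = RateConstants(0, 0, k, 0, 0, 0)
        t_half = math.log(2) / k
        times = np.array([0.0, 1.0, 3.0, t_half, 20.0, 52.0])
        df = simulate(rc, SpeciesState(bridged=20.0), times)
        assert np.allclose(df["bridged"], 20.0 * np.exp(-k * times), rtol=1e-8)
        at_half = df.loc[np.isclose(df["time"], t_half), "bridged"].iloc[0]
        assert at_half == pytest.approx(10.0, rel=1e-6)

    def test_bridged_rises_to_plateau_from_activated_monomer(self):
        # 20 mM *N start: bridged rises to a 2-5 mM peak then declines
        df = simulate(
            RateConstants(),
            SpeciesState(activated_mono=20.0, primer=1e-3),
            np.linspace(0, 52, 105),
        )
        peak = df["bridged"].max()
        assert 2.0 < peak < 5.0
        assert df["bridged"].iloc[-1] < peak

    def test_excess_2ai_suppresses_bridged_below_quarter_mm(self):
        df = simulate(
            RateConstants(),
            SpeciesState(activated_mono=20.0, two_ai=100.0),
            np.linspace(0, 52, 105),
        )
        assert df["bridged"].max() < 0.25 + 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_conservation_and_positivity_random_constants(self, seed):
        rng = np.random.default_rng(seed)
        rc = RateConstants(*rng.uniform(0, 0.2, size=6))
        s0 = SpeciesState(
            activated_mono=rng.uniform(0, 20),
            bridged=rng.uniform(0, 10),
            nmp=rng.uniform(0, 5),
            two_ai=rng.uniform(0, 50),
            primer=rng.uniform(0, 0.01),
        )
        df = simulate(rc, s0, TIMES_100H)
        units0 = s0.nucleotide_units()
        ai0 = s0.ai_units()
        for _, row in df.iterrows():
            ext = sum(
                int(c[3:]) * row[c] for c in df.columns if c.startswith("ext")
            )
            units = row["activated_mono"] + 2 * row["bridged"] + row["nmp"] + ext
            ai = row["two_ai"] + row["activated_mono"] + row["bridged"]
            assert abs(units - units0) / units0 < 1e-9
            assert abs(ai - ai0) / max(ai0, 1e-12) < 1e-9
        assert (df.drop(columns="time") >= -1e-12).all().all()

    def test_bad_time_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate(RateConstants(), SpeciesState(bridged=1.0), [1.0, 2.0])


class TestSteadyState:
    def test_zero_formation_gives_zero(self):
        assert steady_state_bridged(RateConstants(k_form=0.0), 20.0) == 0.0

    def test_detailed_balance_without_hydrolysis(self):
        rc = RateConstants(
            k_form=4.5e-3, k_rev=0.05, k_hyd_bridged=0.0, k_hyd_mono=0.0,
            k_ext_bridged=0.0, k_ext_mono=0.0,
        )
        total, added = 20.0, 5.0
        b = steady_state_bridged(rc, total, added)
        s = total - 2 * b
        assert rc.k_form * s * s == pytest.approx(
            rc.k_rev * b * (added + b), rel=1e-9
        )

    def test_equilibrium_matches_long_time_simulation_without_hydrolysis(self):
        rc = RateConstants(
            k_form=4.5e-3, k_rev=0.05, k_hyd_bridged=0.0, k_hyd_mono=0.0,
            k_ext_bridged=0.0, k_ext_mono=0.0,
        )
        b = steady_state_bridged(rc, 20.0)
        df = simulate(rc, SpeciesState(activated_mono=20.0), np.linspace(0, 2000, 21))
        assert abs(df["bridged"].iloc[-1] - b) < 1e-6

    def test_quasi_steady_root_near_simulated_peak_with_hydrolysis(self):
        rc = RateConstants()
        b = steady_state_bridged(rc, 20.0)
        df = simulate(
            rc, SpeciesState(activated_mono=20.0), np.linspace(0, 52, 209)
        )
        # hydrolysis drains the pool before the peak, so agreement is loose
        assert df["bridged"].max() == pytest.approx(b, rel=0.2)

    def test_monotone_in_added_2ai_and_k_rev(self):
        rc = RateConstants()
        vals = [steady_state_bridged(rc, 20.0, a) for a in (0, 10, 50, 100, 300)]
        assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))
        vals_k = [
            steady_state_bridged(RateConstants(k_rev=k), 20.0, 10.0)
            for k in (0.01, 0.05, 0.1, 0.5)
        ]
        assert all(x >= y - 1e-12 for x, y in zip(vals_k, vals_k[1:]))


class TestCalibration:
    def test_calibrated_k_rev_sits_on_the_suppression_bound(self):
        k_rev = calibrate_k_rev(RateConstants())
        assert k_rev == pytest.approx(0.0668, rel=0.02)


class TestHalfLife:
    def test_ln2_rate_gives_unit_half_life(self):
        assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-12)

    def test_bridged_hydrolysis_half_life_rounds_to_7h(self):
        hl = half_life(0.105)
        assert hl == pytest.approx(6.60, abs=0.005)
        assert round(hl) == 7

    def test_activated_monomer_half_life_about_350h(self):
        assert half_life(1.96e-3) == pytest.approx(354, abs=1)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)
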