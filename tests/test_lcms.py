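"""LC-MS matching and quantification tests: candidate enumeration counts,
ppm-window assignment, mass-ladder discrimination, normalization, site
reactivity, and full pipeline recovery on synthetic compound lists."""

import itertools

import numpy as np
import pytest

from conftest import SEED
from primex.chemistry import (
    SODIUM_ADDUCT_MASS,
    Base,
    NucleotideSpec,
    Sugar,
    oligomer_mass,
)
from primex.lcms import (
    CompoundRecord,
    composition_pipeline,
    enumerate_candidates,
    incorporation_percentages,
    match,
    site_reactivity,
)
from primex.synth import (
    competition_monomers,
    gen_compound_list,
)

MONOMERS = competition_monomers()


def rec(mass, abundance=100.0, rep="rep1", rt=5.0):
    return CompoundRecord(mass, rt, abundance, rep)


class TestEnumerateCandidates:
    def test_counts_terminal_only_primer(self, terminal_only_primer):
        c1 = enumerate_candidates(terminal_only_primer, MONOMERS, 1,
                                  include_primer=False)
        assert len(c1) == 3
        c2 = enumerate_candidates(terminal_only_primer, MONOMERS, 2,
                                  include_primer=False)
        assert len(c2) == 12  # 3 + 9, no internal-branch candidates

    def test_rna_primer_adds_internal_branch_candidates(self, rna6_primer):
        cands = enumerate_candidates(rna6_primer, MONOMERS, 1,
                                     include_primer=False)
        assert len(cands) == 6  # 3 terminal + 3 internal branch
        by_class = {c.site_class for c in cands}
        assert by_class == {"terminal", "internal_branch"}
        # branch candidates are isobaric with their terminal partners
        for c in cands:
            partner = [
                d for d in cands
                if d.terminal_sugar == c.terminal_sugar and d is not c
            ]
            assert partner and partner[0].neutral_mass == pytest.approx(
                c.neutral_mass, abs=1e-9
            )

    def test_candidate_masses_are_consistent_with_mass_engine(self, rna6_primer):
        for c in enumerate_candidates(rna6_primer, MONOMERS, 2):
            assert c.neutral_mass == pytest.approx(
                oligomer_mass(c.oligomer), abs=1e-4
            )

    def test_isobar_safety_of_labeling_strategy(self, rna6_primer):
        """No two +1 candidates with different sugars within 5 ppm below
        3200 Da — the separation the isotope labels exist to guarantee."""
        cands = [
            c
            for c in enumerate_candidates(rna6_primer, MONOMERS, 1,
                                          include_primer=False)
            if c.neutral_mass < 3200
        ]
        for a, b in itertools.combinations(cands, 2):
            if a.terminal_sugar == b.terminal_sugar:
                continue
            ppm = abs(a.neutral_mass - b.neutral_mass) / a.neutral_mass * 1e6
            assert ppm > 5.0


class TestMatch:
    @pytest.fixture
    def plus1(self, terminal_only_primer):
        return enumerate_candidates(terminal_only_primer, MONOMERS, 1)

    def test_exact_mass_matches_with_zero_ppm(self, plus1):
        target = plus1[1]
        mt = match([rec(target.neutral_mass)], plus1)
        assert len(mt.matches) == 1
        assert mt.matches[0].ppm_error == 0.0
        assert mt.matches[0].n_sodium == 0

    def test_twenty_ppm_off_is_unmatched_at_ten_ppm(self, plus1):
        target = plus1[1]
        mt = match([rec(target.neutral_mass * (1 + 20e-6))], plus1, tol_ppm=10)
        assert not mt.matches and len(mt.unmatched) == 1

    def test_ch2_shift_reassigns_to_threo_candidate(self, terminal_only_primer):
        # unlabeled monomers: tC-terminal +1 sits exactly CH2 below rC's
        unlabeled = [
            NucleotideSpec(Base.C, Sugar.ribo),
            NucleotideSpec(Base.C, Sugar.threo),
        ]
        cands = enumerate_candidates(terminal_only_primer, unlabeled, 1)
        ribo = next(c for c in cands if c.terminal_sugar == "ribo")
        mt = match([rec(ribo.neutral_mass - 14.0157)], cands)
        assert len(mt.matches) == 1
        assert mt.matches[0].candidate.terminal_sugar == "threo"

    def test_sodium_adduct_recognized(self, plus1):
        ara = next(c for c in plus1 if c.terminal_sugar == "arabino")
        mt = match([rec(ara.neutral_mass + 2 * SODIUM_ADDUCT_MASS)], plus1)
        assert mt.matches[0].n_sodium == 2
        assert mt.matches[0].candidate.terminal_sugar == "arabino"

    def test_order_invariance(self, plus1):
        records = [
            rec(c.neutral_mass * (1 + d * 1e-6), abundance=10 + i)
            for i, (c, d) in enumerate(zip(plus1, (1, -2, 3, 0.5)))
        ]
        a = match(records, plus1)
        b = match(records[::-1], plus1)
        key = lambda m: (m.record.neutral_mass, m.candidate.neutral_mass)
        assert sorted(map(key, a.matches)) == sorted(map(key, b.matches))

    def test_isobaric_tie_prefers_terminal_site(self, rna6_primer):
        cands = enumerate_candidates(rna6_primer, MONOMERS, 1)
        threo_mass = next(
            c.neutral_mass for c in cands if c.terminal_sugar == "threo"
        )
        mt = match([rec(threo_mass)], cands)
        assert mt.matches[0].candidate.site_class == "terminal"
        assert not mt.ambiguous


class TestIncorporationPercentages:
    def test_single_replicate_identity(self, terminal_only_primer):
        cands = enumerate_candidates(terminal_only_primer, MONOMERS, 1)
        by_sugar = {c.terminal_sugar: c for c in cands if c.depth == 1}
        records = [
            rec(by_sugar["ribo"].neutral_mass, 30.9),
            rec(by_sugar["arabino"].neutral_mass, 44.7),
            rec(by_sugar["threo"].neutral_mass, 24.4),
        ]
        res = incorporation_percentages(match(records, cands), depth=1)
        assert res.mean_percent["ribo"] == pytest.approx(30.9)
        assert res.mean_percent["arabino"] == pytest.approx(44.7)
        assert res.mean_percent["threo"] == pytest.approx(24.4)

    def test_percentages_sum_to_100(self, rna6_primer):
        records = gen_compound_list(
            {1: {"ribo": 0.309, "arabino": 0.447, "threo": 0.244}},
            rna6_primer, MONOMERS, seed=SEED,
        )
        res = composition_pipeline(records, rna6_primer, MONOMERS, depth=1)
        assert sum(res.mean_percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_doublet_and_adduct_abundances_are_summed(self, rna6_primer):
        cands = enumerate_candidates(rna6_primer, MONOMERS, 1)
        ribo = next(
            c for c in cands
            if c.terminal_sugar == "ribo" and c.site_class == "terminal"
        )
        ara = next(
            c for c in cands
            if c.terminal_sugar == "arabino" and c.site_class == "terminal"
        )
        records = [
            rec(ribo.neutral_mass, 30.0, rt=5.0),        # terminal peak
            rec(ribo.neutral_mass, 20.0, rt=5.4),        # branch peak
            rec(ribo.neutral_mass + SODIUM_ADDUCT_MASS, 10.0),  # Na adduct
            rec(ara.neutral_mass, 40.0),
        ]
        res = incorporation_percentages(match(records, cands), depth=1)
        assert res.mean_percent["ribo"] == pytest.approx(60.0)
        assert res.mean_percent["arabino"] == pytest.approx(40.0)

    def test_zero_abundance_replicate_dropped(self, terminal_only_primer):
        cands = enumerate_candidates(terminal_only_primer, MONOMERS, 1)
        m = cands[1].neutral_mass
        records = [rec(m, 10.0, rep="rep1"), rec(m, 0.0, rep="rep2")]
        with pytest.warns(UserWarning):
            res = incorporation_percentages(match(records, cands), depth=1)
        assert res.n_replicates == 1


class TestSiteReactivity:
    def test_free_primer_internal_reactivity_is_25_percent(self):
        assert site_reactivity(1.0, 1.6, 5, 2) == pytest.approx(0.25)

    def test_complement_bound_primer_is_about_10_percent(self):
        assert site_reactivity(0.21, 0.79, 5, 2) == pytest.approx(0.106, abs=5e-4)

    def test_per_site_equal_input_gives_unity(self):
        assert site_reactivity(5.0, 2.0, 5, 2) == pytest.approx(1.0)

    def test_zero_terminal_fraction_rejected(self):
        with pytest.raises(ZeroDivisionError):
            site_reactivity(1.0, 0.0, 5, 2)


class TestPipelineRecovery:
    def test_noiseless_generator_recovers_exactly(self, terminal_only_primer):
        truth = {"ribo": 0.5, "arabino": 0.3, "threo": 0.2}
        records = gen_compound_list(
            {1: truth}, terminal_only_primer, MONOMERS, n_reps=2,
            mass_ppm_sd=0.0, adduct_probs=(1.0,),
            dirichlet_concentration=1e12, abundance_dispersion=0.0, seed=SEED,
        )
        res = composition_pipeline(records, terminal_only_primer, MONOMERS, 1)
        for s, v in truth.items():
            assert res.mean_percent[s] == pytest.approx(100 * v, abs=1e-3)

    def test_means_converge_with_replicates(self, rna6_primer):
        """Recovered means approach truth as replicate count grows."""
        truth = {"ribo": 0.309, "arabino": 0.447, "threo": 0.244}
        errs = {}
        for n in (6, 60):
            records = gen_compound_list(
                {1: truth}, rna6_primer, MONOMERS, n_reps=n, seed=SEED
            )
            res = composition_pipeline(records, rna6_primer, MONOMERS, 1)
            errs[n] = max(
                abs(res.mean_percent[s] - 100 * truth[s]) for s in truth
            )
        assert errs[60] < 2.0
        assert errs[60] <= errs[6] + 0.5
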