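"""Cleavage-variant matching, Edman constraints, ladders and routes."""

import numpy as np
import pytest

from lantimine import (
    NeutralMass,
    Prepeptide,
    apply_nterm_constraint,
    dehydrated_mass,
    enumerate_variants,
    gen_precursor,
    gen_product_ladder,
    gen_signals,
    ladder_infer,
    match_masses,
    processing_routes,
)
from lantimine.masses import STANDARD_TABLE
from lantimine.pipeline import build_prepeptide, deconvolute_signals, match_precursor

WATER = STANDARD_TABLE.water_avg


def _obs(value: float) -> NeutralMass:
    return NeutralMass(value=value, integer_report=int(value))


class TestEnumerateVariants:
    def test_published_window_cores(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        variants = enumerate_variants(pre, (20, 23))
        assert [c[:1] for _, c in variants] == ["D", "L", "G", "D"]
        assert [p for p, _ in variants] == [20, 21, 22, 23]

    def test_width_one_window(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        assert len(enumerate_variants(pre, (21, 21))) == 1

    def test_full_window_gives_n_minus_one_variants(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        n = len(standin_fragment)
        assert len(enumerate_variants(pre, (1, n - 1))) == n - 1

    def test_empty_window(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        assert enumerate_variants(pre, (21, 20)) == []

    def test_cores_are_exact_suffixes(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        for p, core in enumerate_variants(pre, (1, 63)):
            assert core == standin_fragment[p:]


class TestMatchMasses:
    def test_planted_variant_recovered_noiselessly(self):
        pre, truth = gen_precursor(42)
        site = truth.cleavage_sites[1]
        mass = gen_product_ladder(pre, [site], 8)[0][1]
        variants = enumerate_variants(pre, (18, 24))
        result = match_masses(variants, [_obs(mass)])
        top = result.assignments[0]
        assert (top.cleavage_after, top.n_dehydr) == (site, 8)
        assert top.delta == pytest.approx(0.0, abs=1e-9)

    def test_unmodified_core_matches_with_zero_dehydrations(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        core = pre.core_after(21)
        result = match_masses(
            [(21, core)], [_obs(dehydrated_mass(core, 0))], max_dehydr=0
        )
        assert len(result.assignments) == 1
        assert result.assignments[0].n_dehydr == 0

    def test_near_tie_reported_as_dual_assignment(self):
        # An Ala residue (71.078 Da) is within 1 Da of four waters
        # (72.061 Da): cleaving one residue earlier with four extra
        # dehydrations is a genuine near-tie that must be reported, not
        # silently resolved.
        seq = "MKQELFDLDA" + "ASSSSTTTTGWKQPLVAYHE"
        pre = Prepeptide(seq)
        variants = enumerate_variants(pre, (10, 11))
        obs = _obs(dehydrated_mass(pre.core_after(11), 0) - 0.49)
        result = match_masses(variants, [obs], tol=1.0)
        keys = {(a.cleavage_after, a.n_dehydr) for a in result.assignments}
        assert {(11, 0), (10, 4)} <= keys

    def test_unmatched_observations_listed(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        stray = _obs(99999.0)
        result = match_masses(enumerate_variants(pre, (20, 23)), [stray])
        assert result.unmatched == (stray,)

    def test_order_invariance(self):
        pre, truth = gen_precursor(7)
        masses = [m for _, m in gen_product_ladder(pre, truth.cleavage_sites, 8)]
        obs = [_obs(m) for m in masses]
        variants = enumerate_variants(pre, (18, 24))
        a = match_masses(variants, obs)
        b = match_masses(list(reversed(variants)), list(reversed(obs)))
        assert [
            (x.cleavage_after, x.n_dehydr, x.observed.value) for x in a.assignments
        ] == [(x.cleavage_after, x.n_dehydr, x.observed.value) for x in b.assignments]

    def test_every_assignment_verifies_by_recomputation(self):
        pre, truth = gen_precursor(9)
        masses = [m for _, m in gen_product_ladder(pre, truth.cleavage_sites, 8)]
        result = match_masses(
            enumerate_variants(pre, (15, 30)), [_obs(m + 0.3) for m in masses], tol=1.0
        )
        for a in result.assignments:
            assert abs(
                a.observed.value - dehydrated_mass(a.core_seq, a.n_dehydr)
            ) <= 1.0


class TestNtermConstraint:
    def _assignments(self, standin):
        pre = build_prepeptide(standin)
        out = []
        for p, core in enumerate_variants(pre, (19, 24)):
            mass = dehydrated_mass(core, 0)
            out.append(
                match_masses([(p, core)], [_obs(mass)], max_dehydr=0).assignments[0]
            )
        return out

    def test_lgdy_selects_cleavage_after_21(self, standin_fragment):
        kept = apply_nterm_constraint(self._assignments(standin_fragment), "LGDY")
        assert [a.cleavage_after for a in kept] == [21]

    def test_dy_selects_cleavage_after_23(self, standin_fragment):
        kept = apply_nterm_constraint(self._assignments(standin_fragment), "DY")
        assert [a.cleavage_after for a in kept] == [23]

    def test_absent_nterm_empties_the_set(self, standin_fragment):
        assert apply_nterm_constraint(self._assignments(standin_fragment), "WWW") == []


class TestLadderInfer:
    def test_published_integer_ladder(self):
        steps = ladder_infer([4536, 4593, 4706, 4820], tol=0.5)
        assert [s.delta for s in steps] == [57, 113, 114]
        assert [set(s.candidate_residues) for s in steps] == [
            {"G"},
            {"L", "I"},
            {"N"},
        ]

    def test_single_glycine_step(self):
        steps = ladder_infer([4000.0, 4057.05], tol=0.5)
        assert len(steps) == 1 and set(steps[0].candidate_residues) == {"G"}

    def test_unexplained_step_retained(self):
        steps = ladder_infer([4000.0, 4200.0], tol=0.5)
        assert len(steps) == 1 and not steps[0].explained

    def test_step_count_and_telescoping(self):
        rng = np.random.default_rng(3)
        masses = list(4000 + 1000 * rng.random(9))
        steps = ladder_infer(masses, tol=0.5)
        assert len(steps) == len(masses) - 1
        assert sum(s.delta for s in steps) == pytest.approx(
            max(masses) - min(masses), abs=1e-9
        )


class TestProcessingRoutes:
    def _best(self, pre, sites):
        out = []
        for p in sites:
            core = pre.core_after(p)
            out.append(
                match_masses(
                    [(p, core)], [_obs(dehydrated_mass(core, 0))], max_dehydr=0
                ).assignments[0]
            )
        return out

    def test_consecutive_sites_support_both_routes(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        rep = processing_routes(self._best(pre, [20, 21, 22, 23]), pre)
        assert rep.independent_cleavage and rep.sequential_trimming

    def test_gapped_sites_break_sequential_route(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        rep = processing_routes(self._best(pre, [20, 22]), pre)
        assert rep.independent_cleavage and not rep.sequential_trimming

    def test_single_assignment_indeterminate(self, standin_fragment):
        pre = build_prepeptide(standin_fragment)
        rep = processing_routes(self._best(pre, [21]), pre)
        assert rep.status == "indeterminate"


class TestParameterRecovery:
    def test_noiseless_recovery_is_exact(self):
        hits = 0
        for seed in range(200):
            pre, truth = gen_precursor(seed)
            site = truth.cleavage_sites[seed % 4]
            mass = gen_product_ladder(pre, [site], 8)[0][1]
            rows = gen_signals([mass], noise_sd=0.0, seed=seed)
            res = match_precursor(pre, deconvolute_signals(rows))
            a = res.best[0][1]
            hits += (a.cleavage_after, a.n_dehydr) == (site, 8)
        assert hits == 200

    def test_noisy_recovery_at_least_95_percent(self):
        hits = 0
        for seed in range(200):
            pre, truth = gen_precursor(seed + 10_000)
            site = truth.cleavage_sites[seed % 4]
            mass = gen_product_ladder(pre, [site], 8)[0][1]
            rows = gen_signals([mass], noise_sd=0.05, seed=seed)
            res = match_precursor(pre, deconvolute_signals(rows), tol=1.0)
            a = res.best[0][1]
            hits += (a.cleavage_after, a.n_dehydr) == (site, 8)
        assert hits >= 190
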