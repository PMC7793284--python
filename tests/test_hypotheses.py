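"""Death-decision rules, damage dynamics and their closed forms."""

import math
import types

import numpy as np
import pytest

import ctlsim as cs
from ctlsim.hypotheses import DAMAGE_VARIANTS, PROBABILISTIC_VARIANTS


def ctl_with_count(count):
    return types.SimpleNamespace(contact_count=count, kill_param=None)


def target_with(count=0, damage=0.0, susceptibility=None):
    return types.SimpleNamespace(
        contact_count=count, damage=damage, susceptibility=susceptibility
    )


class TestHypothesisSpec:
    def test_missing_parameter_named(self):
        with pytest.raises(ValueError, match="p"):
            cs.HypothesisSpec("null")
        with pytest.raises(ValueError, match="T_max"):
            cs.HypothesisSpec("saturated_damage", d=0.03)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown variant"):
            cs.HypothesisSpec("telepathy", p=1.0)

    @pytest.mark.parametrize(
        "hyp, k",
        [
            (cs.HypothesisSpec("null", p=0.2), 2),
            (cs.HypothesisSpec("infected_integration", k_I=0.09), 2),
            (cs.HypothesisSpec("ctl_integration", k_T=0.1), 2),
            (cs.HypothesisSpec("constant_damage", d=0.03), 2),
            (cs.HypothesisSpec("ctl_integration_damage", k_T=0.008), 2),
            (cs.HypothesisSpec("saturated_damage", d=0.03, T_max=20), 3),
            (cs.HypothesisSpec("damage_repair", d=0.03, r=0.009), 3),
            (cs.HypothesisSpec("ctl_heterogeneity", k_m=0.18, k_s=0.05), 3),
            (cs.HypothesisSpec("infected_heterogeneity", d_m=0.1, d_s=0.05), 3),
        ],
    )
    def test_free_parameter_counts(self, hyp, k):
        """k = killing parameters + 1 for T_death; drives the AIC penalty."""
        assert hyp.free_parameter_count == k


class TestKillProbability:
    @pytest.mark.parametrize(
        "hyp, ctl, target, expected",
        [
            (cs.HypothesisSpec("null", p=0.2), ctl_with_count(7), target_with(9), 0.2),
            (
                cs.HypothesisSpec("infected_integration", k_I=0.09),
                ctl_with_count(1),
                target_with(3),
                0.27,
            ),
            (
                cs.HypothesisSpec("infected_integration", k_I=0.09),
                ctl_with_count(1),
                target_with(12),
                1.0,  # 0.09*12 = 1.08 clamps to 1
            ),
            (
                cs.HypothesisSpec("ctl_integration", k_T=0.1),
                ctl_with_count(4),
                target_with(1),
                0.4,
            ),
            (
                cs.HypothesisSpec("ctl_integration", k_T=0.1, negative_modulation=True),
                ctl_with_count(4),
                target_with(1),
                0.025,
            ),
        ],
    )
    def test_formulas(self, hyp, ctl, target, expected):
        assert cs.contact_end_kill_probability(hyp, ctl, target) == pytest.approx(expected)

    def test_heterogeneity_uses_per_cell_values(self):
        hyp = cs.HypothesisSpec("ctl_heterogeneity", k_m=0.18, k_s=0.05)
        ctl = types.SimpleNamespace(contact_count=5, kill_param=0.11)
        assert cs.contact_end_kill_probability(hyp, ctl, target_with()) == 0.11
        hyp = cs.HypothesisSpec("infected_heterogeneity", d_m=0.1, d_s=0.05)
        assert (
            cs.contact_end_kill_probability(hyp, ctl_with_count(1), target_with(susceptibility=0.3))
            == 0.3
        )

    def test_negative_modulation_is_non_increasing(self):
        hyp = cs.HypothesisSpec("ctl_integration", k_T=0.5, negative_modulation=True)
        probs = [
            cs.contact_end_kill_probability(hyp, ctl_with_count(c), target_with())
            for c in range(1, 12)
        ]
        assert all(b <= a for a, b in zip(probs, probs[1:]))

    def test_probabilities_always_in_unit_interval(self):
        for variant, kwargs in [
            ("null", {"p": 0.9}),
            ("infected_integration", {"k_I": 0.3}),
            ("ctl_integration", {"k_T": 0.3}),
        ]:
            hyp = cs.HypothesisSpec(variant, **kwargs)
            for c in range(1, 30):
                p = cs.contact_end_kill_probability(hyp, ctl_with_count(c), target_with(c))
                assert 0.0 <= p <= 1.0

    def test_damage_variant_has_no_contact_end_decision(self):
        hyp = cs.HypothesisSpec("constant_damage", d=0.03)
        with pytest.raises(ValueError, match="contact-end"):
            cs.contact_end_kill_probability(hyp, ctl_with_count(1), target_with(1))


class TestHeterogeneityInit:
    def test_degenerate_sd_gives_exact_mean(self, rng):
        hyp = cs.HypothesisSpec("ctl_heterogeneity", k_m=0.18, k_s=0.0)
        ctls = [ctl_with_count(0) for _ in range(50)]
        cs.initialize_heterogeneity(hyp, ctls, [], rng)
        assert all(c.kill_param == pytest.approx(0.18) for c in ctls)

    def test_sample_mean_near_k_m(self, rng):
        hyp = cs.HypothesisSpec("ctl_heterogeneity", k_m=0.18, k_s=0.05)
        ctls = [ctl_with_count(0) for _ in range(10_000)]
        cs.initialize_heterogeneity(hyp, ctls, [], rng)
        vals = [c.kill_param for c in ctls]
        assert np.mean(vals) == pytest.approx(0.18, abs=0.002)
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_target_draws_clamped(self, rng):
        hyp = cs.HypothesisSpec("infected_heterogeneity", d_m=0.3, d_s=0.05)
        targets = [target_with() for _ in range(5_000)]
        cs.initialize_heterogeneity(hyp, [], targets, rng)
        assert all(0.0 <= t.susceptibility <= 1.0 for t in targets)

    def test_noop_for_other_variants(self, rng):
        hyp = cs.HypothesisSpec("null", p=0.2)
        ctls = [ctl_with_count(0)]
        cs.initialize_heterogeneity(hyp, ctls, [], rng)
        assert ctls[0].kill_param is None


class Contact(types.SimpleNamespace):
    pass


class TestDamageRate:
    def test_constant_damage_scales_with_ctl_number(self):
        hyp = cs.HypothesisSpec("constant_damage", d=0.03)
        contacts = [Contact(elapsed=1.0), Contact(elapsed=2.0)]
        assert cs.damage_rate_for_target(hyp, contacts) == pytest.approx(0.06)

    def test_saturated_damage_ignores_exhausted_contacts(self):
        hyp = cs.HypothesisSpec("saturated_damage", d=0.03, T_max=20.0)
        contacts = [Contact(elapsed=25.0)]
        assert cs.damage_rate_for_target(hyp, contacts) == 0.0
        contacts = [Contact(elapsed=25.0), Contact(elapsed=5.0)]
        assert cs.damage_rate_for_target(hyp, contacts) == pytest.approx(0.03)

    def test_ctl_integration_damage_sums_contact_counts(self):
        hyp = cs.HypothesisSpec("ctl_integration_damage", k_T=0.008)
        contacts = [Contact(elapsed=1.0)]
        rate = cs.damage_rate_for_target(hyp, contacts, ctl_contact_counts=[5])
        assert rate == pytest.approx(0.04)

    def test_probabilistic_variant_rejected(self):
        with pytest.raises(ValueError, match="damage"):
            cs.damage_rate_for_target(cs.HypothesisSpec("null", p=0.2), [])


class TestDamageStep:
    def test_euler_arithmetic(self):
        hyp = cs.HypothesisSpec("constant_damage", d=0.03)
        tgt = target_with(damage=0.0)
        damage, died = cs.apply_damage_step(tgt, 0.06, hyp, 0.1)
        assert damage == pytest.approx(0.006) and not died

    def test_repair_term(self):
        hyp = cs.HypothesisSpec("damage_repair", d=0.03, r=0.009)
        tgt = target_with(damage=0.5)
        damage, died = cs.apply_damage_step(tgt, 0.0, hyp, 0.1)
        assert damage == pytest.approx(0.49955) and not died

    def test_threshold_crossing_triggers_death(self):
        hyp = cs.HypothesisSpec("constant_damage", d=0.03)
        tgt = target_with(damage=0.999)
        damage, died = cs.apply_damage_step(tgt, 0.03, hyp, 0.1)
        assert damage == pytest.approx(1.002) and died

    def test_damage_never_negative(self):
        hyp = cs.HypothesisSpec("damage_repair", d=0.03, r=10.0)
        tgt = target_with(damage=0.001)
        for _ in range(100):
            damage, _ = cs.apply_damage_step(tgt, 0.0, hyp, 0.1)
            assert damage >= 0.0


class TestClosedForms:
    def test_zero_time_zero_damage(self):
        assert cs.damage_closed_form_first_contact(0.03, 0.009, 0.0) == 0.0

    def test_long_time_plateau_d_over_r(self):
        assert cs.damage_closed_form_first_contact(0.03, 0.009, 1e7) == pytest.approx(10 / 3)

    def test_unit_damage_at_completion_time(self):
        t = cs.time_to_complete_damage(0.03, 0.009)
        assert cs.damage_closed_form_first_contact(0.03, 0.009, t) == pytest.approx(1.0, abs=1e-2)

    def test_no_repair_time_is_inverse_rate(self):
        assert cs.time_to_complete_damage(0.03, 0.0) == pytest.approx(100 / 3)

    def test_repair_free_limit_is_continuous(self):
        # first-order series term is r/(2d^2), so r=1e-10 keeps the gap < 1e-6
        assert cs.time_to_complete_damage(0.03, 1e-10) == pytest.approx(1 / 0.03, abs=1e-6)

    def test_repair_exceeding_damage_rejected(self):
        with pytest.raises(ValueError, match="never reaches"):
            cs.time_to_complete_damage(0.03, 0.03)
        with pytest.raises(ValueError):
            cs.damage_closed_form_first_contact(0.03, 0.0, 10.0)

    def test_euler_matches_closed_form_within_half_percent(self):
        """dt=0.1 Euler integration tracks the analytic solution over 40 min."""
        hyp = cs.HypothesisSpec("damage_repair", d=0.03, r=0.009)
        tgt = target_with(damage=0.0)
        t = 0.0
        for _ in range(400):
            cs.apply_damage_step(tgt, 0.03, hyp, 0.1)
            t += 0.1
        exact = cs.damage_closed_form_first_contact(0.03, 0.009, t)
        assert tgt.damage == pytest.approx(exact, rel=0.005)

    def test_damage_monotone_without_repair(self):
        for variant, kwargs in [
            ("constant_damage", {"d": 0.03}),
            ("saturated_damage", {"d": 0.03, "T_max": 20.0}),
            ("ctl_integration_damage", {"k_T": 0.008}),
        ]:
            hyp = cs.HypothesisSpec(variant, **kwargs)
            tgt = target_with(damage=0.0)
            prev = 0.0
            for _ in range(50):
                damage, _ = cs.apply_damage_step(tgt, 0.01, hyp, 0.1)
                assert damage >= prev
                prev = damage

    def test_variant_partition(self):
        assert PROBABILISTIC_VARIANTS | DAMAGE_VARIANTS == cs.hypotheses.VARIANTS
        assert not PROBABILISTIC_VARIANTS & DAMAGE_VARIANTS
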