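"""Readout computation on hand-built event logs (brute-force enumerable)."""

import numpy as np
import pytest

import ctlsim as cs

NULL = cs.HypothesisSpec("null", p=0.2, T_death=15.0)


def make_result(target_specs, events, n_ctls=5, config=None):
    """Build a SimulationResult by hand.

    ``target_specs``: list of (id, removal_time or None).
    ``events``: list of (ctl_id, target_id, start, end).
    """
    config = config or cs.SimulationConfig(N_T=n_ctls, N_I=len(target_specs))
    targets = []
    for tid, removal in target_specs:
        t = cs.TargetCellState(id=tid, position=np.array([0.0, 0.0, 500.0]))
        if removal is not None:
            t.state = "removed"
            t.removal_time = removal
        targets.append(t)
    ctls = [
        cs.CTLState(
            id=i, position=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]), speed=4.0
        )
        for i in range(n_ctls)
    ]
    evs = [
        cs.ContactEvent(
            ctl_id=c, target_id=t, start_time=s, scheduled_duration=e - s,
            end_time=e, end_reason="scheduled",
        )
        for c, t, s, e in events
    ]
    return cs.SimulationResult(config=config, hyp=NULL, events=evs, ctls=ctls, targets=targets)


class TestKillProbabilityByRank:
    def test_hand_enumeration(self):
        """A: died after 2 contacts; B: alive 3; C: died 1; D: alive 1; E: alive 2."""
        result = make_result(
            [(0, 100.0), (1, None), (2, 50.0), (3, None), (4, None)],
            [
                (0, 0, 10, 12), (1, 0, 20, 22),            # A: 2 contacts, died
                (0, 1, 10, 11), (1, 1, 20, 21), (2, 1, 30, 31),  # B: 3, alive
                (0, 2, 5, 6),                                # C: 1, died
                (1, 3, 5, 6),                                # D: 1, alive
                (2, 4, 5, 6), (3, 4, 15, 16),                # E: 2, alive
            ],
        )
        probs, at_least = cs.kill_probability_by_rank(cs.observe(result), max_rank=3)
        assert probs == pytest.approx([1 / 5, 1 / 3, 0.0])
        assert list(at_least) == [5, 3, 1]

    def test_no_deaths_all_zero(self):
        result = make_result([(0, None)], [(0, 0, 1, 2)])
        probs, _ = cs.kill_probability_by_rank(cs.observe(result))
        assert probs == pytest.approx(np.zeros(6))

    def test_zero_population_ranks_report_zero(self):
        result = make_result([(0, 10.0)], [(0, 0, 1, 2)])
        probs, at_least = cs.kill_probability_by_rank(cs.observe(result), max_rank=4)
        assert probs[0] == 1.0
        assert list(at_least[1:]) == [0, 0, 0] and all(probs[1:] == 0.0)


class TestEliminationTimes:
    def test_definition(self):
        result = make_result([(0, 50.0)], [(0, 0, 10.0, 20.0)])
        hist = cs.elimination_times(cs.observe(result), edges=np.arange(0, 250, 10.0))
        # T_elimination = 50 - 10 = 40 min -> bin [40, 50)
        assert hist[4] == 1.0 and hist.sum() == 1.0

    def test_single_killed_cell_normalises_to_one(self):
        result = make_result([(0, 33.0), (1, None)], [(0, 0, 3.0, 5.0)])
        hist = cs.elimination_times(cs.observe(result), edges=np.arange(0, 250, 10.0))
        assert hist.sum() == pytest.approx(1.0)


class TestContactCountDistributions:
    def test_all_uncontacted_alive_delta_at_zero(self):
        result = make_result([(0, None), (1, None)], [])
        dead, alive = cs.contact_count_distributions(cs.observe(result))
        assert alive[0] == 1.0 and dead.sum() == 0.0

    def test_hand_log(self):
        result = make_result(
            [(0, 40.0), (1, None), (2, None)],
            [(0, 0, 1, 2), (1, 0, 5, 6), (0, 1, 8, 9), (1, 2, 10, 11), (2, 2, 12, 13)],
        )
        dead, alive = cs.contact_count_distributions(cs.observe(result))
        assert dead == pytest.approx([0, 0, 1.0])          # one dead cell with 2 contacts
        assert alive == pytest.approx([0, 0.5, 0.5])       # alive cells with 1 and 2
        assert dead.sum() == alive.sum() == 1.0

    def test_populations_partition_targets(self):
        result = make_result([(0, 40.0), (1, None), (2, None)], [(0, 0, 1, 2)])
        obs = cs.observe(result)
        assert sum(t.dead for t in obs.targets) + sum(not t.dead for t in obs.targets) == 3


class TestContactDurations:
    def test_totals_and_singles(self):
        result = make_result([(0, None)], [(0, 0, 10.0, 13.0), (1, 0, 20.0, 25.0)])
        tot_d, tot_a, sing_d, sing_a = cs.contact_duration_distributions(
            cs.observe(result), edges=np.array([0.0, 4.0, 10.0, np.inf])
        )
        assert tot_a == pytest.approx([0, 1.0, 0])     # total 8 min -> [4, 10)
        assert sing_a == pytest.approx([0.5, 0.5, 0])  # singles 3 and 5 min
        assert tot_d.sum() == 0.0 and sing_d.sum() == 0.0

    def test_simultaneous_contacts_add(self):
        """Two overlapping 4-min contacts advance the total clock by 8 min."""
        result = make_result([(0, None)], [(0, 0, 10.0, 14.0), (1, 0, 10.0, 14.0)])
        tot_d, tot_a, *_ = cs.contact_duration_distributions(
            cs.observe(result), edges=np.array([0.0, 7.0, 9.0, np.inf])
        )
        assert tot_a == pytest.approx([0, 1.0, 0])

    def test_open_contacts_truncated_at_window_end(self):
        result = make_result([(0, None)], [(0, 0, 230.0, 260.0)])
        obs = cs.observe(result)  # window ends at 240
        assert obs.targets[0].contact_durations == pytest.approx([10.0])


class TestSummaries:
    def test_pckr_arithmetic(self):
        """40 kills by 200 CTLs in 240 min extrapolate to 1.2 per CTL per day."""
        specs = [(i, 100.0) for i in range(40)] + [(i, None) for i in range(40, 250)]
        events = [(0, i, 1.0, 2.0) for i in range(40)]
        result = make_result(specs, events, n_ctls=200)
        obs = cs.observe(result)
        assert cs.pckr(obs) == pytest.approx(1.2)
        assert cs.fraction_killed(obs) == pytest.approx(40 / 250)

    def test_pckr_no_kills_zero(self):
        result = make_result([(0, None)], [], n_ctls=10)
        assert cs.pckr(cs.observe(result)) == 0.0

    def test_pckr_without_ctls_undefined(self):
        result = make_result([(0, None)], [], n_ctls=0)
        with pytest.raises(ValueError):
            cs.pckr(cs.observe(result))

    def test_fractions(self):
        specs = [(0, 100.0), (1, None), (2, None), (3, None)]
        result = make_result(specs, [(0, 0, 1, 2), (0, 1, 5, 6)])
        obs = cs.observe(result)
        assert cs.fraction_killed(obs) == 0.25
        assert cs.fraction_never_contacted(obs) == 0.5
        assert cs.fraction_killed(obs) + sum(not t.dead for t in obs.targets) / 4 == 1.0


class TestObservationWindow:
    def test_unknown_history_discards_early_contacts(self):
        """With obs_start=60 the first hour of history is invisible."""
        result = make_result(
            [(0, 100.0), (1, None)],
            [(0, 0, 30.0, 40.0), (1, 0, 70.0, 80.0), (0, 1, 10.0, 20.0)],
        )
        obs = cs.observe(result, obs_start=60.0)
        by_id = {t.target_id: t for t in obs.targets}
        assert by_id[0].n_contacts == 1 and by_id[0].first_contact_time == 70.0
        assert by_id[1].n_contacts == 0  # contacted only before the window

    def test_pre_window_removals_excluded(self):
        result = make_result([(0, 30.0), (1, None)], [])
        obs = cs.observe(result, obs_start=60.0)
        assert [t.target_id for t in obs.targets] == [1]

    def test_death_in_window_with_only_prior_contacts_is_zero_contact(self):
        result = make_result([(0, 100.0)], [(0, 0, 10.0, 20.0)])
        obs = cs.observe(result, obs_start=60.0)
        assert obs.targets[0].dead and obs.targets[0].n_contacts == 0


@pytest.fixture(scope="module")
def readouts(motility):
    config = cs.SimulationConfig(
        X_dim=300.0, Y_dim=300.0, Z_dim=300.0, N_T=16, N_I=20, T_Sim=120.0
    )
    result = cs.run_simulation(config, NULL, motility, rng=8)
    return cs.compute_readouts(result)


class TestReadoutSet:
    def test_normalised_histograms_sum_to_one(self, readouts):
        for name, vec in readouts.datasets().items():
            if name == "kill_prob_by_rank":
                assert ((vec >= 0) & (vec <= 1)).all()
            elif vec.sum() > 0:
                assert vec.sum() == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_through_directory(self, readouts, tmp_path):
        readouts.to_dir(tmp_path / "ro")
        back = cs.ReadoutSet.from_dir(tmp_path / "ro")
        for name, vec in readouts.datasets().items():
            assert back.datasets()[name] == pytest.approx(vec)
        assert back.pckr == pytest.approx(readouts.pckr)
        assert np.isinf(back.dur_edges[-1])

    def test_average_readouts_pads_and_averages(self, readouts):
        avg = cs.average_readouts([readouts, readouts])
        for name, vec in readouts.datasets().items():
            assert avg.datasets()[name] == pytest.approx(vec)
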