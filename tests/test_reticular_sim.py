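import numpy as np
import pytest

from retiform import (
    BehaviorMode,
    CommandState,
    EnvironmentSignal,
    ModeRepertoire,
    ProgramMemory,
    ProgramOutcome,
    abductive_select,
    classify_outcome,
    construct_loop,
    default_loop_binding,
    execute_program_sequence,
    interrupt_reprioritize,
    load_default_modes,
    run_scenario,
    run_schedule,
    schedule_sequence,
    verify_loop,
)
from retiform.errors import ConfigurationError, ValidationError
from retiform.reticular_sim import ActiveProgram


class TestDefaultModes:
    def test_twenty_modes(self, default_repertoire):
        assert len(default_repertoire) == 20

    def test_key_percents(self, default_repertoire):
        assert default_repertoire.percent("Sleeps") == 30
        assert default_repertoire.percent("Works") == 25
        assert default_repertoire.percent("Greeds") == 1
        assert default_repertoire.percent("Interpersonal attends") == 8

    def test_total_is_exactly_100(self, default_repertoire):
        assert default_repertoire.total_percent == 100.0


class TestRepertoireValidation:
    def test_total_outside_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            ModeRepertoire(modes=(BehaviorMode("Sleeps", 30), BehaviorMode("Works", 25)))

    def test_total_within_tolerance_accepted(self):
        rep = ModeRepertoire(
            modes=(BehaviorMode("Sleeps", 60), BehaviorMode("Works", 25))
        )
        assert rep.total_percent == 85

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError):
            ModeRepertoire(
                modes=(BehaviorMode("Sleeps", 50), BehaviorMode("Sleeps", 50))
            )

    def test_negative_percent_rejected(self):
        with pytest.raises(ValidationError):
            BehaviorMode("Sleeps", -1)

    def test_csv_roundtrip(self, default_repertoire, tmp_path):
        path = tmp_path / "modes.csv"
        default_repertoire.to_csv(path)
        back = ModeRepertoire.from_csv(path)
        assert back.modes == default_repertoire.modes


class TestAbductiveSelect:
    def test_argmax_evidence(self, default_repertoire):
        signal = EnvironmentSignal(time=0, evidence={"Eats": 0.9, "Sleeps": 0.1})
        assert abductive_select(signal, default_repertoire).name == "Eats"

    def test_zero_evidence_falls_back_to_prior(self, default_repertoire):
        signal = EnvironmentSignal(time=0, evidence={})
        assert abductive_select(signal, default_repertoire).name == "Sleeps"

    def test_tie_breaks_on_prior_then_name(self):
        rep = ModeRepertoire(
            modes=(
                BehaviorMode("Beta", 40),
                BehaviorMode("Alpha", 40),
                BehaviorMode("Gamma", 20),
            )
        )
        signal = EnvironmentSignal(time=0, evidence={"Alpha": 1.0, "Beta": 1.0})
        assert abductive_select(signal, rep).name == "Alpha"

    def test_single_mode_always_wins(self):
        rep = ModeRepertoire(modes=(BehaviorMode("Only", 100),))
        signal = EnvironmentSignal(time=0, evidence={"Other": 5.0})
        assert abductive_select(signal, rep).name == "Only"

    def test_gains_reweight(self, default_repertoire):
        signal = EnvironmentSignal(time=0, evidence={"Eats": 0.5, "Sleeps": 0.4})
        chosen = abductive_select(
            signal, default_repertoire, gains={"Sleeps": 2.0}
        )
        assert chosen.name == "Sleeps"

    def test_selected_always_has_maximal_evidence(self, default_repertoire):
        rng = np.random.default_rng(0)
        names = [m.name for m in default_repertoire]
        for _ in range(50):
            evidence = {n: float(rng.random()) for n in names}
            chosen = abductive_select(
                EnvironmentSignal(time=0, evidence=evidence), default_repertoire
            )
            assert evidence[chosen.name] == max(evidence.values())

    def test_negative_evidence_rejected(self):
        with pytest.raises(ValidationError):
            EnvironmentSignal(time=0, evidence={"Eats": -1.0})


class TestExecuteSequence:
    def test_single_loop_traces_24_steps(self, quadrivalent_loop):
        state, trace = execute_program_sequence(
            CommandState(), [("Works", quadrivalent_loop)]
        )
        assert len(trace) == 24
        assert state.clock == 24.0
        assert sorted(trace["vertex"]) == list(range(1, 25))

    def test_four_program_sequence(self, quadrivalent_loop):
        programs = [(f"HL{i}", quadrivalent_loop) for i in range(1, 5)]
        state, trace = execute_program_sequence(CommandState(), programs)
        assert len(trace) == 96
        assert list(trace["program"].unique()) == ["HL1", "HL2", "HL3", "HL4"]

    def test_invalid_program_skipped_but_logged(self, quadrivalent_loop, invalid_loop):
        programs = [("Good", quadrivalent_loop), ("Bad", invalid_loop), ("Also", quadrivalent_loop)]
        state, trace = execute_program_sequence(CommandState(), programs)
        assert ("Bad", ProgramOutcome.ERROR_NO_CYCLE) in state.outcome_log
        assert len(trace) == 48
        assert set(trace["program"]) == {"Good", "Also"}

    def test_clock_advances_per_step(self, hexagon_loop):
        _, trace = execute_program_sequence(CommandState(), [("A", hexagon_loop)])
        assert list(trace["time"]) == [float(t) for t in range(6)]


class TestInterrupt:
    def _state_with_active(self, loop, priority=1.0):
        state = CommandState()
        state.active_program = ActiveProgram(name="forward", loop=loop, priority=priority)
        return state

    def test_obstacle_installs_retreat_look_forward(self, quadrivalent_loop):
        state = self._state_with_active(quadrivalent_loop)
        signal = EnvironmentSignal(
            time=3.0,
            evidence={"retreat": 3.0, "look": 2.0, "forward": 1.0},
            priority=9.0,
        )
        interrupt_reprioritize(state, signal)
        assert state.queue == ["retreat", "look", "forward"]
        assert state.active_program is None

    def test_preempted_program_logs_rejection(self, quadrivalent_loop):
        state = self._state_with_active(quadrivalent_loop)
        signal = EnvironmentSignal(time=0, evidence={"retreat": 1.0}, priority=9.0)
        interrupt_reprioritize(state, signal)
        assert state.outcome_log == [("forward", ProgramOutcome.REJECTED_BY_PRIORITY)]

    def test_low_priority_signal_ignored(self, quadrivalent_loop):
        state = self._state_with_active(quadrivalent_loop, priority=5.0)
        signal = EnvironmentSignal(time=0, evidence={"retreat": 1.0}, priority=1.0)
        interrupt_reprioritize(state, signal)
        assert state.active_program is not None
        assert state.queue == []
        assert state.outcome_log == []

    def test_explicit_sequence_wins_over_evidence(self, quadrivalent_loop):
        state = self._state_with_active(quadrivalent_loop)
        signal = EnvironmentSignal(
            time=0,
            evidence={"look": 9.0},
            priority=9.0,
            sequence=("retreat", "look", "forward"),
        )
        interrupt_reprioritize(state, signal)
        assert state.queue == ["retreat", "look", "forward"]

    def test_requires_active_program(self):
        with pytest.raises(ValidationError):
            interrupt_reprioritize(CommandState(), EnvironmentSignal(time=0))


class TestClassifyOutcome:
    def test_invalid_loop(self, invalid_loop):
        outcome = classify_outcome(
            "p", verify_loop(invalid_loop), 0.0, False, ProgramMemory()
        )
        assert outcome == ProgramOutcome.ERROR_NO_CYCLE

    def test_reinforced_but_invalid_is_inconsistent(self, invalid_loop):
        with pytest.raises(ValidationError):
            classify_outcome("p", verify_loop(invalid_loop), 1.0, False, ProgramMemory())

    def test_valid_unreinforced(self, quadrivalent_loop):
        outcome = classify_outcome(
            "p", verify_loop(quadrivalent_loop), 0.0, False, ProgramMemory()
        )
        assert outcome == ProgramOutcome.CYCLE_NOT_REINFORCED

    def test_valid_reinforced_known(self, quadrivalent_loop):
        outcome = classify_outcome(
            "p", verify_loop(quadrivalent_loop), 1.0, False, ProgramMemory(), {"p"}
        )
        assert outcome == ProgramOutcome.CYCLE_ACTIVATED

    def test_outranked(self, quadrivalent_loop):
        outcome = classify_outcome(
            "p", verify_loop(quadrivalent_loop), 1.0, True, ProgramMemory(), {"p"}
        )
        assert outcome == ProgramOutcome.REJECTED_BY_PRIORITY

    def test_novel_cycle(self, quadrivalent_loop):
        outcome = classify_outcome(
            "new", verify_loop(quadrivalent_loop), 1.0, False, ProgramMemory(), {"p"}
        )
        assert outcome == ProgramOutcome.NOVEL_CYCLE

    def test_imprinting_after_threshold(self, quadrivalent_loop):
        memory = ProgramMemory(imprint_threshold=3)
        verdict = verify_loop(quadrivalent_loop)
        outcomes = [
            classify_outcome("p", verdict, 1.0, False, memory, {"p"}) for _ in range(4)
        ]
        assert outcomes[:2] == [ProgramOutcome.CYCLE_ACTIVATED] * 2
        assert outcomes[2] == ProgramOutcome.IMPRINTED
        assert "p" in memory.imprinted

    def test_novel_program_can_imprint_into_memory(self, quadrivalent_loop):
        memory = ProgramMemory(imprint_threshold=2)
        verdict = verify_loop(quadrivalent_loop)
        first = classify_outcome("new", verdict, 1.0, False, memory, set())
        second = classify_outcome("new", verdict, 1.0, False, memory, set())
        third = classify_outcome("new", verdict, 1.0, False, memory, set())
        assert first == ProgramOutcome.NOVEL_CYCLE
        assert second == ProgramOutcome.IMPRINTED
        assert third == ProgramOutcome.IMPRINTED


class TestSchedule:
    def test_sleeps_share_recovery(self, default_repertoire):
        duration = 100_000
        summary = run_schedule(default_repertoire, duration, seed=0)
        sleeps = summary.loc[summary["mode"] == "Sleeps", "empirical_percent"].item()
        tol = 3 * np.sqrt(0.3 * 0.7 / duration) * 100
        assert sleeps == pytest.approx(30.0, abs=tol)

    def test_shares_sum_to_100(self, default_repertoire):
        summary = run_schedule(default_repertoire, 997, seed=4)
        assert summary["empirical_percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_mode_gets_everything(self):
        rep = ModeRepertoire(modes=(BehaviorMode("Only", 100),))
        summary = run_schedule(rep, 50, seed=1)
        assert summary["empirical_percent"].item() == 100.0

    def test_seeded_determinism(self, default_repertoire):
        a = run_schedule(default_repertoire, 5000, seed=11)
        b = run_schedule(default_repertoire, 5000, seed=11)
        assert a.equals(b)
        assert schedule_sequence(default_repertoire, 100, 11) == schedule_sequence(
            default_repertoire, 100, 11
        )

    def test_all_modes_converge_long_run(self, default_repertoire):
        duration = 200_000
        summary = run_schedule(default_repertoire, duration, seed=2)
        for _, row in summary.iterrows():
            p = row["expected_percent"] / 100
            tol = 4 * np.sqrt(p * (1 - p) / duration) * 100
            assert abs(row["empirical_percent"] - row["expected_percent"]) <= tol

    def test_zero_duration_rejected(self, default_repertoire):
        with pytest.raises(ValidationError):
            run_schedule(default_repertoire, 0)


class TestScenario:
    def test_binding_covers_all_modes(self, default_repertoire):
        binding = default_loop_binding(default_repertoire)
        assert set(binding) == {m.name for m in default_repertoire}
        for loop in binding.values():
            assert verify_loop(loop).valid

    def test_oversized_repertoire_rejected(self):
        modes = tuple(BehaviorMode(f"m{i}", 2) for i in range(50))
        rep = ModeRepertoire(modes=modes)
        with pytest.raises(ConfigurationError):
            default_loop_binding(rep)

    def test_simple_scenario_runs_each_signal(self, default_repertoire):
        scenario = [
            EnvironmentSignal(time=0, evidence={"Works": 1.0}, priority=1.0),
            EnvironmentSignal(time=100, evidence={"Eats": 1.0}, priority=1.0),
        ]
        state, trace = run_scenario(default_repertoire, scenario)
        assert [entry[0] for entry in state.outcome_log] == ["Works", "Eats"]
        assert all(o == ProgramOutcome.CYCLE_ACTIVATED for _, o in state.outcome_log)
        assert len(trace) == 48

    def test_midflight_preemption(self, default_repertoire):
        scenario = [
            EnvironmentSignal(time=0, evidence={"Works": 1.0}, priority=1.0),
            EnvironmentSignal(
                time=5,
                evidence={"Escapes": 3.0, "Attends": 2.0, "Works": 1.0},
                priority=9.0,
            ),
        ]
        state, trace = run_scenario(default_repertoire, scenario)
        assert state.outcome_log[0] == ("Works", ProgramOutcome.REJECTED_BY_PRIORITY)
        counts = trace.groupby("program", sort=False).size().to_dict()
        assert counts["Works"] == 5 + 24  # 5 preempted steps, then a full rerun
        assert counts["Escapes"] == 24 and counts["Attends"] == 24

    def test_low_priority_signal_dropped(self, default_repertoire):
        scenario = [
            EnvironmentSignal(time=0, evidence={"Works": 1.0}, priority=9.0),
            EnvironmentSignal(time=5, evidence={"Eats": 1.0}, priority=1.0),
        ]
        state, trace = run_scenario(default_repertoire, scenario)
        assert [entry[0] for entry in state.outcome_log] == ["Works"]
        assert set(trace["program"]) == {"Works"}

    def test_preemption_never_loses_programs(self, default_repertoire):
        """Every selected program is either completed (classified) or rejected."""
        scenario = [
            EnvironmentSignal(time=0, evidence={"Works": 1.0}, priority=1.0),
            EnvironmentSignal(time=3, evidence={"Eats": 1.0}, priority=5.0),
            EnvironmentSignal(time=30, evidence={"Talks": 1.0}, priority=7.0),
        ]
        state, _ = run_scenario(default_repertoire, scenario)
        logged = [entry[0] for entry in state.outcome_log]
        assert "Works" in logged and "Eats" in logged and "Talks" in logged
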