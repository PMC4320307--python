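"""Behavior-mode repertoire, abductive command selection, and program execution.

A perception/relation front end delivers weighted evidence signals; the
command stage abductively selects the best-fitting loop program from the
mode repertoire (every program can command — selection goes to the one
with the best information); an executive stage traverses the selected
Hamilton loop step by step under a timing clock; interrupts with higher
priority preempt the running program and install a new program sequence.
Each program attempt is classified into one of six realization outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from retiform.errors import ConfigurationError, ValidationError
from retiform.hamilton import HamiltonLoop, LoopVerdict, verify_loop

#: Default repertoire: twenty modes of behavior with their percent-of-time
#: shares over an approximately four-week cycle.  Shares sum to exactly 100.
DEFAULT_MODE_TABLE: tuple[tuple[str, float], ...] = (
    ("Sleeps", 30),
    ("Eats", 5),
    ("Drinks", 1),
    ("Voids", 1),
    ("Sexes", 3),
    ("Works", 25),
    ("Rests", 3),
    ("Talks", 5),
    ("Attends", 4),
    ("Motor practices", 4),
    ("Angers", 1),
    ("Escapes", 1),
    ("Anxious-es", 2),
    ("Euphorics", 2),
    ("Laughs", 1),
    ("Aggresses", 1),
    ("Fears, fights, flights", 1),
    ("Interpersonal attends", 8),
    ("Envies", 1),
    ("Greeds", 1),
)

#: Accepted drift on a user-supplied table's percent total (total must lie
#: within 100 +/- this band).
PERCENT_TOLERANCE = 20.0


class ProgramOutcome(Enum):
    """The six possible realizations of one program attempt."""

    ERROR_NO_CYCLE = "error_no_cycle"
    CYCLE_NOT_REINFORCED = "cycle_not_reinforced"
    CYCLE_ACTIVATED = "cycle_activated"
    REJECTED_BY_PRIORITY = "rejected_by_priority"
    NOVEL_CYCLE = "novel_cycle"
    IMPRINTED = "imprinted"


@dataclass(frozen=True)
class BehaviorMode:
    """A named action mode with its time share and (optionally) a bound loop program."""

    name: str
    percent: float
    loop_id: str | None = None

    def __post_init__(self) -> None:
        if self.percent < 0:
            raise ValidationError(f"mode {self.name!r}: percent must be >= 0")


@dataclass(frozen=True)
class ModeRepertoire:
    """An ordered repertoire of behavior modes over a recurring cycle."""

    modes: tuple[BehaviorMode, ...]
    cycle_length_weeks: float = 4.0
    tolerance: float = PERCENT_TOLERANCE

    def __post_init__(self) -> None:
        if not self.modes:
            raise ConfigurationError("repertoire must contain at least one mode")
        names = [m.name for m in self.modes]
        if len(set(names)) != len(names):
            raise ConfigurationError("mode names must be unique")
        total = self.total_percent
        if not (100.0 - self.tolerance <= total <= 100.0 + self.tolerance):
            raise ConfigurationError(
                f"mode percents sum to {total}, outside "
                f"[{100.0 - self.tolerance}, {100.0 + self.tolerance}]"
            )

    @property
    def total_percent(self) -> float:
        return float(sum(m.percent for m in self.modes))

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def mode(self, name: str) -> BehaviorMode:
        for m in self.modes:
            if m.name == name:
                return m
        raise KeyError(name)

    def percent(self, name: str) -> float:
        return self.mode(name).percent

    @classmethod
    def from_records(cls, records, **kwargs) -> "ModeRepertoire":
        def clean_loop_id(value):
            if value is None or (isinstance(value, float) and value != value) or value == "":
                return None
            return str(value)

        modes = tuple(
            BehaviorMode(
                name=str(r["name"]),
                percent=float(r["percent"]),
                loop_id=clean_loop_id(r.get("loop_id")),
            )
            for r in records
        )
        return cls(modes=modes, **kwargs)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ModeRepertoire":
        frame = pd.read_csv(path)
        if "loop_id" not in frame.columns:
            frame["loop_id"] = None
        frame = frame.where(frame.notna(), None)
        return cls.from_records(frame.to_dict("records"), **kwargs)

    @classmethod
    def from_yaml(cls, path, **kwargs) -> "ModeRepertoire":
        import yaml

        with open(path) as fh:
            records = yaml.safe_load(fh)
        if not isinstance(records, list):
            raise ConfigurationError("mode YAML must be a list of {name, percent} entries")
        return cls.from_records(records, **kwargs)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [{"name": m.name, "percent": m.percent, "loop_id": m.loop_id} for m in self.modes]
        ).to_csv(path, index=False)


def load_default_modes() -> ModeRepertoire:
    """The packaged twenty-mode default repertoire (shares sum to exactly 100)."""
    return ModeRepertoire(
        modes=tuple(BehaviorMode(name=n, percent=p) for n, p in DEFAULT_MODE_TABLE)
    )


@dataclass(frozen=True)
class EnvironmentSignal:
    """Timed environmental input: evidence weights per mode and a priority level.

    ``sequence`` optionally names an explicit program sequence the signal
    demands; when absent, interrupts derive one from the evidence weights
    in descending order.
    """

    time: float
    evidence: dict[str, float] = field(default_factory=dict)
    priority: float = 0.0
    sequence: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for name, w in self.evidence.items():
            if w < 0:
                raise ValidationError(f"evidence weight for {name!r} must be >= 0")

    def derived_sequence(self) -> tuple[str, ...]:
        if self.sequence is not None:
            return tuple(self.sequence)
        ranked = sorted(
            (name for name, w in self.evidence.items() if w > 0),
            key=lambda name: (-self.evidence[name], name),
        )
        return tuple(ranked)


@dataclass
class ActiveProgram:
    """The currently commanding loop program and its execution pointer."""

    name: str
    loop: HamiltonLoop
    step: int = 0
    priority: float = 0.0


@dataclass
class CommandState:
    """Mutable simulator state: active program, pending queue, clock, outcome log."""

    active_program: ActiveProgram | None = None
    queue: list[str] = field(default_factory=list)
    clock: float = 0.0
    outcome_log: list[tuple[str, ProgramOutcome]] = field(default_factory=list)

    def log(self, program: str, outcome: ProgramOutcome) -> None:
        self.outcome_log.append((program, outcome))


def abductive_select(
    signal: EnvironmentSignal,
    repertoire: ModeRepertoire,
    state: CommandState | None = None,
    gains: dict[str, float] | None = None,
) -> BehaviorMode:
    """Select the mode with maximal weighted evidence.

    The relation weighting is a product of the signal's evidence with a
    per-mode gain (default 1).  Ties break on the repertoire's prior
    percent, then on name order — so an all-zero signal selects the
    highest-prior mode.
    """
    if len(repertoire) == 0:
        raise ConfigurationError("cannot select from an empty repertoire")
    gains = gains or {}

    def score(mode: BehaviorMode) -> tuple[float, float, str]:
        weight = signal.evidence.get(mode.name, 0.0) * gains.get(mode.name, 1.0)
        # sort key: maximal weight, then maximal prior, then earliest name
        return (-weight, -mode.percent, mode.name)

    return min(repertoire, key=score)


def execute_program_sequence(
    state: CommandState, programs: list[tuple[str, HamiltonLoop]]
) -> tuple[CommandState, pd.DataFrame]:
    """Traverse each program's loop step by step, advancing the clock per step.

    Returns the updated state and a trace with one row per loop step
    (time, program, vertex rank).  Invalid loops log ERROR_NO_CYCLE and are
    skipped; the remaining programs still run.
    """
    rows: list[tuple[float, str, int]] = []
    for name, loop in programs:
        verdict = verify_loop(loop)
        if not verdict.valid:
            state.log(name, ProgramOutcome.ERROR_NO_CYCLE)
            continue
        state.active_program = ActiveProgram(name=name, loop=loop)
        for step, rank in enumerate(loop.visit_ranks(), start=1):
            state.active_program.step = step
            rows.append((state.clock, name, rank))
            state.clock += 1.0
    state.active_program = None
    trace = pd.DataFrame(rows, columns=["time", "program", "vertex"])
    return state, trace


def interrupt_reprioritize(state: CommandState, signal: EnvironmentSignal) -> CommandState:
    """Preempt the active program if the signal outranks it.

    On preemption the active program is logged REJECTED_BY_PRIORITY and the
    queue is replaced by the signal's program sequence; a signal at or
    below the active priority leaves the state unchanged.
    """
    if state.active_program is None:
        raise ValidationError("interrupt requires an active program")
    if signal.priority <= state.active_program.priority:
        return state
    state.log(state.active_program.name, ProgramOutcome.REJECTED_BY_PRIORITY)
    state.queue = list(signal.derived_sequence())
    state.active_program = None
    return state


@dataclass
class ProgramMemory:
    """Activation counts and the imprinted set; imprinting is the only learning."""

    imprint_threshold: int = 3
    activations: dict[str, int] = field(default_factory=dict)
    imprinted: set[str] = field(default_factory=set)


def classify_outcome(
    program: str,
    verify_result: LoopVerdict,
    evidence_weight: float,
    outranked: bool,
    memory: ProgramMemory,
    known_programs: set[str] | None = None,
) -> ProgramOutcome:
    """Map one completed (or failed) program attempt to its realization outcome.

    An invalid loop cannot have been sensorily reinforced; that
    inconsistent combination is rejected.  Valid attempts are, in order:
    outranked, unreinforced, novel (not yet in the repertoire or memory),
    imprinted (once activations reach the threshold), or plainly activated.
    """
    if not verify_result.valid:
        if evidence_weight > 0:
            raise ValidationError(
                f"inconsistent classification inputs for {program!r}: "
                "reinforced but invalid"
            )
        return ProgramOutcome.ERROR_NO_CYCLE
    if outranked:
        return ProgramOutcome.REJECTED_BY_PRIORITY
    if evidence_weight <= 0:
        return ProgramOutcome.CYCLE_NOT_REINFORCED
    known = known_programs if known_programs is not None else set()
    count = memory.activations.get(program, 0) + 1
    memory.activations[program] = count
    if count >= memory.imprint_threshold:
        memory.imprinted.add(program)
        return ProgramOutcome.IMPRINTED
    if program in known or program in memory.imprinted:
        return ProgramOutcome.CYCLE_ACTIVATED
    return ProgramOutcome.NOVEL_CYCLE


def run_schedule(
    repertoire: ModeRepertoire,
    duration: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a stochastic mode sequence and summarize empirical time shares.

    One step is one loop traversal; the mode at each step is drawn
    independently with probability proportional to its percent, which makes
    dwell times geometric and expected shares equal to the configured
    percents.  Returns a summary with expected and empirical percent per
    mode; the empirical column sums to 100.
    """
    if duration <= 0:
        raise ValidationError(f"duration must be a positive number of steps, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [m.name for m in repertoire]
    weights = np.array([m.percent for m in repertoire], dtype=float)
    probs = weights / weights.sum()
    draws = rng.choice(len(names), size=int(duration), p=probs)
    counts = np.bincount(draws, minlength=len(names))
    return pd.DataFrame(
        {
            "mode": names,
            "expected_percent": probs * 100.0,
            "empirical_percent": counts / float(duration) * 100.0,
            "steps": counts,
        }
    )


def schedule_sequence(
    repertoire: ModeRepertoire,
    duration: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """The raw per-step mode sequence underlying :func:`run_schedule` (same draw law)."""
    if duration <= 0:
        raise ValidationError(f"duration must be a positive number of steps, got {duration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    names = [m.name for m in repertoire]
    weights = np.array([m.percent for m in repertoire], dtype=float)
    draws = rng.choice(len(names), size=int(duration), p=weights / weights.sum())
    return [names[i] for i in draws]


def default_loop_binding(
    repertoire: ModeRepertoire, n: int = 4
) -> dict[str, HamiltonLoop]:
    """Bind modes to loop programs in canonical enumeration order.

    Modes are assigned, in table order, the exhaustively enumerated
    undirected loops of the n-valued system sorted by canonical key.  The
    repertoire must not exceed the loop supply (20 modes fit comfortably in
    the 44 quadrivalent loops).
    """
    from retiform.hamilton import canonicalize_loop, enumerate_loops

    enum = enumerate_loops(n, "undirected")
    ordered = sorted(enum.loops, key=lambda lp: canonicalize_loop(lp, "undirected"))
    if len(repertoire) > len(ordered):
        raise ConfigurationError(
            f"repertoire has {len(repertoire)} modes but the n={n} system "
            f"only supplies {len(ordered)} undirected loops"
        )
    return {mode.name: loop for mode, loop in zip(repertoire, ordered)}


def run_scenario(
    repertoire: ModeRepertoire,
    scenario: list[EnvironmentSignal],
    binding: dict[str, HamiltonLoop] | None = None,
    memory: ProgramMemory | None = None,
) -> tuple[CommandState, pd.DataFrame]:
    """Drive the command architecture through a timed scenario script.

    Signals are processed in time order.  While a program sequence is
    running, a higher-priority signal preempts it (the preempted program is
    logged REJECTED_BY_PRIORITY and the signal's sequence replaces the
    queue); otherwise the signal's abductively selected program is
    enqueued.  Queued programs are then executed to completion and each
    attempt is classified.
    """
    binding = binding if binding is not None else default_loop_binding(repertoire)
    memory = memory or ProgramMemory()
    known = set(binding)
    state = CommandState()
    rows: list[tuple[float, str, int]] = []
    events: list[EnvironmentSignal] = sorted(scenario, key=lambda s: s.time)
    current_signal: EnvironmentSignal | None = None
    current_priority = 0.0
    active_ranks: list[int] = []

    def install(signal: EnvironmentSignal) -> None:
        nonlocal current_signal, current_priority
        selected = abductive_select(signal, repertoire, state)
        seq = signal.derived_sequence() or (selected.name,)
        state.queue = [nm for nm in seq if nm in binding]
        current_signal, current_priority = signal, signal.priority

    while events or state.queue or state.active_program is not None:
        if state.active_program is None and state.queue:
            name = state.queue.pop(0)
            loop = binding[name]
            verdict = verify_loop(loop)
            if not verdict.valid:
                state.log(name, ProgramOutcome.ERROR_NO_CYCLE)
                continue
            state.active_program = ActiveProgram(
                name=name, loop=loop, priority=current_priority
            )
            active_ranks = loop.visit_ranks()
            continue
        if state.active_program is not None:
            if events and events[0].time <= state.clock:
                signal = events.pop(0)
                interrupt_reprioritize(state, signal)
                if state.active_program is None:  # preempted mid-program
                    state.queue = [nm for nm in state.queue if nm in binding]
                    current_signal, current_priority = signal, signal.priority
                continue
            active = state.active_program
            rows.append((state.clock, active.name, active_ranks[active.step]))
            active.step += 1
            state.clock += 1.0
            if active.step == len(active_ranks):
                evidence = (
                    current_signal.evidence.get(active.name, 0.0) if current_signal else 0.0
                )
                state.log(
                    active.name,
                    classify_outcome(
                        active.name,
                        verify_loop(active.loop),
                        evidence,
                        False,
                        memory,
                        known_programs=known,
                    ),
                )
                state.active_program = None
            continue
        # idle: jump the clock to the next signal and select a program for it
        signal = events.pop(0)
        state.clock = max(state.clock, signal.time)
        install(signal)

    trace = pd.DataFrame(rows, columns=["time", "program", "vertex"])
    return state, trace
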