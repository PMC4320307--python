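"""Gap-junctional plaque: a container of loop programs with channel turnover.

A plaque stores a repertoire of Hamilton-loop programs closed under
reversal (each undirected loop contributes a forward and a reverse
program) together with a population of unit channels, only a small target
fraction of which is functional at any time.  Channel kinetics follow a
memoryless birth-death process: functional channels decay with a
configured half-life and nonfunctional ones are renewed at the balancing
rate that pins the expected functional fraction at the target.  On a
slower clock the whole plaque dissolves and reassembles, preserving its
loop repertoire (the embodiment is redundant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from retiform.errors import ConfigurationError, ValidationError
from retiform.hamilton import HamiltonLoop, canonicalize_loop, reverse_loop, verify_loop


@dataclass(frozen=True)
class PlaqueParams:
    """Kinetic parameters; defaults sit mid-range of the reported biology."""

    half_life_h: float = 2.5
    target_functional_fraction: float = 0.10
    plaque_lifetime_h: float = 4.0
    renewal_enabled: bool = True

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ConfigurationError(f"half_life_h must be > 0, got {self.half_life_h}")
        if not 0.0 <= self.target_functional_fraction <= 1.0:
            raise ConfigurationError(
                f"target_functional_fraction must lie in [0, 1], got {self.target_functional_fraction}"
            )
        if self.plaque_lifetime_h <= 0:
            raise ConfigurationError(
                f"plaque_lifetime_h must be > 0, got {self.plaque_lifetime_h}"
            )


@dataclass(frozen=True)
class Plaque:
    """Immutable plaque state; turnover steps return new states."""

    programs: tuple[HamiltonLoop, ...]
    channels: np.ndarray = field(repr=False)  # boolean: True = functional
    params: PlaqueParams = field(default_factory=PlaqueParams)
    age_h: float = 0.0

    @property
    def channel_count(self) -> int:
        return int(self.channels.size)

    @property
    def program_count(self) -> int:
        return len(self.programs)


def _initial_channels(channel_count: int, fraction: float) -> np.ndarray:
    functional = round(channel_count * fraction)
    states = np.zeros(channel_count, dtype=bool)
    states[:functional] = True
    return states


def build_plaque(
    loops,
    channel_count: int,
    params: PlaqueParams | None = None,
) -> Plaque:
    """Assemble a plaque from undirected loops, closing the set under reversal.

    Duplicate inputs (same undirected canonical key) are stored once; the
    stored directed program count is twice the number of distinct
    undirected loops.  Channels start at the target functional fraction
    (rounded to a whole channel count).
    """
    params = params or PlaqueParams()
    loops = list(loops)
    if not loops:
        raise ConfigurationError("a plaque needs at least one loop program")
    if channel_count < 1:
        raise ConfigurationError(f"channel_count must be >= 1, got {channel_count}")
    unique: dict[tuple, HamiltonLoop] = {}
    for loop in loops:
        verdict = verify_loop(loop)
        if not verdict:
            raise ValidationError(
                f"invalid loop in plaque input ({verdict.kind} at step {verdict.step})"
            )
        unique.setdefault(canonicalize_loop(loop, "undirected"), loop)
    programs: list[HamiltonLoop] = []
    for loop in unique.values():
        programs.append(loop)
        programs.append(reverse_loop(loop))
    return Plaque(
        programs=tuple(programs),
        channels=_initial_channels(channel_count, params.target_functional_fraction),
        params=params,
    )


def functional_fraction(p: Plaque) -> float:
    """Functional channel count / total, in [0, 1]."""
    return float(np.count_nonzero(p.channels)) / p.channel_count


def step_turnover(p: Plaque, dt: float, rng: np.random.Generator | int) -> Plaque:
    """Advance channel kinetics by ``dt`` hours.

    Each functional channel survives with probability ``2**(-dt/half_life)``;
    nonfunctional channels convert at the balancing rate that keeps the
    expected functional fraction at the target.  If the plaque's age
    crosses its lifetime it dissolves and reassembles: channels are redrawn
    at the target fraction and the loop repertoire is untouched.
    """
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    params = p.params
    survive = 2.0 ** (-dt / params.half_life_h)
    f_star = params.target_functional_fraction
    # stationarity: f* = f*·s + (1-f*)·b  =>  b = f*(1-s)/(1-f*)
    birth = 0.0
    if params.renewal_enabled and f_star < 1.0:
        birth = f_star * (1.0 - survive) / (1.0 - f_star)
    draws = rng.random(p.channel_count)
    nxt = np.where(p.channels, draws < survive, draws < birth)
    age = p.age_h + dt
    if age >= params.plaque_lifetime_h:
        nxt = _initial_channels(p.channel_count, f_star)
        age = age % params.plaque_lifetime_h
    return replace(p, channels=nxt, age_h=age)


def simulate_turnover(
    p: Plaque,
    duration_h: float,
    dt: float,
    seed: int | np.random.Generator = 0,
    dissolve: bool = True,
) -> pd.DataFrame:
    """Run the kinetics and return a (time_h, functional_fraction) time series.

    ``dissolve=False`` suppresses the scheduled dissolution/reassembly so
    the pure birth-death trajectory can be observed.
    """
    if duration_h <= 0 or dt <= 0:
        raise ValidationError("duration_h and dt must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not dissolve:
        p = replace(p, params=replace(p.params, plaque_lifetime_h=float("inf")))
    times = [0.0]
    fractions = [functional_fraction(p)]
    t = 0.0
    while t < duration_h - 1e-12:
        p = step_turnover(p, dt, rng)
        t += dt
        times.append(t)
        fractions.append(functional_fraction(p))
    return pd.DataFrame({"time_h": times, "functional_fraction": fractions})
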