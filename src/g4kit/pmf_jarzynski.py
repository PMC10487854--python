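"""Stage-wise Jarzynski free-energy reconstruction for steered-MD pulling.

In adaptive steered MD the reaction coordinate (here the quadruplex
channel axis) is divided into contiguous stages; in each stage an ensemble
of pulling trajectories yields terminal nonequilibrium work values W_i,
and the stage free-energy change follows from Jarzynski's equality

    dF = -kB T ln < exp(-W / kB T) >,

evaluated with log-sum-exp stabilisation.  Stage increments are stitched
into a potential-of-mean-force profile anchored at zero, from which
barrier heights along the channel are read off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB_KCAL",
    "WorkStage",
    "PMFProfile",
    "stage_free_energy",
    "stitch_pmf",
    "select_seed_trajectory",
    "barrier_height",
]

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872


@dataclass(frozen=True)
class WorkStage:
    """Terminal work samples of one pulling stage."""

    stage_index: int  # 1-based
    start_position: float  # A along the reaction coordinate
    length: float  # A pulled in this stage
    works: tuple[float, ...]  # kcal/mol, one per trajectory

    def __post_init__(self) -> None:
        if self.stage_index < 1:
            raise ValueError("stage_index must be >= 1")
        if self.length <= 0:
            raise ValueError("stage length must be positive")
        if len(self.works) < 1:
            raise ValueError("stage needs at least one work value")
        if not all(math.isfinite(w) for w in self.works):
            raise ValueError("work values must be finite")


@dataclass(frozen=True)
class PMFProfile:
    """Free-energy profile at stage boundaries, anchored at zero."""

    positions: tuple[float, ...]  # A
    free_energy: tuple[float, ...]  # kcal/mol
    temperature: float  # K

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.free_energy):
            raise ValueError("positions and free_energy must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if abs(self.free_energy[0]) > 1e-12:
            raise ValueError("profile must be anchored at zero")

    def value_at(self, position: float) -> float:
        """Linear interpolation of the profile."""
        return float(np.interp(position, self.positions, self.free_energy))


def stage_free_energy(works: Sequence[float], temperature: float = 300.0) -> float:
    """Jarzynski estimate dF = -kB T ln <exp(-W/kB T)> in kcal/mol.

    Uses log-sum-exp so work values spanning hundreds of kcal/mol do not
    overflow.  By Jensen's inequality the estimate never exceeds the mean
    work.
    """
    w = np.asarray(works, float)
    if w.size == 0:
        raise ValueError("works must be non-empty")
    if not np.all(np.isfinite(w)):
        raise ValueError("work values must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (KB_KCAL * temperature)
    return float(-(logsumexp(-beta * w) - math.log(w.size)) / beta)


def stitch_pmf(stages: Sequence[WorkStage], temperature: float = 300.0) -> PMFProfile:
    """Cumulative free-energy profile from contiguous ordered stages.

    Stage i+1 must start where stage i ends; the profile has one point per
    stage boundary, starting at 0 at the first stage's start position.
    """
    if not stages:
        raise ValueError("need at least one stage")
    positions = [stages[0].start_position]
    energies = [0.0]
    for prev, cur in zip(stages, stages[1:]):
        expected = prev.start_position + prev.length
        if not math.isclose(cur.start_position, expected, abs_tol=1e-9):
            raise ValueError(
                f"stage {cur.stage_index} starts at {cur.start_position}, "
                f"expected {expected} (stages must be contiguous)"
            )
    for st in stages:
        positions.append(st.start_position + st.length)
        energies.append(energies[-1] + stage_free_energy(st.works, temperature))
    return PMFProfile(tuple(positions), tuple(energies), temperature)


def select_seed_trajectory(stage: WorkStage, temperature: float = 300.0) -> int:
    """Index of the trajectory whose terminal work is closest to the
    stage's Jarzynski free energy (the adaptive-steering handoff rule);
    ties resolve to the lowest index."""
    dF = stage_free_energy(stage.works, temperature)
    diffs = np.abs(np.asarray(stage.works, float) - dF)
    return int(np.argmin(diffs))


def barrier_height(profile: PMFProfile, window: tuple[float, float]) -> float:
    """max(free energy) within ``window`` minus the value at the window
    start, in kcal/mol."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    pos = np.asarray(profile.positions)
    fe = np.asarray(profile.free_energy)
    if lo < pos[0] - 1e-9 or hi > pos[-1] + 1e-9:
        raise ValueError("window outside profile range")
    mask = (pos >= lo) & (pos <= hi)
    candidates = list(fe[mask]) + [profile.value_at(lo), profile.value_at(hi)]
    return float(max(candidates) - profile.value_at(lo))
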