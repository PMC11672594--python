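"""Reaction free-energy profile bookkeeping for the hemiketal mechanisms.

The profile builder consumes printed stage free energies (kcal/mol) —
no electronic-structure computation happens here. Transition-state
energies are stored as barrier heights relative to their preceding
minimum; whether a published barrier is referenced to the reactant or to
the preceding intermediate is flagged as ambiguous where the source does
not say (``reference`` field).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EnergyState",
    "ReactionPath",
    "build_profile",
    "solve_missing_stage",
    "compare_barriers",
    "check_consistency",
    "PATH1_STAGES",
    "PATH2_STAGES",
    "PATH1_BARRIERS",
    "PATH2_BARRIERS",
    "PATH2_PRINTED_OVERALL",
    "packaged_paths",
]


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyState:
    label: str
    delta_g: float  # kcal/mol relative to the reactant R
    kind: str  # minimum | transition


@dataclass(frozen=True)
class ReactionPath:
    path_id: int | str
    states: tuple[EnergyState, ...]
    stage_deltas: tuple[tuple[str, str, float], ...]
    reference: str = "barrier heights relative to the preceding minimum"

    @property
    def minima(self) -> tuple[EnergyState, ...]:
        return tuple(s for s in self.states if s.kind == "minimum")

    @property
    def transition_states(self) -> tuple[EnergyState, ...]:
        return tuple(s for s in self.states if s.kind == "transition")

    @property
    def overall(self) -> float:
        """Telescoped reactant-to-product free-energy change."""
        return self.minima[-1].delta_g - self.minima[0].delta_g

    def highest_barrier(self) -> tuple[str, float] | None:
        """(label, barrier height above the preceding minimum) or None."""
        best = None
        for i, state in enumerate(self.states):
            if state.kind != "transition":
                continue
            prev_min = next(
                s for s in reversed(self.states[:i]) if s.kind == "minimum"
            )
            height = state.delta_g - prev_min.delta_g
            if best is None or height > best[1]:
                best = (state.label, height)
        return best


def build_profile(
    stage_deltas: list[tuple[str, str, float]],
    barriers: dict[tuple[str, str], float] | None = None,
    path_id: int | str = 1,
) -> ReactionPath:
    """Accumulate stage free energies into a profile anchored at R = 0.

    *stage_deltas* is an ordered list of ``(from_label, to_label, dG)``
    forming a connected chain starting at ``R``. *barriers* optionally
    places a transition state inside a stage, given as its height above
    the stage's starting minimum.
    """
    barriers = barriers or {}
    cumulative = {"R": 0.0}
    states = [EnergyState("R", 0.0, "minimum")]
    previous = "R"
    for n, (src, dst, dg) in enumerate(stage_deltas, start=1):
        if src != previous:
            raise ProfileError(
                f"stage {n} starts at {src!r} but the chain is at {previous!r}: disconnected"
            )
        if (src, dst) in barriers:
            states.append(
                EnergyState(f"TS{len([s for s in states if s.kind == 'transition']) + 1}",
                            cumulative[src] + barriers[(src, dst)], "transition")
            )
        cumulative[dst] = cumulative[src] + dg
        states.append(EnergyState(dst, cumulative[dst], "minimum"))
        previous = dst
    path = ReactionPath(
        path_id=path_id, states=tuple(states), stage_deltas=tuple(stage_deltas)
    )
    for ts_label, height in filter(None, [path.highest_barrier()]):
        if height < 0:
            raise ProfileError(f"{ts_label}: negative barrier relative to preceding minimum")
    return path


def solve_missing_stage(
    stage_deltas: list[tuple[str, str, float | None]], overall: float
) -> list[tuple[str, str, float]]:
    """Fill in the single unknown stage so the stages telescope to *overall*."""
    unknown = [i for i, (_, _, dg) in enumerate(stage_deltas) if dg is None]
    if len(unknown) != 1:
        raise ProfileError(f"exactly one unknown stage required, found {len(unknown)}")
    known_sum = sum(dg for _, _, dg in stage_deltas if dg is not None)
    solved = list(stage_deltas)
    src, dst, _ = solved[unknown[0]]
    solved[unknown[0]] = (src, dst, overall - known_sum)
    return solved


@dataclass(frozen=True)
class BarrierRanking:
    ranked: tuple[tuple[int | str, str, float], ...]  # (path_id, TS label, height)
    excluded: tuple[int | str, ...]
    tie: bool


def compare_barriers(paths: list[ReactionPath]) -> BarrierRanking:
    """Rank paths by their highest barrier, ascending; ties reported."""
    entries = []
    excluded = []
    for path in paths:
        best = path.highest_barrier()
        if best is None:
            excluded.append(path.path_id)
        else:
            entries.append((path.path_id, best[0], best[1]))
    entries.sort(key=lambda e: e[2])
    tie = len(entries) >= 2 and abs(entries[0][2] - entries[1][2]) < 1e-9
    return BarrierRanking(ranked=tuple(entries), excluded=tuple(excluded), tie=tie)


def check_consistency(
    path: ReactionPath, printed_overall: float, tolerance: float
) -> dict:
    """Does the telescoped overall match the printed value within tolerance?"""
    if tolerance < 0:
        raise ProfileError("tolerance must be non-negative")
    deviation = abs(path.overall - printed_overall)
    return {
        "path_id": path.path_id,
        "telescoped_overall": path.overall,
        "printed_overall": printed_overall,
        "deviation": deviation,
        "consistent": deviation <= tolerance,
    }


# ---------------------------------------------------------------------------
# Packaged stage fixtures (printed stage free energies, kcal/mol).
# Path 1: olefin shift then cyclization; Path 2: electrocyclization then
# water addition. Path 2's final stage is not printed; it is solved from
# the printed overall.
# ---------------------------------------------------------------------------

PATH1_STAGES: tuple = (("R", "1", -2.9), ("1", "P", -6.84))
PATH1_BARRIERS: dict = {("1", "P"): 31.6}

PATH2_STAGES: tuple = (("R", "1", 2.45), ("1", "2", -1.76), ("2", "P", None))
PATH2_BARRIERS: dict = {("1", "2"): 25.6, ("2", "P"): 35.0}
PATH2_PRINTED_OVERALL = -4.2
PATH1_PRINTED_OVERALL = -9.73


def packaged_paths() -> tuple[ReactionPath, ReactionPath]:
    """Build both packaged mechanism profiles from the printed stages."""
    path1 = build_profile(list(PATH1_STAGES), PATH1_BARRIERS, path_id=1)
    solved = solve_missing_stage(list(PATH2_STAGES), PATH2_PRINTED_OVERALL)
    path2 = build_profile(solved, PATH2_BARRIERS, path_id=2)
    return path1, path2
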