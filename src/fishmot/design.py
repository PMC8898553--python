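"""Trial enumeration for the two tracking experiments.

Experiment 1: 23 aquarium videos x set sizes {1, 3, 5} x two query
types (target queried / distractor queried) = 138 trials, query type
balanced at exactly 50%.

Experiment 2: three within-subject conditions (fish, fake-fish,
traditional MOT), each with 23 stimuli x loads {2, 4} x two query
types = 92 trials per condition; block order counterbalanced over the
3! = 6 orderings; trial order shuffled per participant.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = [
    "Condition",
    "TrialSpec",
    "build_design_exp1",
    "build_design_exp2",
    "counterbalance_orders",
    "shuffle_trials",
    "design_to_frame",
    "write_design_csv",
    "read_design_csv",
    "CUE_DURATION_S",
    "FIXATION_DURATION_S",
    "TRACK_DURATION_S",
]

# trial-phase timing, recorded as metadata constants
CUE_DURATION_S = 3.0
FIXATION_DURATION_S = 0.075
TRACK_DURATION_S = 10.0


class Condition(enum.Enum):
    FISH = "FISH"
    FAKEFISH = "FAKEFISH"
    TRADITIONAL = "TRADITIONAL"


@dataclass
class TrialSpec:
    """Design of one tracking trial."""

    trial_id: str
    condition: Condition
    stim_id: str
    n_targets: int
    target_ids: frozenset
    queried_id: str
    queried_is_target: bool

    def __post_init__(self) -> None:
        if (self.queried_id in self.target_ids) != self.queried_is_target:
            raise InvalidInputError("queried_id/target membership inconsistent")
        if len(self.target_ids) != self.n_targets:
            raise InvalidInputError("target set size mismatch")


def _objects_for(video, n_objects) -> list[str]:
    count = n_objects[video] if isinstance(n_objects, dict) else int(n_objects)
    return [f"{video}_f{j}" for j in range(count)]


def _make_trial(
    trial_id: str,
    condition: Condition,
    stim_id: str,
    objects: list[str],
    n_targets: int,
    query_target: bool,
    rng: np.random.Generator,
) -> TrialSpec:
    if n_targets >= len(objects):
        raise InvalidInputError(
            f"set size {n_targets} >= object count {len(objects)} in {stim_id}"
        )
    targets = rng.choice(len(objects), size=n_targets, replace=False)
    target_ids = frozenset(objects[i] for i in targets)
    if query_target:
        queried = objects[int(rng.choice(targets))]
    else:
        non_targets = [o for o in objects if o not in target_ids]
        queried = non_targets[int(rng.integers(len(non_targets)))]
    return TrialSpec(
        trial_id=trial_id,
        condition=condition,
        stim_id=stim_id,
        n_targets=n_targets,
        target_ids=target_ids,
        queried_id=queried,
        queried_is_target=query_target,
    )


def build_design_exp1(
    videos: list,
    set_sizes: list[int] = (1, 3, 5),
    n_objects: int | dict = 16,
    seed: int = 0,
) -> list[TrialSpec]:
    """Two trials (one per query type) per video and set size.

    Target sets are drawn uniformly without replacement, independently
    for each trial; the queried distractor is uniform among non-targets.
    23 videos x 3 set sizes x 2 query types = 138 trials, half of them
    target queries.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for video in videos:
        objects = _objects_for(video, n_objects)
        for size in set_sizes:
            for query_target in (True, False):
                tag = "t" if query_target else "d"
                trials.append(
                    _make_trial(
                        trial_id=f"e1_{video}_s{size}_{tag}",
                        condition=Condition.FISH,
                        stim_id=str(video),
                        objects=objects,
                        n_targets=size,
                        query_target=query_target,
                        rng=rng,
                    )
                )
    return trials


def build_design_exp2(
    videos: list,
    loads: list[int] = (2, 4),
    condition: Condition = Condition.FISH,
    n_objects: int | dict = 16,
    seed: int = 0,
) -> list[TrialSpec]:
    """One condition's block: stimuli x loads x query types.

    The fish condition reuses the same video at both loads; the circle
    conditions use trajectory sets unique to the condition, which the
    stimulus identifier makes explicit.
    """
    rng = np.random.default_rng(seed)
    trials = []
    for video in videos:
        for load in loads:
            if condition is Condition.FISH:
                stim_id = str(video)
            else:
                stim_id = f"{condition.value.lower()}_{video}"
            objects = _objects_for(stim_id if condition is not Condition.FISH else video, n_objects)
            for query_target in (True, False):
                tag = "t" if query_target else "d"
                trials.append(
                    _make_trial(
                        trial_id=f"e2_{condition.value.lower()}_{video}_l{load}_{tag}",
                        condition=condition,
                        stim_id=stim_id,
                        objects=objects,
                        n_targets=load,
                        query_target=query_target,
                        rng=rng,
                    )
                )
    return trials


def counterbalance_orders(
    conditions: list[Condition] | list[str] = tuple(Condition),
    n_participants: int = 52,
) -> dict[int, tuple]:
    """Round-robin assignment of participants to the 3! block orderings.

    Returns participant index -> ordering tuple; the counts of any two
    orderings differ by at most one.
    """
    if n_participants < 1:
        raise InvalidInputError("n_participants must be >= 1")
    orderings = list(itertools.permutations(conditions))
    return {p: orderings[p % len(orderings)] for p in range(n_participants)}


def shuffle_trials(trials: list[TrialSpec], participant_seed: int) -> list[TrialSpec]:
    """Deterministic per-participant permutation of the trial list."""
    rng = np.random.default_rng(participant_seed)
    order = rng.permutation(len(trials))
    return [trials[i] for i in order]


def design_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in trials],
            "condition": [t.condition.value for t in trials],
            "stim_id": [t.stim_id for t in trials],
            "n_targets": [t.n_targets for t in trials],
            "target_ids": [";".join(sorted(t.target_ids)) for t in trials],
            "queried_id": [t.queried_id for t in trials],
            "queried_is_target": [t.queried_is_target for t in trials],
        }
    )


def write_design_csv(trials: list[TrialSpec], path) -> None:
    design_to_frame(trials).to_csv(path, index=False)


def read_design_csv(path) -> list[TrialSpec]:
    df = pd.read_csv(path)
    return [
        TrialSpec(
            trial_id=row.trial_id,
            condition=Condition(row.condition),
            stim_id=str(row.stim_id),
            n_targets=int(row.n_targets),
            target_ids=frozenset(str(row.target_ids).split(";")),
            queried_id=str(row.queried_id),
            queried_is_target=bool(row.queried_is_target),
        )
        for row in df.itertuples()
    ]
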