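"""Combine two complementary one-vs-rest trait models into a 4-way state call.

A trait like oxygen requirement has more than two states but very uneven
data; instead of one multi-class model, two complementary binary models are
trained (e.g. AEROBE and ANAEROBE, each with the intermediate states as
negatives). Each strain's pair of calls forms a binary vector:

* ``[1 0]`` → state A (e.g. aerobe)
* ``[0 1]`` → state B (e.g. anaerobe)
* ``[0 0]`` → neither — expected for intermediate states (facultative or
  microaerophilic/aerotolerant strains), which both models were trained to
  reject
* ``[1 1]`` → conflict — one of the two models must be wrong; the conflict
  rate is a quality diagnostic and conflicting strains are withheld from
  export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .classifier import Prediction
from .errors import ValidationError

STATE_A = "state_a"
STATE_B = "state_b"
NEITHER = "neither"
CONFLICT = "conflict"


@dataclass(frozen=True)
class PairedStateCall:
    """Combined call of two complementary trait models for one strain."""

    strain_id: str
    conf_a: float
    conf_b: float
    vector: tuple[int, int]
    state: str


def _state_for(vector: tuple[int, int], label_a: str, label_b: str) -> str:
    return {
        (1, 0): label_a,
        (0, 1): label_b,
        (0, 0): NEITHER,
        (1, 1): CONFLICT,
    }[vector]


def combine_paired(
    predictions_a: Iterable[Prediction],
    predictions_b: Iterable[Prediction],
    threshold: float = 0.5,
    label_a: str = STATE_A,
    label_b: str = STATE_B,
) -> list[PairedStateCall]:
    """Map each strain's two confidences onto the 4-way state vector.

    ``vector = (conf_a ≥ threshold, conf_b ≥ threshold)``; the state follows
    the mapping in the module docstring. Both prediction sets must cover the
    same strains.
    """
    conf_a = {p.strain_id: p.confidence for p in predictions_a}
    conf_b = {p.strain_id: p.confidence for p in predictions_b}
    if set(conf_a) != set(conf_b):
        diff = set(conf_a) ^ set(conf_b)
        raise ValidationError(
            f"prediction sets cover different strains (e.g. {sorted(diff)[:5]})"
        )
    calls = []
    for strain in sorted(conf_a):
        vector = (
            int(conf_a[strain] >= threshold),
            int(conf_b[strain] >= threshold),
        )
        calls.append(
            PairedStateCall(
                strain_id=strain,
                conf_a=conf_a[strain],
                conf_b=conf_b[strain],
                vector=vector,
                state=_state_for(vector, label_a, label_b),
            )
        )
    return calls


@dataclass(frozen=True)
class PairedQualitySummary:
    """Contingency of true group × called state, plus the conflict rate."""

    contingency: pd.DataFrame
    conflict_rate: float
    n: int


def paired_quality(
    calls: Iterable[PairedStateCall],
    truth_groups: Mapping[str, str],
    label_a: str = STATE_A,
    label_b: str = STATE_B,
) -> PairedQualitySummary:
    """Summarize paired calls against canonicalized truth groups.

    Rows of the contingency are the true groups, columns the four called
    states; the conflict rate is the fraction of all strains with a [1 1]
    vector.
    """
    calls = list(calls)
    states = [label_a, label_b, NEITHER, CONFLICT]
    rows: dict[str, dict[str, int]] = {}
    n_conflict = 0
    for call in calls:
        group = truth_groups.get(call.strain_id, "unknown")
        rows.setdefault(group, {s: 0 for s in states})[call.state] += 1
        if call.state == CONFLICT:
            n_conflict += 1
    table = pd.DataFrame.from_dict(rows, orient="index", columns=states).fillna(0)
    table = table.sort_index().astype(int)
    n = len(calls)
    return PairedQualitySummary(
        contingency=table,
        conflict_rate=n_conflict / n if n else 0.0,
        n=n,
    )


def write_paired_calls(
    calls: Iterable[PairedStateCall],
    path: str | Path,
    include_conflicts: bool = False,
) -> None:
    """Write paired calls as TSV (strain, conf_a, conf_b, vector, state).

    Conflicting strains are withheld unless ``include_conflicts`` is set.
    """
    rows = [
        {
            "strain_id": c.strain_id,
            "conf_a": c.conf_a,
            "conf_b": c.conf_b,
            "vector": f"{c.vector[0]} {c.vector[1]}",
            "state": c.state,
        }
        for c in calls
        if include_conflicts or c.state != CONFLICT
    ]
    pd.DataFrame(
        rows, columns=["strain_id", "conf_a", "conf_b", "vector", "state"]
    ).to_csv(path, sep="\t", index=False)
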