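"""Counterbalancing design for the two-trial preferential-looking test phase."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

VERBS = ("gorp", "tam")
AGENTS = ("boy", "girl")
ACTIONS = ("A", "B", "C", "D")
SIDES = ("left", "right")


@dataclass(frozen=True)
class DesignRow:
    sequence_id: int
    trial: int
    verb: str
    agent: str
    target_action: str
    distracter_action: str
    target_side: str
    approach_side: str
    first_video: str

    def __post_init__(self) -> None:
        if self.target_action == self.distracter_action:
            raise ValueError("target and distracter actions must differ")
        if self.verb not in VERBS or self.agent not in AGENTS:
            raise ValueError("unknown verb/agent level")
        if self.target_side not in SIDES or self.approach_side not in SIDES:
            raise ValueError("unknown side level")
        if self.first_video not in ("target", "distracter"):
            raise ValueError("first_video must be target or distracter")


# (verb, agent, target, distracter, target_side, approach_side, first_video)
# for trials 1 and 2 of each of the eight counterbalancing sequences.
_SEQUENCES = {
    1: [("gorp", "boy", "D", "C", "right", "left", "target"),
        ("tam", "girl", "A", "B", "left", "left", "distracter")],
    2: [("gorp", "boy", "C", "A", "left", "left", "distracter"),
        ("tam", "girl", "B", "D", "right", "left", "target")],
    3: [("gorp", "girl", "B", "A", "right", "left", "distracter"),
        ("tam", "boy", "C", "D", "left", "left", "target")],
    4: [("gorp", "girl", "A", "C", "left", "left", "target"),
        ("tam", "boy", "D", "B", "right", "left", "distracter")],
    5: [("tam", "girl", "D", "B", "right", "right", "target"),
        ("gorp", "boy", "A", "C", "left", "right", "distracter")],
    6: [("tam", "girl", "C", "D", "left", "right", "distracter"),
        ("gorp", "boy", "B", "A", "right", "right", "target")],
    7: [("tam", "boy", "B", "D", "right", "right", "distracter"),
        ("gorp", "girl", "C", "A", "left", "right", "target")],
    8: [("tam", "boy", "A", "B", "left", "right", "target"),
        ("gorp", "girl", "D", "C", "right", "right", "distracter")],
}


def generate_design() -> list[DesignRow]:
    """The full 8-sequence x 2-trial counterbalancing design.

    Across the 16 rows each action occurs exactly four times as target and
    four times as distracter, and each target side appears eight times.
    """
    rows = []
    for seq, trials in _SEQUENCES.items():
        for trial, spec in enumerate(trials, start=1):
            verb, agent, targ, dist, side, approach, first = spec
            rows.append(
                DesignRow(
                    sequence_id=seq,
                    trial=trial,
                    verb=verb,
                    agent=agent,
                    target_action=targ,
                    distracter_action=dist,
                    target_side=side,
                    approach_side=approach,
                    first_video=first,
                )
            )
    return rows


def design_frame() -> pd.DataFrame:
    """The counterbalancing design as a DataFrame keyed by (sequence_id, trial)."""
    return pd.DataFrame([vars(r) for r in generate_design()])


def design_lookup() -> dict[tuple[int, int], DesignRow]:
    return {(r.sequence_id, r.trial): r for r in generate_design()}
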