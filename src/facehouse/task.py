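"""Block design of the passive face/house viewing task.

A run consists of blocks of stimulus sequences.  Each block shows each of
the four categories (happy, fearful, neutral faces; houses) exactly once, in
a seeded random order.  A sequence is 9 stimuli of one category, each shown
for 1 s followed by a 1 s fixation cross, so a sequence spans 18 s.  A red
circle (button-press attention check) appears as the first stimulus of the
run and after every block; blocks are separated by rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CIRCLE, CONDITIONS


@dataclass
class TaskDesign:
    """Timed events of one task run.

    ``events`` holds stimulus-level entries ``(condition, onset_s,
    duration_s)``; ``sequences`` holds the merged per-sequence spans used to
    build condition boxcars (one 18 s span per 9-stimulus sequence under the
    defaults, trailing fixation included).
    """

    events: list
    n_blocks: int
    sequences_per_block: int
    stimuli_per_sequence: int
    stimulus_s: float
    fixation_s: float
    rest_s: float
    seed: int
    sequences: list = field(default_factory=list)

    def __post_init__(self):
        onsets = [e[1] for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be time-ordered")
        for (_, o1, d1), (_, o2, _) in zip(self.events, self.events[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise ValueError("events must not overlap")

    @property
    def duration(self) -> float:
        last = self.events[-1]
        return last[1] + last[2] + self.fixation_s

    def condition_spans(self, condition: str) -> list:
        """(onset, duration) spans of all sequences of ``condition``."""
        return [(o, d) for c, o, d in self.sequences if c == condition]


def generate_task_design(
    n_blocks: int = 4,
    sequences_per_block: int = 4,
    stimuli_per_sequence: int = 9,
    stimulus_s: float = 1.0,
    fixation_s: float = 1.0,
    rest_s: float = 10.0,
    seed: int = 0,
) -> TaskDesign:
    """Lay out one run of the face/house task.

    Category order within each block is a seeded uniform permutation of the
    four categories.  Circle events (duration ``stimulus_s``) occur at the
    run start and after each block, ``n_blocks + 1`` in total.
    """
    for name, v in [
        ("n_blocks", n_blocks),
        ("sequences_per_block", sequences_per_block),
        ("stimuli_per_sequence", stimuli_per_sequence),
        ("stimulus_s", stimulus_s),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    if fixation_s < 0 or rest_s < 0:
        raise ValueError("durations must be nonnegative")
    if sequences_per_block != len(CONDITIONS):
        # each block must contain each category exactly once
        raise ValueError(
            f"sequences_per_block must equal {len(CONDITIONS)} so each block "
            "shows every category once"
        )

    rng = np.random.default_rng(seed)
    events = []
    sequences = []
    t = 0.0
    soa = stimulus_s + fixation_s

    def circle():
        nonlocal t
        events.append((CIRCLE, t, stimulus_s))
        t += soa

    circle()
    for _ in range(n_blocks):
        order = rng.permutation(len(CONDITIONS))
        for ci in order:
            cond = CONDITIONS[ci]
            seq_onset = t
            for _ in range(stimuli_per_sequence):
                events.append((cond, t, stimulus_s))
                t += soa
            sequences.append((cond, seq_onset, t - seq_onset))
        circle()
        t += rest_s

    return TaskDesign(
        events=events,
        n_blocks=n_blocks,
        sequences_per_block=sequences_per_block,
        stimuli_per_sequence=stimuli_per_sequence,
        stimulus_s=stimulus_s,
        fixation_s=fixation_s,
        rest_s=rest_s,
        seed=seed,
        sequences=sequences,
    )
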