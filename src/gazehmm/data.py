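"""Fixation-sequence data model and tabular I/O.

A :class:`FixationSequence` holds one trial's ordered fixations in a
face-centered coordinate frame: the origin sits at the midpoint between the
two eye centers, x grows rightward and y grows downward, in pixels.  Trials
are presented at varying screen locations upstream, so screen coordinates are
re-expressed relative to the face before they reach this package; the regions
of interest that the HMMs discover are anatomical (eyes, nose, forehead), not
screen-anchored.

Fixation tables on disk are plain CSV with one row per fixation::

    participant_id,trial_id,phase,learn_mask,recog_mask,fix_index,x,y,duration_ms

``fix_index`` is 1-based and rows are sorted within each trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import InputError

PHASE_LEARNING = "learning"
PHASE_RECOGNITION = "recognition"
PHASES = (PHASE_LEARNING, PHASE_RECOGNITION)

MASK_UNMASKED = "unmasked"
MASK_MASKED = "masked"
MASK_NA = "not_applicable"
MASKS = (MASK_UNMASKED, MASK_MASKED)

#: Column order of the fixation CSV format.
FIXATION_COLUMNS = [
    "participant_id",
    "trial_id",
    "phase",
    "learn_mask",
    "recog_mask",
    "fix_index",
    "x",
    "y",
    "duration_ms",
]


@dataclass(frozen=True)
class FixationSequence:
    """Ordered fixations of a single trial.

    Parameters
    ----------
    participant_id, trial_id
        Opaque identifiers; compared only for equality.
    phase
        ``"learning"`` or ``"recognition"``.
    learn_mask, recog_mask
        Mask condition of the face during learning and recognition.
        Learning-phase trials carry ``recog_mask="not_applicable"``.
    fixations
        Array of shape ``(T, 3)`` with columns x, y (pixels, face-centered)
        and duration (milliseconds, strictly positive).
    """

    participant_id: str
    trial_id: str
    phase: str
    learn_mask: str
    recog_mask: str
    fixations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        fx = np.asarray(self.fixations, dtype=float)
        if fx.ndim != 2 or fx.shape[1] != 3 or fx.shape[0] == 0:
            raise InputError("fixations must be a non-empty (T, 3) array")
        if not np.all(np.isfinite(fx[:, :2])):
            raise InputError("fixation coordinates must be finite")
        if np.any(fx[:, 2] <= 0):
            raise InputError("fixation durations must be strictly positive")
        if self.phase not in PHASES:
            raise InputError(f"unknown phase {self.phase!r}")
        if self.learn_mask not in MASKS:
            raise InputError(f"unknown learn_mask {self.learn_mask!r}")
        if self.phase == PHASE_LEARNING:
            if self.recog_mask != MASK_NA:
                raise InputError(
                    "learning-phase sequences must have recog_mask='not_applicable'"
                )
        elif self.recog_mask not in MASKS:
            raise InputError(f"unknown recog_mask {self.recog_mask!r}")
        object.__setattr__(self, "fixations", fx)

    @property
    def positions(self) -> np.ndarray:
        """(T, 2) array of x/y positions."""
        return self.fixations[:, :2]

    @property
    def durations(self) -> np.ndarray:
        """(T,) array of fixation durations in milliseconds."""
        return self.fixations[:, 2]

    def __len__(self) -> int:
        return self.fixations.shape[0]

    @property
    def condition(self) -> tuple[str, str]:
        """(learn_mask, recog_mask) pair identifying the design cell."""
        return (self.learn_mask, self.recog_mask)


def sequences_to_frame(seqs: Iterable[FixationSequence]) -> pd.DataFrame:
    """Flatten sequences into the one-row-per-fixation CSV layout."""
    rows = []
    for s in seqs:
        for i, (x, y, dur) in enumerate(s.fixations, start=1):
            rows.append(
                (s.participant_id, s.trial_id, s.phase, s.learn_mask,
                 s.recog_mask, i, x, y, dur)
            )
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


def frame_to_sequences(df: pd.DataFrame) -> list[FixationSequence]:
    """Group a fixation table into :class:`FixationSequence` objects.

    Rows are ordered by ``fix_index`` within each (participant, trial) group;
    trial order follows first appearance in the table.
    """
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"fixation table is missing columns: {missing}")
    out: list[FixationSequence] = []
    for (pid, tid), g in df.groupby(["participant_id", "trial_id"], sort=False):
        g = g.sort_values("fix_index")
        meta = g.iloc[0]
        out.append(
            FixationSequence(
                participant_id=str(pid),
                trial_id=str(tid),
                phase=str(meta["phase"]),
                learn_mask=str(meta["learn_mask"]),
                recog_mask=str(meta["recog_mask"]),
                fixations=g[["x", "y", "duration_ms"]].to_numpy(dtype=float),
            )
        )
    return out


def write_fixations(seqs: Sequence[FixationSequence], path) -> None:
    sequences_to_frame(seqs).to_csv(path, index=False)


def read_fixations(path) -> list[FixationSequence]:
    return frame_to_sequences(pd.read_csv(path))
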