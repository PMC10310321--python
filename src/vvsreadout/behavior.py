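"""Simulated observers producing trial-level binary choice tables.

An observer responds "dog" (1) or "cat" (0) to each morph image.  Choice
probability follows a lapse-limited logistic psychometric function of morph
level, plus a per-image offset (drawn once per image per observer) that
creates the reliable image-level idiosyncrasies the consistency analyses
measure.  Offsets are resampled per observer, so between-subject image-level
agreement can arise only through the shared stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.special import expit

from ._rng import rng_for
from .stimuli import StimulusSet

__all__ = ["ObserverParams", "ChoiceTable", "simulate_observer", "CHOICE_COLUMNS"]

CHOICE_COLUMNS = [
    "subject_id",
    "group",
    "experiment_id",
    "sequence_id",
    "morph_level_pct",
    "image_id",
    "repetition",
    "response",
    "correct",
]


@dataclass(frozen=True)
class ObserverParams:
    """Psychometric parameters of a simulated observer.

    slope : logit units per morph percent (steepness about the boundary)
    bias : point of subjective equality, in morph percent
    lapse : lapse rate in [0, 0.5]; choice probabilities are confined to
        [lapse/2, 1 - lapse/2]
    image_effect_sd : SD (logit units) of fixed per-image offsets shared
        across repetitions — the source of reliable image-level variance
    """

    slope: float = 0.15
    bias: float = 50.0
    lapse: float = 0.02
    image_effect_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.image_effect_sd < 0:
            raise ValueError("image_effect_sd must be >= 0")


class ChoiceTable:
    """Trial-level binary responses; convention dog = 1, cat = 0."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"choice table missing columns: {missing}")
        self.df = df.reset_index(drop=True)[CHOICE_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())

    def for_subject(self, subject_id: str, experiment_id: str | None = None) -> "ChoiceTable":
        sub = self.df[self.df["subject_id"] == subject_id]
        if experiment_id is not None:
            sub = sub[sub["experiment_id"] == experiment_id]
        return ChoiceTable(sub)

    def validate(self, stimuli: StimulusSet | None = None) -> None:
        df = self.df
        if not df["response"].isin([0, 1]).all():
            raise ValueError("responses must be binary 0/1")
        if not df["correct"].isin([0, 1]).all():
            raise ValueError("correct must be binary 0/1")
        reps = df.groupby(["subject_id", "image_id"])["repetition"].apply(
            lambda r: sorted(r) == list(range(1, len(r) + 1))
        )
        if not reps.all():
            raise ValueError("repetitions must be consecutive integers starting at 1")
        if stimuli is not None:
            for row in df.itertuples(index=False):
                if int(row.correct) != int(row.response == stimuli.category_label(row.image_id)):
                    raise ValueError(f"correct flag inconsistent for image {row.image_id}")

    @staticmethod
    def concat(tables: list["ChoiceTable"]) -> "ChoiceTable":
        return ChoiceTable(pd.concat([t.df for t in tables], ignore_index=True))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(path, index=False, columns=CHOICE_COLUMNS)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChoiceTable":
        return cls(pd.read_csv(path))


def simulate_observer(
    stimuli: StimulusSet,
    params: ObserverParams,
    n_reps: int,
    subject_id: str = "s0",
    group: str = "intact",
) -> ChoiceTable:
    """Simulate ``n_reps`` Bernoulli choices per image.

    P(dog | image) = lapse/2 + (1 - lapse) * expit(slope * (level - bias) + offset)
    with offset ~ Normal(0, image_effect_sd) drawn once per image.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if group not in ("intact", "lesioned"):
        raise ValueError("group must be 'intact' or 'lesioned'")

    rows = []
    for i, (image_id, _) in enumerate(stimuli):
        exp, seq, level = stimuli.index[image_id]
        irng = rng_for(params.seed, "observer", subject_id, image_id)
        offset = irng.normal(0.0, params.image_effect_sd) if params.image_effect_sd > 0 else 0.0
        p_dog = params.lapse / 2 + (1 - params.lapse) * expit(params.slope * (level - params.bias) + offset)
        responses = (irng.random(n_reps) < p_dog).astype(int)
        label = stimuli.category_label(image_id)
        for r, resp in enumerate(responses, start=1):
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "experiment_id": exp,
                    "sequence_id": seq,
                    "morph_level_pct": level,
                    "image_id": image_id,
                    "repetition": r,
                    "response": int(resp),
                    "correct": int(resp == label),
                }
            )
    return ChoiceTable(pd.DataFrame(rows))
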