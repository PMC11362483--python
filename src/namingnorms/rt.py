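"""Recognition-RT cleaning and per-image mean latencies.

Three trimming stages are applied, in this order, to the pool of valid,
known responses (``include_in_rt``):

1. remove latencies longer than 10 s (participant inattention);
2. remove latencies below 200 ms (motor error);
3. remove latencies at least 2.5 SD away from the owning participant's
   mean, where each participant's mean and SD are computed once on the
   pool surviving stages 1-2 (single pass, not iterated).

After trimming, a participant-level screen flags (and excludes) any
participant whose mean RT deviates at least 2.5 SD from the grand
distribution of participant means.  Per-image mean RT is then the
arithmetic mean over the surviving trials.

Participant SDs use the sample (n-1) denominator.  The SD criteria are
closed bounds ("at least 2.5 SD" removes a trial exactly at 2.5 SD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TrimReport", "trim_rts", "participant_screen", "image_mean_rt"]

logger = logging.getLogger(__name__)

#: Removal-stage labels, in application order.
STAGES = ("over_10s", "under_200ms", "participant_sd")


@dataclass
class TrimReport:
    """Accounting of the three-stage RT trim.

    ``n_retained`` always equals ``n_input`` minus the three removal
    counts, so no trial is silently lost.  ``participants_sd_skipped``
    lists participants with fewer than two surviving trials, for whom the
    within-participant SD stage cannot be applied.
    """

    n_input: int
    n_over_10s: int
    n_under_200ms: int
    n_participant_sd_removed: int
    n_retained: int
    participants_sd_skipped: tuple = ()
    removed: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        expected = (
            self.n_input
            - self.n_over_10s
            - self.n_under_200ms
            - self.n_participant_sd_removed
        )
        if self.n_retained != expected:
            raise ValueError(
                f"trim accounting broken: retained {self.n_retained} != {expected}"
            )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_over_10s": self.n_over_10s,
            "n_under_200ms": self.n_under_200ms,
            "n_participant_sd_removed": self.n_participant_sd_removed,
            "n_retained": self.n_retained,
            "participants_sd_skipped": list(self.participants_sd_skipped),
        }


def trim_rts(
    coded: pd.DataFrame,
    long_ms: float = 10_000.0,
    short_ms: float = 200.0,
    sd_criterion: float = 2.5,
    rt_col: str = "rt_ms",
    participant_col: str = "participant_id",
) -> tuple[pd.DataFrame, TrimReport]:
    """Apply the three-stage RT trim and account for every removed trial.

    ``coded`` may carry an ``include_in_rt`` column restricting the pool
    to valid, known responses; rows outside the pool are neither trimmed
    nor returned.  Returns the retained trials and a :class:`TrimReport`
    whose ``removed`` frame annotates each removed trial with its
    ``removal_stage``.
    """
    pool = coded
    if "include_in_rt" in coded.columns:
        pool = coded[coded["include_in_rt"].astype(bool)]
    rts = pool[rt_col].astype(float)

    over = rts > long_ms
    after1 = pool[~over]
    under = after1[rt_col].astype(float) < short_ms
    after2 = after1[~under]

    # Stage 3: per-participant mean/SD computed once on the stage-2 survivors.
    stats = after2.groupby(participant_col)[rt_col].agg(["mean", "std", "count"])
    skipped = tuple(stats.index[(stats["count"] < 2) | ~(stats["std"] > 0)])
    if len(skipped):
        logger.info(
            "participant-SD stage skipped for %d participant(s) with <2 trials "
            "or zero SD: %s",
            len(skipped),
            list(skipped)[:10],
        )
    mean_p = after2[participant_col].map(stats["mean"])
    sd_p = after2[participant_col].map(stats["std"])
    applicable = ~after2[participant_col].isin(skipped)
    outlier = applicable & (
        (after2[rt_col].astype(float) - mean_p).abs() >= sd_criterion * sd_p
    )
    retained = after2[~outlier]

    removed = pd.concat(
        [
            pool[over].assign(removal_stage=STAGES[0]),
            after1[under].assign(removal_stage=STAGES[1]),
            after2[outlier].assign(removal_stage=STAGES[2]),
        ]
    )
    report = TrimReport(
        n_input=len(pool),
        n_over_10s=int(over.sum()),
        n_under_200ms=int(under.sum()),
        n_participant_sd_removed=int(outlier.sum()),
        n_retained=len(retained),
        participants_sd_skipped=skipped,
        removed=removed,
    )
    return retained, report


def participant_screen(
    retained: pd.DataFrame,
    sd_criterion: float = 2.5,
    rt_col: str = "rt_ms",
    participant_col: str = "participant_id",
) -> tuple[pd.DataFrame, list]:
    """Flag and exclude participants with extreme overall mean RTs.

    A participant is flagged when their mean RT lies at least
    ``sd_criterion`` SDs from the mean of all participants' means
    (sample SD).  Returns the screened trials and the flagged IDs.
    """
    means = retained.groupby(participant_col)[rt_col].mean()
    grand_mean = means.mean()
    grand_sd = means.std(ddof=1)
    if not (grand_sd > 0) or len(means) < 3:
        return retained, []
    flagged = list(means.index[(means - grand_mean).abs() >= sd_criterion * grand_sd])
    if flagged:
        logger.warning("participant screen excluded %s", flagged)
        retained = retained[~retained[participant_col].isin(flagged)]
    return retained, flagged


def image_mean_rt(
    retained: pd.DataFrame,
    rt_col: str = "rt_ms",
    image_col: str = "image_id",
) -> pd.Series:
    """Mean recognition RT per image over the trimmed, screened trials."""
    return retained.groupby(image_col)[rt_col].mean().astype(float)
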