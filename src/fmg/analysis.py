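"""Closed-form statistics around list validation experiments.

Recognition data from a DRM experiment yields a hit rate H ("old"
responses to studied words) and a false-alarm rate F ("old" responses to
unrelated lures) per participant.  A' is the nonparametric signal-
detection discriminability index on [0, 1] (0.5 = chance); participants
below a screening threshold (default 0.7) are flagged for exclusion.

Model comparison between candidate mixed models is summarized by the AIC
evidence ratio exp(dAIC / 2): how many times more likely the lower-AIC
model is to be the better approximation (in Kullback-Leibler terms) of
the data-generating process.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "RecognitionSummary",
    "a_prime",
    "screen_participants",
    "aic_evidence_ratio",
    "read_recognition_summaries",
    "write_screening",
]


@dataclass(frozen=True)
class RecognitionSummary:
    """Hit and false-alarm proportions for one participant."""

    hit_rate: float
    fa_rate: float

    def __post_init__(self) -> None:
        for name, v in (("hit_rate", self.hit_rate), ("fa_rate", self.fa_rate)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def a_prime(summary: RecognitionSummary) -> float:
    """Nonparametric discriminability A' in [0, 1].

    For H >= F:  0.5 + (H - F)(1 + H - F) / (4 H (1 - F));
    for H < F the sign-reflected form; H = F gives exactly 0.5.  The
    H = F branch is evaluated first, so the boundary cases H = 0 and
    F = 1 never divide by zero.
    """
    h, f = summary.hit_rate, summary.fa_rate
    if h == f:
        return 0.5
    if h > f:
        return 0.5 + ((h - f) * (1.0 + h - f)) / (4.0 * h * (1.0 - f))
    return 0.5 - ((f - h) * (1.0 + f - h)) / (4.0 * f * (1.0 - h))


def screen_participants(
    summaries, threshold: float = 0.7
) -> list[bool]:
    """Keep/exclude decision per participant: keep iff A' >= threshold.

    The comparison is strict on the exclusion side (A' < threshold is
    removed), so a participant sitting exactly at the threshold is kept.
    """
    if len(summaries) == 0:
        raise ValidationError("no participants to screen")
    return [a_prime(s) >= threshold for s in summaries]


def aic_evidence_ratio(delta_aic: float) -> float:
    """exp(dAIC / 2): relative likelihood of the lower-AIC model.

    ``delta_aic`` must be oriented non-negative (higher-AIC minus
    lower-AIC); the result is >= 1.
    """
    if delta_aic < 0:
        raise ValidationError(
            "delta_aic must be >= 0 (orient as higher minus lower AIC)"
        )
    return math.exp(delta_aic / 2.0)


def read_recognition_summaries(path) -> pd.DataFrame:
    """Read a per-participant response TSV.

    Columns: participant, hits, misses, false_alarms, correct_rejections
    (counts).  Returns the frame with derived hit_rate and fa_rate columns.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"participant", "hits", "misses", "false_alarms",
                "correct_rejections"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    old = df["hits"] + df["misses"]
    new = df["false_alarms"] + df["correct_rejections"]
    if (old <= 0).any() or (new <= 0).any():
        raise ValidationError("each participant needs old and new trials")
    df = df.copy()
    df["hit_rate"] = df["hits"] / old
    df["fa_rate"] = df["false_alarms"] / new
    return df


def write_screening(path_in, path_out, threshold: float = 0.7) -> pd.DataFrame:
    """Screen a response TSV and write decisions (TSV) next to A' values."""
    df = read_recognition_summaries(path_in)
    summaries = [
        RecognitionSummary(h, f) for h, f in zip(df["hit_rate"], df["fa_rate"])
    ]
    df["a_prime"] = [a_prime(s) for s in summaries]
    df["keep"] = screen_participants(summaries, threshold)
    out = df[["participant", "hit_rate", "fa_rate", "a_prime", "keep"]]
    out.to_csv(path_out, sep="\t", index=False, float_format="%.6f")
    return out
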