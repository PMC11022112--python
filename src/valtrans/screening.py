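"""Questionnaire scoring, probable-PTSD screening, and rating-based exclusions.

The PCL-5 (PTSD Checklist for DSM-5) has 20 items scored 0-4 (total 0-80).
Probable PTSD (pPTSD) is assigned when the total exceeds 33 *and* the DSM-5
symptom-cluster pattern is endorsed (item rated >= 2 counts as endorsed):
at least 1 intrusion item (1-5), 1 avoidance item (6-7), 2 negative
alterations in cognition/mood items (8-14), and 2 arousal/reactivity items
(15-20). Everyone else is a trauma-exposed control (TEC). Emotional numbing
is the items 12-14 subscale (0-12) of the 8-factor PTSD model.

Rating-quality control: a participant whose VAS ratings deviate from the
normative image valence by more than 3 SD on more than 2 images is excluded.
Norms live on the 1-9 source scale while VAS ratings live on [0, 1]; the
norm mean m and SD s are mapped affinely to (m - 1) / 8 and s / 8 before
the rule is applied, which preserves the rule under the rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Pcl5Response",
    "DiagnosisResult",
    "OutlierVerdict",
    "score_pcl5",
    "score_pcl5_frame",
    "numbing_z_scores",
    "flag_outlier",
    "filter_positive_images",
    "rescale_norms_to_vas",
    "PCL5_CUTOFF",
    "NUMBING_ITEMS",
]

#: Diagnostic total-score cutoff: pPTSD requires total > 33.
PCL5_CUTOFF = 33

#: 1-based PCL-5 items forming the emotional-numbing subscale.
NUMBING_ITEMS = (12, 13, 14)

#: 1-based item ranges and minimum endorsement counts per DSM-5 cluster.
CLUSTERS = {
    "intrusion": (range(1, 6), 1),
    "avoidance": (range(6, 8), 1),
    "cogmood": (range(8, 15), 2),
    "arousal": (range(15, 21), 2),
}

ENDORSED_AT = 2  # item rated >= 2 counts as symptom endorsement


@dataclass(frozen=True)
class Pcl5Response:
    """One participant's PCL-5 item vector (20 items, each 0-4)."""

    participant_id: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 20:
            raise ValueError(
                f"participant {self.participant_id}: expected 20 PCL-5 items, "
                f"got {len(self.items)}"
            )
        for i, v in enumerate(self.items, start=1):
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= 4):
                raise ValueError(
                    f"participant {self.participant_id}: item {i} is {v!r}, "
                    "must be an integer in 0-4"
                )
        object.__setattr__(self, "items", tuple(int(v) for v in self.items))

    @property
    def total(self) -> int:
        return sum(self.items)


@dataclass(frozen=True)
class DiagnosisResult:
    """Screening outcome: group label, cluster endorsements, numbing subscale."""

    participant_id: str
    total_score: int
    group: Literal["pPTSD", "TEC"]
    cluster_flags: dict[str, bool]
    numbing_score: int


@dataclass(frozen=True)
class OutlierVerdict:
    """Rating-deviation exclusion verdict for one participant."""

    participant_id: str
    deviation_count: int
    excluded: bool


def score_pcl5(resp: Pcl5Response) -> DiagnosisResult:
    """Score a PCL-5 response and apply the probable-PTSD screening rule.

    pPTSD requires total > 33 *and* every cluster endorsed (>= the cluster's
    minimum count of items rated >= 2); otherwise the label is TEC.
    """
    items = resp.items
    total = sum(items)
    flags = {
        name: sum(items[i - 1] >= ENDORSED_AT for i in rng) >= need
        for name, (rng, need) in CLUSTERS.items()
    }
    group = "pPTSD" if total > PCL5_CUTOFF and all(flags.values()) else "TEC"
    numbing = sum(items[i - 1] for i in NUMBING_ITEMS)
    return DiagnosisResult(
        participant_id=resp.participant_id,
        total_score=total,
        group=group,
        cluster_flags=flags,
        numbing_score=numbing,
    )


def score_pcl5_frame(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Score a questionnaire table (columns participant_id, pcl5_01..pcl5_20).

    Extra columns are ignored. Returns one row per participant with columns
    participant_id, total, group, intrusion, avoidance, cogmood, arousal,
    numbing.
    """
    item_cols = [f"pcl5_{i:02d}" for i in range(1, 21)]
    missing = [c for c in item_cols if c not in questionnaires.columns]
    if missing:
        raise ValueError(f"questionnaire table lacks columns: {missing}")
    rows = []
    for rec in questionnaires.itertuples(index=False):
        resp = Pcl5Response(
            participant_id=str(rec.participant_id),
            items=tuple(int(getattr(rec, c)) for c in item_cols),
        )
        d = score_pcl5(resp)
        rows.append(
            {
                "participant_id": d.participant_id,
                "total": d.total_score,
                "group": d.group,
                **{k: bool(v) for k, v in d.cluster_flags.items()},
                "numbing": d.numbing_score,
            }
        )
    return pd.DataFrame(rows)


def numbing_z_scores(
    scores: Sequence[float], ddof: int = 0
) -> np.ndarray:
    """z-transform emotional-numbing scores (the covariate is centred/scaled
    to improve sampler behaviour).

    By default uses the population-SD convention (``ddof=0``); pass
    ``ddof=1`` for the sample-SD convention. Raises on constant input.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("need a 1-D sequence of at least 2 scores")
    sd = arr.std(ddof=ddof)
    if sd == 0:
        raise ValueError("numbing scores are constant; z-scores undefined")
    return (arr - arr.mean()) / sd


def rescale_norms_to_vas(norms: pd.DataFrame) -> pd.DataFrame:
    """Map normative valence from the 1-9 source scale onto the VAS [0, 1].

    Means map as (m - 1) / 8 and SDs as s / 8 (order-preserving affine map).
    """
    out = norms.copy()
    out["valence_mean"] = (norms["valence_mean"] - 1.0) / 8.0
    out["valence_sd"] = norms["valence_sd"] / 8.0
    return out


def flag_outlier(
    ratings: pd.DataFrame,
    norms: pd.DataFrame,
    *,
    sd_multiplier: float = 3.0,
    max_occasions: int = 2,
) -> OutlierVerdict:
    """Apply the deviation rule to one participant's ratings.

    ``ratings`` holds columns participant_id, image_id, rating (VAS, [0,1]);
    ``norms`` holds image_id, valence_mean, valence_sd on the 1-9 scale.
    A rating "deviates" when |rating - rescaled mean| > 3 x rescaled SD;
    the participant is excluded when that happens on more than 2 images.
    """
    pids = ratings["participant_id"].unique()
    if len(pids) != 1:
        raise ValueError("flag_outlier expects ratings from a single participant")
    pid = str(pids[0])
    merged = ratings.merge(norms, on="image_id", how="left", validate="m:1")
    if merged["valence_mean"].isna().any():
        bad = merged.loc[merged["valence_mean"].isna(), "image_id"].tolist()
        raise ValueError(f"no norm for rated image(s): {bad}")
    mu = (merged["valence_mean"].to_numpy() - 1.0) / 8.0
    sd = merged["valence_sd"].to_numpy() / 8.0
    dev = np.abs(merged["rating"].to_numpy() - mu) > sd_multiplier * sd
    count = int(dev.sum())
    return OutlierVerdict(
        participant_id=pid,
        deviation_count=count,
        excluded=count > max_occasions,
    )


def flag_outliers_frame(ratings: pd.DataFrame, norms: pd.DataFrame) -> pd.DataFrame:
    """Vectorised outlier verdicts for a full rating table."""
    rows = [
        {
            "participant_id": v.participant_id,
            "deviation_count": v.deviation_count,
            "excluded": v.excluded,
        }
        for _, grp in ratings.groupby("participant_id", sort=True)
        for v in [flag_outlier(grp, norms)]
    ]
    return pd.DataFrame(rows)


def filter_positive_images(
    norms: pd.DataFrame, *, threshold: float = 5.0
) -> tuple[pd.DataFrame, int]:
    """Drop positive-valence images (norm mean > 5 on the 1-9 scale).

    Positive images are shown to reduce negativity bias but are omitted from
    the analysis. Returns the retained norms and the number removed.
    """
    keep = norms["valence_mean"] <= threshold
    n_removed = int((~keep).sum())
    retained = norms.loc[keep].reset_index(drop=True)
    if retained.empty:
        warnings.warn("positive-image filter removed every image", stacklevel=2)
    return retained, n_removed
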