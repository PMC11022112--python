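"""Synthetic study data with the structure the analysis assumes.

The generator emulates the study design end to end: a stimulus set of 35
images whose normative valence rises gradually from 1.33 (most negative)
to 5.0 (neutral) plus 5 positive fillers (5.63-7.09, later filtered out);
participants in two groups (TEC and pPTSD) whose VAS ratings follow
participant-specific 5-PL curves with additive Gaussian noise clamped to
[0, 1]; PCL-5 item vectors constructed so the screening rule reproduces
each participant's intended group exactly; and an emotional-numbing
covariate that feeds the participant slope through
``B_i = en_slope_coeff * numbing_z_i + b_i``.

Default truth values are chosen to mirror the study's reported sample:
group numbing means 2.95 (TEC) / 7.94 (pPTSD), PCL-5 totals 17.8 / 46.5,
ages 41.5 / 36.1, Hill-slope means 1.2 (TEC) / 1.45 (pPTSD) — a gap of
the magnitude the group contrast reports — and a numbing-slope
coefficient of 0.1. A ground-truth table is returned for recovery tests;
the inference stages never read it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from valtrans.model import five_pl
from valtrans.screening import numbing_z_scores, score_pcl5, Pcl5Response

__all__ = [
    "StimulusNorm",
    "GroupParams",
    "GeneratorConfig",
    "generate_norms",
    "generate_participants",
    "inject_outliers",
]


@dataclass(frozen=True)
class StimulusNorm:
    """One image's normative valence mean and SD on the 1-9 source scale."""

    image_id: str
    valence_mean: float
    valence_sd: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.valence_mean <= 9.0):
            raise ValueError(f"valence_mean {self.valence_mean} outside [1, 9]")
        if self.valence_sd <= 0:
            raise ValueError("valence_sd must be positive")


def _tn(rng, mu, sd, lower=-np.inf, upper=np.inf, size=None):
    a, b = (lower - mu) / sd, (upper - mu) / sd
    return truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


@dataclass
class GroupParams:
    """True group-level curve parameters for the generator.

    ``a_mean``/``a_sd`` parameterize the lower asymptote through beta-
    distribution moments; the rest are truncated-normal means/SDs with the
    same truncation bounds the model uses. ``sd_b`` defaults to 1.0, the
    participant-level SD the model itself assumes, so the group-level slope
    mean is generated from exactly the population the model describes;
    ``sd_d`` must stay small because ratings cannot exceed the VAS range. ``numbing_mean``/``sd`` and
    ``pcl_total_mean``/``sd`` control the questionnaire construction, and
    ``age_mean``/``sd`` the demographics.
    """

    mu_b: float
    a_mean: float = 0.08
    a_sd: float = 0.05
    mu_c: float = 2.5
    mu_d: float = 0.58
    mu_g: float = 3.5
    sd_b: float = 1.0
    sd_c: float = 0.3
    sd_d: float = 0.04
    sd_g: float = 0.3
    numbing_mean: float = 2.95
    numbing_sd: float = 2.63
    pcl_total_mean: float = 17.81
    pcl_total_sd: float = 10.14
    age_mean: float = 41.5
    age_sd: float = 13.3


def _default_groups() -> dict[str, GroupParams]:
    return {
        "TEC": GroupParams(mu_b=1.2),
        "pPTSD": GroupParams(
            mu_b=1.45,
            numbing_mean=7.94,
            numbing_sd=2.49,
            pcl_total_mean=46.52,
            pcl_total_sd=9.72,
            age_mean=36.1,
            age_sd=10.9,
        ),
    }


@dataclass
class GeneratorConfig:
    """Everything the forward model needs, seed included."""

    n_per_group: int
    seed: int
    n_images: int = 35
    n_positive: int = 5
    noise_sd: float = 0.05
    en_slope_coeff: float = 0.1
    groups: dict[str, GroupParams] = field(default_factory=_default_groups)

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name, gp in self.groups.items():
            if not (0.0 < gp.a_mean < 1.0):
                raise ValueError(f"group {name}: a_mean outside (0, 1)")
            if gp.mu_d + 3.0 * gp.sd_d > 1.0:
                raise ValueError(
                    f"group {name}: mu_d={gp.mu_d} with sd_d={gp.sd_d} implies "
                    "upper asymptotes above the VAS range"
                )
            if not (0.5 < gp.mu_c < 5.0):
                raise ValueError(f"group {name}: mu_c outside (0.5, 5)")
            if gp.mu_b < 0.5:
                raise ValueError(f"group {name}: mu_b below 0.5")
            for sd in (gp.sd_b, gp.sd_c, gp.sd_d, gp.sd_g, gp.a_sd):
                if sd <= 0:
                    raise ValueError(f"group {name}: SDs must be positive")


def generate_norms(
    n_images: int = 35,
    n_positive: int = 5,
    seed: int = 0,
    *,
    jitter: float = 0.02,
    sd_range: tuple[float, float] = (0.8, 1.6),
    negative_range: tuple[float, float] = (1.33, 5.0),
    positive_range: tuple[float, float] = (5.63, 7.09),
) -> pd.DataFrame:
    """Stimulus norms: a gradual negative-to-neutral ramp plus positive fillers.

    ``n_images`` means are evenly spaced over ``negative_range`` with small
    jitter on the interior points (endpoints exact, order preserved), and
    ``n_positive`` positive-image means span ``positive_range``. Norm SDs
    are uniform over ``sd_range``. Deterministic for a fixed seed.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images for a valence ramp")
    rng = np.random.default_rng(seed)
    means = np.linspace(*negative_range, n_images)
    if n_images > 2 and jitter > 0:
        gap = means[1] - means[0]
        means[1:-1] += rng.uniform(-1, 1, n_images - 2) * min(jitter, 0.45 * gap)
    if n_positive > 0:
        pos = (
            np.linspace(*positive_range, n_positive)
            if n_positive > 1
            else np.array([positive_range[0]])
        )
        means = np.concatenate([means, pos])
    sds = rng.uniform(*sd_range, means.size)
    return pd.DataFrame(
        {
            "image_id": [f"img{i + 1:03d}" for i in range(means.size)],
            "valence_mean": means,
            "valence_sd": sds,
        }
    )


def _split_numbing(rng: np.random.Generator, total: int) -> np.ndarray:
    """Split a 0-12 numbing total over items 12-14 (each 0-4), randomized."""
    vals = np.zeros(3, dtype=int)
    order = rng.permutation(3)
    rem = total
    for j in order:
        take = min(4, rem)
        vals[j] = take
        rem -= take
    return vals


def _raise_items(
    rng: np.random.Generator, items: np.ndarray, target: int, protected: Sequence[int]
) -> None:
    """Raise non-protected items (0-based) round-robin until the total hits
    ``target`` or everything saturates at 4."""
    raisable = [i for i in range(20) if i not in protected]
    while items.sum() < target:
        candidates = [i for i in raisable if items[i] < 4]
        if not candidates:
            break
        items[int(rng.choice(candidates))] += 1


def _make_pcl5(rng: np.random.Generator, group: str, gp: GroupParams) -> np.ndarray:
    """Construct one PCL-5 item vector guaranteed to screen into ``group``."""
    numbing = int(np.clip(np.rint(_tn(rng, gp.numbing_mean, gp.numbing_sd, 0, 12)), 0, 12))
    items = np.zeros(20, dtype=int)
    items[11:14] = _split_numbing(rng, numbing)
    protected = (11, 12, 13)
    if group == "pPTSD":
        total = int(np.clip(np.rint(_tn(rng, gp.pcl_total_mean, gp.pcl_total_sd, 34, 76)), 34, 76))
        # endorse each DSM-5 cluster: >=1 intrusion, >=1 avoidance,
        # >=2 cognition/mood (items 8-14), >=2 arousal
        items[int(rng.integers(0, 5))] = max(items[int(rng.integers(0, 5))], 2)
        items[int(rng.integers(5, 7))] = 2
        if int(np.sum(items[7:14] >= 2)) < 2:
            for i in rng.permutation(np.arange(7, 11)):
                if items[i] < 2:
                    items[i] = 2
                if int(np.sum(items[7:14] >= 2)) >= 2:
                    break
        arousal = rng.choice(np.arange(14, 20), size=2, replace=False)
        items[arousal] = np.maximum(items[arousal], 2)
        _raise_items(rng, items, max(total, items.sum()), protected)
    else:
        total = int(np.clip(np.rint(_tn(rng, gp.pcl_total_mean, gp.pcl_total_sd, 0, 33)), 0, 33))
        budget = max(total - numbing, 0)
        _raise_items(rng, items, items.sum() + budget, protected)
        # hard guarantee: a TEC total never exceeds the diagnostic cutoff
        while items.sum() > 33:
            high = [i for i in range(20) if i not in protected and items[i] > 0]
            items[int(rng.choice(high))] -= 1
    return items


def generate_participants(
    cfg: GeneratorConfig, norms: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw participants, their questionnaires, and their image ratings.

    Returns ``(ratings, questionnaires, truth)``. Ratings cover every image
    in ``norms`` (positive fillers included; they are filtered before
    modelling). Curve parameters are drawn from the same truncated
    distributions the model assumes, with the configured true group means
    and between-participant SDs; the participant slope is
    ``B_i = en_slope_coeff * numbing_z_i + b_i``. The truth table carries
    every latent quantity for parameter-recovery checks.
    """
    rng = np.random.default_rng(cfg.seed)
    group_names = list(cfg.groups)
    n_total = cfg.n_per_group * len(group_names)
    pids = [f"P{i + 1:04d}" for i in range(n_total)]
    groups = [g for g in group_names for _ in range(cfg.n_per_group)]

    q_rows = []
    numbing_scores = []
    ages = []
    for pid, grp in zip(pids, groups):
        gp = cfg.groups[grp]
        items = _make_pcl5(rng, grp, gp)
        diag = score_pcl5(Pcl5Response(pid, tuple(int(v) for v in items)))
        assert diag.group == grp, f"questionnaire construction failed for {pid}"
        age = float(np.clip(rng.normal(gp.age_mean, gp.age_sd), 18, 80))
        q_rows.append(
            {
                "participant_id": pid,
                **{f"pcl5_{i + 1:02d}": int(v) for i, v in enumerate(items)},
                "age": round(age, 1),
                "sex": str(rng.choice(["female", "male"])),
            }
        )
        numbing_scores.append(diag.numbing_score)
        ages.append(age)
    questionnaires = pd.DataFrame(q_rows)
    en_z = numbing_z_scores(numbing_scores)

    x = norms["valence_mean"].to_numpy(dtype=float)
    truth_rows = []
    rating_rows = []
    for i, (pid, grp) in enumerate(zip(pids, groups)):
        gp = cfg.groups[grp]
        var = gp.a_sd**2
        kappa = gp.a_mean * (1 - gp.a_mean) / var - 1.0
        if kappa <= 0:
            raise ValueError("a_sd too large for a beta distribution with that mean")
        a = float(rng.beta(gp.a_mean * kappa, (1 - gp.a_mean) * kappa))
        b = float(_tn(rng, gp.mu_b, gp.sd_b, lower=0.5))
        c = float(_tn(rng, gp.mu_c, gp.sd_c, lower=0.5, upper=5.0))
        d = float(_tn(rng, gp.mu_d, gp.sd_d, lower=0.5))
        g = float(_tn(rng, gp.mu_g, gp.sd_g, lower=0.8))
        B = cfg.en_slope_coeff * float(en_z[i]) + b
        f = five_pl(x, a, B, c, d, g)
        y = np.clip(f + rng.normal(0.0, cfg.noise_sd, x.size), 0.0, 1.0)
        rating_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "image_id": norms["image_id"].to_numpy(),
                    "rating": y,
                }
            )
        )
        truth_rows.append(
            {
                "participant_id": pid,
                "group": grp,
                "age": round(ages[i], 1),
                "numbing": numbing_scores[i],
                "en_z": float(en_z[i]),
                "a": a,
                "b": b,
                "B": B,
                "c": c,
                "d": d,
                "g": g,
            }
        )
    ratings = pd.concat(rating_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return ratings, questionnaires, truth


def inject_outliers(
    ratings: pd.DataFrame,
    norms: pd.DataFrame,
    n_participants: int,
    n_images_each: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Push some participants' ratings >3 SD away from the rescaled norms.

    Selected participants get ``n_images_each`` ratings replaced by the
    VAS boundary (0 or 1) farthest from the image's rescaled norm mean,
    choosing the images where that boundary exceeds the 3-SD band by the
    widest margin. Returns the modified table (a copy) and the tampered
    participant ids. Raises if the request is infeasible.
    """
    if n_images_each < 1 and n_participants > 0:
        raise ValueError("n_images_each must be >= 1")
    out = ratings.copy()
    pids = sorted(out["participant_id"].unique())
    if n_participants > len(pids):
        raise ValueError(
            f"asked to tamper with {n_participants} participants, only {len(pids)} exist"
        )
    if n_participants == 0:
        return out, []
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(pids, size=n_participants, replace=False).tolist())

    mu = (norms["valence_mean"].to_numpy() - 1.0) / 8.0
    sd = norms["valence_sd"].to_numpy() / 8.0
    dev_lo, dev_hi = mu - 0.0, 1.0 - mu
    best_dev = np.maximum(dev_lo, dev_hi)
    margin = best_dev / sd  # in units of rescaled SD
    feasible = margin > 3.0
    if feasible.sum() < n_images_each:
        raise ValueError(
            f"only {int(feasible.sum())} images allow a >3 SD deviation within the "
            f"VAS range; {n_images_each} requested"
        )
    order = np.argsort(-margin)
    target_imgs = norms["image_id"].to_numpy()[order[:n_images_each]]
    target_val = np.where(dev_lo >= dev_hi, 0.0, 1.0)[order[:n_images_each]]
    for pid in chosen:
        for img, val in zip(target_imgs, target_val):
            sel = (out["participant_id"] == pid) & (out["image_id"] == img)
            if not sel.any():
                raise ValueError(f"participant {pid} has no rating for image {img}")
            out.loc[sel, "rating"] = val
    return out, chosen
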