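"""Predictive model comparison by PSIS-LOO cross-validation.

The expected log pointwise predictive density (elpd_loo) is estimated by
Pareto-smoothed importance sampling from the pointwise log-likelihood
draws; models are ranked by elpd_loo (higher = better out-of-sample fit)
and given weights. The comparison table mirrors the standard layout:
rank, loo, p_loo (effective parameter count), d_loo (gap to the best
model), weight, se.

PSIS-LOO and the weighting schemes are delegated to arviz; observations
with Pareto shape k > 0.7 are reported as unreliable rather than refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import arviz as az
import numpy as np
import pandas as pd

from valtrans.inference import PosteriorDraws

__all__ = ["LooResult", "compute_loo", "compare_models", "PARETO_K_WARN"]

PARETO_K_WARN = 0.7


@dataclass
class LooResult:
    """PSIS-LOO estimate for one fitted model."""

    name: str
    elpd_loo: float
    p_loo: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    n_obs: int
    _elpd_data: object = None

    @property
    def n_bad_k(self) -> int:
        return int((self.pareto_k > PARETO_K_WARN).sum())


def compute_loo(draws: PosteriorDraws, name: str = "model") -> LooResult:
    """PSIS-LOO elpd from a fit's pointwise log-likelihood draws.

    The SE comes from the variance of the pointwise elpd contributions;
    a warning lists how many observations exceed the Pareto-k reliability
    threshold (0.7).
    """
    if "log_likelihood" not in draws.idata.groups():
        raise ValueError("fit carries no pointwise log likelihood; LOO impossible")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # arviz re-warns on high pareto-k itself
        res = az.loo(draws.idata, pointwise=True)
    out = LooResult(
        name=name,
        elpd_loo=float(res.elpd_loo),
        p_loo=float(res.p_loo),
        se=float(res.se),
        pointwise=np.asarray(res.loo_i),
        pareto_k=np.asarray(res.pareto_k),
        n_obs=int(res.n_data_points),
        _elpd_data=res,
    )
    if out.n_bad_k:
        warnings.warn(
            f"{name}: {out.n_bad_k}/{out.n_obs} observations with Pareto k > "
            f"{PARETO_K_WARN}; their LOO contributions are unreliable",
            stacklevel=2,
        )
    return out


WeightMethod = Literal["stacking", "pseudo-BMA", "BB-pseudo-BMA"]


def compare_models(
    loos: Sequence[LooResult], method: WeightMethod = "stacking"
) -> pd.DataFrame:
    """Rank models by elpd_loo and attach weights.

    All results must come from the same observation set. Returns a frame
    with columns rank, model, loo, p_loo, d_loo, weight, se, dse (rank 0 is
    the best model; d_loo is the elpd gap to it and dse the standard error
    of that gap). ``method`` selects the weighting scheme; stacking is the
    default, pseudo-BMA the tie-friendly alternative.
    """
    if len(loos) < 2:
        raise ValueError("need at least two models to compare")
    n_obs = {r.n_obs for r in loos}
    if len(n_obs) != 1:
        raise ValueError(f"models were evaluated on different observation counts: {n_obs}")
    names = [r.name for r in loos]
    if len(set(names)) != len(names):
        raise ValueError("model names must be unique")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmp = az.compare(
            {r.name: r._elpd_data for r in loos}, ic="loo", method=method
        )
    rows = []
    for model_name, row in cmp.iterrows():
        rows.append(
            {
                "rank": int(row["rank"]),
                "model": model_name,
                "loo": float(row["elpd_loo"]),
                "p_loo": float(row["p_loo"]),
                "d_loo": float(row["elpd_diff"]),
                "weight": float(row["weight"]),
                "se": float(row["se"]),
                "dse": float(row["dse"]),
            }
        )
    out = pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)
    if not np.isclose(out["weight"].sum(), 1.0, atol=1e-6):
        warnings.warn("model weights do not sum to 1", stacklevel=2)
    return out
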