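"""Model fitting, convergence diagnostics, and posterior group contrasts.

``fit`` runs the package's NUTS sampler on a bound :class:`ModelSpec` and
returns a :class:`PosteriorDraws` wrapping an arviz ``InferenceData`` with
``posterior``, ``sample_stats`` and ``log_likelihood`` groups, plus
split-chain R-hat / rank-normalized ESS diagnostics. Convergence is judged
against the published bar (R-hat < 1.01, bulk ESS > 1000).

The group contrast follows the published rule: the pPTSD posterior is
subtracted from the TEC posterior draw-by-draw (flattened chain-major
order) and a difference is "robust" when 0 falls outside the 89% highest
posterior density interval. The HPD is the shortest contiguous window of
the sorted draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from valtrans.model import ModelSpec
from valtrans.nuts import sample_nuts

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "GroupComparison",
    "ConvergenceWarning",
    "fit",
    "hpd",
    "compare_groups",
    "diagnostics_report",
]

RHAT_BAR = 1.01
ESS_BAR = 1000.0


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when a fit misses the convergence bar."""


@dataclass(frozen=True)
class SamplerConfig:
    """NUTS settings; defaults mirror the published run (PyMC defaults):
    1000 draws, 1000 tuning steps, 80% target acceptance, no thinning."""

    draws: int = 1000
    tune: int = 1000
    target_accept: float = 0.8
    chains: int = 4
    seed: int = 0
    thin: int = 1
    max_treedepth: int = 10
    divergence_warn_fraction: float = 0.01

    def __post_init__(self) -> None:
        if min(self.draws, self.tune + 1, self.chains, self.thin) < 1:
            raise ValueError("draws, chains and thin must be positive; tune >= 0")
        if not (0.0 < self.target_accept < 1.0):
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class PosteriorDraws:
    """Posterior draws with sampler statistics and pointwise log likelihood."""

    idata: az.InferenceData
    model_kind: str = "unknown"
    participant_ids: list[str] = field(default_factory=list)

    def stacked(self, param: str) -> np.ndarray:
        """Draws of one parameter flattened chain-major to (n_draws, ...)."""
        da = self.idata.posterior[param]
        return da.stack(sample=("chain", "draw")).transpose("sample", ...).to_numpy()

    @property
    def parameters(self) -> list[str]:
        return list(self.idata.posterior.data_vars)

    def diagnostics(self) -> pd.DataFrame:
        return diagnostics_report(self)

    def to_zarr(self, path) -> None:
        self.idata.to_datatree().to_zarr(str(path))

    @classmethod
    def from_zarr(cls, path, model_kind: str = "unknown") -> "PosteriorDraws":
        import xarray as xr

        dt = xr.open_datatree(str(path), engine="zarr")
        idata = az.InferenceData.from_datatree(dt)
        attrs = idata.posterior.attrs
        kind = attrs.get("model_kind", model_kind)
        pids = list(np.asarray(idata.posterior.coords.get("participant", [])).astype(str))
        return cls(idata=idata, model_kind=kind, participant_ids=pids)


def fit(spec: ModelSpec, cfg: SamplerConfig | None = None) -> PosteriorDraws:
    """Fit a model by NUTS and attach diagnostics and pointwise log likelihood.

    Emits :class:`ConvergenceWarning` if any parameter has split R-hat >=
    1.01 or bulk ESS < 1000 (the published convergence criteria), and a
    divergence warning when the post-warmup divergence rate exceeds the
    configured threshold.
    """
    cfg = cfg or SamplerConfig()
    dens = spec.log_density()
    Z, stats = sample_nuts(
        dens,
        draws=cfg.draws,
        tune=cfg.tune,
        chains=cfg.chains,
        target_accept=cfg.target_accept,
        seed=cfg.seed,
        max_treedepth=cfg.max_treedepth,
    )
    if cfg.thin > 1:
        Z = Z[:, :: cfg.thin]

    params = dens.constrain(Z)  # dict name -> (chain, draw, ...)
    dims = dens.param_dims()
    coords = {"participant": spec.participant_ids}
    posterior = {k: np.asarray(v) for k, v in params.items()}
    post_dims = {k: ["chain", "draw", *d] for k, d in dims.items()}

    n_draws = Z.shape[1]
    loglik = np.empty((Z.shape[0], n_draws, spec.n_obs))
    for c in range(Z.shape[0]):
        loglik[c] = dens.pointwise_loglik(Z[c])

    thin_slice = slice(None, None, cfg.thin)
    sample_stats = {
        "lp": np.stack([s.lp[thin_slice] for s in stats]),
        "energy": np.stack([s.energy[thin_slice] for s in stats]),
        "acceptance_rate": np.stack([s.acceptance_rate[thin_slice] for s in stats]),
        "tree_depth": np.stack([s.tree_depth[thin_slice] for s in stats]),
        "n_steps": np.stack([s.n_leapfrog[thin_slice] for s in stats]),
        "diverging": np.stack([s.diverging[thin_slice] for s in stats]),
    }
    idata = az.from_dict(
        posterior=posterior,
        sample_stats=sample_stats,
        log_likelihood={"y": loglik},
        coords=coords,
        dims={**post_dims, "y": ["chain", "draw", "obs"]},
    )
    idata.posterior.attrs["model_kind"] = spec.model_kind
    draws_out = PosteriorDraws(
        idata=idata, model_kind=spec.model_kind, participant_ids=spec.participant_ids
    )

    n_div = int(sample_stats["diverging"].sum())
    total = sample_stats["diverging"].size
    if n_div > cfg.divergence_warn_fraction * total:
        warnings.warn(
            f"{n_div} divergent transitions out of {total} post-warmup draws",
            ConvergenceWarning,
            stacklevel=2,
        )
    if Z.shape[0] >= 2:
        report = diagnostics_report(draws_out)
        bad = report[report["flagged"]]
        if not bad.empty:
            worst = bad.iloc[0]
            warnings.warn(
                f"convergence bar missed for {len(bad)} parameter(s); worst: "
                f"{worst['parameter']} (rhat={worst['rhat']:.4f}, "
                f"bulk ESS={worst['ess_bulk']:.0f})",
                ConvergenceWarning,
                stacklevel=2,
            )
    return draws_out


def hpd(samples: Sequence[float], mass: float = 0.89) -> tuple[float, float]:
    """Shortest contiguous interval holding ``ceil(mass * n)`` sorted draws.

    For a unimodal posterior this is the highest-posterior-density interval;
    89% is the analysis convention. Ties are broken toward the lowest
    starting index.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie strictly between 0 and 1")
    arr = np.sort(np.asarray(samples, dtype=float).ravel())
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    k = int(np.ceil(mass * n))
    k = min(max(k, 1), n)
    if k == n:
        return float(arr[0]), float(arr[-1])
    widths = arr[k - 1 :] - arr[: n - k + 1]
    i = int(np.argmin(widths))
    return float(arr[i]), float(arr[i + k - 1])


@dataclass(frozen=True)
class GroupComparison:
    """Posterior difference (group1 - group2) for one parameter."""

    parameter: str
    difference: np.ndarray
    hpd_low: float
    hpd_high: float
    robust: bool
    mass: float = 0.89

    @property
    def mean(self) -> float:
        return float(self.difference.mean())


def compare_groups(
    draws1: PosteriorDraws,
    draws2: PosteriorDraws,
    params: Sequence[str],
    mass: float = 0.89,
    seed: int = 0,
) -> list[GroupComparison]:
    """Subtract group2's posterior from group1's, parameter by parameter.

    Call with the TEC fit first and the pPTSD fit second to reproduce the
    published direction (TEC - pPTSD; a steeper pPTSD slope gives a
    negative difference). Draws are paired by flattened (chain, draw)
    index; the fits are independent, so any pairing yields the same
    distribution. Unequal draw counts are reconciled by subsampling the
    longer set without replacement (seeded). A difference is robust when 0
    lies outside the HPD.
    """
    out = []
    rng = np.random.default_rng(seed)
    for p in params:
        for d, tag in ((draws1, "first"), ((draws2), "second")):
            if p not in d.parameters:
                raise KeyError(f"parameter {p!r} missing from the {tag} posterior")
        s1 = draws1.stacked(p).ravel()
        s2 = draws2.stacked(p).ravel()
        if s1.size != s2.size:
            m = min(s1.size, s2.size)
            if s1.size > m:
                s1 = s1[np.sort(rng.choice(s1.size, m, replace=False))]
            else:
                s2 = s2[np.sort(rng.choice(s2.size, m, replace=False))]
        diff = s1 - s2
        lo, hi = hpd(diff, mass)
        out.append(
            GroupComparison(
                parameter=p,
                difference=diff,
                hpd_low=lo,
                hpd_high=hi,
                robust=bool(lo > 0.0 or hi < 0.0),
                mass=mass,
            )
        )
    return out


def comparison_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Tabulate group comparisons (one row per parameter)."""
    return pd.DataFrame(
        [
            {
                "parameter": c.parameter,
                "mean_difference": c.mean,
                "hpd_low": c.hpd_low,
                "hpd_high": c.hpd_high,
                "mass": c.mass,
                "robust": c.robust,
            }
            for c in comparisons
        ]
    )


def diagnostics_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Split-chain R-hat and rank-normalized bulk/tail ESS per parameter.

    Vector parameters are expanded to one row per element. The ``flagged``
    column marks violations of the convergence bar (R-hat < 1.01, bulk
    ESS > 1000).
    """
    post = draws.idata.posterior
    if post.sizes["chain"] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    rhat = az.rhat(post)
    ess_bulk = az.ess(post, method="bulk")
    ess_tail = az.ess(post, method="tail")
    rows = []
    for name in post.data_vars:
        r = np.atleast_1d(np.asarray(rhat[name]))
        eb = np.atleast_1d(np.asarray(ess_bulk[name]))
        et = np.atleast_1d(np.asarray(ess_tail[name]))
        labels = (
            [name]
            if r.size == 1
            else [f"{name}[{i}]" for i in range(r.size)]
        )
        for lab, rv, ebv, etv in zip(labels, r.ravel(), eb.ravel(), et.ravel()):
            rows.append(
                {
                    "parameter": lab,
                    "rhat": float(rv),
                    "ess_bulk": float(ebv),
                    "ess_tail": float(etv),
                    "flagged": bool(rv >= RHAT_BAR or ebv <= ESS_BAR),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["flagged", "rhat"], ascending=[False, False]).reset_index(
        drop=True
    )
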