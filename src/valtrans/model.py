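"""Probabilistic model definitions for the valence-rating analysis.

Three model families share one observation model (VAS rating y in [0, 1],
Gaussian noise around a participant-specific mean curve of normative image
valence x on the 1-9 source scale):

* ``fivepl`` — hierarchical 5-parameter logistic,
  ``f(x) = d + (a - d) / (1 + (x / c)^b)^g``,
  with lower asymptote ``a`` (rating of the most negative images), Hill
  slope ``b`` (speed of the neutral-to-negative transition), inflection
  point ``c``, upper asymptote ``d`` (rating of neutral images), and
  asymmetry ``g``.
* ``linear`` — hierarchical straight line ``f(x) = b x + a``, the
  comparison model.
* ``fivepl_en`` (and age variants) — the 5-PL with the participant slope
  replaced by a fixed-slope random-intercept regression on the z-scored
  emotional-numbing score: ``B_i = numbing_z_i * EN + b_i`` (age variants
  add ``age_z_i * AGE`` and ``numbing_z_i * age_z_i * INT``).

Priors follow the published hierarchical specification: participant-level
parameters are drawn around group-level means with unit SD and hard
truncation bounds (``a ~ Beta(alpha1, alpha2)``; ``b``, ``c``, ``d``, ``g``
truncated normals), and the group-level means carry truncated-normal
hyperpriors. All constants live in :data:`PRIOR_CONSTANTS` and can be
overridden per model via the ``priors`` argument.

The observation noise model (unstated in the source specification) is
``y ~ Normal(f(x), sigma)`` with ``sigma ~ HalfNormal(0.2)`` shared across
participants.

Each :class:`ModelSpec` can produce a log-density object exposing the
unconstrained-space log posterior and its analytic gradient, which is what
the NUTS sampler in :mod:`valtrans.inference` consumes.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.special import betaln, digamma, expit, log_ndtr

from valtrans._kernels import (
    fivepl_logp_grad,
    fivepl_logp_grad_nc,
    linear_logp_grad,
    pack_fivepl_priors,
    pack_linear_priors,
)

__all__ = [
    "FivePLParams",
    "ModelSpec",
    "PRIOR_CONSTANTS",
    "five_pl",
    "build_5pl_model",
    "build_linear_model",
    "build_en_model",
    "log_density_constrained",
]

ModelKind = Literal[
    "fivepl", "linear", "fivepl_en", "fivepl_en_age", "fivepl_en_age_interaction"
]

#: Every prior constant of the model families, config-visible and overridable.
#: Group-level entries give the hyperprior (mu, sd, bounds); participant-level
#: entries give the fixed SD and truncation bounds around the group mean.
PRIOR_CONSTANTS: dict[str, dict[str, float]] = {
    "alpha1": {"mu": 2.0, "sd": 1.0, "lower": 1.0},
    "alpha2": {"mu": 10.0, "sd": 1.0},
    "mu_b": {"mu": 2.0, "sd": 1.0, "lower": 1.0},
    "mu_c": {"mu": 2.0, "sd": 1.0, "lower": 0.5},
    "mu_d": {"mu": 2.0, "sd": 1.0, "lower": 0.0},
    "mu_g": {"mu": 4.0, "sd": 1.0, "lower": 1.0},
    "b": {"sd": 1.0, "lower": 0.5},
    "c": {"sd": 1.0, "lower": 0.5, "upper": 5.0},
    "d": {"sd": 1.0, "lower": 0.5},
    "g": {"sd": 1.0, "lower": 0.8},
    "linear_mu_a": {"mu": 0.0, "sd": 0.2, "lower": 0.0},
    "linear_mu_b": {"mu": 0.0, "sd": 0.5, "lower": 0.0},
    "linear_a": {"sd": 1.0, "lower": 0.0},
    "linear_b": {"sd": 1.0, "lower": 0.0},
    "en": {"mu": 0.0, "sd": 1.0},
    "age": {"mu": 0.0, "sd": 1.0},
    "interaction": {"mu": 0.0, "sd": 1.0},
    "sigma": {"sd": 0.2},
    "slope_sd": {"sd": 1.0},
}

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class FivePLParams:
    """One 5-PL curve: (a, b, c, d, g) with the published truncation bounds."""

    a: float
    b: float
    c: float
    d: float
    g: float

    def __post_init__(self) -> None:
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"a={self.a} outside (0, 1)")
        if self.b < 0.5:
            raise ValueError(f"b={self.b} below 0.5")
        if not (0.5 < self.c < 5.0):
            raise ValueError(f"c={self.c} outside (0.5, 5)")
        if self.d <= 0.0:
            raise ValueError(f"d={self.d} not positive")
        if self.g <= 0.0:
            raise ValueError(f"g={self.g} not positive")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.g)


def five_pl(x, a, b=None, c=None, d=None, g=None):
    """Evaluate the asymmetric logistic ``d + (a - d) / (1 + (x/c)^b)^g``.

    ``x`` must be positive (the power ``(x/c)^b`` requires it). Accepts
    either ``five_pl(x, params)`` with a :class:`FivePLParams` or the five
    scalars/arrays directly. Computed in log space so large ``b`` values do
    not overflow.
    """
    if isinstance(a, FivePLParams):
        a, b, c, d, g = a.as_tuple()
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("five_pl requires x > 0")
    w = np.asarray(b, dtype=float) * (np.log(x) - np.log(c))
    h = np.exp(-np.asarray(g, dtype=float) * np.logaddexp(0.0, w))
    out = d + (a - d) * h
    return out if out.ndim else float(out)


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class ModelSpec:
    """A fully bound model: kind, data, covariates, and prior constants.

    ``x``/``y``/``participant_idx`` are flat per-observation arrays;
    ``participant_idx`` maps each observation to ``participant_ids``.
    """

    model_kind: ModelKind
    x: np.ndarray
    y: np.ndarray
    participant_idx: np.ndarray
    participant_ids: list[str]
    numbing_z: np.ndarray | None = None
    age_z: np.ndarray | None = None
    priors: dict[str, dict[str, float]] = field(default_factory=dict)
    estimate_slope_sd: bool = False
    noncentered: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.participant_idx = np.asarray(self.participant_idx, dtype=np.int64)
        merged = copy.deepcopy(PRIOR_CONSTANTS)
        for key, sub in (self.priors or {}).items():
            merged.setdefault(key, {}).update(sub)
        self.priors = merged
        self._validate()

    def _validate(self) -> None:
        n = self.x.shape[0]
        if self.y.shape[0] != n or self.participant_idx.shape[0] != n:
            raise ValueError("x, y and participant_idx must be equally long")
        if np.any(self.x <= 0):
            raise ValueError("norm valence x must be positive")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("ratings y must lie in [0, 1]")
        P = len(self.participant_ids)
        if P < 2:
            raise ValueError("need at least 2 participants")
        idx = np.unique(self.participant_idx)
        if idx.min() < 0 or idx.max() >= P:
            raise ValueError("participant_idx outside the id table")
        if len(idx) != P:
            missing = sorted(set(range(P)) - set(idx.tolist()))
            raise ValueError(f"participants with no observations: {missing}")
        if self.model_kind.startswith("fivepl_en"):
            if self.numbing_z is None or len(self.numbing_z) != P:
                raise ValueError("EN models need one numbing_z per participant")
            self.numbing_z = np.asarray(self.numbing_z, dtype=float)
            if abs(float(self.numbing_z.mean())) > 1e-6:
                raise ValueError("numbing_z must be centred (mean 0)")
        if self.model_kind in ("fivepl_en_age", "fivepl_en_age_interaction"):
            if self.age_z is None or len(self.age_z) != P:
                raise ValueError("age models need one age_z per participant")
            self.age_z = np.asarray(self.age_z, dtype=float)

    @property
    def n_obs(self) -> int:
        return int(self.x.shape[0])

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def to_json(self) -> str:
        payload = {
            "model_kind": self.model_kind,
            "priors": self.priors,
            "estimate_slope_sd": self.estimate_slope_sd,
            "noncentered": self.noncentered,
            "participant_ids": self.participant_ids,
            "x": self.x.tolist(),
            "y": self.y.tolist(),
            "participant_idx": self.participant_idx.tolist(),
            "numbing_z": None if self.numbing_z is None else self.numbing_z.tolist(),
            "age_z": None if self.age_z is None else self.age_z.tolist(),
            "checksums": {"x": _sha256(self.x), "y": _sha256(self.y)},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        p = json.loads(text)
        spec = cls(
            model_kind=p["model_kind"],
            x=np.array(p["x"]),
            y=np.array(p["y"]),
            participant_idx=np.array(p["participant_idx"]),
            participant_ids=list(p["participant_ids"]),
            numbing_z=None if p["numbing_z"] is None else np.array(p["numbing_z"]),
            age_z=None if p["age_z"] is None else np.array(p["age_z"]),
            priors=p["priors"],
            estimate_slope_sd=bool(p["estimate_slope_sd"]),
            noncentered=bool(p.get("noncentered", False)),
        )
        chk = p.get("checksums", {})
        if chk and (chk["x"] != _sha256(spec.x) or chk["y"] != _sha256(spec.y)):
            raise ValueError("data checksum mismatch on deserialization")
        return spec

    def log_density(self):
        """Build the unconstrained log-density object the sampler consumes."""
        if self.model_kind == "linear":
            return _LinearDensity(self)
        return _FivePLDensity(self)


def sample_prior(
    spec: ModelSpec, n_draws: int = 500, seed: int = 0
) -> dict[str, np.ndarray]:
    """Forward draws from the hierarchical prior (no likelihood).

    Group-level parameters come from their hyperpriors, participant-level
    parameters from the truncated distributions around them; used for
    prior-predictive checks of the truncation structure.
    """
    from scipy.stats import truncnorm

    rng = np.random.default_rng(seed)
    pr = spec.priors
    P = spec.n_participants

    def tn(mu, sd, lower=-np.inf, upper=np.inf, size=None):
        return truncnorm.rvs(
            (lower - mu) / sd, (upper - mu) / sd, loc=mu, scale=sd, size=size,
            random_state=rng,
        )

    out: dict[str, list] = {}
    if spec.model_kind == "linear":
        for _ in range(n_draws):
            mu_a = tn(pr["linear_mu_a"]["mu"], pr["linear_mu_a"]["sd"], 0.0)
            mu_b = tn(pr["linear_mu_b"]["mu"], pr["linear_mu_b"]["sd"], 0.0)
            out.setdefault("mu_a", []).append(mu_a)
            out.setdefault("mu_b", []).append(mu_b)
            out.setdefault("a", []).append(tn(mu_a, pr["linear_a"]["sd"], 0.0, size=P))
            out.setdefault("b", []).append(tn(mu_b, pr["linear_b"]["sd"], 0.0, size=P))
        return {k: np.asarray(v) for k, v in out.items()}
    for _ in range(n_draws):
        alpha1 = tn(pr["alpha1"]["mu"], pr["alpha1"]["sd"], pr["alpha1"]["lower"])
        alpha2 = rng.normal(pr["alpha2"]["mu"], pr["alpha2"]["sd"])
        while alpha2 <= 0:  # positivity guard; ~7.6e-24 prior mass
            alpha2 = rng.normal(pr["alpha2"]["mu"], pr["alpha2"]["sd"])
        mus = {
            k: tn(pr[k]["mu"], pr[k]["sd"], pr[k]["lower"])
            for k in ("mu_b", "mu_c", "mu_d", "mu_g")
        }
        out.setdefault("alpha1", []).append(alpha1)
        out.setdefault("alpha2", []).append(alpha2)
        for k, v in mus.items():
            out.setdefault(k, []).append(v)
        out.setdefault("a", []).append(rng.beta(alpha1, alpha2, size=P))
        out.setdefault("b", []).append(tn(mus["mu_b"], pr["b"]["sd"], pr["b"]["lower"], size=P))
        out.setdefault("c", []).append(
            tn(mus["mu_c"], pr["c"]["sd"], pr["c"]["lower"], pr["c"]["upper"], size=P)
        )
        out.setdefault("d", []).append(tn(mus["mu_d"], pr["d"]["sd"], pr["d"]["lower"], size=P))
        out.setdefault("g", []).append(tn(mus["mu_g"], pr["g"]["sd"], pr["g"]["lower"], size=P))
    return {k: np.asarray(v) for k, v in out.items()}


def _as_long_format(
    ratings, norms, participant_index
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Join a rating table with norms into flat x/y/index arrays.

    ``ratings``: DataFrame (participant_id, image_id, rating); ``norms``:
    DataFrame (image_id, valence_mean, ...); ``participant_index``: ordered
    participant ids (rows of the covariate vectors), or None to take sorted
    unique ids from the ratings.
    """
    merged = ratings.merge(
        norms[["image_id", "valence_mean"]], on="image_id", how="left", validate="m:1"
    )
    if merged["valence_mean"].isna().any():
        bad = merged.loc[merged["valence_mean"].isna(), "image_id"].unique().tolist()
        raise ValueError(f"no norm for rated image(s): {bad}")
    if participant_index is None:
        participant_index = sorted(merged["participant_id"].astype(str).unique())
    ids = [str(p) for p in participant_index]
    pos = {p: i for i, p in enumerate(ids)}
    unknown = set(merged["participant_id"].astype(str)) - set(ids)
    if unknown:
        raise ValueError(f"ratings for participants missing from index: {sorted(unknown)}")
    idx = merged["participant_id"].astype(str).map(pos).to_numpy(dtype=np.int64)
    return (
        merged["valence_mean"].to_numpy(dtype=float),
        merged["rating"].to_numpy(dtype=float),
        idx,
        ids,
    )


def build_5pl_model(
    ratings,
    norms,
    participant_index=None,
    *,
    priors=None,
    estimate_slope_sd=False,
    noncentered=False,
) -> ModelSpec:
    """Bind the hierarchical 5-PL model to positive-image-filtered data.

    ``noncentered=True`` switches the participant-level truncated normals
    to their quantile (non-centered) parameterization — the same posterior,
    better conditioned when participant parameters are weakly identified.
    """
    x, y, idx, ids = _as_long_format(ratings, norms, participant_index)
    return ModelSpec(
        model_kind="fivepl",
        x=x,
        y=y,
        participant_idx=idx,
        participant_ids=ids,
        priors=priors or {},
        estimate_slope_sd=estimate_slope_sd,
        noncentered=noncentered,
    )


def build_linear_model(ratings, norms, participant_index=None, *, priors=None) -> ModelSpec:
    """Bind the hierarchical linear comparison model ``f(x) = b x + a``."""
    x, y, idx, ids = _as_long_format(ratings, norms, participant_index)
    return ModelSpec(
        model_kind="linear",
        x=x,
        y=y,
        participant_idx=idx,
        participant_ids=ids,
        priors=priors or {},
    )


def build_en_model(
    ratings,
    norms,
    participant_index,
    numbing_z,
    extra: Literal["none", "age", "age_interaction"] = "none",
    age_z=None,
    *,
    priors=None,
    estimate_slope_sd=True,
    noncentered=False,
) -> ModelSpec:
    """Bind the emotional-numbing slope extension ``B_i = numbing_z_i * EN + b_i``.

    ``extra="age"`` adds ``age_z_i * AGE`` to the slope; ``"age_interaction"``
    further adds ``numbing_z_i * age_z_i * INT``. Covariates are one value
    per participant in ``participant_index`` order; ``numbing_z`` must be
    centred. The between-participant slope SD is estimated by default (a
    HalfNormal(1) prior); set ``estimate_slope_sd=False`` for the fixed
    unit SD used by the base model.
    """
    kind = {
        "none": "fivepl_en",
        "age": "fivepl_en_age",
        "age_interaction": "fivepl_en_age_interaction",
    }[extra]
    x, y, idx, ids = _as_long_format(ratings, norms, participant_index)
    return ModelSpec(
        model_kind=kind,
        x=x,
        y=y,
        participant_idx=idx,
        participant_ids=ids,
        numbing_z=numbing_z,
        age_z=age_z,
        priors=priors or {},
        estimate_slope_sd=estimate_slope_sd,
        noncentered=noncentered,
    )


# --------------------------------------------------------------------------
# log-density machinery (unconstrained parameterization, analytic gradients)
# --------------------------------------------------------------------------


def _phi(t):
    return np.exp(-0.5 * t * t - 0.5 * _LOG2PI)


def _mills(t):
    """phi(t) / Phi(t), stable for very negative t."""
    return np.exp(-0.5 * t * t - 0.5 * _LOG2PI - log_ndtr(t))


def _log_diff_ndtr(hi, lo):
    """log(Phi(hi) - Phi(lo)) for hi > lo, in log space."""
    a, b = log_ndtr(hi), log_ndtr(lo)
    return a + np.log1p(-np.exp(np.minimum(b - a, -1e-12)))


class _FivePLDensity:
    """Unconstrained log posterior + gradient for the 5-PL family.

    Parameter vector layout: 6 group-level transforms (alpha1, alpha2,
    mu_b, mu_c, mu_d, mu_g), then P-vectors for a, b, c, d, g, then
    log sigma, then optional covariate coefficients (EN / AGE / INT,
    identity-transformed) and optional log slope-SD.

    Transforms: lower-bounded parameters use ``L + exp(t)``; ``a`` uses the
    logistic map onto (0, 1); ``c`` uses a scaled logistic onto (0.5, 5);
    ``alpha2`` and the covariate coefficients are untransformed (``alpha2``
    carries a hard positivity guard, effectively never active under its
    Normal(10, 1) prior).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.P = spec.n_participants
        self.n = spec.n_obs
        self.x = spec.x
        self.y = spec.y
        self.idx = spec.participant_idx
        self.logx = np.log(spec.x)
        self.pr = spec.priors
        self.kind = spec.model_kind
        self.n_coeffs = {
            "fivepl": 0,
            "fivepl_en": 1,
            "fivepl_en_age": 2,
            "fivepl_en_age_interaction": 3,
        }[self.kind]
        self.estimate_slope_sd = spec.estimate_slope_sd
        P = self.P
        self.slices = {
            "group": slice(0, 6),
            "a": slice(6, 6 + P),
            "b": slice(6 + P, 6 + 2 * P),
            "c": slice(6 + 2 * P, 6 + 3 * P),
            "d": slice(6 + 3 * P, 6 + 4 * P),
            "g": slice(6 + 4 * P, 6 + 5 * P),
        }
        pos = 6 + 5 * P
        self.i_sigma = pos
        pos += 1
        self.i_coeffs = slice(pos, pos + self.n_coeffs)
        pos += self.n_coeffs
        self.i_slope_sd = pos if self.estimate_slope_sd else None
        self.n_dim = pos + (1 if self.estimate_slope_sd else 0)
        if self.n_coeffs >= 1:
            self.nz = np.asarray(spec.numbing_z, dtype=float)
        if self.n_coeffs >= 2:
            self.az = np.asarray(spec.age_z, dtype=float)
        self._nz_arr = self.nz if self.n_coeffs >= 1 else np.zeros(P)
        self._az_arr = self.az if self.n_coeffs >= 2 else np.zeros(P)
        self._pr_vec = pack_fivepl_priors(self.pr)
        # dense mass-matrix blocks: one per participant (their five curve
        # parameters ride a strong likelihood ridge, e.g. inflection vs
        # asymmetry) and one for the group-level scalars
        scalars = list(range(6)) + [self.i_sigma]
        scalars += list(range(self.i_coeffs.start, self.i_coeffs.stop))
        if self.estimate_slope_sd:
            scalars.append(self.i_slope_sd)
        self.mass_blocks = [np.asarray(scalars, dtype=np.int64)] + [
            np.asarray([6 + k * P + i for k in range(5)], dtype=np.int64)
            for i in range(P)
        ]

    # -- transforms --------------------------------------------------------

    def constrain(self, z: np.ndarray) -> dict[str, np.ndarray]:
        """Map unconstrained draws (..., n_dim) to named constrained arrays."""
        z = np.asarray(z, dtype=float)
        pr = self.pr
        s = self.slices
        out = {
            "alpha1": pr["alpha1"]["lower"] + np.exp(z[..., 0]),
            "alpha2": z[..., 1],
            "mu_b": pr["mu_b"]["lower"] + np.exp(z[..., 2]),
            "mu_c": pr["mu_c"]["lower"] + np.exp(z[..., 3]),
            "mu_d": pr["mu_d"]["lower"] + np.exp(z[..., 4]),
            "mu_g": pr["mu_g"]["lower"] + np.exp(z[..., 5]),
            "a": expit(z[..., s["a"]]),
            "sigma": np.exp(z[..., self.i_sigma]),
        }
        names = ["en", "age_coeff", "interaction"][: self.n_coeffs]
        for k, name in enumerate(names):
            out[name] = z[..., self.i_coeffs.start + k]
        if self.estimate_slope_sd:
            out["slope_sd"] = np.exp(z[..., self.i_slope_sd])
        if not self.spec.noncentered:
            out["b"] = pr["b"]["lower"] + np.exp(z[..., s["b"]])
            out["c"] = pr["c"]["lower"] + (
                pr["c"]["upper"] - pr["c"]["lower"]
            ) * expit(z[..., s["c"]])
            out["d"] = pr["d"]["lower"] + np.exp(z[..., s["d"]])
            out["g"] = pr["g"]["lower"] + np.exp(z[..., s["g"]])
            return out
        # non-centered: raw normal variates through the truncated-normal
        # quantile given the (per-draw) group means
        from scipy.special import ndtr, ndtri

        def tq(zraw, mu, sd, lo, hi=np.inf):
            mu = np.asarray(mu)[..., None]
            sd = np.asarray(sd)[..., None] if np.ndim(sd) else sd
            u = ndtr(zraw)
            p_lo = ndtr((lo - mu) / sd)
            p_hi = ndtr((hi - mu) / sd) if np.isfinite(hi) else 1.0
            t = np.clip(p_lo + u * (p_hi - p_lo), 1e-15, 1 - 1e-15)
            return mu + sd * ndtri(t)

        sd_b = out["slope_sd"] if self.estimate_slope_sd else pr["b"]["sd"]
        out["b"] = tq(z[..., s["b"]], out["mu_b"], sd_b, pr["b"]["lower"])
        out["c"] = tq(
            z[..., s["c"]], out["mu_c"], pr["c"]["sd"], pr["c"]["lower"],
            pr["c"]["upper"],
        )
        out["d"] = tq(z[..., s["d"]], out["mu_d"], pr["d"]["sd"], pr["d"]["lower"])
        out["g"] = tq(z[..., s["g"]], out["mu_g"], pr["g"]["sd"], pr["g"]["lower"])
        return out

    def param_dims(self) -> dict[str, tuple[str, ...]]:
        per_p = ("participant",)
        dims = {k: () for k in ("alpha1", "alpha2", "mu_b", "mu_c", "mu_d", "mu_g", "sigma")}
        dims.update({k: per_p for k in ("a", "b", "c", "d", "g")})
        for name in ["en", "age_coeff", "interaction"][: self.n_coeffs]:
            dims[name] = ()
        if self.estimate_slope_sd:
            dims["slope_sd"] = ()
        return dims

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
        """A reasonable unconstrained start plus uniform jitter."""
        z = np.empty(self.n_dim)
        z[0] = np.log(2.0 - self.pr["alpha1"]["lower"])  # alpha1 = 2
        z[1] = 10.0  # alpha2 (identity)
        z[2] = np.log(1.8 - self.pr["mu_b"]["lower"])
        z[3] = np.log(2.5 - self.pr["mu_c"]["lower"])
        z[4] = np.log(1.0 - self.pr["mu_d"]["lower"])
        z[5] = np.log(4.0 - self.pr["mu_g"]["lower"])
        s = self.slices
        z[s["a"]] = np.log(0.1 / 0.9)  # a = 0.1
        if self.spec.noncentered:
            z[s["b"]] = 0.0  # standard-normal variates
            z[s["c"]] = 0.0
            z[s["d"]] = 0.0
            z[s["g"]] = 0.0
        else:
            z[s["b"]] = np.log(1.8 - self.pr["b"]["lower"])
            z[s["c"]] = 0.0  # midpoint of (0.5, 5)
            z[s["d"]] = np.log(0.7 - self.pr["d"]["lower"])
            z[s["g"]] = np.log(2.5 - self.pr["g"]["lower"])
        z[self.i_sigma] = np.log(0.1)
        z[self.i_coeffs] = 0.0
        if self.estimate_slope_sd:
            z[self.i_slope_sd] = np.log(0.5)
        jit = rng.uniform(-jitter, jitter, size=self.n_dim)
        jit[1] *= 0.5  # alpha2 is on its natural scale
        return z + jit

    # -- density -----------------------------------------------------------

    def _slope_per_participant(self, b, coeffs):
        B = b
        if self.n_coeffs >= 1:
            B = B + coeffs[0] * self.nz
        if self.n_coeffs >= 2:
            B = B + coeffs[1] * self.az
        if self.n_coeffs >= 3:
            B = B + coeffs[2] * (self.nz * self.az)
        return B

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        """Fast path: the compiled kernel (same math as the reference)."""
        kern = fivepl_logp_grad_nc if self.spec.noncentered else fivepl_logp_grad
        return kern(
            z,
            self.logx,
            self.y,
            self.idx,
            self.P,
            self.n_coeffs,
            1 if self.estimate_slope_sd else 0,
            self._nz_arr,
            self._az_arr,
            self._pr_vec,
        )

    def logp_grad_reference(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        """Pure numpy/scipy implementation of the same log density; the
        compiled path is asserted against it in the tests. Centered
        parameterization only (the non-centered kernel is validated by
        finite differences and posterior equivalence instead)."""
        if self.spec.noncentered:
            raise NotImplementedError("reference path covers the centered form")
        pr, P, s = self.pr, self.P, self.slices
        grad = np.zeros_like(z)

        # transforms
        alpha1 = pr["alpha1"]["lower"] + np.exp(z[0])
        alpha2 = z[1]
        mu_b = pr["mu_b"]["lower"] + np.exp(z[2])
        mu_c = pr["mu_c"]["lower"] + np.exp(z[3])
        mu_d = pr["mu_d"]["lower"] + np.exp(z[4])
        mu_g = pr["mu_g"]["lower"] + np.exp(z[5])
        ta, tb, tc, td, tg = z[s["a"]], z[s["b"]], z[s["c"]], z[s["d"]], z[s["g"]]
        a = expit(ta)
        b = pr["b"]["lower"] + np.exp(tb)
        c_lo, c_hi = pr["c"]["lower"], pr["c"]["upper"]
        sc = expit(tc)
        c = c_lo + (c_hi - c_lo) * sc
        d = pr["d"]["lower"] + np.exp(td)
        g = pr["g"]["lower"] + np.exp(tg)
        sigma = np.exp(z[self.i_sigma])
        coeffs = z[self.i_coeffs]
        if self.estimate_slope_sd:
            sd_b = np.exp(z[self.i_slope_sd])
        else:
            sd_b = pr["b"]["sd"]

        if not np.isfinite(alpha2) or alpha2 <= 0.0:
            return -np.inf, grad

        lp = 0.0

        # log|Jacobian| of the transforms
        log_a = -np.logaddexp(0.0, -ta)  # log(expit(ta))
        log_1ma = -np.logaddexp(0.0, ta)
        log_sc = -np.logaddexp(0.0, -tc)
        log_1msc = -np.logaddexp(0.0, tc)
        lp += z[0] + z[2] + z[3] + z[4] + z[5]
        lp += float(np.sum(log_a + log_1ma))
        lp += float(np.sum(tb + td + tg)) + float(np.sum(log_sc + log_1msc)) + P * np.log(
            c_hi - c_lo
        )
        lp += z[self.i_sigma]
        grad[0] += 1.0
        grad[2:6] += 1.0
        grad[s["a"]] += 1.0 - 2.0 * a
        grad[s["b"]] += 1.0
        grad[s["c"]] += 1.0 - 2.0 * sc
        grad[s["d"]] += 1.0
        grad[s["g"]] += 1.0
        grad[self.i_sigma] += 1.0
        if self.estimate_slope_sd:
            lp += z[self.i_slope_sd]
            grad[self.i_slope_sd] += 1.0

        # chain-rule factors d(constrained)/d(unconstrained)
        J = {
            "a": a * (1.0 - a),
            "b": b - pr["b"]["lower"],
            "c": (c_hi - c_lo) * sc * (1.0 - sc),
            "d": d - pr["d"]["lower"],
            "g": g - pr["g"]["lower"],
        }
        dgroup = np.array(
            [
                alpha1 - pr["alpha1"]["lower"],
                1.0,
                mu_b - pr["mu_b"]["lower"],
                mu_c - pr["mu_c"]["lower"],
                mu_d - pr["mu_d"]["lower"],
                mu_g - pr["mu_g"]["lower"],
            ]
        )
        # accumulate constrained-space gradients here, chain-rule at the end
        gC = {k: np.zeros(P) for k in ("a", "b", "c", "d", "g")}
        gG = np.zeros(6)  # alpha1, alpha2, mu_b, mu_c, mu_d, mu_g
        g_sigma = 0.0
        g_coeffs = np.zeros(self.n_coeffs)
        g_sd_b = 0.0

        # group-level hyperpriors (truncation normalizers are constant)
        for j, name in enumerate(("alpha1", "alpha2", "mu_b", "mu_c", "mu_d", "mu_g")):
            m, sd = pr[name]["mu"], pr[name]["sd"]
            v = (alpha1, alpha2, mu_b, mu_c, mu_d, mu_g)[j]
            lp += -0.5 * ((v - m) / sd) ** 2
            gG[j] += -(v - m) / sd**2

        # a_i ~ Beta(alpha1, alpha2)
        lp += float(
            np.sum((alpha1 - 1.0) * log_a + (alpha2 - 1.0) * log_1ma)
        ) - P * betaln(alpha1, alpha2)
        # beta-prior gradient taken in unconstrained space (the division by
        # a(1-a) cancels against the logistic Jacobian)
        grad[s["a"]] += (alpha1 - 1.0) * (1.0 - a) - (alpha2 - 1.0) * a
        dig_sum = digamma(alpha1 + alpha2)
        gG[0] += float(np.sum(log_a)) - P * (digamma(alpha1) - dig_sum)
        gG[1] += float(np.sum(log_1ma)) - P * (digamma(alpha2) - dig_sum)

        # b_i ~ TruncNormal(mu_b, sd_b, lower 0.5)
        tau = (mu_b - pr["b"]["lower"]) / sd_b
        r = _mills(tau)
        resid_b = (b - mu_b) / sd_b
        lp += float(np.sum(-0.5 * resid_b**2)) - P * (np.log(sd_b) + log_ndtr(tau))
        gC["b"] += -resid_b / sd_b
        gG[2] += float(np.sum(resid_b)) / sd_b - P * r / sd_b
        if self.estimate_slope_sd:
            g_sd_b += (
                float(np.sum(resid_b**2)) / sd_b - P / sd_b + P * r * tau / sd_b
            )
            # HalfNormal prior on the estimated slope SD
            ssd = pr["slope_sd"]["sd"]
            lp += -0.5 * (sd_b / ssd) ** 2
            g_sd_b += -sd_b / ssd**2

        # c_i ~ TruncNormal(mu_c, 1, 0.5, 5)
        logZ_c = _log_diff_ndtr(c_hi - mu_c, c_lo - mu_c)
        lp += float(np.sum(-0.5 * (c - mu_c) ** 2)) - P * logZ_c
        gC["c"] += -(c - mu_c)
        dlogZ_c = (_phi(c_lo - mu_c) - _phi(c_hi - mu_c)) / np.exp(logZ_c)
        gG[3] += float(np.sum(c - mu_c)) - P * dlogZ_c

        # d_i ~ TruncNormal(mu_d, 1, lower 0.5); g_i ~ TruncNormal(mu_g, 1, lower 0.8)
        for name, v, mu_v, gi in (("d", d, mu_d, 4), ("g", g, mu_g, 5)):
            lo = pr[name]["lower"]
            tau = mu_v - lo
            lp += float(np.sum(-0.5 * (v - mu_v) ** 2)) - P * log_ndtr(tau)
            gC[name] += -(v - mu_v)
            gG[gi] += float(np.sum(v - mu_v)) - P * _mills(tau)

        # covariate coefficients ~ Normal(0, 1)
        for k, name in enumerate(["en", "age", "interaction"][: self.n_coeffs]):
            m, sd = pr[name]["mu"], pr[name]["sd"]
            lp += -0.5 * ((coeffs[k] - m) / sd) ** 2
            g_coeffs[k] += -(coeffs[k] - m) / sd**2

        # sigma ~ HalfNormal(0.2)
        ssig = pr["sigma"]["sd"]
        lp += -0.5 * (sigma / ssig) ** 2
        g_sigma += -sigma / ssig**2

        # likelihood
        B = self._slope_per_participant(b, coeffs)
        idx = self.idx
        Bp, Cp, Gp, Ap, Dp = B[idx], c[idx], g[idx], a[idx], d[idx]
        logc = np.log(c)
        w = Bp * (self.logx - logc[idx])
        log1pu = np.logaddexp(0.0, w)
        h = np.exp(-Gp * log1pu)
        f = Dp + (Ap - Dp) * h
        resid = self.y - f
        inv_s2 = 1.0 / (sigma * sigma)
        lp += -0.5 * inv_s2 * float(np.sum(resid * resid)) - self.n * np.log(sigma)
        if not np.isfinite(lp):
            return -np.inf, grad

        dll_df = resid * inv_s2
        e1 = np.exp(w - (Gp + 1.0) * log1pu)  # u / (1+u)^(g+1)
        amd = Ap - Dp
        df_dB = -amd * Gp * e1 * (self.logx - logc[idx])
        df_dc = amd * Gp * e1 * Bp / Cp
        df_dg = -amd * h * log1pu

        def acc(v):
            return np.bincount(idx, weights=dll_df * v, minlength=P)

        gC["a"] += acc(h)
        gC["d"] += acc(1.0 - h)
        gB_lik = acc(df_dB)
        gC["b"] += gB_lik
        gC["c"] += acc(df_dc)
        gC["g"] += acc(df_dg)
        g_sigma += inv_s2 / sigma * float(np.sum(resid * resid)) - self.n / sigma
        if self.n_coeffs >= 1:
            g_coeffs[0] += float(np.sum(gB_lik * self.nz))
        if self.n_coeffs >= 2:
            g_coeffs[1] += float(np.sum(gB_lik * self.az))
        if self.n_coeffs >= 3:
            g_coeffs[2] += float(np.sum(gB_lik * self.nz * self.az))

        # chain rule back to unconstrained space
        grad[:6] += gG * dgroup
        for name in ("a", "b", "c", "d", "g"):
            grad[s[name]] += gC[name] * J[name]
        grad[self.i_sigma] += g_sigma * sigma
        grad[self.i_coeffs] += g_coeffs
        if self.estimate_slope_sd:
            grad[self.i_slope_sd] += g_sd_b * sd_b
        if not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(z)
        return float(lp), grad

    # -- pointwise log likelihood (for LOO) --------------------------------

    def pointwise_loglik(self, Z: np.ndarray, chunk: int = 200) -> np.ndarray:
        """Per-observation Gaussian log likelihood for draws Z (ndraw, n_dim)."""
        Z = np.atleast_2d(Z)
        out = np.empty((Z.shape[0], self.n))
        for lo in range(0, Z.shape[0], chunk):
            zc = Z[lo : lo + chunk]
            p = self.constrain(zc)
            b = p["b"]
            co = [p[k] for k in ["en", "age_coeff", "interaction"][: self.n_coeffs]]
            B = b
            if self.n_coeffs >= 1:
                B = B + co[0][:, None] * self.nz
            if self.n_coeffs >= 2:
                B = B + co[1][:, None] * self.az
            if self.n_coeffs >= 3:
                B = B + co[2][:, None] * (self.nz * self.az)
            idx = self.idx
            w = B[:, idx] * (self.logx - np.log(p["c"])[:, idx])
            h = np.exp(-p["g"][:, idx] * np.logaddexp(0.0, w))
            f = p["d"][:, idx] + (p["a"][:, idx] - p["d"][:, idx]) * h
            sig = p["sigma"][:, None]
            out[lo : lo + chunk] = (
                -0.5 * ((self.y - f) / sig) ** 2 - np.log(sig) - 0.5 * _LOG2PI
            )
        return out


class _LinearDensity:
    """Unconstrained log posterior + gradient for the hierarchical linear model.

    Layout: [t_mu_a, t_mu_b, t_a (P), t_b (P), t_sigma]; every parameter is
    lower-bounded at 0 and mapped through exp.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.P = spec.n_participants
        self.n = spec.n_obs
        self.x, self.y, self.idx = spec.x, spec.y, spec.participant_idx
        self.pr = spec.priors
        P = self.P
        self.s_a = slice(2, 2 + P)
        self.s_b = slice(2 + P, 2 + 2 * P)
        self.i_sigma = 2 + 2 * P
        self.n_dim = 2 + 2 * P + 1
        self._pr_vec = pack_linear_priors(self.pr)
        self.mass_blocks = [
            np.asarray([0, 1, self.i_sigma], dtype=np.int64)
        ] + [
            np.asarray([2 + i, 2 + P + i], dtype=np.int64) for i in range(P)
        ]

    def constrain(self, z: np.ndarray) -> dict[str, np.ndarray]:
        z = np.asarray(z, dtype=float)
        return {
            "mu_a": np.exp(z[..., 0]),
            "mu_b": np.exp(z[..., 1]),
            "a": np.exp(z[..., self.s_a]),
            "b": np.exp(z[..., self.s_b]),
            "sigma": np.exp(z[..., self.i_sigma]),
        }

    def param_dims(self) -> dict[str, tuple[str, ...]]:
        return {
            "mu_a": (),
            "mu_b": (),
            "a": ("participant",),
            "b": ("participant",),
            "sigma": (),
        }

    def initial_point(self, rng: np.random.Generator, jitter: float = 0.3) -> np.ndarray:
        z = np.empty(self.n_dim)
        z[0] = np.log(0.05)
        z[1] = np.log(0.1)
        z[self.s_a] = np.log(0.05)
        z[self.s_b] = np.log(0.1)
        z[self.i_sigma] = np.log(0.1)
        return z + rng.uniform(-jitter, jitter, size=self.n_dim)

    def logp_grad(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        """Fast path: the compiled kernel (same math as the reference)."""
        return linear_logp_grad(z, self.x, self.y, self.idx, self.P, self._pr_vec)

    def logp_grad_reference(self, z: np.ndarray) -> tuple[float, np.ndarray]:
        pr, P = self.pr, self.P
        grad = np.zeros_like(z)
        mu_a, mu_b = np.exp(z[0]), np.exp(z[1])
        a, b = np.exp(z[self.s_a]), np.exp(z[self.s_b])
        sigma = np.exp(z[self.i_sigma])

        lp = z[0] + z[1] + float(np.sum(z[self.s_a]) + np.sum(z[self.s_b])) + z[self.i_sigma]
        grad[:] = 1.0  # d log|J| / dt for pure exp transforms

        g_mu_a = g_mu_b = 0.0
        ga = np.zeros(P)
        gb = np.zeros(P)
        g_sigma = 0.0

        sa, sb = pr["linear_mu_a"]["sd"], pr["linear_mu_b"]["sd"]
        lp += -0.5 * (mu_a / sa) ** 2 - 0.5 * (mu_b / sb) ** 2
        g_mu_a += -mu_a / sa**2
        g_mu_b += -mu_b / sb**2

        # participant-level truncated normals around the group means, SD 1
        for v, mu_v, gvec, which in ((a, mu_a, ga, 0), (b, mu_b, gb, 1)):
            lp += float(np.sum(-0.5 * (v - mu_v) ** 2)) - P * log_ndtr(mu_v)
            gvec += -(v - mu_v)
            gmu = float(np.sum(v - mu_v)) - P * _mills(mu_v)
            if which == 0:
                g_mu_a += gmu
            else:
                g_mu_b += gmu

        ssig = pr["sigma"]["sd"]
        lp += -0.5 * (sigma / ssig) ** 2
        g_sigma += -sigma / ssig**2

        idx = self.idx
        f = a[idx] + b[idx] * self.x
        resid = self.y - f
        inv_s2 = 1.0 / (sigma * sigma)
        lp += -0.5 * inv_s2 * float(np.sum(resid * resid)) - self.n * np.log(sigma)
        if not np.isfinite(lp):
            return -np.inf, np.zeros_like(z)
        dll_df = resid * inv_s2
        ga += np.bincount(idx, weights=dll_df, minlength=P)
        gb += np.bincount(idx, weights=dll_df * self.x, minlength=P)
        g_sigma += inv_s2 / sigma * float(np.sum(resid * resid)) - self.n / sigma

        grad[0] += g_mu_a * mu_a
        grad[1] += g_mu_b * mu_b
        grad[self.s_a] += ga * a
        grad[self.s_b] += gb * b
        grad[self.i_sigma] += g_sigma * sigma
        if not np.all(np.isfinite(grad)):
            return -np.inf, np.zeros_like(z)
        return float(lp), grad

    def pointwise_loglik(self, Z: np.ndarray, chunk: int = 500) -> np.ndarray:
        Z = np.atleast_2d(Z)
        out = np.empty((Z.shape[0], self.n))
        for lo in range(0, Z.shape[0], chunk):
            p = self.constrain(Z[lo : lo + chunk])
            f = p["a"][:, self.idx] + p["b"][:, self.idx] * self.x
            sig = p["sigma"][:, None]
            out[lo : lo + chunk] = (
                -0.5 * ((self.y - f) / sig) ** 2 - np.log(sig) - 0.5 * _LOG2PI
            )
        return out


def log_density_constrained(spec: ModelSpec, params: Mapping[str, np.ndarray]) -> float:
    """Log posterior density at a constrained parameter point.

    Returns ``-inf`` outside the truncation bounds. Mainly a validation and
    testing surface; sampling happens in unconstrained space.
    """
    pr = spec.priors
    dens = spec.log_density()
    if spec.model_kind == "linear":
        vals = [params["mu_a"], params["mu_b"]]
        if min(vals) < 0 or np.min(params["a"]) < 0 or np.min(params["b"]) < 0:
            return -np.inf
        if params["sigma"] <= 0:
            return -np.inf
        z = np.concatenate(
            [
                np.log([params["mu_a"], params["mu_b"]]),
                np.log(np.asarray(params["a"], dtype=float)),
                np.log(np.asarray(params["b"], dtype=float)),
                [np.log(params["sigma"])],
            ]
        )
        lp, _ = dens.logp_grad(z)
        # subtract the Jacobian to report the density of the constrained point
        return lp - float(np.sum(z))
    # 5-PL family
    try:
        a = np.asarray(params["a"], dtype=float)
        b = np.asarray(params["b"], dtype=float)
        c = np.asarray(params["c"], dtype=float)
        d = np.asarray(params["d"], dtype=float)
        g = np.asarray(params["g"], dtype=float)
        bounds_ok = (
            params["alpha1"] > pr["alpha1"]["lower"]
            and params["alpha2"] > 0
            and params["mu_b"] > pr["mu_b"]["lower"]
            and params["mu_c"] > pr["mu_c"]["lower"]
            and params["mu_d"] > pr["mu_d"]["lower"]
            and params["mu_g"] > pr["mu_g"]["lower"]
            and np.all((a > 0) & (a < 1))
            and np.all(b > pr["b"]["lower"])
            and np.all((c > pr["c"]["lower"]) & (c < pr["c"]["upper"]))
            and np.all(d > pr["d"]["lower"])
            and np.all(g > pr["g"]["lower"])
            and params["sigma"] > 0
        )
        if not bounds_ok:
            return -np.inf
        c_lo, c_hi = pr["c"]["lower"], pr["c"]["upper"]
        sc = (c - c_lo) / (c_hi - c_lo)
        z = np.concatenate(
            [
                [
                    np.log(params["alpha1"] - pr["alpha1"]["lower"]),
                    params["alpha2"],
                    np.log(params["mu_b"] - pr["mu_b"]["lower"]),
                    np.log(params["mu_c"] - pr["mu_c"]["lower"]),
                    np.log(params["mu_d"] - pr["mu_d"]["lower"]),
                    np.log(params["mu_g"] - pr["mu_g"]["lower"]),
                ],
                np.log(a / (1.0 - a)),
                np.log(b - pr["b"]["lower"]),
                np.log(sc / (1.0 - sc)),
                np.log(d - pr["d"]["lower"]),
                np.log(g - pr["g"]["lower"]),
                [np.log(params["sigma"])],
            ]
        )
        extras = []
        for name in ["en", "age_coeff", "interaction"][: dens.n_coeffs]:
            extras.append(params[name])
        if extras:
            z = np.concatenate([z, extras])
        if dens.estimate_slope_sd:
            z = np.concatenate([z, [np.log(params["slope_sd"])]])
    except (ValueError, FloatingPointError):
        return -np.inf
    lp, _ = dens.logp_grad(z)
    if not np.isfinite(lp):
        return -np.inf
    # remove the transform Jacobian: recompute it from the pieces
    P = dens.P
    s = dens.slices
    log_jac = (
        z[0] + z[2] + z[3] + z[4] + z[5]
        + float(np.sum(np.log(a * (1.0 - a))))
        + float(np.sum(z[s["b"]]) + np.sum(z[s["d"]]) + np.sum(z[s["g"]]))
        + float(np.sum(np.log((c_hi - c_lo) * sc * (1.0 - sc))))
        + z[dens.i_sigma]
    )
    if dens.estimate_slope_sd:
        log_jac += z[dens.i_slope_sd]
    return lp - log_jac
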