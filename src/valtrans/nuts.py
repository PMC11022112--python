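"""No-U-Turn Sampler with adaptive step size and structured mass matrix.

A self-contained implementation of dynamic Hamiltonian Monte Carlo in the
style PyMC/Stan use by default: multinomial sampling over the leapfrog
trajectory, doubling until the generalized U-turn criterion fires (or a
divergence is hit), dual-averaging step-size adaptation toward a target
acceptance statistic, and windowed estimation of the inverse mass matrix
from the tuning draws.

The inverse mass matrix is diagonal, optionally with dense blocks over
designated index sets (``model.mass_blocks``) plus a low-rank correction.
Hierarchical models use one block per participant's curve parameters plus
one for the group-level scalars: the strong within-participant
correlations (e.g. the inflection/asymmetry ridge) and the correlated
hyperparameters are whitened blockwise, which a purely diagonal metric
cannot do, while the cross-participant structure stays cheap. On top of
the blocks, the leading principal components of the block-whitened tuning
draws are added to the metric: hierarchical posteriors typically have a
handful of slow *collective* modes (all participants' parameters sliding
coherently along a shared likelihood ridge) that no blockwise metric can
capture. Blocks of equal size are batched, so the metric costs a handful
of einsums and small matrix-vector products per leapfrog step.

The sampler consumes any object with

* ``n_dim`` — dimension of the unconstrained parameter vector,
* ``logp_grad(z) -> (float, ndarray)`` — log density and gradient,
* ``initial_point(rng) -> ndarray`` — a starting point,
* optionally ``mass_blocks`` — a list of index arrays, one per block.

Draws are returned in unconstrained space together with per-iteration
sample statistics; callers map them back through the model's ``constrain``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_DIVERGENCE_ENERGY = 1000.0  # energy error treated as a divergent transition


@dataclass
class _Leaf:
    z: np.ndarray
    r: np.ndarray
    v: np.ndarray  # velocity M^{-1} r
    grad: np.ndarray
    lp: float
    H: float


@dataclass
class _Tree:
    minus: _Leaf
    plus: _Leaf
    proposal: _Leaf
    logw: float
    sum_alpha: float
    n_alpha: int
    n_leapfrog: int
    divergent: bool
    turning: bool


@dataclass
class NutsStats:
    """Per-chain sampler statistics (post-warmup iterations)."""

    lp: np.ndarray
    energy: np.ndarray
    acceptance_rate: np.ndarray
    tree_depth: np.ndarray
    n_leapfrog: np.ndarray
    diverging: np.ndarray
    step_size: float
    inv_mass: np.ndarray


class _BlockGroup:
    """A batch of equally sized dense inverse-mass blocks."""

    def __init__(self, idx: np.ndarray):
        self.idx = idx  # (m, k) index matrix
        m, k = idx.shape
        self.A = np.broadcast_to(np.eye(k), (m, k, k)).copy()
        self.L = self.A.copy()  # cholesky of A

    def set(self, cov: np.ndarray) -> None:
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = cov.copy()
            for j in range(cov.shape[-1]):
                cov[:, j, j] += 1e-6
            L = np.linalg.cholesky(cov)
        self.A = cov
        self.L = L


class _Chain:
    """One NUTS chain with its metric.

    Inverse mass: ``C = L (I + V diag(lam) V^T) L^T`` where ``L`` is the
    blockwise cholesky of the block-diagonal covariance estimate (diagonal
    outside the blocks) and ``V``/``lam`` hold the leading principal
    components of the block-whitened tuning draws (empty when no collective
    mode stands out).
    """

    def __init__(self, model, rng, target_accept, max_treedepth,
                 low_rank_max=4, low_rank_threshold=5.0):
        self.model = model
        self.rng = rng
        self.target = target_accept
        self.max_depth = max_treedepth
        self.low_rank_max = low_rank_max
        self.low_rank_threshold = low_rank_threshold
        n = model.n_dim
        self.inv_diag = np.ones(n)
        self.sqrt_diag = np.ones(n)
        blocks = getattr(model, "mass_blocks", None)
        self.groups: list[_BlockGroup] = []
        if blocks:
            by_size: dict[int, list] = {}
            for b in blocks:
                b = np.asarray(b, dtype=np.int64)
                if len(b) >= 2:
                    by_size.setdefault(len(b), []).append(b)
            self.groups = [_BlockGroup(np.stack(v)) for v in by_size.values()]
        self.V = np.zeros((n, 0))  # low-rank directions (whitened space)
        self.lam = np.zeros(0)

    # -- metric ------------------------------------------------------------

    def _apply_L(self, x):
        y = self.sqrt_diag * x
        for bg in self.groups:
            y[bg.idx] = np.einsum("mij,mj->mi", bg.L, x[bg.idx])
        return y

    def _apply_LT(self, x):
        y = self.sqrt_diag * x
        for bg in self.groups:
            y[bg.idx] = np.einsum("mji,mj->mi", bg.L, x[bg.idx])
        return y

    def _solve_L(self, x):
        y = x / self.sqrt_diag
        for bg in self.groups:
            y[bg.idx] = np.linalg.solve(bg.L, x[bg.idx][..., None])[..., 0]
        return y

    def _solve_LT(self, x):
        y = x / self.sqrt_diag
        for bg in self.groups:
            LT = np.transpose(bg.L, (0, 2, 1))
            y[bg.idx] = np.linalg.solve(LT, x[bg.idx][..., None])[..., 0]
        return y

    def velocity(self, r):
        w = self._apply_LT(r)
        if self.lam.size:
            w = w + self.V @ (self.lam * (self.V.T @ w))
        return self._apply_L(w)

    def set_mass(self, var_diag, cov_groups, window_draws=None, mean=None):
        self.inv_diag = np.maximum(var_diag, 1e-12)
        for bg, cov in zip(self.groups, cov_groups):
            if cov is not None:
                bg.set(cov)
                m, k = bg.idx.shape
                self.inv_diag[bg.idx] = bg.A[:, np.arange(k), np.arange(k)]
        self.sqrt_diag = np.sqrt(self.inv_diag)
        self.V = np.zeros((self.model.n_dim, 0))
        self.lam = np.zeros(0)
        if (
            self.low_rank_max > 0
            and window_draws is not None
            and len(window_draws) >= 150
        ):
            self._fit_low_rank(np.asarray(window_draws), mean)

    def _fit_low_rank(self, draws, mean):
        max_rank, var_threshold = self.low_rank_max, self.low_rank_threshold
        T = draws.shape[0]
        resid = draws - (mean if mean is not None else draws.mean(axis=0))
        white = np.empty_like(resid)
        for t in range(T):
            white[t] = self._solve_L(resid[t])
        try:
            _, s, vt = np.linalg.svd(white / np.sqrt(T - 1), full_matrices=False)
        except np.linalg.LinAlgError:
            return
        var = s**2
        keep = np.where(var > var_threshold)[0][:max_rank]
        if keep.size:
            self.V = vt[keep].T
            self.lam = var[keep] - 1.0

    def _draw_momentum(self):
        u = self.rng.standard_normal(self.model.n_dim)
        if self.lam.size:
            scale = 1.0 - 1.0 / np.sqrt(1.0 + self.lam)
            u = u - self.V @ (scale * (self.V.T @ u))
        return self._solve_LT(u)

    # -- hamiltonian pieces -------------------------------------------------

    def _leapfrog(self, leaf: _Leaf, eps: float) -> _Leaf:
        with np.errstate(over="ignore", invalid="ignore"):
            r = leaf.r + 0.5 * eps * leaf.grad
            z = leaf.z + eps * self.velocity(r)
            lp, grad = self.model.logp_grad(z)
            r = r + 0.5 * eps * grad
            v = self.velocity(r)
            kin = 0.5 * float(np.dot(r, v))
            H = lp - kin if np.isfinite(lp) and np.isfinite(kin) else -np.inf
        return _Leaf(z=z, r=r, v=v, grad=grad, lp=lp, H=H)

    def _uturn(self, minus: _Leaf, plus: _Leaf) -> bool:
        dz = plus.z - minus.z
        return (
            float(np.dot(dz, minus.v)) < 0.0 or float(np.dot(dz, plus.v)) < 0.0
        )

    # -- tree building ------------------------------------------------------

    def _build_tree(self, leaf: _Leaf, depth: int, direction: int, eps: float,
                    H0: float) -> _Tree:
        if depth == 0:
            new = self._leapfrog(leaf, direction * eps)
            dH = new.H - H0
            divergent = not np.isfinite(new.H) or (H0 - new.H) > _DIVERGENCE_ENERGY
            logw = -np.inf if divergent else dH
            alpha = 0.0 if divergent else min(1.0, float(np.exp(min(dH, 0.0))))
            return _Tree(
                minus=new, plus=new, proposal=new, logw=logw,
                sum_alpha=alpha, n_alpha=1, n_leapfrog=1,
                divergent=divergent, turning=False,
            )
        first = self._build_tree(leaf, depth - 1, direction, eps, H0)
        if first.divergent or first.turning:
            return first
        start = first.plus if direction == 1 else first.minus
        second = self._build_tree(start, depth - 1, direction, eps, H0)
        logw = np.logaddexp(first.logw, second.logw)
        proposal = first.proposal
        if np.isfinite(second.logw):
            if np.log(self.rng.uniform()) < second.logw - logw:
                proposal = second.proposal
        minus = first.minus if direction == 1 else second.minus
        plus = second.plus if direction == 1 else first.plus
        turning = second.turning or self._uturn(minus, plus)
        return _Tree(
            minus=minus, plus=plus, proposal=proposal, logw=logw,
            sum_alpha=first.sum_alpha + second.sum_alpha,
            n_alpha=first.n_alpha + second.n_alpha,
            n_leapfrog=first.n_leapfrog + second.n_leapfrog,
            divergent=second.divergent, turning=turning,
        )

    def step(self, leaf: _Leaf, eps: float):
        """One NUTS transition from ``leaf``; returns (new_leaf, stats_dict)."""
        r0 = self._draw_momentum()
        v0 = self.velocity(r0)
        H0 = leaf.lp - 0.5 * float(np.dot(r0, v0))
        state = _Leaf(z=leaf.z, r=r0, v=v0, grad=leaf.grad, lp=leaf.lp, H=H0)
        minus = plus = state
        proposal = state
        logw = 0.0  # weight of the initial point relative to exp(H0)
        sum_alpha = 0.0
        n_alpha = 0
        n_leapfrog = 0
        divergent = False
        depth = 0
        while depth < self.max_depth:
            direction = 1 if self.rng.uniform() < 0.5 else -1
            sub = self._build_tree(
                plus if direction == 1 else minus, depth, direction, eps, H0
            )
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            n_leapfrog += sub.n_leapfrog
            if sub.divergent:
                divergent = True
                break
            if direction == 1:
                plus = sub.plus
            else:
                minus = sub.minus
            if not sub.turning and np.isfinite(sub.logw):
                # biased progressive sampling: favour the fresh subtree
                if np.log(self.rng.uniform()) < sub.logw - logw:
                    proposal = sub.proposal
                logw = np.logaddexp(logw, sub.logw)
            if sub.turning or self._uturn(minus, plus):
                break
            depth += 1
        accept_stat = sum_alpha / max(n_alpha, 1)
        stats = {
            "lp": proposal.lp,
            "energy": -proposal.H,
            "acceptance_rate": accept_stat,
            "tree_depth": depth,
            "n_leapfrog": n_leapfrog,
            "diverging": divergent,
        }
        return proposal, stats

    # -- adaptation ---------------------------------------------------------

    def find_initial_step(self, leaf: _Leaf) -> float:
        eps = 1.0
        r0 = self._draw_momentum()
        v0 = self.velocity(r0)
        H0 = leaf.lp - 0.5 * float(np.dot(r0, v0))
        probe = _Leaf(z=leaf.z, r=r0, v=v0, grad=leaf.grad, lp=leaf.lp, H=H0)
        new = self._leapfrog(probe, eps)
        dH = new.H - H0 if np.isfinite(new.H) else -np.inf
        direction = 1.0 if dH > np.log(0.5) else -1.0
        for _ in range(60):
            eps *= 2.0**direction
            new = self._leapfrog(probe, eps)
            dH = new.H - H0 if np.isfinite(new.H) else -np.inf
            if direction * dH <= direction * np.log(0.5):
                break
            if eps > 1e7 or eps < 1e-10:
                break
        return eps


def _window_schedule(tune: int, init_buffer=75, term_buffer=50, base_window=25):
    """Stan-style warmup schedule: returns the set of iterations that close a
    mass-matrix window and the first iteration of slow adaptation."""
    if tune < 20:
        return set(), tune  # step-size-only warmup
    if init_buffer + term_buffer + base_window > tune:
        init_buffer = int(0.15 * tune)
        term_buffer = int(0.10 * tune)
        base_window = tune - init_buffer - term_buffer
    ends = []
    pos = init_buffer
    w = base_window
    while pos + w < tune - term_buffer:
        if pos + w + 2 * w >= tune - term_buffer:
            ends.append(tune - term_buffer - 1)
            pos = tune - term_buffer
            break
        ends.append(pos + w - 1)
        pos += w
        w *= 2
    if pos < tune - term_buffer:
        ends.append(tune - term_buffer - 1)
    return set(ends), init_buffer


@dataclass
class _DualAveraging:
    mu: float
    target: float
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75
    m: int = 0
    h_bar: float = 0.0
    log_eps_bar: float = 0.0

    @classmethod
    def start(cls, eps: float, target: float) -> "_DualAveraging":
        return cls(mu=float(np.log(10.0 * eps)), target=target)

    def update(self, alpha: float) -> float:
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - alpha)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        eta = self.m**-self.kappa
        self.log_eps_bar = eta * log_eps + (1.0 - eta) * self.log_eps_bar
        return float(np.exp(log_eps))

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


class _Welford:
    """Running mean/variance, plus dense covariance for batched blocks."""

    def __init__(self, n_dim, groups=()):
        self.count = 0
        self.mean = np.zeros(n_dim)
        self.m2 = np.zeros(n_dim)
        self.group_idx = [g.idx for g in groups]
        self.m2_blocks = [np.zeros((*idx.shape, idx.shape[1])) for idx in self.group_idx]
        self.store: list[np.ndarray] = []

    def add(self, z):
        self.count += 1
        delta = z - self.mean
        self.mean += delta / self.count
        delta2 = z - self.mean
        self.m2 += delta * delta2
        for idx, m2b in zip(self.group_idx, self.m2_blocks):
            m2b += np.einsum("mi,mj->mij", delta[idx], delta2[idx])
        self.store.append(z.copy())

    def variance(self):
        if self.count < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.count - 1)
        n = self.count
        # Stan's shrinkage toward unit scale for stability in short windows
        return var * (n / (n + 5.0)) + 1e-3 * (5.0 / (n + 5.0))

    def covariance_blocks(self):
        out = []
        n = self.count
        for idx, m2b in zip(self.group_idx, self.m2_blocks):
            k = idx.shape[1]
            if n < k + 3:
                out.append(None)
                continue
            cov = m2b / (n - 1)
            shrunk = cov * (n / (n + 5.0))
            jj = np.arange(k)
            shrunk[:, jj, jj] += 1e-3 * (5.0 / (n + 5.0))
            out.append(shrunk)
        return out


def _run_chain(model, seed_seq, draws, tune, target_accept, max_treedepth,
               init_jitter, low_rank_max, low_rank_threshold):
    rng = np.random.default_rng(seed_seq)
    chain = _Chain(model, rng, target_accept, max_treedepth,
                   low_rank_max, low_rank_threshold)

    leaf = None
    for _ in range(100):
        z0 = model.initial_point(rng, init_jitter)
        lp, grad = model.logp_grad(z0)
        if np.isfinite(lp):
            leaf = _Leaf(
                z=z0, r=np.zeros_like(z0), v=np.zeros_like(z0), grad=grad,
                lp=lp, H=lp,
            )
            break
    if leaf is None:
        raise RuntimeError("could not find a finite initial log density")

    eps = chain.find_initial_step(leaf)
    da = _DualAveraging.start(eps, target_accept)
    window_ends, slow_start = _window_schedule(tune)
    welford = _Welford(model.n_dim, chain.groups)

    for it in range(tune):
        leaf, stats = chain.step(leaf, eps)
        eps = da.update(stats["acceptance_rate"])
        if it >= slow_start:
            welford.add(leaf.z)
        if it in window_ends:
            chain.set_mass(
                welford.variance(),
                welford.covariance_blocks(),
                welford.store,
                welford.mean,
            )
            welford = _Welford(model.n_dim, chain.groups)
            eps = da.adapted
            da = _DualAveraging.start(eps, target_accept)
    if tune > 0:
        eps = da.adapted

    Z = np.empty((draws, model.n_dim))
    rec = {
        "lp": np.empty(draws),
        "energy": np.empty(draws),
        "acceptance_rate": np.empty(draws),
        "tree_depth": np.empty(draws, dtype=np.int64),
        "n_leapfrog": np.empty(draws, dtype=np.int64),
        "diverging": np.empty(draws, dtype=bool),
    }
    for it in range(draws):
        leaf, stats = chain.step(leaf, eps)
        Z[it] = leaf.z
        for k in rec:
            rec[k][it] = stats[k]
    stats_out = NutsStats(
        lp=rec["lp"],
        energy=rec["energy"],
        acceptance_rate=rec["acceptance_rate"],
        tree_depth=rec["tree_depth"],
        n_leapfrog=rec["n_leapfrog"],
        diverging=rec["diverging"],
        step_size=eps,
        inv_mass=chain.inv_diag.copy(),
    )
    return Z, stats_out


def sample_nuts(
    model,
    *,
    draws: int = 1000,
    tune: int = 1000,
    chains: int = 4,
    target_accept: float = 0.8,
    seed: int = 0,
    max_treedepth: int = 10,
    init_jitter: float = 0.3,
    low_rank_max: int = 4,
    low_rank_threshold: float = 5.0,
) -> tuple[np.ndarray, list[NutsStats]]:
    """Sample ``chains`` independent NUTS chains.

    Returns unconstrained draws of shape (chains, draws, n_dim) and the
    per-chain statistics. Fully deterministic for a fixed seed.
    """
    if draws < 1 or tune < 0 or chains < 1:
        raise ValueError("draws, tune and chains must be positive")
    if not (0.0 < target_accept < 1.0):
        raise ValueError("target_accept must lie in (0, 1)")
    seqs = np.random.SeedSequence(seed).spawn(chains)
    Z = np.empty((chains, draws, model.n_dim))
    all_stats = []
    for c in range(chains):
        Zc, st = _run_chain(
            model, seqs[c], draws, tune, target_accept, max_treedepth,
            init_jitter, low_rank_max, low_rank_threshold,
        )
        Z[c] = Zc
        all_stats.append(st)
    return Z, all_stats
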