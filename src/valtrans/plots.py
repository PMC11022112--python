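"""Basic diagnostic graphics: fitted-curve overlays and posterior densities."""

from __future__ import annotations

import numpy as np

from valtrans.model import five_pl

__all__ = ["plot_curve_overlay", "plot_posterior_density"]


def plot_curve_overlay(draws, ratings, norms, n_curves: int = 30, ax=None):
    """Scatter the ratings against norm valence and overlay posterior curves.

    Draws ``n_curves`` group-mean 5-PL curves from the posterior of the
    group-level parameters (participant-population means approximated by
    the hypermeans) over the pooled rating scatter.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    merged = ratings.merge(norms[["image_id", "valence_mean"]], on="image_id")
    ax.scatter(
        merged["valence_mean"], merged["rating"], s=4, alpha=0.15, color="gray",
        label="ratings",
    )
    xs = np.linspace(merged["valence_mean"].min(), merged["valence_mean"].max(), 200)
    post = draws.idata.posterior
    a_mean = float(post["a"].mean()) if "a" in post else 0.1
    n_total = post["mu_b"].size
    pick = np.linspace(0, n_total - 1, n_curves, dtype=int)
    for k, name in enumerate(("mu_b", "mu_c", "mu_d", "mu_g")):
        if name not in post:
            raise ValueError("curve overlay needs a 5-PL family fit")
    mb = post["mu_b"].values.ravel()[pick]
    mc = post["mu_c"].values.ravel()[pick]
    md = np.clip(post["d"].mean(dim="participant").values.ravel()[pick], 0.5, None)
    mg = np.clip(post["g"].mean(dim="participant").values.ravel()[pick], 0.8, None)
    for b, c, d, g in zip(mb, mc, md, mg):
        ax.plot(xs, five_pl(xs, a_mean, b, np.clip(c, 0.51, 4.99), d, g),
                color="C1", alpha=0.2, lw=1)
    ax.set_xlabel("normative valence (1-9)")
    ax.set_ylabel("VAS rating")
    return ax


def plot_posterior_density(draws, param: str, ax=None, **kwargs):
    """Kernel-density plot of one parameter's pooled posterior draws."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots()
    samples = np.asarray(draws.stacked(param)).ravel()
    grid = np.linspace(samples.min(), samples.max(), 400)
    ax.plot(grid, gaussian_kde(samples)(grid), **kwargs)
    ax.set_xlabel(param)
    ax.set_ylabel("posterior density")
    return ax
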