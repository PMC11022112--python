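"""Numba-compiled log-posterior kernels.

The NUTS sampler evaluates the unconstrained log posterior and gradient
hundreds of times per transition, so the full computation for the 5-PL
family — transforms, hierarchical priors, Gaussian likelihood, Jacobians —
runs as a single compiled pass. A pure numpy/scipy reference implementation
of the same density lives in :mod:`valtrans.model`; the two are asserted
equal in the test suite.

Special functions are implemented numba-side: ``lgamma``/``erfc`` come from
``math``, the digamma function uses the standard recurrence plus asymptotic
series, and the normal log-CDF switches to its tail expansion for very
negative arguments.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["fivepl_logp_grad", "linear_logp_grad", "PriorPack", "pack_fivepl_priors",
           "pack_linear_priors"]

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _digamma(x):
    acc = 0.0
    while x < 12.0:
        acc -= 1.0 / x
        x += 1.0
    inv = 1.0 / x
    inv2 = inv * inv
    return acc + math.log(x) - 0.5 * inv - inv2 * (
        1.0 / 12.0 - inv2 * (1.0 / 120.0 - inv2 / 252.0)
    )


@njit(cache=True)
def _log_phi(t):
    return -0.5 * t * t - 0.5 * _LOG2PI


@njit(cache=True)
def _log_ndtr(t):
    if t > 6.0:
        return -0.5 * math.erfc(t / _SQRT2)
    if t < -8.0:
        t2 = t * t
        return _log_phi(t) - math.log(-t) + math.log1p(-1.0 / t2 + 3.0 / (t2 * t2))
    return math.log(0.5 * math.erfc(-t / _SQRT2))


@njit(cache=True)
def _mills(t):
    """phi(t) / Phi(t)."""
    return math.exp(_log_phi(t) - _log_ndtr(t))


@njit(cache=True)
def _ndtr(t):
    return 0.5 * math.erfc(-t / _SQRT2)


@njit(cache=True)
def _phi_f(t):
    return math.exp(-0.5 * t * t) / math.sqrt(2.0 * math.pi)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard-normal CDF (Wichura's AS 241, double precision)."""
    q = p - 0.5
    if abs(q) <= 0.425:
        r = 0.180625 - q * q
        num = (((((((2.5090809287301226727e3 * r + 3.3430575583588128105e4) * r
            + 6.7265770927008700853e4) * r + 4.5921953931549871457e4) * r
            + 1.3731693765509461125e4) * r + 1.9715909503065514427e3) * r
            + 1.3314166789178437745e2) * r + 3.3871328727963666080e0)
        den = (((((((5.2264952788528545610e3 * r + 2.8729085735721942674e4) * r
            + 3.9307895800092710610e4) * r + 2.1213794301586595867e4) * r
            + 5.3941960214247511077e3) * r + 6.8718700749205790830e2) * r
            + 4.2313330701600911252e1) * r + 1.0)
        return q * num / den
    r = p if q < 0.0 else 1.0 - p
    if r <= 0.0:
        return -np.inf if q < 0.0 else np.inf
    r = math.sqrt(-math.log(r))
    if r <= 5.0:
        r = r - 1.6
        num = (((((((7.74545014278341407640e-4 * r + 2.27238449892691845833e-2) * r
            + 2.41780725177450611770e-1) * r + 1.27045825245236838258e0) * r
            + 3.64784832476320460504e0) * r + 5.76949722146069140550e0) * r
            + 4.63033784615654529590e0) * r + 1.42343711074968357734e0)
        den = (((((((1.05075007164441684324e-9 * r + 5.47593808499534494600e-4) * r
            + 1.51986665636164571966e-2) * r + 1.48103976427480074590e-1) * r
            + 6.89767334985100004550e-1) * r + 1.67638483018380384940e0) * r
            + 2.05319162663775882187e0) * r + 1.0)
    else:
        r = r - 5.0
        num = (((((((2.01033439929228813265e-7 * r + 2.71155556874348757815e-5) * r
            + 1.24266094738807843860e-3) * r + 2.65321895265761230930e-2) * r
            + 2.96560571828504891230e-1) * r + 1.78482653991729133580e0) * r
            + 5.46378491116411436990e0) * r + 6.65790464350110377720e0)
        den = (((((((2.04426310338993978564e-15 * r + 1.42151175831644588870e-7) * r
            + 1.84631831751005468180e-5) * r + 7.86869131145613259100e-4) * r
            + 1.48753612908506148525e-2) * r + 1.36929880922735805310e-1) * r
            + 5.99832206555887937690e-1) * r + 1.0)
    val = num / den
    return -val if q < 0.0 else val


@njit(cache=True)
def _tn_quantile(zraw, mu, sd, lo, hi, has_hi):
    """Map a standard-normal variate onto TruncNormal(mu, sd, lo, hi).

    Returns (value, d value/d zraw, d value/d mu, d value/d sd).
    """
    u = _ndtr(zraw)
    alpha = (lo - mu) / sd
    p_lo = _ndtr(alpha)
    if has_hi:
        beta = (hi - mu) / sd
        p_hi = _ndtr(beta)
        phi_beta = _phi_f(beta)
    else:
        beta = 0.0
        p_hi = 1.0
        phi_beta = 0.0
    span = p_hi - p_lo
    t = p_lo + u * span
    if t < 1e-15:
        t = 1e-15
    elif t > 1.0 - 1e-15:
        t = 1.0 - 1e-15
    q = _ndtri(t)
    val = mu + sd * q
    phi_q = _phi_f(q)
    phi_alpha = _phi_f(alpha)
    d_z = sd * _phi_f(zraw) * span / phi_q
    d_mu = 1.0 - ((1.0 - u) * phi_alpha + u * phi_beta) / phi_q
    d_sd = q - (alpha * phi_alpha * (1.0 - u) + beta * phi_beta * u) / phi_q
    return val, d_z, d_mu, d_sd


@njit(cache=True)
def fivepl_logp_grad(z, logx, y, idx, P, n_coeffs, est_sd, nz, azv, pr):
    """Log posterior and gradient of the hierarchical 5-PL family.

    ``pr`` packs the prior constants (see :func:`pack_fivepl_priors`);
    ``n_coeffs`` selects the EN / age / interaction extension; ``est_sd``
    switches the participant slope SD from fixed to estimated.
    Returns ``(lp, grad)``; non-finite densities return ``(-inf, 0)``.
    """
    n_dim = z.shape[0]
    grad = np.zeros(n_dim)
    n = y.shape[0]

    (a1_mu, a1_sd, a1_lo, a2_mu, a2_sd,
     mb_mu, mb_sd, mb_lo, mc_mu, mc_sd, mc_lo,
     md_mu, md_sd, md_lo, mg_mu, mg_sd, mg_lo,
     b_sd, b_lo, c_sd, c_lo, c_hi, d_sd, d_lo, g_sd, g_lo,
     sig_sd, ssd_sd, en_mu, en_sd, age_mu, age_sd, int_mu, int_sd) = (
        pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], pr[6], pr[7], pr[8], pr[9],
        pr[10], pr[11], pr[12], pr[13], pr[14], pr[15], pr[16], pr[17], pr[18],
        pr[19], pr[20], pr[21], pr[22], pr[23], pr[24], pr[25], pr[26], pr[27],
        pr[28], pr[29], pr[30], pr[31], pr[32], pr[33])

    # ---- group-level transforms ----
    alpha1 = a1_lo + math.exp(z[0])
    alpha2 = z[1]
    mu_b = mb_lo + math.exp(z[2])
    mu_c = mc_lo + math.exp(z[3])
    mu_d = md_lo + math.exp(z[4])
    mu_g = mg_lo + math.exp(z[5])
    if not math.isfinite(alpha2) or alpha2 <= 0.0:
        return -np.inf, grad

    i_sigma = 6 + 5 * P
    sigma = math.exp(z[i_sigma])
    i_coef = i_sigma + 1
    sd_b = b_sd
    if est_sd == 1:
        sd_b = math.exp(z[i_coef + n_coeffs])
    if not (1e-150 < sigma < 1e150) or not (1e-150 < sd_b < 1e150):
        return -np.inf, grad

    lp = 0.0
    # Jacobians of the scalar transforms
    lp += z[0] + z[2] + z[3] + z[4] + z[5] + z[i_sigma]
    grad[0] += 1.0
    grad[2] += 1.0
    grad[3] += 1.0
    grad[4] += 1.0
    grad[5] += 1.0
    grad[i_sigma] += 1.0
    if est_sd == 1:
        lp += z[i_coef + n_coeffs]
        grad[i_coef + n_coeffs] += 1.0

    # group-level hyperpriors (normalizers constant)
    lp += -0.5 * ((alpha1 - a1_mu) / a1_sd) ** 2
    lp += -0.5 * ((alpha2 - a2_mu) / a2_sd) ** 2
    lp += -0.5 * ((mu_b - mb_mu) / mb_sd) ** 2
    lp += -0.5 * ((mu_c - mc_mu) / mc_sd) ** 2
    lp += -0.5 * ((mu_d - md_mu) / md_sd) ** 2
    lp += -0.5 * ((mu_g - mg_mu) / mg_sd) ** 2
    gA1 = -(alpha1 - a1_mu) / (a1_sd * a1_sd)
    gA2 = -(alpha2 - a2_mu) / (a2_sd * a2_sd)
    gMb = -(mu_b - mb_mu) / (mb_sd * mb_sd)
    gMc = -(mu_c - mc_mu) / (mc_sd * mc_sd)
    gMd = -(mu_d - md_mu) / (md_sd * md_sd)
    gMg = -(mu_g - mg_mu) / (mg_sd * mg_sd)

    # ---- participant-level transforms, priors, Jacobians ----
    a = np.empty(P)
    b = np.empty(P)
    c = np.empty(P)
    d = np.empty(P)
    g = np.empty(P)
    B = np.empty(P)
    ga = np.zeros(P)
    gb = np.zeros(P)
    gc = np.zeros(P)
    gd = np.zeros(P)
    gg = np.zeros(P)

    sum_log_a = 0.0
    sum_log_1ma = 0.0
    lb = math.lgamma(alpha1) + math.lgamma(alpha2) - math.lgamma(alpha1 + alpha2)
    dig_sum = _digamma(alpha1 + alpha2)
    dig_a1 = _digamma(alpha1)
    dig_a2 = _digamma(alpha2)

    tau_b = (mu_b - b_lo) / sd_b
    log_z_b = _log_ndtr(tau_b)
    mills_b = _mills(tau_b)
    tau_d = (mu_d - d_lo) / d_sd
    log_z_d = _log_ndtr(tau_d)
    mills_d = _mills(tau_d)
    tau_g = (mu_g - g_lo) / g_sd
    log_z_g = _log_ndtr(tau_g)
    mills_g = _mills(tau_g)
    # two-sided truncation for c
    hi_t = (c_hi - mu_c) / c_sd
    lo_t = (c_lo - mu_c) / c_sd
    la = _log_ndtr(hi_t)
    lbnd = _log_ndtr(lo_t)
    diff = lbnd - la
    if diff > -1e-12:
        diff = -1e-12
    log_z_c = la + math.log1p(-math.exp(diff))
    dlog_z_c = (math.exp(_log_phi(lo_t) - log_z_c)
                - math.exp(_log_phi(hi_t) - log_z_c)) / c_sd

    g_sd_b = 0.0
    for i in range(P):
        ta = z[6 + i]
        tb = z[6 + P + i]
        tc = z[6 + 2 * P + i]
        td = z[6 + 3 * P + i]
        tg = z[6 + 4 * P + i]
        # a: logistic onto (0,1)
        if ta >= 0.0:
            e = math.exp(-ta)
            ai = 1.0 / (1.0 + e)
            l1ma = -ta - math.log1p(e)
            la_i = -math.log1p(e)
        else:
            e = math.exp(ta)
            ai = e / (1.0 + e)
            la_i = ta - math.log1p(e)
            l1ma = -math.log1p(e)
        a[i] = ai
        sum_log_a += la_i
        sum_log_1ma += l1ma
        lp += la_i + l1ma  # Jacobian
        grad[6 + i] += 1.0 - 2.0 * ai
        # beta-prior gradient in unconstrained space (division cancels
        # against the logistic Jacobian, so the boundary is safe)
        grad[6 + i] += (alpha1 - 1.0) * (1.0 - ai) - (alpha2 - 1.0) * ai

        # b: lower-bounded exp transform
        eb = math.exp(tb)
        bi = b_lo + eb
        b[i] = bi
        lp += tb
        grad[6 + P + i] += 1.0
        rb = (bi - mu_b) / sd_b
        lp += -0.5 * rb * rb - math.log(sd_b) - log_z_b
        gb[i] += -rb / sd_b
        gMb += rb / sd_b - mills_b / sd_b
        if est_sd == 1:
            g_sd_b += rb * rb / sd_b - 1.0 / sd_b + mills_b * tau_b / sd_b

        # c: scaled logistic onto (c_lo, c_hi)
        if tc >= 0.0:
            e = math.exp(-tc)
            sc = 1.0 / (1.0 + e)
            lsc = -math.log1p(e)
            l1msc = -tc - math.log1p(e)
        else:
            e = math.exp(tc)
            sc = e / (1.0 + e)
            lsc = tc - math.log1p(e)
            l1msc = -math.log1p(e)
        ci = c_lo + (c_hi - c_lo) * sc
        c[i] = ci
        lp += lsc + l1msc + math.log(c_hi - c_lo)
        grad[6 + 2 * P + i] += 1.0 - 2.0 * sc
        rc = (ci - mu_c) / c_sd
        lp += -0.5 * rc * rc - log_z_c
        gc[i] += -rc / c_sd
        gMc += rc / c_sd - dlog_z_c

        # d, g: lower-bounded exp transforms
        ed = math.exp(td)
        di = d_lo + ed
        d[i] = di
        lp += td
        grad[6 + 3 * P + i] += 1.0
        rd = (di - mu_d) / d_sd
        lp += -0.5 * rd * rd - log_z_d
        gd[i] += -rd / d_sd
        gMd += rd / d_sd - mills_d / d_sd

        eg = math.exp(tg)
        gi = g_lo + eg
        g[i] = gi
        lp += tg
        grad[6 + 4 * P + i] += 1.0
        rg = (gi - mu_g) / g_sd
        lp += -0.5 * rg * rg - log_z_g
        gg[i] += -rg / g_sd
        gMg += rg / g_sd - mills_g / g_sd

    lp += (alpha1 - 1.0) * sum_log_a + (alpha2 - 1.0) * sum_log_1ma - P * lb
    gA1 += sum_log_a - P * (dig_a1 - dig_sum)
    gA2 += sum_log_1ma - P * (dig_a2 - dig_sum)

    # covariate coefficients
    en = 0.0
    age = 0.0
    inter = 0.0
    g_en = 0.0
    g_age = 0.0
    g_int = 0.0
    if n_coeffs >= 1:
        en = z[i_coef]
        lp += -0.5 * ((en - en_mu) / en_sd) ** 2
        g_en += -(en - en_mu) / (en_sd * en_sd)
    if n_coeffs >= 2:
        age = z[i_coef + 1]
        lp += -0.5 * ((age - age_mu) / age_sd) ** 2
        g_age += -(age - age_mu) / (age_sd * age_sd)
    if n_coeffs >= 3:
        inter = z[i_coef + 2]
        lp += -0.5 * ((inter - int_mu) / int_sd) ** 2
        g_int += -(inter - int_mu) / (int_sd * int_sd)
    for i in range(P):
        B[i] = b[i]
        if n_coeffs >= 1:
            B[i] += en * nz[i]
        if n_coeffs >= 2:
            B[i] += age * azv[i]
        if n_coeffs >= 3:
            B[i] += inter * nz[i] * azv[i]

    if est_sd == 1:
        lp += -0.5 * (sd_b / ssd_sd) ** 2
        g_sd_b += -sd_b / (ssd_sd * ssd_sd)

    # sigma prior
    lp += -0.5 * (sigma / sig_sd) ** 2
    g_sigma = -sigma / (sig_sd * sig_sd)

    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)

    # ---- likelihood ----
    inv_s2 = 1.0 / (sigma * sigma)
    ss = 0.0
    logc = np.log(c)
    gB = np.zeros(P)
    for k in range(n):
        p = idx[k]
        dx = logx[k] - logc[p]
        w = B[p] * dx
        if w > 0.0:
            e = math.exp(-w)
            log1pu = w + math.log1p(e)
            sig_w = 1.0 / (1.0 + e)
        else:
            e = math.exp(w)
            log1pu = math.log1p(e)
            sig_w = e / (1.0 + e)
        h = math.exp(-g[p] * log1pu)
        amd = a[p] - d[p]
        r = y[k] - (d[p] + amd * h)
        ss += r * r
        dll = r * inv_s2
        e1 = sig_w * h
        ga[p] += dll * h
        gd[p] += dll * (1.0 - h)
        gB[p] += dll * (-amd * g[p] * e1 * dx)
        gc[p] += dll * (amd * g[p] * e1 * B[p] / c[p])
        gg[p] += dll * (-amd * h * log1pu)

    lp += -0.5 * inv_s2 * ss - n * math.log(sigma)
    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)
    g_sigma += inv_s2 / sigma * ss - n / sigma

    # slope gradient feeds b and the covariate coefficients
    for i in range(P):
        gb[i] += gB[i]
        if n_coeffs >= 1:
            g_en += gB[i] * nz[i]
        if n_coeffs >= 2:
            g_age += gB[i] * azv[i]
        if n_coeffs >= 3:
            g_int += gB[i] * nz[i] * azv[i]

    # ---- chain rule to unconstrained space ----
    grad[0] += gA1 * (alpha1 - a1_lo)
    grad[1] += gA2
    grad[2] += gMb * (mu_b - mb_lo)
    grad[3] += gMc * (mu_c - mc_lo)
    grad[4] += gMd * (mu_d - md_lo)
    grad[5] += gMg * (mu_g - mg_lo)
    for i in range(P):
        ai = a[i]
        grad[6 + i] += ga[i] * ai * (1.0 - ai)
        grad[6 + P + i] += gb[i] * (b[i] - b_lo)
        sc = (c[i] - c_lo) / (c_hi - c_lo)
        grad[6 + 2 * P + i] += gc[i] * (c_hi - c_lo) * sc * (1.0 - sc)
        grad[6 + 3 * P + i] += gd[i] * (d[i] - d_lo)
        grad[6 + 4 * P + i] += gg[i] * (g[i] - g_lo)
    grad[i_sigma] += g_sigma * sigma
    if n_coeffs >= 1:
        grad[i_coef] += g_en
    if n_coeffs >= 2:
        grad[i_coef + 1] += g_age
    if n_coeffs >= 3:
        grad[i_coef + 2] += g_int
    if est_sd == 1:
        grad[i_coef + n_coeffs] += g_sd_b * sd_b

    for j in range(n_dim):
        if not math.isfinite(grad[j]):
            return -np.inf, np.zeros(n_dim)
    return lp, grad


@njit(cache=True)
def fivepl_logp_grad_nc(z, logx, y, idx, P, n_coeffs, est_sd, nz, azv, pr):
    """Non-centered variant: participant-level b, c, d, g slots hold raw
    standard-normal variates mapped through the truncated-normal quantile
    given the group means, so the hypermeans decouple from the participants'
    prior-dominated ridge directions. Same posterior as the centered form.
    """
    n_dim = z.shape[0]
    grad = np.zeros(n_dim)
    n = y.shape[0]

    (a1_mu, a1_sd, a1_lo, a2_mu, a2_sd,
     mb_mu, mb_sd, mb_lo, mc_mu, mc_sd, mc_lo,
     md_mu, md_sd, md_lo, mg_mu, mg_sd, mg_lo,
     b_sd, b_lo, c_sd, c_lo, c_hi, d_sd, d_lo, g_sd, g_lo,
     sig_sd, ssd_sd, en_mu, en_sd, age_mu, age_sd, int_mu, int_sd) = (
        pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], pr[6], pr[7], pr[8], pr[9],
        pr[10], pr[11], pr[12], pr[13], pr[14], pr[15], pr[16], pr[17], pr[18],
        pr[19], pr[20], pr[21], pr[22], pr[23], pr[24], pr[25], pr[26], pr[27],
        pr[28], pr[29], pr[30], pr[31], pr[32], pr[33])

    alpha1 = a1_lo + math.exp(z[0])
    alpha2 = z[1]
    mu_b = mb_lo + math.exp(z[2])
    mu_c = mc_lo + math.exp(z[3])
    mu_d = md_lo + math.exp(z[4])
    mu_g = mg_lo + math.exp(z[5])
    if not math.isfinite(alpha2) or alpha2 <= 0.0:
        return -np.inf, grad

    i_sigma = 6 + 5 * P
    sigma = math.exp(z[i_sigma])
    i_coef = i_sigma + 1
    sd_b = b_sd
    if est_sd == 1:
        sd_b = math.exp(z[i_coef + n_coeffs])
    if not (1e-150 < sigma < 1e150) or not (1e-150 < sd_b < 1e150):
        return -np.inf, grad

    lp = z[0] + z[2] + z[3] + z[4] + z[5] + z[i_sigma]
    grad[0] += 1.0
    grad[2] += 1.0
    grad[3] += 1.0
    grad[4] += 1.0
    grad[5] += 1.0
    grad[i_sigma] += 1.0
    if est_sd == 1:
        lp += z[i_coef + n_coeffs]
        grad[i_coef + n_coeffs] += 1.0

    lp += -0.5 * ((alpha1 - a1_mu) / a1_sd) ** 2
    lp += -0.5 * ((alpha2 - a2_mu) / a2_sd) ** 2
    lp += -0.5 * ((mu_b - mb_mu) / mb_sd) ** 2
    lp += -0.5 * ((mu_c - mc_mu) / mc_sd) ** 2
    lp += -0.5 * ((mu_d - md_mu) / md_sd) ** 2
    lp += -0.5 * ((mu_g - mg_mu) / mg_sd) ** 2
    gA1 = -(alpha1 - a1_mu) / (a1_sd * a1_sd)
    gA2 = -(alpha2 - a2_mu) / (a2_sd * a2_sd)
    gMb = -(mu_b - mb_mu) / (mb_sd * mb_sd)
    gMc = -(mu_c - mc_mu) / (mc_sd * mc_sd)
    gMd = -(mu_d - md_mu) / (md_sd * md_sd)
    gMg = -(mu_g - mg_mu) / (mg_sd * mg_sd)

    a = np.empty(P)
    b = np.empty(P)
    c = np.empty(P)
    d = np.empty(P)
    g = np.empty(P)
    B = np.empty(P)
    # quantile-transform derivatives per participant
    db_dz = np.empty(P)
    db_dmu = np.empty(P)
    db_dsd = np.empty(P)
    dc_dz = np.empty(P)
    dc_dmu = np.empty(P)
    dd_dz = np.empty(P)
    dd_dmu = np.empty(P)
    dg_dz = np.empty(P)
    dg_dmu = np.empty(P)
    ga = np.zeros(P)

    sum_log_a = 0.0
    sum_log_1ma = 0.0
    lb = math.lgamma(alpha1) + math.lgamma(alpha2) - math.lgamma(alpha1 + alpha2)
    dig_sum = _digamma(alpha1 + alpha2)
    dig_a1 = _digamma(alpha1)
    dig_a2 = _digamma(alpha2)

    for i in range(P):
        ta = z[6 + i]
        if ta >= 0.0:
            e = math.exp(-ta)
            ai = 1.0 / (1.0 + e)
            l1ma = -ta - math.log1p(e)
            la_i = -math.log1p(e)
        else:
            e = math.exp(ta)
            ai = e / (1.0 + e)
            la_i = ta - math.log1p(e)
            l1ma = -math.log1p(e)
        a[i] = ai
        sum_log_a += la_i
        sum_log_1ma += l1ma
        lp += la_i + l1ma
        grad[6 + i] += 1.0 - 2.0 * ai
        grad[6 + i] += (alpha1 - 1.0) * (1.0 - ai) - (alpha2 - 1.0) * ai

        zb = z[6 + P + i]
        zc = z[6 + 2 * P + i]
        zd = z[6 + 3 * P + i]
        zg = z[6 + 4 * P + i]
        lp += -0.5 * (zb * zb + zc * zc + zd * zd + zg * zg)
        grad[6 + P + i] += -zb
        grad[6 + 2 * P + i] += -zc
        grad[6 + 3 * P + i] += -zd
        grad[6 + 4 * P + i] += -zg
        b[i], db_dz[i], db_dmu[i], db_dsd[i] = _tn_quantile(
            zb, mu_b, sd_b, b_lo, 0.0, False
        )
        c[i], dc_dz[i], dc_dmu[i], _ = _tn_quantile(zc, mu_c, c_sd, c_lo, c_hi, True)
        d[i], dd_dz[i], dd_dmu[i], _ = _tn_quantile(zd, mu_d, d_sd, d_lo, 0.0, False)
        g[i], dg_dz[i], dg_dmu[i], _ = _tn_quantile(zg, mu_g, g_sd, g_lo, 0.0, False)

    lp += (alpha1 - 1.0) * sum_log_a + (alpha2 - 1.0) * sum_log_1ma - P * lb
    gA1 += sum_log_a - P * (dig_a1 - dig_sum)
    gA2 += sum_log_1ma - P * (dig_a2 - dig_sum)

    en = 0.0
    age = 0.0
    inter = 0.0
    g_en = 0.0
    g_age = 0.0
    g_int = 0.0
    if n_coeffs >= 1:
        en = z[i_coef]
        lp += -0.5 * ((en - en_mu) / en_sd) ** 2
        g_en += -(en - en_mu) / (en_sd * en_sd)
    if n_coeffs >= 2:
        age = z[i_coef + 1]
        lp += -0.5 * ((age - age_mu) / age_sd) ** 2
        g_age += -(age - age_mu) / (age_sd * age_sd)
    if n_coeffs >= 3:
        inter = z[i_coef + 2]
        lp += -0.5 * ((inter - int_mu) / int_sd) ** 2
        g_int += -(inter - int_mu) / (int_sd * int_sd)
    for i in range(P):
        B[i] = b[i]
        if n_coeffs >= 1:
            B[i] += en * nz[i]
        if n_coeffs >= 2:
            B[i] += age * azv[i]
        if n_coeffs >= 3:
            B[i] += inter * nz[i] * azv[i]

    g_sd_b = 0.0
    if est_sd == 1:
        lp += -0.5 * (sd_b / ssd_sd) ** 2
        g_sd_b += -sd_b / (ssd_sd * ssd_sd)

    lp += -0.5 * (sigma / sig_sd) ** 2
    g_sigma = -sigma / (sig_sd * sig_sd)

    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)

    inv_s2 = 1.0 / (sigma * sigma)
    ss = 0.0
    logc = np.log(c)
    gB = np.zeros(P)
    gc = np.zeros(P)
    gd = np.zeros(P)
    gg = np.zeros(P)
    for k in range(n):
        p = idx[k]
        dx = logx[k] - logc[p]
        w = B[p] * dx
        if w > 0.0:
            e = math.exp(-w)
            log1pu = w + math.log1p(e)
            sig_w = 1.0 / (1.0 + e)
        else:
            e = math.exp(w)
            log1pu = math.log1p(e)
            sig_w = e / (1.0 + e)
        h = math.exp(-g[p] * log1pu)
        amd = a[p] - d[p]
        r = y[k] - (d[p] + amd * h)
        ss += r * r
        dll = r * inv_s2
        e1 = sig_w * h
        ga[p] += dll * h
        gd[p] += dll * (1.0 - h)
        gB[p] += dll * (-amd * g[p] * e1 * dx)
        gc[p] += dll * (amd * g[p] * e1 * B[p] / c[p])
        gg[p] += dll * (-amd * h * log1pu)

    lp += -0.5 * inv_s2 * ss - n * math.log(sigma)
    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)
    g_sigma += inv_s2 / sigma * ss - n / sigma

    for i in range(P):
        if n_coeffs >= 1:
            g_en += gB[i] * nz[i]
        if n_coeffs >= 2:
            g_age += gB[i] * azv[i]
        if n_coeffs >= 3:
            g_int += gB[i] * nz[i] * azv[i]
        # chain rule through the quantile transforms
        grad[6 + i] += ga[i] * a[i] * (1.0 - a[i])
        grad[6 + P + i] += gB[i] * db_dz[i]
        grad[6 + 2 * P + i] += gc[i] * dc_dz[i]
        grad[6 + 3 * P + i] += gd[i] * dd_dz[i]
        grad[6 + 4 * P + i] += gg[i] * dg_dz[i]
        gMb += gB[i] * db_dmu[i]
        gMc += gc[i] * dc_dmu[i]
        gMd += gd[i] * dd_dmu[i]
        gMg += gg[i] * dg_dmu[i]
        if est_sd == 1:
            g_sd_b += gB[i] * db_dsd[i]

    grad[0] += gA1 * (alpha1 - a1_lo)
    grad[1] += gA2
    grad[2] += gMb * (mu_b - mb_lo)
    grad[3] += gMc * (mu_c - mc_lo)
    grad[4] += gMd * (mu_d - md_lo)
    grad[5] += gMg * (mu_g - mg_lo)
    grad[i_sigma] += g_sigma * sigma
    if n_coeffs >= 1:
        grad[i_coef] += g_en
    if n_coeffs >= 2:
        grad[i_coef + 1] += g_age
    if n_coeffs >= 3:
        grad[i_coef + 2] += g_int
    if est_sd == 1:
        grad[i_coef + n_coeffs] += g_sd_b * sd_b

    for j in range(n_dim):
        if not math.isfinite(grad[j]):
            return -np.inf, np.zeros(n_dim)
    return lp, grad


@njit(cache=True)
def linear_logp_grad(z, x, y, idx, P, pr):
    """Log posterior and gradient of the hierarchical linear model."""
    n_dim = z.shape[0]
    grad = np.ones(n_dim)  # d log|J| / dt for pure exp transforms
    n = y.shape[0]
    (ma_mu, ma_sd, mb_mu, mb_sd, a_sd, b_sd, sig_sd) = (
        pr[0], pr[1], pr[2], pr[3], pr[4], pr[5], pr[6])

    mu_a = math.exp(z[0])
    mu_b = math.exp(z[1])
    i_sigma = 2 + 2 * P
    sigma = math.exp(z[i_sigma])
    if not (1e-150 < sigma < 1e150) or not math.isfinite(mu_a + mu_b):
        return -np.inf, grad

    lp = z[0] + z[1] + z[i_sigma]
    lp += -0.5 * ((mu_a - ma_mu) / ma_sd) ** 2 - 0.5 * ((mu_b - mb_mu) / mb_sd) ** 2
    g_mu_a = -(mu_a - ma_mu) / (ma_sd * ma_sd)
    g_mu_b = -(mu_b - mb_mu) / (mb_sd * mb_sd)

    log_z_a = _log_ndtr(mu_a / a_sd)
    mills_a = _mills(mu_a / a_sd)
    log_z_b = _log_ndtr(mu_b / b_sd)
    mills_b = _mills(mu_b / b_sd)

    a = np.empty(P)
    b = np.empty(P)
    ga = np.zeros(P)
    gb = np.zeros(P)
    for i in range(P):
        ta = z[2 + i]
        tb = z[2 + P + i]
        ai = math.exp(ta)
        bi = math.exp(tb)
        a[i] = ai
        b[i] = bi
        lp += ta + tb
        ra = (ai - mu_a) / a_sd
        rb = (bi - mu_b) / b_sd
        lp += -0.5 * ra * ra - log_z_a - 0.5 * rb * rb - log_z_b
        ga[i] += -ra / a_sd
        gb[i] += -rb / b_sd
        g_mu_a += ra / a_sd - mills_a / a_sd
        g_mu_b += rb / b_sd - mills_b / b_sd

    lp += -0.5 * (sigma / sig_sd) ** 2
    g_sigma = -sigma / (sig_sd * sig_sd)

    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)

    inv_s2 = 1.0 / (sigma * sigma)
    ss = 0.0
    for k in range(n):
        p = idx[k]
        r = y[k] - (a[p] + b[p] * x[k])
        ss += r * r
        dll = r * inv_s2
        ga[p] += dll
        gb[p] += dll * x[k]
    lp += -0.5 * inv_s2 * ss - n * math.log(sigma)
    if not math.isfinite(lp):
        return -np.inf, np.zeros(n_dim)
    g_sigma += inv_s2 / sigma * ss - n / sigma

    grad[0] += g_mu_a * mu_a
    grad[1] += g_mu_b * mu_b
    for i in range(P):
        grad[2 + i] += ga[i] * a[i]
        grad[2 + P + i] += gb[i] * b[i]
    grad[i_sigma] += g_sigma * sigma
    for j in range(n_dim):
        if not math.isfinite(grad[j]):
            return -np.inf, np.zeros(n_dim)
    return lp, grad


class PriorPack:
    """Fixed packing order for the prior-constant vectors."""


def pack_fivepl_priors(pr: dict) -> np.ndarray:
    return np.array(
        [
            pr["alpha1"]["mu"], pr["alpha1"]["sd"], pr["alpha1"]["lower"],
            pr["alpha2"]["mu"], pr["alpha2"]["sd"],
            pr["mu_b"]["mu"], pr["mu_b"]["sd"], pr["mu_b"]["lower"],
            pr["mu_c"]["mu"], pr["mu_c"]["sd"], pr["mu_c"]["lower"],
            pr["mu_d"]["mu"], pr["mu_d"]["sd"], pr["mu_d"]["lower"],
            pr["mu_g"]["mu"], pr["mu_g"]["sd"], pr["mu_g"]["lower"],
            pr["b"]["sd"], pr["b"]["lower"],
            pr["c"]["sd"], pr["c"]["lower"], pr["c"]["upper"],
            pr["d"]["sd"], pr["d"]["lower"],
            pr["g"]["sd"], pr["g"]["lower"],
            pr["sigma"]["sd"], pr["slope_sd"]["sd"],
            pr["en"]["mu"], pr["en"]["sd"],
            pr["age"]["mu"], pr["age"]["sd"],
            pr["interaction"]["mu"], pr["interaction"]["sd"],
        ],
        dtype=np.float64,
    )


def pack_linear_priors(pr: dict) -> np.ndarray:
    return np.array(
        [
            pr["linear_mu_a"]["mu"], pr["linear_mu_a"]["sd"],
            pr["linear_mu_b"]["mu"], pr["linear_mu_b"]["sd"],
            pr["linear_a"]["sd"], pr["linear_b"]["sd"],
            pr["sigma"]["sd"],
        ],
        dtype=np.float64,
    )
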