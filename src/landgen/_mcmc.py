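"""Numba kernel for the beta-binomial allele-frequency covariance sampler.

One Metropolis-within-Gibbs chain, fully jitted.  The model: per-locus
latent population frequencies theta ~ MVN(mu_l, mu_l(1-mu_l)*Omega)
truncated to [0,1], with Omega = R/alpha0, R = exp(-(aD*D + sum aE_k
E_k)^a2) (unit diagonal); observed alternate-allele counts are
beta-binomial around theta with per-population dispersion phi_p.

The latent field is sampled in the scale-non-centered parameterization

    theta[p, l] = mu_l + alpha0^(-1/2) * eps[p, l],
    eps[:, l] ~ MVN(0, mu_l(1-mu_l) * R),

an exact reparameterization (the alpha0^(P/2) Jacobian moves the scale
out of the latent prior).  In the centered form the joint density grows
without bound as alpha0 rises and the latent field shrinks toward mu —
a funnel that traps random-walk samplers in a regime where all count
variation is mis-attributed to the beta-binomial layer; non-centering
removes that geometry while leaving the posterior over (theta, alpha)
identical.

Updates per step: one rotating global parameter (alphaD / alphaE_k
touch only the cached per-locus quadratic forms; alpha0 touches only
the beta-binomial terms), a rotating contiguous block of loci for
single-site eps updates and mu independence proposals, and a rotating
population's dispersion.  Priors: exponential on alpha0 (rate
``rate_alpha0``) and on each effect size alphaD / alphaE_k (rate
``rate_effect``) — a log-flat prior would leave a huge
equal-likelihood plateau where the exponent saturates, R is numerically
the identity and the effect-size ratio just diffuses over prior volume;
log-flat on phi; everything restricted to log bounds [lb, ub].
Truncation of theta to (0, 1) is enforced
by clipping into [eps_freq, 1-eps_freq] before the likelihood, whose
own geometry then penalizes boundary states.  All caches are refreshed
periodically to bound float drift.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

EPS_FREQ = 1e-6


@njit(cache=True)
def _cholesky(A, Lout):
    """Lower Cholesky of A into Lout; returns False if not PD."""
    n = A.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = A[i, j]
            for k in range(j):
                s -= Lout[i, k] * Lout[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                Lout[i, i] = math.sqrt(s)
            else:
                Lout[i, j] = s / Lout[j, j]
    for i in range(n):
        for j in range(i + 1, n):
            Lout[i, j] = 0.0
    return True


@njit(cache=True)
def _inv_from_cholesky(L, Ainv):
    """A^-1 from lower Cholesky L (A = L L^T), via column solves."""
    n = L.shape[0]
    for col in range(n):
        z = np.zeros(n)
        for i in range(col, n):
            s = 1.0 if i == col else 0.0
            for k in range(i):
                s -= L[i, k] * z[k]
            z[i] = s / L[i, i]
        for i in range(n - 1, -1, -1):
            s = z[i]
            for k in range(i + 1, n):
                s -= L[k, i] * Ainv[k, col]
            Ainv[i, col] = s / L[i, i]
    for i in range(n):
        for j in range(i):
            v = 0.5 * (Ainv[i, j] + Ainv[j, i])
            Ainv[i, j] = v
            Ainv[j, i] = v


@njit(cache=True)
def _build_R(D, E, ad, ae, a2, R):
    P = D.shape[0]
    K = E.shape[0]
    for i in range(P):
        R[i, i] = 1.0
        for j in range(i + 1, P):
            s = ad * D[i, j]
            for k in range(K):
                s += ae[k] * E[k, i, j]
            if a2 == 1.0:
                v = math.exp(-s)
            else:
                v = math.exp(-(s ** a2))
            R[i, j] = v
            R[j, i] = v


@njit(cache=True)
def _factorize(R, Lbuf, Rinv, jitter_tries=6):
    """Cholesky + inverse + logdet of R, with diagonal jitter fallback.

    Near-singular R (correlations approaching an all-ones block when the
    exponent vanishes) is refused outright: an ill-conditioned inverse
    would poison every cached quadratic form, so the caller treats the
    state as rejected instead.
    """
    P = R.shape[0]
    for attempt in range(jitter_tries + 1):
        if attempt > 0:
            jit = 1e-10 * (10.0 ** (attempt - 1))
            for i in range(P):
                R[i, i] = 1.0 + jit
        if _cholesky(R, Lbuf):
            ok = True
            for i in range(P):
                if Lbuf[i, i] < 1e-7:
                    ok = False
            if not ok:
                continue
            logdet = 0.0
            for i in range(P):
                logdet += 2.0 * math.log(Lbuf[i, i])
            _inv_from_cholesky(Lbuf, Rinv)
            return True, logdet
    return False, 0.0


@njit(cache=True)
def _clip01(v):
    if v < EPS_FREQ:
        return EPS_FREQ
    if v > 1.0 - EPS_FREQ:
        return 1.0 - EPS_FREQ
    return v


@njit(cache=True)
def _bb_var_term(k, mm, th, phi):
    """Theta-dependent part of the beta-binomial log pmf."""
    if mm <= 0.0:
        return 0.0
    th = _clip01(th)
    a = th * phi
    b = (1.0 - th) * phi
    return (
        math.lgamma(k + a) - math.lgamma(a)
        + math.lgamma(mm - k + b) - math.lgamma(b)
    )


@njit(cache=True)
def _beta_draw(a, b):
    g1 = np.random.gamma(a, 1.0)
    g2 = np.random.gamma(b, 1.0)
    if g1 + g2 <= 0.0:
        return 0.5
    return g1 / (g1 + g2)


@njit(cache=True)
def run_chain_kernel(
    kalt, m, D, E, alpha2, seed,
    n_steps, thin, tune_end, tune_interval, target_rate,
    subset_size, phi_period, refresh_interval,
    eps, mu, la0, lad, lae, lphi, pooled, mu_conc,
    sig_glob, sig_eps, sig_phi, sig_shift, lb, ub, rate_alpha0, rate_effect,
    alpha0_cycle,
):
    """Run one chain; mutates eps/mu/lae/lphi/sig_* in place.

    Returns (trace, acc, prop): trace rows are
    [la0, lad, lae_0..K-1, lphi_0..P-1, logpost] every ``thin`` steps;
    acc/prop count post-tuning proposals per block (globals, eps per
    population, phi per population, mu).
    """
    np.random.seed(seed)
    P, L = eps.shape
    K = E.shape[0]
    # global blocks: alpha0, alphaD, alphaE_k, plus one antithetic
    # "exchange" move per covariate (lad -> lad - d, lae_k -> lae_k + d)
    # that travels along the poorly-identified alphaE/alphaD trade-off
    # direction, where single-parameter walks cross between modes slowly
    nglob = 2 + 2 * K
    # final block is the theta-preserving mu shift (interweaving move)
    nblocks = nglob + 2 * P + 2

    R = np.empty((P, P))
    Lbuf = np.empty((P, P))
    Rinv = np.empty((P, P))
    R2 = np.empty((P, P))
    L2 = np.empty((P, P))
    Rinv2 = np.empty((P, P))

    _build_R(D, E, math.exp(lad), np.exp(lae), alpha2, R)
    ok, logdetR = _factorize(R, Lbuf, Rinv)
    rootinv = math.exp(-0.5 * la0)  # alpha0^(-1/2)
    rcol = np.empty(P)  # Rinv @ 1, for common-direction (mu shift) moves
    for p in range(P):
        rcol[p] = Rinv[p, :].sum()
    rsum = rcol.sum()

    y = np.empty((P, L))       # Rinv @ eps, per locus column
    quadR = np.empty(L)        # eps^T Rinv eps
    prior_ll = np.empty(L)     # latent-prior log density per locus (no consts)
    bbvar = np.zeros((P, L))
    bbconst = np.zeros(P)
    s = np.empty(L)
    phis = np.exp(lphi)

    # --- full cache refresh ---
    for l in range(L):
        s[l] = mu[l] * (1.0 - mu[l])
        q = 0.0
        for p in range(P):
            acc_ = 0.0
            for pp in range(P):
                acc_ += Rinv[p, pp] * eps[pp, l]
            y[p, l] = acc_
            q += eps[p, l] * acc_
        quadR[l] = q
        prior_ll[l] = -0.5 * q / s[l] - 0.5 * (P * math.log(s[l]) + logdetR)
    for p in range(P):
        cst = 0.0
        for l in range(L):
            if m[p, l] > 0.0:
                th = _clip01(mu[l] + rootinv * eps[p, l])
                bbvar[p, l] = _bb_var_term(kalt[p, l], m[p, l], th, phis[p])
                cst += math.lgamma(phis[p]) - math.lgamma(m[p, l] + phis[p])
        bbconst[p] = cst

    n_rec = (n_steps + thin - 1) // thin
    ncol = 2 + K + P + 1
    trace = np.empty((n_rec, ncol))
    acc = np.zeros(nblocks)
    prop = np.zeros(nblocks)

    bb_buf = np.empty((P, L))  # proposal buffer (alpha0, phi updates)
    y2 = np.empty((P, L))
    quadR2 = np.empty(L)
    prior2 = np.empty(L)
    xcol = np.empty(P)
    ycol = np.empty(P)

    rec = 0
    for t in range(n_steps):
        # ---- global covariance parameter (rotating) ----
        # alpha0 is the costly update (full likelihood recompute); it takes
        # its slot only every alpha0_cycle-th cycle, alphaD absorbing the rest
        j = t % nglob
        if j == 0 and (t // nglob) % alpha0_cycle != 0:
            j = 1
        if j == 0:
            # alpha0: latent prior invariant; only theta = mu + a0^(-1/2) eps moves
            la0p = la0 + sig_glob[0] * np.random.normal()
            prop[0] += 1.0
            if lb <= la0p <= ub:
                rp = math.exp(-0.5 * la0p)
                # exponential prior on alpha0, density in log space
                delta = (la0p - rate_alpha0 * math.exp(la0p)) - (
                    la0 - rate_alpha0 * math.exp(la0)
                )
                for p in range(P):
                    phi_p = phis[p]
                    for l in range(L):
                        if m[p, l] > 0.0:
                            th = _clip01(mu[l] + rp * eps[p, l])
                            nb = _bb_var_term(kalt[p, l], m[p, l], th, phi_p)
                            bb_buf[p, l] = nb
                            delta += nb - bbvar[p, l]
                if math.log(np.random.random()) < delta:
                    acc[0] += 1.0
                    la0 = la0p
                    rootinv = rp
                    for p in range(P):
                        for l in range(L):
                            if m[p, l] > 0.0:
                                bbvar[p, l] = bb_buf[p, l]
        else:
            # proposal: single-parameter walk, or an exchange move shifting
            # weight between alphaD and one alphaE along the ratio direction
            prop[j] += 1.0
            lad2 = lad
            lae_k = -1
            lae2 = 0.0
            in_bounds = True
            if j <= 1 + K:
                step = sig_glob[j] * np.random.normal()
                if j == 1:
                    lad2 = lad + step
                    in_bounds = lb <= lad2 <= ub
                else:
                    lae_k = j - 2
                    lae2 = lae[lae_k] + step
                    in_bounds = lb <= lae2 <= ub
            else:
                step = sig_glob[j] * np.random.normal()
                lae_k = j - (2 + K)
                lad2 = lad - step
                lae2 = lae[lae_k] + step
                in_bounds = (lb <= lad2 <= ub) and (lb <= lae2 <= ub)
            if in_bounds:
                aep = np.exp(lae)
                if lae_k >= 0:
                    aep[lae_k] = math.exp(lae2)
                _build_R(D, E, math.exp(lad2), aep, alpha2, R2)
                ok2, logdet2 = _factorize(R2, L2, Rinv2)
                if ok2:
                    # exponential priors on effect sizes, density in log space
                    delta = (lad2 - rate_effect * math.exp(lad2)) - (
                        lad - rate_effect * math.exp(lad)
                    )
                    if lae_k >= 0:
                        delta += (lae2 - rate_effect * math.exp(lae2)) - (
                            lae[lae_k] - rate_effect * math.exp(lae[lae_k])
                        )
                    for l in range(L):
                        q = 0.0
                        for p in range(P):
                            acc_ = 0.0
                            for pp in range(P):
                                acc_ += Rinv2[p, pp] * eps[pp, l]
                            y2[p, l] = acc_
                            q += eps[p, l] * acc_
                        quadR2[l] = q
                        prior2[l] = -0.5 * q / s[l] - 0.5 * (P * math.log(s[l]) + logdet2)
                        delta += prior2[l] - prior_ll[l]
                    if math.log(np.random.random()) < delta:
                        acc[j] += 1.0
                        lad = lad2
                        if lae_k >= 0:
                            lae[lae_k] = lae2
                        for i in range(P):
                            for jj in range(P):
                                Rinv[i, jj] = Rinv2[i, jj]
                        logdetR = logdet2
                        for p in range(P):
                            rcol[p] = Rinv[p, :].sum()
                        rsum = rcol.sum()
                        for l in range(L):
                            quadR[l] = quadR2[l]
                            prior_ll[l] = prior2[l]
                            for p in range(P):
                                y[p, l] = y2[p, l]

        # ---- latent deviations eps, rotating block of loci ----
        start = (t * subset_size) % L
        for ii in range(subset_size):
            l = (start + ii) % L
            inv_s = 1.0 / s[l]
            for p in range(P):
                prop[nglob + p] += 1.0
                dlt = sig_eps[p] * np.random.normal()
                epn = eps[p, l] + dlt
                dq = 2.0 * dlt * y[p, l] + dlt * dlt * Rinv[p, p]
                dprior = -0.5 * inv_s * dq
                if m[p, l] > 0.0:
                    th = _clip01(mu[l] + rootinv * epn)
                    nb = _bb_var_term(kalt[p, l], m[p, l], th, phis[p])
                    dbb = nb - bbvar[p, l]
                else:
                    nb = 0.0
                    dbb = 0.0
                if math.log(np.random.random()) < dprior + dbb:
                    acc[nglob + p] += 1.0
                    eps[p, l] = epn
                    quadR[l] += dq
                    prior_ll[l] += dprior
                    bbvar[p, l] = nb
                    for pp in range(P):
                        y[pp, l] += dlt * Rinv[pp, p]

        # ---- ancestral means mu, same block (independence proposals) ----
        imu = nglob + 2 * P
        for ii in range(subset_size):
            l = (start + ii) % L
            prop[imu] += 1.0
            ap = mu_conc * pooled[l] + 1.0
            bp = mu_conc * (1.0 - pooled[l]) + 1.0
            mup = _beta_draw(ap, bp)
            if mup < EPS_FREQ or mup > 1.0 - EPS_FREQ:
                continue
            sp = mup * (1.0 - mup)
            prior_new = -0.5 * quadR[l] / sp - 0.5 * (P * math.log(sp) + logdetR)
            dbb = 0.0
            for p in range(P):
                if m[p, l] > 0.0:
                    th = _clip01(mup + rootinv * eps[p, l])
                    xcol[p] = _bb_var_term(kalt[p, l], m[p, l], th, phis[p])
                    dbb += xcol[p] - bbvar[p, l]
                else:
                    xcol[p] = 0.0
            dq_prop = (ap - 1.0) * (math.log(mu[l]) - math.log(mup)) + (bp - 1.0) * (
                math.log(1.0 - mu[l]) - math.log(1.0 - mup)
            )
            if math.log(np.random.random()) < prior_new - prior_ll[l] + dbb + dq_prop:
                acc[imu] += 1.0
                mu[l] = mup
                s[l] = sp
                prior_ll[l] = prior_new
                for p in range(P):
                    bbvar[p, l] = xcol[p]

        # ---- interweaving: shift mu with compensating eps, theta fixed ----
        # moves the shared component of the latent field between mu and eps
        # without touching the likelihood; without it, states where mu has
        # absorbed the common signal reorganize extremely slowly
        ishift = nglob + 2 * P + 1
        for ii in range(subset_size):
            l = (start + ii) % L
            prop[ishift] += 1.0
            dmu = sig_shift[0] * np.random.normal()
            mup = mu[l] + dmu
            if mup < EPS_FREQ or mup > 1.0 - EPS_FREQ:
                continue
            deps = -dmu / rootinv
            sy = 0.0
            for p in range(P):
                sy += y[p, l]
            qn = quadR[l] + 2.0 * deps * sy + deps * deps * rsum
            sp = mup * (1.0 - mup)
            prior_new = -0.5 * qn / sp - 0.5 * (P * math.log(sp) + logdetR)
            if math.log(np.random.random()) < prior_new - prior_ll[l]:
                acc[ishift] += 1.0
                mu[l] = mup
                s[l] = sp
                quadR[l] = qn
                prior_ll[l] = prior_new
                for p in range(P):
                    eps[p, l] += deps
                    y[p, l] += deps * rcol[p]

        # ---- dispersion phi, rotating population ----
        if t % phi_period == 0:
            p = (t // phi_period) % P
            iphi = nglob + P + p
            prop[iphi] += 1.0
            lpp = lphi[p] + sig_phi[p] * np.random.normal()
            if lb <= lpp <= ub:
                phin = math.exp(lpp)
                delta = 0.0
                cst_new = 0.0
                for l in range(L):
                    if m[p, l] > 0.0:
                        th = _clip01(mu[l] + rootinv * eps[p, l])
                        nb = _bb_var_term(kalt[p, l], m[p, l], th, phin)
                        bb_buf[p, l] = nb
                        delta += nb - bbvar[p, l]
                        cst_new += math.lgamma(phin) - math.lgamma(m[p, l] + phin)
                    else:
                        bb_buf[p, l] = 0.0
                delta += cst_new - bbconst[p]
                if math.log(np.random.random()) < delta:
                    acc[iphi] += 1.0
                    lphi[p] = lpp
                    phis[p] = phin
                    bbconst[p] = cst_new
                    for l in range(L):
                        bbvar[p, l] = bb_buf[p, l]

        # ---- proposal tuning (discarded window only) ----
        if t < tune_end and (t + 1) % tune_interval == 0:
            for bi in range(nglob):
                if prop[bi] > 0:
                    rate = acc[bi] / prop[bi]
                    sig_glob[bi] = min(max(sig_glob[bi] * math.exp(rate - target_rate), 1e-4), 10.0)
            for p in range(P):
                bi = nglob + p
                if prop[bi] > 0:
                    rate = acc[bi] / prop[bi]
                    sig_eps[p] = min(max(sig_eps[p] * math.exp(rate - target_rate), 1e-4), 5.0)
                bi = nglob + P + p
                if prop[bi] > 0:
                    rate = acc[bi] / prop[bi]
                    sig_phi[p] = min(max(sig_phi[p] * math.exp(rate - target_rate), 1e-4), 10.0)
            bi = nglob + 2 * P + 1
            if prop[bi] > 0:
                rate = acc[bi] / prop[bi]
                sig_shift[0] = min(max(sig_shift[0] * math.exp(rate - target_rate), 1e-4), 0.5)
            for bi in range(nblocks):
                acc[bi] = 0.0
                prop[bi] = 0.0
        if t + 1 == tune_end:
            for bi in range(nblocks):
                acc[bi] = 0.0
                prop[bi] = 0.0

        # ---- periodic cache refresh against float drift ----
        if (t + 1) % refresh_interval == 0:
            for l in range(L):
                q = 0.0
                for p in range(P):
                    acc_ = 0.0
                    for pp in range(P):
                        acc_ += Rinv[p, pp] * eps[pp, l]
                    y[p, l] = acc_
                    q += eps[p, l] * acc_
                quadR[l] = q
                prior_ll[l] = -0.5 * q / s[l] - 0.5 * (P * math.log(s[l]) + logdetR)

        # ---- record ----
        if t % thin == 0:
            lp = 0.0
            for l in range(L):
                lp += prior_ll[l]
            for p in range(P):
                lp += bbconst[p]
                for l in range(L):
                    lp += bbvar[p, l]
            trace[rec, 0] = la0
            trace[rec, 1] = lad
            for k in range(K):
                trace[rec, 2 + k] = lae[k]
            for p in range(P):
                trace[rec, 2 + K + p] = lphi[p]
            trace[rec, 2 + K + P] = lp
            rec += 1

    return trace, acc, prop
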