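"""Numba kernels: banded forward filtering and backward sampling on the
truncated latent-abundance state space.

The latent chain lives on {0, ..., K}.  Transition rows are Poisson(lam*m)
pmfs; by default the tail mass beyond K is dropped (standard truncation for
open N-mixture likelihoods), or optionally folded into state K so rows sum
to one.  Emissions are Binomial(y; n, p) weights.  All loops run over adaptive
"active windows" — index ranges outside which the filtered mass is below
1e-13 of the maximum — which keeps the cost proportional to the posterior
spread of N rather than to K.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

NEG_INF = -1.0e300


@njit(cache=True, fastmath=True, inline="always")
def _poisson_band(mu, K):
    """Inclusive index range holding all but ~1e-10 of a Poisson(mu) pmf."""
    sd = math.sqrt(mu)
    lo = int(mu - 6.5 * sd - 20.0)
    if lo < 0:
        lo = 0
    if lo > K:
        lo = K
    hi = int(mu + 6.5 * sd + 20.0)
    if hi > K:
        hi = K
    return lo, hi


@njit(cache=True, fastmath=True, inline="always")
def _poisson_tail(mu, K, lgam):
    """P(X >= K) for X ~ Poisson(mu), by upward summation (full relative
    precision for small tails; call only when the tail is known small)."""
    q = math.exp(K * math.log(mu) - mu - lgam[K + 1])
    t = q
    n = K
    while q > t * 1e-16:
        q = q * mu / (n + 1.0)
        t += q
        n += 1
    return t


@njit(cache=True, fastmath=True, inline="always")
def _fold_remainder(mu, K, below, lgam):
    """Tail mass folded into state K given the summed pmf ``below`` < K.

    ``1 - below`` cancels catastrophically when the tail is tiny, so small
    tails are recomputed by direct summation.
    """
    rem = 1.0 - below
    if rem < 0.01:  # cancellation regime (including exact 0): sum directly
        return _poisson_tail(mu, K, lgam)
    return rem


@njit(cache=True, fastmath=True)
def forward_pass(obs, y, lam, pv, K, lam_init, init_uniform, lgam,
                 fold, store, alpha, lo_s, hi_s):
    """Forward algorithm over one site's calendar span.

    Parameters are per span-year arrays: ``obs[j]`` marks surveyed years,
    ``y[j]`` the count (only read where observed), ``lam[j]`` the growth
    rate of the transition *into* year j (``lam[0]`` unused), ``pv[j]`` the
    detection probability (only read where observed).  ``lgam[i]`` must
    hold lgamma(i) for i in 0..K+1.

    Returns the log marginal likelihood (NEG_INF when the data fall outside
    the numerically representable support).  ``fold`` selects the
    truncation convention: False drops Poisson mass beyond K (the
    likelihood of the data with N never exceeding K), True folds it into
    state K so transition rows stay normalised.  With ``store`` set, filtered
    state distributions (normalised) and their active windows are written
    to ``alpha``, ``lo_s``, ``hi_s`` for backward sampling.
    """
    S = obs.shape[0]
    a = np.zeros(K + 1)
    b = np.zeros(K + 1)
    recip = np.empty(K + 4)
    rr = np.empty(K + 4)  # rr[n] = 1/(n*(n-1)): two-step pmf recursion factor
    recip[0] = 0.0
    rr[0] = 0.0
    rr[1] = 0.0
    for i in range(1, K + 4):
        recip[i] = 1.0 / i
        if i >= 2:
            rr[i] = recip[i] * recip[i - 1]
    loglik = 0.0
    lo = 0
    hi = 0

    # initial latent distribution over {0..K}
    if init_uniform:
        lo = 0
        hi = K
        v = 1.0 / (K + 1)
        for n in range(K + 1):
            a[n] = v
    else:
        mu = lam_init
        if mu <= 0.0:
            a[0] = 1.0
        else:
            lo, hi = _poisson_band(mu, K)
            logq = lo * math.log(mu) - mu - lgam[lo + 1]
            q = math.exp(logq)
            tot = 0.0
            for n in range(lo, hi + 1):
                if n < K:
                    a[n] = q
                    tot += q
                else:
                    a[K] = q  # raw truncated pmf at the bound
                q = q * mu * recip[n + 1]
            if fold and hi == K:
                a[K] = _fold_remainder(mu, K, tot, lgam)

    for j in range(S):
        if j > 0:
            lj = lam[j]
            if lj <= 0.0 or not math.isfinite(lj):
                return NEG_INF
            # destination window across all source rows (bands are monotone in m)
            blo, _ = _poisson_band(lj * lo, K)
            if lo == 0:
                blo = 0
            _, bhi = _poisson_band(lj * hi, K)
            nb_lo = blo
            nb_hi = bhi
            for n in range(nb_lo, nb_hi + 1):
                b[n] = 0.0
            for m in range(lo, hi + 1):
                am = a[m]
                if am <= 0.0:
                    continue
                if m == 0:
                    b[0] += am  # Poisson(0) is a point mass at zero
                    continue
                mu = lj * m
                rlo, rhi = _poisson_band(mu, K)
                if rlo >= K:
                    if fold:
                        b[K] += am  # entire band beyond the bound folds to K
                    continue
                logq = rlo * math.log(mu) - mu - lgam[rlo + 1]
                # two interleaved pmf recursions hide the serial multiply
                # latency of the q_{n+1} = q_n * mu / (n+1) chain
                q0 = math.exp(logq)
                q1 = q0 * mu * recip[rlo + 1]
                mu2 = mu * mu
                tot = 0.0
                rhi_eff = (rhi if rhi < K else K - 1) if fold else rhi
                n = rlo
                while n + 1 <= rhi_eff:
                    b[n] += am * q0
                    b[n + 1] += am * q1
                    tot += q0 + q1
                    q0 = q0 * mu2 * rr[n + 2]
                    q1 = q1 * mu2 * rr[n + 3]
                    n += 2
                if n <= rhi_eff:
                    b[n] += am * q0
                    tot += q0
                if fold and rhi == K:
                    b[K] += am * _fold_remainder(mu, K, tot, lgam)
            for n in range(nb_lo, nb_hi + 1):
                a[n] = b[n]
            lo = nb_lo
            hi = nb_hi

        if obs[j]:
            yj = y[j]
            p = pv[j]
            if yj > hi:
                return NEG_INF  # count above every plausible latent state
            if p >= 1.0:
                if yj < lo:
                    return NEG_INF
                norm = a[yj]
                if norm <= 0.0:
                    return NEG_INF
                loglik += math.log(norm)
                a[yj] = 1.0
                lo = yj
                hi = yj
            else:
                elo = lo if lo > yj else yj
                log_p = math.log(p)
                log_1mp = math.log(1.0 - p)
                logw = (lgam[elo + 1] - lgam[elo - yj + 1] - lgam[yj + 1]
                        + yj * log_p + (elo - yj) * log_1mp)
                w = math.exp(logw)
                norm = 0.0
                for n in range(elo, hi + 1):
                    an = a[n] * w
                    a[n] = an
                    norm += an
                    w = w * (n + 1.0) * recip[n + 1 - yj] * (1.0 - p)
                if norm <= 0.0:
                    return NEG_INF
                loglik += math.log(norm)
                inv = 1.0 / norm
                for n in range(elo, hi + 1):
                    a[n] *= inv
                lo = elo

        # shrink the active window
        amax = 0.0
        for n in range(lo, hi + 1):
            if a[n] > amax:
                amax = a[n]
        if amax <= 0.0:
            return NEG_INF
        thr = amax * 1e-13
        while lo < hi and a[lo] <= thr:
            lo += 1
        while hi > lo and a[hi] <= thr:
            hi -= 1

        if store:
            tot = 0.0
            for n in range(lo, hi + 1):
                tot += a[n]
            inv = 1.0 / tot
            for n in range(lo, hi + 1):
                alpha[j, n] = a[n] * inv
            lo_s[j] = lo
            hi_s[j] = hi

    return loglik


@njit(cache=True, fastmath=True)
def backward_sample(lam, K, lgam, fold, alpha, lo_s, hi_s, u, N_out):
    """Sample a latent trajectory given stored filtered distributions.

    ``u`` supplies one uniform variate per span year (drawn by the caller,
    which owns the RNG).  Returns the number of years whose sampled state
    hit the truncation bound K.
    """
    S = lam.shape[0]
    wbuf = np.zeros(K + 1)
    bound_hits = 0

    j = S - 1
    lo = lo_s[j]
    hi = hi_s[j]
    r = u[j]
    acc = 0.0
    pick = hi
    for n in range(lo, hi + 1):
        acc += alpha[j, n]
        if acc >= r:
            pick = n
            break
    N_out[j] = pick
    if pick == K:
        bound_hits += 1

    for j in range(S - 2, -1, -1):
        nn = N_out[j + 1]
        lj = lam[j + 1]
        lo = lo_s[j]
        hi = hi_s[j]
        tot = 0.0
        for m in range(lo, hi + 1):
            am = alpha[j, m]
            w = 0.0
            if am > 0.0:
                mu = lj * m
                if mu <= 0.0:
                    w = am if nn == 0 else 0.0
                elif nn < K or not fold:
                    w = am * math.exp(nn * math.log(mu) - mu - lgam[nn + 1])
                else:
                    # folded state: weight is the upper Poisson tail P(X >= K)
                    w = am * _poisson_tail(mu, K, lgam)
            wbuf[m] = w
            tot += w
        if tot <= 0.0:
            # numerically dead conditional; fall back to the filtered mode
            best = lo
            for m in range(lo, hi + 1):
                if alpha[j, m] > alpha[j, best]:
                    best = m
            N_out[j] = best
        else:
            r = u[j] * tot
            acc = 0.0
            pick = hi
            for m in range(lo, hi + 1):
                acc += wbuf[m]
                if acc >= r:
                    pick = m
                    break
            N_out[j] = pick
        if N_out[j] == K:
            bound_hits += 1

    return bound_hits
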