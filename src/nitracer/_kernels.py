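"""Compiled numerical kernels for the five-pool tracing model.

State layout used throughout: a length-10 vector ``y`` holding the five
pool amounts (ug N / g soil) followed by the five 15N sub-amounts
(ug 15N / g soil).  Pool order: NH4+, NO3-, N_lab, N_rec, NH4+_ads.

Every flux removes nitrogen from its source pool at the source pool's
current 15N atom fraction and delivers it unchanged to the sink, so both
total N and total 15N are linear invariants of the ODE system.
"""

import numpy as np
from numba import njit

# pool indices
NH4, NO3, NLAB, NREC, NH4ADS = 0, 1, 2, 3, 4

# kinetic-law codes
ZERO_ORDER, FIRST_ORDER, MICHAELIS_MENTEN = 0, 1, 2

# transformation order (fixed): source pool, sink pool per entry
TRANSFORM_NAMES = (
    "M_Nrec", "I_NH4_Nrec", "M_Nlab", "I_NH4_Nlab", "O_Nrec",
    "I_NO3", "O_NH4", "D_NO3", "A_NH4", "R_NH4a",
)
SRC = np.array([NREC, NH4, NLAB, NH4, NREC, NO3, NH4, NO3, NH4, NH4ADS],
               dtype=np.int64)
SNK = np.array([NH4, NREC, NH4, NLAB, NO3, NREC, NO3, NH4, NH4ADS, NH4],
               dtype=np.int64)

# linear ramp width (ug N/g) below which zero-order laws taper to zero
ZERO_ORDER_RAMP = 0.01


@njit(cache=True)
def transformation_rates(y, kinds, k, km, out):
    """Instantaneous gross rates (ug N/g/day) for all ten transformations."""
    for j in range(10):
        s = y[SRC[j]]
        if s <= 0.0:
            out[j] = 0.0
        elif kinds[j] == ZERO_ORDER:
            if s < ZERO_ORDER_RAMP:
                out[j] = k[j] * s / ZERO_ORDER_RAMP
            else:
                out[j] = k[j]
        elif kinds[j] == FIRST_ORDER:
            out[j] = k[j] * s
        else:
            out[j] = k[j] * s / (km[j] + s)


@njit(cache=True)
def rhs(y, kinds, k, km, dydt):
    """Time derivative of the 10-component state."""
    for i in range(10):
        dydt[i] = 0.0
    rates = np.empty(10)
    transformation_rates(y, kinds, k, km, rates)
    for j in range(10):
        src = SRC[j]
        snk = SNK[j]
        r = rates[j]
        amt = y[src]
        if amt > 1e-12:
            f = y[5 + src] / amt
            if f < 0.0:
                f = 0.0
            elif f > 1.0:
                f = 1.0
        else:
            f = 0.0
        dydt[src] -= r
        dydt[snk] += r
        dydt[5 + src] -= r * f
        dydt[5 + snk] += r * f


@njit(cache=True)
def integrate_rk4(y0, t0, times, kinds, k, km, hmax):
    """Classic RK4 with fixed sub-steps; returns states at ``times``.

    ``times`` must be ascending and start at or after ``t0``.  The step
    count per output interval is chosen so sub-steps never exceed hmax.
    """
    n = times.shape[0]
    out = np.empty((n, 10))
    y = y0.copy()
    t = t0
    k1 = np.empty(10)
    k2 = np.empty(10)
    k3 = np.empty(10)
    k4 = np.empty(10)
    ytmp = np.empty(10)
    for i in range(n):
        dt_total = times[i] - t
        if dt_total > 0.0:
            nsteps = int(np.ceil(dt_total / hmax))
            h = dt_total / nsteps
            for _ in range(nsteps):
                rhs(y, kinds, k, km, k1)
                for m in range(10):
                    ytmp[m] = y[m] + 0.5 * h * k1[m]
                rhs(ytmp, kinds, k, km, k2)
                for m in range(10):
                    ytmp[m] = y[m] + 0.5 * h * k2[m]
                rhs(ytmp, kinds, k, km, k3)
                for m in range(10):
                    ytmp[m] = y[m] + h * k3[m]
                rhs(ytmp, kinds, k, km, k4)
                for m in range(10):
                    y[m] += h / 6.0 * (k1[m] + 2.0 * k2[m] + 2.0 * k3[m] + k4[m])
                    if y[m] < 0.0:
                        y[m] = 0.0
            t = times[i]
        out[i, :] = y
    return out


@njit(cache=True)
def gaussian_loglik(y0_a, y0_b, obs_times, kinds, k, km,
                    obs_vals_a, obs_vals_b, obs_sd, hmax):
    """Log-likelihood of paired-labelling observations.

    obs_vals_* and obs_sd are (ntimes, 4) arrays in the order
    (NH4 conc, NO3 conc, NH4 atom fraction, NO3 atom fraction);
    NaN entries are skipped.  Treatments a and b share kinetics and
    differ only in the initial 15N distribution.
    """
    total = 0.0
    for trt in range(2):
        if trt == 0:
            states = integrate_rk4(y0_a, 0.0, obs_times, kinds, k, km, hmax)
            vals = obs_vals_a
        else:
            states = integrate_rk4(y0_b, 0.0, obs_times, kinds, k, km, hmax)
            vals = obs_vals_b
        for i in range(obs_times.shape[0]):
            nh4 = states[i, NH4]
            no3 = states[i, NO3]
            f_nh4 = states[i, 5 + NH4] / nh4 if nh4 > 1e-12 else 0.0
            f_no3 = states[i, 5 + NO3] / no3 if no3 > 1e-12 else 0.0
            model = (nh4, no3, f_nh4, f_no3)
            for v in range(4):
                o = vals[i, v]
                if not np.isnan(o):
                    sd = obs_sd[i, v]
                    z = (o - model[v]) / sd
                    total += -0.5 * z * z - 0.5 * np.log(2.0 * np.pi) - np.log(sd)
    return total


@njit(cache=True)
def metropolis_chain(x0, steps, log_u, lo, hi, free_idx,
                     kinds, k0, km, y0_a, y0_b, obs_times,
                     obs_vals_a, obs_vals_b, obs_sd, hmax,
                     burn_in, adapt_target, scale0):
    """Random-walk Metropolis on log-transformed rate constants.

    ``steps`` is an (n, d) array of standard-normal increments and
    ``log_u`` an (n,) array of log-uniforms, both pre-drawn so the chain
    is bit-reproducible.  Priors are uniform on [lo, hi] on the natural
    scale; the log-scale walk therefore carries a Jacobian term equal to
    the product of the parameters.  A single global proposal scale is
    adapted towards ``adapt_target`` acceptance during burn-in only.
    """
    n, d = steps.shape
    chain = np.empty((n, d))
    logliks = np.empty(n)
    x = x0.copy()          # natural scale, free parameters only
    lx = np.log(x)
    k = k0.copy()
    for j in range(d):
        k[free_idx[j]] = x[j]
    lp = gaussian_loglik(y0_a, y0_b, obs_times, kinds, k, km,
                         obs_vals_a, obs_vals_b, obs_sd, hmax)
    scale = scale0
    n_accept = 0
    accept_window = 0
    consec_reject = 0
    max_consec_reject = 0
    window = 200
    for i in range(n):
        lx_prop = lx + scale * steps[i]
        inside = True
        log_jac = 0.0
        for j in range(d):
            xv = np.exp(lx_prop[j])
            if xv < lo[j] or xv > hi[j]:
                inside = False
                break
            log_jac += lx_prop[j] - lx[j]
        if inside:
            kprop = k.copy()
            for j in range(d):
                kprop[free_idx[j]] = np.exp(lx_prop[j])
            lp_prop = gaussian_loglik(y0_a, y0_b, obs_times, kinds, kprop,
                                      km, obs_vals_a, obs_vals_b, obs_sd,
                                      hmax)
            if log_u[i] < lp_prop - lp + log_jac:
                lx = lx_prop
                lp = lp_prop
                k = kprop
                n_accept += 1
                accept_window += 1
                consec_reject = -1
        consec_reject += 1
        if consec_reject > max_consec_reject:
            max_consec_reject = consec_reject
        for j in range(d):
            chain[i, j] = np.exp(lx[j])
        logliks[i] = lp
        if i < burn_in and (i + 1) % window == 0:
            rate = accept_window / window
            scale *= np.exp(1.5 * (rate - adapt_target))
            if scale < 1e-6:
                scale = 1e-6
            elif scale > 10.0:
                scale = 10.0
            accept_window = 0
    return chain, logliks, n_accept, scale, max_consec_reject
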