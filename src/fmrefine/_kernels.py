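"""Compiled inner loops for the replica MCMC sampler.

The sweep kernel consumes pre-generated random streams (one array per move
type), which keeps runs bit-reproducible under a fixed seed and lets the
whole loop compile under numba.  Observables must be grouped contiguously by
forward-model set; per-state Karplus basis matrices (cos^2, cos) are
precomputed so that theta moves and gradients are cheap.

State kept incrementally across moves, per observable j:
  S1[j] = sum_r g_j(X_r)        S2[j] = sum_r g_j(X_r)^2
  T2[j] = sum_r cos^2(phi)      T1[j] = sum_r cos(phi)
The replica mean, SEM, data energy and theta-gradient all derive from these.

Conventions baked in (mirroring the reference implementations in
``likelihood``): Heaviside H(0) = 0, so with sigma0 >= sigma_SEM and
phi >= 1 both mixture components are always active.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG_2PI = float(np.log(2.0 * np.pi))
LN2 = float(np.log(2.0))

# model_flag: 0 = gaussian, 1 = good_bad
# sem_mode:   0 = sample stdev / sqrt(N), 1 = population stdev
# prefac:     0 = 1/(2 phi) (as printed), 1 = 1/2


@njit(cache=True)
def data_term_kernel(S1, S2, d, set_idx, sigma_b, phi_sc, N,
                     model_flag, sem_mode, prefac, w, want_w):
    """-N sum_j ln L_j for the current running sums; optionally fill the
    responsibility-weighted residual weights w_j (d ln L_j / d g_j = w_j)."""
    n_obs = d.shape[0]
    total = 0.0
    invN = 1.0 / N
    for j in range(n_obs):
        mean = S1[j] * invN
        var = S2[j] * invN - mean * mean
        if var < 0.0:
            var = 0.0
        if N > 1:
            if sem_mode == 0:
                sem2 = var * N / (N - 1.0) * invN
            else:
                sem2 = var
        else:
            sem2 = 0.0
        k = set_idx[j]
        sb = sigma_b[k]
        s0sq = sb * sb + sem2
        s0 = np.sqrt(s0sq)
        r = d[j] - mean
        phi = phi_sc[k]
        if model_flag == 0 or phi == 1.0:
            lnl = -0.5 * LOG_2PI - np.log(s0) - 0.5 * r * r / s0sq
            if want_w:
                w[j] = r / s0sq
        else:
            t1 = -LN2 - 0.5 * LOG_2PI - np.log(s0) - 0.5 * r * r / s0sq
            t2 = (-LN2 - 0.5 * LOG_2PI - np.log(phi * s0)
                  - 0.5 * r * r / (phi * phi * s0sq))
            if prefac == 0:
                t2 -= np.log(phi)
            if t1 >= t2:
                lnl = t1 + np.log1p(np.exp(t2 - t1))
            else:
                lnl = t2 + np.log1p(np.exp(t1 - t2))
            if want_w:
                w[j] = (np.exp(t1 - lnl) * r / s0sq
                        + np.exp(t2 - lnl) * r / (phi * phi * s0sq))
        total -= lnl
    return N * total


@njit(cache=True)
def theta_grad_kernel(T2, T1, w, set_idx, N, K, xi, out):
    """xi-scaled gradient of u w.r.t. theta[k] = (A, B, C) from weights w."""
    for k in range(K):
        out[k, 0] = 0.0
        out[k, 1] = 0.0
        out[k, 2] = 0.0
    n_obs = w.shape[0]
    for j in range(n_obs):
        k = set_idx[j]
        out[k, 0] -= T2[j] * w[j]
        out[k, 1] -= T1[j] * w[j]
        out[k, 2] -= N * w[j]
    for k in range(K):
        out[k, 0] *= xi
        out[k, 1] *= xi
        out[k, 2] *= xi


@njit(cache=True)
def run_sweeps(n_sweeps, n_states, N, K, xi,
               C2, C1, G, G2, states, counts, S1, S2, T2, T1,
               d, set_idx, obs_lo, obs_hi,
               logp_state, theta, sigma_b, phi_sc,
               model_flag, sem_mode, prefac,
               sb_lo, sb_hi, ph_lo, ph_hi,
               do_states, sample_sigma, sample_phi, do_theta, grad_on,
               lrate, eta, sigma_step, phi_step,
               thin, collect_grad, record_aux,
               r_state_u, r_state_acc, r_sig_z, r_sig_acc,
               r_phi_z, r_phi_acc, r_th_z, r_th_acc,
               out_theta, out_sigma, out_phi,
               out_energy, out_prior, out_data,
               out_grad, out_w, out_counts, occ_sum, acc):
    n_obs = d.shape[0]
    S1t = np.empty(n_obs)
    S2t = np.empty(n_obs)
    w = np.empty(n_obs)
    gbuf = np.empty((K, 3))

    Ed = data_term_kernel(S1, S2, d, set_idx, sigma_b, phi_sc, N,
                          model_flag, sem_mode, prefac, w, False)
    prior_state = 0.0
    for r in range(N):
        prior_state -= logp_state[states[r]]
    prior_nuis = 0.0
    for k in range(K):
        prior_nuis += np.log(sigma_b[k]) + np.log(phi_sc[k])

    for i in range(n_sweeps):
        # --- replica state swaps -------------------------------------------
        if do_states:
            for r in range(N):
                acc[0, 1] += 1
                s_old = states[r]
                s_new = int(r_state_u[i, r] * n_states)
                if s_new >= n_states:
                    s_new = n_states - 1
                if s_new == s_old:
                    acc[0, 0] += 1
                    continue
                for j in range(n_obs):
                    S1t[j] = S1[j] + G[s_new, j] - G[s_old, j]
                    S2t[j] = S2[j] + G2[s_new, j] - G2[s_old, j]
                Ed_new = data_term_kernel(S1t, S2t, d, set_idx, sigma_b,
                                          phi_sc, N, model_flag, sem_mode,
                                          prefac, w, False)
                du = (logp_state[s_old] - logp_state[s_new]
                      + xi * (Ed_new - Ed))
                if du <= 0.0 or r_state_acc[i, r] < np.exp(-du):
                    for j in range(n_obs):
                        S1[j] = S1t[j]
                        S2[j] = S2t[j]
                        T2[j] += C2[s_new, j] - C2[s_old, j]
                        T1[j] += C1[s_new, j] - C1[s_old, j]
                    counts[s_old] -= 1
                    counts[s_new] += 1
                    states[r] = s_new
                    prior_state += logp_state[s_old] - logp_state[s_new]
                    Ed = Ed_new
                    acc[0, 0] += 1

        # --- sigma_B log-space random walk ---------------------------------
        if sample_sigma:
            for k in range(K):
                acc[1, 1] += 1
                sb_old = sigma_b[k]
                y_old = np.log(sb_old)
                y_new = y_old + sigma_step * r_sig_z[i, k]
                sb_new = np.exp(y_new)
                if sb_new < sb_lo or sb_new > sb_hi:
                    continue
                sigma_b[k] = sb_new
                Ed_new = data_term_kernel(S1, S2, d, set_idx, sigma_b,
                                          phi_sc, N, model_flag, sem_mode,
                                          prefac, w, False)
                du = (y_new - y_old) + xi * (Ed_new - Ed)
                # Jacobian of the log-space walk cancels the Jeffreys prior
                log_a = -du + (y_new - y_old)
                if log_a >= 0.0 or np.log(r_sig_acc[i, k]) < log_a:
                    prior_nuis += y_new - y_old
                    Ed = Ed_new
                    acc[1, 0] += 1
                else:
                    sigma_b[k] = sb_old

        # --- phi reflected random walk -------------------------------------
        if sample_phi and model_flag == 1:
            width = ph_hi - ph_lo
            for k in range(K):
                acc[2, 1] += 1
                p_old = phi_sc[k]
                x = p_old + phi_step * r_phi_z[i, k] - ph_lo
                x = x % (2.0 * width)
                if x < 0.0:
                    x += 2.0 * width
                if x > width:
                    x = 2.0 * width - x
                p_new = ph_lo + x
                phi_sc[k] = p_new
                Ed_new = data_term_kernel(S1, S2, d, set_idx, sigma_b,
                                          phi_sc, N, model_flag, sem_mode,
                                          prefac, w, False)
                du = (np.log(p_new) - np.log(p_old)) + xi * (Ed_new - Ed)
                if du <= 0.0 or r_phi_acc[i, k] < np.exp(-du):
                    prior_nuis += np.log(p_new) - np.log(p_old)
                    Ed = Ed_new
                    acc[2, 0] += 1
                else:
                    phi_sc[k] = p_old

        # --- theta moves (gradient drift during burn-in only) --------------
        if do_theta:
            if grad_on and lrate > 0.0:
                data_term_kernel(S1, S2, d, set_idx, sigma_b, phi_sc, N,
                                 model_flag, sem_mode, prefac, w, True)
                theta_grad_kernel(T2, T1, w, set_idx, N, K, xi, gbuf)
            for k in range(K):
                acc[3, 1] += 1
                thA = theta[k, 0] + eta * r_th_z[i, k, 0]
                thB = theta[k, 1] + eta * r_th_z[i, k, 1]
                thC = theta[k, 2] + eta * r_th_z[i, k, 2]
                if grad_on and lrate > 0.0:
                    thA -= lrate * gbuf[k, 0]
                    thB -= lrate * gbuf[k, 1]
                    thC -= lrate * gbuf[k, 2]
                for j in range(n_obs):
                    S1t[j] = S1[j]
                    S2t[j] = S2[j]
                for j in range(obs_lo[k], obs_hi[k]):
                    s1 = 0.0
                    s2 = 0.0
                    for s in range(n_states):
                        c = counts[s]
                        if c > 0:
                            v = thA * C2[s, j] + thB * C1[s, j] + thC
                            s1 += c * v
                            s2 += c * v * v
                    S1t[j] = s1
                    S2t[j] = s2
                Ed_new = data_term_kernel(S1t, S2t, d, set_idx, sigma_b,
                                          phi_sc, N, model_flag, sem_mode,
                                          prefac, w, False)
                du = xi * (Ed_new - Ed)
                if du <= 0.0 or r_th_acc[i, k] < np.exp(-du):
                    theta[k, 0] = thA
                    theta[k, 1] = thB
                    theta[k, 2] = thC
                    for j in range(obs_lo[k], obs_hi[k]):
                        S1[j] = S1t[j]
                        S2[j] = S2t[j]
                        for s in range(n_states):
                            v = thA * C2[s, j] + thB * C1[s, j] + thC
                            G[s, j] = v
                            G2[s, j] = v * v
                    Ed = Ed_new
                    acc[3, 0] += 1

        # --- bookkeeping ----------------------------------------------------
        for r in range(N):
            occ_sum[states[r]] += 1

        if (i + 1) % thin == 0:
            irec = (i + 1) // thin - 1
            for k in range(K):
                out_theta[irec, k, 0] = theta[k, 0]
                out_theta[irec, k, 1] = theta[k, 1]
                out_theta[irec, k, 2] = theta[k, 2]
                out_sigma[irec, k] = sigma_b[k]
                out_phi[irec, k] = phi_sc[k]
            out_prior[irec] = prior_state + prior_nuis
            out_data[irec] = Ed
            out_energy[irec] = prior_state + prior_nuis + xi * Ed
            if collect_grad or record_aux:
                data_term_kernel(S1, S2, d, set_idx, sigma_b, phi_sc, N,
                                 model_flag, sem_mode, prefac, w, True)
            if collect_grad:
                theta_grad_kernel(T2, T1, w, set_idx, N, K, xi, gbuf)
                for k in range(K):
                    out_grad[irec, k, 0] = gbuf[k, 0]
                    out_grad[irec, k, 1] = gbuf[k, 1]
                    out_grad[irec, k, 2] = gbuf[k, 2]
            if record_aux:
                for j in range(n_obs):
                    out_w[irec, j] = w[j]
                for s in range(n_states):
                    out_counts[irec, s] = counts[s]
    return Ed
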