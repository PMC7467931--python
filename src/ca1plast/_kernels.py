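"""Compiled inner loops for the simulation engines.

The chunked per-step updates of both protocols are implemented as numba
kernels operating on pre-generated noise arrays; orchestration (RNG
substreams, chunking, recording layout) stays in :mod:`ca1plast.protocols`.
A pure-Python fallback keeps the package importable without numba, at a
large speed cost. Update order within a step matches the documented
contract: inputs, interneuron rates from the previous step's soma,
dendrite, soma, plasticity.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def explore_chunk(tuning, perm, xi_sc, xi_ta, mu_ta,
                  r_dend, r_soma, w_pv, w_sst, w_sc,
                  k_euler, g_gain, g_slope, thr,
                  eta_sc_dt, eta_pv_dt, eta_sst_dt,
                  norm_target, w_min, w_max,
                  exc_active, pv_active, sst_active,
                  rec_every, t_offset, rec_start,
                  rec_r_dend, rec_r_soma, rec_w_pv, rec_w_sst):
    """Advance one exploration chunk in place; returns next record index.

    ``tuning`` is (C, N) noise-free place tuning at the chunk's positions,
    ``perm`` (n, N) maps each trial's input neuron to a center index,
    ``xi_sc`` (n, C, N) and ``xi_ta`` (n, C) are OU noise samples (any float
    dtype). Trials are independent, so the loop is trial-major for cache
    locality. Interneuron rates are constant at 1 (exploration uses
    constant-rate mode); input rates are rectified at 0 after noise
    addition.
    """
    n, C, N = xi_sc.shape
    rec_i = rec_start
    for i in range(n):
        rd = r_dend[i]
        rs = r_soma[i]
        wp = w_pv[i]
        ws = w_sst[i]
        rec_i = rec_start
        for t in range(C):
            ta = mu_ta + xi_ta[i, t]
            if ta < 0.0:
                ta = 0.0
            drive = ta - ws
            if drive < 0.0:
                drive = 0.0
            rd += k_euler * (drive - rd)
            scd = 0.0
            for j in range(N):
                rate = tuning[t, perm[i, j]] + xi_sc[i, t, j]
                if rate < 0.0:
                    rate = 0.0
                scd += w_sc[i, j] * rate
            arg = rd + scd - wp
            th = math.tanh(g_slope * arg)
            if th < 0.0:
                th = 0.0
            rs += k_euler * (g_gain * th - rs)
            if exc_active:
                post = rd * rs - thr
                if post < 0.0:
                    post = 0.0
                mean = 0.0
                for j in range(N):
                    rate = tuning[t, perm[i, j]] + xi_sc[i, t, j]
                    if rate < 0.0:
                        rate = 0.0
                    w_sc[i, j] += eta_sc_dt * post * rate
                    mean += w_sc[i, j]
                mean /= N
                for j in range(N):
                    w = w_sc[i, j] - mean + norm_target
                    if w < 0.0:
                        w = 0.0
                    w_sc[i, j] = w
            if pv_active:
                wp -= eta_pv_dt * rs
                if wp < w_min:
                    wp = w_min
                elif wp > w_max:
                    wp = w_max
            if sst_active:
                ws += eta_sst_dt * rs
                if ws < w_min:
                    ws = w_min
                elif ws > w_max:
                    ws = w_max
            if (t_offset + t + 1) % rec_every == 0:
                rec_r_dend[rec_i, i] = rd
                rec_r_soma[rec_i, i] = rs
                rec_w_pv[rec_i, i] = wp
                rec_w_sst[rec_i, i] = ws
                rec_i += 1
        r_dend[i] = rd
        r_soma[i] = rs
        w_pv[i] = wp
        w_sst[i] = ws
    return rec_i


@njit(cache=True)
def io_chunk(sc_in, ta_in,
             r_dend, r_soma, w_pv, w_sst, w_sc,
             k_euler, g_gain, g_slope,
             sst_a, sst_b, sst_g, pv_a, pv_b, pv_g,
             eta_pv_dt, eta_sst_dt, w_min, w_max,
             plast_on, pv_rule, sst_rule,
             rec_every, t_offset, rec_start,
             rec_r_dend, rec_r_soma, rec_w_pv, rec_w_sst):
    """Advance one input-output chunk in place; returns next record index.

    ``sc_in``/``ta_in`` are (C, n) pre-rectified stimulation traces (zero
    for a silent pathway). Interneuron rates are the connectivity-driven
    linear combinations with the supplied effective coefficients
    (toggle * coefficient), computed from the previous step's soma and
    rectified at 0.
    """
    C, n = sc_in.shape
    rec_i = rec_start
    for t in range(C):
        for i in range(n):
            sc = sc_in[t, i]
            ta = ta_in[t, i]
            r_sst = sst_a * sc + sst_b * ta + sst_g * r_soma[i]
            if r_sst < 0.0:
                r_sst = 0.0
            r_pv = pv_a * sc + pv_b * ta + pv_g * r_soma[i]
            if r_pv < 0.0:
                r_pv = 0.0
            drive = ta - w_sst[i] * r_sst
            if drive < 0.0:
                drive = 0.0
            r_dend[i] += k_euler * (drive - r_dend[i])
            arg = r_dend[i] + w_sc * sc - w_pv[i] * r_pv
            th = math.tanh(g_slope * arg)
            if th < 0.0:
                th = 0.0
            r_soma[i] += k_euler * (g_gain * th - r_soma[i])
            if plast_on:
                if pv_rule:
                    w = w_pv[i] - eta_pv_dt * r_pv * r_soma[i]
                    if w < w_min:
                        w = w_min
                    elif w > w_max:
                        w = w_max
                    w_pv[i] = w
                if sst_rule:
                    w = w_sst[i] + eta_sst_dt * r_sst * r_soma[i]
                    if w < w_min:
                        w = w_min
                    elif w > w_max:
                        w = w_max
                    w_sst[i] = w
        if (t_offset + t + 1) % rec_every == 0:
            for i in range(n):
                rec_r_dend[rec_i, i] = r_dend[i]
                rec_r_soma[rec_i, i] = r_soma[i]
                rec_w_pv[rec_i, i] = w_pv[i]
                rec_w_sst[rec_i, i] = w_sst[i]
            rec_i += 1
    return rec_i
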