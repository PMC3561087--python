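"""Compiled right-hand-side kernels for the built-in models.

The Monte-Carlo estimators integrate the ODE systems tens of thousands of
times, so the per-evaluation cost of the right-hand side matters.  Each
kernel is compiled once per process with numba; if numba is unavailable the
pure-NumPy fallbacks below are used unchanged (they are the reference
implementations — the compiled path must match them bit-for-bit up to
floating-point evaluation order, which is identical here).
"""

from __future__ import annotations

import numpy as np


def _repressilator_core(x, t, theta, u, gene_scales):
    a0, a, b, n = theta[0], theta[1], theta[2], theta[3]
    out = np.empty(6)
    # gene i is repressed by the protein of the previous gene in the loop
    rep0, rep1, rep2 = x[5], x[3], x[4]
    out[0] = -x[0] + gene_scales[0, 1] * a / (1.0 + rep0 ** n) + gene_scales[0, 0] * a0
    out[1] = -x[1] + gene_scales[1, 1] * a / (1.0 + rep1 ** n) + gene_scales[1, 0] * a0
    out[2] = -x[2] + gene_scales[2, 1] * a / (1.0 + rep2 ** n) + gene_scales[2, 0] * a0
    out[3] = -gene_scales[0, 2] * b * (x[3] - x[0])
    out[4] = -gene_scales[1, 2] * b * (x[4] - x[1])
    out[5] = -gene_scales[2, 2] * b * (x[5] - x[2])
    return out


def _hes1_core(x, t, theta, u, kdeg):
    P0, h, k1, nu = theta[0], theta[1], theta[2], theta[3]
    m, p1, p2 = x[0], x[1], x[2]
    rep = 1.0 / (1.0 + (p2 / P0) ** h)
    out = np.empty(3)
    out[0] = -kdeg * m + rep
    out[1] = -kdeg * p1 + nu * m - k1 * p1
    out[2] = -kdeg * p2 + k1 * p1
    return out


def _akt_core(x, t, theta, u, track_rate):
    k_bind, k_phos, k_turn, k_deg = theta[0], theta[1], theta[2], theta[3]
    k_a_on, k_a_cat, k_a_off = theta[4], theta[5], theta[6]
    k_s_on, k_s_cat, k_s_off = theta[7], theta[8], theta[9]
    egf, egfr, pegfr, pegfr_akt, akt = x[0], x[1], x[2], x[3], x[4]
    pakt, s6, pakt_s6, ps6, proegfr, egf_egfr = x[5], x[6], x[7], x[8], x[9], x[10]
    bind = k_bind * egf * egfr
    phos = k_phos * egf_egfr
    a_on = k_a_on * pegfr * akt
    a_cat = k_a_cat * pegfr_akt
    s_on = k_s_on * pakt * s6
    s_cat = k_s_cat * pakt_s6
    out = np.empty(11)
    out[0] = track_rate * (u - egf) - bind          # EGF
    out[1] = k_turn * proegfr - bind                # EGFR
    out[2] = phos - k_deg * pegfr - a_on + a_cat    # pEGFR
    out[3] = a_on - a_cat                           # pEGFR-AKT
    out[4] = -a_on + k_a_off * pakt                 # AKT
    out[5] = a_cat - k_a_off * pakt - s_on + s_cat  # pAKT
    out[6] = -s_on + k_s_off * ps6                  # S6
    out[7] = s_on - s_cat                           # pAKT-S6
    out[8] = s_cat - k_s_off * ps6                  # pS6
    out[9] = -k_turn * proegfr                      # pro-EGFR
    out[10] = bind - phos                           # EGF-EGFR
    return out


try:  # compiled fast path
    from numba import njit

    repressilator_core = njit(cache=True, fastmath=False)(_repressilator_core)
    hes1_core = njit(cache=True, fastmath=False)(_hes1_core)
    akt_core = njit(cache=True, fastmath=False)(_akt_core)
except ImportError:  # pragma: no cover - numba is an optional accelerator
    repressilator_core = _repressilator_core
    hes1_core = _hes1_core
    akt_core = _akt_core
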