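"""Compiled inner loop of the explicit integrator.

The kernel advances voltage, gates, and submembrane calcium for every
compartment over many time steps.  Gates use the Rush-Larsen exponential
update (exact for frozen voltage); the voltage uses a local exponential
update in which the ionic conductances act implicitly through the local
membrane time constant while axial and external currents enter as a frozen
source term.  As the local conductance goes to zero the update degenerates
exactly to forward Euler, so pure-diffusion problems retain the explicit
scheme's conservation property.

Rate functional forms are evaluated by integer code; the codes must match
``pcseq.channels.FORM_CODES``.
"""

import math

import numba
import numpy as np


@numba.njit(inline="always", cache=True)
def _eval_form(code, p0, p1, p2, p3, v):
    if code == 0:      # constant
        return p0
    elif code == 1:    # exp
        return p0 * math.exp((v - p1) / p2)
    elif code == 2:    # sigmoid
        return p0 / (1.0 + math.exp((v - p1) / p2))
    elif code == 3:    # gauss
        d = (v - p2) / p3
        return p0 + p1 * math.exp(-d * d)
    else:              # dualexp
        return p0 / (math.exp((v - p1) / p2) + math.exp(-(v - p1) / p3))


@numba.njit(cache=True)
def integrate(v, x, ca, n_steps, dt, t0,
              parent, gax, area, ctcode, cm,
              erev, carries, gdens,
              g_start, g_count,
              gkind, gexp, gcahalf, gf,
              f1, p1, f2, p2,
              ca_rest, ca_scale, ca_tau,
              pcomp, pt0, pw, pulse_width, ramped, tau_i,
              stride, rec_idx, rec_buf, rec_row0):
    n = v.shape[0]
    n_ch = erev.shape[0]
    n_pulse = pcomp.shape[0]
    iax = np.empty(n)
    iext_arr = np.empty(n)
    row = rec_row0
    for istep in range(n_steps):
        if stride > 0 and istep % stride == 0 and row < rec_buf.shape[0]:
            for r in range(rec_idx.shape[0]):
                rec_buf[row, r] = v[rec_idx[r]]
            row += 1
        t = t0 + istep * dt
        # axial currents, nA (computed from the pre-step voltages)
        for i in range(n):
            iax[i] = 0.0
            iext_arr[i] = 0.0
        for i in range(n):
            p = parent[i]
            if p >= 0:
                cur = gax[i] * (v[p] - v[i])
                iax[i] += cur
                iax[p] -= cur
        for q in range(n_pulse):
            tt = t - pt0[q]
            if 0.0 <= tt < pulse_width:
                if ramped:
                    iext_arr[pcomp[q]] += pw[q] * (1.0 - math.exp(-tt / tau_i))
                else:
                    iext_arr[pcomp[q]] += pw[q]
        # membrane update
        for i in range(n):
            ct = ctcode[i]
            gloc = 0.0
            g_e = 0.0
            i_ca = 0.0
            for k in range(n_ch):
                gk = gdens[ct, k]
                if gk == 0.0:
                    continue
                open_frac = 1.0
                for gs in range(g_start[k], g_start[k] + g_count[k]):
                    if gkind[gs] == 0:  # alpha-beta
                        a = _eval_form(f1[gs], p1[gs, 0], p1[gs, 1], p1[gs, 2], p1[gs, 3], v[i])
                        b = _eval_form(f2[gs], p2[gs, 0], p2[gs, 1], p2[gs, 2], p2[gs, 3], v[i])
                        xinf = a / (a + b)
                        tau = gf[gs] / (a + b)
                    else:               # direct
                        xinf = _eval_form(f1[gs], p1[gs, 0], p1[gs, 1], p1[gs, 2], p1[gs, 3], v[i])
                        if gcahalf[gs] > 0.0:
                            xinf *= ca[i] / (ca[i] + gcahalf[gs])
                        tau = gf[gs] * _eval_form(f2[gs], p2[gs, 0], p2[gs, 1],
                                                  p2[gs, 2], p2[gs, 3], v[i])
                    xn = xinf + (x[i, gs] - xinf) * math.exp(-dt / tau)
                    if xn < 0.0:
                        xn = 0.0
                    elif xn > 1.0:
                        xn = 1.0
                    x[i, gs] = xn
                    for _ in range(gexp[gs]):
                        open_frac *= xn
                g_open = gk * open_frac
                gloc += g_open
                g_e += g_open * erev[k]
                if carries[k]:
                    i_ca += g_open * (v[i] - erev[k])
            i_other = (iax[i] + iext_arr[i]) * 1.0e-3 / area[i]   # uA/cm^2
            i_total = -(gloc * v[i] - g_e) + i_other              # uA/cm^2
            xfac = gloc * dt / cm[i]
            if xfac > 1.0e-9:
                phi = (1.0 - math.exp(-xfac)) / xfac
            else:
                phi = 1.0 - 0.5 * xfac
            v[i] = v[i] + phi * dt * i_total / cm[i]
            # calcium shell (inward Ca current is negative -> raises [Ca])
            target = ca_rest - ca_scale * ca_tau * i_ca
            can = target + (ca[i] - target) * math.exp(-dt / ca_tau)
            ca[i] = can if can > 0.0 else 0.0
    return row
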