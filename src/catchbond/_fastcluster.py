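"""Compiled inner loop for cluster simulations.

Semantics mirror :mod:`catchbond.cluster`'s reference Python stepper
(`_advance`): quasi-static tridiagonal fiber mechanics (affine in the
applied force for a fixed bond topology), Bernoulli event sampling per
adaptive step, receptor state memory, and reference-lattice rebinding with
velocity suppression.  Only constant and single-sinusoid force protocols are
supported, which covers every cluster load used in practice.

The random stream is numba's MT19937 seeded per run; results are
bit-reproducible for a fixed (parameters, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

EXP_CAP = 700.0


@njit(cache=True)
def _thomas(diag, off, rhs):
    """Solve a symmetric tridiagonal system (off = constant off-diagonal)."""
    n = diag.shape[0]
    cp = np.empty(n)
    dp = np.empty(n)
    cp[0] = off / diag[0]
    dp[0] = rhs[0] / diag[0]
    for i in range(1, n):
        m = diag[i] - off * cp[i - 1]
        cp[i] = off / m
        dp[i] = (rhs[i] - off * dp[i - 1]) / m
    x = np.empty(n)
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]
    return x


@njit(cache=True)
def _bexp(x):
    if x > EXP_CAP:
        x = EXP_CAP
    return np.exp(x)


@njit(cache=True)
def run_cluster(
    n, N, l0, EA, kLR, k0_reb, v0, lbind, kBT, W,
    # model: rupture and switch Bell parameters per state (1-indexed by s-1)
    k0_rup1, Fb_rup1, k0_rup2, Fb_rup2, k0_sw1, Fb_sw1, k0_sw2, Fb_sw2,
    # protocol: F(t) = Fmean + amp*sin(omega*t + phase); amp=0 -> constant
    Fmean, amp, omega, phase,
    dt_base, dt_floor, event_cap, max_time, seed,
):
    np.random.seed(seed)
    ke = EA / l0

    bound = np.ones(n, dtype=np.bool_)
    lig_of = np.arange(n)
    state = np.ones(n, dtype=np.int8)
    lig_free = np.zeros(N, dtype=np.bool_)
    for j in range(n, N):
        lig_free[j] = True

    diag = np.empty(n)
    w = np.zeros(n)
    c = np.zeros(n)
    e_last = np.zeros(n)
    e_last[n - 1] = 1.0
    anchor = np.zeros(n)
    u_prev = np.zeros(n)
    dt_prev = -1.0
    topo_dirty = True

    t = 0.0
    n_steps = 0
    n_bound = n

    while t < max_time:
        if n_bound == 0:
            return t, False, n_steps
        if topo_dirty:
            for i in range(n):
                diag[i] = 0.0
                if i > 0:
                    diag[i] += ke
                if i < n - 1:
                    diag[i] += ke
                if bound[i]:
                    diag[i] += kLR
                anchor[i] = kLR * (lig_of[i] - i) * l0 if bound[i] else 0.0
            w = _thomas(diag, -ke, e_last)
            c = _thomas(diag, -ke, anchor)
            topo_dirty = False

        F_now = Fmean + amp * np.sin(omega * t + phase) if amp != 0.0 else Fmean
        u = F_now * w + c

        # rates
        max_rate = 0.0
        rup = np.zeros(n)
        sw = np.zeros(n)
        reb_tot = np.zeros(n)
        for i in range(n):
            if bound[i]:
                stretch = abs(u[i] - (lig_of[i] - i) * l0)
                Fi = kLR * stretch
                if state[i] == 1:
                    rup[i] = k0_rup1 * _bexp(Fi / Fb_rup1)
                    sw[i] = k0_sw1 * _bexp(Fi / Fb_sw1) if k0_sw1 > 0.0 else 0.0
                else:
                    rup[i] = k0_rup2 * _bexp(Fi / Fb_rup2)
                    sw[i] = k0_sw2 * _bexp(Fi / Fb_sw2) if k0_sw2 > 0.0 else 0.0
                tot = rup[i] + sw[i]
                if tot > max_rate:
                    max_rate = tot
            else:
                vi = 0.0 if dt_prev <= 0.0 else (u[i] - u_prev[i]) / dt_prev
                vfac = v0 / (v0 + abs(vi))
                tot = 0.0
                jlo = i - W if i - W > 0 else 0
                jhi = i + W + 1 if i + W + 1 < N else N
                for j in range(jlo, jhi):
                    if lig_free[j]:
                        slack = abs(i - j) * l0 - lbind
                        if slack < 0.0:
                            slack = 0.0
                        x = kLR * slack * slack / (2.0 * kBT)
                        if x < EXP_CAP:
                            tot += k0_reb * vfac * np.exp(-x)
                reb_tot[i] = tot
                if tot > max_rate:
                    max_rate = tot

        dt = dt_base
        if max_rate > 0.0 and event_cap / max_rate < dt:
            dt = event_cap / max_rate
        if dt < dt_floor:
            dt = dt_floor

        # closed-bond events
        for i in range(n):
            if bound[i]:
                tot = rup[i] + sw[i]
                if tot > 0.0 and np.random.random() < -np.expm1(-tot * dt):
                    if np.random.random() * tot < rup[i]:
                        bound[i] = False
                        lig_free[lig_of[i]] = True
                        n_bound -= 1
                        topo_dirty = True
                    else:
                        state[i] = 3 - state[i]

        # rebinding in random receptor order, ligand exclusivity enforced
        order = np.empty(n, dtype=np.int64)
        m = 0
        for i in range(n):
            if not bound[i] and reb_tot[i] > 0.0:
                order[m] = i
                m += 1
        for k in range(m - 1, 0, -1):
            r = np.random.randint(0, k + 1)
            tmp = order[k]; order[k] = order[r]; order[r] = tmp
        for kk in range(m):
            i = order[kk]
            vi = 0.0 if dt_prev <= 0.0 else (u[i] - u_prev[i]) / dt_prev
            vfac = v0 / (v0 + abs(vi))
            # recompute candidate rates against currently free ligands
            tot = 0.0
            jlo = i - W if i - W > 0 else 0
            jhi = i + W + 1 if i + W + 1 < N else N
            for j in range(jlo, jhi):
                if lig_free[j]:
                    slack = abs(i - j) * l0 - lbind
                    if slack < 0.0:
                        slack = 0.0
                    x = kLR * slack * slack / (2.0 * kBT)
                    if x < EXP_CAP:
                        tot += k0_reb * vfac * np.exp(-x)
            if tot <= 0.0:
                continue
            if np.random.random() < -np.expm1(-tot * dt):
                pick = np.random.random() * tot
                acc = 0.0
                for j in range(jlo, jhi):
                    if lig_free[j]:
                        slack = abs(i - j) * l0 - lbind
                        if slack < 0.0:
                            slack = 0.0
                        x = kLR * slack * slack / (2.0 * kBT)
                        if x < EXP_CAP:
                            acc += k0_reb * vfac * np.exp(-x)
                        if pick <= acc:
                            bound[i] = True
                            lig_of[i] = j
                            lig_free[j] = False
                            n_bound += 1
                            topo_dirty = True
                            break

        t += dt
        for i in range(n):
            u_prev[i] = u[i]
        dt_prev = dt
        n_steps += 1

    return max_time, True, n_steps
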