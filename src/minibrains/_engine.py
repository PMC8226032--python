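"""Compiled inner loop of the simulation engine.

A single numba kernel advances a flat batch of embodied agents through all
Euler steps of a trial; `experiments.simulate_batch` prepares the batched
arrays and reshapes the results.  The kernel is strict IEEE (no fastmath),
single-threaded, and allocation-free inside the time loop, so simulations
are bit-reproducible.  The test suite cross-checks its trajectories against
the step-by-step composition of the public layer operations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def step_loop(n_steps, dt, coupled,
              w_rec, w_sens, w_act, dt_over_tau, theta, gain, sg, sb, ab,
              poses, radius, off0, off1, occ, dmin, inv_square, hard_shadow,
              rec_y, rec_out, rec_sens, rec_act, rec_int, rec_pose, full):
    F = w_rec.shape[0]
    A = w_rec.shape[1]
    n = w_rec.shape[2]

    y = np.zeros((F, A, n))
    out = np.empty((F, A, n))
    act = np.empty((F, A, 3))
    emit = np.empty((F, A))
    sens = np.empty((F, A, 2))
    inten = np.zeros((F, A, 2))
    newy = np.empty(n)

    # initial state: y = 0, emitter from the initial actuator outputs
    for f in range(F):
        for a in range(A):
            for i in range(n):
                out[f, a, i] = 1.0 / (1.0 + math.exp(-gain[f, a, i] * theta[f, a, i]))
            for o in range(3):
                s = ab[f, a]
                for i in range(n):
                    s += w_act[f, a, i, o] * out[f, a, i]
                act[f, a, o] = 1.0 / (1.0 + math.exp(-s))
            emit[f, a] = act[f, a, 2]

    for t in range(n_steps):
        for f in range(F):
            # 1. sensing from the previous step's poses and emitters
            #    (synchronous for both agents)
            if coupled:
                for a in range(A):
                    b = 1 - a
                    px = poses[f, a, 0]
                    py = poses[f, a, 1]
                    phi = poses[f, a, 2]
                    qx = poses[f, b, 0]
                    qy = poses[f, b, 1]
                    for k in range(2):
                        ang = phi + (off0 if k == 0 else off1)
                        ca = math.cos(ang)
                        sa = math.sin(ang)
                        dx = qx - (px + radius * ca)
                        dy = qy - (py + radius * sa)
                        d = math.sqrt(dx * dx + dy * dy)
                        if d > 0.0:
                            cpsi = (dx * ca + dy * sa) / d
                        else:
                            cpsi = 1.0
                        if hard_shadow:
                            shade = 1.0 if cpsi >= 0.0 else occ
                        else:
                            shade = 0.5 * (1.0 + cpsi)
                        de = d if d > dmin else dmin
                        att = 1.0 / (de * de) if inv_square else 1.0 / de
                        inten[f, a, k] = emit[f, b] * att * shade
            for a in range(A):
                # 2. sensor nodes
                for k in range(2):
                    sens[f, a, k] = 1.0 / (1.0 + math.exp(
                        -(sg[f, a] * inten[f, a, k] + sb[f, a])))
                # 3. CTRNN Euler step (recurrent drive from previous outputs)
                for i in range(n):
                    drive = 0.0
                    for j in range(n):
                        drive += w_rec[f, a, j, i] * out[f, a, j]
                    for k in range(2):
                        drive += w_sens[f, a, k, i] * sens[f, a, k]
                    newy[i] = y[f, a, i] + dt_over_tau[f, a, i] * (
                        -y[f, a, i] + drive)
                for i in range(n):
                    y[f, a, i] = newy[i]
                    out[f, a, i] = 1.0 / (1.0 + math.exp(
                        -gain[f, a, i] * (newy[i] + theta[f, a, i])))
                # 4. actuator nodes
                for o in range(3):
                    s = ab[f, a]
                    for i in range(n):
                        s += w_act[f, a, i, o] * out[f, a, i]
                    act[f, a, o] = 1.0 / (1.0 + math.exp(-s))
                # 5. move body (translate along current heading, then turn)
                v = 0.5 * (act[f, a, 0] + act[f, a, 1])
                om = (act[f, a, 1] - act[f, a, 0]) / radius
                phi = poses[f, a, 2]
                poses[f, a, 0] += v * math.cos(phi) * dt
                poses[f, a, 1] += v * math.sin(phi) * dt
                poses[f, a, 2] = phi + om * dt
                emit[f, a] = act[f, a, 2]

                for i in range(n):
                    rec_y[t, f, a, i] = y[f, a, i]
                    rec_out[t, f, a, i] = out[f, a, i]
                if full:
                    for k in range(2):
                        rec_sens[t, f, a, k] = sens[f, a, k]
                        rec_int[t, f, a, k] = inten[f, a, k]
                    for o in range(3):
                        rec_act[t, f, a, o] = act[f, a, o]
                        rec_pose[t, f, a, o] = poses[f, a, o]
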