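"""Optional numba-compiled Euler kernel.

Mirrors :func:`skewadapt.circuit.step` operation for operation (derivatives
from the pre-step state, element-wise clipping with overshoot tracking) so
the fast and reference paths produce the same trajectories; a unit test
asserts the agreement.  Falls back silently when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def euler_run(
    v1,
    vmt,
    yff,
    yfb,
    kernel,
    k_r,
    n_steps,
    dt,
    tau,
    tau_syn,
    lam,
    alpha_ff,
    beta_ff,
    alpha_fb,
    beta_fb,
):
    n = v1.size
    acc1 = np.zeros(n)
    accmt = np.zeros(n)
    over = 0.0
    for _ in range(n_steps):
        rect1 = np.maximum(v1, 0.0)
        rectmt = np.maximum(vmt, 0.0)
        i_mod = yfb * rectmt
        i_ex_v1 = k_r * (1.0 + lam * i_mod)
        i_inh_v1 = i_ex_v1.sum() / n
        i_ex_mt = yff * np.dot(kernel, rect1)
        i_inh_mt = i_ex_mt.sum() / n

        v1 = v1 + (dt / tau) * (
            -v1 + (1.0 - v1) * i_ex_v1 - (1.0 + v1) * i_inh_v1
        )
        vmt = vmt + (dt / tau) * (
            -vmt + (1.0 - vmt) * i_ex_mt - (1.0 + vmt) * i_inh_mt
        )
        yff = yff + (dt / tau_syn) * (alpha_ff * (1.0 - yff) - beta_ff * yff * rect1)
        yfb = yfb + (dt / tau_syn) * (alpha_fb * (1.0 - yfb) - beta_fb * yfb * rectmt)

        for i in range(n):
            if v1[i] > 1.0:
                over = max(over, v1[i] - 1.0)
                v1[i] = 1.0
            elif v1[i] < -1.0:
                over = max(over, -1.0 - v1[i])
                v1[i] = -1.0
            if vmt[i] > 1.0:
                over = max(over, vmt[i] - 1.0)
                vmt[i] = 1.0
            elif vmt[i] < -1.0:
                over = max(over, -1.0 - vmt[i])
                vmt[i] = -1.0
            if yff[i] > 1.0:
                over = max(over, yff[i] - 1.0)
                yff[i] = 1.0
            elif yff[i] < 0.0:
                over = max(over, -yff[i])
                yff[i] = 0.0
            if yfb[i] > 1.0:
                over = max(over, yfb[i] - 1.0)
                yfb[i] = 1.0
            elif yfb[i] < 0.0:
                over = max(over, -yfb[i])
                yfb[i] = 0.0
            acc1[i] += max(v1[i], 0.0)
            accmt[i] += max(vmt[i], 0.0)
    return v1, vmt, yff, yfb, acc1, accmt, over
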