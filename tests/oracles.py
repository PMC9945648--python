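"""Independent fine-step reference integrators used only as oracles.

These deliberately share no code with the package's propagators: plain
explicit RK4 at a fixed small step, vectorized over parameter draws.
"""

import numpy as np


def rk4_tcm(ve, vp, Fp_per_min, PS_per_min, t_grid, Ca_grid, dt=1e-3):
    """Fine-step RK4 integration of the two-compartment exchange ODEs.

    Parameters may be scalars or arrays of shape (m,) for m simultaneous
    draws; the AIF (piecewise linear on ``t_grid``) is shared.  Returns
    ``(Cp, Ce)`` of shape (m, len(t_grid)).
    """
    ve = np.atleast_1d(np.asarray(ve, dtype=float))
    vp = np.atleast_1d(np.asarray(vp, dtype=float))
    Fp = np.atleast_1d(np.asarray(Fp_per_min, dtype=float)) / 60.0
    PS = np.atleast_1d(np.asarray(PS_per_min, dtype=float)) / 60.0
    m = ve.size
    tf = np.arange(t_grid[0], t_grid[-1] + dt / 2, dt)
    Caf = np.interp(tf, t_grid, Ca_grid)

    def rhs(y, Ca):
        Cp, Ce = y[:, 0], y[:, 1]
        return np.stack(
            [(Fp * (Ca - Cp) - PS * (Cp - Ce)) / vp, PS * (Cp - Ce) / ve], axis=1
        )

    y = np.zeros((m, 2))
    out = np.zeros((m, t_grid.size, 2))
    grid_idx = np.searchsorted(tf, t_grid)
    nxt = int(grid_idx[0] == 0)
    for k in range(tf.size - 1):
        Ca0, Ca1 = Caf[k], Caf[k + 1]
        Cam = 0.5 * (Ca0 + Ca1)
        k1 = rhs(y, Ca0)
        k2 = rhs(y + dt / 2 * k1, Cam)
        k3 = rhs(y + dt / 2 * k2, Cam)
        k4 = rhs(y + dt * k3, Ca1)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        while nxt < t_grid.size and k + 1 == grid_idx[nxt]:
            out[:, nxt] = y
            nxt += 1
    return out[..., 0], out[..., 1]


def rk4_three_pool(A, Meq, M0_init, t_end, dt=1e-4):
    """RK4 integration of dM/dt = A (M - M_eq) for stacked systems.

    ``A``: (m, 3, 3), ``Meq``/``M0_init``: (m, 3).  Returns M(t_end).
    """
    M = np.array(M0_init, dtype=float)
    n = int(round(t_end / dt))

    def rhs(M):
        return np.einsum("mij,mj->mi", A, M - Meq)

    for _ in range(n):
        k1 = rhs(M)
        k2 = rhs(M + dt / 2 * k1)
        k3 = rhs(M + dt / 2 * k2)
        k4 = rhs(M + dt * k3)
        M = M + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return M
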