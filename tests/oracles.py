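"""Independent numerical oracles used only by the tests.

The package computes the internal radii from monotone algebraic equations.
These helpers recompute them by a genuinely different route: a conservative
finite-volume solve of the steady nutrient diffusion problem on a fixed
grid, with the free necrotic boundary located by bisection on the outer
problem.  Nothing here imports the package's solvers.
"""

import numpy as np
from scipy.linalg import solve_banded


def solve_deficit_fd(n_core: float, n_grid: int = 20001):
    """Finite-volume solution of the scaled deficit profile v(x) on [0, 1].

    v = u / Ro^2, x = r / Ro.  Conservative discretisation of
    d/dx (x^2 dv/dx) = -6 x^2 outside the core of radius ``n_core`` (zero
    source inside), with v(1) = 0 and zero flux at the centre; the source
    is cell-averaged exactly so partially consuming cells are second-order
    accurate.  Returns (x, v) arrays.
    """
    h = 1.0 / (n_grid - 1)
    x = np.linspace(0.0, 1.0, n_grid)
    face = (x[:-1] + h / 2.0) ** 2 / h      # x_{j+1/2}^2 / h, j = 0..N-1

    N = n_grid - 1                           # unknowns v_0 .. v_{N-1}
    fl = np.concatenate(([0.0], face[:-1]))  # zero flux at the centre
    fr = face
    ab = np.zeros((3, N))
    ab[1, :] = -(fl + fr) / h
    ab[2, :-1] = fl[1:] / h                  # sub-diagonal
    ab[0, 1:] = fr[:-1] / h                  # super-diagonal

    lo = np.maximum(x[:N] - h / 2.0, 0.0)
    hi = np.minimum(x[:N] + h / 2.0, 1.0)
    a = np.maximum(lo, n_core)
    rhs = np.where(hi > a, -(2.0 * (hi ** 3 - a ** 3)) / h, 0.0)

    v = np.append(solve_banded((1, 1), ab, rhs), 0.0)
    return x, v


def internal_radii_fd(Ro: float, Rc: float, Q: float,
                      n_grid: int = 20001) -> tuple[float, float]:
    """(Ri, Rn) located on the finite-volume nutrient profile.

    The necrotic boundary n solves v_n(n) = (Rc/Ro)^2, where v_n is the FD
    profile computed with core size n; the residual is monotone in n, so
    bisection converges.  The inhibited boundary is where the converged
    profile crosses Q^2 (Rc/Ro)^2.
    """
    B = (Rc / Ro) ** 2
    if B >= 1.0:
        n = 0.0
        x, v = solve_deficit_fd(0.0, n_grid)
    else:
        a, b = 0.0, 1.0 - 1e-6
        for _ in range(50):
            m = 0.5 * (a + b)
            x, v = solve_deficit_fd(m, n_grid)
            if np.interp(m, x, v) > B:
                a = m
            else:
                b = m
        n = 0.5 * (a + b)
        x, v = solve_deficit_fd(n, n_grid)

    target = Q * Q * B
    if v[0] <= target:
        ri = 0.0
    else:
        lo, hi = n, 1.0
        for _ in range(60):
            m = 0.5 * (lo + hi)
            if np.interp(m, x, v) > target:
                lo = m
            else:
                hi = m
        ri = 0.5 * (lo + hi)
    return ri * Ro, n * Ro
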