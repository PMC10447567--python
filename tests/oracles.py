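"""Independent oracles shared between test modules.

These deliberately avoid the package's assembled right-hand side: the cosh
oracle drives only the diffusion operator against a closed-form
reaction–diffusion solution.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

import biofilmhp as bh
from biofilmhp.grid import BiofilmGrid
from biofilmhp.solver import solute_diffusion


def cosh_oracle_max_rel_error(Nz: int) -> float:
    """Steady first-order solute consumption versus the analytic profile.

    D*S'' = k*S on [0, Lf] with a no-flux base and boundary-layer flux
    matching at the surface has the solution S(z) = C*cosh(z/lam),
    lam = sqrt(D/k), with C fixed by
    D*C*sinh(Lf/lam)/lam = D_aq*(S_t - C*cosh(Lf/lam))/L_L.
    Returns the max relative error of the discrete steady profile.
    """
    p = bh.ModelParameters().replace(Nz=Nz)
    g = BiofilmGrid(Nz)
    Lf, S_t_val, k = 150e-6, 100.0, 14444.0  # lam ~ 30 um: resolved at Nz=50
    D, D_aq = p.D_b_G, p.D_aq_G
    S_t = np.array([S_t_val, 0.0])

    def rhs(t, y):
        S_b = np.vstack([y, np.zeros_like(y)])
        term, _, _ = solute_diffusion(S_b, S_t, Lf, p, g)
        return term[0] - k * y

    sol = solve_ivp(rhs, (0.0, 5.0), np.zeros(Nz), method="BDF",
                    rtol=1e-10, atol=1e-12)
    numeric = sol.y[:, -1]

    lam = np.sqrt(D / k)
    z = g.z_centers(Lf)
    C = (D_aq * S_t_val / p.L_L) / (
        D * np.sinh(Lf / lam) / lam + D_aq * np.cosh(Lf / lam) / p.L_L)
    analytic = C * np.cosh(z / lam)
    return float(np.max(np.abs(numeric - analytic)) / analytic.max())
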