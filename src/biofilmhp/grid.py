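"""Normalized grid over the moving biofilm domain.

The biofilm occupies 0 <= z <= Lf(t).  The PDEs are solved on the fixed
normalized coordinate zeta = z/Lf with ``Nz`` uniform cells, which keeps the
system size constant while the thickness evolves; chain-rule factors (1/Lf,
1/Lf^2) and a grid-motion flux proportional to zeta*dLf/dt account for the
moving boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BiofilmGrid:
    """Uniform cell-centered grid on zeta = z/Lf in [0, 1].

    zeta = 0 is the substratum (base of the film); zeta = 1 is the
    biofilm–liquid interface.
    """

    Nz: int
    zeta_centers: np.ndarray = field(init=False, repr=False)
    zeta_faces: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.Nz < 2:
            raise ValueError(f"Nz must be >= 2, got {self.Nz}")
        object.__setattr__(self, "zeta_faces", np.linspace(0.0, 1.0, self.Nz + 1))
        object.__setattr__(
            self, "zeta_centers", (np.arange(self.Nz) + 0.5) / self.Nz
        )

    @property
    def dzeta(self) -> float:
        return 1.0 / self.Nz

    def z_centers(self, Lf: float) -> np.ndarray:
        """Physical cell-center depths z = zeta*Lf (m), base to surface."""
        return self.zeta_centers * Lf

    def dz(self, Lf: float) -> float:
        """Physical cell width Lf/Nz (m)."""
        return Lf / self.Nz
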