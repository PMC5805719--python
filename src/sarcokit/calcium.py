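"""Free-calcium chemistry of EGTA-buffered physiological solutions.

Skinned-fiber and motility experiments set [Ca2+] by mixing an activating
solution (Ca-loaded EGTA) with a relaxing solution (Ca-free EGTA) in varying
volume ratios.  The free-calcium concentration of each mixture follows from
the 1:1 Ca:EGTA binding equilibrium with a single apparent dissociation
constant at fixed pH and ionic strength:

    free + total_egta * free / (free + kd_app) = total_ca

The default ``kd_app`` of 5e-8 M makes an equimolar 20 mM Ca-EGTA / 20 mM
EGTA activating solution come out at pCa 4.50, the conventional label for a
maximally activating solution.  Results are reported as pCa = -log10[Ca2+].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidSpecificationError

__all__ = [
    "SolutionSpec",
    "free_calcium",
    "pca_of",
    "mixing_series",
    "DEFAULT_KD_APP",
    "PCA_CAP",
]

#: apparent Ca-EGTA dissociation constant, M (pH 7.0, ~0.18 M ionic strength)
DEFAULT_KD_APP = 5e-8
#: pCa reported for a solution with no free calcium
PCA_CAP = 12.0


@dataclass(frozen=True)
class SolutionSpec:
    """Total composition of one EGTA-buffered solution (concentrations in M)."""

    total_ca: float
    total_egta: float
    kd_app: float = DEFAULT_KD_APP

    def __post_init__(self):
        if self.total_ca < 0 or self.total_egta < 0:
            raise InvalidSpecificationError("total concentrations must be >= 0")
        if self.kd_app <= 0:
            raise InvalidSpecificationError("kd_app must be > 0")


def free_calcium(sol: SolutionSpec) -> float:
    """Free [Ca2+] (M) of a solution, from the 1:1 binding equilibrium.

    Solved by bracketed root finding on [0, total_ca]; the bound-calcium
    term is monotone in free Ca so the root is unique.
    """
    ca_t, egta_t, kd = sol.total_ca, sol.total_egta, sol.kd_app
    if ca_t == 0.0:
        return 0.0
    if egta_t == 0.0:
        return ca_t

    def residual(free):
        return free + egta_t * free / (free + kd) - ca_t

    # residual(0) = -ca_t < 0, residual(ca_t) >= 0: bracket always valid
    return float(brentq(residual, 0.0, ca_t, xtol=1e-24, rtol=8.9e-16))


def pca_of(free_ca: float, cap: float = PCA_CAP) -> float:
    """pCa = -log10(free [Ca2+] in M); zero maps to the configured cap."""
    if free_ca < 0:
        raise InvalidSpecificationError("free calcium must be >= 0")
    if free_ca == 0:
        return cap
    return float(min(-np.log10(free_ca), cap))


def mixing_series(
    activating: SolutionSpec,
    relaxing: SolutionSpec,
    volume_fractions: Sequence[float],
    cap: float = PCA_CAP,
) -> list[float]:
    """pCa of volumetric activating/relaxing mixtures.

    ``volume_fractions`` are the fractions of activating solution; totals
    combine linearly by volume.  Both stocks must share ``kd_app``.
    """
    if activating.kd_app != relaxing.kd_app:
        raise InvalidSpecificationError("stock solutions must share kd_app")
    fracs = np.asarray(volume_fractions, dtype=float)
    if np.any((fracs < 0) | (fracs > 1)):
        raise InvalidSpecificationError("volume fractions must lie in [0, 1]")
    out = []
    for f in fracs:
        mix = SolutionSpec(
            total_ca=f * activating.total_ca + (1 - f) * relaxing.total_ca,
            total_egta=f * activating.total_egta + (1 - f) * relaxing.total_egta,
            kd_app=activating.kd_app,
        )
        out.append(pca_of(free_calcium(mix), cap=cap))
    return out
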