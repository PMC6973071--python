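"""Furanose ring pseudorotation analysis.

Endocyclic torsions are indexed

    nu0 = C4'-O4'-C1'-C2'
    nu1 = O4'-C1'-C2'-C3'
    nu2 = C1'-C2'-C3'-C4'
    nu3 = C2'-C3'-C4'-O4'
    nu4 = C3'-C4'-O4'-C1'

and the phase/amplitude pair (P, tau_m) follows the cosine model

    nu_j = tau_m * cos(P + 144 deg * (j - 2)),

so P = 0 has nu2 maximal.  Getting the index order or a sign wrong shifts
P by multiples of 72 degrees -- the torsion order above is therefore the
single source of truth for this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._geometry import dihedral

__all__ = [
    "FiveTorsions",
    "SugarPucker",
    "RING_ATOMS",
    "ring_torsions",
    "pseudorotation",
    "torsions_from_pucker",
    "classify_pucker",
]

#: furanose ring atoms in ring order (O4' first)
RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")

#: atom quadruples defining nu0..nu4
TORSION_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),
    ("O4'", "C1'", "C2'", "C3'"),
    ("C1'", "C2'", "C3'", "C4'"),
    ("C2'", "C3'", "C4'", "O4'"),
    ("C3'", "C4'", "O4'", "C1'"),
)

#: below this amplitude the phase angle is numerically unstable
NEAR_PLANAR_TAU_M = 5.0

_OCTANTS = (
    "north",
    "north-east",
    "east",
    "south-east",
    "south",
    "south-west",
    "west",
    "north-west",
)

# envelope labels every 36 deg starting at P = 18 (C3'-endo); the twist
# bins between adjacent envelopes carry both names
_ENVELOPES = (
    "C3'-endo",
    "C4'-exo",
    "O4'-endo",
    "C1'-exo",
    "C2'-endo",
    "C3'-exo",
    "C4'-endo",
    "O4'-exo",
    "C1'-endo",
    "C2'-exo",
)


@dataclass(frozen=True)
class FiveTorsions:
    """Endocyclic torsions nu0..nu4, degrees, each in (-180, 180]."""

    nu: tuple[float, float, float, float, float]

    def __post_init__(self):
        if len(self.nu) != 5:
            raise ValueError("exactly five torsions required")
        for v in self.nu:
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"torsion {v} outside (-180, 180]")


@dataclass(frozen=True)
class SugarPucker:
    """Pseudorotation phase/amplitude with domain labels.

    ``P`` is in [0, 360); ``p_defined`` is False for near-planar rings
    (tau_m < 5 deg) where the phase is numerically meaningless.
    """

    P: float
    tau_m: float
    octant: str
    canonical: str
    p_defined: bool = True


def ring_torsions(residue) -> FiveTorsions:
    """Compute nu0..nu4 from a residue's ring-atom coordinates.

    ``residue`` must expose ``atoms[name].xyz`` for all five ring atoms.
    """
    missing = [n for n in RING_ATOMS if n not in residue.atoms]
    if missing:
        raise ValueError(
            f"residue {getattr(residue, 'seq_index', '?')} missing ring atoms: {missing}"
        )
    coords = {n: residue.atoms[n].xyz for n in RING_ATOMS}
    nu = tuple(dihedral(*(coords[a] for a in quad)) for quad in TORSION_ATOMS)
    return FiveTorsions(nu=nu)


def pseudorotation(t: FiveTorsions) -> SugarPucker:
    """Invert the cosine model: Altona-Sundaralingam phase and amplitude.

    tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72)),
    tau_m = nu2 / cos P, with P shifted by 180 deg when nu2 < 0 and
    mapped to [0, 360).
    """
    nu0, nu1, nu2, nu3, nu4 = t.nu
    if all(abs(v) < 1e-12 for v in t.nu):
        raise ValueError("all torsions are zero: pucker undefined for a planar ring")
    denom = 2.0 * nu2 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    numer = (nu4 + nu1) - (nu3 + nu0)
    if abs(nu2) < 1e-12:
        # cos P = 0 exactly: P is +/-90 by the sign of the numerator
        P = 90.0 if numer > 0 else 270.0
        tau_m = abs(numer) / (
            2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
        )
    else:
        P = math.degrees(math.atan(numer / denom))
        if nu2 < 0.0:
            P += 180.0
        P %= 360.0
        tau_m = nu2 / math.cos(math.radians(P))
    octant, canonical = classify_pucker(P)
    defined = tau_m >= NEAR_PLANAR_TAU_M
    return SugarPucker(
        P=P, tau_m=tau_m, octant=octant, canonical=canonical, p_defined=defined
    )


def torsions_from_pucker(P: float, tau_m: float) -> FiveTorsions:
    """Forward cosine model nu_j = tau_m * cos(P + 144 deg * (j - 2))."""
    if tau_m < 0:
        raise ValueError("tau_m must be >= 0")
    nu = tuple(
        tau_m * math.cos(math.radians(P + 144.0 * (j - 2))) for j in range(5)
    )
    return FiveTorsions(nu=nu)


def classify_pucker(P: float) -> tuple[str, str]:
    """Octant (45-deg bins centred on N = 0 deg) and the nearest of the 20
    standard 18-deg envelope/twist bins.  Bins are left-closed."""
    if not (0.0 <= P < 360.0):
        raise ValueError("P must be in [0, 360)")
    octant = _OCTANTS[int(((P + 22.5) % 360.0) // 45.0)]
    bin18 = int(((P + 9.0) % 360.0) // 18.0)  # 0 at P=0, 1 at P=18, ...
    if bin18 % 2 == 1:  # envelope bins are centred at odd multiples of 18
        canonical = _ENVELOPES[bin18 // 2]
    else:
        prev_env = _ENVELOPES[(bin18 // 2 - 1) % 10]
        next_env = _ENVELOPES[bin18 // 2]
        canonical = f"{prev_env}/{next_env}"
    return octant, canonical
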