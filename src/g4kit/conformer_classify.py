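"""Glycosidic torsion classification, base-plane geometry and
pseudo-hydrogen-bond screening.

chi is defined O4'-C1'-N9-C4 for purines and O4'-C1'-N1-C2 for
pyrimidines.  Default class ranges (degrees, config-overridable):

    syn        chi in [0, +90]
    high-anti  chi in [-90, 0)
    anti       chi in [-180, -90) and (+90, +180]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._geometry import bond_angle, dihedral, fit_plane

__all__ = [
    "GlycosidicConf",
    "BasePlane",
    "ChiRanges",
    "glycosidic_chi",
    "classify_chi",
    "base_plane",
    "detect_pseudo_hbonds",
    "PURINE_SIX_RING",
]

PURINES = ("G", "A")
PURINE_SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PYRIMIDINE_SIX_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


@dataclass(frozen=True)
class GlycosidicConf:
    chi: float  # degrees in (-180, 180]
    cls: str  # syn | anti | high-anti


@dataclass(frozen=True)
class BasePlane:
    centroid6: tuple[float, float, float]
    normal: tuple[float, float, float]
    max_residual: float


@dataclass(frozen=True)
class ChiRanges:
    """Boundaries of the syn window and the high-anti window."""

    syn_lo: float = 0.0
    syn_hi: float = 90.0
    high_anti_lo: float = -90.0


def classify_chi(chi: float, ranges: ChiRanges | None = None) -> str:
    if ranges is None:
        ranges = ChiRanges()
    if not (-180.0 < chi <= 180.0):
        raise ValueError("chi must be in (-180, 180]")
    if ranges.syn_lo <= chi <= ranges.syn_hi:
        return "syn"
    if ranges.high_anti_lo <= chi < ranges.syn_lo:
        return "high-anti"
    return "anti"


def _chi_atoms(residue) -> tuple[str, str, str, str]:
    if residue.base_type in PURINES or "N9" in residue.atoms:
        return ("O4'", "C1'", "N9", "C4")
    return ("O4'", "C1'", "N1", "C2")


def glycosidic_chi(residue, ranges: ChiRanges | None = None) -> GlycosidicConf:
    """Signed glycosidic torsion and its conformational class."""
    names = _chi_atoms(residue)
    missing = [n for n in names if n not in residue.atoms]
    if missing:
        raise ValueError(
            f"residue {residue.seq_index}: missing atoms for chi: {missing}"
        )
    chi = dihedral(*(residue.coord(n) for n in names))
    return GlycosidicConf(chi=chi, cls=classify_chi(chi, ranges))


def base_plane(residue) -> BasePlane:
    """Least-squares plane of the six-membered base ring.

    The normal sign follows the ring winding of the atom order (N1, C2,
    N3, C4, C5, C6), making it a pure function of the base geometry and
    hence consistent across residues of equal handedness.
    """
    ring = PURINE_SIX_RING if (residue.base_type in PURINES or "N9" in residue.atoms) else PYRIMIDINE_SIX_RING
    missing = [n for n in ring if n not in residue.atoms]
    if missing:
        raise ValueError(
            f"residue {residue.seq_index}: missing six-ring atoms: {missing}"
        )
    pts = np.array([residue.coord(n) for n in ring])
    centroid, normal, residuals = fit_plane(pts)
    return BasePlane(
        centroid6=tuple(centroid),
        normal=tuple(normal),
        max_residual=float(np.abs(residuals).max()),
    )


# ---------------------------------------------------------------------------
# pseudo-hydrogen bonds

#: donor heavy atoms and their attached hydrogens (base + backbone amines)
_N_DONORS = {
    "N1": ("H1",),
    "N2": ("H21", "H22"),
    "N6": ("H61", "H62"),
    "N4": ("H41", "H42"),
    "N3": ("H3",),
}
_C_DONORS = {
    "C8": ("H8",),
    "C6": ("H6",),
    "C1'": ("H1'",),
    "C2'": ("H2'", "H2''"),
    "C3'": ("H3'",),
}


def detect_pseudo_hbonds(
    ensemble,
    acceptors: tuple[str, ...] = ("F2'", "O2'"),
    max_h_dist: float = 2.7,
    min_angle: float = 110.0,
    heavy_fallback_dist: float = 3.5,
    include_ch: bool = False,
) -> list[dict]:
    """Screen donor-H...acceptor contacts to 2'-substituent acceptors.

    With explicit hydrogens: H...acceptor <= ``max_h_dist`` and
    donor-H...acceptor angle >= ``min_angle``.  Without hydrogens the
    heavy-atom distance <= ``heavy_fallback_dist`` is used and the
    contact is flagged ``no_h``.  Intra-residue pairs are skipped.
    """
    donors = dict(_N_DONORS)
    if include_ch:
        donors.update(_C_DONORS)
    contacts = []
    for m, model in enumerate(ensemble.models):
        acceptor_sites = [
            (res, a)
            for res in model
            for a in acceptors
            if a in res.atoms
        ]
        for res, acc_name in acceptor_sites:
            acc = res.coord(acc_name)
            for other in model:
                if other is res:
                    continue
                for d_name, h_names in donors.items():
                    if d_name not in other.atoms:
                        continue
                    dpos = other.coord(d_name)
                    hs = [h for h in h_names if h in other.atoms]
                    if hs:
                        for h in hs:
                            hpos = other.coord(h)
                            dist = float(np.linalg.norm(hpos - acc))
                            ang = bond_angle(dpos, hpos, acc)
                            if dist <= max_h_dist and ang >= min_angle:
                                contacts.append(
                                    {
                                        "model": m,
                                        "donor_res": other.seq_index,
                                        "donor_atom": d_name,
                                        "h_atom": h,
                                        "acceptor_res": res.seq_index,
                                        "acceptor_atom": acc_name,
                                        "h_acc_dist": dist,
                                        "angle": ang,
                                        "no_h": False,
                                    }
                                )
                    else:
                        dist = float(np.linalg.norm(dpos - acc))
                        if dist <= heavy_fallback_dist:
                            contacts.append(
                                {
                                    "model": m,
                                    "donor_res": other.seq_index,
                                    "donor_atom": d_name,
                                    "h_atom": None,
                                    "acceptor_res": res.seq_index,
                                    "acceptor_atom": acc_name,
                                    "h_acc_dist": dist,
                                    "angle": float("nan"),
                                    "no_h": True,
                                }
                            )
    return contacts
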