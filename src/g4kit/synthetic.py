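"""Synthetic structure generators.

Everything the analysis chain consumes can be generated here: furanose
rings at prescribed pseudorotation, nucleotides at prescribed glycosidic
torsion, idealized Hoogsteen tetrads, and complete mock quadruplexes
realized from a declarative topology specification.  Loop backbones are
schematic (interpolated, not energy-refined); detectors only rely on
base, ring and phosphate geometry.

Conventions
-----------
* Layers are indexed 0 (top, 5'-proximal outer tetrad) downward; layer l
  sits at z = -l * rise, so the top->bottom stack axis is -z.
* Each tetrad layer carries a face sign: '+' layers use the in-plane
  mirrored tetrad template (donor cycle slot 0 -> 3 -> 2 -> 1); '-'
  layers the unmirrored one (cycle 0 -> 1 -> 2 -> 3).
* A core residue's strand orientation is emergent:
  up  <=>  (face == '+') == (chi class is anti-like).
  Both pairings were calibrated jointly (against IUPAC-signed dihedrals
  of beta-D sugars) so that groove-width patterns and strand topology
  come out as in experimentally determined quadruplexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

from ._geometry import (
    dihedral,
    fit_plane,
    kabsch,
    place_atom,
    rotation_about_axis,
    tetrahedral_directions,
)
from .structure_io import Atom, Residue, StructureEnsemble
from .sugar_pucker import (
    RING_ATOMS,
    FiveTorsions,
    pseudorotation,
    ring_torsions,
    torsions_from_pucker,
)

__all__ = [
    "RingBuildResult",
    "CoreResidueSpec",
    "ColumnSpec",
    "LoopSpec",
    "TopologySpec",
    "build_sugar_ring",
    "build_nucleotide",
    "build_quadruplex",
    "perturb_ensemble",
    "preset",
    "PRESET_NAMES",
    "guanine_template",
    "tetrad_template",
]

# bond-length targets (Angstrom)
_RING_BONDS = {
    ("O4'", "C1'"): 1.414,
    ("C1'", "C2'"): 1.528,
    ("C2'", "C3'"): 1.525,
    ("C3'", "C4'"): 1.528,
    ("C4'", "O4'"): 1.446,
}
_GLYCOSIDIC_BOND = 1.47

_CHI_BY_CLASS = {"syn": 60.0, "anti": -120.0, "high-anti": -45.0}
_ANTI_LIKE = {"anti", "high-anti"}


# ---------------------------------------------------------------------------
# furanose ring at prescribed (P, tau_m)


@dataclass(frozen=True)
class RingBuildResult:
    coords: dict  # atom name -> np.ndarray, ring atoms + C5'/O3' stubs
    achieved_P: float
    achieved_tau_m: float
    closure_residual: float


def _ring_residuals(x, target_nu):
    pts = x.reshape(5, 3)
    names = list(RING_ATOMS)
    res = []
    for (a, b), target in _RING_BONDS.items():
        d = np.linalg.norm(pts[names.index(a)] - pts[names.index(b)])
        res.append(50.0 * (d - target))
    quads = [(4, 0, 1, 2), (0, 1, 2, 3), (1, 2, 3, 4), (2, 3, 4, 0), (3, 4, 0, 1)]
    for (i, j, k, l), nu in zip(quads, target_nu):
        diff = dihedral(pts[i], pts[j], pts[k], pts[l]) - nu
        diff = (diff + 180.0) % 360.0 - 180.0
        res.append(0.25 * diff)
    # weak bond-angle restraints keep the pentagon chemically shaped
    ring = [(4, 0, 1), (0, 1, 2), (1, 2, 3), (2, 3, 4), (3, 4, 0)]
    for i, j, k in ring:
        v1 = pts[i] - pts[j]
        v2 = pts[k] - pts[j]
        ang = math.degrees(
            math.acos(
                np.clip(
                    np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                    -1,
                    1,
                )
            )
        )
        res.append(0.05 * (ang - 104.0))
    # gauge fixing: O4' at origin, C1' on +x, C2' in the z >= 0 ... plane
    res.extend(10.0 * pts[0])
    res.append(10.0 * pts[1][1])
    res.append(10.0 * pts[1][2])
    res.append(10.0 * pts[2][2])
    return np.asarray(res)


@lru_cache(maxsize=512)
def _build_sugar_ring_cached(P: float, tau_m: float) -> RingBuildResult:
    target_nu = torsions_from_pucker(P, tau_m).nu
    # initial guess: planar pentagon + cosine out-of-plane displacements
    r0 = 1.49 / (2.0 * math.sin(math.pi / 5.0))
    pts0 = []
    for j, ang in enumerate(np.linspace(0, 2 * math.pi, 5, endpoint=False)):
        z = 0.45 * (tau_m / 38.0) * math.cos(math.radians(P + 144.0 * (j - 2)))
        pts0.append([r0 * math.cos(ang), r0 * math.sin(ang), z])
    pts0 = np.asarray(pts0)
    pts0 -= pts0[0]
    sol = least_squares(
        _ring_residuals, pts0.ravel(), args=(target_nu,), xtol=1e-14, ftol=1e-14
    )
    pts = sol.x.reshape(5, 3)
    coords = {name: pts[i].copy() for i, name in enumerate(RING_ATOMS)}
    bond_err = max(
        abs(np.linalg.norm(coords[a] - coords[b]) - t)
        for (a, b), t in _RING_BONDS.items()
    )
    if bond_err > 0.02:
        raise RuntimeError(
            f"ring closure failed for P={P}, tau_m={tau_m}: bond residual {bond_err:.4f} A"
        )
    # exocyclic stubs: C5' on C4' (base side), O3' on C3' (opposite side)
    normal = _ring_normal(coords)
    c5_dir = _slot_dir(coords["C4'"], coords["C3'"], coords["O4'"], -normal)
    o3_dir = _slot_dir(coords["C3'"], coords["C2'"], coords["C4'"], +normal)
    coords["C5'"] = coords["C4'"] + 1.51 * c5_dir
    coords["O3'"] = coords["C3'"] + 1.42 * o3_dir
    nus = FiveTorsions(
        nu=tuple(
            dihedral(
                coords[q[0]], coords[q[1]], coords[q[2]], coords[q[3]]
            )
            for q in (
                ("C4'", "O4'", "C1'", "C2'"),
                ("O4'", "C1'", "C2'", "C3'"),
                ("C1'", "C2'", "C3'", "C4'"),
                ("C2'", "C3'", "C4'", "O4'"),
                ("C3'", "C4'", "O4'", "C1'"),
            )
        )
    )
    if tau_m < 1.0:
        achieved_p, achieved_tm = 0.0, max(abs(v) for v in nus.nu)
    else:
        pk = pseudorotation(nus)
        achieved_p, achieved_tm = pk.P, pk.tau_m
    return RingBuildResult(
        coords=coords,
        achieved_P=achieved_p,
        achieved_tau_m=achieved_tm,
        closure_residual=bond_err,
    )


def build_sugar_ring(P: float, tau_m: float) -> RingBuildResult:
    """Construct a furanose ring realizing the requested pseudorotation.

    Achieved P is within 2 degrees of the request for tau_m in the
    chemically relevant range (validated through :func:`pseudorotation`).
    """
    if not (0.0 <= tau_m <= 50.0):
        raise ValueError("tau_m must be in [0, 50] degrees")
    res = _build_sugar_ring_cached(round(float(P) % 360.0, 4), round(float(tau_m), 4))
    return RingBuildResult(
        coords={k: v.copy() for k, v in res.coords.items()},
        achieved_P=res.achieved_P,
        achieved_tau_m=res.achieved_tau_m,
        closure_residual=res.closure_residual,
    )


def _ring_normal(coords) -> np.ndarray:
    pts = [coords[n] for n in RING_ATOMS]
    _, normal, _ = fit_plane(pts)
    return normal


def _slot_dir(center, nb1, nb2, side_vector) -> np.ndarray:
    d_plus, d_minus = tetrahedral_directions(center, nb1, nb2)
    return d_plus if np.dot(d_plus, side_vector) >= np.dot(d_minus, side_vector) else d_minus


# ---------------------------------------------------------------------------
# sugar decoration (substituents, backbone stubs)


def _decorate_sugar(coords: dict, variant: str, with_backbone: bool = True) -> dict:
    """Add hydrogens, the 2' substituent and O5'/P stubs to a bare ring.

    Face convention (empirically matched to beta-D nucleosides): with the
    ring normal defined by the winding of (O4', C1', C2', C3', C4'), the
    base and C5' sit on the -normal side; O3' and the ribo 2' substituent
    sit on the +normal side.
    """
    out = {k: np.asarray(v, dtype=float).copy() for k, v in coords.items()}
    normal = _ring_normal(out)
    beta = -normal  # base side

    def slot(center, nb1, nb2, side):
        return _slot_dir(out[center], out[nb1], out[nb2], side)

    out["H1'"] = out["C1'"] + 1.09 * slot("C1'", "O4'", "C2'", -beta)
    out["H3'"] = out["C3'"] + 1.09 * slot("C3'", "C2'", "C4'", beta)
    out["H4'"] = out["C4'"] + 1.09 * slot("C4'", "C3'", "O4'", -beta)
    if variant in ("ribo", "2F-ribo", "LNA"):
        sub = "O2'" if variant in ("ribo", "LNA") else "F2'"
        out[sub] = out["C2'"] + (1.40 if sub == "O2'" else 1.39) * slot(
            "C2'", "C1'", "C3'", -beta
        )
        out["H2'"] = out["C2'"] + 1.09 * slot("C2'", "C1'", "C3'", beta)
    elif variant == "2F-arabino":
        out["F2'"] = out["C2'"] + 1.39 * slot("C2'", "C1'", "C3'", beta)
        out["H2'"] = out["C2'"] + 1.09 * slot("C2'", "C1'", "C3'", -beta)
    else:  # deoxy / unknown
        out["H2'"] = out["C2'"] + 1.09 * slot("C2'", "C1'", "C3'", beta)
        out["H2''"] = out["C2'"] + 1.09 * slot("C2'", "C1'", "C3'", -beta)
    if with_backbone:
        out["O5'"] = place_atom(out["C3'"], out["C4'"], out["C5'"], 1.44, 110.0, 54.0)
        out["P"] = place_atom(out["C4'"], out["C5'"], out["O5'"], 1.60, 120.0, 180.0)
    return out


def _sugar_attachment_dir(coords) -> np.ndarray:
    """Unit vector of the glycosidic slot on C1' (base side)."""
    normal = _ring_normal(coords)
    return _slot_dir(coords["C1'"], coords["O4'"], coords["C2'"], -normal)


# ---------------------------------------------------------------------------
# planar base templates


def _hexagon(names, side=1.39):
    coords = {}
    for k, name in enumerate(names):
        ang = math.radians(60.0 * k)
        coords[name] = np.array([side * math.cos(ang), side * math.sin(ang), 0.0])
    return coords


def _outward(coords, name, center, dist):
    d = coords[name] - center
    d = d / np.linalg.norm(d)
    return coords[name] + dist * d


@lru_cache(maxsize=8)
def _base_template(base: str):
    """Idealized planar base in the z=0 plane.

    Returns (atoms, attach_atom, attach_dir): ``attach_atom`` is the
    glycosidic nitrogen, ``attach_dir`` the in-plane unit vector toward
    the C1' position.
    """
    if base in ("G", "A"):
        atoms = _hexagon(("N1", "C2", "N3", "C4", "C5", "C6"))
        hex_center = np.zeros(3)
        # fuse the five-membered ring on the C4-C5 edge
        c4, c5 = atoms["C4"], atoms["C5"]
        mid = (c4 + c5) / 2.0
        out = mid - hex_center
        out /= np.linalg.norm(out)
        s = np.linalg.norm(c5 - c4)
        apothem = s / (2.0 * math.tan(math.pi / 5.0))
        rc = s / (2.0 * math.sin(math.pi / 5.0))
        pc = mid + apothem * out
        a4 = math.atan2(*(c4 - pc)[1::-1])
        a5 = math.atan2(*(c5 - pc)[1::-1])
        step = 2.0 * math.pi / 5.0
        # choose walking direction away from C5
        diff = (a5 - a4 + math.pi) % (2 * math.pi) - math.pi
        sgn = -1.0 if diff > 0 else 1.0
        for i, nm in enumerate(("N9", "C8", "N7"), start=1):
            ang = a4 + sgn * step * i
            atoms[nm] = pc + np.array([rc * math.cos(ang), rc * math.sin(ang), 0.0])
        atoms["H8"] = _outward(atoms, "C8", pc, 1.08)
        if base == "G":
            atoms["O6"] = _outward(atoms, "C6", hex_center, 1.23)
            atoms["N2"] = _outward(atoms, "C2", hex_center, 1.34)
            atoms["H1"] = _outward(atoms, "N1", hex_center, 1.03)
            n2dir = atoms["N2"] - atoms["C2"]
            n2dir /= np.linalg.norm(n2dir)
            for nm, rot in (("H21", 60.0), ("H22", -60.0)):
                R = rotation_about_axis([0, 0, 1.0], rot)
                atoms[nm] = atoms["N2"] + 1.01 * (R @ n2dir)
        else:  # adenine
            atoms["N6"] = _outward(atoms, "C6", hex_center, 1.34)
            atoms["H2"] = _outward(atoms, "C2", hex_center, 1.08)
            n6dir = atoms["N6"] - atoms["C6"]
            n6dir /= np.linalg.norm(n6dir)
            for nm, rot in (("H61", 60.0), ("H62", -60.0)):
                R = rotation_about_axis([0, 0, 1.0], rot)
                atoms[nm] = atoms["N6"] + 1.01 * (R @ n6dir)
        attach_atom = "N9"
        attach_dir = atoms["N9"] - pc
    else:  # pyrimidines C, T, U
        atoms = _hexagon(("N1", "C2", "N3", "C4", "C5", "C6"))
        hex_center = np.zeros(3)
        atoms["O2"] = _outward(atoms, "C2", hex_center, 1.24)
        atoms["H6"] = _outward(atoms, "C6", hex_center, 1.08)
        if base == "C":
            atoms["N4"] = _outward(atoms, "C4", hex_center, 1.33)
            atoms["H5"] = _outward(atoms, "C5", hex_center, 1.08)
        else:  # T / U
            atoms["O4"] = _outward(atoms, "C4", hex_center, 1.23)
            atoms["H3"] = _outward(atoms, "N3", hex_center, 1.03)
            if base == "T":
                atoms["C7"] = _outward(atoms, "C5", hex_center, 1.50)
            else:
                atoms["H5"] = _outward(atoms, "C5", hex_center, 1.08)
        attach_atom = "N1"
        attach_dir = atoms["N1"] - hex_center
    attach_dir = attach_dir / np.linalg.norm(attach_dir)
    return atoms, attach_atom, attach_dir


def guanine_template() -> dict:
    """Planar idealized guanine (z = 0), atom name -> coordinates."""
    atoms, _, _ = _base_template("G")
    return {k: v.copy() for k, v in atoms.items()}


# ---------------------------------------------------------------------------
# tetrad template


@lru_cache(maxsize=4)
def _tetrad_base0():
    """Pose of tetrad slot 0 such that rotations by -90 deg about z
    generate a Hoogsteen cycle with N1(i)->O6(i+1) and N2(i)->N7(i+1)
    at 2.9 A (slot k sits at angle -90k deg; donor cycle 0 -> 1 -> 2 -> 3).

    The third (weak) residual keeps the four O6 atoms on the ~2.4 A
    central channel square, which selects the physical, clash-free branch
    of the exact H-bond solution family.
    """
    template, _, attach_dir = _base_template("G")
    names = sorted(template.keys())
    heavy = [n for n in names if not n.startswith("H")]
    pts = np.array([template[n] for n in names])
    rot_next = rotation_about_axis([0, 0, 1.0], -90.0)

    def pose(params):
        alpha, tx, ty = params
        R = rotation_about_axis([0, 0, 1.0], alpha)
        moved = pts @ R.T + np.array([tx, ty, 0.0])
        return {n: moved[i] for i, n in enumerate(names)}

    def residuals(params):
        b0 = pose(params)
        b1 = {n: rot_next @ v for n, v in b0.items()}
        return [
            np.linalg.norm(b0["N1"] - b1["O6"]) - 2.90,
            np.linalg.norm(b0["N2"] - b1["N7"]) - 2.90,
            0.2 * (np.linalg.norm(b0["O6"][:2]) - 2.45),
        ]

    best = None
    for alpha0 in range(0, 360, 20):
        for phi in range(0, 360, 60):
            Ra = rotation_about_axis([0, 0, 1.0], float(alpha0))
            o6r = Ra @ template["O6"]
            target = 2.45 * np.array(
                [math.cos(math.radians(phi)), math.sin(math.radians(phi)), 0.0]
            )
            t = target - o6r
            sol = least_squares(
                residuals, [float(alpha0), t[0], t[1]], xtol=1e-15, ftol=1e-15
            )
            # polish within the selected branch: exact H-bond lengths only
            sol = least_squares(
                lambda p: residuals(p)[:2], sol.x, xtol=1e-15, ftol=1e-15
            )
            b0 = pose(sol.x)
            b1 = {n: rot_next @ v for n, v in b0.items()}
            hb_err = max(
                abs(np.linalg.norm(b0["N1"] - b1["O6"]) - 2.90),
                abs(np.linalg.norm(b0["N2"] - b1["N7"]) - 2.90),
            )
            clash = min(
                np.linalg.norm(b0[a] - b1[b]) for a in heavy for b in heavy
            )
            if hb_err > 1e-6 or clash < 2.4:
                continue
            h_lin = np.linalg.norm(b0["H1"] - b1["O6"]) + min(
                np.linalg.norm(b0["H21"] - b1["N7"]),
                np.linalg.norm(b0["H22"] - b1["N7"]),
            )
            if best is None or h_lin < best[0]:
                best = (h_lin, sol.x.copy())
    if best is None:
        raise RuntimeError("tetrad template optimization failed")
    b0 = pose(best[1])
    # rotate the whole solution so the slot-0 base centroid sits at angle 0
    centroid = np.mean([b0[n] for n in names], axis=0)
    ang = math.degrees(math.atan2(centroid[1], centroid[0]))
    Rfix = rotation_about_axis([0, 0, 1.0], -ang)
    b0 = {n: Rfix @ v for n, v in b0.items()}
    # carry the glycosidic attachment direction as a virtual point
    alpha = best[1][0]
    Ra = rotation_about_axis([0, 0, 1.0], alpha)
    b0["_C1dir"] = b0["N9"] + Rfix @ (Ra @ attach_dir)
    return {n: v.copy() for n, v in b0.items()}


def tetrad_template(face: str = "+") -> list[dict]:
    """Four guanine bases forming one idealized Hoogsteen tetrad.

    Slot k sits at angle -90k deg about z.  ``face`` '+' uses the
    in-plane mirrored (y -> -y) base pose, giving donor cycle slot
    0->3->2->1; '-' uses the unmirrored pose (cycle 0->1->2->3).  The
    pairing of mirror state with face letter was calibrated so that the
    emergent groove-width pattern around syn/anti columns matches the
    narrow/wide assignments observed in real quadruplexes.
    """
    b0 = _tetrad_base0()
    if face == "+":
        M = np.diag([1.0, -1.0, 1.0])
        b0 = {n: M @ v for n, v in b0.items()}
    bases = []
    for k in range(4):
        R = rotation_about_axis([0, 0, 1.0], -90.0 * k)
        bases.append({n: R @ v for n, v in b0.items()})
    return bases


# ---------------------------------------------------------------------------
# nucleotide assembly


def _align_vectors_rotation(v_from, v_to) -> np.ndarray:
    v_from = v_from / np.linalg.norm(v_from)
    v_to = v_to / np.linalg.norm(v_to)
    c = float(np.dot(v_from, v_to))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # 180 deg: rotate about any perpendicular axis
        perp = np.cross(v_from, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(v_from, [0.0, 1.0, 0.0])
        return rotation_about_axis(perp, 180.0)
    axis = np.cross(v_from, v_to)
    ang = math.degrees(math.acos(np.clip(c, -1, 1)))
    return rotation_about_axis(axis, ang)


def _attach_sugar_to_base(
    base_atoms: dict,
    chi: float,
    P: float,
    tau_m: float,
    variant: str,
    attach_atom: str = "N9",
    with_backbone: bool = True,
) -> dict:
    """Place a sugar (plus backbone stubs) onto an already-positioned base
    so that the glycosidic torsion equals ``chi``."""
    ring = build_sugar_ring(P, tau_m)
    sugar = _decorate_sugar(ring.coords, variant, with_backbone=with_backbone)
    v_base = _sugar_attachment_dir(ring.coords)

    n9 = np.asarray(base_atoms[attach_atom], dtype=float)
    c1dir = base_atoms["_C1dir"] - n9
    c1dir = c1dir / np.linalg.norm(c1dir)
    c1_target = n9 + _GLYCOSIDIC_BOND * c1dir
    u = -c1dir  # direction C1' -> N9

    R1 = _align_vectors_rotation(v_base, u)
    c1_local = sugar["C1'"].copy()
    moved = {n: R1 @ (v - c1_local) + c1_target for n, v in sugar.items()}

    ref = "C4" if attach_atom == "N9" else "C2"
    current = dihedral(moved["O4'"], c1_target, n9, base_atoms[ref])
    delta = chi - current
    for signed in (delta, -delta):
        spin = rotation_about_axis(u, signed)
        trial = {n: spin @ (v - c1_target) + c1_target for n, v in moved.items()}
        achieved = dihedral(trial["O4'"], c1_target, n9, base_atoms[ref])
        if abs((achieved - chi + 180.0) % 360.0 - 180.0) < 1e-6:
            return trial
    raise RuntimeError("glycosidic spin failed to achieve requested chi")


def build_nucleotide(
    P: float,
    tau_m: float,
    chi: float,
    base: str = "G",
    variant: str = "deoxy",
    seq_index: int = 1,
    chain_id: str = "A",
    with_backbone: bool = True,
) -> Residue:
    """Standalone nucleotide: sugar at (P, tau_m), base at exact ``chi``."""
    base_atoms, attach_atom, _ = _base_template(base)
    ring = build_sugar_ring(P, tau_m)
    sugar = _decorate_sugar(ring.coords, variant, with_backbone=with_backbone)
    v_base = _sugar_attachment_dir(ring.coords)
    n_pos = sugar["C1'"] + _GLYCOSIDIC_BOND * v_base
    ref = "C4" if attach_atom == "N9" else "C2"
    other = "C8" if attach_atom == "N9" else "C6"
    c_ref = place_atom(sugar["O4'"], sugar["C1'"], n_pos, 1.37, 127.0, chi)
    c_other = place_atom(sugar["O4'"], sugar["C1'"], n_pos, 1.37, 127.0, chi + 180.0)
    tmpl_pts = np.array([base_atoms[attach_atom], base_atoms[ref], base_atoms[other]])
    target_pts = np.array([n_pos, c_ref, c_other])
    R, t, _ = kabsch(tmpl_pts, target_pts)
    placed = {n: v @ R.T + t for n, v in base_atoms.items()}
    atoms = dict(sugar)
    atoms.update(placed)
    return _to_residue(atoms, base, variant, seq_index, chain_id)


_VARIANT_RES_NAMES = {
    ("G", "deoxy"): "DG",
    ("A", "deoxy"): "DA",
    ("C", "deoxy"): "DC",
    ("T", "deoxy"): "DT",
    ("G", "ribo"): "G",
    ("A", "ribo"): "A",
    ("C", "ribo"): "C",
    ("U", "ribo"): "U",
    ("G", "2F-ribo"): "GF2",
    ("G", "2F-arabino"): "GFL",
    ("G", "LNA"): "LCG",
}


def _to_residue(atoms: dict, base: str, variant: str, seq_index: int, chain_id: str) -> Residue:
    name = _VARIANT_RES_NAMES.get((base, variant), "UNK")
    res_atoms = {}
    for n, xyz in atoms.items():
        if n.startswith("_"):
            continue
        element = "P" if n == "P" else n[0]
        res_atoms[n] = Atom(name=n, element=element, xyz=tuple(float(v) for v in xyz))
    return Residue(
        chain_id=chain_id,
        seq_index=seq_index,
        name=name,
        base_type=base,
        variant=variant,
        atoms=res_atoms,
    )


# ---------------------------------------------------------------------------
# topology specification


@dataclass(frozen=True)
class CoreResidueSpec:
    seq_index: int
    layer: int
    chi: str | float  # class name or explicit degrees
    P: float = 18.0
    tau_m: float = 38.0
    variant: str = "deoxy"

    @property
    def chi_value(self) -> float:
        if isinstance(self.chi, str):
            return _CHI_BY_CLASS[self.chi]
        return float(self.chi)

    @property
    def chi_class(self) -> str:
        if isinstance(self.chi, str):
            return self.chi
        from .conformer_classify import classify_chi

        return classify_chi(self.chi_value)


@dataclass(frozen=True)
class ColumnSpec:
    slot: int
    residues: tuple[CoreResidueSpec, ...]


@dataclass(frozen=True)
class LoopSpec:
    cls: str  # lateral | diagonal | propeller | V
    residues: tuple[int, ...]  # intervening seq indices (may be empty)


@dataclass
class TopologySpec:
    """Declarative generating specification of a mock quadruplex.

    Also serves as the oracle: expected tetrad cycles, orientations and
    loop classes are derived combinatorially (never from coordinates).
    """

    name: str
    n_layers: int
    layer_faces: tuple[str, ...]  # '+'/'-' per layer, index 0 = top
    columns: tuple[ColumnSpec, ...]
    loops: tuple[LoopSpec, ...] = ()
    sequence: dict = field(default_factory=dict)  # seq_index -> base letter (loops)
    expected_grooves: dict = field(default_factory=dict)  # "slotA-slotB" -> label
    chains: int = 1

    def __post_init__(self):
        if len(self.layer_faces) != self.n_layers:
            raise ValueError("one face sign per layer required")
        if len(self.columns) != 4:
            raise ValueError("exactly 4 columns required")
        for col in self.columns:
            layers = [r.layer for r in col.residues]
            if sorted(layers) != list(range(self.n_layers)):
                raise ValueError(f"column at slot {col.slot}: one residue per layer required")
        self._validate_wiring()

    def _validate_wiring(self):
        core = {r.seq_index for col in self.columns for r in col.residues}
        for loop in self.loops:
            if loop.cls != "V" and len(loop.residues) < 1:
                raise ValueError(f"{loop.cls} loop must have >= 1 intervening residue")
            for idx in loop.residues:
                if idx in core:
                    raise ValueError(f"loop residue {idx} is also a core residue")

    # -- oracle side ------------------------------------------------------

    def core_residues(self) -> dict:
        """seq_index -> (column_slot, layer, CoreResidueSpec)"""
        out = {}
        for col in self.columns:
            for r in col.residues:
                out[r.seq_index] = (col.slot, r.layer, r)
        return out

    def expected_orientation(self, r: CoreResidueSpec) -> str:
        face = self.layer_faces[r.layer]
        anti_like = r.chi_class in _ANTI_LIKE
        return "up" if (face == "+") == anti_like else "down"

    def expected_column_orientations(self) -> dict:
        out = {}
        for col in self.columns:
            ups = sum(self.expected_orientation(r) == "up" for r in col.residues)
            out[col.slot] = "up" if ups * 2 > len(col.residues) else "down"
        return out

    def expected_tetrads(self) -> list[list[int]]:
        """Donor->acceptor cycles per layer, starting at the lowest index."""
        cycles = []
        for l in range(self.n_layers):
            by_slot = {}
            for col in self.columns:
                for r in col.residues:
                    if r.layer == l:
                        by_slot[col.slot] = r.seq_index
            order = [0, 3, 2, 1] if self.layer_faces[l] == "+" else [0, 1, 2, 3]
            cyc = [by_slot[s] for s in order]
            start = cyc.index(min(cyc))
            cycles.append(cyc[start:] + cyc[:start])
        return cycles

    def expected_stacking(self) -> list[str]:
        return [
            "homopolar" if self.layer_faces[l] == self.layer_faces[l + 1] else "heteropolar"
            for l in range(self.n_layers - 1)
        ]

    def expected_loop_classes(self) -> list[str]:
        return [lp.cls for lp in self.loops]

    def all_seq_indices(self) -> list[int]:
        idx = set(self.sequence.keys())
        idx.update(self.core_residues().keys())
        return sorted(idx)


# ---------------------------------------------------------------------------
# quadruplex assembly


def build_quadruplex(spec: TopologySpec, rise: float = 3.3, twist: float = 30.0) -> StructureEnsemble:
    """Realize a TopologySpec as a single-model coordinate ensemble."""
    core = spec.core_residues()
    residues: dict[int, Residue] = {}
    base_letters = dict(spec.sequence)

    for seq_index, (slot, layer, rspec) in core.items():
        face = spec.layer_faces[layer]
        bases = tetrad_template(face)
        Rtw = rotation_about_axis([0, 0, 1.0], twist * layer)
        shift = np.array([0.0, 0.0, -rise * layer])
        base_atoms = {n: Rtw @ v + shift for n, v in bases[slot].items()}
        sugar = _attach_sugar_to_base(
            base_atoms,
            chi=rspec.chi_value,
            P=rspec.P,
            tau_m=rspec.tau_m,
            variant=rspec.variant,
        )
        atoms = dict(sugar)
        atoms.update(base_atoms)
        residues[seq_index] = _to_residue(atoms, "G", rspec.variant, seq_index, "A")

    # schematic loop / flanking nucleotides
    all_idx = spec.all_seq_indices()
    for loop in spec.loops:
        if not loop.residues:
            continue
        lo = min(loop.residues)
        hi = max(loop.residues)
        a5 = max((i for i in core if i < lo), default=None)
        a3 = min((i for i in core if i > hi), default=None)
        start = residues[a5].coord("O3'") if a5 is not None else None
        end = residues[a3].coord("C5'") if a3 is not None else None
        if start is None:
            start = end + np.array([4.0, 4.0, 2.0])
        if end is None:
            end = start + np.array([4.0, 4.0, 2.0])
        n = len(loop.residues)
        for i, seq_index in enumerate(sorted(loop.residues), start=1):
            t = i / (n + 1.0)
            point = start + t * (end - start)
            radial = point.copy()
            radial[2] = 0.0
            norm = np.linalg.norm(radial)
            if norm < 1e-6:
                radial = np.array([1.0, 0.0, 0.0])
                norm = 1.0
            point = point + (radial / norm) * 4.0
            letter = base_letters.get(seq_index, "T")
            nt = build_nucleotide(
                162.0, 35.0, -120.0, base=letter, variant="deoxy",
                seq_index=seq_index, chain_id="A",
            )
            offset = point - nt.coord("C1'")
            moved = {
                n2: Atom(a.name, a.element, tuple(np.asarray(a.xyz) + offset))
                for n2, a in nt.atoms.items()
            }
            nt.atoms = moved
            residues[seq_index] = nt

    ordered = [residues[i] for i in sorted(residues.keys())]
    _bridge_phosphates(ordered, core_set=set(core))
    return StructureEnsemble(models=[ordered], source_id=spec.name)


def _bridge_phosphates(ordered: list[Residue], core_set: set | None = None) -> None:
    """Re-place phosphates linking two core residues onto the
    O3'(i-1) -> C5'(i) path; other residues keep their sugar-derived
    phosphate stub (loop backbones are schematic, so bridged positions
    through loop residues would be meaningless).

    The 5'-terminal residue loses its phosphate (as in real depositions).
    """
    core_set = core_set if core_set is not None else set()
    first = ordered[0]
    for nm in ("P", "O5'"):
        first.atoms.pop(nm, None)
    for prev, res in zip(ordered, ordered[1:]):
        if not (prev.seq_index in core_set and res.seq_index in core_set):
            continue
        o3 = prev.coord("O3'")
        c5 = res.coord("C5'")
        link = c5 - o3
        norm = np.linalg.norm(link)
        if norm < 1e-6:
            continue
        p = o3 + link * (1.6 / max(norm, 3.2))
        o5 = c5 - link * (1.44 / max(norm, 3.2))
        res.atoms["P"] = Atom("P", "P", tuple(float(v) for v in p))
        res.atoms["O5'"] = Atom("O5'", "O", tuple(float(v) for v in o5))


def perturb_ensemble(
    structure: StructureEnsemble, n_models: int, noise_sd: float, seed: int
) -> StructureEnsemble:
    """i.i.d. Gaussian coordinate noise per atom per model (seeded)."""
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    template = structure.models[0]
    models = []
    for _ in range(n_models):
        model = []
        for res in template:
            atoms = {}
            for n, a in res.atoms.items():
                xyz = np.asarray(a.xyz) + rng.normal(0.0, noise_sd, size=3)
                atoms[n] = Atom(a.name, a.element, tuple(float(v) for v in xyz))
            model.append(
                Residue(
                    chain_id=res.chain_id,
                    seq_index=res.seq_index,
                    name=res.name,
                    base_type=res.base_type,
                    variant=res.variant,
                    atoms=atoms,
                )
            )
        models.append(model)
    return StructureEnsemble(models=models, source_id=structure.source_id)


# ---------------------------------------------------------------------------
# presets


PRESET_NAMES = ("parallel", "hybrid-ODN", "vloop-ODN1415", "vloop-typeB")


def _col(slot, entries):
    return ColumnSpec(slot=slot, residues=tuple(CoreResidueSpec(*e) for e in entries))


def preset(name: str) -> TopologySpec:
    """Named topology presets shared by tests, CLI and documentation."""
    south = (162.0, 38.0)
    north = (18.0, 38.0)
    ne = (54.0, 38.0)
    if name == "parallel":
        return TopologySpec(
            name="parallel",
            n_layers=3,
            layer_faces=("+", "+", "+"),
            columns=(
                _col(0, [(1, 0, "anti", *south), (2, 1, "anti", *south), (3, 2, "anti", *south)]),
                _col(1, [(5, 0, "anti", *south), (6, 1, "anti", *south), (7, 2, "anti", *south)]),
                _col(2, [(9, 0, "anti", *south), (10, 1, "anti", *south), (11, 2, "anti", *south)]),
                _col(3, [(13, 0, "anti", *south), (14, 1, "anti", *south), (15, 2, "anti", *south)]),
            ),
            loops=(
                LoopSpec("propeller", (4,)),
                LoopSpec("propeller", (8,)),
                LoopSpec("propeller", (12,)),
            ),
            sequence={4: "T", 8: "T", 12: "T"},
            expected_grooves={
                "0-1": "medium",
                "1-2": "medium",
                "2-3": "medium",
                "3-0": "medium",
            },
        )
    if name == "hybrid-ODN":
        return TopologySpec(
            name="hybrid-ODN",
            n_layers=3,
            layer_faces=("-", "+", "+"),
            columns=(
                _col(0, [(1, 0, "syn", *south), (2, 1, "anti", *south), (3, 2, "anti", *south)]),
                _col(1, [(7, 0, "syn", *south), (8, 1, "anti", *south), (9, 2, "anti", *south)]),
                _col(2, [(19, 0, "syn", *south), (20, 1, "anti", *south), (21, 2, "anti", *south)]),
                _col(3, [(15, 0, "anti", *south), (14, 1, "syn", *south), (13, 2, "syn", *south)]),
            ),
            loops=(
                LoopSpec("propeller", (4, 5, 6)),
                LoopSpec("diagonal", (10, 11, 12)),
                LoopSpec("lateral", (16, 17, 18)),
            ),
            sequence={4: "T", 5: "T", 6: "A", 10: "T", 11: "T", 12: "A", 16: "T", 17: "T", 18: "A"},
            expected_grooves={
                "0-1": "medium",
                "1-2": "medium",
                "2-3": "narrow",
                "3-0": "wide",
            },
        )
    if name in ("vloop-ODN1415", "vloop-typeB"):
        chi15 = "anti" if name == "vloop-ODN1415" else "syn"
        return TopologySpec(
            name=name,
            n_layers=3,
            layer_faces=("-", "+", "+"),
            columns=(
                # broken first tract: G2 (top), G1 (central), FrG14 (bottom)
                _col(0, [(2, 0, "anti", *south), (1, 1, "syn", *south), (14, 2, "syn", *ne, "2F-ribo")]),
                # second tract: G6..G8
                _col(1, [(6, 0, "syn", *south), (7, 1, "anti", *south), (8, 2, "anti", *south)]),
                # fourth tract: G20..G22
                _col(2, [(20, 0, "syn", *south), (21, 1, "anti", *south), (22, 2, "anti", *south)]),
                # third tract: FrG15 (top), G16, G17
                _col(3, [(15, 0, chi15, *ne, "2F-ribo"), (16, 1, "anti", *south), (17, 2, "anti", *south)]),
            ),
            loops=(
                LoopSpec("lateral", (3, 4, 5)),
                LoopSpec("lateral", (9, 10, 11, 12, 13)),
                LoopSpec("V", ()),
                LoopSpec("propeller", (18, 19)),
            ),
            sequence={3: "G", 4: "A", 5: "T", 9: "A", 10: "C", 11: "A", 12: "C", 13: "A", 18: "A", 19: "C"},
            expected_grooves={
                "0-1": "wide",
                "1-2": "medium",
                "2-3": "medium",
                "3-0": "narrow",
            },
        )
    raise ValueError(f"unknown preset {name!r} (available: {PRESET_NAMES})")
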