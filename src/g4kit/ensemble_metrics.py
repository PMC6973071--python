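"""Ensemble geometry: superposition, RMSD statistics, interproton
distances, ring proximity, and the V-loop pucker survey.

RMSD conventions:

* ``pairwise`` -- mean over all model pairs of the RMSD after optimal
  superposition of each pair.
* ``to_mean``  -- iterative superposition onto the running mean
  structure until convergence, then the mean RMSD to that mean.

Both are reported with the convention echoed, since published values
rarely state theirs.
"""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass

import numpy as np

from ._geometry import kabsch
from .conformer_classify import base_plane
from .g4_topology import NoTetradsError, analyze_topology
from .sugar_pucker import pseudorotation, ring_torsions

logger = logging.getLogger(__name__)

__all__ = [
    "Superposition",
    "EnsembleStats",
    "PuckerSurveyRow",
    "superpose",
    "ensemble_rmsd",
    "resolve_selection",
    "interproton_distance_stats",
    "ring_proximity",
    "survey_vloop_puckers",
]


@dataclass(frozen=True)
class Superposition:
    rotation: tuple  # 3x3, det = +1
    translation: tuple
    rmsd: float


@dataclass(frozen=True)
class EnsembleStats:
    selection: str
    mode: str  # pairwise | to_mean
    rmsd_mean: float
    rmsd_matrix: tuple  # model x model (pairwise); empty for to_mean
    n_atoms: int


@dataclass(frozen=True)
class PuckerSurveyRow:
    structure_id: str
    model_index: int
    residue: int
    role: str  # preceding_vloop | following_vloop
    P: float


def superpose(coords_a, coords_b) -> Superposition:
    """Least-squares rigid superposition of ``coords_a`` onto
    ``coords_b`` (reflections excluded)."""
    R, t, rmsd = kabsch(coords_a, coords_b)
    return Superposition(
        rotation=tuple(map(tuple, R)), translation=tuple(t), rmsd=rmsd
    )


# ---------------------------------------------------------------------------
# atom selection mini-language

#: residues of the G-core (detected per ensemble when "core" is used)


def resolve_selection(ensemble, selection: str) -> list[tuple[int, str, str]]:
    """Resolve a selection string to (seq_index, chain, atom_name) triples.

    Grammar: ``<residues>[@<atom globs>]`` where residues is ``all``,
    ``core`` (tetrad guanines, detected on model 1) or a comma list of
    indices/ranges (``1-3,7``); atom globs are comma-separated fnmatch
    patterns (default ``heavy`` = all non-hydrogen atoms; ``heavy`` may
    also be given explicitly; ``all`` keeps hydrogens).
    """
    if "@" in selection:
        res_part, atom_part = selection.split("@", 1)
    else:
        res_part, atom_part = selection, "heavy"
    res_part = res_part.strip() or "all"
    atom_part = atom_part.strip() or "heavy"

    model0 = ensemble.models[0]
    if res_part == "all":
        wanted = {(r.chain_id, r.seq_index) for r in model0}
    elif res_part == "core":
        topo = analyze_topology(model0)
        core = {i for t in topo.tetrads for i in t.cycle}
        wanted = {(r.chain_id, r.seq_index) for r in model0 if r.seq_index in core}
    else:
        idx = set()
        for tok in res_part.split(","):
            tok = tok.strip()
            if "-" in tok.lstrip("-"):
                lo, hi = tok.split("-", 1)
                idx.update(range(int(lo), int(hi) + 1))
            else:
                idx.add(int(tok))
        wanted = {(r.chain_id, r.seq_index) for r in model0 if r.seq_index in idx}

    globs = [g.strip() for g in atom_part.split(",")]
    triples = []
    for r in model0:
        if (r.chain_id, r.seq_index) not in wanted:
            continue
        for name, atom in r.atoms.items():
            if "heavy" in globs or "all" in globs:
                if "heavy" in globs and atom.element == "H":
                    continue
            elif not any(fnmatch.fnmatch(name, g) for g in globs):
                continue
            triples.append((r.seq_index, r.chain_id, name))
    # keep only atoms present in every model
    for model in ensemble.models[1:]:
        have = {
            (r.seq_index, r.chain_id, n) for r in model for n in r.atoms
        }
        triples = [t for t in triples if t in have]
    return triples


def _coords(model, triples) -> np.ndarray:
    by_key = {(r.seq_index, r.chain_id): r for r in model}
    return np.array(
        [by_key[(s, c)].coord(name) for s, c, name in triples]
    )


def ensemble_rmsd(ensemble, selection: str = "all@heavy", mode: str = "pairwise") -> EnsembleStats:
    """Ensemble RMSD over an atom selection under the given convention."""
    triples = resolve_selection(ensemble, selection)
    if len(triples) < 3:
        raise ValueError(f"selection {selection!r} resolves to <3 atoms")
    coords = [_coords(m, triples) for m in ensemble.models]
    n = len(coords)
    if mode == "pairwise":
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                _, _, r = kabsch(coords[i], coords[j])
                mat[i, j] = mat[j, i] = r
        vals = mat[np.triu_indices(n, k=1)]
        return EnsembleStats(
            selection=selection,
            mode=mode,
            rmsd_mean=float(vals.mean()) if len(vals) else 0.0,
            rmsd_matrix=tuple(map(tuple, mat)),
            n_atoms=len(triples),
        )
    if mode == "to_mean":
        aligned = [c.copy() for c in coords]
        mean = aligned[0].copy()
        prev = np.inf
        for _ in range(100):
            for i in range(n):
                R, t, _ = kabsch(aligned[i], mean)
                aligned[i] = aligned[i] @ R.T + t
            mean = np.mean(aligned, axis=0)
            rmsds = [
                float(np.sqrt(((a - mean) ** 2).sum() / len(mean))) for a in aligned
            ]
            cur = float(np.mean(rmsds))
            if abs(prev - cur) < 1e-6:
                break
            prev = cur
        return EnsembleStats(
            selection=selection,
            mode=mode,
            rmsd_mean=cur,
            rmsd_matrix=(),
            n_atoms=len(triples),
        )
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# distances and ring proximity

#: idealized X-H bond lengths for geometric proton reconstruction
_H_PARENT = {
    "H8": ("C8", 1.08),
    "H6": ("C6", 1.08),
    "H1'": ("C1'", 1.09),
    "H2'": ("C2'", 1.09),
    "H2''": ("C2'", 1.09),
    "H3'": ("C3'", 1.09),
    "H4'": ("C4'", 1.09),
}


def _proton_coord(res, name: str) -> tuple[np.ndarray, bool]:
    """Coordinates of a named proton, geometrically rebuilt when absent."""
    if name in res.atoms:
        return res.coord(name), False
    if name not in _H_PARENT:
        raise KeyError(f"cannot reconstruct proton {name}")
    parent, bond = _H_PARENT[name]
    if parent not in res.atoms:
        raise KeyError(f"residue {res.seq_index}: no parent atom {parent} for {name}")
    p = res.coord(parent)
    neighbors = [
        res.coord(n)
        for n in res.atoms
        if n != parent
        and res.atoms[n].element != "H"
        and np.linalg.norm(res.coord(n) - p) < 1.8
    ]
    if not neighbors:
        raise KeyError(f"residue {res.seq_index}: isolated parent atom {parent}")
    d = -np.sum([(nb - p) / np.linalg.norm(nb - p) for nb in neighbors], axis=0)
    norm = np.linalg.norm(d)
    if norm < 1e-6:
        raise KeyError(f"residue {res.seq_index}: degenerate geometry at {parent}")
    return p + bond * d / norm, True


def interproton_distance_stats(ensemble, atom_a, atom_b) -> dict:
    """Per-model Euclidean distances between two (residue, atom) protons.

    Returns min/mean/max plus the per-model list; missing protons are
    rebuilt geometrically and flagged.
    """
    (res_a, name_a), (res_b, name_b) = atom_a, atom_b
    dists = []
    rebuilt = False
    for model in ensemble.models:
        ra = next(r for r in model if r.seq_index == res_a)
        rb = next(r for r in model if r.seq_index == res_b)
        ca, fa = _proton_coord(ra, name_a)
        cb, fb = _proton_coord(rb, name_b)
        rebuilt = rebuilt or fa or fb
        dists.append(float(np.linalg.norm(ca - cb)))
    return {
        "atom_a": f"{res_a}:{name_a}",
        "atom_b": f"{res_b}:{name_b}",
        "min": min(dists),
        "mean": float(np.mean(dists)),
        "max": max(dists),
        "per_model": dists,
        "protons_rebuilt": rebuilt,
    }


def ring_proximity(
    ensemble, proton, base_residue: int, in_plane_height: float = 1.5
) -> list[dict]:
    """Geometry of a proton relative to a base six-ring, per model.

    Returns centroid distance, signed height above the base plane and an
    in-plane flag (|height| < ``in_plane_height``).
    """
    res_p, name_p = proton
    out = []
    for m, model in enumerate(ensemble.models):
        rp = next(r for r in model if r.seq_index == res_p)
        rb = next(r for r in model if r.seq_index == base_residue)
        cp, flagged = _proton_coord(rp, name_p)
        plane = base_plane(rb)
        rel = cp - np.asarray(plane.centroid6)
        height = float(np.dot(rel, plane.normal))
        out.append(
            {
                "model": m,
                "centroid_distance": float(np.linalg.norm(rel)),
                "height": height,
                "in_plane": abs(height) < in_plane_height,
                "proton_rebuilt": flagged,
            }
        )
    return out


def survey_vloop_puckers(ensembles) -> list[PuckerSurveyRow]:
    """Pseudorotation phases of V-loop flanking residues, per model.

    Ensembles without a detectable V-loop are skipped with a warning.
    """
    rows = []
    for ens in ensembles:
        try:
            topo0 = analyze_topology(ens.models[0])
        except (NoTetradsError, ValueError) as exc:
            logger.warning("skipping %s: %s", ens.source_id, exc)
            continue
        if not topo0.vloops:
            logger.warning("skipping %s: no V-loop detected", ens.source_id)
            continue
        anchors = [(v.anchor5, v.anchor3) for v in topo0.vloops]
        for m, model in enumerate(ens.models):
            by_idx = {r.seq_index: r for r in model}
            for a5, a3 in anchors:
                for res_idx, role in ((a5, "preceding_vloop"), (a3, "following_vloop")):
                    pk = pseudorotation(ring_torsions(by_idx[res_idx]))
                    rows.append(
                        PuckerSurveyRow(
                            structure_id=ens.source_id,
                            model_index=m,
                            residue=res_idx,
                            role=role,
                            P=pk.P,
                        )
                    )
    return rows
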