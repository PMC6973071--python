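"""G-quadruplex topology detection.

Tetrads are found as directed 4-cycles in the Hoogsteen hydrogen-bond
graph (edge i -> j when N1(i)-O6(j) and N2(i)-N7(j) heavy-atom distances
both fall below cutoff and the base planes are roughly parallel), then
assembled into a stack, four G-columns, grooves and loops.

Orientation convention: the stack axis points from the "top" outer
tetrad (the one containing the 5'-most core guanine) toward the bottom.
A core residue runs "up" (5'->3' along that axis) iff its base face and
glycosidic class agree per the tetrad-polarity rule:

    up  <=>  (base normal points along the axis) == (chi class is anti-like)

which encodes that flipping a strand while switching syn/anti leaves the
base face in the tetrad unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from ._geometry import fit_plane
from .conformer_classify import PURINE_SIX_RING, glycosidic_chi
from .sugar_pucker import pseudorotation, ring_torsions

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryCutoffs",
    "HoogsteenEdge",
    "Tetrad",
    "Column",
    "Loop",
    "TopologyModel",
    "VLoopRecord",
    "AmbiguityError",
    "VLoopClassificationError",
    "NoTetradsError",
    "detect_hoogsteen_pairs",
    "detect_tetrads",
    "stack_tetrads",
    "extract_columns",
    "classify_grooves",
    "classify_loops",
    "detect_vloops",
    "analyze_topology",
]

#: atoms a residue must have to count as a guanine for tetrad detection
_GUANINE_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9", "O6", "N2")

_ANTI_LIKE = {"anti", "high-anti"}


class AmbiguityError(ValueError):
    """A residue participates in more than one candidate tetrad."""


class VLoopClassificationError(ValueError):
    """A V-classified loop violates the V-loop anchor invariants."""


class NoTetradsError(ValueError):
    """Structure contains no detectable tetrad."""


@dataclass(frozen=True)
class GeometryCutoffs:
    n1_o6_max: float = 3.5
    n2_n7_max: float = 3.5
    plane_angle_max: float = 35.0
    # P-P distance thresholds, calibrated on the synthetic templates
    # (schematic backbones sit closer in than fully refined ones)
    groove_narrow_max: float = 12.5
    groove_medium_max: float = 15.5
    groove_narrow_max_c1: float = 11.0  # C1'-C1' fallback thresholds
    groove_medium_max_c1: float = 15.0
    reverse_donor_convention: bool = False


@dataclass(frozen=True)
class HoogsteenEdge:
    donor_res: int
    acceptor_res: int
    bonds: tuple  # ((donor atom, acceptor atom, distance, plane angle), ...)


@dataclass
class Tetrad:
    cycle: tuple[int, int, int, int]  # donor->acceptor order, lowest first
    layer_index: int = -1
    centroid: tuple = ()
    sense: int = 0  # +1 / -1 cycle sense viewed along the stack axis


@dataclass
class Column:
    residues: tuple[int, ...]  # ordered by layer (top first)
    orientation: str  # up | down (majority)
    per_residue_orientation: tuple[str, ...] = ()
    broken: bool = False
    inversions: tuple[tuple[int, int], ...] = ()  # (layer, layer+1) pairs
    angle: float = 0.0  # angular position about the stack axis


@dataclass
class Loop:
    cls: str  # lateral | diagonal | propeller | V
    residues: tuple[int, ...]  # intervening (may be empty)
    anchor5: int = 0
    anchor3: int = 0


@dataclass
class VLoopRecord:
    anchor5: int
    anchor3: int
    n_intervening: int
    chi5: object = None
    chi3: object = None
    pucker5: object = None
    pucker3: object = None
    turn_locus: str = ""  # within_following_tract | between_linked_residues


@dataclass
class TopologyModel:
    tetrads: list[Tetrad] = field(default_factory=list)
    columns: list[Column] = field(default_factory=list)
    grooves: dict = field(default_factory=dict)
    loops: list[Loop] = field(default_factory=list)
    stacking: list[str] = field(default_factory=list)
    axis_down: tuple = ()
    vloops: list[VLoopRecord] = field(default_factory=list)


def _is_guanine(res) -> bool:
    return all(a in res.atoms for a in _GUANINE_ATOMS)


def _base_normal(res) -> np.ndarray:
    pts = [res.coord(n) for n in PURINE_SIX_RING]
    _, normal, _ = fit_plane(pts)
    return normal


def _base_centroid(res) -> np.ndarray:
    return np.mean([res.coord(n) for n in PURINE_SIX_RING], axis=0)


# ---------------------------------------------------------------------------


def detect_hoogsteen_pairs(model, cutoffs: GeometryCutoffs | None = None) -> list[HoogsteenEdge]:
    """Directed Hoogsteen edges i -> j among the guanines of one model."""
    if cutoffs is None:
        cutoffs = GeometryCutoffs()
    gs = [r for r in model if _is_guanine(r)]
    normals = {r.seq_index: _base_normal(r) for r in gs}
    edges = []
    for ri in gs:
        for rj in gs:
            if ri is rj:
                continue
            d1 = float(np.linalg.norm(ri.coord("N1") - rj.coord("O6")))
            d2 = float(np.linalg.norm(ri.coord("N2") - rj.coord("N7")))
            if d1 > cutoffs.n1_o6_max or d2 > cutoffs.n2_n7_max:
                continue
            cosang = abs(np.dot(normals[ri.seq_index], normals[rj.seq_index]))
            ang = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
            if ang > cutoffs.plane_angle_max:
                continue
            donor, acceptor = ri.seq_index, rj.seq_index
            if cutoffs.reverse_donor_convention:
                donor, acceptor = acceptor, donor
            edges.append(
                HoogsteenEdge(
                    donor_res=donor,
                    acceptor_res=acceptor,
                    bonds=(("N1", "O6", d1, ang), ("N2", "N7", d2, ang)),
                )
            )
    return edges


def detect_tetrads(edges: list[HoogsteenEdge]) -> list[Tetrad]:
    """All simple directed 4-cycles, deduplicated by residue set.

    Cycles are reported starting from their lowest seq_index, following
    the donor -> acceptor direction.
    """
    g = nx.DiGraph()
    for e in edges:
        g.add_edge(e.donor_res, e.acceptor_res)
    seen = {}
    for cyc in nx.simple_cycles(g, length_bound=4):
        if len(cyc) != 4:
            continue
        key = frozenset(cyc)
        if key in seen:
            continue
        start = cyc.index(min(cyc))
        seen[key] = tuple(cyc[start:] + cyc[:start])
    tetrads = [Tetrad(cycle=c) for c in seen.values()]
    counts = {}
    for t in tetrads:
        for r in t.cycle:
            counts.setdefault(r, []).append(t.cycle)
    shared = {r: cs for r, cs in counts.items() if len(cs) > 1}
    if shared:
        raise AmbiguityError(
            "residues in multiple candidate tetrads: "
            + "; ".join(f"{r}: {cs}" for r, cs in sorted(shared.items()))
        )
    return tetrads


def stack_tetrads(tetrads: list[Tetrad], model) -> tuple[list[Tetrad], list[str], np.ndarray]:
    """Order tetrads along the stack axis and label interface polarities.

    Returns (ordered tetrads with layer_index/sense set, per-interface
    stacking labels, axis_down unit vector).
    """
    if len(tetrads) < 2:
        raise ValueError("need at least two tetrads to stack")
    res_by_idx = {r.seq_index: r for r in model}
    centroids = []
    for t in tetrads:
        pts = np.array([_base_centroid(res_by_idx[i]) for i in t.cycle])
        centroids.append(pts.mean(axis=0))
    centroids = np.array(centroids)
    mean_c = centroids.mean(axis=0)
    if len(tetrads) == 2:
        axis = centroids[1] - centroids[0]
    else:
        _, _, vt = np.linalg.svd(centroids - mean_c)
        axis = vt[0]
    axis = axis / np.linalg.norm(axis)
    proj = (centroids - mean_c) @ axis
    order = np.argsort(proj)
    ordered = [tetrads[i] for i in order]
    # outer tetrad holding the 5'-most core guanine defines the top
    outer = (ordered[0], ordered[-1])
    if min(outer[1].cycle) < min(outer[0].cycle):
        ordered = ordered[::-1]
        axis = -axis
    for layer, t in enumerate(ordered):
        t.layer_index = layer
        pts = np.array([_base_centroid(res_by_idx[i]) for i in t.cycle])
        c = pts.mean(axis=0)
        t.centroid = tuple(c)
        winding = np.zeros(3)
        rel = pts - c
        for k in range(4):
            winding += np.cross(rel[k - 1], rel[k])
        t.sense = 1 if np.dot(winding, axis) > 0 else -1
    stacking = [
        "homopolar" if a.sense == b.sense else "heteropolar"
        for a, b in zip(ordered, ordered[1:])
    ]
    return ordered, stacking, axis


def _orientation(res, axis_down) -> str:
    conf = glycosidic_chi(res)
    anti_like = conf.cls in _ANTI_LIKE
    face_up = bool(np.dot(_base_normal(res), axis_down) > 0)
    return "up" if (face_up == anti_like) else "down"


def extract_columns(stack: list[Tetrad], model, axis_down) -> list[Column]:
    """Group vertically stacked residues into 4 columns.

    Layer-to-layer matching minimizes total base-centroid displacement
    (optimal bipartite assignment).  Column 0 contains the lowest core
    seq_index; the rest follow in right-handed angular order about the
    stack axis.
    """
    res_by_idx = {r.seq_index: r for r in model}
    layers = [list(t.cycle) for t in stack]
    cents = {
        i: _base_centroid(res_by_idx[i]) for layer in layers for i in layer
    }
    chains = [[i] for i in layers[0]]
    for l in range(len(layers) - 1):
        cur = [c[-1] for c in chains]
        nxt = layers[l + 1]
        cost = np.array(
            [[np.linalg.norm(cents[a] - cents[b]) for b in nxt] for a in cur]
        )
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            chains[r].append(nxt[c])

    # angular positions in a right-handed frame about axis_down
    axis_down = np.asarray(axis_down, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis_down)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - np.dot(ref, axis_down) * axis_down
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis_down, e1)
    center = np.mean([cents[i] for c in chains for i in c], axis=0)

    columns = []
    for chain in chains:
        mid = np.mean([cents[i] for i in chain], axis=0) - center
        ang = math.degrees(math.atan2(np.dot(mid, e2), np.dot(mid, e1))) % 360.0
        per_res = tuple(_orientation(res_by_idx[i], axis_down) for i in chain)
        ups = sum(o == "up" for o in per_res)
        inversions = tuple(
            (l, l + 1)
            for l in range(len(per_res) - 1)
            if per_res[l] != per_res[l + 1]
        )
        seqs = [res_by_idx[i].seq_index for i in chain]
        broken = any(abs(a - b) != 1 for a, b in zip(seqs, seqs[1:]))
        columns.append(
            Column(
                residues=tuple(chain),
                orientation="up" if ups * 2 > len(per_res) else "down",
                per_residue_orientation=per_res,
                broken=broken,
                inversions=inversions,
                angle=ang,
            )
        )
    # order: start at the column holding the lowest seq index, then walk
    # by increasing angle (counterclockwise viewed along axis_down)
    start_col = min(columns, key=lambda c: min(c.residues))
    columns.sort(key=lambda c: (c.angle - start_col.angle) % 360.0)
    return columns


def classify_grooves(
    columns: list[Column],
    model,
    cutoffs: GeometryCutoffs | None = None,
    axis_down=None,
) -> dict:
    """Label the four grooves between angularly adjacent columns.

    Groove width is the mean nearest-pair phosphorus-phosphorus distance
    between the two columns' core phosphates, measured in the plane
    perpendicular to the stack axis (so layer offsets do not inflate
    it).  Falls back to C1'-C1' distances (shifted thresholds) when P
    atoms are missing.
    """
    if cutoffs is None:
        cutoffs = GeometryCutoffs()
    if len(columns) != 4:
        raise ValueError("groove classification requires exactly 4 columns")
    res_by_idx = {r.seq_index: r for r in model}

    def project(p):
        if axis_down is None:
            return p
        ax = np.asarray(axis_down, dtype=float)
        return p - np.dot(p, ax) * ax

    core = {r for col in columns for r in col.residues}

    def column_phosphates(col):
        # phosphates on core-core backbone linkages only: loop-entry
        # phosphates reflect loop conformation, not the groove wall
        pts = []
        for r in col.residues:
            res = res_by_idx[r]
            if "P" in res.atoms and (r - 1) in core:
                pts.append(project(res.coord("P")))
        return pts

    grooves = {}
    for i in range(4):
        a, b = columns[i], columns[(i + 1) % 4]
        pa, pb = column_phosphates(a), column_phosphates(b)
        if pa and pb:
            da = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
            db = [min(np.linalg.norm(p - q) for q in pa) for p in pb]
            d = float(np.mean(da + db))
            narrow_max, medium_max = cutoffs.groove_narrow_max, cutoffs.groove_medium_max
            basis = "P-P"
        else:
            ca = [project(res_by_idx[r].coord("C1'")) for r in a.residues if "C1'" in res_by_idx[r].atoms]
            cb = [project(res_by_idx[r].coord("C1'")) for r in b.residues if "C1'" in res_by_idx[r].atoms]
            if not (ca and cb):
                raise ValueError("no P or C1' atoms available for groove widths")
            da = [min(np.linalg.norm(p - q) for q in cb) for p in ca]
            db = [min(np.linalg.norm(p - q) for q in ca) for p in cb]
            d = float(np.mean(da + db))
            narrow_max, medium_max = cutoffs.groove_narrow_max_c1, cutoffs.groove_medium_max_c1
            basis = "C1'-C1'"
        label = "narrow" if d < narrow_max else ("medium" if d < medium_max else "wide")
        grooves[f"{i}-{(i + 1) % 4}"] = {
            "label": label,
            "mean_distance": d,
            "basis": basis,
            "columns": (a.residues, b.residues),
        }
    return grooves


def classify_loops(model, stack: list[Tetrad], columns: list[Column]) -> list[Loop]:
    """Classify every inter-column connector along the sequence."""
    core = sorted({i for t in stack for i in t.cycle})
    col_of = {}
    layer_in_col = {}
    for ci, col in enumerate(columns):
        for layer, r in enumerate(col.residues):
            col_of[r] = ci
            layer_in_col[r] = layer
    layer_of = {}
    for t in stack:
        for r in t.cycle:
            layer_of[r] = t.layer_index
    n_layers = len(stack)
    all_seq = sorted(r.seq_index for r in model)
    loops = []
    for a, b in zip(core, core[1:]):
        same_col = col_of[a] == col_of[b]
        if same_col and b - a == 1 and abs(layer_of[a] - layer_of[b]) == 1:
            continue  # tract continuation
        intervening = tuple(i for i in all_seq if a < i < b and i not in core)
        if same_col:
            logger.warning("connector %s-%s stays in one column; skipping", a, b)
            continue
        rank_diff = (col_of[b] - col_of[a]) % 4
        adjacent = rank_diff in (1, 3)
        la, lb = layer_of[a], layer_of[b]
        outer = {0, n_layers - 1}
        if la == lb and la in outer:
            cls = "lateral" if adjacent else "diagonal"
        elif {la, lb} == outer:
            if not adjacent:
                logger.warning(
                    "connector %s-%s spans opposite faces of opposite columns", a, b
                )
                cls = "diagonal"
            else:
                same_dir = columns[col_of[a]].orientation == columns[col_of[b]].orientation
                cls = "propeller" if same_dir else "V"
        else:
            logger.warning("connector %s-%s has non-canonical anchors", a, b)
            cls = "lateral" if la == lb else "propeller"
        loops.append(Loop(cls=cls, residues=intervening, anchor5=a, anchor3=b))
    return loops


def detect_vloops(model, stack: list[Tetrad], columns: list[Column], loops: list[Loop]) -> list[VLoopRecord]:
    """One record per V loop, with anchor conformations and turn locus."""
    res_by_idx = {r.seq_index: r for r in model}
    layer_of = {r: t.layer_index for t in stack for r in t.cycle}
    col_of = {}
    layer_in_col = {}
    for ci, col in enumerate(columns):
        for layer, r in enumerate(col.residues):
            col_of[r] = ci
            layer_in_col[r] = layer
    n_layers = len(stack)
    records = []
    for loop in loops:
        if loop.cls != "V":
            continue
        a5, a3 = loop.anchor5, loop.anchor3
        la, lb = layer_of[a5], layer_of[a3]
        if {la, lb} != {0, n_layers - 1}:
            raise VLoopClassificationError(
                f"V-loop anchors {a5} (layer {la}) / {a3} (layer {lb}) "
                "are not on opposite outer tetrads"
            )
        rank_diff = (col_of[a3] - col_of[a5]) % 4
        if rank_diff not in (1, 3):
            raise VLoopClassificationError(
                f"V-loop anchors {a5}/{a3} occupy non-adjacent columns"
            )
        col3 = columns[col_of[a3]]
        l3 = layer_in_col[a3]
        next_layer = l3 + 1 if l3 == 0 else l3 - 1
        pair = (min(l3, next_layer), max(l3, next_layer))
        turn = (
            "within_following_tract"
            if pair in col3.inversions
            else "between_linked_residues"
        )
        r5, r3 = res_by_idx[a5], res_by_idx[a3]
        records.append(
            VLoopRecord(
                anchor5=a5,
                anchor3=a3,
                n_intervening=len(loop.residues),
                chi5=glycosidic_chi(r5),
                chi3=glycosidic_chi(r3),
                pucker5=pseudorotation(ring_torsions(r5)),
                pucker3=pseudorotation(ring_torsions(r3)),
                turn_locus=turn,
            )
        )
    return records


def analyze_topology(model, cutoffs: GeometryCutoffs | None = None) -> TopologyModel:
    """Full per-model topology: tetrads, stack, columns, grooves, loops,
    V-loop records.  Raises :class:`NoTetradsError` when no tetrad is
    detectable."""
    if cutoffs is None:
        cutoffs = GeometryCutoffs()
    edges = detect_hoogsteen_pairs(model, cutoffs)
    tetrads = detect_tetrads(edges)
    if not tetrads:
        raise NoTetradsError("no guanine tetrad detected")
    stack, stacking, axis = stack_tetrads(tetrads, model)
    columns = extract_columns(stack, model, axis)
    grooves = classify_grooves(columns, model, cutoffs, axis_down=axis)
    loops = classify_loops(model, stack, columns)
    vloops = detect_vloops(model, stack, columns, loops)
    return TopologyModel(
        tetrads=stack,
        columns=columns,
        grooves=grooves,
        loops=loops,
        stacking=stacking,
        axis_down=tuple(axis),
        vloops=vloops,
    )
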