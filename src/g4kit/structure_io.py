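"""Coordinate file I/O and nomenclature normalization.

Multi-model PDB/mmCIF files are parsed with biotite; the resulting
ensembles use a small internal data model (Atom / Residue / model lists)
that every analysis stage consumes.  Primed atom names are canonical
internally ("C1'"); legacy star forms ("C1*") and known synonyms
("O1'" -> "O4'") are normalized on read.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "StructureEnsemble",
    "FormatError",
    "ConsistencyError",
    "read_structure",
    "read_structure_text",
    "normalize_nomenclature",
    "load_alias_table",
    "write_report",
    "write_pdb",
]

BASE_TYPES = ("G", "A", "C", "T", "U", "other")
VARIANTS = ("deoxy", "ribo", "2F-ribo", "2F-arabino", "LNA", "unknown")

#: atom-name synonyms applied after star->prime normalization
ATOM_SYNONYMS = {
    "O1'": "O4'",
    "C5M": "C7",
    "OL": "O1P",
    "OR": "O2P",
    "OP1": "O1P",
    "OP2": "O2P",
}


class FormatError(ValueError):
    """File could not be parsed under the named standard."""


class ConsistencyError(ValueError):
    """Models of one ensemble disagree in residue content."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self):
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")


@dataclass
class Residue:
    chain_id: str
    seq_index: int
    name: str
    base_type: str = "other"
    variant: str = "unknown"
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_index, self.name)

    def coord(self, atom_name: str) -> np.ndarray:
        try:
            return np.asarray(self.atoms[atom_name].xyz, dtype=float)
        except KeyError:
            raise KeyError(
                f"residue {self.chain_id}:{self.seq_index} ({self.name}) has no atom {atom_name}"
            ) from None

    def has(self, *atom_names: str) -> bool:
        return all(a in self.atoms for a in atom_names)


@dataclass
class StructureEnsemble:
    """Ordered models sharing one residue list (same chain/seq/name)."""

    models: list[list[Residue]]
    source_id: str = ""

    def __post_init__(self):
        if not self.models:
            raise ValueError("ensemble needs at least one model")
        ref = [r.key for r in self.models[0]]
        for i, model in enumerate(self.models[1:], start=2):
            keys = [r.key for r in model]
            if keys != ref:
                offender = _first_mismatch(ref, keys)
                raise ConsistencyError(
                    f"model {i} residue list differs from model 1 "
                    f"(first offending residue: {offender})"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_keys(self) -> list[tuple[str, int, str]]:
        return [r.key for r in self.models[0]]

    def residue(self, model: int, seq_index: int, chain_id: str | None = None) -> Residue:
        for r in self.models[model]:
            if r.seq_index == seq_index and (chain_id is None or r.chain_id == chain_id):
                return r
        raise KeyError(f"no residue {seq_index} (chain {chain_id}) in model {model}")


def _first_mismatch(ref, other):
    for a, b in zip(ref, other):
        if a != b:
            return b
    longer = ref if len(ref) > len(other) else other
    return longer[min(len(ref), len(other))]


# ---------------------------------------------------------------------------
# reading


def _normalize_atom_name(name: str) -> str:
    name = name.strip().replace("*", "'")
    return ATOM_SYNONYMS.get(name, name)


def read_structure(path, fmt: str = "auto") -> StructureEnsemble:
    """Read a multi-model PDB or mmCIF file into a StructureEnsemble.

    Alternate locations are resolved to the highest occupancy; models with
    mismatched residue lists raise :class:`ConsistencyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    return read_structure_text(path.read_text(), fmt=fmt, source_id=path.stem)


def read_structure_text(text: str, fmt: str = "pdb", source_id: str = "") -> StructureEnsemble:
    """Parse structure file content from a string (formats: pdb, mmcif)."""
    import biotite.structure as struc

    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile

        try:
            f = PDBFile.read(io.StringIO(text))
            n_models = f.get_model_count()
            arrays = [
                f.get_structure(model=i, altloc="occupancy")
                for i in range(1, n_models + 1)
            ]
        except ConsistencyError:
            raise
        except Exception as exc:  # biotite raises various parse errors
            raise FormatError(f"cannot parse PDB content: {exc}") from exc
    elif fmt == "mmcif":
        from biotite.structure.io.pdbx import CIFFile, get_structure

        try:
            f = CIFFile.read(io.StringIO(text))
            stack = get_structure(f, model=None, altloc="occupancy")
            arrays = list(stack)
        except Exception as exc:
            raise FormatError(f"cannot parse mmCIF content: {exc}") from exc
    else:
        raise ValueError(f"unknown format: {fmt}")

    if not arrays:
        raise FormatError("file contains no models")

    models = []
    for arr in arrays:
        arr = arr[~struc.filter_solvent(arr)]
        arr = arr[~arr.hetero | np.isin(arr.res_name, _known_residue_names())]
        models.append(_array_to_residues(arr))
    return StructureEnsemble(models=models, source_id=source_id)


def _array_to_residues(arr) -> list[Residue]:
    import biotite.structure as struc

    residues = []
    for start, stop in zip(*_residue_slices(arr)):
        sub = arr[start:stop]
        atoms = {}
        for i in range(sub.array_length()):
            name = _normalize_atom_name(sub.atom_name[i])
            atoms[name] = Atom(
                name=name,
                element=str(sub.element[i]).capitalize(),
                xyz=tuple(float(x) for x in sub.coord[i]),
            )
        residues.append(
            Residue(
                chain_id=str(sub.chain_id[0]),
                seq_index=int(sub.res_id[0]),
                name=str(sub.res_name[0]).strip(),
                atoms=atoms,
            )
        )
    return residues


def _residue_slices(arr):
    import biotite.structure as struc

    starts = struc.get_residue_starts(arr)
    stops = list(starts[1:]) + [arr.array_length()]
    return starts, stops


def _known_residue_names():
    return np.array(sorted(load_alias_table().keys()))


# ---------------------------------------------------------------------------
# nomenclature


def load_alias_table(path=None) -> dict[str, tuple[str, str]]:
    """Residue-name alias table mapping name -> (base_type, variant).

    The default table ships as package data and can be replaced or
    extended by passing a TSV path with columns name/base_type/variant.
    """
    if path is None:
        path = Path(__file__).parent / "data" / "residue_aliases.tsv"
    table = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, base, variant = line.split("\t")
        if base not in BASE_TYPES or variant not in VARIANTS:
            raise ValueError(f"bad alias entry: {line!r}")
        table[name] = (base, variant)
    return table


def normalize_nomenclature(
    ensemble: StructureEnsemble, aliases: dict | None = None
) -> StructureEnsemble:
    """Resolve base_type/variant for every residue via the alias table.

    Unknown residue names pass through with variant "unknown" and a
    logged warning; the operation never fails.
    """
    if aliases is None:
        aliases = load_alias_table()
    warned = set()
    new_models = []
    for model in ensemble.models:
        new_residues = []
        for res in model:
            if res.name in aliases:
                base, variant = aliases[res.name]
            else:
                base, variant = "other", "unknown"
                if res.name not in warned:
                    logger.warning(
                        "unknown residue name %r: base_type=other, variant=unknown",
                        res.name,
                    )
                    warned.add(res.name)
            new_residues.append(replace(res, base_type=base, variant=variant))
        new_models.append(new_residues)
    return StructureEnsemble(models=new_models, source_id=ensemble.source_id)


# ---------------------------------------------------------------------------
# writing


def write_pdb(ensemble: StructureEnsemble, path) -> None:
    """Write a multi-MODEL PDB file (coordinates at PDB precision)."""
    lines = []
    for m, model in enumerate(ensemble.models, start=1):
        lines.append(f"MODEL     {m:4d}")
        serial = 1
        for res in model:
            for atom in res.atoms.values():
                name = atom.name
                # PDB column convention: 4-char names start in col 13
                pdb_name = f" {name:<3s}" if len(name) < 4 else name
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {pdb_name:<4s} {res.name:>3s} {res.chain_id:1s}"
                    f"{res.seq_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_report(report, path, fmt: str = "json") -> None:
    """Serialize an analysis report deterministically.

    JSON keeps insertion order and fixed float formatting; TSV expects a
    list of dicts (one row each) with identical keys.
    """
    path = Path(path)
    if fmt == "json":
        text = json.dumps(_round_floats(report), indent=2, allow_nan=False)
        path.write_text(text + "\n")
    elif fmt == "tsv":
        if not isinstance(report, list):
            raise ValueError("TSV reports must be a list of row dicts")
        if report:
            cols = list(report[0].keys())
        else:
            cols = []
        lines = ["\t".join(cols)]
        for row in report:
            lines.append("\t".join(_fmt_cell(row[c]) for c in cols))
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format: {fmt}")


def _fmt_cell(v) -> str:
    if isinstance(v, float):
        return f"{v:.4f}"
    return str(v)


def _round_floats(obj):
    if isinstance(obj, float):
        if obj != obj:  # NaN -> null
            return None
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj
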