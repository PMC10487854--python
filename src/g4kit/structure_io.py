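"""Multi-model PDB input/output and atom selection.

Coordinates are handled as ordered ensembles of atom records: every model
must contain the same atoms in the same (chain, residue, atom-name) order,
as is the case for NMR ensembles deposited in the PDB.  Parsing and writing
are delegated to :mod:`gemmi`; this module owns the ensemble invariants and
the selection semantics used by all downstream geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureEnsemble",
    "Selection",
    "PDBParseError",
    "StructureError",
    "SelectionError",
    "ION_RES_NAMES",
    "read_pdb",
    "write_pdb",
    "select",
    "parse_selection",
]

#: Residue names recognised as single-ion HETATM records.  Deposited files
#: vary in their ion naming, hence a configurable set; for ammonium the
#: nitrogen is the positional atom.
ION_RES_NAMES = frozenset({"K", "NH4", "NA", "TL", "TLA", "RB", "CS"})


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class StructureError(ValueError):
    """Raised when ensemble invariants are violated."""


class SelectionError(ValueError):
    """Raised for malformed selection expressions."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one model, PDB column conventions."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    xyz: tuple[float, float, float]
    model_index: int = 1
    het: bool = False

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in self.xyz):
            raise StructureError(f"non-finite coordinate for atom {self.name}")

    @property
    def is_ion(self) -> bool:
        return self.res_name.strip().upper() in ION_RES_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element.strip().upper() in {"H", "D"}

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity of the atom across models."""
        return (self.chain_id, self.res_seq, self.name)


@dataclass
class StructureEnsemble:
    """Ordered list of models, each a list of :class:`AtomRecord`."""

    models: list[list[AtomRecord]]
    metadata: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise StructureError("ensemble must contain at least one model")
        ref_keys = [a.key for a in self.models[0]]
        if len(set(ref_keys)) != len(ref_keys):
            dupes = {k for k in ref_keys if ref_keys.count(k) > 1}
            raise StructureError(f"duplicate atom keys within model: {sorted(dupes)[:3]}")
        for i, model in enumerate(self.models[1:], start=2):
            keys = [a.key for a in model]
            if keys != ref_keys:
                raise StructureError(
                    f"model {i} atom list differs from model 1 "
                    f"({len(keys)} vs {len(ref_keys)} atoms)"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_atoms(self) -> int:
        return len(self.models[0])

    def coords(self, model: int = 0) -> np.ndarray:
        """(N, 3) coordinate array of one model (0-based index)."""
        return np.array([a.xyz for a in self.models[model]], dtype=float)

    def atoms(self, model: int = 0) -> list[AtomRecord]:
        return self.models[model]

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.models[0]:
            seen.setdefault(a.chain_id)
        return list(seen)

    def residues(self, model: int = 0) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_seq, res_name) of a model."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.models[model]:
            seen.setdefault((a.chain_id, a.res_seq), a.res_name)
        return [(c, s, n) for (c, s), n in seen.items()]

    def residue_atoms(self, chain_id: str, res_seq: int, model: int = 0) -> dict[str, AtomRecord]:
        return {
            a.name: a
            for a in self.models[model]
            if a.chain_id == chain_id and a.res_seq == res_seq
        }


def read_pdb(path: str | Path, ion_res_names: Iterable[str] = ION_RES_NAMES) -> StructureEnsemble:
    """Read a (possibly multi-model) PDB file into a :class:`StructureEnsemble`.

    HETATM ion records are retained; alternate locations other than ''/'A'
    are dropped.  Residue numbering follows the source file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(errors="replace")
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if line.strip():
                raise PDBParseError(f"{path}: no ATOM/HETATM records (first content at line {lineno})")
        raise PDBParseError(f"{path}: empty file")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"{path}: {exc}") from exc

    ions = {n.upper() for n in ion_res_names}
    models: list[list[AtomRecord]] = []
    for mi, model in enumerate(st, start=1):
        records: list[AtomRecord] = []
        serial = 0
        for chain in model:
            for res in chain:
                het = res.het_flag == "H" or res.name.strip().upper() in ions
                for atom in res:
                    if atom.altloc not in ("", "A", "\x00"):
                        continue
                    serial += 1
                    records.append(
                        AtomRecord(
                            serial=serial,
                            name=atom.name,
                            element=atom.element.name,
                            res_name=res.name.strip(),
                            res_seq=res.seqid.num,
                            chain_id=chain.name,
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                            model_index=mi,
                            het=het,
                        )
                    )
        models.append(records)
    return StructureEnsemble(models=models, metadata=str(path))


def write_pdb(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write an ensemble as a PDB file re-readable by :func:`read_pdb`.

    Coordinates are written to 3 decimals (PDB fixed columns).  Multi-model
    ensembles get MODEL/ENDMDL records; ion residues are written as HETATM.
    """
    if not isinstance(ensemble, StructureEnsemble):
        raise TypeError("write_pdb expects a StructureEnsemble")
    st = gemmi.Structure()
    st.name = "g4kit"
    for mi, model_atoms in enumerate(ensemble.models, start=1):
        # group first: chain -> residue -> atoms, preserving encounter order
        # (building gemmi containers incrementally invalidates references)
        chains: dict[str, dict[tuple[int, str, bool], list[AtomRecord]]] = {}
        for a in model_atoms:
            rkey = (a.res_seq, a.res_name, a.het or a.is_ion)
            chains.setdefault(a.chain_id, {}).setdefault(rkey, []).append(a)
        model = gemmi.Model(mi)
        for chain_id, residues in chains.items():
            chain = gemmi.Chain(chain_id)
            for (res_seq, res_name, het), atoms_ in residues.items():
                res = gemmi.Residue()
                res.name = res_name
                res.seqid = gemmi.SeqId(res_seq, " ")
                res.het_flag = "H" if het else "A"
                for a in atoms_:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.xyz)
                    atom.occ = 1.0
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


@dataclass(frozen=True)
class Selection:
    """Declarative atom-selection criteria; ``None`` means no constraint."""

    chains: tuple[str, ...] | None = None
    res_seq_range: tuple[int, int] | None = None
    res_names: tuple[str, ...] | None = None
    atom_names: tuple[str, ...] | None = None
    heavy_only: bool = False

    def matches(self, atom: AtomRecord) -> bool:
        if self.chains is not None and atom.chain_id not in self.chains:
            return False
        if self.res_seq_range is not None:
            lo, hi = self.res_seq_range
            if not (lo <= atom.res_seq <= hi):
                return False
        if self.res_names is not None and atom.res_name.upper() not in self.res_names:
            return False
        if self.atom_names is not None and atom.name.upper() not in self.atom_names:
            return False
        if self.heavy_only and atom.is_hydrogen:
            return False
        return True


def parse_selection(expr: str) -> Selection:
    """Parse a small selection language: clauses joined by ``and``.

    Clauses: ``chain A,B`` — ``resi 1-4`` (or ``resi 3``) — ``resname DG,DC``
    — ``name O6,N1`` — ``heavy``.  An empty expression selects everything.
    """
    kwargs: dict = {}
    expr = expr.strip()
    if not expr:
        return Selection()
    for clause in expr.split(" and "):
        parts = clause.strip().split(None, 1)
        if not parts:
            continue
        key = parts[0].lower()
        if key == "heavy":
            if len(parts) > 1:
                raise SelectionError(f"'heavy' takes no argument: {clause!r}")
            kwargs["heavy_only"] = True
            continue
        if len(parts) != 2:
            raise SelectionError(f"clause needs an argument: {clause!r}")
        arg = parts[1].strip()
        if key == "chain":
            kwargs["chains"] = tuple(s.strip() for s in arg.split(","))
        elif key == "resi":
            try:
                if "-" in arg:
                    lo, hi = (int(x) for x in arg.split("-", 1))
                else:
                    lo = hi = int(arg)
            except ValueError as exc:
                raise SelectionError(f"bad residue range: {arg!r}") from exc
            kwargs["res_seq_range"] = (lo, hi)
        elif key == "resname":
            kwargs["res_names"] = tuple(s.strip().upper() for s in arg.split(","))
        elif key == "name":
            kwargs["atom_names"] = tuple(s.strip().upper() for s in arg.split(","))
        else:
            raise SelectionError(f"unknown selection keyword {key!r}")
    return Selection(**kwargs)


def select(ensemble: StructureEnsemble, criteria: Selection | str) -> StructureEnsemble:
    """Subset an ensemble, preserving model alignment.

    Empty selections are allowed and yield an ensemble whose models are all
    empty lists (the at-least-one-model invariant still holds).
    """
    if isinstance(criteria, str):
        criteria = parse_selection(criteria)
    keep = [criteria.matches(a) for a in ensemble.models[0]]
    models = [[a for a, k in zip(model, keep) if k] for model in ensemble.models]
    return StructureEnsemble(models=models, metadata=ensemble.metadata)
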