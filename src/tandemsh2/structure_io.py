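"""Protein structures and conformer ensembles: PDB I/O, atom selection,
topology checks.

A :class:`Structure` is one conformer stored as parallel numpy arrays (an
array-of-structs view is available through :attr:`Structure.atoms`); an
:class:`Ensemble` is an ordered collection of conformers sharing an identical
atom topology, with optional statistical weights.  Multi-model PDB is the
ensemble interchange format; parsing and writing are delegated to biotite.

Residue numbering is 1-based and follows the deposited numbering of the
tandem SH2 construct: N-SH2 spans residues 3-104, the interdomain linker
105-111 and C-SH2 112-216.  Intervals are inclusive on both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from . import constants


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class TopologyError(ValueError):
    """Raised when conformers of an ensemble disagree in atom topology."""


class SelectionError(ValueError):
    """Raised when a selection yields no atoms on a structure."""


@dataclass(frozen=True)
class Atom:
    """One atom of a conformer (a read-only view row of a Structure)."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain_id: str
    element: str
    position: np.ndarray
    ins_code: str = ""


@dataclass(frozen=True)
class Selection:
    """Atom selection by inclusive residue interval(s), atom names and chains.

    ``residue_ranges`` is a tuple of (low, high) inclusive intervals;
    ``atom_names``/``chain_ids`` of ``None`` mean "any".
    """

    residue_ranges: tuple[tuple[int, int], ...] = ()
    atom_names: frozenset[str] | None = None
    chain_ids: frozenset[str] | None = None

    def mask(self, structure: "Structure") -> np.ndarray:
        m = np.ones(structure.n_atoms, dtype=bool)
        if self.residue_ranges:
            rm = np.zeros(structure.n_atoms, dtype=bool)
            for lo, hi in self.residue_ranges:
                rm |= (structure.residue_numbers >= lo) & (structure.residue_numbers <= hi)
            m &= rm
        if self.atom_names is not None:
            m &= np.isin(structure.atom_names, sorted(self.atom_names))
        if self.chain_ids is not None:
            m &= np.isin(structure.chain_ids, sorted(self.chain_ids))
        return m


def ca_selection(lo: int, hi: int, chains: Iterable[str] | None = None) -> Selection:
    """Cα atoms of the inclusive residue interval [lo, hi]."""
    return Selection(
        residue_ranges=((lo, hi),),
        atom_names=frozenset({"CA"}),
        chain_ids=frozenset(chains) if chains is not None else None,
    )


# Named selections of the tandem SH2 construct (Cα level).
N_SH2_CA = ca_selection(*constants.N_SH2_RANGE)
C_SH2_CA = ca_selection(*constants.C_SH2_RANGE)
LINKER_CA = ca_selection(*constants.LINKER_RANGE)
PCA_CA = ca_selection(*constants.PCA_RANGE)


class Structure:
    """One conformer: ordered atoms with coordinates in Å."""

    def __init__(
        self,
        atom_names: Sequence[str],
        residue_numbers: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        serials: Sequence[int] | None = None,
        ins_codes: Sequence[str] | None = None,
        label: str = "",
    ):
        n = len(atom_names)
        if n == 0:
            raise ValueError("a Structure must contain at least one atom")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.residue_numbers = np.asarray(residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype="U5")
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.ascontiguousarray(coords, dtype=np.float64).reshape(n, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.serials = (
            np.asarray(serials, dtype=np.int64)
            if serials is not None
            else np.arange(1, n + 1, dtype=np.int64)
        )
        self.ins_codes = (
            np.asarray(ins_codes, dtype="U1") if ins_codes is not None else np.full(n, "", dtype="U1")
        )
        self.label = label

    # ------------------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def atoms(self) -> Iterator[Atom]:
        for i in range(self.n_atoms):
            yield Atom(
                serial=int(self.serials[i]),
                name=str(self.atom_names[i]),
                residue_number=int(self.residue_numbers[i]),
                residue_name=str(self.residue_names[i]),
                chain_id=str(self.chain_ids[i]),
                element=str(self.elements[i]),
                position=self.coords[i].copy(),
                ins_code=str(self.ins_codes[i]),
            )

    def masses(self) -> np.ndarray:
        return np.array(
            [constants.ATOMIC_MASSES.get(e, constants.DEFAULT_MASS) for e in self.elements]
        )

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """New Structure sharing this topology with replaced coordinates."""
        s = Structure.__new__(Structure)
        s.atom_names = self.atom_names
        s.residue_numbers = self.residue_numbers
        s.residue_names = self.residue_names
        s.chain_ids = self.chain_ids
        s.elements = self.elements
        s.coords = np.ascontiguousarray(coords, dtype=np.float64).reshape(self.n_atoms, 3)
        s.serials = self.serials
        s.ins_codes = self.ins_codes
        s.label = self.label if label is None else label
        return s

    def select(self, selection: Selection) -> "Structure":
        return select(self, selection)

    def topology_key(self) -> tuple:
        return (
            self.atom_names.tobytes(),
            self.residue_numbers.tobytes(),
            self.residue_names.tobytes(),
            self.chain_ids.tobytes(),
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Structure {self.label or '?'}: {self.n_atoms} atoms>"


def select(structure: Structure, selection: Selection) -> Structure:
    """Sub-structure of atoms matched by ``selection``, order preserved."""
    m = selection.mask(structure)
    if not m.any():
        wanted = ", ".join(f"{lo}-{hi}" for lo, hi in selection.residue_ranges) or "any"
        raise SelectionError(
            f"selection matched no atoms (residues {wanted}, "
            f"names {sorted(selection.atom_names) if selection.atom_names else 'any'})"
        )
    return Structure(
        structure.atom_names[m],
        structure.residue_numbers[m],
        structure.residue_names[m],
        structure.chain_ids[m],
        structure.elements[m],
        structure.coords[m],
        serials=structure.serials[m],
        ins_codes=structure.ins_codes[m],
        label=structure.label,
    )


class Ensemble:
    """Ordered conformers sharing identical topology, with weights."""

    def __init__(self, conformers: Sequence[Structure], weights: Sequence[float] | None = None):
        if len(conformers) == 0:
            raise ValueError("an Ensemble must contain at least one conformer")
        key = conformers[0].topology_key()
        for i, c in enumerate(conformers[1:], start=1):
            if c.topology_key() != key:
                raise TopologyError(f"conformer {i} differs in topology from conformer 0")
        self.conformers = list(conformers)
        if weights is None:
            w = np.full(len(conformers), 1.0 / len(conformers))
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (len(conformers),) or (w < 0).any():
                raise ValueError("weights must be non-negative, one per conformer")
            total = w.sum()
            if total <= 0:
                raise ValueError("weights sum to zero")
            if abs(total - 1.0) > 1e-9:
                w = w / total
        self.weights = w

    def __len__(self) -> int:
        return len(self.conformers)

    def __getitem__(self, i) -> Structure:
        return self.conformers[i]

    def __iter__(self) -> Iterator[Structure]:
        return iter(self.conformers)

    def coords_array(self) -> np.ndarray:
        """(n_conformers, n_atoms, 3) coordinate stack."""
        return np.stack([c.coords for c in self.conformers])

    def select(self, selection: Selection) -> "Ensemble":
        return Ensemble([c.select(selection) for c in self.conformers], self.weights)

    def subset(self, indices: Sequence[int], renormalize: bool = True) -> "Ensemble":
        idx = list(indices)
        w = self.weights[idx]
        return Ensemble([self.conformers[i] for i in idx], w / w.sum() if renormalize else None)


# ----------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ----------------------------------------------------------------------

def _from_atom_array(arr: bst.AtomArray, label: str) -> Structure:
    elements = np.array(
        [e if e else (n.lstrip("0123456789")[:1] or "C") for e, n in zip(arr.element, arr.atom_name)],
        dtype="U2",
    )
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else np.full(arr.array_length(), "")
    return Structure(
        arr.atom_name,
        arr.res_id,
        arr.res_name,
        arr.chain_id,
        elements,
        arr.coord,
        ins_codes=ins,
        label=label,
    )


def read_pdb(
    path: str | Path,
    multi_model_policy: str = "all",
    include_hetero: bool = False,
) -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble.

    MODEL/ENDMDL blocks become conformers.  Altloc conflicts are resolved to
    the highest-occupancy location (ties to the first / 'A'); HETATM records
    are dropped unless ``include_hetero``; insertion codes are preserved.
    """
    path = Path(path)
    if multi_model_policy not in ("all", "first"):
        raise ValueError("multi_model_policy must be 'all' or 'first'")
    try:
        pdb = PDBFile.read(str(path))
        if multi_model_policy == "first":
            arr = pdb.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
            models = [arr]
        else:
            stack = pdb.get_structure(altloc="occupancy", extra_fields=["occupancy"])
            models = list(stack) if isinstance(stack, bst.AtomArrayStack) else [stack]
    except bst.BadStructureError as exc:
        raise TopologyError(f"{path.name}: inconsistent topology across MODELs: {exc}") from exc
    except Exception as exc:  # biotite raises bare ValueError with line context
        raise StructureParseError(f"{path.name}: {exc}") from exc
    conformers = []
    for i, arr in enumerate(models):
        if not include_hetero:
            arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise StructureParseError(f"{path.name}: model {i + 1} contains no ATOM records")
        conformers.append(_from_atom_array(arr, label=f"{path.stem}[{i}]"))
    try:
        return Ensemble(conformers)
    except TopologyError as exc:
        raise TopologyError(f"{path.name}: {exc}") from exc


def _to_atom_array(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.atom_name = s.atom_names
    arr.res_id = s.residue_numbers
    arr.res_name = s.residue_names
    arr.chain_id = np.array([c[:1] or "A" for c in s.chain_ids], dtype="U1")
    arr.element = s.elements
    arr.set_annotation("ins_code", s.ins_codes)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_pdb(ensemble: Ensemble | Structure, path: str | Path) -> None:
    """Write an Ensemble (or single Structure) as a standards-conformant PDB.

    Multi-conformer ensembles get one MODEL/ENDMDL pair per conformer;
    coordinates are written to 3 decimals (PDB fixed-width convention).
    """
    if isinstance(ensemble, Structure):
        ensemble = Ensemble([ensemble])
    arrays = [_to_atom_array(c) for c in ensemble.conformers]
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        stack = bst.stack(arrays)
        pdb.set_structure(stack)
    pdb.write(str(path))
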