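"""Domain types and I/O for protein-ligand complexes, trajectories, QM
property tables and affinity metadata.

The in-memory types mirror the hierarchical layout of the on-disk store:
one group per complex (keyed by a PDB-ID-like string) holding per-atom
(``atoms_*``), per-frame (``frames_*``) and per-trajectory (``trajectory_*``)
MD datasets, and ``molecular_*`` / ``atomic_*`` QM datasets.  Coordinates are
Cartesian Å; atom and frame indices are 0-based everywhere.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .config import (
    AMINO_ACIDS,
    ATOMIC_MASSES,
    FormatError,
    H5_KEY_MAP,
    ION_RESIDUES,
    LookupError_,
    SUPPORTED_ELEMENTS,
    ValidationError,
    WATER_RESIDUES,
)

ROLES = ("protein", "ligand", "ion", "water")
AFFINITY_TYPES = ("Ki", "Kd", "IC50")
HYBRIDIZATIONS = ("sp", "sp2", "sp3", "other")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AtomRecord:
    """One atom: identity, location in the polymer, role and coordinates."""

    element: str
    atom_name: str
    residue_index: int
    residue_name: str
    chain_id: str
    role: str
    position: np.ndarray
    b_factor: float | None = None
    mass: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(
                f"atom {self.atom_name}: position must be a finite 3-vector"
            )
        if self.element not in SUPPORTED_ELEMENTS:
            raise ValidationError(f"unsupported element {self.element!r}")
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.mass is None:
            self.mass = ATOMIC_MASSES.get(self.element)
        if self.mass is not None and self.mass <= 0:
            raise ValidationError(f"atom {self.atom_name}: mass must be > 0")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclasses.dataclass
class ComplexRecord:
    """A binary protein-ligand complex (waters/ions retained but inert).

    ``protein_indices`` / ``ligand_indices`` are derived from atom roles when
    not given explicitly.  They must be disjoint, non-empty and in bounds.
    """

    entry_id: str
    atoms: list[AtomRecord]
    protein_indices: np.ndarray | None = None
    ligand_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        roles = np.array([a.role for a in self.atoms])
        if self.protein_indices is None:
            self.protein_indices = np.flatnonzero(roles == "protein")
        if self.ligand_indices is None:
            self.ligand_indices = np.flatnonzero(roles == "ligand")
        self.protein_indices = np.asarray(self.protein_indices, dtype=int)
        self.ligand_indices = np.asarray(self.ligand_indices, dtype=int)
        n = len(self.atoms)
        for name, idx in (
            ("protein", self.protein_indices),
            ("ligand", self.ligand_indices),
        ):
            if idx.size == 0:
                raise ValidationError(f"{self.entry_id}: no {name} atoms")
            if idx.min() < 0 or idx.max() >= n:
                raise ValidationError(f"{self.entry_id}: {name} index out of bounds")
        if np.intersect1d(self.protein_indices, self.ligand_indices).size:
            raise ValidationError(
                f"{self.entry_id}: protein and ligand indices overlap"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def masses(self) -> np.ndarray:
        out = np.array(
            [a.mass if a.mass is not None else np.nan for a in self.atoms]
        )
        return out

    def heavy_indices(self, indices: np.ndarray | None = None) -> np.ndarray:
        """Subset of ``indices`` (default: all atoms) that are not hydrogen."""
        if indices is None:
            indices = np.arange(self.n_atoms)
        return np.array(
            [i for i in indices if not self.atoms[int(i)].is_hydrogen], dtype=int
        )

    def subset(self, indices: Sequence[int], entry_id: str | None = None) -> "ComplexRecord":
        """New record from an atom subset, re-deriving the role partitions."""
        atoms = [self.atoms[int(i)] for i in indices]
        return ComplexRecord(entry_id or self.entry_id, atoms)


@dataclasses.dataclass
class TrajectoryRecord:
    """Frame-stacked coordinates and per-frame / per-trajectory scalars."""

    entry_id: str
    coordinates: np.ndarray              # [n_frames, n_atoms, 3], Å
    frame_times: np.ndarray | None = None  # [n_frames], ns
    frame_properties: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    trajectory_properties: dict[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValidationError("coordinates must have shape [frames, atoms, 3]")
        if self.n_frames < 1:
            raise ValidationError("a trajectory needs at least one frame")
        if self.frame_times is None:
            # MISATO-style default: 8 ns stored over the available snapshots
            self.frame_times = np.linspace(0.0, 8.0, self.n_frames)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.n_frames,):
            raise ValidationError("frame_times length must equal n_frames")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValidationError("frame_times must be strictly increasing")
        for name, arr in self.frame_properties.items():
            if np.asarray(arr).shape[0] != self.n_frames:
                raise ValidationError(f"frame property {name!r} length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


@dataclasses.dataclass
class QMRecord:
    """Quantum-chemistry-derived descriptors for one ligand.

    These values are *consumed* by the toolkit (as regression targets and QC
    inputs); nothing here computes electronic structure.  ``molecular`` holds
    scalars (electron_affinity, chemical_hardness, ... in eV where
    applicable); ``atomic`` holds per-atom arrays (partial charges per
    scheme, polarizabilities Å³, hybridizations, ...).  ``bond_orders`` in
    ``atomic`` is an [n_bonds, 3] array of (i, j, order) rows.
    """

    entry_id: str
    molecular: dict[str, float] = dataclasses.field(default_factory=dict)
    atomic: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        if self.n_atoms is not None:
            for name, arr in self.atomic.items():
                if name == "bond_orders":
                    continue
                if np.asarray(arr).shape[0] != self.n_atoms:
                    raise ValidationError(
                        f"{self.entry_id}: atomic array {name!r} length "
                        f"{np.asarray(arr).shape[0]} != n_atoms {self.n_atoms}"
                    )


@dataclasses.dataclass
class AffinityRecord:
    """One affinity measurement attached to a complex."""

    entry_id: str
    affinity_value: float   # nM
    affinity_type: str      # Ki | Kd | IC50
    protein_group: str      # UniProt-like identifier
    publication_id: str
    has_site_cofactor_or_metal: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.affinity_value) or self.affinity_value <= 0:
            raise ValidationError(
                f"{self.entry_id}: affinity must be a positive number, "
                f"got {self.affinity_value!r}"
            )
        normalized = {t.lower(): t for t in AFFINITY_TYPES}
        key = str(self.affinity_type).lower()
        if key not in normalized:
            raise ValidationError(
                f"{self.entry_id}: unknown affinity type {self.affinity_type!r} "
                f"(expected one of {AFFINITY_TYPES})"
            )
        self.affinity_type = normalized[key]


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------
# Fixed-column reader/writer for ATOM/HETATM records.  Kept in-package so
# that parse failures can name the offending line and so the role partition
# (protein / ligand / ion / water) is assigned during parsing.  Only the
# first model of a multi-model file is read.


def _role_from_record(record_type: str, residue_name: str, element: str) -> str:
    if residue_name in WATER_RESIDUES:
        return "water"
    if record_type == "ATOM":
        return "protein"
    if residue_name in ION_RESIDUES:
        return "ion"
    return "ligand"


def _guess_element(atom_name: str, residue_name: str) -> str:
    """Fallback element inference when columns 77-78 are blank."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if residue_name in AMINO_ACIDS or residue_name in WATER_RESIDUES:
        # biopolymer naming: the element is the first alphabetic character
        for ch in name:
            if ch.isalpha():
                return ch.upper()
    stripped = name.lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in SUPPORTED_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_complex_pdb(path: str | Path, entry_id: str | None = None) -> ComplexRecord:
    """Read a PDB file into a :class:`ComplexRecord`.

    Atoms keep file order.  Roles come from the record type and residue name
    (HETATM that is neither water nor a monatomic ion becomes ligand).  The
    B-factor column is captured when present; blank means absent, not zero.
    """
    path = Path(path)
    atoms: list[AtomRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            record_type = line[:6].strip()
            if record_type == "ENDMDL":
                break  # first model only
            if record_type not in ("ATOM", "HETATM"):
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16].strip() if len(line) > 16 else ""
                residue_name = line[17:20].strip()
                chain_id = line[21].strip() if len(line) > 21 else ""
                residue_index = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                b_text = line[60:66].strip()
                b_factor = float(b_text) if b_text else None
                element = line[76:78].strip().capitalize() if len(line) > 76 else ""
                if not element:
                    element = _guess_element(atom_name, residue_name)
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path.name}, line {lineno}: unparsable "
                    f"{record_type} record ({exc})"
                ) from exc
            if altloc not in ("", "A"):
                continue  # keep the primary alternate location only
            role = _role_from_record(record_type, residue_name, element)
            try:
                atoms.append(
                    AtomRecord(
                        element=element,
                        atom_name=atom_name,
                        residue_index=residue_index,
                        residue_name=residue_name,
                        chain_id=chain_id,
                        role=role,
                        position=np.array([x, y, z]),
                        b_factor=b_factor,
                    )
                )
            except ValidationError as exc:
                raise FormatError(f"{path.name}, line {lineno}: {exc}") from exc
    if entry_id is None:
        entry_id = path.stem[:4].upper().ljust(4, "X")
    roles = {a.role for a in atoms}
    if "protein" not in roles or "ligand" not in roles:
        raise ValidationError(
            f"{path.name}: file must contain both protein and ligand atoms "
            f"(found roles: {sorted(roles) or 'none'})"
        )
    return ComplexRecord(entry_id=entry_id, atoms=atoms)


def write_complex_pdb(complex_: ComplexRecord, path: str | Path) -> None:
    """Write a :class:`ComplexRecord` as minimal ATOM/HETATM records."""
    lines = []
    for serial, atom in enumerate(complex_.atoms, start=1):
        record = "ATOM  " if atom.role == "protein" else "HETATM"
        name = atom.atom_name
        # PDB convention: 1-2 char element names start in column 14
        name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
        b = atom.b_factor if atom.b_factor is not None else 0.0
        b_field = f"{b:6.2f}" if atom.b_factor is not None else "      "
        x, y, z = atom.position
        lines.append(
            f"{record}{serial:5d} {name_field}{'':1s}{atom.residue_name:>3s} "
            f"{atom.chain_id or 'A':1s}{atom.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{b_field}          "
            f"{atom.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Hierarchical HDF5 I/O
# ---------------------------------------------------------------------------

_HYB_CODES = {h: i for i, h in enumerate(HYBRIDIZATIONS)}


def _datasets_for(record: TrajectoryRecord | QMRecord) -> dict[str, np.ndarray]:
    """Flatten a record into its prefixed dataset name -> array mapping."""
    out: dict[str, np.ndarray] = {}
    if isinstance(record, TrajectoryRecord):
        out["trajectory_coordinates"] = record.coordinates
        out["frames_time"] = record.frame_times
        for name, arr in record.frame_properties.items():
            out[f"frames_{name}"] = np.asarray(arr)
        for name, value in record.trajectory_properties.items():
            out[f"trajectory_{name}"] = np.asarray(value)
    elif isinstance(record, QMRecord):
        for name, value in record.molecular.items():
            out[f"molecular_{name}"] = np.asarray(value)
        for name, arr in record.atomic.items():
            if name == "hybridization":
                arr = np.array([_HYB_CODES.get(str(h), 3) for h in arr])
            out[f"atomic_{name}"] = np.asarray(arr)
    else:  # pragma: no cover - guarded by type hints
        raise ValidationError(f"cannot serialize {type(record).__name__}")
    return out


def write_h5(
    records: Iterable[TrajectoryRecord | QMRecord],
    path: str | Path,
    mode: str = "a",
) -> None:
    """Write records into ``/{ENTRY_ID}/{dataset}`` hierarchical layout.

    Per-atom MD datasets are prefixed ``atoms_``, per-frame ``frames_``,
    per-trajectory ``trajectory_``; QM datasets use ``molecular_`` /
    ``atomic_``.  Arrays round-trip bit-identically.
    """
    records = list(records)
    ids = [r.entry_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("entry ids must be unique within one write")
    with h5py.File(path, mode) as fh:
        for record in records:
            if record.entry_id in fh:
                del fh[record.entry_id]
            group = fh.create_group(record.entry_id)
            for name, arr in _datasets_for(record).items():
                group.create_dataset(name, data=arr)


def write_h5_datasets(
    path: str | Path, entry_id: str, datasets: dict[str, np.ndarray]
) -> None:
    """Write already-prefixed datasets (e.g. ``atoms_adaptability``)."""
    with h5py.File(path, "a") as fh:
        group = fh.require_group(entry_id)
        for name, arr in datasets.items():
            if name in group:
                del group[name]
            group.create_dataset(name, data=np.asarray(arr))


def read_h5(path: str | Path, entry_id: str, property_name: str) -> np.ndarray:
    """Read one dataset; unknown keys raise listing what is available."""
    property_name = H5_KEY_MAP.get(property_name, property_name)
    with h5py.File(path, "r") as fh:
        if entry_id not in fh:
            raise LookupError_(
                f"no entry {entry_id!r} in {path} "
                f"(available: {sorted(fh.keys())[:20]})"
            )
        group = fh[entry_id]
        if property_name not in group:
            raise LookupError_(
                f"no property {property_name!r} for entry {entry_id!r} "
                f"(available: {sorted(group.keys())})"
            )
        return group[property_name][()]


def list_h5_properties(path: str | Path, entry_id: str) -> list[str]:
    with h5py.File(path, "r") as fh:
        if entry_id not in fh:
            raise LookupError_(
                f"no entry {entry_id!r} in {path} "
                f"(available: {sorted(fh.keys())[:20]})"
            )
        return sorted(fh[entry_id].keys())


def list_h5_entries(path: str | Path) -> list[str]:
    with h5py.File(path, "r") as fh:
        return sorted(fh.keys())


# ---------------------------------------------------------------------------
# Affinity CSV I/O
# ---------------------------------------------------------------------------

_AFFINITY_COLUMNS = [
    "entry_id",
    "affinity_value",
    "affinity_type",
    "protein_group",
    "publication_id",
    "has_site_cofactor_or_metal",
]


def read_affinity_table(path: str | Path) -> list[AffinityRecord]:
    """Read affinity metadata from CSV (one record per row).

    Required columns: entry_id, affinity_value (nM), affinity_type
    (Ki/Kd/IC50, case-insensitive), protein_group, publication_id.  The
    cofactor/metal flag column is optional and defaults to False.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"cannot read affinity table {path}: {exc}") from exc
    missing = [c for c in _AFFINITY_COLUMNS[:5] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            AffinityRecord(
                entry_id=str(row.entry_id),
                affinity_value=float(row.affinity_value),
                affinity_type=str(row.affinity_type),
                protein_group=str(row.protein_group),
                publication_id=str(row.publication_id),
                has_site_cofactor_or_metal=bool(
                    getattr(row, "has_site_cofactor_or_metal", False)
                ),
            )
        )
    return records


def write_affinity_table(records: Sequence[AffinityRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "entry_id": r.entry_id,
                "affinity_value": r.affinity_value,
                "affinity_type": r.affinity_type,
                "protein_group": r.protein_group,
                "publication_id": r.publication_id,
                "has_site_cofactor_or_metal": r.has_site_cofactor_or_metal,
            }
            for r in records
        ],
        columns=_AFFINITY_COLUMNS,
    )
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")
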