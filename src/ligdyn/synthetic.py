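"""Seeded synthetic fixtures: toy complexes, trajectories with controlled
per-atom mobility, QM property tables with planted outliers, and affinity
clusters with a known ground-truth affinity function.

Every generator is a pure function of (seed, parameters), so repeated calls
are bit-identical.  Trajectory displacements are i.i.d. isotropic Gaussian
rather than force-field dynamics: the ground-truth adaptability of an atom
with per-axis displacement s.d. sigma is then known in closed form,
E|r - r_ref| = sigma * sqrt(8/pi) (the mean of a Maxwell distribution),
which is exactly what a fixture should provide.  A shared random rigid
motion is applied to every frame so that alignment is exercised,
defaulting to rotations up to 10 degrees and translations up to 3 Å.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .config import LigdynError
from .datamodel import (
    AffinityRecord,
    AtomRecord,
    ComplexRecord,
    QMRecord,
    TrajectoryRecord,
)

#: Fixed linear ground-truth coefficients, eV per atom of each element, used
#: for the QM-table targets: target = intercept + sum(coef[element] * count).
QM_TRUTH = {
    "electron_affinity": {
        "intercept": 1.2,
        "C": 0.05, "N": 0.22, "O": 0.31, "S": 0.18, "F": 0.40, "Cl": 0.27,
    },
    "chemical_hardness": {
        "intercept": 4.0,
        "C": -0.04, "N": -0.12, "O": -0.20, "S": -0.25, "F": 0.15, "Cl": -0.08,
    },
}

#: Per-element slope/intercept of the planted charge-polarizability line.
CHARGE_POLARIZABILITY_LINE = {
    "F": (-2.0, 0.6), "Cl": (-3.5, 2.4), "Br": (-4.0, 3.4), "I": (-4.5, 5.2),
}


@dataclasses.dataclass
class MobilityProfile:
    """Ground-truth per-atom mobility: per-axis displacement s.d., Å."""

    sigma: np.ndarray
    correlation_length: float = 0.0   # residues; 0 = independent atoms

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma < 0):
            raise LigdynError("mobility sigma must be >= 0")


# ---------------------------------------------------------------------------
# Complex generator
# ---------------------------------------------------------------------------

# canonical backbone geometry (Å): N-CA 1.46, CA-C 1.52, C-O 1.23, C-N 1.33
_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.20, 0.83, 0.0]),
    "C": np.array([2.55, 0.14, 0.0]),
    "O": np.array([2.70, -1.08, 0.35]),
}
_RESIDUE_STEP = np.array([3.35, 0.0, 0.0])   # C(i) -> N(i+1) ~ 1.33 Å gap

_LIGAND_ELEMENTS = ("C", "C", "C", "N", "O", "C", "S", "C", "N", "O",
                    "C", "F", "C", "Cl", "C")


def generate_complex(
    seed: int,
    n_residues: int = 20,
    n_ligand_atoms: int = 10,
    entry_id: str | None = None,
) -> ComplexRecord:
    """A toy protein-ligand complex with plausible, clash-free geometry.

    The protein is a meandering backbone trace of 4-atom pseudo-residues
    (N, CA, C, O at canonical bond lengths); direction changes gently per
    residue so the chain is self-avoiding.  The ligand is a zig-zag chain
    of mixed elements at 1.5 Å spacing placed so at least one heavy atom
    lies within 4 Å of the protein without steric clashes.  Deterministic
    per seed.
    """
    if n_residues < 3:
        raise LigdynError("need at least 3 residues")
    if n_ligand_atoms < 2:
        raise LigdynError("need at least 2 ligand atoms")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    origin = np.zeros(3)
    direction = 0.0
    for res in range(n_residues):
        # gentle in-plane turn plus small vertical drift keeps the trace
        # self-avoiding without any search
        direction += rng.uniform(-0.25, 0.25)
        rot = Rotation.from_euler("z", direction).as_matrix()
        lift = np.array([0.0, 0.0, 0.4 * np.sin(res * 0.7)])
        for name in ("N", "CA", "C", "O"):
            element = name[0]
            position = origin + rot @ _BACKBONE_OFFSETS[name] + lift
            atoms.append(
                AtomRecord(
                    element=element,
                    atom_name=name,
                    residue_index=res + 1,
                    residue_name="GLY",
                    chain_id="A",
                    role="protein",
                    position=position,
                )
            )
        origin = origin + rot @ _RESIDUE_STEP
    protein_coords = np.array([a.position for a in atoms])
    # ligand: zig-zag chain placed above the chain midpoint, then backed
    # away along +z until clash-free but still in 4 Å contact
    elements = [
        _LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)] for i in range(n_ligand_atoms)
    ]
    chain = np.zeros((n_ligand_atoms, 3))
    for i in range(1, n_ligand_atoms):
        step = np.array(
            [1.30, 0.75 * (-1) ** i, 0.25 * np.sin(i * 1.3)]
        )
        chain[i] = chain[i - 1] + step
    mid = protein_coords[len(protein_coords) // 2]
    anchor = mid + np.array([0.0, 2.0, 3.4])
    placed = None
    for attempt in range(40):
        candidate = chain - chain.mean(axis=0) + anchor + np.array(
            [0.0, 0.0, 0.15 * attempt]
        )
        d = np.linalg.norm(
            candidate[:, None, :] - protein_coords[None, :, :], axis=2
        )
        if d.min() >= 2.7 and d.min() <= 4.0:
            placed = candidate
            break
    if placed is None:
        raise LigdynError("ligand placement failed after bounded retries")
    for i, (element, position) in enumerate(zip(elements, placed)):
        atoms.append(
            AtomRecord(
                element=element,
                atom_name=f"{element}{i + 1}",
                residue_index=n_residues + 1,
                residue_name="LIG",
                chain_id="A",
                role="ligand",
                position=position,
            )
        )
    if entry_id is None:
        entry_id = f"S{seed % 1000:03d}"
    return ComplexRecord(entry_id=entry_id, atoms=atoms)


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------


def generate_trajectory(
    complex_: ComplexRecord,
    profile: MobilityProfile,
    n_frames: int = 100,
    seed: int = 0,
    rigid_rotation_deg: float = 10.0,
    rigid_translation: float = 3.0,
    total_time_ns: float = 8.0,
) -> TrajectoryRecord:
    """Frames = reference + per-atom Gaussian displacement + shared rigid
    motion.

    Frame 0 is the input structure.  Every later frame displaces atom x by
    i.i.d. N(0, sigma_x^2) per axis and then applies one random rigid
    rotation (up to ``rigid_rotation_deg``) and translation (up to
    ``rigid_translation`` Å) shared by all atoms of that frame, so
    downstream alignment has real work to do.  Times are evenly spaced
    over ``total_time_ns``.
    """
    sigma = profile.sigma
    if sigma.shape[0] != complex_.n_atoms:
        raise LigdynError(
            f"profile length {sigma.shape[0]} != atom count {complex_.n_atoms}"
        )
    rng = np.random.default_rng(seed)
    reference = complex_.coordinates
    frames = np.empty((n_frames, complex_.n_atoms, 3))
    frames[0] = reference
    for f in range(1, n_frames):
        displaced = reference + rng.normal(0.0, 1.0, reference.shape) * sigma[:, None]
        angle = np.deg2rad(rigid_rotation_deg) * rng.uniform(-1.0, 1.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rot = Rotation.from_rotvec(angle * axis).as_matrix()
        shift = rng.uniform(-rigid_translation, rigid_translation, size=3)
        center = displaced.mean(axis=0)
        frames[f] = (displaced - center) @ rot.T + center + shift
    return TrajectoryRecord(
        entry_id=complex_.entry_id,
        coordinates=frames,
        frame_times=np.linspace(0.0, total_time_ns, n_frames),
    )


# ---------------------------------------------------------------------------
# QM table generator
# ---------------------------------------------------------------------------


def generate_qm_table(
    seed: int,
    n_molecules: int = 300,
    outlier_rate: float = 0.0,
    target_noise: float = 0.02,
    n_atoms_range: tuple[int, int] = (6, 16),
) -> tuple[list[QMRecord], list[ComplexRecord], dict]:
    """QM records with linear-in-composition targets and planted outliers.

    Molecular targets: electron affinity and chemical hardness are fixed
    linear functions of the element counts plus Gaussian noise of s.d.
    ``target_noise`` eV.  Atomic tables: per-halogen partial charge and
    polarizability lie on a noisy element-specific line; a fraction
    ``outlier_rate`` of molecules gets one halogen pushed far off its line
    (recorded in the returned truth dict).  Also returns matching toy
    complexes so the molecules can be graph-featurized.

    Truth dict keys: ``targets`` [n, 2] noiseless values,
    ``outlier_entries`` (entry ids), ``outlier_atoms``
    {entry_id: atom index}.
    """
    if not 0.0 <= outlier_rate < 0.5:
        raise LigdynError("outlier_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    records: list[QMRecord] = []
    complexes: list[ComplexRecord] = []
    clean_targets = np.zeros((n_molecules, 2))
    outlier_entries: list[str] = []
    outlier_atoms: dict[str, int] = {}
    n_outliers = int(round(outlier_rate * n_molecules))
    outlier_set = set(
        rng.choice(n_molecules, size=n_outliers, replace=False).tolist()
    ) if n_outliers else set()
    for m in range(n_molecules):
        entry_id = f"Q{m:04d}"
        n_atoms = int(rng.integers(n_atoms_range[0], n_atoms_range[1] + 1))
        complex_ = generate_complex(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_residues=3,
            n_ligand_atoms=n_atoms,
            entry_id=entry_id,
        )
        elements = complex_.elements[complex_.ligand_indices]
        ea = QM_TRUTH["electron_affinity"]["intercept"]
        hardness = QM_TRUTH["chemical_hardness"]["intercept"]
        for element in elements:
            ea += QM_TRUTH["electron_affinity"].get(element, 0.0)
            hardness += QM_TRUTH["chemical_hardness"].get(element, 0.0)
        clean_targets[m] = (ea, hardness)
        charges = np.full(len(elements), np.nan)
        polarizabilities = np.full(len(elements), np.nan)
        for i, element in enumerate(elements):
            line = CHARGE_POLARIZABILITY_LINE.get(element)
            if line is None:
                charges[i] = rng.normal(0.0, 0.2)
                polarizabilities[i] = rng.uniform(0.8, 2.0)
                continue
            slope, intercept = line
            charge = rng.uniform(-0.35, -0.05)
            charges[i] = charge
            polarizabilities[i] = (
                intercept + slope * charge + rng.normal(0.0, 0.03)
            )
        if m in outlier_set:
            halogen_positions = [
                i for i, e in enumerate(elements)
                if e in CHARGE_POLARIZABILITY_LINE
            ]
            if halogen_positions:
                i = int(rng.choice(halogen_positions))
                # push the point ~10x the line's residual spread off-line
                polarizabilities[i] += rng.choice([-1.0, 1.0]) * 1.0
                outlier_entries.append(entry_id)
                outlier_atoms[entry_id] = i
        records.append(
            QMRecord(
                entry_id=entry_id,
                molecular={
                    "electron_affinity": float(
                        ea + rng.normal(0.0, target_noise)
                    ),
                    "chemical_hardness": float(
                        hardness + rng.normal(0.0, target_noise)
                    ),
                    "homo_lumo_gap": float(rng.uniform(2.0, 6.0)),
                    "n_electrons": float(2 * rng.integers(10, 60)),
                    "closed_shell": 1.0,
                },
                atomic={
                    "partial_charge": charges,
                    "atomic_polarizability": polarizabilities,
                },
                n_atoms=len(elements),
            )
        )
        complexes.append(complex_)
    truth = {
        "targets": clean_targets,
        "outlier_entries": outlier_entries,
        "outlier_atoms": outlier_atoms,
    }
    return records, complexes, truth


# ---------------------------------------------------------------------------
# Affinity cluster generator
# ---------------------------------------------------------------------------

#: Ground-truth log10-affinity contribution per ligand heavy element.
#: Effect sizes chosen so a cluster of ligand variants spans the multi-decade
#: affinity range typical of a published SAR series.
AFFINITY_TRUTH = {
    "intercept": 4.0,   # log10 nM
    "C": -0.10, "N": -0.60, "O": -0.45, "S": 0.30, "F": -0.90, "Cl": 0.50,
}


def true_log10_affinity(elements: np.ndarray) -> float:
    """Noiseless planted affinity law: linear in ligand composition."""
    value = AFFINITY_TRUTH["intercept"]
    for element in elements:
        value += AFFINITY_TRUTH.get(element, 0.0)
    return float(value)


def generate_affinity_clusters(
    seed: int,
    n_clusters: int = 6,
    cluster_size_range: tuple[int, int] = (4, 8),
    label_noise: float = 0.05,
    violation_fraction: float = 0.0,
) -> tuple[list[AffinityRecord], dict[str, ComplexRecord], dict]:
    """Affinity clusters with a known composition-linear affinity law.

    Each cluster shares a protein (its own protein_group and
    publication_id) and affinity type; members are ligand variants of a
    shared scaffold differing in composition.  True log10 affinity is
    linear in ligand element counts plus Gaussian noise of s.d.
    ``label_noise``.  A fraction of clusters is made to violate benchmark
    filters (too small, low dynamic range, or cofactor-flagged), recorded
    in the truth dict under ``violations``.
    """
    rng = np.random.default_rng(seed)
    records: list[AffinityRecord] = []
    complexes: dict[str, ComplexRecord] = {}
    violations: dict[str, str] = {}
    affinity_types = ("Ki", "Kd", "IC50")
    n_violating = int(round(violation_fraction * n_clusters))
    violating = set(range(n_violating))   # first clusters violate, by design
    for c in range(n_clusters):
        group = f"P{c:03d}"
        publication = f"PUB{c:03d}"
        affinity_type = affinity_types[c % 3]
        size = int(rng.integers(cluster_size_range[0], cluster_size_range[1] + 1))
        violation = None
        if c in violating:
            violation = ("small", "low_range", "cofactor")[c % 3]
            if violation == "small":
                size = 1
        protein_seed = int(rng.integers(0, 2**31 - 1))
        for m in range(size):
            entry_id = f"A{c:02d}{m:02d}"
            complex_ = generate_complex(
                seed=protein_seed + m + 1,
                n_residues=8,
                n_ligand_atoms=int(rng.integers(6, 19)),
                entry_id=entry_id,
            )
            complexes[entry_id] = complex_
            elements = complex_.elements[complex_.ligand_indices]
            log_affinity = true_log10_affinity(elements) + rng.normal(
                0.0, label_noise
            )
            if violation == "low_range":
                log_affinity = 2.0 + rng.uniform(0.0, 0.3)
            records.append(
                AffinityRecord(
                    entry_id=entry_id,
                    affinity_value=float(10.0**log_affinity),
                    affinity_type=affinity_type,
                    protein_group=group,
                    publication_id=publication,
                    has_site_cofactor_or_metal=(violation == "cofactor"),
                )
            )
        if violation:
            violations[group] = violation
    truth = {"violations": violations, "law": dict(AFFINITY_TRUTH)}
    return records, complexes, truth
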