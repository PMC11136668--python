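"""Trajectory-derived descriptors of protein-ligand dynamics.

Core quantity: per-atom *adaptability*

    gamma_x = (1 / N_frames) * sum_i | r_ref,x - r_i,x |

the mean Euclidean distance of atom x from its reference-frame position,
taken over all frames of the trajectory after each frame is rigidly
superposed onto the reference frame.  Adaptability measures induced-fit
plasticity: atoms that drift far from their starting position score high.
Companion descriptors: RMSF (fluctuation about the time-mean position),
ligand RMSD after protein-frame alignment, protein-ligand center-of-mass
distance, and buried solvent-accessible surface area on complex formation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.transform import Rotation

from .config import (
    DEFAULTS,
    AlignmentError,
    ConfigurationError,
    ValidationError,
    VDW_RADII,
)
from .datamodel import ComplexRecord, TrajectoryRecord


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``transform(x)`` applies ``x @ rotation.T + translation``; ``rmsd`` is
    evaluated over the selection used for the fit.
    """

    rotation: np.ndarray     # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Å
    rmsd: float              # Å

    def transform(self, coordinates: np.ndarray) -> np.ndarray:
        return coordinates @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``reference``.

    The transform is fitted over ``selection`` (default: all atoms) and can
    then be applied to the full coordinate set.  Requires >= 3 non-collinear
    selected atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise AlignmentError(
            f"shape mismatch: mobile {mobile.shape} vs reference {reference.shape}"
        )
    if selection is None:
        selection = np.arange(mobile.shape[0])
    selection = np.asarray(selection, dtype=int)
    if selection.size < 3:
        raise AlignmentError("superposition needs at least 3 selected atoms")
    mob = mobile[selection]
    ref = reference[selection]
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    mob_c = mob - mob_center
    # collinearity check: rank of the centered cloud
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise AlignmentError("degenerate (collinear) selection")
    rot, _ = Rotation.align_vectors(ref - ref_center, mob_c)
    rotation = rot.as_matrix()
    translation = ref_center - mob_center @ rotation.T
    moved = mob @ rotation.T + translation
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum(axis=1).mean()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def _aligned_frames(
    traj: TrajectoryRecord,
    reference_frame: int,
    align_selection: np.ndarray | None,
) -> np.ndarray:
    """Superpose every frame onto the reference frame; returns [F, N, 3]."""
    coords = traj.coordinates
    if not (0 <= reference_frame < traj.n_frames):
        raise IndexError(
            f"reference frame {reference_frame} out of range "
            f"[0, {traj.n_frames})"
        )
    reference = coords[reference_frame]
    aligned = np.empty_like(coords)
    for i in range(traj.n_frames):
        fit = superpose(coords[i], reference, align_selection)
        aligned[i] = fit.transform(coords[i])
    return aligned


# ---------------------------------------------------------------------------
# Adaptability and RMSF
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AdaptabilityProfile:
    """Per-atom adaptability gamma (Å) plus the indices it covers."""

    entry_id: str
    gamma: np.ndarray
    atom_indices: np.ndarray
    reference_frame: int = 0


def adaptability(
    traj: TrajectoryRecord,
    complex_: ComplexRecord | None = None,
    reference_frame: int = 0,
    align_selection: np.ndarray | None = None,
    drop_hydrogens: bool = True,
    include_reference_frame: bool = True,
) -> AdaptabilityProfile:
    """Per-atom mean displacement from the reference frame, aligned.

    Every frame is first superposed onto ``reference_frame`` over
    ``align_selection`` (default: protein heavy atoms when a complex is
    given, else all atoms).  gamma_x is then the mean over frames of the
    Euclidean distance of atom x from its reference position.  The
    reference frame's own (zero) term is included in the average by
    default, matching a denominator of N_frames; set
    ``include_reference_frame=False`` to average over the other frames
    only.  Hydrogens are dropped from the profile when requested.
    """
    if align_selection is None and complex_ is not None:
        align_selection = complex_.heavy_indices(complex_.protein_indices)
    aligned = _aligned_frames(traj, reference_frame, align_selection)
    reference = aligned[reference_frame]
    distances = np.linalg.norm(aligned - reference, axis=2)  # [F, N]
    if include_reference_frame:
        gamma = distances.mean(axis=0)
    else:
        if traj.n_frames < 2:
            raise ValidationError(
                "excluding the reference frame needs at least 2 frames"
            )
        keep = np.arange(traj.n_frames) != reference_frame
        gamma = distances[keep].mean(axis=0)
    if drop_hydrogens and complex_ is not None:
        atom_indices = complex_.heavy_indices()
    else:
        atom_indices = np.arange(traj.n_atoms)
    return AdaptabilityProfile(
        entry_id=traj.entry_id,
        gamma=gamma[atom_indices],
        atom_indices=atom_indices,
        reference_frame=reference_frame,
    )


def rmsf(
    traj: TrajectoryRecord,
    align_selection: np.ndarray | None = None,
    reference_frame: int = 0,
) -> np.ndarray:
    """Root-mean-square fluctuation about the time-mean position, aligned.

    Frames are superposed to the reference frame first; RMSF_x is the RMS
    of atom x's deviation from its own mean position across frames.
    """
    if traj.n_frames < 2:
        raise ValidationError("RMSF is undefined for a single frame")
    aligned = _aligned_frames(traj, reference_frame, align_selection)
    mean_positions = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean_positions) ** 2).sum(axis=2).mean(axis=0))


def ligand_rmsd(
    traj: TrajectoryRecord,
    complex_: ComplexRecord,
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame ligand RMSD after aligning each frame on the protein.

    No separate ligand fit is performed: the ligand RMSD therefore captures
    both internal ligand motion and drift within the protein frame.
    """
    ligand = complex_.ligand_indices
    if ligand.size == 0:
        raise ValidationError("ligand index set is empty")
    protein = complex_.heavy_indices(complex_.protein_indices)
    aligned = _aligned_frames(traj, reference_frame, protein)
    reference = aligned[reference_frame][ligand]
    deltas = aligned[:, ligand, :] - reference
    return np.sqrt((deltas**2).sum(axis=2).mean(axis=1))


def com_distance(
    traj: TrajectoryRecord,
    complex_: ComplexRecord,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame distance between protein and ligand centers of mass."""
    protein = complex_.protein_indices
    ligand = complex_.ligand_indices
    if mass_weighted:
        masses = complex_.masses
        if np.any(~np.isfinite(masses[np.concatenate([protein, ligand])])):
            raise ConfigurationError("missing atomic masses for COM weighting")
        w_p = masses[protein]
        w_l = masses[ligand]
    else:
        w_p = np.ones(protein.size)
        w_l = np.ones(ligand.size)
    coords = traj.coordinates
    com_p = (coords[:, protein, :] * w_p[None, :, None]).sum(axis=1) / w_p.sum()
    com_l = (coords[:, ligand, :] * w_l[None, :, None]).sum(axis=1) / w_l.sum()
    return np.linalg.norm(com_p - com_l, axis=1)


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley, Fibonacci lattice)
# ---------------------------------------------------------------------------


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately equidistributed unit vectors (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    coordinates: np.ndarray,
    elements: np.ndarray,
    probe_radius: float = DEFAULTS.probe_radius,
    n_sphere_points: int = DEFAULTS.n_sphere_points,
    radii: dict[str, float] | None = None,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Å².

    For each atom, ``n_sphere_points`` lattice points are placed on the
    expanded sphere of radius r_vdw + probe; the accessible fraction is the
    share of points outside every neighbour's expanded sphere.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii_table = radii or VDW_RADII
    try:
        r = np.array([radii_table[e] for e in elements]) + probe_radius
    except KeyError as exc:
        raise ConfigurationError(f"no van der Waals radius for element {exc}") from exc
    n = coordinates.shape[0]
    sphere = _fibonacci_sphere(n_sphere_points)
    areas = np.empty(n)
    # neighbour lists via a single distance matrix; fixtures are small
    deltas = coordinates[:, None, :] - coordinates[None, :, :]
    dist = np.sqrt((deltas**2).sum(axis=2))
    for i in range(n):
        neighbours = np.flatnonzero((dist[i] < r[i] + r) & (np.arange(n) != i))
        points = coordinates[i] + r[i] * sphere
        if neighbours.size:
            sep = points[:, None, :] - coordinates[neighbours][None, :, :]
            buried = (
                (sep**2).sum(axis=2) < (r[neighbours] ** 2)[None, :]
            ).any(axis=1)
            accessible = np.count_nonzero(~buried)
        else:
            accessible = n_sphere_points
        areas[i] = 4.0 * np.pi * r[i] ** 2 * accessible / n_sphere_points
    return areas


def buried_sasa(
    complex_: ComplexRecord,
    coordinates: np.ndarray | None = None,
    probe_radius: float = DEFAULTS.probe_radius,
    n_sphere_points: int = DEFAULTS.n_sphere_points,
) -> float:
    """Interface area buried on binding: SASA(P) + SASA(L) - SASA(PL), Å².

    Computed over protein + ligand heavy-atom-and-hydrogen sets as stored;
    waters and ions are excluded.  Non-negative up to lattice sampling
    noise.
    """
    coords = complex_.coordinates if coordinates is None else np.asarray(coordinates)
    elements = complex_.elements
    protein = complex_.protein_indices
    ligand = complex_.ligand_indices
    both = np.concatenate([protein, ligand])
    sasa_p = shrake_rupley_sasa(
        coords[protein], elements[protein], probe_radius, n_sphere_points
    ).sum()
    sasa_l = shrake_rupley_sasa(
        coords[ligand], elements[ligand], probe_radius, n_sphere_points
    ).sum()
    sasa_pl = shrake_rupley_sasa(
        coords[both], elements[both], probe_radius, n_sphere_points
    ).sum()
    return float(sasa_p + sasa_l - sasa_pl)
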