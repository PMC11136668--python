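"""Shared configuration: element tables, reference geometry, defaults, errors.

All numeric tables used across the package live here so that a single
config object can replace them (e.g. alternative radii sets, a different
one-hot vocabulary, or a key map adapting the HDF5 reader to an external
file layout).  Distances are in Å throughout, masses in Da, energies in eV.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

# ---------------------------------------------------------------------------
# Errors and exit codes
# ---------------------------------------------------------------------------


class LigdynError(Exception):
    """Base class; ``exit_code`` maps errors onto CLI exit statuses."""

    exit_code = 5


class FormatError(LigdynError):
    """Unparsable input file (bad PDB line, malformed CSV...)."""

    exit_code = 3


class ValidationError(LigdynError):
    """Input parsed but violates a domain contract (negative affinity...)."""

    exit_code = 4


class LookupError_(LigdynError):
    """Unknown entry id / property name in a hierarchical store."""

    exit_code = 4


class AlignmentError(LigdynError):
    """Degenerate geometry: too few or collinear atoms for superposition."""

    exit_code = 4


class ConfigurationError(LigdynError):
    """A required table entry (radius, mass...) is missing."""

    exit_code = 4


class SchemaError(LigdynError):
    """Feature schema mismatch between a trained model and its input."""

    exit_code = 4


# ---------------------------------------------------------------------------
# Element tables
# ---------------------------------------------------------------------------

#: Elements the toolkit recognises.  Parsing an element outside this set is a
#: validation error; the graph one-hot additionally buckets rare elements
#: into "other".
SUPPORTED_ELEMENTS = frozenset(
    {
        "H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I",
        "B", "Si", "Se",
        # common structural ions
        "Na", "K", "Mg", "Ca", "Zn", "Mn", "Fe", "Cu", "Ni", "Co", "Cd",
    }
)

#: Default one-hot vocabulary for graph node features; everything else maps
#: to the trailing "other" bucket.
ONE_HOT_VOCABULARY = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "other")

#: Standard atomic masses, Da.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "Mg": 24.305, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ca": 40.078, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Se": 78.971, "Br": 79.904, "Cd": 112.414, "I": 126.904,
}

#: Bondi van der Waals radii, Å (used by the SASA calculator).
VDW_RADII: Mapping[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
    "Na": 2.27, "K": 2.75, "Mg": 1.73, "Ca": 2.31, "Zn": 1.39,
    "Mn": 1.97, "Fe": 1.94, "Cu": 1.40, "Ni": 1.63, "Co": 1.92,
    "Cd": 1.58,
}

#: Single-bond covalent radii, Å (Cordero-style consensus values).
COVALENT_RADII: Mapping[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02,
    "Se": 1.20, "Br": 1.20, "I": 1.39,
    "Na": 1.66, "K": 2.03, "Mg": 1.41, "Ca": 1.76, "Zn": 1.22,
    "Mn": 1.39, "Fe": 1.32, "Cu": 1.32, "Ni": 1.24, "Co": 1.26,
    "Cd": 1.44,
}

#: Maximum bond-order sum per element for the valence audit.  A tuple gives
#: (neutral, cationic) allowances; the audit adds the formal charge for N-like
#: elements (N carries 3 bonds neutral, 4 when +1).
ALLOWED_VALENCE: Mapping[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 5, "S": 6, "Cl": 1, "Br": 1, "I": 1, "Se": 2,
}

#: Residue names treated as water and as monatomic ions during role
#: assignment.  Everything else arriving on a HETATM record is a ligand.
WATER_RESIDUES = frozenset({"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SOL"})
ION_RESIDUES = frozenset(
    {
        "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU",
        "CU1", "NI", "CO", "CD", "BR", "IOD", "LI", "CS", "SR", "BA",
    }
)

#: The 20 canonical amino acids plus common variants, for ATOM-record sanity.
AMINO_ACIDS = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL", "MSE", "SEC", "PYL", "HID", "HIE", "HIP", "CYX",
    }
)

# ---------------------------------------------------------------------------
# Reference geometry (CCCBDB-style experimental equilibrium values)
# ---------------------------------------------------------------------------

#: Reference bond lengths, Å, keyed by (element pair sorted, order).
#: Used by check_geometry to flag contracted / elongated bonds.
REFERENCE_BOND_LENGTHS: Mapping[tuple[str, str, float], float] = {
    ("C", "C", 1): 1.536, ("C", "C", 1.5): 1.397, ("C", "C", 2): 1.339,
    ("C", "C", 3): 1.203,
    ("C", "N", 1): 1.469, ("C", "N", 1.5): 1.352, ("C", "N", 2): 1.279,
    ("C", "N", 3): 1.153,
    ("C", "O", 1): 1.428, ("C", "O", 1.5): 1.278, ("C", "O", 2): 1.208,
    ("N", "O", 1): 1.463, ("N", "O", 1.5): 1.224, ("N", "O", 2): 1.212,
    ("N", "N", 1): 1.449, ("N", "N", 1.5): 1.308, ("N", "N", 2): 1.252,
    ("O", "O", 1): 1.475,
    ("C", "S", 1): 1.819, ("C", "S", 2): 1.611,
    ("S", "O", 1): 1.658, ("S", "O", 2): 1.431,
    ("C", "F", 1): 1.385, ("C", "Cl", 1): 1.785, ("C", "Br", 1): 1.933,
    ("C", "I", 1): 2.139,
    ("C", "P", 1): 1.858, ("P", "O", 1): 1.621, ("P", "O", 2): 1.480,
    ("C", "H", 1): 1.090, ("N", "H", 1): 1.010, ("O", "H", 1): 0.960,
    ("S", "H", 1): 1.340,
}

#: Thresholds below which a perceived bond is upgraded from single order,
#: keyed by sorted element pair -> (aromatic_below, double_below,
#: triple_below) in Å; 0 disables a tier.  Values are midpoints between the
#: reference equilibrium lengths of adjacent orders.
BOND_ORDER_THRESHOLDS: Mapping[tuple[str, str], tuple[float, float, float]] = {
    ("C", "C"): (1.47, 1.37, 1.27),
    ("C", "N"): (1.41, 1.32, 1.22),
    ("C", "O"): (1.35, 1.24, 0.0),
    ("N", "O"): (1.34, 1.218, 0.0),
    ("N", "N"): (1.38, 1.28, 1.18),
    ("C", "S"): (0.0, 1.72, 0.0),
    ("S", "O"): (0.0, 1.54, 0.0),
    ("P", "O"): (0.0, 1.55, 0.0),
}

#: Ideal VSEPR angles, degrees, per hybridization of the central atom.
IDEAL_ANGLES = {"sp": 180.0, "sp2": 120.0, "sp3": 109.47}

# ---------------------------------------------------------------------------
# Defaults
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Defaults:
    """Package-wide default parameters (all overridable per call)."""

    # featurization
    edge_cutoff: float = 4.5            # Å, radius for graph edges
    pocket_cutoff: float = 8.0          # Å, residue inclusion around ligand
    augment_amplitude: float = 0.05     # Å, per-axis uniform node translation
    target_outlier_sd: float = 20.0     # s.d., training-target filter
    # structure QC
    clash_overlap_fraction: float = 0.5     # of summed covalent radii
    bond_tolerance: float = 0.45            # Å beyond covalent-radius sum
    bond_length_tolerance: float = 0.10     # fractional deviation flagged
    angle_tolerance: float = 12.0           # degrees from ideal VSEPR
    planarity_tolerance: float = 0.25       # Å out-of-plane for sp2 centers
    qc_outlier_sd: float = 4.0              # robust-z cutoff, property screen
    homo_lumo_gap_threshold: float = 0.1    # eV, convergence proxy
    # SASA
    probe_radius: float = 1.4           # Å, water probe
    n_sphere_points: int = 960          # Fibonacci lattice points per atom
    # benchmark
    min_benchmark_entries: int = 15
    min_dynamic_range: float = 2.0      # log10 units
    max_cooccurrence: int = 5
    similarity_threshold: float = 0.3   # sequence-identity fraction
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    modal_bfactor_fraction: float = 0.8


DEFAULTS = Defaults()

#: Mapping from the internal HDF5 dataset names to names used by an external
#: hierarchical file; identity by default.  ``read_h5`` consults this so the
#: published MISATO files can be read by swapping in their key strings.
H5_KEY_MAP: dict[str, str] = {}
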