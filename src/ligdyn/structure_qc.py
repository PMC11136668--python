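"""Geometry-level structure curation checks for ligand (and complex) quality.

Re-expresses a QM-based curation protocol as deterministic geometry and
connectivity heuristics: steric-clash search, distance-based bond and
hybridization perception, valence / local-protonation audit, deviation of
bond lengths, angles and sp2 planarity from reference values, connectivity
comparison across structure versions, bivariate property-outlier screening,
and electronic-structure sanity flags consumed from QM inputs.  Every check
is deterministic and permutation-covariant; results are findings in a
report, never automatic repairs.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import (
    ALLOWED_VALENCE,
    BOND_ORDER_THRESHOLDS,
    COVALENT_RADII,
    DEFAULTS,
    IDEAL_ANGLES,
    REFERENCE_BOND_LENGTHS,
    ConfigurationError,
    ValidationError,
)
from .datamodel import QMRecord

FINDING_KINDS = (
    "clash",
    "bond_length_deviation",
    "angle_deviation",
    "planarity_deviation",
    "valence_violation",
    "local_charge_excess",
    "connectivity_change",
    "property_outlier",
    "convergence_proxy",
)


@dataclasses.dataclass
class QCFinding:
    kind: str
    atom_indices: tuple[int, ...]
    measured: float | None = None
    reference: float | None = None
    units: str = ""
    severity: str = "warn"   # info | warn | fail
    detail: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FINDING_KINDS:
            raise ValidationError(f"unknown finding kind {self.kind!r}")
        self.atom_indices = tuple(int(i) for i in self.atom_indices)


@dataclasses.dataclass
class BondTable:
    """Perceived connectivity: unordered bonded pairs with order, plus
    per-atom hybridization (sp/sp2/sp3/other)."""

    bonds: dict[tuple[int, int], float]
    hybridization: list[str]

    @staticmethod
    def key(i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise ValidationError("self-bonds are not allowed")
        return (min(i, j), max(i, j))

    def neighbors(self, i: int) -> list[int]:
        return sorted(
            b if a == i else a for (a, b) in self.bonds if i in (a, b)
        )

    def order_sum(self, i: int) -> float:
        return sum(o for (a, b), o in self.bonds.items() if i in (a, b))


@dataclasses.dataclass
class QCReport:
    entry_id: str
    findings: list[QCFinding]

    @property
    def verdict(self) -> str:
        severities = {f.severity for f in self.findings}
        if "fail" in severities:
            return "reject"
        if "warn" in severities:
            return "needs_review"
        return "clean"

    def to_dict(self) -> dict:
        return {
            "entry_id": self.entry_id,
            "verdict": self.verdict,
            "findings": [dataclasses.asdict(f) for f in self.findings],
        }


def _covalent_radii(elements: Sequence[str]) -> np.ndarray:
    try:
        return np.array([COVALENT_RADII[e] for e in elements])
    except KeyError as exc:
        raise ConfigurationError(f"no covalent radius for element {exc}") from exc


# ---------------------------------------------------------------------------
# Clash detection
# ---------------------------------------------------------------------------


def detect_clashes(
    coordinates: np.ndarray,
    elements: Sequence[str],
    overlap_fraction: float = DEFAULTS.clash_overlap_fraction,
    bonds: BondTable | None = None,
) -> list[QCFinding]:
    """Flag non-bonded pairs closer than a fraction of summed covalent radii.

    Uses a KD-tree neighbour query; results are identical to all-pairs
    enumeration.  Pairs listed in ``bonds`` are exempt.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    radii = _covalent_radii(elements)
    max_cut = overlap_fraction * 2.0 * radii.max()
    tree = cKDTree(coordinates)
    bonded = set(bonds.bonds) if bonds is not None else set()
    findings = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        if (i, j) in bonded:
            continue
        cutoff = overlap_fraction * (radii[i] + radii[j])
        distance = float(np.linalg.norm(coordinates[i] - coordinates[j]))
        if distance < cutoff:
            findings.append(
                QCFinding(
                    kind="clash",
                    atom_indices=(i, j),
                    measured=distance,
                    reference=cutoff,
                    units="Å",
                    severity="fail",
                    detail=f"{elements[i]}-{elements[j]} overlap",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Bond & hybridization perception
# ---------------------------------------------------------------------------


def _pyramidalization(center: np.ndarray, neighbors: np.ndarray) -> float:
    """Out-of-plane distance of a center from its 3+ neighbours' LS plane."""
    centroid = neighbors.mean(axis=0)
    # plane normal = smallest principal axis of the neighbour cloud
    _, _, vt = np.linalg.svd(neighbors - centroid)
    normal = vt[-1]
    return float(abs((center - centroid) @ normal))


def perceive_bonds(
    coordinates: np.ndarray,
    elements: Sequence[str],
    tolerance: float = DEFAULTS.bond_tolerance,
) -> tuple[BondTable, list[QCFinding]]:
    """Distance-based bond perception with order and hybridization estimates.

    A pair is bonded when its distance is at most the covalent-radius sum
    plus ``tolerance``; order is upgraded (1 -> 1.5/2/3) when the distance
    drops below element-pair thresholds.  Hybridization follows heavy
    connectivity count, corrected by planarity for 3-coordinate centers.
    Over-bonded atoms yield embedded valence findings rather than errors.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    elements = list(elements)
    radii = _covalent_radii(elements)
    n = len(elements)
    tree = cKDTree(coordinates)
    bonds: dict[tuple[int, int], float] = {}
    for i, j in sorted(tree.query_pairs(2.0 * radii.max() + tolerance)):
        distance = float(np.linalg.norm(coordinates[i] - coordinates[j]))
        if distance > radii[i] + radii[j] + tolerance or distance < 1e-6:
            continue
        pair = tuple(sorted((elements[i], elements[j])))
        order = 1.0
        thresholds = BOND_ORDER_THRESHOLDS.get(pair)
        if thresholds is not None:
            aromatic_below, double_below, triple_below = thresholds
            if triple_below and distance < triple_below:
                order = 3.0
            elif double_below and distance < double_below:
                order = 2.0
            elif aromatic_below and distance < aromatic_below:
                order = 1.5
        bonds[(i, j)] = order
    table = BondTable(bonds=bonds, hybridization=["other"] * n)
    findings: list[QCFinding] = []
    for i in range(n):
        neighbors = table.neighbors(i)
        heavy = [j for j in neighbors if elements[j] != "H"]
        degree = len(neighbors)
        if elements[i] == "H" or degree == 0:
            hyb = "other"
        elif degree >= 4:
            hyb = "sp3"
        elif degree == 3:
            hyb = "sp2" if _pyramidalization(
                coordinates[i], coordinates[neighbors]
            ) < DEFAULTS.planarity_tolerance else "sp3"
        elif degree == 2:
            a, b = neighbors
            v1 = coordinates[a] - coordinates[i]
            v2 = coordinates[b] - coordinates[i]
            cosang = np.clip(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1
            )
            angle = np.degrees(np.arccos(cosang))
            hyb = "sp" if angle > 155.0 else ("sp2" if angle > 115.0 else "sp3")
        else:  # terminal heavy atom: infer from its bond order
            order = table.order_sum(i)
            hyb = "sp" if order >= 3 else ("sp2" if order >= 1.5 else "sp3")
        table.hybridization[i] = hyb
        allowed = ALLOWED_VALENCE.get(elements[i])
        # a positive formal charge (unknown here) buys one bond for donors
        cap = allowed + 1 if elements[i] in ("N", "P", "O", "S") else allowed
        if allowed is not None and degree > cap:
            findings.append(
                QCFinding(
                    kind="valence_violation",
                    atom_indices=(i,),
                    measured=float(degree),
                    reference=float(cap),
                    units="bonds",
                    severity="fail",
                    detail=f"{elements[i]} with {degree} perceived bonds",
                )
            )
        _ = heavy
    return table, findings


# ---------------------------------------------------------------------------
# Valence / protonation audit
# ---------------------------------------------------------------------------


def audit_valence(
    elements: Sequence[str],
    bonds: BondTable,
    formal_charges: Sequence[int] | None = None,
) -> list[QCFinding]:
    """Flag over-valent atoms and hot local charge concentrations.

    An atom is over-valent when its bond-order sum exceeds the element's
    allowed valence plus its formal charge allowance (e.g. N carries 3
    bonds when neutral, 4 as N+).  Any atom whose one-bond neighbourhood
    (itself plus direct neighbours) accumulates formal charge >= +2 is
    flagged as local charge excess — the signature of over-protonation
    such as a guanidino carbon surrounded by three NH2+ groups (+3 within
    one bond).
    """
    n = len(elements)
    charges = np.zeros(n, dtype=int) if formal_charges is None else np.asarray(
        formal_charges, dtype=int
    )
    findings = []
    for i in range(n):
        allowed = ALLOWED_VALENCE.get(elements[i])
        if allowed is None:
            continue
        # positive formal charge buys one extra bond for N-like donors;
        # a 0.5 slack tolerates perceived aromatic/amide resonance orders
        cap = allowed + max(0, charges[i]) if elements[i] in ("N", "P", "O", "S") else allowed
        order_sum = bonds.order_sum(i)
        if order_sum - 0.5 - 1e-9 > cap:
            findings.append(
                QCFinding(
                    kind="valence_violation",
                    atom_indices=(i,),
                    measured=float(order_sum),
                    reference=float(cap),
                    units="bond order",
                    severity="fail",
                    detail=(
                        f"{elements[i]} bond-order sum {order_sum:g} exceeds "
                        f"allowance {cap} at formal charge {charges[i]:+d}"
                    ),
                )
            )
    for i in range(n):
        neighborhood = [i] + bonds.neighbors(i)
        local = int(charges[neighborhood].sum())
        if local >= 2:
            findings.append(
                QCFinding(
                    kind="local_charge_excess",
                    atom_indices=tuple(neighborhood),
                    measured=float(local),
                    reference=1.0,
                    units="e",
                    severity="fail",
                    detail=(
                        f"formal charge {local:+d} within one bond of atom {i} "
                        f"({elements[i]})"
                    ),
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Reference-geometry deviations
# ---------------------------------------------------------------------------


def check_geometry(
    coordinates: np.ndarray,
    elements: Sequence[str],
    bonds: BondTable,
    length_tolerance: float = DEFAULTS.bond_length_tolerance,
    angle_tolerance: float = DEFAULTS.angle_tolerance,
    planarity_tolerance: float = DEFAULTS.planarity_tolerance,
) -> list[QCFinding]:
    """Flag bonds, angles and sp2 planarity deviating from reference values.

    Bond lengths are compared against an internal reference table per
    (element pair, order); angles against the ideal VSEPR value for the
    central atom's hybridization; sp2 centers with 3 neighbours against an
    out-of-plane displacement tolerance.  A missing reference entry yields
    an info finding, never a failure.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    elements = list(elements)
    findings = []
    for (i, j), order in sorted(bonds.bonds.items()):
        pair = tuple(sorted((elements[i], elements[j])))
        reference = REFERENCE_BOND_LENGTHS.get((pair[0], pair[1], order))
        distance = float(np.linalg.norm(coordinates[i] - coordinates[j]))
        if reference is None:
            findings.append(
                QCFinding(
                    kind="bond_length_deviation",
                    atom_indices=(i, j),
                    measured=distance,
                    units="Å",
                    severity="info",
                    detail=f"no reference length for {pair[0]}-{pair[1]} order {order:g}",
                )
            )
            continue
        deviation = (distance - reference) / reference
        if abs(deviation) > length_tolerance:
            findings.append(
                QCFinding(
                    kind="bond_length_deviation",
                    atom_indices=(i, j),
                    measured=distance,
                    reference=reference,
                    units="Å",
                    severity="warn",
                    detail=(
                        f"{elements[i]}-{elements[j]} bond {deviation:+.1%} "
                        f"vs reference"
                    ),
                )
            )
    for center in range(len(elements)):
        neighbors = bonds.neighbors(center)
        hyb = bonds.hybridization[center]
        ideal = IDEAL_ANGLES.get(hyb)
        if len(neighbors) >= 2 and ideal is not None:
            for a, b in itertools.combinations(neighbors, 2):
                v1 = coordinates[a] - coordinates[center]
                v2 = coordinates[b] - coordinates[center]
                cosang = np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1
                )
                angle = float(np.degrees(np.arccos(cosang)))
                if abs(angle - ideal) > angle_tolerance:
                    findings.append(
                        QCFinding(
                            kind="angle_deviation",
                            atom_indices=(a, center, b),
                            measured=angle,
                            reference=ideal,
                            units="deg",
                            severity="warn",
                            detail=(
                                f"{elements[a]}-{elements[center]}-{elements[b]} "
                                f"angle vs {hyb} ideal"
                            ),
                        )
                    )
        if hyb == "sp2" and len(neighbors) == 3:
            oop = _pyramidalization(coordinates[center], coordinates[neighbors])
            if oop > planarity_tolerance:
                findings.append(
                    QCFinding(
                        kind="planarity_deviation",
                        atom_indices=(center, *neighbors),
                        measured=oop,
                        reference=planarity_tolerance,
                        units="Å",
                        severity="warn",
                        detail=f"sp2 {elements[center]} pyramidalized",
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# Connectivity comparison (before vs after optimization)
# ---------------------------------------------------------------------------


def compare_connectivity(before: BondTable, after: BondTable) -> list[QCFinding]:
    """Report created/broken bonds and order changes between two tables."""
    n_before = len(before.hybridization)
    n_after = len(after.hybridization)
    if n_before != n_after:
        raise ValidationError(
            f"atom count mismatch: {n_before} vs {n_after}"
        )
    findings = []
    all_pairs = sorted(set(before.bonds) | set(after.bonds))
    for pair in all_pairs:
        in_before = pair in before.bonds
        in_after = pair in after.bonds
        if in_before and not in_after:
            findings.append(
                QCFinding(
                    kind="connectivity_change",
                    atom_indices=pair,
                    measured=0.0,
                    reference=before.bonds[pair],
                    severity="warn",
                    detail="bond broken",
                )
            )
        elif in_after and not in_before:
            findings.append(
                QCFinding(
                    kind="connectivity_change",
                    atom_indices=pair,
                    measured=after.bonds[pair],
                    reference=0.0,
                    severity="warn",
                    detail="bond created",
                )
            )
        elif before.bonds[pair] != after.bonds[pair]:
            findings.append(
                QCFinding(
                    kind="connectivity_change",
                    atom_indices=pair,
                    measured=after.bonds[pair],
                    reference=before.bonds[pair],
                    severity="info",
                    detail="bond order changed",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Property-outlier screening (charge vs polarizability style)
# ---------------------------------------------------------------------------


def flag_property_outliers(
    x: np.ndarray,
    y: np.ndarray,
    group: Sequence[str],
    k_sd: float = DEFAULTS.qc_outlier_sd,
    min_group_size: int = 8,
) -> list[QCFinding]:
    """Per-group robust regression outliers in a bivariate property plot.

    Within each group (typically an element), a least-squares line of y on
    x is fitted and points whose residual robust z-score (median/MAD)
    exceeds ``k_sd`` are flagged — the screen used to catch wrong atom
    assignments in charge-polarizability space.  Groups smaller than
    ``min_group_size`` are skipped with an info finding; a degenerate
    (constant-x) group falls back to a univariate test on y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    findings = []
    for label in sorted(set(group.tolist())):
        members = np.flatnonzero(group == label)
        if members.size < min_group_size:
            findings.append(
                QCFinding(
                    kind="property_outlier",
                    atom_indices=tuple(members),
                    severity="info",
                    detail=f"group {label!r}: too few points ({members.size})",
                )
            )
            continue
        gx, gy = x[members], y[members]
        if np.ptp(gx) < 1e-12:
            residuals = gy - np.median(gy)
        else:
            slope, intercept = np.polyfit(gx, gy, 1)
            residuals = gy - (slope * gx + intercept)
        mad = np.median(np.abs(residuals - np.median(residuals)))
        scale = 1.4826 * mad if mad > 1e-12 else residuals.std() or 1e-12
        z = np.abs(residuals - np.median(residuals)) / scale
        for local_idx in np.flatnonzero(z > k_sd):
            findings.append(
                QCFinding(
                    kind="property_outlier",
                    atom_indices=(int(members[local_idx]),),
                    measured=float(z[local_idx]),
                    reference=k_sd,
                    units="robust z",
                    severity="warn",
                    detail=f"group {label!r} bivariate outlier",
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Electronic-structure sanity flags (consumed from QM inputs)
# ---------------------------------------------------------------------------


def screen_electronic_flags(
    qm: QMRecord,
    gap_threshold: float = DEFAULTS.homo_lumo_gap_threshold,
) -> list[QCFinding]:
    """Flag vanishing HOMO-LUMO gaps and electron-count parity problems.

    Consumes ``homo_lumo_gap`` (eV), ``n_electrons`` and the declared
    ``closed_shell`` flag from the QM record's molecular table; never
    computes them.
    """
    findings = []
    gap = qm.molecular.get("homo_lumo_gap")
    if gap is None:
        findings.append(
            QCFinding(
                kind="convergence_proxy",
                atom_indices=(),
                severity="info",
                detail="no HOMO-LUMO gap supplied",
            )
        )
    elif gap < gap_threshold:
        findings.append(
            QCFinding(
                kind="convergence_proxy",
                atom_indices=(),
                measured=float(gap),
                reference=gap_threshold,
                units="eV",
                severity="warn",
                detail="vanishing HOMO-LUMO gap",
            )
        )
    n_electrons = qm.molecular.get("n_electrons")
    closed_shell = bool(qm.molecular.get("closed_shell", 1))
    if n_electrons is None:
        findings.append(
            QCFinding(
                kind="convergence_proxy",
                atom_indices=(),
                severity="info",
                detail="no electron count supplied",
            )
        )
    elif closed_shell and int(n_electrons) % 2 == 1:
        findings.append(
            QCFinding(
                kind="convergence_proxy",
                atom_indices=(),
                measured=float(n_electrons),
                severity="fail",
                detail="odd electron count for a declared closed-shell ligand",
            )
        )
    return findings


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


def run_qc(
    coordinates: np.ndarray,
    elements: Sequence[str],
    entry_id: str = "XXXX",
    formal_charges: Sequence[int] | None = None,
    qm: QMRecord | None = None,
) -> QCReport:
    """Run the full geometry QC protocol on one molecule."""
    findings: list[QCFinding] = []
    bonds, perception_findings = perceive_bonds(coordinates, elements)
    findings.extend(detect_clashes(coordinates, elements, bonds=bonds))
    findings.extend(perception_findings)
    findings.extend(audit_valence(elements, bonds, formal_charges))
    findings.extend(check_geometry(coordinates, elements, bonds))
    if qm is not None:
        findings.extend(screen_electronic_flags(qm))
    return QCReport(entry_id=entry_id, findings=findings)
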