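"""Benchmark-set construction, leakage-aware splitting and experimental
validation against crystallographic B factors.

A reliable affinity benchmark set keeps only groups of complexes that
share a publication, protein and affinity type, are large enough, span a
wide affinity range, are not over-represented elsewhere in the collection,
and carry no cofactor or metal at the binding site.  Train/validation/test
splitting clusters protein sequences first (30% identity by default) and
assigns whole clusters to splits so similar structural motifs never leak
across the boundary.  The B-factor procedure correlates per-atom
crystallographic B factors with MD-derived RMSF after discarding entries
whose B-factor column is dominated by a single repeated value.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .config import DEFAULTS, ValidationError
from .datamodel import AffinityRecord, ComplexRecord, TrajectoryRecord
from .trajectory_metrics import rmsf


@dataclasses.dataclass
class BenchmarkSet:
    """One benchmark group: same publication, protein and affinity type."""

    name: str
    members: list[AffinityRecord]
    dynamic_range: float     # log10 units

    @property
    def size(self) -> int:
        return len(self.members)


@dataclasses.dataclass
class SplitAssignment:
    assignment: dict[str, str]   # entry_id -> train | validation | test
    cluster_ids: dict[str, int]  # entry_id -> cluster

    def split_of(self, entry_id: str) -> str:
        return self.assignment[entry_id]

    @property
    def fractions(self) -> dict[str, float]:
        n = len(self.assignment)
        out = {"train": 0.0, "validation": 0.0, "test": 0.0}
        for split in self.assignment.values():
            out[split] += 1.0 / n
        return out


# ---------------------------------------------------------------------------
# Benchmark construction
# ---------------------------------------------------------------------------


def build_benchmark(
    records: Sequence[AffinityRecord],
    min_entries: int = DEFAULTS.min_benchmark_entries,
    min_dynamic_range: float = DEFAULTS.min_dynamic_range,
    max_cooccurrence: int = DEFAULTS.max_cooccurrence,
    exclude_site_cofactors: bool = True,
) -> list[BenchmarkSet]:
    """Filter candidate groups into benchmark sets.

    Groups are keyed by (publication_id, protein_group, affinity_type) and
    must pass, in order: size >= ``min_entries``; affinity span
    log10(max/min) >= ``min_dynamic_range``; at most ``max_cooccurrence``
    records of the same protein elsewhere in the collection; and (when
    enabled) no member flagged as having a cofactor or metal at the site.
    Output order and content are independent of input record order.
    """
    groups: dict[tuple[str, str, str], list[AffinityRecord]] = {}
    protein_counts: dict[str, int] = {}
    for record in records:
        key = (record.publication_id, record.protein_group, record.affinity_type)
        groups.setdefault(key, []).append(record)
        protein_counts[record.protein_group] = (
            protein_counts.get(record.protein_group, 0) + 1
        )
    out = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda r: r.entry_id)
        if len(members) < min_entries:
            continue
        values = np.array([m.affinity_value for m in members])
        dynamic_range = float(np.log10(values.max() / values.min()))
        if dynamic_range < min_dynamic_range:
            continue
        outside = protein_counts[key[1]] - len(members)
        if outside > max_cooccurrence:
            continue
        if exclude_site_cofactors and any(
            m.has_site_cofactor_or_metal for m in members
        ):
            continue
        out.append(
            BenchmarkSet(
                name="|".join(key), members=members, dynamic_range=dynamic_range
            )
        )
    return out


# ---------------------------------------------------------------------------
# Sequence clustering and splitting
# ---------------------------------------------------------------------------


def kmer_identity(a: str, b: str, k: int = 3) -> float:
    """k-mer containment identity: shared k-mers over the smaller k-mer set.

    A lightweight stand-in for alignment-based percent identity with the
    same use: thresholding whether two sequences are similar enough to
    leak information across a data split.
    """
    if len(a) < k or len(b) < k:
        return 1.0 if a == b else 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / min(len(ka), len(kb))


def cluster_sequences(
    sequences: Mapping[str, str],
    threshold: float = DEFAULTS.similarity_threshold,
    k: int = 3,
) -> dict[str, int]:
    """Greedy single-linkage clustering at a k-mer identity threshold."""
    ids = sorted(sequences)
    parent = {i: i for i in range(len(ids))}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if kmer_identity(sequences[ids[i]], sequences[ids[j]], k) >= threshold:
                parent[find(i)] = find(j)
    roots = sorted({find(i) for i in range(len(ids))})
    renumber = {root: n for n, root in enumerate(roots)}
    return {ids[i]: renumber[find(i)] for i in range(len(ids))}


def split_by_sequence(
    sequences: Mapping[str, str],
    fractions: tuple[float, float, float] = DEFAULTS.split_fractions,
    similarity_threshold: float = DEFAULTS.similarity_threshold,
    seed: int = 0,
    k: int = 3,
) -> SplitAssignment:
    """Cluster sequences, then assign whole clusters to train/val/test.

    Clusters are shuffled deterministically by seed and assigned greedily
    to the split currently furthest below its target fraction, so achieved
    fractions land within one cluster's mass of the targets.  A cluster is
    never divided across splits.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValidationError(f"fractions must sum to 1, got {fractions}")
    if not sequences:
        raise ValidationError("no sequences to split")
    for entry_id, seq in sequences.items():
        if not seq:
            raise ValidationError(f"{entry_id}: empty sequence")
    cluster_ids = cluster_sequences(sequences, similarity_threshold, k)
    clusters: dict[int, list[str]] = {}
    for entry_id, cid in cluster_ids.items():
        clusters.setdefault(cid, []).append(entry_id)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(clusters))
    split_names = ("train", "validation", "test")
    targets = dict(zip(split_names, fractions))
    counts = {name: 0 for name in split_names}
    total = len(sequences)
    assignment: dict[str, str] = {}
    for cid in order:
        deficits = {
            name: targets[name] - counts[name] / total for name in split_names
        }
        chosen = max(split_names, key=lambda name: deficits[name])
        for entry_id in clusters[cid]:
            assignment[entry_id] = chosen
        counts[chosen] += len(clusters[cid])
    return SplitAssignment(assignment=assignment, cluster_ids=cluster_ids)


# ---------------------------------------------------------------------------
# B-factor / RMSF validation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class BFactorValidation:
    correlations: dict[str, float]
    omitted: list[str]
    skipped: list[str]

    @property
    def mean_correlation(self) -> float:
        values = list(self.correlations.values())
        return float(np.mean(values)) if values else float("nan")


def bfactor_rmsf_validation(
    complexes: Sequence[ComplexRecord],
    trajectories: Sequence[TrajectoryRecord],
    modal_fraction: float = DEFAULTS.modal_bfactor_fraction,
) -> BFactorValidation:
    """Correlate crystallographic B factors with MD-derived RMSF per entry.

    Entries whose modal B value accounts for at least ``modal_fraction``
    of atoms with a B factor are omitted (a column dominated by one
    repeated value carries no flexibility signal).  RMSF is computed after
    superposition of each frame to the first, over protein heavy atoms.
    Returns per-entry Pearson correlations and their mean.
    """
    correlations: dict[str, float] = {}
    omitted: list[str] = []
    skipped: list[str] = []
    for complex_, traj in zip(complexes, trajectories):
        atoms = complex_.heavy_indices(complex_.protein_indices)
        b = np.array(
            [
                complex_.atoms[int(i)].b_factor
                if complex_.atoms[int(i)].b_factor is not None
                else np.nan
                for i in atoms
            ]
        )
        have_b = np.isfinite(b)
        if have_b.sum() < 3:
            skipped.append(complex_.entry_id)
            continue
        values, counts = np.unique(b[have_b], return_counts=True)
        if counts.max() / have_b.sum() >= modal_fraction:
            omitted.append(complex_.entry_id)
            continue
        fluctuation = rmsf(traj, align_selection=atoms)[atoms]
        keep = have_b & np.isfinite(fluctuation)
        if keep.sum() < 3:
            skipped.append(complex_.entry_id)
            continue
        correlations[complex_.entry_id] = float(
            stats.pearsonr(b[keep], fluctuation[keep])[0]
        )
    return BFactorValidation(
        correlations=correlations, omitted=omitted, skipped=skipped
    )
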