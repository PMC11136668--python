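"""Molecular-graph construction and training-set preparation.

Nodes are heavy atoms carrying a one-hot element block (with an "other"
bucket) plus optional appended per-atom feature blocks (partial charge,
adaptability, ...).  Edges connect every atom pair within a radius cutoff
(default 4.5 Å) and are weighted by inverse distance.  Also here: binding
pocket selection, the wide (20 s.d.) training-target outlier filter, random
node-translation augmentation, and construction of relative-affinity
training pairs (per protein-and-affinity-type cluster, one base complex
paired against every other member; label = log10 affinity ratio).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import DEFAULTS, ONE_HOT_VOCABULARY, ValidationError
from .datamodel import AffinityRecord, ComplexRecord


@dataclasses.dataclass
class Graph:
    """Featurized molecular graph.

    ``edges`` holds each unordered pair once (i < j); ``edge_weights`` are
    1/distance in Å⁻¹.  ``node_origin`` is 0 for protein, 1 for ligand.
    ``feature_blocks`` names the column blocks of ``node_features`` in
    order, e.g. ``["one_hot", "partial_charge", "partial_charge_mask"]``.
    """

    node_features: np.ndarray   # [n, f]
    coordinates: np.ndarray     # [n, 3] Å
    edges: np.ndarray           # [m, 2] int, i < j
    edge_weights: np.ndarray    # [m] Å^-1
    node_origin: np.ndarray     # [n] int, 0 protein / 1 ligand
    feature_blocks: tuple[str, ...] = ("one_hot",)
    entry_id: str = ""

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]


@dataclasses.dataclass
class PairSample:
    """A relative-affinity training pair: predict log10(K_target/K_base)."""

    target_graph: Graph
    base_graph: Graph
    label: float
    cluster_id: str
    target_id: str = ""
    base_id: str = ""


def one_hot_elements(
    elements: Sequence[str],
    vocabulary: Sequence[str] = ONE_HOT_VOCABULARY,
) -> np.ndarray:
    """One-hot encode element symbols; unknown symbols hit "other"."""
    index = {e: i for i, e in enumerate(vocabulary)}
    other = index.get("other", len(vocabulary) - 1)
    out = np.zeros((len(elements), len(vocabulary)))
    for row, element in enumerate(elements):
        out[row, index.get(element, other)] = 1.0
    return out


def _radius_edges(coordinates: np.ndarray, cutoff: float) -> tuple[np.ndarray, np.ndarray]:
    """All unordered pairs within ``cutoff`` plus their inverse distances."""
    tree = cKDTree(coordinates)
    pairs = sorted(tree.query_pairs(cutoff))
    if not pairs:
        return np.zeros((0, 2), dtype=int), np.zeros(0)
    edges = np.array(pairs, dtype=int)
    distances = np.linalg.norm(
        coordinates[edges[:, 0]] - coordinates[edges[:, 1]], axis=1
    )
    return edges, 1.0 / distances


def build_graph(
    complex_: ComplexRecord,
    cutoff: float = DEFAULTS.edge_cutoff,
    drop_hydrogens: bool = True,
    extra_node_features: Mapping[str, np.ndarray] | None = None,
    vocabulary: Sequence[str] = ONE_HOT_VOCABULARY,
    atom_indices: np.ndarray | None = None,
) -> Graph:
    """Build the model-facing graph for a complex.

    Retained atoms (protein + ligand, hydrogens dropped by default, waters
    and ions always excluded) become nodes; an edge joins every pair within
    ``cutoff`` Å, weighted 1/d.  ``extra_node_features`` are appended as
    columns in declared order, each with a companion 0/1 mask column;
    arrays may cover all atoms (indexed by the retained set) and missing
    (NaN) values are zero-filled with mask 0.
    """
    if atom_indices is None:
        atom_indices = np.concatenate(
            [complex_.protein_indices, complex_.ligand_indices]
        )
        atom_indices = np.sort(atom_indices)
    if drop_hydrogens:
        atom_indices = complex_.heavy_indices(atom_indices)
    if atom_indices.size == 0:
        raise ValidationError(f"{complex_.entry_id}: empty graph")
    if atom_indices.size < 2:
        raise ValidationError(f"{complex_.entry_id}: need at least 2 atoms")
    elements = complex_.elements[atom_indices]
    coordinates = complex_.coordinates[atom_indices]
    ligand_set = set(complex_.ligand_indices.tolist())
    origin = np.array([1 if i in ligand_set else 0 for i in atom_indices])
    blocks = [one_hot_elements(elements, vocabulary)]
    block_names = ["one_hot"]
    for name, values in (extra_node_features or {}).items():
        values = np.asarray(values, dtype=float)
        column = values[atom_indices] if values.shape[0] > atom_indices.size else values
        column = np.asarray(column, dtype=float).reshape(-1)
        if column.shape[0] != atom_indices.size:
            raise ValidationError(
                f"extra feature {name!r}: length {column.shape[0]} does not "
                f"match {atom_indices.size} retained atoms"
            )
        mask = np.isfinite(column).astype(float)
        column = np.where(np.isfinite(column), column, 0.0)
        blocks.append(column[:, None])
        blocks.append(mask[:, None])
        block_names.extend([name, f"{name}_mask"])
    edges, weights = _radius_edges(coordinates, cutoff)
    return Graph(
        node_features=np.hstack(blocks),
        coordinates=coordinates,
        edges=edges,
        edge_weights=weights,
        node_origin=origin,
        feature_blocks=tuple(block_names),
        entry_id=complex_.entry_id,
    )


def select_pocket(
    complex_: ComplexRecord,
    pocket_cutoff: float = DEFAULTS.pocket_cutoff,
) -> np.ndarray:
    """Binding-pocket atom indices: whole protein residues with any heavy
    atom within ``pocket_cutoff`` Å of any ligand heavy atom, plus all
    ligand atoms.  Residues enter or leave atomically."""
    ligand_heavy = complex_.heavy_indices(complex_.ligand_indices)
    protein_heavy = complex_.heavy_indices(complex_.protein_indices)
    if ligand_heavy.size == 0:
        raise ValidationError("ligand has no heavy atoms")
    coords = complex_.coordinates
    tree = cKDTree(coords[ligand_heavy])
    near = tree.query_ball_point(coords[protein_heavy], pocket_cutoff)
    touched_residues = {
        (complex_.atoms[int(i)].chain_id, complex_.atoms[int(i)].residue_index)
        for i, hits in zip(protein_heavy, near)
        if hits
    }
    selected = [
        i
        for i in complex_.protein_indices
        if (
            complex_.atoms[int(i)].chain_id,
            complex_.atoms[int(i)].residue_index,
        )
        in touched_residues
    ]
    selected.extend(complex_.ligand_indices.tolist())
    return np.array(sorted(selected), dtype=int)


def filter_target_outliers(
    values: np.ndarray,
    k_sd: float = DEFAULTS.target_outlier_sd,
) -> np.ndarray:
    """Indices of entries within ``k_sd`` standard deviations of the mean.

    Single pass: mean and s.d. are computed once over all entries.  With
    zero spread everything is retained.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("outlier filter needs at least 2 entries")
    sd = values.std()
    if sd == 0:
        return np.arange(values.size)
    keep = np.abs(values - values.mean()) <= k_sd * sd
    return np.flatnonzero(keep)


def augment_translate(
    graph: Graph,
    amplitude: float = DEFAULTS.augment_amplitude,
    seed: int = 0,
    distribution: str = "uniform",
) -> Graph:
    """Jitter every node independently and rebuild edges from the new
    coordinates.

    Per-axis displacement is uniform in [-amplitude, +amplitude] (or
    Gaussian with s.d. ``amplitude`` when requested).  Deterministic for a
    fixed seed.  The edge cutoff is recovered from the original graph's
    minimum edge weight (1/longest edge); for an edgeless graph the
    default cutoff is used.
    """
    if amplitude < 0:
        raise ValidationError("amplitude must be >= 0")
    if amplitude == 0:
        return dataclasses.replace(graph)
    rng = np.random.default_rng(seed)
    if distribution == "uniform":
        delta = rng.uniform(-amplitude, amplitude, size=graph.coordinates.shape)
    elif distribution == "gaussian":
        delta = rng.normal(0.0, amplitude, size=graph.coordinates.shape)
    else:
        raise ValidationError(f"unknown distribution {distribution!r}")
    coordinates = graph.coordinates + delta
    if graph.n_edges:
        cutoff = 1.0 / graph.edge_weights.min() + 2.0 * amplitude * np.sqrt(3.0)
    else:
        cutoff = DEFAULTS.edge_cutoff
    edges, weights = _radius_edges(coordinates, cutoff)
    return dataclasses.replace(
        graph, coordinates=coordinates, edges=edges, edge_weights=weights
    )


def make_pairs(
    records: Sequence[AffinityRecord],
    graphs: Mapping[str, Graph],
    include_self_pair: bool = False,
) -> list[PairSample]:
    """Relative-affinity pairs from clustered records.

    Records are grouped by (protein_group, affinity_type); groups with
    fewer than two members are discarded.  Within each cluster the base
    complex is the member with the median affinity (lower median for even
    sizes; ties broken by lexicographically smallest entry id) and pairs
    it with every other member.  Label = log10(K_target / K_base).
    """
    clusters: dict[tuple[str, str], list[AffinityRecord]] = {}
    for record in records:
        clusters.setdefault(
            (record.protein_group, record.affinity_type), []
        ).append(record)
    pairs: list[PairSample] = []
    for (group, affinity_type), members in sorted(clusters.items()):
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda r: (r.affinity_value, r.entry_id))
        base = members[(len(members) - 1) // 2]
        cluster_id = f"{group}|{affinity_type}"
        for record in members:
            if record.entry_id == base.entry_id and not include_self_pair:
                continue
            pairs.append(
                PairSample(
                    target_graph=graphs[record.entry_id],
                    base_graph=graphs[base.entry_id],
                    label=float(
                        np.log10(record.affinity_value / base.affinity_value)
                    ),
                    cluster_id=cluster_id,
                    target_id=record.entry_id,
                    base_id=base.entry_id,
                )
            )
    return pairs
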