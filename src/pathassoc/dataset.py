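"""Pair dataset: compound x pathway cross-join with binary labels.

An entry is a (compound, pathway) pair whose concatenated feature vector
carries a binary label: 1 if the compound is associated with the pathway
after upward annotation propagation.  The cross-join is never materialized
as one table -- the dataset keeps the compound matrix (n_c x d_c) and the
pathway matrix (n_p x d_p) separately plus the label matrix, and entry
``k`` maps to the pair ``(k // n_p, k % n_p)``.  Duplicate feature vectors
are removed *before* the cross-join so the same vector cannot sit in both
a training and a test fold.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy import sparse
from sklearn.model_selection import train_test_split


class DatasetError(ValueError):
    pass


def pathway_filter_grid() -> list[int]:
    """The 20 pathway-size thresholds: 5..50 by 5, 50..100 by 10, 100..200 by 20."""
    return (
        list(range(5, 51, 5)) + list(range(60, 101, 10)) + list(range(120, 201, 20))
    )


def deduplicate_entities(
    vectors: Mapping[str, sparse.csr_matrix] | Mapping[str, np.ndarray],
) -> tuple[list[str], list[tuple[str, str]]]:
    """Keep one representative per group of exactly-equal feature vectors.

    Within a group the lexicographically smallest id is kept.  Returns
    ``(kept_ids, removed)`` where ``removed`` lists ``(removed_id,
    kept_id)`` pairs.  Idempotent: re-running on the kept set removes
    nothing.
    """
    groups: dict[tuple, list[str]] = {}
    for entity_id in vectors:
        vec = vectors[entity_id]
        if sparse.issparse(vec):
            v = vec.tocsr()
            v.sum_duplicates()
            v.eliminate_zeros()
            key = (v.shape[1], tuple(v.indices.tolist()), tuple(v.data.tolist()))
        else:
            arr = np.asarray(vec).ravel()
            key = tuple(arr.tolist())
        groups.setdefault(key, []).append(entity_id)

    kept: list[str] = []
    removed: list[tuple[str, str]] = []
    for ids in groups.values():
        ids = sorted(ids)
        kept.append(ids[0])
        removed.extend((other, ids[0]) for other in ids[1:])
    return sorted(kept), sorted(removed)


@dataclass(frozen=True)
class PairDataset:
    """Cross-join of compounds and pathways with binary association labels.

    ``labels[i, j]`` is 1 iff ``pathway_ids[j]`` is in the expanded
    annotation set of ``compound_ids[i]``.  The number of conceptual
    entries is ``n_compounds * n_pathways``.
    """

    compound_ids: tuple[str, ...]
    pathway_ids: tuple[str, ...]
    compound_matrix: sparse.csr_matrix  # n_c x d_c, counts
    pathway_matrix: sparse.csr_matrix  # n_p x d_p, counts
    labels: np.ndarray  # n_c x n_p, uint8
    compound_sizes: np.ndarray  # n_c, heavy-atom counts
    pathway_sizes: np.ndarray  # n_p, summed member sizes
    pathway_levels: tuple[str, ...]  # per pathway: L1/L2/L3

    def __post_init__(self) -> None:
        n_c, n_p = len(self.compound_ids), len(self.pathway_ids)
        if n_c == 0 or n_p == 0:
            raise DatasetError("dataset needs at least one compound and one pathway")
        if self.labels.shape != (n_c, n_p):
            raise DatasetError(
                f"labels shape {self.labels.shape} != ({n_c}, {n_p})"
            )

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_entries(self) -> int:
        return self.n_compounds * self.n_pathways

    @property
    def d_compound(self) -> int:
        return self.compound_matrix.shape[1]

    @property
    def d_pathway(self) -> int:
        return self.pathway_matrix.shape[1]

    @property
    def input_dim(self) -> int:
        return self.d_compound + self.d_pathway

    def entry_pairs(self, entry_indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map flat entry indices ``k`` to ``(compound_row, pathway_row)``."""
        k = np.asarray(entry_indices)
        if k.size and (k.min() < 0 or k.max() >= self.n_entries):
            raise IndexError(
                f"entry index outside 0..{self.n_entries - 1}"
            )
        return k // self.n_pathways, k % self.n_pathways

    def entry_labels(self, entry_indices: np.ndarray) -> np.ndarray:
        i_c, i_p = self.entry_pairs(entry_indices)
        return self.labels[i_c, i_p]

    def all_labels_flat(self) -> np.ndarray:
        return self.labels.reshape(-1)

    def level_of(self, pathway_id: str) -> str:
        return self.pathway_levels[self.pathway_ids.index(pathway_id)]


def cross_join(
    compound_ids: Sequence[str],
    compound_matrix: sparse.csr_matrix,
    compound_sizes: Sequence[int],
    pathway_ids: Sequence[str],
    pathway_matrix: sparse.csr_matrix,
    pathway_sizes: Sequence[int],
    pathway_levels: Sequence[str],
    expanded: Mapping[str, set[str]],
) -> PairDataset:
    """Pair every compound with every pathway; labels from ``expanded``."""
    if len(compound_ids) == 0 or len(pathway_ids) == 0:
        raise DatasetError("cross-join requires non-empty compound and pathway sets")
    col_of = {p: j for j, p in enumerate(pathway_ids)}
    labels = np.zeros((len(compound_ids), len(pathway_ids)), dtype=np.uint8)
    for i, c in enumerate(compound_ids):
        for p in expanded.get(c, ()):
            j = col_of.get(p)
            if j is not None:
                labels[i, j] = 1
    return PairDataset(
        compound_ids=tuple(compound_ids),
        pathway_ids=tuple(pathway_ids),
        compound_matrix=compound_matrix.tocsr(),
        pathway_matrix=pathway_matrix.tocsr(),
        labels=labels,
        compound_sizes=np.asarray(compound_sizes, dtype=np.int64),
        pathway_sizes=np.asarray(pathway_sizes, dtype=np.int64),
        pathway_levels=tuple(pathway_levels),
    )


def _select_compounds(ds: PairDataset, keep: np.ndarray) -> PairDataset:
    if keep.size == 0:
        raise DatasetError("filter removed every compound")
    return replace(
        ds,
        compound_ids=tuple(ds.compound_ids[i] for i in keep),
        compound_matrix=ds.compound_matrix[keep, :].tocsr(),
        labels=ds.labels[keep, :],
        compound_sizes=ds.compound_sizes[keep],
    )


def _select_pathways(ds: PairDataset, keep: np.ndarray) -> PairDataset:
    if keep.size == 0:
        raise DatasetError("filter removed every pathway")
    return replace(
        ds,
        pathway_ids=tuple(ds.pathway_ids[j] for j in keep),
        pathway_matrix=ds.pathway_matrix[keep, :].tocsr(),
        labels=ds.labels[:, keep],
        pathway_sizes=ds.pathway_sizes[keep],
        pathway_levels=tuple(ds.pathway_levels[j] for j in keep),
    )


def filter_compounds_by_size(ds: PairDataset, threshold: int) -> PairDataset:
    """Drop compounds with fewer than ``threshold`` heavy atoms."""
    if threshold < 1:
        raise DatasetError(f"threshold must be >= 1, got {threshold}")
    return _select_compounds(ds, np.flatnonzero(ds.compound_sizes >= threshold))


def filter_pathways_by_size(ds: PairDataset, threshold: int) -> PairDataset:
    """Drop pathways whose summed member size is below ``threshold``."""
    if threshold < 1:
        raise DatasetError(f"threshold must be >= 1, got {threshold}")
    return _select_pathways(ds, np.flatnonzero(ds.pathway_sizes >= threshold))


def filter_by_levels(ds: PairDataset, levels: set[str]) -> PairDataset:
    """Keep only pathways at the given hierarchy levels; compounds untouched."""
    if not levels:
        raise DatasetError("levels must be a non-empty subset of {L1, L2, L3}")
    keep = np.flatnonzero([lv in levels for lv in ds.pathway_levels])
    return _select_pathways(ds, keep)


@dataclass(frozen=True)
class SplitPlan:
    """One stratified train/test partition of the entry indices."""

    iteration: int
    seed: int
    train_indices: np.ndarray
    test_indices: np.ndarray


def stratified_split(
    ds: PairDataset, test_fraction: float, seed: int, iteration: int = 0
) -> SplitPlan:
    """Label-stratified partition of all ``n_c * n_p`` entry indices.

    Deterministic for a given seed; the test-side positive fraction matches
    the global one up to stratum rounding.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DatasetError(f"test_fraction must be in (0, 1), got {test_fraction}")
    y = ds.all_labels_flat()
    if y.min() == y.max():
        raise DatasetError("dataset needs at least one positive and one negative entry")
    n_test = int(round(ds.n_entries * test_fraction))
    if n_test == 0 or n_test == ds.n_entries:
        raise DatasetError(
            f"test_fraction {test_fraction} leaves an empty train or test side"
        )
    idx = np.arange(ds.n_entries)
    train, test = train_test_split(
        idx, test_size=test_fraction, random_state=seed, stratify=y
    )
    return SplitPlan(
        iteration=iteration,
        seed=seed,
        train_indices=np.sort(train),
        test_indices=np.sort(test),
    )


# ---------------------------------------------------------------------------
# HDF5 container

def _write_csr(group: h5py.Group, name: str, mat: sparse.csr_matrix) -> None:
    g = group.create_group(name)
    g.create_dataset("data", data=mat.data)
    g.create_dataset("indices", data=mat.indices)
    g.create_dataset("indptr", data=mat.indptr)
    g.attrs["shape"] = mat.shape


def _read_csr(group: h5py.Group, name: str) -> sparse.csr_matrix:
    g = group[name]
    return sparse.csr_matrix(
        (g["data"][...], g["indices"][...], g["indptr"][...]),
        shape=tuple(g.attrs["shape"]),
    )


def save_dataset(ds: PairDataset, path: str | Path) -> None:
    """Persist the dataset: CSR triplets, positive-pair list, ids, levels."""
    pos_i, pos_j = np.nonzero(ds.labels)
    with h5py.File(path, "w") as f:
        _write_csr(f, "compound_matrix", ds.compound_matrix)
        _write_csr(f, "pathway_matrix", ds.pathway_matrix)
        f.create_dataset("labels", data=np.stack([pos_i, pos_j], axis=1))
        str_dt = h5py.string_dtype()
        f.create_dataset("compound_ids", data=list(ds.compound_ids), dtype=str_dt)
        f.create_dataset("pathway_ids", data=list(ds.pathway_ids), dtype=str_dt)
        f.create_dataset("levels", data=list(ds.pathway_levels), dtype=str_dt)
        f.create_dataset("compound_sizes", data=ds.compound_sizes)
        f.create_dataset("pathway_sizes", data=ds.pathway_sizes)


def load_dataset(path: str | Path) -> PairDataset:
    with h5py.File(path, "r") as f:
        compound_ids = tuple(s.decode() for s in f["compound_ids"][...])
        pathway_ids = tuple(s.decode() for s in f["pathway_ids"][...])
        labels = np.zeros((len(compound_ids), len(pathway_ids)), dtype=np.uint8)
        pairs = f["labels"][...]
        if pairs.size:
            labels[pairs[:, 0], pairs[:, 1]] = 1
        return PairDataset(
            compound_ids=compound_ids,
            pathway_ids=pathway_ids,
            compound_matrix=_read_csr(f, "compound_matrix"),
            pathway_matrix=_read_csr(f, "pathway_matrix"),
            labels=labels,
            compound_sizes=f["compound_sizes"][...],
            pathway_sizes=f["pathway_sizes"][...],
            pathway_levels=tuple(s.decode() for s in f["levels"][...]),
        )
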