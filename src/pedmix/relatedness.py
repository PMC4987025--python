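"""Relationship covariance structures built from a pedigree.

Two families of structures are produced:

* the additive (numerator) relationship matrix ``A`` — expected additive
  genetic covariance between relatives, ``A = 2 x kinship`` — built by the
  tabular-method recursion in topological order, and
* 0/1 group-sharing matrices for spouse, sibship, and household
  environments, block matrices of ones over a partition of individuals.

All matrices over one pedigree share the same deterministic id ordering
(topological, ties broken by input order), so they can be used together
as random-effect covariances in one mixed model.  Storage is sparse: a
family cohort's relationship matrix is block diagonal by family.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .pedigree import Pedigree, PedigreeError, topological_order

__all__ = [
    "RelationshipStructure",
    "additive_relationship_matrix",
    "inbreeding_coefficients",
    "group_covariance_matrix",
    "household_structure_from_file",
]

GROUP_KINDS = ("spouse_share", "sib_share", "household_share")


@dataclass
class RelationshipStructure:
    """A symmetric PSD covariance structure over ordered individuals."""

    ids: tuple[str, ...]
    matrix: sp.csr_matrix
    kind: str  # additive | spouse_share | sib_share | household_share

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id list")
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def to_dense(self) -> np.ndarray:
        return self.matrix.toarray()

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    def submatrix(self, ids: list[str]) -> np.ndarray:
        idx = [self._index[i] for i in ids]
        return self.matrix[np.ix_(idx, idx)].toarray()

    def reordered(self, ids: list[str]) -> "RelationshipStructure":
        """The same structure over a permutation of the id list."""
        idx = [self._index[i] for i in ids]
        return RelationshipStructure(
            ids=tuple(ids), matrix=self.matrix[np.ix_(idx, idx)].tocsr(), kind=self.kind
        )

    # -- serialization ------------------------------------------------

    def write_triplets(self, matrix_path: str | Path, ids_path: str | Path) -> None:
        """Coordinate-format text (1-based i, j, value; upper triangle)
        with a sidecar id list, one id per line."""
        coo = sp.triu(self.matrix).tocoo()
        with open(matrix_path, "w") as fh:
            fh.write(f"# kind={self.kind}\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i + 1}\t{j + 1}\t{v:.10g}\n")
        Path(ids_path).write_text("".join(f"{i}\n" for i in self.ids))

    @classmethod
    def read_triplets(cls, matrix_path: str | Path, ids_path: str | Path) -> "RelationshipStructure":
        ids = tuple(Path(ids_path).read_text().split())
        kind = "additive"
        rows, cols, vals = [], [], []
        with open(matrix_path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "kind=" in line:
                        kind = line.split("kind=", 1)[1].strip()
                    continue
                i, j, v = line.split("\t")
                rows.append(int(i) - 1)
                cols.append(int(j) - 1)
                vals.append(float(v))
        n = len(ids)
        m = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        upper = sp.triu(m, k=1)
        return cls(ids=ids, matrix=(m + upper.T).tocsr(), kind=kind)

    def write_npz(self, path: str | Path) -> None:
        sp.save_npz(str(path), self.matrix.tocsr())
        side = Path(str(path) + ".ids")
        side.write_text(self.kind + "\n" + "".join(f"{i}\n" for i in self.ids))

    @classmethod
    def read_npz(cls, path: str | Path) -> "RelationshipStructure":
        matrix = sp.load_npz(str(path))
        lines = Path(str(path) + ".ids").read_text().split()
        return cls(ids=tuple(lines[1:]), matrix=matrix, kind=lines[0])


def _genetic_components(ped: Pedigree) -> list[list[int]]:
    """Connected components of the parent-child graph, in id order."""
    n = len(ped)
    rows, cols = [], []
    for k, ind in enumerate(ped.individuals):
        for p in (ind.father, ind.mother):
            if p is not None:
                rows.append(k)
                cols.append(ped.index_of(p))
    adj = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = sp.csgraph.connected_components(adj, directed=False)
    groups: list[list[int]] = [[] for _ in range(ncomp)]
    for k, lab in enumerate(labels):
        groups[lab].append(k)
    return groups


def additive_relationship_matrix(ped: Pedigree) -> RelationshipStructure:
    """Numerator relationship matrix by the tabular method.

    In topological order, for individual ``i`` with parents ``f, m``:
    ``A_ii = 1 + 0.5 A_fm`` (1 when a parent is unknown — the unknown
    parent is a unique non-inbred founder) and ``A_ij = 0.5 (A_jf + A_jm)``
    for previously placed ``j``, an unknown parent contributing 0.
    Computed densely within each family (connected component) and stored
    sparse block-diagonal over the whole cohort.
    """
    order = topological_order(ped)
    pos_in_order = {iid: k for k, iid in enumerate(order)}
    blocks_rows: list[np.ndarray] = []
    blocks_cols: list[np.ndarray] = []
    blocks_vals: list[np.ndarray] = []
    for comp in _genetic_components(ped):
        members = sorted((ped.individuals[k].id for k in comp), key=pos_in_order.__getitem__)
        local = {iid: k for k, iid in enumerate(members)}
        m = len(members)
        A = np.zeros((m, m))
        for k, iid in enumerate(members):
            ind = ped[iid]
            fi = local.get(ind.father) if ind.father is not None else None
            mi = local.get(ind.mother) if ind.mother is not None else None
            col = np.zeros(k)
            if fi is not None:
                col += 0.5 * A[:k, fi]
            if mi is not None:
                col += 0.5 * A[:k, mi]
            A[:k, k] = col
            A[k, :k] = col
            A[k, k] = 1.0 + (0.5 * A[fi, mi] if fi is not None and mi is not None else 0.0)
        gi = np.array([pos_in_order[iid] for iid in members])
        rr, cc = np.nonzero(A)
        blocks_rows.append(gi[rr])
        blocks_cols.append(gi[cc])
        blocks_vals.append(A[rr, cc])
    n = len(ped)
    matrix = sp.coo_matrix(
        (np.concatenate(blocks_vals), (np.concatenate(blocks_rows), np.concatenate(blocks_cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipStructure(ids=tuple(order), matrix=matrix, kind="additive")


def inbreeding_coefficients(A: RelationshipStructure) -> dict[str, float]:
    """Per-individual inbreeding coefficient ``F_i = A_ii - 1``."""
    if A.kind != "additive":
        raise ValueError(f"inbreeding coefficients require an additive structure, got {A.kind!r}")
    diag = A.matrix.diagonal()
    return {iid: float(diag[k] - 1.0) for k, iid in enumerate(A.ids)}


def _partition_groups(ped: Pedigree, kind: str) -> list[tuple[str, ...]]:
    if kind == "spouse_share":
        # union partnerships: an individual with several recorded partners
        # shares environment with all of them (connected components of the
        # couple graph), keeping the matrix a valid 0/1 partition
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        for a, b in ped.couples:
            parent.setdefault(a, a)
            parent.setdefault(b, b)
            parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for x in parent:
            groups.setdefault(find(x), []).append(x)
        return [tuple(v) for v in groups.values() if len(v) > 1]
    if kind == "sib_share":
        return [v for v in ped.sibships.values() if len(v) > 1]
    if kind == "household_share":
        return [tuple(v) for v in ped.households.values() if len(v) > 1]
    raise ValueError(f"unknown group kind {kind!r}; expected one of {GROUP_KINDS}")


def household_structure_from_file(ped: Pedigree, path: str | Path) -> RelationshipStructure:
    """A household-share structure from a standalone household TSV
    (columns household, id), independent of the pedigree's own household
    assignment.  Several household variables (e.g. current and earlier
    residences) can be modelled side by side by building one structure
    per file; within each file an individual may appear in only one
    household."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("household", "id"):
        if col not in df.columns:
            raise PedigreeError(f"household file {path} lacks column {col!r}")
    seen: dict[str, str] = {}
    groups: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        iid, label = str(row.id).strip(), str(row.household).strip()
        if iid not in ped:
            raise PedigreeError(f"household member {iid!r} not in pedigree")
        if iid in seen and seen[iid] != label:
            raise PedigreeError(
                f"individual {iid!r} appears in households {seen[iid]!r} and {label!r}"
            )
        seen[iid] = label
        groups.setdefault(label, []).append(iid)
    order = topological_order(ped)
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(ped)
    rows_, cols_ = list(range(n)), list(range(n))
    for members in groups.values():
        idx = [pos[i] for i in set(members)]
        for a in idx:
            for b in idx:
                if a != b:
                    rows_.append(a)
                    cols_.append(b)
    matrix = sp.coo_matrix((np.ones(len(rows_)), (rows_, cols_)), shape=(n, n)).tocsr()
    return RelationshipStructure(ids=tuple(order), matrix=matrix,
                                 kind="household_share")


def group_covariance_matrix(ped: Pedigree, kind: str) -> RelationshipStructure:
    """0/1 shared-environment covariance: entry (i, j) is 1 when i and j
    share a group of the requested kind (or i = j), else 0.  Individuals
    in no group form singleton blocks (identity rows)."""
    order = topological_order(ped)
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(ped)
    rows = list(range(n))
    cols = list(range(n))
    for group in _partition_groups(ped, kind):
        idx = [pos[i] for i in group]
        for a in idx:
            for b in idx:
                if a != b:
                    rows.append(a)
                    cols.append(b)
    matrix = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipStructure(ids=tuple(order), matrix=matrix, kind=kind)
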