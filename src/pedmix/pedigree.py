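"""Pedigree parsing and validation.

A :class:`Pedigree` holds individuals with parent links plus the grouping
variables used to model shared environment: couples (current or previous
partners), households, and sibships (full sibs sharing both parents,
derived rather than supplied).  Unknown parents are encoded as ``"0"`` or
an empty field in input files and as ``None`` in memory.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "PedigreeStructureError",
    "PedigreeReferenceError",
    "parse_pedigree",
    "topological_order",
]

#: strings read as "parent unknown" in pedigree files
MISSING_TOKENS = {"", "0", "na", "nan", "none", "."}

_SEX_MAP = {
    "f": "female", "female": "female", "2": "female",
    "m": "male", "male": "male", "1": "male",
}


class PedigreeError(Exception):
    """Base class for pedigree validation failures."""


class PedigreeStructureError(PedigreeError):
    """The parent graph is structurally invalid (e.g. contains a cycle)."""


class PedigreeReferenceError(PedigreeError):
    """An id is duplicated, missing, or refers to an unknown individual."""


@dataclass(frozen=True)
class Individual:
    id: str
    father: str | None
    mother: str | None
    sex: str = "unknown"  # female / male / unknown


@dataclass
class Pedigree:
    """A validated pedigree with couple and household assignments.

    Parameters
    ----------
    individuals
        Records in input order; order is meaningful (it breaks ties in
        :func:`topological_order` and hence fixes matrix id ordering).
    couples
        Unordered pairs of ids.  When built by :func:`parse_pedigree`
        without an explicit couples file these are inferred parent pairs
        sharing at least one offspring.
    households
        Mapping from household label to the member id set.  An individual
        may belong to at most one household.
    """

    individuals: list[Individual]
    couples: list[tuple[str, str]] = field(default_factory=list)
    households: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._index: dict[str, int] = {}
        for ind in self.individuals:
            if ind.id in self._index:
                raise PedigreeReferenceError(f"duplicate individual id {ind.id!r}")
            self._index[ind.id] = len(self._index)
        for ind in self.individuals:
            for parent in (ind.father, ind.mother):
                if parent is not None and parent not in self._index:
                    raise PedigreeReferenceError(
                        f"individual {ind.id!r} refers to unknown parent {parent!r}"
                    )
            if ind.id in (ind.father, ind.mother):
                raise PedigreeStructureError(
                    f"individual {ind.id!r} is listed as its own parent"
                )
        couples = []
        for a, b in self.couples:
            if a == b:
                raise PedigreeReferenceError(f"couple ({a!r}, {b!r}) is not a pair")
            for x in (a, b):
                if x not in self._index:
                    raise PedigreeReferenceError(f"couple member {x!r} not in pedigree")
            couples.append(tuple(sorted((a, b), key=self._index.__getitem__)))
        self.couples = sorted(set(couples), key=lambda p: self._index[p[0]])
        seen_hh: dict[str, str] = {}
        for label, members in self.households.items():
            for m in members:
                if m not in self._index:
                    raise PedigreeReferenceError(
                        f"household {label!r} member {m!r} not in pedigree"
                    )
                if m in seen_hh:
                    raise PedigreeReferenceError(
                        f"individual {m!r} appears in households {seen_hh[m]!r} and {label!r}"
                    )
                seen_hh[m] = label
        # acyclicity is established by attempting a topological sort
        topological_order(self)

    # -- basic access -------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._index

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[self._index[iid]]

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self.individuals if i.father is None and i.mother is None]

    @property
    def sibships(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """Full sibships keyed by the (father, mother) pair, both known."""
        groups: dict[tuple[str, str], list[str]] = {}
        for ind in self.individuals:
            if ind.father is not None and ind.mother is not None:
                groups.setdefault((ind.father, ind.mother), []).append(ind.id)
        return {k: tuple(v) for k, v in groups.items()}

    def inferred_couples(self) -> list[tuple[str, str]]:
        """Parent pairs with at least one shared offspring."""
        pairs = {
            tuple(sorted(k, key=self._index.__getitem__)) for k in self.sibships
        }
        return sorted(pairs, key=lambda p: self._index[p[0]])


def _clean_token(value: object) -> str | None:
    s = "" if value is None or (isinstance(value, float) and pd.isna(value)) else str(value).strip()
    return None if s.lower() in MISSING_TOKENS else s


def _find_cycle(ped_rows: dict[str, tuple[str | None, str | None]]) -> list[str]:
    """Locate one directed cycle parent -> child for the error message."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = dict.fromkeys(ped_rows, WHITE)
    stack: list[str] = []

    def visit(node: str) -> list[str] | None:
        colour[node] = GREY
        stack.append(node)
        for parent in ped_rows[node]:
            if parent is None:
                continue
            if colour[parent] == GREY:
                return stack[stack.index(parent):] + [parent]
            if colour[parent] == WHITE:
                found = visit(parent)
                if found:
                    return found
        colour[node] = BLACK
        stack.pop()
        return None

    for node in ped_rows:
        if colour[node] == WHITE:
            found = visit(node)
            if found:
                return found
    return []


def topological_order(ped: Pedigree) -> list[str]:
    """Order ids so every parent precedes all of its offspring.

    Deterministic: among individuals whose parents are already placed,
    the one earliest in input order goes first.
    """
    index = {ind.id: i for i, ind in enumerate(ped.individuals)}
    children: dict[str, list[str]] = {ind.id: [] for ind in ped.individuals}
    pending = {}
    for ind in ped.individuals:
        parents = {p for p in (ind.father, ind.mother) if p is not None}
        pending[ind.id] = len(parents)
        for p in parents:
            children[p].append(ind.id)
    ready = [index[i] for i, k in pending.items() if k == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        iid = ped.individuals[heapq.heappop(ready)].id
        order.append(iid)
        for child in children[iid]:
            pending[child] -= 1
            if pending[child] == 0:
                heapq.heappush(ready, index[child])
    if len(order) < len(ped.individuals):
        rows = {i.id: (i.father, i.mother) for i in ped.individuals}
        cycle = _find_cycle(rows)
        raise PedigreeStructureError(
            "pedigree parent graph contains a cycle: " + " -> ".join(cycle)
        )
    return order


def _read_tsv(path: Path, required: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PedigreeReferenceError(
            f"{what} file {path} lacks required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def parse_pedigree(
    pedigree_file: str | Path,
    couples_file: str | Path | None = None,
    households_file: str | Path | None = None,
) -> Pedigree:
    """Read a pedigree TSV (columns id, father, mother, sex) and optional
    couples (id1, id2) and households (household, id) tables.

    When no couples file is given, couples are inferred as parent pairs
    sharing at least one offspring.
    """
    df = _read_tsv(Path(pedigree_file), ["id", "father", "mother", "sex"], "pedigree")
    individuals = []
    for row in df.itertuples(index=False):
        sex = _clean_token(row.sex)
        individuals.append(
            Individual(
                id=str(row.id).strip(),
                father=_clean_token(row.father),
                mother=_clean_token(row.mother),
                sex=_SEX_MAP.get((sex or "").lower(), "unknown"),
            )
        )
    couples: list[tuple[str, str]] = []
    if couples_file is not None:
        cdf = _read_tsv(Path(couples_file), ["id1", "id2"], "couples")
        couples = [(str(r.id1).strip(), str(r.id2).strip()) for r in cdf.itertuples(index=False)]
    households: dict[str, frozenset[str]] = {}
    if households_file is not None:
        hdf = _read_tsv(Path(households_file), ["household", "id"], "households")
        tmp: dict[str, set[str]] = {}
        for r in hdf.itertuples(index=False):
            tmp.setdefault(str(r.household).strip(), set()).add(str(r.id).strip())
        households = {k: frozenset(v) for k, v in tmp.items()}
    ped = Pedigree(individuals=individuals, couples=couples, households=households)
    if couples_file is None:
        ped.couples = ped.inferred_couples()
    return ped
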