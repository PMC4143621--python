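"""Pedigree data model, LINKAGE/PLINK file I/O, loop handling and kinship.

The pedigree is the unit of likelihood computation: a family graph in which
every non-founder has both parents present and founders are assumed mutually
unrelated.  Codes follow the LINKAGE convention: missing parent ``0``, sex
``1`` male / ``2`` female, affection ``1`` unaffected / ``2`` affected /
``0`` unknown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Iterator

import networkx as nx
import numpy as np

MISSING_PARENT = "0"


class Sex(IntEnum):
    MALE = 1
    FEMALE = 2


class Affection(IntEnum):
    UNKNOWN = 0
    UNAFFECTED = 1
    AFFECTED = 2


class PedigreeError(Exception):
    """Base class for pedigree structure and parsing errors."""


class MalformedRecordError(PedigreeError):
    """A pedigree file record has the wrong number of columns or a bad code."""


class UnknownParentError(PedigreeError):
    """A named parent is not a member of the family."""


class ParentSexError(PedigreeError):
    """A named father is not male, or a named mother is not female."""


class CyclicParentageError(PedigreeError):
    """The parent relation contains a cycle (an individual is its own ancestor)."""


class LoopBreakError(PedigreeError):
    """A loop-breaking operation failed to remove the targeted loop."""


@dataclass
class Individual:
    id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.MALE
    age: float | None = None
    affection: Affection = Affection.UNKNOWN
    genotyped: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id}: father and mother must both be "
                "present or both absent"
            )


@dataclass
class Loop:
    """A cycle in the marriage-node graph of a pedigree.

    ``kind`` is ``"inbreeding"`` when some union on the cycle joins two
    spouses sharing a common ancestor, ``"marriage"`` otherwise (e.g. one
    person with children by members of two connected sibships).
    """

    kind: str
    member_ids: tuple[str, ...]


class Pedigree:
    """A single family: ordered members with enforced structural invariants."""

    def __init__(self, family_id: str, members: Iterable[Individual] = ()):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            self.add(ind)

    def add(self, ind: Individual) -> None:
        if ind.id in self.members:
            raise PedigreeError(
                f"family {self.family_id}: duplicate individual id {ind.id}"
            )
        self.members[ind.id] = ind

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __getitem__(self, ind_id: str) -> Individual:
        return self.members[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    @property
    def ids(self) -> list[str]:
        return list(self.members)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def nonfounders(self) -> list[Individual]:
        return [i for i in self if not i.is_founder]

    def children_of(self, ind_id: str) -> list[Individual]:
        return [i for i in self if ind_id in (i.father_id, i.mother_id)]

    def descendants_of(self, ind_id: str) -> set[str]:
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            cur = stack.pop()
            for child in self.children_of(cur):
                if child.id not in out:
                    out.add(child.id)
                    stack.append(child.id)
        return out

    def nuclear_families(self) -> dict[tuple[str, str], list[str]]:
        """Map (father_id, mother_id) -> child ids, in member order."""
        fams: dict[tuple[str, str], list[str]] = {}
        for ind in self:
            if not ind.is_founder:
                fams.setdefault((ind.father_id, ind.mother_id), []).append(ind.id)
        return fams

    def validate(self) -> None:
        for ind in self:
            for pid, role, want in (
                (ind.father_id, "father", Sex.MALE),
                (ind.mother_id, "mother", Sex.FEMALE),
            ):
                if pid is None:
                    continue
                if pid not in self.members:
                    raise UnknownParentError(
                        f"family {self.family_id}: {role} {pid} of {ind.id} "
                        "is not a family member"
                    )
                if self.members[pid].sex != want:
                    raise ParentSexError(
                        f"family {self.family_id}: {role} {pid} of {ind.id} "
                        f"is not {'male' if want == Sex.MALE else 'female'}"
                    )
        self.topological_order()  # raises CyclicParentageError on a cycle

    def topological_order(self) -> list[str]:
        """Member ids with every parent preceding its children."""
        order: list[str] = []
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(ind_id: str, chain: tuple[str, ...]) -> None:
            st = state.get(ind_id)
            if st == 1:
                return
            if st == 0:
                raise CyclicParentageError(
                    f"family {self.family_id}: cyclic parentage involving "
                    f"{' -> '.join(chain + (ind_id,))}"
                )
            state[ind_id] = 0
            ind = self.members[ind_id]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None and pid in self.members:
                    visit(pid, chain + (ind_id,))
            state[ind_id] = 1
            order.append(ind_id)

        for ind_id in self.members:
            visit(ind_id, ())
        return order


class PedigreeSet:
    """An ordered collection of pedigrees keyed by family id."""

    def __init__(self, pedigrees: Iterable[Pedigree] = ()):
        self.families: dict[str, Pedigree] = {}
        for p in pedigrees:
            if p.family_id in self.families:
                raise PedigreeError(f"duplicate family id {p.family_id}")
            self.families[p.family_id] = p

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self) -> Iterator[Pedigree]:
        return iter(self.families.values())

    def __getitem__(self, family_id: str) -> Pedigree:
        return self.families[family_id]

    @property
    def n_individuals(self) -> int:
        return sum(len(p) for p in self)

    def individuals(self) -> Iterator[Individual]:
        for p in self:
            yield from p

    def individual_ids(self) -> list[tuple[str, str]]:
        """(family_id, individual_id) pairs in file order."""
        return [(p.family_id, i.id) for p in self for i in p]


# ---------------------------------------------------------------------------
# File I/O (pre-makeped LINKAGE and PLINK .fam dialects)
# ---------------------------------------------------------------------------

def _parse_affection(token: str, dialect: str) -> Affection:
    if dialect == "plink" and token == "-9":
        return Affection.UNKNOWN
    if token == "1":
        return Affection.UNAFFECTED
    if token == "2":
        return Affection.AFFECTED
    return Affection.UNKNOWN


def read_pedigrees(path, dialect: str = "linkage") -> PedigreeSet:
    """Read a whitespace-delimited pedigree file.

    The six leading columns are family, individual, father, mother, sex and
    affection; extra columns (e.g. PLINK genotypes) are ignored.  ``0``
    denotes a missing parent.  All structural invariants are enforced and
    violations raise line-identified errors.
    """
    if dialect not in ("linkage", "plink"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    peds: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 6:
                raise MalformedRecordError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            fam, iid, fa, mo, sex_tok, aff_tok = fields[:6]
            if (fa == MISSING_PARENT) != (mo == MISSING_PARENT):
                raise MalformedRecordError(
                    f"{path}:{lineno}: individual {iid} has exactly one "
                    "known parent; both or neither required"
                )
            if sex_tok not in ("1", "2"):
                raise MalformedRecordError(
                    f"{path}:{lineno}: bad sex code {sex_tok!r} (expect 1 or 2)"
                )
            if iid in (fa, mo):
                raise CyclicParentageError(
                    f"{path}:{lineno}: individual {iid} lists itself as a parent"
                )
            ind = Individual(
                id=iid,
                family_id=fam,
                father_id=None if fa == MISSING_PARENT else fa,
                mother_id=None if mo == MISSING_PARENT else mo,
                sex=Sex(int(sex_tok)),
                affection=_parse_affection(aff_tok, dialect),
            )
            try:
                peds.setdefault(fam, Pedigree(fam)).add(ind)
            except PedigreeError as exc:
                raise MalformedRecordError(f"{path}:{lineno}: {exc}") from exc
    out = PedigreeSet(peds.values())
    for p in out:
        p.validate()
    return out


def write_pedigrees(peds: PedigreeSet, path, dialect: str = "linkage") -> None:
    """Write the six-column pedigree table (round-trips through read_pedigrees)."""
    unknown = "-9" if dialect == "plink" else "0"
    with open(path, "w") as fh:
        for p in peds:
            for ind in p:
                aff = (
                    unknown
                    if ind.affection == Affection.UNKNOWN
                    else str(int(ind.affection))
                )
                fh.write(
                    f"{p.family_id}\t{ind.id}\t{ind.father_id or '0'}\t"
                    f"{ind.mother_id or '0'}\t{int(ind.sex)}\t{aff}\n"
                )


# ---------------------------------------------------------------------------
# Loops
# ---------------------------------------------------------------------------

def marriage_graph(p: Pedigree) -> nx.Graph:
    """Bipartite individual/union graph used for loop detection and peeling.

    One node per individual; one union node per mated pair; edges connect
    each spouse to the union and the union to each child.
    """
    g = nx.Graph()
    for ind in p:
        g.add_node(ind.id, kind="individual")
    for (fa, mo), children in p.nuclear_families().items():
        u = ("union", fa, mo)
        g.add_node(u, kind="union")
        g.add_edge(fa, u)
        g.add_edge(mo, u)
        for c in children:
            g.add_edge(u, c)
    return g


def _ancestors(p: Pedigree, ind_id: str) -> set[str]:
    out: set[str] = set()
    stack = [ind_id]
    while stack:
        ind = p[stack.pop()]
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None and pid not in out:
                out.add(pid)
                stack.append(pid)
    return out


def detect_loops(p: Pedigree) -> list[Loop]:
    """Return one Loop per independent cycle of the marriage-node graph.

    An empty result means the pedigree peels without any loop handling.
    """
    g = marriage_graph(p)
    loops: list[Loop] = []
    for cycle in nx.cycle_basis(g):
        kind = "marriage"
        for node in cycle:
            if isinstance(node, tuple) and node[0] == "union":
                _, fa, mo = node
                if _ancestors(p, fa) & _ancestors(p, mo):
                    kind = "inbreeding"
                    break
        members = tuple(n for n in cycle if not isinstance(n, tuple))
        loops.append(Loop(kind=kind, member_ids=members))
    return loops


def break_loops(
    p: Pedigree,
    strategy: str,
    target_id: str,
    cascade: bool = True,
) -> Pedigree:
    """Break pedigree loops by removing or duplicating one individual.

    ``remove_individual`` deletes the target (and, by default, all of its
    descendants, since the connecting line must be pruned for the loop to
    open).  ``duplicate_individual`` splits the target in two: the original
    keeps its parents and loses its children; a copy with identical
    phenotype/genotype data becomes a founder and receives the children.
    The result must contain strictly fewer loops than the input.
    """
    if target_id not in p:
        raise PedigreeError(f"family {p.family_id}: no individual {target_id}")
    before = detect_loops(p)
    if not before:
        warnings.warn(
            f"family {p.family_id}: no loops to break; returned unchanged",
            stacklevel=2,
        )
        return p

    if strategy == "remove_individual":
        drop = {target_id}
        if cascade:
            desc = p.descendants_of(target_id)
            if desc:
                warnings.warn(
                    f"family {p.family_id}: cascade-removing "
                    f"{len(desc)} descendant(s) of {target_id}",
                    stacklevel=2,
                )
            drop |= desc
        elif p.children_of(target_id):
            raise PedigreeError(
                f"family {p.family_id}: {target_id} has children; "
                "enable cascade or remove them first"
            )
        new = Pedigree(
            p.family_id, [replace(i) for i in p if i.id not in drop]
        )
    elif strategy == "duplicate_individual":
        target = p[target_id]
        if target.is_founder:
            raise PedigreeError(
                f"family {p.family_id}: duplicate_individual requires the "
                f"target's parents in the pedigree; {target_id} is a founder"
            )
        if not p.children_of(target_id):
            raise PedigreeError(
                f"family {p.family_id}: duplicate_individual requires the "
                f"target to have children; {target_id} has none"
            )
        n = 1
        while f"{target_id}__dup{n}" in p:
            n += 1
        dup_id = f"{target_id}__dup{n}"
        new = Pedigree(p.family_id)
        for ind in p:
            cp = replace(ind)
            if target_id in (cp.father_id, cp.mother_id):
                if cp.father_id == target_id:
                    cp.father_id = dup_id
                else:
                    cp.mother_id = dup_id
            new.add(cp)
        new.add(
            replace(target, id=dup_id, father_id=None, mother_id=None)
        )
    else:
        raise ValueError(f"unknown loop-breaking strategy {strategy!r}")

    new.validate()
    after = detect_loops(new)
    if len(after) >= len(before):
        raise LoopBreakError(
            f"family {p.family_id}: {strategy} on {target_id} did not reduce "
            f"the loop count ({len(before)} -> {len(after)})"
        )
    return new


def write_loop_report(peds: PedigreeSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tloop_kind\tmember_ids\n")
        for p in peds:
            for loop in detect_loops(p):
                fh.write(
                    f"{p.family_id}\t{loop.kind}\t{','.join(loop.member_ids)}\n"
                )


# ---------------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Kinship coefficients phi for one pedigree, founders assumed unrelated."""

    ids: tuple[str, ...]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {iid: k for k, iid in enumerate(self.ids)}

    def phi(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


def kinship_matrix(p: Pedigree) -> KinshipMatrix:
    """Recursive kinship: phi(i,i) = (1 + phi(fa_i, mo_i)) / 2 and
    phi(i,j) = (phi(fa_i, j) + phi(mo_i, j)) / 2 with parents processed first.
    """
    order = p.topological_order()
    idx = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for i, iid in enumerate(order):
        ind = p[iid]
        if ind.is_founder:
            phi[i, i] = 0.5
        else:
            f, m = idx[ind.father_id], idx[ind.mother_id]
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            for j in range(i):
                phi[i, j] = phi[j, i] = 0.5 * (phi[f, j] + phi[m, j])
    # restore the pedigree's member order
    perm = [idx[iid] for iid in p.ids]
    phi = phi[np.ix_(perm, perm)]
    return KinshipMatrix(ids=tuple(p.ids), values=phi)
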