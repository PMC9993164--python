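"""Search-space definition: variable groups, group tuples, enumeration,
unranking and contiguous partitioning.

A :class:`TupleSpace` is built from named, pairwise-disjoint *variable
groups* and ordered *group tuples* (templates).  Each template generates
variable tuples by drawing one member per slot from that slot's group:

* slots referencing distinct groups form the full cross product in
  row-major order (last slot fastest);
* a run of slots repeating one group enumerates strictly increasing
  member combinations (unordered, no self-pairs), since the measures are
  permutation symmetric;
* mixed templates combine both rules: combinations within each repeated
  block, cross product across blocks.

The enumeration is a strict total order over ranks ``[0, total_count)``
(templates concatenated in listed order), supports O(d) unranking with
cost independent of rank, and partitions into equally sized contiguous
working sets so parallel workers need no communication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence

from .datamodel import Dataset


@dataclass(frozen=True)
class VariableGroup:
    """A named, ordered set of distinct variable indices."""

    name: str
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(int(m) for m in self.members)
        object.__setattr__(self, "members", members)
        if len(set(members)) != len(members):
            raise ValueError(f"group {self.name!r} has duplicate members")
        if not members:
            raise ValueError(f"group {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class GroupTuple:
    """An ordered template of group names; length is the tuple order."""

    slots: tuple[str, ...]

    def __post_init__(self) -> None:
        slots = tuple(str(s) for s in self.slots)
        object.__setattr__(self, "slots", slots)
        if not 2 <= len(slots) <= 4:
            raise ValueError(
                f"template length {len(slots)} unsupported (tuple orders 2-4)"
            )


@dataclass(frozen=True)
class WorkingSet:
    """Half-open rank interval [start_rank, end_rank) assigned to one worker."""

    start_rank: int
    end_rank: int

    def __len__(self) -> int:
        return self.end_rank - self.start_rank

    def ranks(self) -> range:
        return range(self.start_rank, self.end_rank)


def _blocks(slots: Sequence[str]) -> list[tuple[str, int]]:
    """Collapse a template into (group, multiplicity) runs."""
    blocks: list[tuple[str, int]] = []
    for s in slots:
        if blocks and blocks[-1][0] == s:
            blocks[-1] = (s, blocks[-1][1] + 1)
        else:
            blocks.append((s, 1))
    return blocks


def _unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """Lexicographic unranking of a k-combination of range(n)."""
    out = []
    prev = -1
    for pos in range(k):
        c = prev + 1
        while True:
            count = comb(n - c - 1, k - pos - 1)
            if rank < count:
                break
            rank -= count
            c += 1
        out.append(c)
        prev = c
    return tuple(out)


class TupleSpace:
    """Enumerable, partitionable set of variable tuples.

    Mirrors the programmatic construction style of the counting engine's
    API: ``add_variable_group`` then ``add_variable_group_tuple``.
    """

    def __init__(self) -> None:
        self.groups: dict[str, VariableGroup] = {}
        self.group_tuples: list[GroupTuple] = []

    # -- construction -------------------------------------------------
    def add_variable_group(self, name: str, members: Sequence[int]) -> str:
        """Register a disjoint, ordered variable group; returns its name."""
        if name in self.groups:
            raise ValueError(f"group {name!r} already defined")
        group = VariableGroup(name, tuple(members))
        taken = {m for g in self.groups.values() for m in g.members}
        overlap = taken & set(group.members)
        if overlap:
            raise ValueError(
                f"group {name!r} overlaps existing groups on indices "
                f"{sorted(overlap)}"
            )
        self.groups[name] = group
        return name

    # camelCase aliases matching the original engine's API surface
    addVariableGroup = add_variable_group

    def add_variable_group_tuple(self, slots: Sequence[str]) -> None:
        """Register a template; each slot names a previously added group."""
        gt = GroupTuple(tuple(slots))
        for s in gt.slots:
            if s not in self.groups:
                raise KeyError(f"template references unknown group {s!r}")
        blocks = _blocks(gt.slots)
        names = [g for g, _ in blocks]
        if len(set(names)) != len(names):
            raise ValueError(
                "a group may only repeat in adjacent slots (one combination "
                f"block); got template {gt.slots}"
            )
        self.group_tuples.append(gt)

    addVariableGroupTuple = add_variable_group_tuple

    # -- counting ------------------------------------------------------
    def _template_count(self, gt: GroupTuple) -> int:
        total = 1
        for name, mult in _blocks(gt.slots):
            total *= comb(len(self.groups[name]), mult)
        return total

    @property
    def total_count(self) -> int:
        return sum(self._template_count(gt) for gt in self.group_tuples)

    def count_tuples(self) -> int:
        """Exact number of variable tuples the space generates."""
        return self.total_count

    # -- enumeration / unranking --------------------------------------
    def tuple_at(self, rank: int) -> tuple[int, ...]:
        """Variable tuple at ``rank``; inverse of enumeration order.

        Mixed-radix unranking across blocks (row-major, last block
        fastest) with combinatorial unranking inside repeated blocks;
        cost independent of rank.
        """
        if rank < 0:
            raise IndexError(f"rank {rank} out of range")
        for gt in self.group_tuples:
            size = self._template_count(gt)
            if rank < size:
                return self._unrank_template(gt, rank)
            rank -= size
        raise IndexError("rank out of range")

    def _unrank_template(self, gt: GroupTuple, rank: int) -> tuple[int, ...]:
        blocks = _blocks(gt.slots)
        radices = [comb(len(self.groups[g]), mult) for g, mult in blocks]
        digits = []
        for radix in reversed(radices):
            digits.append(rank % radix)
            rank //= radix
        digits.reverse()
        out: list[int] = []
        for (gname, mult), digit in zip(blocks, digits):
            members = self.groups[gname].members
            if mult == 1:
                out.append(members[digit])
            else:
                out.extend(members[i] for i in
                           _unrank_combination(digit, len(members), mult))
        return tuple(out)

    def __iter__(self) -> Iterator[tuple[int, ...]]:
        for rank in range(self.total_count):
            yield self.tuple_at(rank)

    def __len__(self) -> int:
        return self.total_count

    # -- partitioning --------------------------------------------------
    def partition(self, n_workers: int) -> list[WorkingSet]:
        """Split [0, total_count) into ``n_workers`` contiguous intervals
        whose sizes differ by at most one (trailing intervals may be empty
        when workers outnumber tuples)."""
        if n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        total = self.total_count
        base, extra = divmod(total, n_workers)
        sets = []
        start = 0
        for w in range(n_workers):
            size = base + (1 if w < extra else 0)
            sets.append(WorkingSet(start, start + size))
            start += size
        return sets

    # -- config --------------------------------------------------------
    @classmethod
    def from_config(cls, config: dict, ds: Dataset) -> "TupleSpace":
        """Build from a declarative mapping, resolving members against a
        dataset.

        ``config["groups"]`` maps group names to member specs: a list of
        variable names, a glob pattern (``"SNP*"``), or a 0-based column
        range ``"start:stop"``.  ``config["templates"]`` is a list of
        group-name lists (a single comma-separated string also accepted).
        """
        ts = cls()
        for name, spec in config["groups"].items():
            ts.add_variable_group(name, resolve_members(spec, ds))
        for tmpl in config["templates"]:
            slots = tmpl.split(",") if isinstance(tmpl, str) else list(tmpl)
            ts.add_variable_group_tuple([s.strip() for s in slots])
        return ts


def resolve_members(spec, ds: Dataset) -> list[int]:
    """Resolve a member spec (name list, glob pattern, or ``a:b`` range)
    to variable indices of ``ds``."""
    from fnmatch import fnmatch

    if isinstance(spec, (list, tuple)):
        return [m if isinstance(m, int) else ds.index_of(str(m)) for m in spec]
    text = str(spec)
    if ":" in text and all(p.strip().lstrip("-").isdigit() or p == ""
                           for p in text.split(":", 1)):
        a, b = text.split(":", 1)
        start = int(a) if a.strip() else 0
        stop = int(b) if b.strip() else ds.n_variables
        return list(range(start, stop))
    if any(ch in text for ch in "*?["):
        hits = [i for i, n in enumerate(ds.names) if fnmatch(n, text)]
        if not hits:
            raise KeyError(f"pattern {text!r} matches no variables")
        return hits
    return [ds.index_of(text)]
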