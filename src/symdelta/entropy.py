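"""Joint count tables and Shannon entropies for variable tuples.

Two interchangeable counting algorithms produce identical tables:

* ``bitset`` -- each joint cell is the popcount of the bitwise AND of one
  presence plane per variable (64 samples per word op).  The number of
  popcount passes for a d-tuple is the product of the bin counts.
* ``vector`` -- one pass over the samples, accumulating a flattened joint
  histogram and skipping samples missing in any tuple variable.

All counts are complete-case with respect to a *restriction set* of
variables (by default the tuple itself): a sample contributes only if it is
non-missing in every restriction variable.  This keeps every entropy term
of one measure on a single probability space.

Entropies are in bits (base-2 logarithms) and may be memoized in an
:class:`EntropyCache` keyed so that a cached value always equals the
freshly computed one.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .datamodel import Dataset

CacheKey = tuple[tuple[int, ...], tuple[int, ...]]


class UndefinedEntropyError(ValueError):
    """Raised when an entropy is requested on an empty effective sample set."""


@dataclass(frozen=True)
class CountTable:
    """Joint occurrence counts over a variable tuple.

    ``counts`` has one axis per tuple variable, of length B_i; the sum of
    all cells is ``n_effective``, the number of samples observed in every
    restriction variable.
    """

    tuple_indices: tuple[int, ...]
    counts: np.ndarray
    n_effective: int

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.counts.shape)

    def marginal(self, axes: Sequence[int]) -> "CountTable":
        """Marginal table over a subset of the tuple's positions."""
        axes = tuple(axes)
        drop = tuple(i for i in range(self.counts.ndim) if i not in axes)
        counts = self.counts.sum(axis=drop) if drop else self.counts
        if len(axes) > 1:  # surviving axes come out sorted; restore requested order
            kept = sorted(axes)
            counts = counts.transpose([kept.index(a) for a in axes])
        return CountTable(
            tuple(self.tuple_indices[i] for i in axes), counts, self.n_effective
        )


def _check_tuple(ds: Dataset, tuple_indices: Sequence[int]) -> tuple[int, ...]:
    idx = tuple(int(i) for i in tuple_indices)
    if len(idx) < 1:
        raise ValueError("tuple must contain at least one variable")
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate variable index in tuple {idx}")
    for i in idx:
        if not 0 <= i < ds.n_variables:
            raise IndexError(f"variable index {i} out of range")
    return idx


def _restriction(ds: Dataset, tuple_indices, restrict_to) -> tuple[int, ...]:
    if restrict_to is None:
        return tuple(tuple_indices)
    restrict = tuple(int(i) for i in restrict_to)
    if not set(tuple_indices) <= set(restrict):
        raise ValueError("restriction set must contain the tuple variables")
    return restrict


def count_bitset(
    ds: Dataset,
    tuple_indices: Sequence[int],
    restrict_to: Sequence[int] | None = None,
) -> CountTable:
    """Joint counts via bitwise-AND of presence planes and popcount."""
    idx = _check_tuple(ds, tuple_indices)
    restrict = _restriction(ds, idx, restrict_to)
    planes = [ds.bitplanes(i) for i in idx]
    # presence planes already imply their own variable's validity; extra
    # restriction variables contribute their validity mask
    extra = None
    for r in restrict:
        if r not in idx and ds.variables[r].n_missing:
            v = ds.bitplanes(r).valid
            extra = v if extra is None else extra & v
    shape = tuple(p.n_bins for p in planes)
    counts = np.zeros(shape, dtype=np.int64)
    for cell in np.ndindex(*shape):
        w = planes[0].planes[cell[0]]
        for k in range(1, len(idx)):
            w = w & planes[k].planes[cell[k]]
        if extra is not None:
            w = w & extra
        counts[cell] = int(np.bitwise_count(w).sum())
    return CountTable(idx, counts, int(counts.sum()))


def count_vector(
    ds: Dataset,
    tuple_indices: Sequence[int],
    restrict_to: Sequence[int] | None = None,
) -> CountTable:
    """Joint counts via direct per-sample accumulation."""
    idx = _check_tuple(ds, tuple_indices)
    restrict = _restriction(ds, idx, restrict_to)
    valid = np.ones(ds.n_samples, dtype=bool)
    for r in restrict:
        v = ds.variables[r]
        if v.n_missing:
            valid &= ~v.missing_mask
    shape = tuple(ds.variables[i].n_bins for i in idx)
    cols = [ds.variables[i].codes[valid] for i in idx]
    if cols[0].size == 0:
        return CountTable(idx, np.zeros(shape, dtype=np.int64), 0)
    flat = np.ravel_multi_index(cols, shape)
    counts = np.bincount(flat, minlength=int(np.prod(shape))).reshape(shape)
    return CountTable(idx, counts.astype(np.int64), int(counts.sum()))


def count_table(
    ds: Dataset,
    tuple_indices: Sequence[int],
    algorithm: str = "auto",
    restrict_to: Sequence[int] | None = None,
) -> CountTable:
    """Dispatch to a counting algorithm.

    ``auto`` uses the bitset algorithm when the number of popcount passes
    (product of bin counts) is small relative to the sample count, and the
    vector algorithm otherwise -- mirroring the B^d * M scaling of the
    word-level counter.
    """
    if algorithm == "bitset":
        return count_bitset(ds, tuple_indices, restrict_to)
    if algorithm == "vector":
        return count_vector(ds, tuple_indices, restrict_to)
    if algorithm != "auto":
        raise ValueError(f"unknown counting algorithm {algorithm!r}")
    n_cells = int(np.prod([ds.variables[int(i)].n_bins for i in tuple_indices]))
    if n_cells * max(ds.n_samples // 64, 1) <= 4 * ds.n_samples:
        return count_bitset(ds, tuple_indices, restrict_to)
    return count_vector(ds, tuple_indices, restrict_to)


def entropy_bits(ct: CountTable) -> float:
    """Plug-in Shannon entropy of a count table, in bits.

    H = -sum p log2 p over non-empty cells; zero cells contribute nothing.
    """
    n = ct.n_effective
    if n < 1:
        raise UndefinedEntropyError(
            f"entropy undefined for tuple {ct.tuple_indices}: no jointly "
            "observed samples"
        )
    c = ct.counts[ct.counts > 0].astype(np.float64)
    return float(np.log2(n) - (c * np.log2(c)).sum() / n)


@dataclass
class EntropyCache:
    """LRU memo of joint entropies.

    The key is the sorted tuple of variable indices together with the
    sorted indices of restriction variables that carry missing values
    (those determine the complete-case mask, hence the value).  With this
    key a cached entry always equals the freshly computed entropy.
    """

    capacity: int | None = 1 << 20
    hits: int = 0
    misses: int = 0
    _store: OrderedDict = field(default_factory=OrderedDict, repr=False)

    def key(self, ds: Dataset, tuple_indices, restrict) -> CacheKey:
        mask_vars = tuple(sorted(
            r for r in restrict if ds.variables[r].n_missing
        ))
        return (tuple(sorted(tuple_indices)), mask_vars)

    def get(self, key: CacheKey) -> float | None:
        if key in self._store:
            self.hits += 1
            self._store.move_to_end(key)
            return self._store[key]
        self.misses += 1
        return None

    def put(self, key: CacheKey, value: float) -> None:
        self._store[key] = value
        self._store.move_to_end(key)
        if self.capacity is not None and len(self._store) > self.capacity:
            self._store.popitem(last=False)

    def __len__(self) -> int:
        return len(self._store)


def joint_entropy(
    ds: Dataset,
    tuple_indices: Sequence[int],
    cache: EntropyCache | None = None,
    algorithm: str = "auto",
    restrict_to: Sequence[int] | None = None,
) -> float:
    """Joint entropy in bits of a variable tuple, optionally memoized.

    ``restrict_to`` widens the complete-case restriction beyond the tuple
    itself (used when the tuple is a margin of a larger measure's tuple).
    """
    idx = _check_tuple(ds, tuple_indices)
    restrict = _restriction(ds, idx, restrict_to)
    if cache is not None:
        key = cache.key(ds, idx, restrict)
        hit = cache.get(key)
        if hit is not None:
            return hit
    h = entropy_bits(count_table(ds, idx, algorithm, restrict))
    if cache is not None:
        cache.put(key, h)
    return h


def subset_entropies(
    ds: Dataset,
    tuple_indices: Sequence[int],
    subsets: Iterable[tuple[int, ...]],
    cache: EntropyCache | None = None,
    algorithm: str = "auto",
) -> dict[tuple[int, ...], float]:
    """Entropies of several subsets of one tuple, all on the tuple's
    joint complete-case sample set."""
    idx = _check_tuple(ds, tuple_indices)
    return {
        s: joint_entropy(ds, s, cache=cache, algorithm=algorithm, restrict_to=idx)
        for s in subsets
    }
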