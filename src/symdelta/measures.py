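"""Information measures: mutual information, interaction information,
asymmetric deltas, and the symmetric delta for 3 and 4 variables.

All measures are plug-in estimates built from joint entropies in bits,
with every entropy term of one measure computed on the tuple's joint
complete-case sample set.

Sign conventions
----------------
Interaction information follows McGill's recursion

    I(X,Y,Z) = I(X,Y) - I(X,Y|Z)
    I(W,X,Y,Z) = I(X,Y,Z) - I(X,Y,Z|W)

equivalently the alternating inclusion-exclusion over joint entropies
(+ for odd subsets, - for even).  A purely synergistic triple (XOR) gives
I3 = -1 bit; four-way parity gives I4 = +1 bit.

The asymmetric delta for target X in a triple is
``dX = I(X,Y,Z) - I(Y,Z)``, the change in interaction information from
adding X.  The symmetric delta is the product of the asymmetric deltas
over all choices of target; it vanishes whenever any variable of the
tuple is independent of the rest, and its magnitude ranks how collectively
interdependent the tuple is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .datamodel import Dataset
from .entropy import CountTable, EntropyCache, entropy_bits, subset_entropies

#: measure name -> tuple order
MEASURE_ORDER = {"mi": 2, "d3": 3, "d4": 4}


@dataclass(frozen=True)
class MeasureResult:
    """One scored tuple.

    ``value`` is in bits for MI, bits^3 for the 3-way symmetric delta and
    bits^4 for the 4-way; ``components`` holds the named sub-quantities
    (entropies, pairwise MIs, asymmetric deltas) from which ``value`` is
    exactly recomputable.
    """

    tuple_indices: tuple[int, ...]
    measure_name: str
    value: float
    components: dict[str, float]
    n_effective: int


def _entropies(ds, idx, cache, algorithm):
    """All non-empty subset entropies of the tuple, shared sample set."""
    subsets = [
        s for r in range(1, len(idx) + 1) for s in combinations(idx, r)
    ]
    return subset_entropies(ds, idx, subsets, cache=cache, algorithm=algorithm)


def mutual_information(
    ds: Dataset,
    x: int,
    y: int,
    cache: EntropyCache | None = None,
    algorithm: str = "auto",
) -> MeasureResult:
    """Pairwise mutual information I(X,Y) = H(X) + H(Y) - H(X,Y), in bits."""
    idx = (int(x), int(y))
    h = _entropies(ds, idx, cache, algorithm)
    value = h[(idx[0],)] + h[(idx[1],)] - h[idx]
    n_eff = _n_effective(ds, idx)
    comps = {"h_x": h[(idx[0],)], "h_y": h[(idx[1],)], "h_xy": h[idx]}
    return MeasureResult(idx, "mi", value, comps, n_eff)


def mi_from_counts(counts: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Mutual information in bits straight from a joint contingency table.

    Convenience for published genotype-count tables: rows index one
    variable, columns the other; zero cells contribute nothing.
    """
    ct = CountTable((0, 1), np.asarray(counts, dtype=np.int64), int(np.sum(counts)))
    hx = entropy_bits(ct.marginal((0,)))
    hy = entropy_bits(ct.marginal((1,)))
    return hx + hy - entropy_bits(ct)


def _n_effective(ds: Dataset, idx: tuple[int, ...]) -> int:
    valid = np.ones(ds.n_samples, dtype=bool)
    for i in idx:
        v = ds.variables[i]
        if v.n_missing:
            valid &= ~v.missing_mask
    return int(valid.sum())


def _interaction_information(h: dict, idx: tuple[int, ...]) -> float:
    """Alternating inclusion-exclusion: + odd subsets, - even subsets."""
    total = 0.0
    for r in range(1, len(idx) + 1):
        sign = 1.0 if r % 2 else -1.0
        for s in combinations(idx, r):
            total += sign * h[s]
    return total


def interaction_information3(
    ds: Dataset, x: int, y: int, z: int,
    cache: EntropyCache | None = None, algorithm: str = "auto",
) -> float:
    """Three-way interaction information I(X,Y,Z) = I(X,Y) - I(X,Y|Z), bits.

    Negative values indicate synergy (information visible only jointly,
    e.g. XOR); positive values indicate redundancy.
    """
    idx = (int(x), int(y), int(z))
    h = _entropies(ds, idx, cache, algorithm)
    return _interaction_information(h, idx)


def interaction_information4(
    ds: Dataset, w: int, x: int, y: int, z: int,
    cache: EntropyCache | None = None, algorithm: str = "auto",
) -> float:
    """Four-way interaction information via the same alternating expansion."""
    idx = (int(w), int(x), int(y), int(z))
    h = _entropies(ds, idx, cache, algorithm)
    return _interaction_information(h, idx)


def asymmetric_deltas3(
    ds: Dataset, x: int, y: int, z: int,
    cache: EntropyCache | None = None, algorithm: str = "auto",
) -> tuple[float, float, float]:
    """(dX, dY, dZ) with dX = I(X,Y,Z) - I(Y,Z) and cyclically.

    Each delta measures the change in interaction information from adding
    its target variable to the remaining pair.
    """
    idx = (int(x), int(y), int(z))
    h = _entropies(ds, idx, None if cache is None else cache, algorithm)
    i3 = _interaction_information(h, idx)
    mis = {
        pair: h[(pair[0],)] + h[(pair[1],)] - h[pair]
        for pair in combinations(idx, 2)
    }
    return tuple(
        i3 - mis[tuple(j for j in idx if j != target)] for target in idx
    )


def symmetric_delta3(
    ds: Dataset, x: int, y: int, z: int,
    cache: EntropyCache | None = None, algorithm: str = "auto",
) -> MeasureResult:
    """Symmetric delta of a triple: the product dX * dY * dZ (bits^3).

    Zero whenever any of the three variables is independent of the other
    two; symmetric under any permutation of the inputs.  Components carry
    the interaction information, each asymmetric delta and each pairwise
    MI (raw, unclamped, so the product is exactly recomputable).
    """
    idx = (int(x), int(y), int(z))
    h = _entropies(ds, idx, cache, algorithm)
    i3 = _interaction_information(h, idx)
    pairs = list(combinations(idx, 2))
    mis = {p: h[(p[0],)] + h[(p[1],)] - h[p] for p in pairs}
    deltas = [i3 - mis[tuple(j for j in idx if j != t)] for t in idx]
    value = deltas[0] * deltas[1] * deltas[2]
    comps = {"i3": i3, "d_x": deltas[0], "d_y": deltas[1], "d_z": deltas[2]}
    comps.update({
        f"mi_{min(a, b)}_{max(a, b)}": mis[(a, b)] for (a, b) in pairs
    })
    return MeasureResult(idx, "d3", value, comps, _n_effective(ds, idx))


def symmetric_delta4(
    ds: Dataset, w: int, x: int, y: int, z: int,
    cache: EntropyCache | None = None, algorithm: str = "auto",
) -> MeasureResult:
    """Symmetric delta of a 4-tuple: product of the four asymmetric deltas
    dW = I4(W,X,Y,Z) - I3(X,Y,Z) etc. (bits^4)."""
    idx = (int(w), int(x), int(y), int(z))
    h = _entropies(ds, idx, cache, algorithm)
    i4 = _interaction_information(h, idx)
    deltas = []
    comps: dict[str, float] = {"i4": i4}
    for t in idx:
        rest = tuple(j for j in idx if j != t)
        i3_rest = _interaction_information(h, rest)
        deltas.append(i4 - i3_rest)
        comps[f"i3_excl_{t}"] = i3_rest
    for k, t in enumerate(idx):
        comps[f"d_{t}"] = deltas[k]
    value = float(np.prod(deltas))
    return MeasureResult(idx, "d4", value, comps, _n_effective(ds, idx))


def compute_measure(
    ds: Dataset,
    measure: str,
    tuple_indices: Sequence[int],
    cache: EntropyCache | None = None,
    algorithm: str = "auto",
) -> MeasureResult:
    """Uniform entry point used by the search driver and permutation stage."""
    idx = tuple(int(i) for i in tuple_indices)
    if measure not in MEASURE_ORDER:
        raise ValueError(f"unknown measure {measure!r}")
    if len(idx) != MEASURE_ORDER[measure]:
        raise ValueError(
            f"measure {measure!r} needs {MEASURE_ORDER[measure]} variables, "
            f"got {len(idx)}"
        )
    if measure == "mi":
        return mutual_information(ds, *idx, cache=cache, algorithm=algorithm)
    if measure == "d3":
        return symmetric_delta3(ds, *idx, cache=cache, algorithm=algorithm)
    return symmetric_delta4(ds, *idx, cache=cache, algorithm=algorithm)
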