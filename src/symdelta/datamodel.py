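"""Discrete data matrices: encoding, validation, missingness, bit-plane form.

A dataset is a samples-by-variables matrix of small non-negative integer
codes (for genotypes: 0 = major homozygote, 1 = minor homozygote,
2 = heterozygote) with a sentinel, by default -1, marking missing entries.
Each variable carries a bin count B; every non-missing code lies in
[0, B-1].  The counting engine consumes variables recast as B presence
bitsets plus one validity bitset, packed into 64-bit words.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Default sentinel for a missing observation.
MISSING: int = -1

_WORD = 64


class DataFormatError(ValueError):
    """Raised when an input matrix cannot be parsed or validated."""


class EmptyDatasetError(ValueError):
    """Raised when an operation would leave a dataset with no variables."""


@dataclass(frozen=True)
class DiscreteVariable:
    """A named, integer-coded observation vector with missingness.

    Parameters
    ----------
    name : str
        Unique label of the variable.
    index : int
        0-based position of the variable in its dataset.
    codes : numpy.ndarray
        Length-M int vector; entries are in ``[0, n_bins - 1]`` or equal
        to the missing sentinel.
    n_bins : int
        Number of distinct codes (B) the variable may take.
    """

    name: str
    index: int
    codes: np.ndarray
    n_bins: int
    missing_sentinel: int = MISSING

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 1 or codes.size < 1:
            raise DataFormatError(
                f"variable {self.name!r}: codes must be a non-empty 1-D vector"
            )
        if self.n_bins < 1:
            raise DataFormatError(f"variable {self.name!r}: n_bins must be >= 1")
        observed = codes[codes != self.missing_sentinel]
        if observed.size and (observed.min() < 0 or observed.max() >= self.n_bins):
            raise DataFormatError(
                f"variable {self.name!r}: codes outside [0, {self.n_bins - 1}]"
            )

    @property
    def n_samples(self) -> int:
        return int(self.codes.size)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == self.missing_sentinel

    @property
    def n_missing(self) -> int:
        return int(np.count_nonzero(self.missing_mask))

    @classmethod
    def from_codes(
        cls,
        name: str,
        index: int,
        codes: Sequence[int] | np.ndarray,
        n_bins: int | None = None,
        missing_sentinel: int = MISSING,
    ) -> "DiscreteVariable":
        """Build a variable, inferring B as max observed code + 1 if not given."""
        codes = np.asarray(codes, dtype=np.int64)
        if n_bins is None:
            observed = codes[codes != missing_sentinel]
            n_bins = int(observed.max()) + 1 if observed.size else 1
        return cls(name, index, codes, n_bins, missing_sentinel)


@dataclass(frozen=True)
class BitPlaneVariable:
    """Bit-plane form of a discrete variable.

    ``planes[b]`` is a packed uint64 bitset with bit *i* set iff sample *i*
    has code *b*; ``valid`` has bit *i* set iff sample *i* is non-missing.
    Planes are pairwise disjoint and OR together to ``valid``; bits beyond
    the sample count are zero (tail-masked).
    """

    planes: np.ndarray  # shape (B, n_words), uint64
    valid: np.ndarray   # shape (n_words,), uint64
    n_samples: int

    @property
    def n_bins(self) -> int:
        return int(self.planes.shape[0])

    def decode(self, missing_sentinel: int = MISSING) -> np.ndarray:
        """Reconstruct the code vector (inverse of :func:`to_bitplanes`)."""
        out = np.full(self.n_samples, missing_sentinel, dtype=np.int64)
        for b in range(self.n_bins):
            out[_unpack(self.planes[b], self.n_samples)] = b
        return out


def _n_words(m: int) -> int:
    return (m + _WORD - 1) // _WORD


def _pack(mask: np.ndarray) -> np.ndarray:
    """Pack a boolean sample mask into little-bit-order uint64 words.

    Bits past the sample count stay zero, so word-level AND/popcount never
    sees tail garbage.
    """
    m = mask.size
    padded = np.zeros(_n_words(m) * _WORD, dtype=bool)
    padded[:m] = mask
    return np.packbits(padded, bitorder="little").view(np.uint64)


def _unpack(words: np.ndarray, m: int) -> np.ndarray:
    bits = np.unpackbits(words.view(np.uint8), bitorder="little")
    return bits[:m].astype(bool)


def popcount(words: np.ndarray) -> int:
    """Total number of set bits across a packed word array."""
    return int(np.bitwise_count(words).sum())


def to_bitplanes(v: DiscreteVariable) -> BitPlaneVariable:
    """Recast a variable as B presence bitsets plus a validity bitset."""
    planes = np.empty((v.n_bins, _n_words(v.n_samples)), dtype=np.uint64)
    for b in range(v.n_bins):
        planes[b] = _pack(v.codes == b)
    valid = _pack(~v.missing_mask)
    return BitPlaneVariable(planes=planes, valid=valid, n_samples=v.n_samples)


@dataclass
class Dataset:
    """An ordered collection of equally sized discrete variables."""

    variables: list[DiscreteVariable]
    sample_ids: list[str] | None = None
    _bitplanes: dict[int, BitPlaneVariable] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.variables:
            raise EmptyDatasetError("dataset has no variables")
        m = self.variables[0].n_samples
        for v in self.variables:
            if v.n_samples != m:
                raise DataFormatError(
                    f"variable {v.name!r} has {v.n_samples} samples, expected {m}"
                )
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataFormatError(f"duplicate variable names: {dupes}")
        self._name_to_index = {v.name: i for i, v in enumerate(self.variables)}

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_samples(self) -> int:
        return self.variables[0].n_samples

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def __getitem__(self, key: int | str) -> DiscreteVariable:
        if isinstance(key, str):
            key = self.index_of(key)
        return self.variables[key]

    def index_of(self, name: str) -> int:
        try:
            return self._name_to_index[name]
        except KeyError:
            raise KeyError(f"no variable named {name!r}") from None

    def bitplanes(self, index: int) -> BitPlaneVariable:
        """Bit-plane form of variable ``index`` (memoized)."""
        bp = self._bitplanes.get(index)
        if bp is None:
            bp = to_bitplanes(self.variables[index])
            self._bitplanes[index] = bp
        return bp

    def to_frame(self) -> pd.DataFrame:
        """Samples-as-rows DataFrame of the raw codes."""
        data = {v.name: v.codes for v in self.variables}
        idx = self.sample_ids if self.sample_ids is not None else None
        return pd.DataFrame(data, index=idx)

    @classmethod
    def from_matrix(
        cls,
        matrix: np.ndarray,
        names: Sequence[str],
        missing_sentinel: int = MISSING,
        n_bins: Sequence[int] | None = None,
        sample_ids: list[str] | None = None,
    ) -> "Dataset":
        """Build from a samples-by-variables integer matrix."""
        matrix = np.asarray(matrix, dtype=np.int64)
        if matrix.ndim != 2:
            raise DataFormatError("matrix must be 2-D (samples x variables)")
        if matrix.shape[1] != len(names):
            raise DataFormatError("number of names does not match columns")
        variables = [
            DiscreteVariable.from_codes(
                str(names[j]), j, matrix[:, j],
                n_bins=None if n_bins is None else int(n_bins[j]),
                missing_sentinel=missing_sentinel,
            )
            for j in range(matrix.shape[1])
        ]
        return cls(variables, sample_ids=sample_ids)


def load_matrix(
    path: str | Path,
    orientation: str = "samples-as-rows",
    missing_sentinel: int = MISSING,
    delimiter: str | None = None,
) -> Dataset:
    """Load a delimited integer matrix with a header line of variable names.

    Parameters
    ----------
    path : path
        TSV (default) or CSV file.  The header row names the variables when
        ``orientation="samples-as-rows"``; with ``"variables-as-rows"`` the
        first column names them and the header labels samples.
    orientation : {"samples-as-rows", "variables-as-rows"}
    missing_sentinel : int
        Code marking a missing observation (default -1).
    """
    path = Path(path)
    if orientation not in ("samples-as-rows", "variables-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if delimiter is None:
        delimiter = "," if path.suffix.lower() == ".csv" else "\t"
    if orientation == "samples-as-rows":
        # validate the raw header before pandas mangles duplicates to A.1
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(delimiter)
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise DataFormatError(f"{path}: duplicate variable names {dupes}")
    try:
        df = pd.read_csv(path, sep=delimiter, header=0,
                         index_col=0 if orientation == "variables-as-rows" else None)
    except pd.errors.ParserError as exc:
        raise DataFormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    if orientation == "variables-as-rows":
        df = df.T
        df.columns = [str(c) for c in df.columns]
    for col in df.columns:
        if not pd.api.types.is_integer_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataFormatError(
                    f"{path}: non-integer cell at row {row}, column {col!r}"
                )
            df[col] = coerced.astype(np.int64)
    sample_ids = None
    if orientation == "variables-as-rows":
        sample_ids = [str(s) for s in df.index]
    return Dataset.from_matrix(
        df.to_numpy(dtype=np.int64), [str(c) for c in df.columns],
        missing_sentinel=missing_sentinel, sample_ids=sample_ids,
    )


def write_matrix(ds: Dataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write a dataset as a samples-as-rows delimited matrix with header."""
    ds.to_frame().to_csv(path, sep=delimiter, index=False)


def prune_by_missingness(
    ds: Dataset,
    max_missing: int | float,
    protected: Sequence[str] = (),
) -> Dataset:
    """Drop variables with more than ``max_missing`` missing values.

    ``max_missing`` is an absolute count, or a fraction of the sample count
    when given as a float in [0, 1).  Variables named in ``protected``
    (e.g. the phenotype) are always retained.  Original order is preserved
    and the operation is idempotent.
    """
    if isinstance(max_missing, float) and 0 <= max_missing < 1:
        threshold = int(max_missing * ds.n_samples)
    else:
        threshold = int(max_missing)
    if threshold < 0:
        raise ValueError("max_missing must be >= 0")
    protected_set = set(protected)
    kept = [
        v for v in ds.variables
        if v.n_missing <= threshold or v.name in protected_set
    ]
    if not kept:
        raise EmptyDatasetError(
            f"pruning at max_missing={threshold} removes every variable"
        )
    reindexed = [
        DiscreteVariable(v.name, i, v.codes, v.n_bins, v.missing_sentinel)
        for i, v in enumerate(kept)
    ]
    return Dataset(reindexed, sample_ids=ds.sample_ids)
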