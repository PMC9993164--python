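"""Search driver: score every tuple of a TupleSpace with the configured
measure, merge per-worker top-k results deterministically, write TSV.

Workers own contiguous working sets of the rank order and share nothing
(each has its own entropy cache), so the merged output is identical for
any worker count.  Ranking is by absolute measure value, descending, with
ties broken by tuple rank ascending -- magnitudes rank the degree of
collective interdependence for the delta measures, and MI is nonnegative
so the rule reduces to plain descending order there.
"""

from __future__ import annotations

import heapq
import logging
import sys
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .datamodel import Dataset
from .entropy import EntropyCache, UndefinedEntropyError
from .measures import MEASURE_ORDER, MeasureResult, compute_measure
from .tuplespace import TupleSpace, WorkingSet

log = logging.getLogger("symdelta")


class ConfigError(ValueError):
    """Raised for inconsistent search configurations."""


@dataclass
class SearchConfig:
    """Configuration of one search run.

    ``top_k = 0`` keeps every scored tuple; otherwise each worker holds a
    bounded heap of size ``top_k`` and the merge is global top-k.
    """

    measure: str = "mi"
    algorithm: str = "auto"
    n_workers: int = 1
    top_k: int = 0
    cache_enabled: bool = True
    cache_capacity: int | None = 1 << 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.measure not in MEASURE_ORDER:
            raise ConfigError(f"unknown measure {self.measure!r}")
        if self.top_k < 0:
            raise ConfigError("top_k must be >= 0")
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")


@dataclass(frozen=True)
class SearchResult:
    """A scored tuple plus rank-order metadata and variable names."""

    tuple_indices: tuple[int, ...]
    variable_names: tuple[str, ...]
    measure_name: str
    value: float
    components: dict[str, float]
    n_effective: int
    tuple_rank: int

    @classmethod
    def from_measure(cls, mr: MeasureResult, names, rank: int) -> "SearchResult":
        return cls(mr.tuple_indices, tuple(names), mr.measure_name,
                   mr.value, mr.components, mr.n_effective, rank)

    @property
    def sort_key(self):
        # larger |value| first; ties broken by earlier rank
        return (-abs(self.value), self.tuple_rank)


@dataclass
class SearchStats:
    n_scored: int = 0
    n_skipped: int = 0
    cache_hits: int = 0
    cache_misses: int = 0


def _score_working_set(
    ds: Dataset, ts: TupleSpace, cfg: SearchConfig, ws: WorkingSet,
) -> tuple[list[SearchResult], SearchStats]:
    cache = (EntropyCache(capacity=cfg.cache_capacity)
             if cfg.cache_enabled else None)
    stats = SearchStats()
    heap: list[tuple] = []  # max-heap by sort_key via negation
    keep_all = cfg.top_k == 0
    results: list[SearchResult] = []
    for rank in ws.ranks():
        idx = ts.tuple_at(rank)
        try:
            mr = compute_measure(ds, cfg.measure, idx,
                                 cache=cache, algorithm=cfg.algorithm)
        except UndefinedEntropyError:
            stats.n_skipped += 1
            continue
        stats.n_scored += 1
        sr = SearchResult.from_measure(mr, [ds.variables[i].name for i in idx],
                                       rank)
        if keep_all:
            results.append(sr)
        else:
            # heap keeps the top_k best keys; root is the worst retained
            entry = (tuple(-v for v in sr.sort_key), sr)
            if len(heap) < cfg.top_k:
                heapq.heappush(heap, entry)
            elif entry[0] > heap[0][0]:
                heapq.heapreplace(heap, entry)
    if not keep_all:
        results = [e[1] for e in heap]
    if cache is not None:
        stats.cache_hits = cache.hits
        stats.cache_misses = cache.misses
    return results, stats


def run_search(
    ds: Dataset,
    ts: TupleSpace,
    cfg: SearchConfig,
    stats_out: SearchStats | None = None,
) -> list[SearchResult]:
    """Score every tuple in the space exactly once and return the merged,
    sorted (by |value| desc, tuple rank asc) top-k results.

    The output is independent of ``cfg.n_workers``; tuples whose effective
    sample set is empty are excluded and counted in the skip log.
    """
    order = MEASURE_ORDER[cfg.measure]
    for gt in ts.group_tuples:
        if len(gt.slots) != order:
            raise ConfigError(
                f"measure {cfg.measure!r} scores {order}-tuples but template "
                f"{gt.slots} has length {len(gt.slots)}"
            )
    parts = ts.partition(cfg.n_workers)
    if cfg.n_workers == 1:
        chunks = [_score_working_set(ds, ts, cfg, parts[0])]
    else:
        with ThreadPoolExecutor(max_workers=cfg.n_workers) as pool:
            chunks = list(pool.map(
                lambda ws: _score_working_set(ds, ts, cfg, ws), parts))
    merged: list[SearchResult] = []
    total_stats = SearchStats()
    for results, stats in chunks:
        merged.extend(results)
        total_stats.n_scored += stats.n_scored
        total_stats.n_skipped += stats.n_skipped
        total_stats.cache_hits += stats.cache_hits
        total_stats.cache_misses += stats.cache_misses
    merged.sort(key=lambda r: r.sort_key)
    if cfg.top_k:
        merged = merged[:cfg.top_k]
    if total_stats.n_skipped:
        log.info("skipped %d tuples with empty effective sample set",
                 total_stats.n_skipped)
    log.info("scored %d tuples (cache: %d hits / %d misses)",
             total_stats.n_scored, total_stats.cache_hits,
             total_stats.cache_misses)
    if stats_out is not None:
        stats_out.n_scored = total_stats.n_scored
        stats_out.n_skipped = total_stats.n_skipped
        stats_out.cache_hits = total_stats.cache_hits
        stats_out.cache_misses = total_stats.cache_misses
    return merged


# -- output ------------------------------------------------------------

#: component columns surfaced per measure, mirroring the published layouts:
#: pairwise scans print the MI and effective n; three-way modifier scans
#: print the delta plus its three pairwise MI components.
_COMPONENT_COLUMNS = {
    "mi": [],
    "d3": ["mi_pair_01", "mi_pair_02", "mi_pair_12"],
    "d4": [],
}


def results_frame(results: Sequence[SearchResult]) -> pd.DataFrame:
    """Tabular form of a result list (one row per scored tuple)."""
    if not results:
        return pd.DataFrame(columns=["measure", "value", "n"])
    measure = results[0].measure_name
    order = MEASURE_ORDER[measure]
    rows = []
    for r in results:
        row = {f"var{k}": r.variable_names[k] for k in range(order)}
        row[measure] = r.value
        if r.components.get("p") is not None:
            row["p"] = r.components["p"]
        if measure == "d3":
            a, b, c = r.tuple_indices
            row["mi_pair_01"] = r.components[f"mi_{min(a,b)}_{max(a,b)}"]
            row["mi_pair_02"] = r.components[f"mi_{min(a,c)}_{max(a,c)}"]
            row["mi_pair_12"] = r.components[f"mi_{min(b,c)}_{max(b,c)}"]
        row["n"] = r.n_effective
        rows.append(row)
    df = pd.DataFrame(rows)
    if measure == "mi":
        # plug-in MI can be -epsilon from float error; clamp only here in
        # reported output, never inside delta arithmetic
        df[measure] = df[measure].clip(lower=0.0)
    if "p" in df.columns:  # p after the measure column
        cols = [c for c in df.columns if c != "p"]
        k = cols.index(measure) + 1
        df = df[cols[:k] + ["p"] + cols[k:]]
    return df


def write_results(results: Sequence[SearchResult], path: str | Path) -> None:
    """Write results as a TSV with header; floats at 8 significant digits.

    An empty result list produces a header-only file.
    """
    df = results_frame(results)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Re-parse a results TSV (round-trips values at written precision)."""
    return pd.read_csv(path, sep="\t")


def setup_logging(quiet: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.WARNING if quiet else logging.INFO)
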