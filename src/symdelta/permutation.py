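"""Permutation-based p-values for high-scoring tuples.

The null is built by independently shuffling a designated subset of the
tuple's variables over samples while leaving the rest untouched, so the
joint structure (e.g. linkage between genotype variables) of the
non-permuted block is preserved exactly while its dependence on the
shuffled variables is destroyed.  The estimator is

    p = (b + 1) / (n_permutations + 1)

with b the number of permuted statistics at least as extreme as the
observed one (never zero; the floor at 10,000 permutations is
1/10001 ~ 0.0001).  Shuffles act on the full sample vector including
missing entries, so each variable's missingness pattern is preserved
marginally and the complete-case mask is re-derived per permutation.

Each tuple draws its permutations from a dedicated substream of the
master seed (spawn-keyed by the sorted variable indices), so p-values do
not depend on evaluation order or worker count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .datamodel import Dataset, DiscreteVariable
from .measures import MEASURE_ORDER, compute_measure
from .search import SearchResult

TAILS = ("greater", "greater-abs")


@dataclass(frozen=True)
class PermutationPlan:
    """How to randomize: which variables to shuffle, how many times, and
    which tail defines "at least as extreme".

    ``tail="greater-abs"`` (the default for the delta measures, whose
    ranking is by magnitude) compares |statistic|; ``"greater"`` compares
    the raw statistic and suits MI.
    """

    permute_vars: tuple[int, ...]
    n_permutations: int = 10_000
    seed: int = 0
    tail: str = "greater-abs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "permute_vars",
                           tuple(int(v) for v in self.permute_vars))
        if not self.permute_vars:
            raise ValueError("permute_vars must be non-empty")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tail not in TAILS:
            raise ValueError(f"tail must be one of {TAILS}")


def default_tail(measure: str) -> str:
    return "greater" if measure == "mi" else "greater-abs"


def _extremity(value: float, tail: str) -> float:
    return abs(value) if tail == "greater-abs" else value


def shuffled_variables(
    base_vars: list[DiscreteVariable],
    positions: Sequence[int],
    rng: np.random.Generator,
) -> list[DiscreteVariable]:
    """Independently shuffle the designated variables over samples.

    The shuffle acts on the full code vector, missing entries included,
    so each variable keeps its multiset of codes (hence its missingness
    pattern marginally); all other variables are returned untouched.
    """
    variables = list(base_vars)
    m = base_vars[0].n_samples
    for k in positions:
        v = base_vars[k]
        variables[k] = DiscreteVariable(
            v.name, k, v.codes[rng.permutation(m)], v.n_bins,
            v.missing_sentinel,
        )
    return variables


def permutation_pvalue(
    ds: Dataset,
    tuple_indices: Sequence[int],
    measure: str,
    plan: PermutationPlan,
    algorithm: str = "auto",
) -> float:
    """Permutation p-value of ``measure`` on one tuple under ``plan``.

    The designated variables are shuffled independently of one another;
    the non-designated block is never touched, so its internal joint
    counts are identical under every permutation.
    """
    idx = tuple(int(i) for i in tuple_indices)
    if len(idx) != MEASURE_ORDER[measure]:
        raise ValueError(f"measure {measure!r} expects "
                         f"{MEASURE_ORDER[measure]} variables")
    pset = set(plan.permute_vars)
    if not pset < set(idx):
        raise ValueError(
            "permute_vars must be a strict subset of the tuple "
            f"(tuple {idx}, permuting {sorted(pset)})"
        )
    # work on a compact sub-dataset holding just the tuple's variables
    base_vars = [
        DiscreteVariable(ds.variables[i].name, k, ds.variables[i].codes,
                         ds.variables[i].n_bins, ds.variables[i].missing_sentinel)
        for k, i in enumerate(idx)
    ]
    sub = Dataset(base_vars)
    local = tuple(range(len(idx)))
    observed = _extremity(
        compute_measure(sub, measure, local, algorithm=algorithm).value,
        plan.tail,
    )
    positions = [k for k, i in enumerate(idx) if i in pset]
    rng = np.random.default_rng(
        np.random.SeedSequence(plan.seed, spawn_key=tuple(sorted(idx)))
    )
    b = 0
    for _ in range(plan.n_permutations):
        permuted = Dataset(shuffled_variables(base_vars, positions, rng))
        stat = _extremity(
            compute_measure(permuted, measure, local,
                            algorithm=algorithm).value,
            plan.tail,
        )
        if stat >= observed:
            b += 1
    return (b + 1) / (plan.n_permutations + 1)


def attach_pvalues(
    results: list[SearchResult],
    ds: Dataset,
    plan: PermutationPlan,
    top_n: int = 200,
    algorithm: str = "auto",
) -> list[SearchResult]:
    """Compute p-values for the ``top_n`` ranked results and re-sort.

    Results come back ordered by (p ascending, |value| descending, tuple
    rank ascending); entries beyond ``top_n`` keep no p-value and follow
    after all p-valued ones, still in magnitude order.  ``top_n = 0``
    returns the input unchanged.
    """
    if top_n == 0:
        return list(results)
    if top_n > len(results):
        import logging
        logging.getLogger("symdelta").warning(
            "perm-top %d exceeds %d results; clamping", top_n, len(results))
        top_n = len(results)
    out: list[SearchResult] = []
    for k, r in enumerate(results):
        if k < top_n:
            p = permutation_pvalue(ds, r.tuple_indices, r.measure_name,
                                   plan, algorithm=algorithm)
            comps = dict(r.components)
            comps["p"] = p
            out.append(replace(r, components=comps))
        else:
            out.append(r)
    out.sort(key=lambda r: (r.components.get("p", np.inf),
                            -abs(r.value), r.tuple_rank))
    return out
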