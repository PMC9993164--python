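"""Synthetic fixtures: a 90-variable functional-dependency test set and a
case/control genotype screen with a planted anchor SNP and a planted
pure-epistatic modifier SNP.

Both generators return a :class:`~symdelta.datamodel.Dataset` plus a
manifest naming every planted relationship, so recovery can be checked
blind to the generator's internals.  Generation is fully reproducible
from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .datamodel import MISSING, Dataset


class SpecError(ValueError):
    """Raised for infeasible generator specifications."""


# ---------------------------------------------------------------------
# functional-dependency test data
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class TestDataSpec:
    """Layout of the functional-dependency test set.

    The variables split into three equal blocks: pairs with a strong
    deterministic ``f(X) = 2X`` dependence (an injective relabeling of a
    3-level uniform X, corrupted at ``strong_noise_rate``), pairs with
    the same construction at ``weak_noise_rate``, and triples with a
    three-way ``Z = XOR(X, Y)`` dependence (binary uniform inputs,
    corrupted at ``strong_noise_rate``).  Noise replaces a symbol with a
    uniform draw over the variable's codes.  Block positions that cannot
    complete a pair/triple are filled with independent variables.
    """

    __test__ = False  # bare data container despite the Test* name

    n_variables: int = 90
    n_samples: int = 1000
    strong_noise_rate: float = 0.05
    weak_noise_rate: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variables % 3 != 0:
            raise SpecError("n_variables must be divisible by 3")
        if self.n_samples < 1:
            raise SpecError("n_samples must be >= 1")
        for r in (self.strong_noise_rate, self.weak_noise_rate):
            if not 0 <= r <= 1:
                raise SpecError("noise rates must lie in [0, 1]")


def _corrupt(rng, codes: np.ndarray, n_bins: int, rate: float) -> np.ndarray:
    """Replace each symbol, with probability ``rate``, by a uniform draw."""
    out = codes.copy()
    hit = rng.random(codes.size) < rate
    out[hit] = rng.integers(0, n_bins, hit.sum())
    return out


def generate_test_data(spec: TestDataSpec = TestDataSpec()) -> tuple[Dataset, list[dict]]:
    """Generate the functional-dependency test set and its manifest.

    Returns ``(dataset, manifest)`` where each manifest entry records a
    planted relationship: ``{"kind": "pair_strong" | "pair_weak" | "xor",
    "variables": (...names...)}``.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_samples
    block = spec.n_variables // 3
    columns: list[np.ndarray] = []
    names: list[str] = []
    manifest: list[dict] = []

    def pair_block(label: str, rate: float) -> None:
        n_pairs, leftover = divmod(block, 2)
        for i in range(n_pairs):
            x = rng.integers(0, 3, m)
            y = _corrupt(rng, (2 * x) % 3, 3, rate)  # injective relabeling of x
            nx, ny = f"{label}{i:02d}_x", f"{label}{i:02d}_y"
            columns.extend([x, y])
            names.extend([nx, ny])
            manifest.append({"kind": f"pair_{label}", "variables": (nx, ny)})
        for i in range(leftover):
            columns.append(rng.integers(0, 3, m))
            names.append(f"{label}_indep{i:02d}")

    pair_block("strong", spec.strong_noise_rate)
    pair_block("weak", spec.weak_noise_rate)

    n_triples, leftover = divmod(block, 3)
    for i in range(n_triples):
        x = rng.integers(0, 2, m)
        y = rng.integers(0, 2, m)
        z = _corrupt(rng, x ^ y, 2, spec.strong_noise_rate)
        nx, ny, nz = (f"xor{i:02d}_x", f"xor{i:02d}_y", f"xor{i:02d}_z")
        columns.extend([x, y, z])
        names.extend([nx, ny, nz])
        manifest.append({"kind": "xor", "variables": (nx, ny, nz)})
    for i in range(leftover):
        columns.append(rng.integers(0, 2, m))
        names.append(f"xor_indep{i:02d}")

    ds = Dataset.from_matrix(np.column_stack(columns), names)
    return ds, manifest


# ---------------------------------------------------------------------
# case/control genotype screen
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeScreenSpec:
    """Case/control genotype matrix with planted structure.

    Genotypes are coded 0 = major homozygote, 1 = minor homozygote,
    2 = heterozygote, -1 = missing; the phenotype is 1 for cases and 0
    for controls.  The anchor SNP's minor-allele frequency is shifted by
    ``anchor_effect`` between cases and controls (a direct marginal
    association).  The modifier SNP is purely epistatic: its carrier
    probability depends on the *combination* of phenotype and anchor
    carrier status, with the strata weighted so the modifier's marginal
    distribution is identical in cases and controls -- pairwise
    modifier-phenotype MI is ~0 in population while the three-way delta
    with (phenotype, anchor) is large.  ``modifier_effect`` is the
    carrier-probability shift within a stratum.
    """

    n_cases: int = 2778
    n_controls: int = 2778
    n_snps: int = 1000
    anchor_effect: float = 0.15
    modifier_effect: float = 0.15
    anchor_maf: float = 0.25
    modifier_carrier_rate: float = 0.30
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) < 1 or self.n_snps < 3:
            raise SpecError("need >= 1 case, >= 1 control and >= 3 SNPs")
        for r in (self.missing_rate, self.modifier_carrier_rate):
            if not 0 <= r <= 1:
                raise SpecError("rates must lie in [0, 1]")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise SpecError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for q in (self.anchor_maf - self.anchor_effect,
                  self.anchor_maf + self.anchor_effect):
            if not 0 <= q <= 1:
                raise SpecError("anchor_effect pushes allele frequency "
                                "outside [0, 1]")


def _hwe_genotypes(rng, q: float, n: int) -> np.ndarray:
    """Sample genotypes under Hardy-Weinberg at minor-allele frequency q,
    in the 0=major-hom, 1=minor-hom, 2=het coding."""
    probs = [(1 - q) ** 2, q ** 2, 2 * q * (1 - q)]
    return rng.choice(3, size=n, p=probs)


def generate_genotype_screen(
    spec: GenotypeScreenSpec = GenotypeScreenSpec(),
) -> tuple[Dataset, dict[str, Any]]:
    """Generate the screen matrix and a manifest of the planted SNPs.

    The dataset's first column is the phenotype ``AD``; SNP columns are
    named ``SNP0000`` onward, with the anchor and modifier hidden at
    rng-chosen positions (recorded in the manifest).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cases + spec.n_controls
    pheno = np.concatenate([
        np.ones(spec.n_cases, dtype=np.int64),
        np.zeros(spec.n_controls, dtype=np.int64),
    ])

    # anchor: marginal case/control allele-frequency shift
    q_case = spec.anchor_maf + spec.anchor_effect
    q_ctrl = spec.anchor_maf - spec.anchor_effect
    anchor = np.empty(n, dtype=np.int64)
    anchor[pheno == 1] = _hwe_genotypes(rng, q_case, spec.n_cases)
    anchor[pheno == 0] = _hwe_genotypes(rng, q_ctrl, spec.n_controls)

    # modifier: carrier probability depends on (phenotype XOR anchor-carrier)
    # with stratum weights chosen so the phenotype marginal is exactly flat
    carrier = (anchor > 0)
    c, d = spec.modifier_carrier_rate, spec.modifier_effect
    p_carrier = np.empty(n, dtype=float)
    for s in (0, 1):
        in_s = pheno == s
        alpha = carrier[in_s].mean()  # realized P(anchor carrier | phenotype)
        if alpha in (0.0, 1.0):
            raise SpecError("anchor carriers are monomorphic within a "
                            "phenotype class; cannot balance the modifier")
        sign = 1.0 if s == 1 else -1.0
        # offsets +d(1-alpha) for carriers, -d*alpha for non-carriers keep
        # the phenotype marginal exactly flat for any realized alpha
        p_hi = c + sign * d * (1 - alpha)
        p_lo = c - sign * d * alpha
        if not (0 <= p_hi <= 1 and 0 <= p_lo <= 1):
            raise SpecError(
                f"modifier_effect={d} infeasible: stratum carrier "
                f"probabilities ({p_hi:.3f}, {p_lo:.3f}) outside [0, 1]"
            )
        p_carrier[in_s & carrier] = p_hi
        p_carrier[in_s & ~carrier] = p_lo
    mod_carrier = rng.random(n) < p_carrier
    # split carriers into het / minor-hom (het twice as likely)
    modifier = np.zeros(n, dtype=np.int64)
    modifier[mod_carrier] = np.where(rng.random(mod_carrier.sum()) < 2 / 3, 2, 1)

    # background SNPs, independent of everything
    snps = np.empty((n, spec.n_snps), dtype=np.int64)
    positions = rng.choice(spec.n_snps, size=2, replace=False)
    anchor_pos, modifier_pos = int(positions[0]), int(positions[1])
    for j in range(spec.n_snps):
        if j == anchor_pos:
            snps[:, j] = anchor
        elif j == modifier_pos:
            snps[:, j] = modifier
        else:
            q = rng.uniform(*spec.maf_range)
            snps[:, j] = _hwe_genotypes(rng, q, n)

    if spec.missing_rate > 0:
        mask = rng.random(snps.shape) < spec.missing_rate
        snps[mask] = MISSING

    names = ["AD"] + [f"SNP{j:04d}" for j in range(spec.n_snps)]
    matrix = np.column_stack([pheno, snps])
    ds = Dataset.from_matrix(matrix, names)
    manifest = {
        "phenotype": "AD",
        "anchor": f"SNP{anchor_pos:04d}",
        "modifier": f"SNP{modifier_pos:04d}",
        "anchor_effect": spec.anchor_effect,
        "modifier_effect": spec.modifier_effect,
        "n_cases": spec.n_cases,
        "n_controls": spec.n_controls,
    }
    return ds, manifest
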