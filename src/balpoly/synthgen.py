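"""Synthetic-data generators for every analysis in the package.

Emulates the statistical structure of the study data: Hardy-Weinberg
genotypes with a fully dominant causal locus, Poisson low-coverage reads
with base error, neutral and balanced-locus haplotype windows for the
selection-scan statistics, and normally distributed preference differences
for behavioral power analysis.  All generators are bit-reproducible given
their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .windows import MISSING, HaplotypeWindow

__all__ = [
    "PopulationSim",
    "ReadCountSim",
    "TrialDataset",
    "dominant_allele_freq",
    "simulate_population",
    "simulate_reads",
    "simulate_neutral_window",
    "simulate_balanced_window",
    "simulate_trials",
]


def dominant_allele_freq(f_pheno: float) -> float:
    """Allele frequency of a fully dominant allele with phenotype frequency
    ``f_pheno`` under Hardy-Weinberg equilibrium: ``d = 1 - sqrt(1 - f)``."""
    if not 0.0 <= f_pheno <= 1.0:
        raise ValueError(f"phenotype frequency must be in [0, 1], got {f_pheno}")
    return 1.0 - np.sqrt(1.0 - f_pheno)


@dataclass
class PopulationSim:
    """Diploid genotypes with a dominant causal site and binary phenotypes.

    ``genotypes`` is ``(n_individuals, n_sites)`` alternate-allele dosage in
    {0, 1, 2}; phenotype is 1 for carriers of the causal allele with
    probability ``penetrance``.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    causal_index: int | None
    allele_freqs: np.ndarray
    seed: int

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]


@dataclass
class ReadCountSim:
    """Per-cell reference/alternate read counts drawn from a PopulationSim."""

    ref_counts: np.ndarray
    alt_counts: np.ndarray
    coverage: float
    error_rate: float
    source: PopulationSim = field(repr=False)
    seed: int = 0


@dataclass
class TrialDataset:
    """Per-female preference differences from dichotomous choice trials.

    ``diffs`` are differences in the proportion of trial time spent with the
    two stimuli, hence each lies in [-1, 1].
    """

    diffs: np.ndarray
    group_label: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=float)
        if np.any(np.abs(self.diffs) > 1.0):
            raise ValueError("preference differences must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.diffs.size

    @property
    def sd(self) -> float:
        return float(np.std(self.diffs, ddof=1))


MafSampler = Callable[[np.random.Generator, int], np.ndarray]


def _resolve_maf_sampler(spec: MafSampler | Sequence | None) -> MafSampler:
    # default: alternate-allele frequencies uniform on [0.05, 0.5], a
    # realistic post-filter site-frequency range for a GWAS panel
    if spec is None:
        spec = ("uniform", 0.05, 0.5)
    if callable(spec):
        return spec
    kind, *args = spec
    if kind == "uniform":
        lo, hi = args
        return lambda rng, L: rng.uniform(lo, hi, size=L)
    if kind == "constant":
        (value,) = args
        return lambda rng, L: np.full(L, float(value))
    raise ValueError(f"unknown maf_sampler spec: {spec!r}")


def simulate_population(
    n: int,
    L: int,
    f_pheno: float,
    penetrance: float = 1.0,
    maf_sampler: MafSampler | Sequence | None = None,
    causal: bool = True,
    seed: int = 0,
) -> PopulationSim:
    """Simulate HWE genotypes with an optional fully dominant causal site.

    The causal site (placed at column ``L // 2``) segregates at allele
    frequency ``d = 1 - sqrt(1 - f_pheno)`` so that carriers — who express
    the phenotype with probability ``penetrance`` — occur at phenotype
    frequency ``f_pheno``.  Non-causal sites are independent HWE draws at
    frequencies from ``maf_sampler``.
    """
    if not 0.0 < f_pheno < 1.0:
        raise ValueError(f"phenotype frequency must be in (0, 1), got {f_pheno}")
    if n < 2 or L < 1:
        raise ValueError("need n >= 2 individuals and L >= 1 sites")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(_resolve_maf_sampler(maf_sampler)(rng, L), dtype=float)
    causal_index: int | None = None
    if causal:
        causal_index = L // 2
        freqs[causal_index] = dominant_allele_freq(f_pheno)
    genotypes = rng.binomial(2, freqs[None, :], size=(n, L)).astype(np.int8)
    if causal:
        carriers = genotypes[:, causal_index] >= 1
        phenotypes = np.zeros(n, dtype=np.int8)
        phenotypes[carriers] = rng.random(carriers.sum()) < penetrance
    else:
        # no causal site: phenotype is an independent coin at f_pheno
        phenotypes = (rng.random(n) < f_pheno).astype(np.int8)
    return PopulationSim(genotypes, phenotypes, causal_index, freqs, seed)


def simulate_reads(
    pop: PopulationSim,
    coverage: float = 0.35,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadCountSim:
    """Simulate low-coverage shotgun read counts over a population.

    Per cell the total read count is Poisson(``coverage``); each read
    reports the allele of a uniformly chosen chromosome, flipped with
    probability ``error_rate``.  Marginally each read is alternate with
    probability ``(g/2)(1 - e) + (1 - g/2)e`` for dosage ``g``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    total = rng.poisson(coverage, size=pop.genotypes.shape)
    p_alt = pop.genotypes / 2.0
    p_alt = p_alt * (1.0 - error_rate) + (1.0 - p_alt) * error_rate
    alt = rng.binomial(total, p_alt)
    return ReadCountSim(
        ref_counts=(total - alt).astype(np.int32),
        alt_counts=alt.astype(np.int32),
        coverage=coverage,
        error_rate=error_rate,
        source=pop,
        seed=seed,
    )


def _coalescent_mutations(
    n_hap: int, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """Neutral Kingman coalescent with infinite-sites mutation.

    Builds the tree by merging uniformly chosen lineage pairs at
    Exp(C(k,2)) intervals, drops Poisson(theta/2 * branch_length) mutations
    on each branch, and returns the (n_hap, S) derived-allele matrix with
    columns in arbitrary order.
    """
    # each active lineage: (accumulated branch length, descendant mask)
    lengths = np.zeros(n_hap)
    masks = [np.eye(n_hap, dtype=bool)[i] for i in range(n_hap)]
    columns: list[np.ndarray] = []

    def shed(i: int) -> None:
        n_mut = rng.poisson(theta / 2.0 * lengths[i])
        columns.extend(masks[i] for _ in range(n_mut))

    k = n_hap
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        lengths[:k] += t
        i, j = rng.choice(k, size=2, replace=False)
        shed(i)
        shed(j)
        merged = masks[i] | masks[j]
        keep = [x for x in range(k) if x not in (i, j)]
        lengths[: k - 2] = lengths[keep]
        lengths[k - 2] = 0.0
        masks = [masks[x] for x in keep] + [merged]
        k -= 1
    if not columns:
        return np.zeros((n_hap, 0), dtype=np.int8)
    return np.array(columns, dtype=np.int8).T


def _place_positions(
    n_mut: int, length_bp: int, window_start: int, rng: np.random.Generator
) -> np.ndarray:
    if n_mut > length_bp:
        raise ValueError(
            f"{n_mut} segregating sites cannot fit in {length_bp} bp "
            "(infinite-sites on a finite grid)"
        )
    pos = rng.choice(length_bp, size=n_mut, replace=False) + window_start
    return np.sort(pos)


def simulate_neutral_window(
    n_hap: int,
    theta: float,
    length_bp: int = 8800,
    window_start: int = 1,
    seed: int = 0,
) -> HaplotypeWindow:
    """Simulate one neutral single-population coalescent window.

    ``theta`` is the window-wide population mutation rate (4*Ne*mu*L);
    the expected number of segregating sites is ``theta * sum_{i<n} 1/i``.
    Mutation positions are uniform without replacement on the window.
    """
    if n_hap < 2:
        raise ValueError("need at least 2 haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    rng = np.random.default_rng(seed)
    alleles = _coalescent_mutations(n_hap, theta, rng)
    positions = _place_positions(alleles.shape[1], length_bp, window_start, rng)
    return HaplotypeWindow(
        alleles=alleles,
        positions=positions,
        window_start=window_start,
        window_length=length_bp,
        n_monomorphic_covered=length_bp - alleles.shape[1],
        seed=seed,
    )


def simulate_balanced_window(
    n_hap: int,
    tf: float = 0.3,
    theta_within: float = 5.0,
    t_split: float = 5.0,
    length_bp: int = 8800,
    window_start: int = 1,
    seed: int = 0,
) -> HaplotypeWindow:
    """Simulate a window containing an old balanced polymorphism.

    Haplotypes are split into two allelic classes with expected frequencies
    ``tf`` and ``1 - tf``; each class receives an independent within-class
    coalescent (``theta_within``), and Poisson(``theta_within * t_split``)
    class-diagnostic mutations accumulate on the internal branch separating
    them.  This structural emulation produces the signature of long-term
    balancing selection — elevated diversity and intermediate-frequency
    variants — without simulating selection dynamically.  ``t_split = 0``
    degenerates to :func:`simulate_neutral_window`.
    """
    if not 0.0 < tf < 1.0:
        raise ValueError("target frequency tf must be in (0, 1)")
    if t_split == 0:
        return simulate_neutral_window(
            n_hap, theta_within, length_bp, window_start, seed
        )
    rng = np.random.default_rng(seed)
    while True:  # resample until both classes have >= 1 haplotype
        n_a = rng.binomial(n_hap, tf)
        if 1 <= n_a <= n_hap - 1:
            break
    n_b = n_hap - n_a
    blocks: list[np.ndarray] = []
    # class-diagnostic mutations from the internal divergence branch
    n_div = rng.poisson(theta_within * t_split)
    div = np.zeros((n_hap, n_div), dtype=np.int8)
    div[:n_a, :] = 1
    blocks.append(div)
    for size, rows in ((n_a, slice(0, n_a)), (n_b, slice(n_a, n_hap))):
        if size >= 2:
            theta_cls = theta_within * size / n_hap
            within = _coalescent_mutations(size, theta_cls, rng)
            block = np.zeros((n_hap, within.shape[1]), dtype=np.int8)
            block[rows, :] = within
            blocks.append(block)
    alleles = np.concatenate(blocks, axis=1)
    # shuffle haplotype order so class membership is not positional
    alleles = alleles[rng.permutation(n_hap), :]
    positions = _place_positions(alleles.shape[1], length_bp, window_start, rng)
    order = rng.permutation(alleles.shape[1])
    alleles = alleles[:, order]
    window = HaplotypeWindow(
        alleles=alleles,
        positions=positions,
        window_start=window_start,
        window_length=length_bp,
        n_monomorphic_covered=length_bp - alleles.shape[1],
        seed=seed,
    )
    window.balanced_class_size = n_a  # minor/major split actually drawn
    return window


def simulate_trials(
    n: int,
    effect: float,
    sd: float,
    group_label: str = "",
    seed: int = 0,
) -> TrialDataset:
    """Draw per-female preference differences, Normal(effect, sd) truncated
    to [-1, 1] (differences of proportions cannot leave that interval)."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    from scipy.stats import truncnorm

    a, b = (-1.0 - effect) / sd, (1.0 - effect) / sd
    rng = np.random.default_rng(seed)
    diffs = truncnorm.rvs(a, b, loc=effect, scale=sd, size=n, random_state=rng)
    return TrialDataset(diffs=diffs, group_label=group_label, seed=seed)
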