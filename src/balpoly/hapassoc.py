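"""Haplotype-phenotype association statistics and diagnostic-SNP filtering.

Small-sample exact tests connecting a structural haplotype with a binary
phenotype, the probability calculation for observing only heterozygous
carriers in a small sample of phenotype-positive individuals under HWE
with complete dominance, and the fixed-difference filter used to nominate
diagnostic SNPs from aligned haplotype groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "HaplotypeGroupAlignment",
    "fisher_exact",
    "prob_all_het",
    "diagnostic_snps",
    "two_prop_z",
]

BASES = frozenset("ACGT")


@dataclass
class ContingencyTable2x2:
    """Counts with rows = phenotype classes and columns = haplotype states."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("all cell counts must be non-negative")
        if sum(cells) < 1:
            raise ValueError("grand total must be at least 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class HaplotypeGroupAlignment:
    """Two groups of aligned haplotype sequences plus indel coordinates.

    Sequences are over {A, C, G, T, -, N}; all must share one length and
    ``indel_positions`` are 1-based coordinates within that length.
    """

    group_a: list[str]
    group_b: list[str]
    indel_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both haplotype groups must be non-empty")
        lengths = {len(s) for s in self.group_a} | {len(s) for s in self.group_b}
        if len(lengths) != 1:
            raise ValueError("all sequences must have equal (aligned) length")
        self.length = lengths.pop()
        if self.length == 0:
            raise ValueError("zero-length alignment")
        self.group_a = [s.upper() for s in self.group_a]
        self.group_b = [s.upper() for s in self.group_b]
        self.indel_positions = frozenset(int(p) for p in self.indel_positions)
        if any(p < 1 or p > self.length for p in self.indel_positions):
            raise ValueError("indel positions must fall within the alignment")


def fisher_exact(
    table: ContingencyTable2x2 | np.ndarray, sided: str = "two"
) -> float:
    """Fisher's exact test p-value for a 2x2 table.

    One-sided: hypergeometric tail toward enrichment of cell ``a``
    (alternative 'greater').  Two-sided: the sum of point probabilities of
    all tables with the observed margins no more probable than the
    observed one (the dominant statistical-software convention, with
    relative tolerance 1 + 1e-7).
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table)
    alternative = {"one": "greater", "two": "two-sided"}.get(sided)
    if alternative is None:
        raise ValueError("sided must be 'one' or 'two'")
    return float(sps.fisher_exact(arr, alternative=alternative).pvalue)


def prob_all_het(
    f_pheno: float,
    n_sampled: int,
    method: str = "analytic",
    n_reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Probability that ``n_sampled`` phenotype-positive individuals are all
    heterozygous at a fully dominant locus under HWE.

    With allele frequency ``d = 1 - sqrt(1 - f_pheno)``, a carrier is
    heterozygous with probability ``2 d (1 - d) / f_pheno``; the analytic
    answer is that probability to the ``n_sampled``-th power.  The
    simulation draws genotypes from HWE, rejects non-carriers, and tallies
    all-heterozygote samples across ``n_reps`` replicates.
    """
    if n_sampled < 0:
        raise ValueError("n_sampled must be non-negative")
    if n_sampled == 0:
        return 1.0
    if not 0.0 < f_pheno < 1.0:
        if f_pheno == 1.0:
            return 0.0  # every carrier is homozygous when d = 1
        raise ValueError("phenotype frequency must be in (0, 1)")
    d = 1.0 - math.sqrt(1.0 - f_pheno)
    p_het = 2.0 * d * (1.0 - d) / f_pheno
    if method == "analytic":
        return p_het**n_sampled
    if method != "simulation":
        raise ValueError("method must be 'analytic' or 'simulation'")
    rng = np.random.default_rng(seed)
    needed = n_reps * n_sampled
    carriers = np.empty(0, dtype=np.int64)
    # rejection-sample carrier genotypes from HWE dosage draws
    while carriers.size < needed:
        batch = max(1024, int(1.5 * (needed - carriers.size) / f_pheno))
        dosages = rng.binomial(2, d, size=batch)
        carriers = np.concatenate([carriers, dosages[dosages >= 1]])
    samples = carriers[:needed].reshape(n_reps, n_sampled)
    return float(np.mean(np.all(samples == 1, axis=1)))


def diagnostic_snps(
    alns: HaplotypeGroupAlignment, indel_buffer_bp: int = 5
) -> list[int]:
    """Positions (1-based) of fixed nucleotide differences between groups.

    A position qualifies when group A is fixed for one base, group B fixed
    for a different base, no sequence carries a gap or N there, and its
    distance to every indel position exceeds ``indel_buffer_bp``.
    """
    out: list[int] = []
    for pos in range(1, alns.length + 1):
        i = pos - 1
        a_chars = {s[i] for s in alns.group_a}
        b_chars = {s[i] for s in alns.group_b}
        if len(a_chars) != 1 or len(b_chars) != 1:
            continue
        a_base, b_base = a_chars.pop(), b_chars.pop()
        if a_base not in BASES or b_base not in BASES or a_base == b_base:
            continue
        if any(abs(pos - q) <= indel_buffer_bp for q in alns.indel_positions):
            continue
        out.append(pos)
    return out


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-proportion z test with pooled variance; two-sided normal p.

    Degenerate pooled proportion (0 or 1, i.e. no variation) returns
    ``(0.0, 1.0)``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be at least 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie within their sample sizes")
    p_pool = (x1 + x2) / (n1 + n2)
    if p_pool in (0.0, 1.0):
        return 0.0, 1.0
    se = math.sqrt(p_pool * (1.0 - p_pool) * (1.0 / n1 + 1.0 / n2))
    z = (x1 / n1 - x2 / n2) / se
    return z, float(2.0 * sps.norm.sf(abs(z)))
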