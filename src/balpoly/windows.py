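"""Haplotype window container and minimal VCF round-trip.

A :class:`HaplotypeWindow` holds a biallelic haplotype matrix over a genomic
interval together with the count of covered invariant sites, which the
missing-data-aware diversity estimators need for their denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class HaplotypeWindow:
    """Biallelic haplotypes over a genomic interval.

    Parameters
    ----------
    alleles
        ``(n_haplotypes, n_sites)`` integer matrix over {0, 1, -1};
        -1 marks a missing call.
    positions
        1-based coordinates of the variant columns, strictly increasing,
        all inside ``[window_start, window_start + window_length)``.
    window_start, window_length
        Interval the window tiles, in base pairs.
    n_monomorphic_covered
        Number of invariant sites with calls in the interval.  These
        contribute zero differences but full pair counts to pi.
    """

    alleles: np.ndarray
    positions: np.ndarray
    window_start: int = 1
    window_length: int = 8800
    n_monomorphic_covered: int = 0
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions length must match number of sites")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        lo, hi = self.window_start, self.window_start + self.window_length
        if self.positions.size and (
            self.positions[0] < lo or self.positions[-1] >= hi
        ):
            raise ValueError("positions fall outside the window interval")
        if not np.isin(self.alleles, (0, 1, MISSING)).all():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]


def write_vcf(window: HaplotypeWindow, path: str, chrom: str = "2") -> None:
    """Write a window as a minimal VCF 4.2 with pseudo-diploid phased GT.

    Consecutive haplotype pairs become one diploid sample; ``n_haplotypes``
    must therefore be even.  Missing alleles are written as ``.``.
    """
    n_hap = window.n_haplotypes
    if n_hap % 2:
        raise ValueError("pseudo-diploid VCF output needs an even haplotype count")
    n_ind = n_hap // 2
    samples = [f"ind{i}" for i in range(n_ind)]
    contig_len = window.window_start + window.window_length - 1
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={contig_len}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    code = {0: "0", 1: "1", MISSING: "."}
    for j, pos in enumerate(window.positions):
        col = window.alleles[:, j]
        gts = [
            f"{code[int(col[2 * i])]}|{code[int(col[2 * i + 1])]}"
            for i in range(n_ind)
        ]
        lines.append(
            f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
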