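"""Windowed balancing-selection statistics.

Computes nucleotide diversity (pi, ratio-of-sums with invariant sites in
the denominator), Tajima's D, and the non-central deviation statistic NCD1
over non-overlapping windows of a chromosome, with empirical quantile
ranking and recombination-matched null window filtering.

Conventions
-----------
* pi handles missing data per site: a site with ``m`` non-missing alleles
  and derived count ``k`` contributes ``k (m - k)`` differences and
  ``C(m, 2)`` comparable pairs; invariant covered sites contribute zero
  differences and full pair counts.
* Tajima's D uses only sites genotyped in all haplotypes; it is undefined
  (NaN) when no site segregates.
* NCD1(tf) is the root-mean-square deviation of SNP minor-allele
  frequencies from the target frequency ``tf``; small values indicate
  frequencies clustered near ``tf``, the footprint of long-term balancing
  selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .windows import MISSING, HaplotypeWindow

__all__ = [
    "WindowStats",
    "pi_window",
    "tajimas_d",
    "ncd1",
    "scan",
    "rank_windows",
    "empirical_quantile",
    "recomb_matched",
    "read_recombination_map",
]


@dataclass
class WindowStats:
    chrom: str
    start: int  # 1-based
    length_bp: int
    pi: float
    tajimas_d: float
    ncd1: float
    n_snps: int
    quantile_pi: float = math.nan
    quantile_d: float = math.nan
    quantile_ncd1: float = math.nan


def _site_counts(window: HaplotypeWindow):
    """Per-site non-missing sample size m and derived-allele count k."""
    obs = window.alleles != MISSING
    m = obs.sum(axis=0)
    k = np.where(obs, window.alleles, 0).sum(axis=0)
    return m, k


def pi_window(window: HaplotypeWindow, per_bp: bool = False) -> float:
    """Nucleotide diversity by the ratio-of-sums estimator.

    pi = sum_sites(differing pairs among non-missing alleles) /
    sum_sites(comparable pairs), where the sums run over variant columns
    plus ``n_monomorphic_covered`` invariant sites assumed fully covered.
    With ``per_bp=True`` the sum of per-site diversities is divided by the
    window length instead (sites without calls contribute nothing).
    Returns NaN when no comparable pair exists.
    """
    m, k = _site_counts(window)
    diffs = k * (m - k)
    pairs = m * (m - 1) // 2
    n = window.n_haplotypes
    full_pairs = n * (n - 1) // 2
    if per_bp:
        with np.errstate(invalid="ignore", divide="ignore"):
            per_site = np.where(pairs > 0, diffs / np.maximum(pairs, 1), 0.0)
        return float(per_site.sum() / window.window_length)
    denom = int(pairs.sum()) + window.n_monomorphic_covered * full_pairs
    if denom == 0:
        return math.nan
    return float(diffs.sum() / denom)


def _tajima_constants(n: int) -> tuple[float, float]:
    """(a1, e1, e2) -> returns (e1, e2) with a1 also needed; see below."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(window: HaplotypeWindow) -> float:
    """Tajima's D over sites genotyped in all haplotypes.

    D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S - 1)) with the 1989
    normalizing constants; pi_sum is the mean pairwise-difference count
    over segregating sites.  NaN when S = 0 or n < 4.
    """
    n = window.n_haplotypes
    if n < 4:
        return math.nan
    complete = (window.alleles != MISSING).all(axis=0)
    cols = window.alleles[:, complete]
    k = cols.sum(axis=0)
    seg = (k > 0) & (k < n)
    k = k[seg]
    S = int(seg.sum())
    if S == 0:
        return math.nan
    pairs = n * (n - 1) / 2.0
    pi_sum = float(np.sum(k * (n - k)) / pairs)
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - S / a1) / math.sqrt(var))


def ncd1(window: HaplotypeWindow, tf: float = 0.3) -> float:
    """Non-central deviation statistic over within-window SNPs.

    NCD1 = sqrt( mean_i (MAF_i - tf)^2 ) over segregating sites' minor
    allele frequencies (computed over non-missing calls).  NaN when the
    window has no SNP.
    """
    if not 0.0 < tf < 1.0:
        raise ValueError("target frequency must be in (0, 1)")
    m, k = _site_counts(window)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(m > 0, k / np.maximum(m, 1), np.nan)
    seg = (k > 0) & (k < m)
    if not seg.any():
        return math.nan
    maf = np.minimum(freq[seg], 1.0 - freq[seg])
    return float(np.sqrt(np.mean((maf - tf) ** 2)))


def empirical_quantile(focal: float, all_values, tail: str = "upper") -> float:
    """Empirical tail quantile of ``focal`` among ``all_values``.

    ``upper``: fraction of values >= focal; ``lower``: fraction <= focal.
    Ties (including the focal value itself when present) count toward the
    tail, so "top X%" statements are conservative.  NaN values are ignored.
    """
    vals = np.asarray(all_values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("all_values must contain at least one finite value")
    if not math.isfinite(focal):
        raise ValueError("focal value must be finite")
    if tail == "upper":
        return float(np.count_nonzero(vals >= focal) / vals.size)
    if tail == "lower":
        return float(np.count_nonzero(vals <= focal) / vals.size)
    raise ValueError("tail must be 'upper' or 'lower'")


def _windows_from_vcf(
    vcf_path: str,
    chrom: str,
    window_bp: int,
    assume_invariant_covered: bool,
    chrom_length: int | None,
):
    """Read diploid GTs from a VCF and tile them into HaplotypeWindows."""
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    positions: list[int] = []
    columns: list[np.ndarray] = []
    invariant_positions: list[int] = []
    try:
        length = chrom_length
        if length is None:
            try:
                length = dict(zip(vcf.seqnames, vcf.seqlens)).get(chrom)
            except AttributeError:
                length = None
        for rec in vcf:
            if rec.CHROM != chrom:
                continue
            gts = rec.genotypes  # [allele_a, allele_b, phased] per sample
            col = np.empty(2 * len(gts), dtype=np.int8)
            for i, g in enumerate(gts):
                col[2 * i] = MISSING if g[0] < 0 else g[0]
                col[2 * i + 1] = MISSING if g[1] < 0 else g[1]
            if not rec.ALT or np.all(col[col != MISSING] == 0):
                invariant_positions.append(rec.POS)
                continue
            if col.max() > 1:
                raise ValueError(
                    f"multi-allelic record at {chrom}:{rec.POS}; "
                    "only biallelic sites are supported"
                )
            positions.append(rec.POS)
            columns.append(col)
    finally:
        vcf.close()
    if length is None:
        length = max(positions) if positions else window_bp
    pos = np.asarray(positions, dtype=np.int64)
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    mat = (
        np.array([columns[i] for i in order], dtype=np.int8).T
        if columns
        else np.zeros((0, 0), dtype=np.int8)
    )
    inv_pos = np.asarray(invariant_positions, dtype=np.int64)
    windows = []
    for start in range(1, int(length) + 1, window_bp):
        in_win = (pos >= start) & (pos < start + window_bp)
        sub = mat[:, in_win] if mat.size else np.zeros((mat.shape[0], 0), np.int8)
        n_var = int(in_win.sum())
        if assume_invariant_covered:
            n_mono = window_bp - n_var
        else:
            # only positions with an explicit invariant record count as covered
            n_mono = int(np.count_nonzero((inv_pos >= start) & (inv_pos < start + window_bp)))
        windows.append(
            HaplotypeWindow(
                alleles=sub,
                positions=pos[in_win],
                window_start=start,
                window_length=window_bp,
                n_monomorphic_covered=n_mono,
            )
        )
    return windows


def scan(
    vcf_path: str,
    chrom: str,
    window_bp: int = 8800,
    tf: float = 0.3,
    assume_invariant_covered: bool = True,
    chrom_length: int | None = None,
) -> list[WindowStats]:
    """Compute pi, Tajima's D and NCD1 in non-overlapping tiled windows.

    Windows are half-open ``[start, start + window_bp)`` tiled from
    coordinate 1.  Diploid genotypes are split into two pseudo-haplotypes
    per individual, ignoring phase (all three statistics are phase-free).
    ``assume_invariant_covered`` declares positions without a VCF record
    as covered invariant sites for the pi denominator; otherwise only
    variant columns contribute.
    """
    windows = _windows_from_vcf(
        vcf_path, chrom, window_bp, assume_invariant_covered, chrom_length
    )
    out = []
    for w in windows:
        m, k = _site_counts(w)
        n_snps = int(np.count_nonzero((k > 0) & (k < m)))
        out.append(
            WindowStats(
                chrom=chrom,
                start=w.window_start,
                length_bp=window_bp,
                pi=pi_window(w),
                tajimas_d=tajimas_d(w),
                ncd1=ncd1(w, tf=tf),
                n_snps=n_snps,
            )
        )
    return rank_windows(out)


def rank_windows(stats: list[WindowStats]) -> list[WindowStats]:
    """Fill empirical quantile ranks in place: pi and Tajima's D are ranked
    in the upper tail (balancing selection elevates them), NCD1 in the
    lower tail (it shrinks toward 0 near a balanced locus)."""
    pis = np.array([s.pi for s in stats])
    ds = np.array([s.tajimas_d for s in stats])
    ncds = np.array([s.ncd1 for s in stats])
    for s in stats:
        if math.isfinite(s.pi):
            s.quantile_pi = empirical_quantile(s.pi, pis, "upper")
        if math.isfinite(s.tajimas_d):
            s.quantile_d = empirical_quantile(s.tajimas_d, ds, "upper")
        if math.isfinite(s.ncd1):
            s.quantile_ncd1 = empirical_quantile(s.ncd1, ncds, "lower")
    return stats


def recomb_matched(
    stats: list[WindowStats],
    rho_per_bp,
    quantile_cut: float = 0.08,
) -> list[WindowStats]:
    """Restrict a scan to low-recombination windows.

    Retains windows whose recombination rate is <= the ``quantile_cut``
    empirical (inverse-ECDF) quantile of all windows' rates; ties at the
    cutoff are included.  ``rho_per_bp`` must align 1:1 with ``stats``.
    """
    rho = np.asarray(rho_per_bp, dtype=float)
    if rho.shape[0] != len(stats):
        raise ValueError(
            f"recombination map has {rho.shape[0]} windows, scan has {len(stats)}"
        )
    if not 0.0 < quantile_cut <= 1.0:
        raise ValueError("quantile_cut must be in (0, 1]")
    cutoff = np.quantile(rho, quantile_cut, method="inverted_cdf")
    return [s for s, r in zip(stats, rho) if r <= cutoff]


def read_recombination_map(path: str) -> "pandas.DataFrame":
    """Read a per-window recombination map TSV with columns
    chrom, window_start, rho_per_bp."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "window_start", "rho_per_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"recombination map needs columns {sorted(required)}")
    return df
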