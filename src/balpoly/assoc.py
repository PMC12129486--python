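"""Case-control association on low-coverage allele read counts.

The association statistic is a binomial likelihood-ratio test on allele
counts pooled within phenotype class at each site: under H0 both classes
share one allele frequency, under H1 each class has its own ML frequency;
2 * (l1 - l0) is referred to chi-square with 1 df.  Genome-wide
significance is calibrated by permuting phenotypes and taking the lower
tail of the distribution of per-permutation minimum p-values (family-wise
error control without a distributional model of the genome).

Structure correction follows the pseudo-haploid route: one read sampled
per site per individual gives an unbiased (if noisy) call matrix on which
PCA is run; per-site logistic regressions with leading PCs as covariates
give structure-adjusted p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AlleleCountMatrix",
    "GwasResult",
    "PseudoHaploidCalls",
    "site_lrt",
    "run_gwas",
    "permutation_threshold",
    "gwas_with_threshold",
    "pseudo_haploid",
    "filter_calls",
    "covariate_association",
    "pairwise_r2",
]

CALL_MISSING = -1


@dataclass
class AlleleCountMatrix:
    """Per-site, per-individual reference/alternate read counts."""

    ref_counts: np.ndarray  # (n_individuals, n_sites)
    alt_counts: np.ndarray
    chrom: np.ndarray | None = None  # per-site chromosome labels
    pos: np.ndarray | None = None  # per-site 1-based positions
    min_mapq_note: str = ""

    def __post_init__(self) -> None:
        self.ref_counts = np.asarray(self.ref_counts)
        self.alt_counts = np.asarray(self.alt_counts)
        if self.ref_counts.shape != self.alt_counts.shape:
            raise ValueError("ref and alt count matrices must have equal shape")
        if (self.ref_counts < 0).any() or (self.alt_counts < 0).any():
            raise ValueError("read counts must be non-negative")
        if self.pos is None:
            self.pos = np.arange(1, self.n_sites + 1, dtype=np.int64)
        else:
            self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.chrom is None:
            self.chrom = np.full(self.n_sites, "1", dtype=object)
        else:
            self.chrom = np.asarray(self.chrom, dtype=object)

    @property
    def n_individuals(self) -> int:
        return self.ref_counts.shape[0]

    @property
    def n_sites(self) -> int:
        return self.ref_counts.shape[1]

    @classmethod
    def from_read_sim(cls, sim) -> "AlleleCountMatrix":
        return cls(ref_counts=sim.ref_counts, alt_counts=sim.alt_counts)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: chrom, pos, individual, ref_count, alt_count."""
        n, L = self.ref_counts.shape
        return pd.DataFrame(
            {
                "chrom": np.repeat(self.chrom, n),
                "pos": np.repeat(self.pos, n),
                "individual": np.tile(np.arange(n), L),
                "ref_count": self.ref_counts.T.ravel(),
                "alt_count": self.alt_counts.T.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AlleleCountMatrix":
        df = df.sort_values(["chrom", "pos", "individual"], kind="stable")
        sites = df[["chrom", "pos"]].drop_duplicates()
        inds = np.sort(df["individual"].unique())
        n, L = len(inds), len(sites)
        ref = df["ref_count"].to_numpy().reshape(L, n).T
        alt = df["alt_count"].to_numpy().reshape(L, n).T
        return cls(
            ref_counts=ref,
            alt_counts=alt,
            chrom=sites["chrom"].to_numpy(),
            pos=sites["pos"].to_numpy(),
        )


@dataclass
class GwasResult:
    """Per-site LRT p-values with an optional permutation threshold."""

    p_values: np.ndarray  # NaN = site not testable
    lrt_stats: np.ndarray
    threshold: float = math.nan
    n_permutations: int = 0
    perm_min_p: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_tested(self) -> int:
        return int(np.count_nonzero(~np.isnan(self.p_values)))

    def significant(self) -> np.ndarray:
        """Indices of sites at or below the permutation threshold (ties at
        the threshold are declared significant)."""
        with np.errstate(invalid="ignore"):
            return np.flatnonzero(self.p_values <= self.threshold)


@dataclass
class PseudoHaploidCalls:
    """One randomly sampled read per cell: 0 = ref, 1 = alt, -1 = missing."""

    calls: np.ndarray
    seed: int
    site_index: np.ndarray | None = None  # original columns after filtering

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]


def _binom_loglik(alt, tot):
    """Binomial log-likelihood at the ML frequency, dropping the constant
    binomial coefficient (cancels in the LRT)."""
    alt = np.asarray(alt, dtype=float)
    tot = np.asarray(tot, dtype=float)
    ref = tot - alt
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), 0.0)
        ll = np.where(alt > 0, alt * np.log(np.maximum(p, 1e-300)), 0.0)
        ll += np.where(ref > 0, ref * np.log(np.maximum(1 - p, 1e-300)), 0.0)
    return ll


def _lrt_arrays(case_ref, case_alt, ctrl_ref, ctrl_alt, williams=False):
    case_ref = np.asarray(case_ref, dtype=float)
    case_alt = np.asarray(case_alt, dtype=float)
    ctrl_ref = np.asarray(ctrl_ref, dtype=float)
    ctrl_alt = np.asarray(ctrl_alt, dtype=float)
    case_tot = case_ref + case_alt
    ctrl_tot = ctrl_ref + ctrl_alt
    pool_alt = case_alt + ctrl_alt
    pool_tot = case_tot + ctrl_tot
    stat = 2.0 * (
        _binom_loglik(case_alt, case_tot)
        + _binom_loglik(ctrl_alt, ctrl_tot)
        - _binom_loglik(pool_alt, pool_tot)
    )
    stat = np.maximum(stat, 0.0)  # guard tiny negative round-off
    if williams:
        # Williams' small-sample correction for the 2x2 G-test
        pool_ref = case_ref + ctrl_ref
        with np.errstate(all="ignore"):
            q = 1.0 + (
                (pool_tot / case_tot + pool_tot / ctrl_tot - 1.0)
                * (pool_tot / pool_ref + pool_tot / pool_alt - 1.0)
            ) / (6.0 * pool_tot)
        stat = np.where(np.isfinite(q) & (q > 0), stat / q, stat)
    p = sps.chi2.sf(stat, df=1)
    # untestable: no reads in a class, or pooled-monomorphic site
    bad = (case_tot == 0) | (ctrl_tot == 0) | (pool_alt == 0) | (pool_alt == pool_tot)
    stat = np.where(bad, np.nan, stat)
    p = np.where(bad, np.nan, p)
    return stat, p


def site_lrt(
    case_ref: int, case_alt: int, ctrl_ref: int, ctrl_alt: int
) -> tuple[float, float]:
    """Binomial likelihood-ratio test of equal allele frequency in the two
    phenotype classes at one site.

    Returns ``(statistic, p)``; the statistic is 0 and p is 1 when the ML
    frequencies coincide.  Raises if either class has no reads.
    """
    if case_ref + case_alt == 0 or ctrl_ref + ctrl_alt == 0:
        raise ValueError("each phenotype class needs at least one read")
    case_tot = case_ref + case_alt
    ctrl_tot = ctrl_ref + ctrl_alt
    stat = 2.0 * float(
        _binom_loglik(case_alt, case_tot)
        + _binom_loglik(ctrl_alt, ctrl_tot)
        - _binom_loglik(case_alt + ctrl_alt, case_tot + ctrl_tot)
    )
    stat = max(stat, 0.0)
    return stat, float(sps.chi2.sf(stat, df=1))


def run_gwas(
    counts: AlleleCountMatrix,
    phenotypes,
    effective_counts: bool = True,
    williams: bool = True,
) -> GwasResult:
    """Per-site binomial LRT with reads pooled within phenotype class.

    Reads from one individual share a genotype, so raw pooled read counts
    are overdispersed relative to binomial sampling: a cell with ``t``
    reads carries the information of only ``2t / (t + 1)`` independent
    allele draws (variance matching; infinitely many reads resolve just
    the two chromosomes).  With ``effective_counts`` each cell's reads are
    weighted accordingly before pooling, and ``williams`` applies the
    Williams small-sample correction to the resulting G statistic; both
    are needed for calibrated p-values at shallow coverage and are on by
    default.

    Sites with no reads in either class, or monomorphic in the pooled
    reads, are flagged with NaN p-values.
    """
    phen = np.asarray(phenotypes).astype(int)
    if phen.shape[0] != counts.n_individuals:
        raise ValueError("phenotype length must match number of individuals")
    if not (np.any(phen == 1) and np.any(phen == 0)):
        raise ValueError("both phenotype classes must be non-empty")
    ref, alt = _weighted_counts(counts, effective_counts)
    stat, p = _pooled_lrt(ref, alt, phen, williams)
    return GwasResult(p_values=p, lrt_stats=stat)


def _weighted_counts(counts: AlleleCountMatrix, effective: bool):
    ref = counts.ref_counts.astype(float)
    alt = counts.alt_counts.astype(float)
    if effective:
        tot = ref + alt
        w = np.where(tot > 0, 2.0 / (tot + 1.0), 0.0)
        ref, alt = ref * w, alt * w
    return ref, alt


def _pooled_lrt(ref: np.ndarray, alt: np.ndarray, phen: np.ndarray, williams: bool):
    case = (phen == 1).astype(float)
    case_ref = case @ ref
    case_alt = case @ alt
    ctrl_ref = ref.sum(axis=0) - case_ref
    ctrl_alt = alt.sum(axis=0) - case_alt
    return _lrt_arrays(case_ref, case_alt, ctrl_ref, ctrl_alt, williams=williams)


def permutation_threshold(
    counts: AlleleCountMatrix,
    phenotypes,
    n_perm: int = 500,
    fwer: float = 0.05,
    seed: int = 0,
    return_minima: bool = False,
):
    """Permutation-calibrated genome-wide significance threshold.

    Phenotypes are shuffled uniformly without replacement ``n_perm`` times;
    for each shuffle the GWAS is re-run and the minimum p-value recorded.
    The threshold is the inverse-ECDF lower ``fwer`` quantile of those
    minima, i.e. the ``ceil(n_perm * fwer)``-th smallest.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    rng = np.random.default_rng(seed)
    phen = np.asarray(phenotypes).astype(int)
    ref, alt = _weighted_counts(counts, effective=True)
    minima = np.empty(n_perm)
    for b in range(n_perm):
        shuffled = rng.permutation(phen)
        _, p = _pooled_lrt(ref, alt, shuffled, williams=True)
        valid = p[~np.isnan(p)]
        minima[b] = valid.min() if valid.size else 1.0
    k = math.ceil(n_perm * fwer)
    threshold = float(np.sort(minima)[k - 1])
    if return_minima:
        return threshold, minima
    return threshold


def gwas_with_threshold(
    counts: AlleleCountMatrix,
    phenotypes,
    n_perm: int = 500,
    fwer: float = 0.05,
    seed: int = 0,
) -> GwasResult:
    """Run the GWAS and attach its permutation significance threshold."""
    res = run_gwas(counts, phenotypes)
    threshold, minima = permutation_threshold(
        counts, phenotypes, n_perm=n_perm, fwer=fwer, seed=seed, return_minima=True
    )
    res.threshold = threshold
    res.n_permutations = n_perm
    res.perm_min_p = minima
    return res


def pseudo_haploid(counts: AlleleCountMatrix, seed: int = 0) -> PseudoHaploidCalls:
    """Sample one read uniformly at random per cell and call its allele.

    Equivalent to a Bernoulli(alt/(ref+alt)) alternate call per covered
    cell; cells with zero reads are missing.
    """
    rng = np.random.default_rng(seed)
    tot = counts.ref_counts + counts.alt_counts
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = np.where(tot > 0, counts.alt_counts / np.maximum(tot, 1), 0.0)
    calls = (rng.random(tot.shape) < p_alt).astype(np.int8)
    calls[tot == 0] = CALL_MISSING
    return PseudoHaploidCalls(calls=calls, seed=seed)


def filter_calls(
    calls: PseudoHaploidCalls,
    maf_min: float = 0.02,
    max_missing: float = 0.75,
) -> PseudoHaploidCalls:
    """Drop sites with minor allele frequency < ``maf_min`` (over
    non-missing calls) or missing fraction >= ``max_missing``.

    Boundary semantics: a site at exactly the MAF cutoff is retained; a
    site missing in exactly ``max_missing`` of individuals is removed.
    """
    c = calls.calls
    n = c.shape[0]
    obs = c != CALL_MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs, c, 0).sum(axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(freq, 1.0 - freq)
    missing_frac = 1.0 - n_obs / n
    keep = (n_obs > 0) & (maf >= maf_min) & (missing_frac < max_missing)
    if not keep.any():
        import warnings

        warnings.warn("all sites removed by MAF/missingness filter")
    idx = np.flatnonzero(keep)
    if calls.site_index is not None:
        idx = calls.site_index[idx]
    return PseudoHaploidCalls(calls=c[:, keep], seed=calls.seed, site_index=idx)


def _pca_scores(calls: np.ndarray, n_pcs: int) -> np.ndarray:
    """PCA of the call matrix with per-site mean imputation of missing
    calls, centering, and no scaling.  Returns (n_individuals, n_pcs)."""
    x = calls.astype(float)
    x[calls == CALL_MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(x))
    x[inds] = col_mean[inds[1]]
    x -= x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_pcs, s.size)
    return u[:, :k] * s[:k]


def covariate_association(
    calls: PseudoHaploidCalls,
    phenotypes,
    n_pcs: int = 4,
) -> np.ndarray:
    """Structure-corrected per-site association on pseudo-haploid calls.

    Fits phenotype ~ call + PC1..PCn by logistic regression at each site
    (missing calls dropped site-wise) and returns the Wald p-value for the
    call coefficient.  PCA is computed once on the full call matrix.
    Sites where the fit fails (e.g. complete separation) get NaN.
    """
    import warnings

    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    phen = np.asarray(phenotypes).astype(float)
    if phen.shape[0] != calls.n_individuals:
        raise ValueError("phenotype length must match number of individuals")
    pcs = _pca_scores(calls.calls, n_pcs) if n_pcs > 0 else None
    p_out = np.full(calls.n_sites, np.nan)
    for j in range(calls.n_sites):
        col = calls.calls[:, j]
        ok = col != CALL_MISSING
        y = phen[ok]
        if y.size < 3 or len(np.unique(y)) < 2 or len(np.unique(col[ok])) < 2:
            continue
        cols = [col[ok].astype(float)]
        if pcs is not None:
            cols.append(pcs[ok])
        X = sm.add_constant(np.column_stack(cols))
        try:
            with np.errstate(all="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            p = fit.pvalues[1]
            if np.isfinite(p) and np.isfinite(fit.bse[1]) and fit.bse[1] < 1e3:
                p_out[j] = p
        except Exception:
            continue
    return p_out


def pairwise_r2(
    matrix: np.ndarray,
    focal_site: int,
    positions: np.ndarray | None = None,
    window_bp: int = 1_000_000,
) -> np.ndarray:
    """Composite LD: squared Pearson correlation of each site's dosage (or
    call) vector with the focal site's, over individuals non-missing at
    both sites.

    Missing entries are coded as negative values or NaN.  Sites outside
    ``window_bp`` of the focal position (when ``positions`` is given), and
    pairs monomorphic in the shared individuals, return NaN.
    """
    m = np.asarray(matrix, dtype=float)
    m[m < 0] = np.nan
    n_sites = m.shape[1]
    if not 0 <= focal_site < n_sites:
        raise ValueError("focal site index out of range")
    focal = m[:, focal_site]
    out = np.full(n_sites, np.nan)
    if positions is not None:
        positions = np.asarray(positions)
        in_range = np.abs(positions - positions[focal_site]) <= window_bp
    else:
        in_range = np.ones(n_sites, dtype=bool)
    for j in np.flatnonzero(in_range):
        both = ~np.isnan(focal) & ~np.isnan(m[:, j])
        if both.sum() < 2:
            continue
        x, y = focal[both], m[both, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue  # monomorphic in the shared individuals: r2 undefined
        r = np.corrcoef(x, y)[0, 1]
        out[j] = r * r
    return out
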