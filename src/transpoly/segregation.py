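"""Heterozygote excess in an AB x AB cross with a read-depth-aware null.

Finite read depth biases genotype calling against heterozygotes: a true het
sequenced to depth d is called homozygous whenever every read happens to
show the same allele (probability 2 * (1/2)^d for the transparent
both-alleles caller).  Any test for heterozygote excess in F1 offspring of a
double-heterozygote cross must therefore compare the observed genotype
frequencies and F_IS not against the naive 1:2:1 Mendelian ratio but against
a null that pushes 1:2:1 cohorts through the same depths and the same
caller.  This module provides the expected called frequencies, observed
segregation frequencies, per-gene F_IS = 1 - H_obs/H_exp, and the simulated
null F_IS distribution with the observed value's quantile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "CrossObservation",
    "FisResult",
    "ThresholdCaller",
    "LikelihoodCaller",
    "expected_segregation",
    "observed_segregation",
    "fis",
    "gene_fis",
    "fis_null",
    "hwe_genotype_expectation",
]

NO_CALL = -1  # genotype code for depth-0 / uncallable


# ---------------------------------------------------------------------------
# calling models
# ---------------------------------------------------------------------------

class GenotypeCaller(Protocol):
    def __call__(self, ref_reads: np.ndarray, alt_reads: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class ThresholdCaller:
    """Call heterozygote iff both alleles are observed at least once.

    Otherwise homozygote for the observed allele; no-call at depth 0.  The
    model is transparent and exactly enumerable, and reproduces the
    depth-driven heterozygote undercalling that the read-depth-aware null
    exists to control.
    """

    def __call__(self, ref_reads: np.ndarray, alt_reads: np.ndarray) -> np.ndarray:
        ref_reads = np.asarray(ref_reads)
        alt_reads = np.asarray(alt_reads)
        out = np.full(ref_reads.shape, NO_CALL, dtype=np.int8)
        out[(ref_reads > 0) & (alt_reads == 0)] = 0
        out[(ref_reads > 0) & (alt_reads > 0)] = 1
        out[(ref_reads == 0) & (alt_reads > 0)] = 2
        return out


@dataclass(frozen=True)
class LikelihoodCaller:
    """Maximum-binomial-likelihood caller with symmetric error rate.

    Genotype likelihoods use alt-read probabilities (error, 1/2, 1-error)
    for (hom-ref, het, hom-alt); ties resolve toward the heterozygote.
    """

    error_rate: float = 0.01

    def __call__(self, ref_reads: np.ndarray, alt_reads: np.ndarray) -> np.ndarray:
        ref_reads = np.asarray(ref_reads, dtype=float)
        alt_reads = np.asarray(alt_reads, dtype=float)
        e = min(max(self.error_rate, 1e-12), 0.5)
        probs = np.array([e, 0.5, 1 - e])
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = (
                alt_reads[..., None] * np.log(probs)
                + ref_reads[..., None] * np.log(1 - probs)
            )
        order = np.array([1, 0, 2])  # het wins ties
        out = order[np.argmax(ll[..., order], axis=-1)].astype(np.int8)
        out[(ref_reads + alt_reads) == 0] = NO_CALL
        return out


DEFAULT_CALLER = ThresholdCaller()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CrossObservation:
    """F1 genotype counts at a gene's SNPs plus per-offspring read depths.

    ``genotype_counts`` is (n_snps, 3) counts of called (AA, AB, BB);
    ``depths`` holds one integer array of per-offspring total depths per SNP.
    """

    gene_id: str
    snp_ids: list[str]
    genotype_counts: np.ndarray
    depths: list[np.ndarray]

    def __post_init__(self) -> None:
        self.genotype_counts = np.asarray(self.genotype_counts, dtype=np.int64)
        if self.genotype_counts.shape != (len(self.snp_ids), 3):
            raise ValueError("genotype_counts must be (n_snps, 3)")
        if (self.genotype_counts < 0).any():
            raise ValueError("genotype counts must be non-negative")
        if len(self.depths) != len(self.snp_ids):
            raise ValueError("one depth vector per SNP required")
        self.depths = [np.asarray(d, dtype=np.int64) for d in self.depths]


@dataclass(slots=True)
class FisResult:
    gene_id: str
    observed_fis: float
    null_fis: np.ndarray
    quantile: float

    @property
    def null_mean(self) -> float:
        return float(np.nanmean(self.null_fis))

    def null_percentile(self, q: float) -> float:
        return float(np.nanpercentile(self.null_fis, q))


# ---------------------------------------------------------------------------
# expected and observed segregation
# ---------------------------------------------------------------------------

def _simulate_reads(
    true_geno: np.ndarray, depths: np.ndarray, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-call (ref, alt) read counts given true genotypes and total depths."""
    p_alt = np.select(
        [true_geno == 0, true_geno == 1, true_geno == 2],
        [error_rate, 0.5, 1 - error_rate],
    )
    alt = rng.binomial(depths, p_alt)
    return depths - alt, alt


def expected_segregation(
    depths: Sequence[int] | np.ndarray,
    caller: GenotypeCaller = DEFAULT_CALLER,
    n_sim: int = 10_000,
    seed: int = 0,
    error_rate: float = 0.0,
    method: str = "auto",
) -> np.ndarray:
    """Expected called (AA, AB, BB) frequencies for 1:2:1 F1s at given depths.

    True F1 genotypes segregate 1:2:1; reads are drawn at each offspring's
    depth and pushed through the caller; frequencies are taken over calls
    (no-calls excluded).  For the default both-alleles caller with zero error
    an exact closed form is used (``method='exact'`` / 'auto'); otherwise
    Monte Carlo over ``n_sim`` replicate cohorts.
    """
    depths = np.asarray(depths, dtype=np.int64)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    if (depths < 0).any():
        raise ValueError("depths must be non-negative")

    exact_ok = isinstance(caller, ThresholdCaller) and error_rate == 0.0
    if method == "exact" and not exact_ok:
        raise ValueError("exact path only available for ThresholdCaller with error_rate=0")
    if method in ("exact", "auto") and exact_ok:
        d = depths[depths > 0].astype(float)
        if d.size == 0:
            raise ValueError("all depths are zero: nothing is callable")
        # true het called het w.p. 1 - 2*(1/2)^d, miscalled each homozygote w.p. (1/2)^d
        miss = 0.5**d
        f_ab = float((0.5 * (1 - 2 * miss)).mean())
        f_aa = float((0.25 + 0.5 * miss).mean())
        return np.array([f_aa, f_ab, f_aa])

    rng = np.random.default_rng(seed)
    n = len(depths)
    freqs = np.zeros(3)
    n_used = 0
    for _ in range(n_sim):
        true = rng.choice(3, size=n, p=[0.25, 0.5, 0.25])
        ref, alt = _simulate_reads(true, depths, error_rate, rng)
        called = caller(ref, alt)
        ok = called >= 0
        if not ok.any():
            continue
        counts = np.bincount(called[ok], minlength=3)
        freqs += counts / counts.sum()
        n_used += 1
    if n_used == 0:
        raise ValueError("no callable offspring in any replicate")
    return freqs / n_used


def observed_segregation(
    obs: CrossObservation, weighted: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP and gene-average (AA, AB, BB) frequencies from called counts.

    The gene average is the unweighted mean over SNPs by default;
    ``weighted=True`` pools counts across SNPs instead.
    """
    counts = obs.genotype_counts
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every SNP needs at least one called offspring")
    per_snp = counts / totals[:, None]
    gene = counts.sum(axis=0) / counts.sum() if weighted else per_snp.mean(axis=0)
    return per_snp, gene


# ---------------------------------------------------------------------------
# F_IS
# ---------------------------------------------------------------------------

def fis(n_AA: int, n_AB: int, n_BB: int) -> float:
    """F_IS = 1 - H_obs/H_exp from genotype counts (NaN if monomorphic).

    H_obs is the heterozygote fraction, H_exp = 2*p*(1-p) at the sample
    allele frequency.  Negative values indicate heterozygote excess.
    """
    n = n_AA + n_AB + n_BB
    if n <= 0:
        raise ValueError("fis needs at least one genotype")
    p = (2 * n_AA + n_AB) / (2 * n)
    h_exp = 2 * p * (1 - p)
    if h_exp == 0:
        return float("nan")
    return 1.0 - (n_AB / n) / h_exp


def gene_fis(genotype_counts: np.ndarray) -> float:
    """Gene-level F_IS: unweighted mean of per-SNP F_IS (NaN SNPs skipped)."""
    vals = np.array([fis(*row) for row in np.asarray(genotype_counts, dtype=np.int64)])
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))


def fis_null(
    obs: CrossObservation,
    caller: GenotypeCaller = DEFAULT_CALLER,
    n_sim: int = 1000,
    seed: int = 0,
    error_rate: float = 0.0,
    mode: str = "f1",
    allele_freq: float = 0.5,
) -> FisResult:
    """Simulated null distribution of gene-average F_IS at empirical depths.

    Each replicate draws a cohort of true genotypes per SNP -- 1:2:1 for
    ``mode='f1'`` (offspring of an AB x AB cross) or Hardy-Weinberg at
    ``allele_freq`` for ``mode='cohort'`` (unrelated individuals) -- pushes
    reads through the caller at the gene's empirical depths, and records the
    gene-average F_IS of the *called* genotypes.  Reported quantile is the
    fraction of null values <= the observed gene F_IS.
    """
    if mode not in ("f1", "cohort"):
        raise ValueError(f"unknown mode {mode!r}")
    p = allele_freq
    probs = (
        np.array([0.25, 0.5, 0.25])
        if mode == "f1"
        else np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    )
    rng = np.random.default_rng(seed)
    observed = gene_fis(obs.genotype_counts)
    null = np.empty(n_sim)
    for r in range(n_sim):
        counts = np.zeros((len(obs.snp_ids), 3), dtype=np.int64)
        for s, depths in enumerate(obs.depths):
            true = rng.choice(3, size=len(depths), p=probs)
            ref, alt = _simulate_reads(true, depths, error_rate, rng)
            called = caller(ref, alt)
            counts[s] = np.bincount(called[called >= 0], minlength=3)[:3]
        null[r] = gene_fis(counts)
    quant = float(np.nanmean(null <= observed)) if np.isfinite(observed) else float("nan")
    return FisResult(
        gene_id=obs.gene_id, observed_fis=observed, null_fis=null, quantile=quant
    )


def hwe_genotype_expectation(freqs: Sequence[float]) -> np.ndarray:
    """HWE genotype frequencies at the same allele frequency as the input."""
    f = np.asarray(freqs, dtype=float)
    if f.shape != (3,) or (f < 0).any() or not np.isclose(f.sum(), 1.0):
        raise ValueError("freqs must be a genotype frequency triple summing to 1")
    p = f[0] + f[1] / 2
    return np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
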