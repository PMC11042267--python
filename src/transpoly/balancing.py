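"""Balancing-selection statistics: alpha_b and the folded beta(1) window scan.

alpha_b contrasts the non-synonymous/synonymous composition of shared
polymorphisms against that of within-species-only polymorphisms, in the
spirit of a McDonald-Kreitman odds ratio:

    alpha_b = 1 - (Poly_NS * SP_SYN) / (Poly_SYN * SP_NS) = 1 - 1/OR

with OR = (SP_NS/SP_SYN) / (Poly_NS/Poly_SYN).  It is positive exactly when
shared polymorphisms are NS-enriched relative to non-shared ones, and is
interpreted as the proportion of non-synonymous shared polymorphisms
attributable to balancing selection.  Confidence intervals come from a
gene-level bootstrap (genes, not SNPs, are the resampling unit, to respect
linkage).

beta(1) is a folded-spectrum statistic for balancing selection: around a
core SNP it contrasts a mutation-scale estimator that up-weights window SNPs
whose folded frequency resembles the core's (theta_beta) against Watterson's
theta on the same window.  Linked variants accumulated at the balanced
equilibrium frequency push theta_beta above theta_W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenotypeMatrix, SiteClassTable

logger = logging.getLogger("transpoly")

__all__ = [
    "AlphaBTable",
    "AlphaBResult",
    "BootstrapResult",
    "alpha_b",
    "alpha_b_bootstrap",
    "BetaWindow",
    "beta1_folded",
    "beta1_scan",
]


# ---------------------------------------------------------------------------
# alpha_b
# ---------------------------------------------------------------------------

@dataclass
class AlphaBTable:
    """Counts of SYN/NS polymorphisms, split non-shared ("poly") vs shared ("sp").

    ``per_gene`` optionally holds the same four counts per gene
    (columns gene_id, poly_syn, poly_ns, sp_syn, sp_ns) for bootstrapping.
    """

    poly_syn: int
    poly_ns: int
    sp_syn: int
    sp_ns: int
    per_gene: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if min(self.poly_syn, self.poly_ns, self.sp_syn, self.sp_ns) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_site_classes(cls, classes: SiteClassTable) -> "AlphaBTable":
        """Build the table from a classification: shared vs private SYN/NS SNPs.

        Within-species ("Poly") and shared ("SP") categories are disjoint:
        private_A and private_B sites are the non-shared polymorphisms.
        """
        df = classes.frame
        shared = df["label"] == "shared_poly"
        poly = df["label"].isin(["private_A", "private_B"])
        syn = df["annotation"] == "SYN"
        ns = df["annotation"] == "NS"
        per_gene = None
        if df["gene_id"].notna().any():
            per_gene = (
                pd.DataFrame(
                    {
                        "gene_id": df["gene_id"],
                        "poly_syn": (poly & syn).astype(int),
                        "poly_ns": (poly & ns).astype(int),
                        "sp_syn": (shared & syn).astype(int),
                        "sp_ns": (shared & ns).astype(int),
                    }
                )
                .groupby("gene_id", dropna=True)
                .sum()
                .reset_index()
            )
        return cls(
            poly_syn=int((poly & syn).sum()),
            poly_ns=int((poly & ns).sum()),
            sp_syn=int((shared & syn).sum()),
            sp_ns=int((shared & ns).sum()),
            per_gene=per_gene,
        )


@dataclass(slots=True)
class AlphaBResult:
    value: float
    poly_ns_syn_ratio: float
    sp_ns_syn_ratio: float


def alpha_b(
    table: AlphaBTable, positive_when_shared_ns_enriched: bool = True
) -> AlphaBResult:
    """alpha_b = 1 - (poly_ns * sp_syn) / (poly_syn * sp_ns).

    Positive when shared polymorphisms are NS-enriched relative to non-shared
    ones.  The orientation flag flips the odds ratio for audit purposes.
    """
    if table.poly_syn == 0 or table.sp_ns == 0:
        raise ValueError(
            "alpha_b undefined: needs poly_syn > 0 and sp_ns > 0 "
            f"(got poly_syn={table.poly_syn}, sp_ns={table.sp_ns})"
        )
    ratio = (table.poly_ns * table.sp_syn) / (table.poly_syn * table.sp_ns)
    if not positive_when_shared_ns_enriched:
        if table.poly_ns == 0 or table.sp_syn == 0:
            raise ValueError("alpha_b (flipped orientation) undefined: zero denominator")
        ratio = 1.0 / ratio
    return AlphaBResult(
        value=1.0 - ratio,
        poly_ns_syn_ratio=table.poly_ns / table.poly_syn,
        sp_ns_syn_ratio=np.inf if table.sp_syn == 0 else table.sp_ns / table.sp_syn,
    )


@dataclass(slots=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    n_boot: int
    n_genes: int
    unreliable: bool
    replicates: np.ndarray = field(repr=False, default=None)


def alpha_b_bootstrap(
    table: AlphaBTable, n_boot: int = 1000, seed: int = 0
) -> BootstrapResult:
    """Gene-level bootstrap for alpha_b: percentile CI and one-sided p vs 0.

    Genes are resampled with replacement, counts re-summed and alpha_b
    recomputed; replicates with a zero denominator are dropped.  The one-sided
    p-value is the bootstrap fraction on the opposite side of 0 from the
    point estimate.
    """
    if table.per_gene is None or len(table.per_gene) == 0:
        raise ValueError("alpha_b_bootstrap needs per-gene counts")
    point = alpha_b(table).value
    genes = table.per_gene[["poly_syn", "poly_ns", "sp_syn", "sp_ns"]].to_numpy(
        dtype=np.int64
    )
    n_genes = len(genes)
    unreliable = n_genes < 10
    if unreliable:
        logger.warning("alpha_b_bootstrap: only %d genes; CI unreliable", n_genes)
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_genes, n_genes)
        ps, pn, ss, sn = genes[idx].sum(axis=0)
        if ps == 0 or sn == 0:
            continue
        reps.append(1.0 - (pn * ss) / (ps * sn))
    reps = np.array(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    if point >= 0:
        p = float((reps <= 0).mean())
    else:
        p = float((reps >= 0).mean())
    return BootstrapResult(
        point=point,
        ci_low=float(lo),
        ci_high=float(hi),
        p_one_sided=p,
        n_boot=len(reps),
        n_genes=n_genes,
        unreliable=unreliable,
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# beta(1), folded
# ---------------------------------------------------------------------------

@dataclass
class BetaWindow:
    """A core SNP's folded frequency plus its window's folded frequencies.

    ``n`` is the haploid sample size used both for folding and for the
    estimator normalizations; the core SNP itself is excluded from the
    window.
    """

    core_freq: float
    window_freqs: np.ndarray
    n: int

    def __post_init__(self) -> None:
        self.window_freqs = np.asarray(self.window_freqs, dtype=float)
        if self.n < 4:
            raise ValueError("beta(1) requires haploid sample size n >= 4")
        if not 0 < self.core_freq <= 0.5:
            raise ValueError("core folded frequency must be in (0, 0.5]")
        if len(self.window_freqs) and not (
            (self.window_freqs > 0) & (self.window_freqs <= 0.5)
        ).all():
            raise ValueError("window folded frequencies must be in (0, 0.5]")


def _similarity(f: np.ndarray, core: float, p: float) -> np.ndarray:
    # kernel on the folded frequency scale [0, 0.5]; max distance 0.5
    return (1.0 - np.abs(f - core) / 0.5) ** p


def _folded_class_expectation(n: int) -> np.ndarray:
    """E[# SNPs at folded count k] / theta for k = 1..floor(n/2)."""
    ks = np.arange(1, n // 2 + 1)
    g = 1.0 / ks + 1.0 / (n - ks)
    g[ks == n - ks] /= 2.0
    return g


def beta1_folded(win: BetaWindow, p_exponent: float = 2.0) -> float:
    """beta(1) = theta_beta - theta_W over one window (0 for an empty window).

    theta_beta = sum_i w(f_i) / sum_k w(k/n) g(k, n) where w is the
    similarity kernel between folded frequencies and g(k, n) the neutral
    folded-class expectation (1/k + 1/(n-k), halved at k = n/2), so that
    theta_beta is unbiased for theta under neutrality; theta_W = S / a_n.
    """
    if len(win.window_freqs) == 0:
        return 0.0
    n = win.n
    ks = np.arange(1, n // 2 + 1)
    denom = float(
        (_similarity(ks / n, win.core_freq, p_exponent) * _folded_class_expectation(n)).sum()
    )
    theta_beta = float(_similarity(win.window_freqs, win.core_freq, p_exponent).sum()) / denom
    a_n = float((1.0 / np.arange(1, n)).sum())
    theta_w = len(win.window_freqs) / a_n
    return theta_beta - theta_w


def beta1_scan(
    gm: GenotypeMatrix,
    species: str,
    classes: SiteClassTable,
    window_bp: int = 500,
    p_exponent: float = 2.0,
    annotation_groups: tuple[str, ...] = ("SYN", "NS", "intron", "intergenic", "UTR5", "UTR3"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """beta(1) at every polymorphic core site of one species, plus summaries.

    ``window_bp`` is the half-width of the window on each side of the core.
    Returns (per-site table, summary by annotation class x shared flag with
    mean, SE, n and a one-sample t-test of mean vs 0, reported descriptively).
    Annotation classes with zero sites are omitted with a log entry.
    """
    freqs = gm.allele_freq(species)
    folded = np.minimum(freqs, 1 - freqs)
    _, n_alleles = gm.allele_counts(species)
    n_nominal = int(2 * gm.species_mask(species).sum())
    poly = np.isfinite(folded) & (folded > 0)

    chroms = np.array([s.chrom for s in gm.sites])
    pos = np.array([s.pos for s in gm.sites])
    shared = (classes.frame["label"] == "shared_poly").to_numpy()
    ann = classes.frame["annotation"].to_numpy()

    rows = []
    core_idx = np.flatnonzero(poly)
    for i in core_idx:
        in_win = (
            (chroms == chroms[i])
            & (np.abs(pos - pos[i]) <= window_bp)
            & poly
        )
        in_win[i] = False
        wfreqs = folded[in_win]
        win = BetaWindow(core_freq=float(folded[i]), window_freqs=wfreqs, n=n_nominal)
        rows.append(
            {
                "chrom": chroms[i],
                "pos": int(pos[i]),
                "annotation": ann[i],
                "shared": bool(shared[i]),
                "core_maf": float(folded[i]),
                "n_window_snps": int(in_win.sum()),
                "beta1": beta1_folded(win, p_exponent=p_exponent),
            }
        )
    per_site = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "annotation", "shared", "core_maf", "n_window_snps", "beta1"],
    )

    summaries = []
    for a in annotation_groups:
        for sh in (True, False):
            vals = per_site.loc[
                (per_site["annotation"] == a) & (per_site["shared"] == sh), "beta1"
            ].to_numpy()
            if len(vals) == 0:
                logger.info("beta1_scan: no %s sites (shared=%s); omitted", a, sh)
                continue
            mean = float(vals.mean())
            se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
            if len(vals) > 1 and vals.std(ddof=1) > 0:
                t, p = sps.ttest_1samp(vals, 0.0)
            else:
                t, p = np.nan, np.nan
            summaries.append(
                {
                    "annotation": a,
                    "shared": sh,
                    "n": len(vals),
                    "mean_beta1": mean,
                    "se_beta1": se,
                    "t_vs_0": float(t),
                    "p_vs_0": float(p),
                }
            )
    return per_site, pd.DataFrame(
        summaries,
        columns=["annotation", "shared", "n", "mean_beta1", "se_beta1", "t_vs_0", "p_vs_0"],
    )
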