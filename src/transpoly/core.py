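"""Core data model, VCF I/O, filtering, site classification and small QC statistics.

The central container is :class:`GenotypeMatrix`: biallelic SNP sites by diploid
samples, genotypes stored as alt-allele dosage (0/1/2, -1 for missing), with
optional per-call allele depths and optional phased haplotypes.  Sites are
classified relative to two focal species as shared polymorphisms, private
polymorphisms, fixed differences or monomorphic, following a minor-allele
frequency threshold applied within each species.

Coordinates are 1-based inclusive at the VCF boundary; any internal window
arithmetic is 0-based half-open, with conversion confined to the I/O layer.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("transpoly")

MISSING = -1

ANNOTATIONS = ("SYN", "NS", "intron", "intergenic", "UTR5", "UTR3", "unknown")
SITE_LABELS = ("shared_poly", "private_A", "private_B", "fixed_diff", "monomorphic")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class SampleInfo:
    """A diploid sample with its species/population assignment."""

    sample_id: str
    species: str
    population: str = ""
    mlg_id: str | None = None


@dataclass(slots=True)
class SiteRecord:
    """A biallelic SNP site (1-based VCF position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    annotation: str = "unknown"
    gene_id: str | None = None
    mean_depth: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.annotation not in ANNOTATIONS:
            raise ValueError(f"unknown annotation {self.annotation!r}")


@dataclass
class GenotypeMatrix:
    """Sites x samples alt-allele dosages with optional depths and phase.

    genotypes[i, j] is the alt-allele dosage of sample j at site i, in
    {0, 1, 2} or -1 for missing.  allele_depths[i, j] is (ref reads, alt
    reads) with -1 for missing.  phased_haplotypes[i, 2j] / [i, 2j+1] are the
    two haploid alleles of sample j where phase is known (-1 elsewhere); at
    non-missing phased calls the haplotype pair sums to the dosage.
    """

    sites: list[SiteRecord]
    samples: list[SampleInfo]
    genotypes: np.ndarray
    allele_depths: np.ndarray | None = None
    phased_haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sites), len(self.samples)):
            raise ValueError(
                f"genotype shape {self.genotypes.shape} inconsistent with "
                f"{len(self.sites)} sites x {len(self.samples)} samples"
            )
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
            if self.allele_depths.shape != (*self.genotypes.shape, 2):
                raise ValueError("allele_depths shape mismatch")
        if self.phased_haplotypes is not None:
            self.phased_haplotypes = np.asarray(self.phased_haplotypes, dtype=np.int8)
            if self.phased_haplotypes.shape != (len(self.sites), 2 * len(self.samples)):
                raise ValueError("phased_haplotypes shape mismatch")
            hap = self.phased_haplotypes
            ok = (hap[:, 0::2] >= 0) & (hap[:, 1::2] >= 0) & (self.genotypes >= 0)
            if not np.array_equal(
                (hap[:, 0::2] + hap[:, 1::2])[ok], self.genotypes[ok]
            ):
                raise ValueError("phased haplotype sums disagree with dosages")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def species_labels(self) -> np.ndarray:
        return np.array([s.species for s in self.samples])

    def species_mask(self, species: str) -> np.ndarray:
        mask = self.species_labels == species
        if not mask.any():
            raise ValueError(f"unknown species label {species!r}")
        return mask

    def sample_index(self, sample_id: str) -> int:
        for j, s in enumerate(self.samples):
            if s.sample_id == sample_id:
                return j
        raise KeyError(sample_id)

    def sample_mean_depth(self) -> np.ndarray:
        """Per-sample mean total read depth over non-missing AD calls (NaN if no AD)."""
        if self.allele_depths is None:
            return np.full(self.n_samples, np.nan)
        tot = self.allele_depths.sum(axis=2).astype(float)
        tot[self.allele_depths.min(axis=2) < 0] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(tot, axis=0)

    def subset(
        self,
        site_idx: np.ndarray | Sequence[int] | None = None,
        sample_idx: np.ndarray | Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        si = np.arange(self.n_sites) if site_idx is None else np.asarray(site_idx)
        sj = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        hap = None
        if self.phased_haplotypes is not None:
            hcols = np.stack([2 * sj, 2 * sj + 1], axis=1).ravel()
            hap = self.phased_haplotypes[np.ix_(si, hcols)]
        return GenotypeMatrix(
            sites=[self.sites[int(i)] for i in si],
            samples=[replace(self.samples[int(j)]) for j in sj],
            genotypes=self.genotypes[np.ix_(si, sj)],
            allele_depths=None
            if self.allele_depths is None
            else self.allele_depths[np.ix_(si, sj)],
            phased_haplotypes=hap,
        )

    def allele_counts(self, species: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, non-missing allele count) within a species."""
        mask = self.species_mask(species)
        g = self.genotypes[:, mask]
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return alt.astype(np.int64), n.astype(np.int64)

    def allele_freq(self, species: str) -> np.ndarray:
        """Per-site alt-allele frequency in a species (NaN where no calls)."""
        alt, n = self.allele_counts(species)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.sites],
                "pos": [s.pos for s in self.sites],
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "annotation": [s.annotation for s in self.sites],
                "gene_id": [s.gene_id for s in self.sites],
                "mean_depth": [s.mean_depth for s in self.sites],
            }
        )


@dataclass
class SiteClassTable:
    """Per-site classification relative to two focal species.

    The frame has columns chrom, pos, ref, alt, annotation, gene_id, freq_A,
    freq_B, maf_A, maf_B, label, unassessable.  Labels partition the sites;
    `unassessable` flags sites with zero calls in one species (labelled
    monomorphic rather than silently dropped, which would bias shared counts).
    """

    frame: pd.DataFrame
    species_A: str
    species_B: str
    maf_min: float

    @property
    def labels(self) -> pd.Series:
        return self.frame["label"]

    def counts(self) -> dict[str, int]:
        c = self.frame["label"].value_counts()
        return {lab: int(c.get(lab, 0)) for lab in SITE_LABELS}

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero((self.frame["label"] == label).to_numpy())

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class FilterReport:
    n_sites_in: int
    n_samples_in: int
    n_samples_removed: int
    n_sites_removed_depth: int
    n_sites_removed_missing: int
    n_sites_no_depth: int
    n_sites_out: int
    n_samples_out: int
    removed_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if k != "removed_samples"}
        d["removed_samples"] = ",".join(self.removed_samples)
        return pd.DataFrame([d])


# ---------------------------------------------------------------------------
# sample tables and VCF I/O
# ---------------------------------------------------------------------------

def read_sample_table(path) -> dict[str, SampleInfo]:
    """Read a 3-column TSV (sample_id, species, population) into SampleInfo records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:3])
    out: dict[str, SampleInfo] = {}
    for _, row in df.iterrows():
        sid = str(row[cols[0]])
        if sid in out:
            raise ValueError(f"duplicate sample_id {sid!r} in sample table")
        out[sid] = SampleInfo(
            sample_id=sid,
            species=str(row[cols[1]]),
            population=str(row[cols[2]]) if len(cols) > 2 else "",
        )
    return out


def write_sample_table(samples: Iterable[SampleInfo], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "species": [s.species for s in samples],
            "population": [s.population for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_vcf(path, sample_table: Mapping[str, SampleInfo] | str) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF (v4.2, GT required) into a GenotypeMatrix.

    Non-biallelic or non-SNP records are skipped with a logged count.  AD is
    captured when present; pipe-separated genotypes populate the phased
    haplotype array.  Samples absent from the sample table are a hard error.
    """
    from cyvcf2 import VCF

    if isinstance(sample_table, (str, bytes)) or hasattr(sample_table, "__fspath__"):
        sample_table = read_sample_table(sample_table)

    vcf = VCF(str(path), gts012=False)
    if "##FORMAT=<ID=GT" not in vcf.raw_header and "FORMAT=<ID=GT," not in vcf.raw_header:
        raise ValueError(f"VCF {path} has no GT FORMAT field")
    vcf_samples = list(vcf.samples)
    for sid in vcf_samples:
        if sid not in sample_table:
            raise ValueError(f"sample {sid!r} in VCF but absent from sample table")
    samples = [replace(sample_table[sid]) for sid in vcf_samples]
    nsam = len(samples)

    sites: list[SiteRecord] = []
    geno_rows, ad_rows, hap_rows = [], [], []
    any_ad = False
    any_phase = False
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ann = var.INFO.get("ANN") or "unknown"
        gene = var.INFO.get("GENE")
        md = var.INFO.get("DPM")
        if md is None:
            try:
                dp = var.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                dp = dp.astype(float).ravel()
                dp[dp < 0] = np.nan
                md = float(np.nanmean(dp)) if np.isfinite(dp).any() else float("nan")
            else:
                md = float("nan")
        sites.append(
            SiteRecord(
                chrom=var.CHROM,
                pos=var.POS,
                ref=var.REF,
                alt=var.ALT[0],
                annotation=ann if ann in ANNOTATIONS else "unknown",
                gene_id=gene,
                mean_depth=float(md),
            )
        )
        g = np.full(nsam, MISSING, dtype=np.int8)
        h = np.full(2 * nsam, MISSING, dtype=np.int8)
        for j, call in enumerate(var.genotypes):
            a0, a1, phased = call[0], call[1], call[-1]
            if a0 >= 0 and a1 >= 0:
                g[j] = a0 + a1
                if phased:
                    h[2 * j] = a0
                    h[2 * j + 1] = a1
                    any_phase = True
        geno_rows.append(g)
        hap_rows.append(h)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            any_ad = True
            a = ad[:, :2].astype(np.int32)
            a[a < 0] = MISSING
            ad_rows.append(a)
        else:
            ad_rows.append(np.full((nsam, 2), MISSING, dtype=np.int32))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)

    gm = GenotypeMatrix(
        sites=sites,
        samples=samples,
        genotypes=np.array(geno_rows, dtype=np.int8).reshape(len(sites), nsam),
        allele_depths=np.array(ad_rows, dtype=np.int32).reshape(len(sites), nsam, 2)
        if any_ad
        else None,
        phased_haplotypes=np.array(hap_rows, dtype=np.int8).reshape(len(sites), 2 * nsam)
        if any_phase
        else None,
    )
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 text, preserving GT, phase and AD.

    Site annotation, gene id and mean depth are carried in INFO (ANN, GENE,
    DPM) so that read_vcf -> write_vcf -> read_vcf round-trips the matrix.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=ANN,Number=1,Type=String,Description="Site annotation">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">\n')
        fh.write('##INFO=<ID=DPM,Number=1,Type=Float,Description="Mean site depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.allele_depths is not None:
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n'
            )
        for chrom in dict.fromkeys(s.chrom for s in gm.sites):
            maxpos = max(s.pos for s in gm.sites if s.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        fmt = "GT" if gm.allele_depths is None else "GT:AD"
        for i, site in enumerate(gm.sites):
            info = [f"ANN={site.annotation}"]
            if site.gene_id:
                info.append(f"GENE={site.gene_id}")
            if np.isfinite(site.mean_depth):
                info.append(f"DPM={site.mean_depth:.4f}")
            cols = [
                site.chrom,
                str(site.pos),
                ".",
                site.ref,
                site.alt,
                ".",
                ".",
                ";".join(info),
                fmt,
            ]
            for j in range(gm.n_samples):
                g = gm.genotypes[i, j]
                if g < 0:
                    gt = "./."
                elif (
                    gm.phased_haplotypes is not None
                    and gm.phased_haplotypes[i, 2 * j] >= 0
                ):
                    gt = f"{gm.phased_haplotypes[i, 2 * j]}|{gm.phased_haplotypes[i, 2 * j + 1]}"
                else:
                    gt = "0/0" if g == 0 else ("0/1" if g == 1 else "1/1")
                if gm.allele_depths is not None:
                    ad = gm.allele_depths[i, j]
                    adtxt = ".,." if ad[0] < 0 else f"{ad[0]},{ad[1]}"
                    gt = f"{gt}:{adtxt}"
                cols.append(gt)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_sites(
    gm: GenotypeMatrix,
    max_missing: float = 0.10,
    depth_lo: float | None = 8,
    depth_hi: float | None = 35,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Post-hoc numeric filters: sample missingness, site depth, site missingness.

    Samples whose genome-wide call missingness exceeds ``max_missing`` are
    removed first; then sites with mean depth <= depth_lo or >= depth_hi, and
    sites whose missingness over the remaining samples exceeds ``max_missing``.
    Sites with no depth annotation are retained and counted in the report.
    """
    miss = gm.genotypes < 0
    sample_miss = miss.mean(axis=0) if gm.n_sites else np.zeros(gm.n_samples)
    keep_samples = np.flatnonzero(sample_miss <= max_missing)
    removed_samples = [gm.samples[j].sample_id for j in np.flatnonzero(sample_miss > max_missing)]

    depth = np.array([s.mean_depth for s in gm.sites], dtype=float)
    if depth_lo is not None or depth_hi is not None:
        if gm.n_sites and not np.isfinite(depth).any():
            raise ValueError("depth filtering requested but no site has mean_depth")
    bad_depth = np.zeros(gm.n_sites, dtype=bool)
    if depth_lo is not None:
        bad_depth |= np.isfinite(depth) & (depth <= depth_lo)
    if depth_hi is not None:
        bad_depth |= np.isfinite(depth) & (depth >= depth_hi)

    sub_miss = miss[:, keep_samples]
    site_miss = sub_miss.mean(axis=1) if len(keep_samples) else np.ones(gm.n_sites)
    bad_miss = ~bad_depth & (site_miss > max_missing)

    keep_sites = np.flatnonzero(~bad_depth & ~bad_miss)
    report = FilterReport(
        n_sites_in=gm.n_sites,
        n_samples_in=gm.n_samples,
        n_samples_removed=gm.n_samples - len(keep_samples),
        n_sites_removed_depth=int(bad_depth.sum()),
        n_sites_removed_missing=int(bad_miss.sum()),
        n_sites_no_depth=int((~np.isfinite(depth)).sum()),
        n_sites_out=len(keep_sites),
        n_samples_out=len(keep_samples),
        removed_samples=removed_samples,
    )
    if len(keep_sites) == 0:
        warnings.warn("filter_sites removed every site", stacklevel=2)
    return gm.subset(keep_sites, keep_samples), report


# ---------------------------------------------------------------------------
# site classification
# ---------------------------------------------------------------------------

def classify_sites(
    gm: GenotypeMatrix,
    species_A: str,
    species_B: str,
    maf_min: float = 0.01,
) -> SiteClassTable:
    """Label every site as shared/private/fixed/monomorphic between two species.

    A site is a shared polymorphism iff its within-species minor allele
    frequency exceeds ``maf_min`` in both species; a fixed difference iff the
    species are fixed for opposite alleles; private iff polymorphic above the
    threshold in exactly one species; monomorphic otherwise.  Frequencies use
    non-missing calls only; a site with zero calls in one species is labelled
    monomorphic with the ``unassessable`` flag set.
    """
    alt_A, n_A = gm.allele_counts(species_A)
    alt_B, n_B = gm.allele_counts(species_B)
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = np.where(n_A > 0, alt_A / np.maximum(n_A, 1), np.nan)
        fB = np.where(n_B > 0, alt_B / np.maximum(n_B, 1), np.nan)
    mafA = np.minimum(fA, 1 - fA)
    mafB = np.minimum(fB, 1 - fB)

    unassessable = (n_A == 0) | (n_B == 0)
    fixed = ~unassessable & (
        ((fA == 0.0) & (fB == 1.0)) | ((fA == 1.0) & (fB == 0.0))
    )
    polyA = ~unassessable & (mafA > maf_min)
    polyB = ~unassessable & (mafB > maf_min)

    label = np.full(gm.n_sites, "monomorphic", dtype=object)
    label[fixed] = "fixed_diff"
    label[~fixed & polyA & polyB] = "shared_poly"
    label[~fixed & polyA & ~polyB] = "private_A"
    label[~fixed & ~polyA & polyB] = "private_B"

    frame = gm.site_frame()
    frame["freq_A"] = fA
    frame["freq_B"] = fB
    frame["maf_A"] = mafA
    frame["maf_B"] = mafB
    frame["label"] = pd.Categorical(label, categories=list(SITE_LABELS))
    frame["unassessable"] = unassessable
    return SiteClassTable(frame=frame, species_A=species_A, species_B=species_B, maf_min=maf_min)


# ---------------------------------------------------------------------------
# multi-locus genotypes
# ---------------------------------------------------------------------------

def genotype_mismatch(gm: GenotypeMatrix, j1: int, j2: int) -> float:
    """Mismatch fraction between two samples over mutually non-missing sites."""
    g1, g2 = gm.genotypes[:, j1], gm.genotypes[:, j2]
    both = (g1 >= 0) & (g2 >= 0)
    n = int(both.sum())
    if n == 0:
        return float("nan")
    return float((g1[both] != g2[both]).sum() / n)


def assign_mlg(gm: GenotypeMatrix, max_mismatch: float = 0.0) -> GenotypeMatrix:
    """Group samples into multi-locus genotypes by single-linkage identity.

    Samples whose pairwise genotype mismatch fraction (over mutually
    non-missing sites) is <= ``max_mismatch`` are linked; connected components
    become MLGs.  Returns a copy with ``mlg_id`` set on every sample.
    """
    from scipy.sparse import lil_matrix
    from scipy.sparse.csgraph import connected_components

    n = gm.n_samples
    adj = lil_matrix((n, n), dtype=np.int8)
    for j1 in range(n):
        for j2 in range(j1 + 1, n):
            d = genotype_mismatch(gm, j1, j2)
            if np.isfinite(d) and d <= max_mismatch:
                adj[j1, j2] = 1
    _, comp = connected_components(adj.tocsr(), directed=False)
    out = gm.subset()
    # stable MLG numbering by first sample occurrence
    seen: dict[int, str] = {}
    for j, c in enumerate(comp):
        if c not in seen:
            seen[c] = f"MLG_{len(seen):04d}"
        out.samples[j].mlg_id = seen[c]
    return out


def mlg_representatives(gm: GenotypeMatrix) -> list[str]:
    """One representative sample per MLG: highest mean depth, ties broken by id."""
    if any(s.mlg_id is None for s in gm.samples):
        raise ValueError("run assign_mlg first")
    depth = gm.sample_mean_depth()
    depth = np.where(np.isfinite(depth), depth, 0.0)
    best: dict[str, tuple[float, str]] = {}
    for j, s in enumerate(gm.samples):
        key = (-depth[j], s.sample_id)
        if s.mlg_id not in best or key < best[s.mlg_id]:
            best[s.mlg_id] = key
    return sorted(sid for _, sid in best.values())


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

@dataclass
class AlleleBalance:
    species: str
    mean_ref_fraction: float
    ci_low: float
    ci_high: float
    n_calls: int


def allele_balance_qc(
    gm: GenotypeMatrix,
    n_sites: int = 1000,
    n_boot: int = 100,
    seed: int = 0,
) -> dict[str, AlleleBalance]:
    """Mean reference-read fraction at heterozygous calls, per species.

    A reference-bias screen: samples up to ``n_sites`` heterozygous calls per
    species (without replacement), reports the mean ref/(ref+alt) read
    fraction with a percentile bootstrap CI.  Values near 0.5 indicate no
    systematic reference allele bias.
    """
    if gm.allele_depths is None:
        raise ValueError("allele_balance_qc requires allele depths")
    rng = np.random.default_rng(seed)
    out: dict[str, AlleleBalance] = {}
    for species in dict.fromkeys(s.species for s in gm.samples):
        mask = gm.species_mask(species)
        het = gm.genotypes[:, mask] == 1
        ad = gm.allele_depths[:, mask]
        tot = ad.sum(axis=2)
        usable = het & (ad.min(axis=2) >= 0) & (tot > 0)
        ii, jj = np.nonzero(usable)
        if len(ii) == 0:
            raise ValueError(f"no heterozygous calls with depth for species {species!r}")
        if len(ii) > n_sites:
            pick = rng.choice(len(ii), size=n_sites, replace=False)
            ii, jj = ii[pick], jj[pick]
        frac = ad[ii, jj, 0] / tot[ii, jj]
        boots = np.array(
            [frac[rng.integers(0, len(frac), len(frac))].mean() for _ in range(n_boot)]
        )
        lo, hi = np.percentile(boots, [2.5, 97.5])
        out[species] = AlleleBalance(
            species=species,
            mean_ref_fraction=float(frac.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            n_calls=len(frac),
        )
    return out


def het_at_fixed_differences(
    gm: GenotypeMatrix, classes: SiteClassTable, test_sample: str
) -> float:
    """Fraction of fixed-difference sites heterozygous in one test sample.

    High values flag hybrid ancestry: a fixed difference between two species
    is heterozygous in an F1 by construction.
    """
    j = gm.sample_index(test_sample)
    idx = classes.indices("fixed_diff")
    g = gm.genotypes[idx, j]
    g = g[g >= 0]
    if len(g) == 0:
        raise ValueError(f"no usable fixed-difference sites for sample {test_sample!r}")
    return float((g == 1).mean())


def het_at_fixed_differences_batch(
    gm: GenotypeMatrix, classes: SiteClassTable, sample_ids: Sequence[str] | None = None
) -> pd.Series:
    """Distribution of the fixed-difference heterozygosity over samples.

    Defaults to one representative per MLG when MLGs are assigned.
    """
    if sample_ids is None:
        sample_ids = (
            mlg_representatives(gm)
            if all(s.mlg_id is not None for s in gm.samples)
            else gm.sample_ids
        )
    vals = {}
    for sid in sample_ids:
        try:
            vals[sid] = het_at_fixed_differences(gm, classes, sid)
        except ValueError:
            logger.info("het_at_fixed_differences: no usable sites for %s", sid)
    return pd.Series(vals, dtype=float)


def pairwise_r2(
    gm: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    species: str,
    maf_min: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise linkage disequilibrium (r^2) between SNPs in a region.

    ``start``/``end`` are 1-based inclusive.  r^2 is the squared Pearson
    correlation of dosage vectors over mutually non-missing samples of the
    given species.  Monomorphic / below-threshold sites are excluded (logged).
    Returns (matrix, indices of retained sites in gm).
    """
    smask = gm.species_mask(species)
    in_region = np.array(
        [s.chrom == chrom and start <= s.pos <= end for s in gm.sites]
    )
    idx = np.flatnonzero(in_region)
    freqs = gm.allele_freq(species)[idx]
    maf = np.minimum(freqs, 1 - freqs)
    keep = idx[np.isfinite(maf) & (maf > maf_min)]
    n_dropped = len(idx) - len(keep)
    if n_dropped:
        logger.info("pairwise_r2: excluded %d monomorphic/low-MAF sites", n_dropped)
    if len(keep) < 2:
        raise ValueError("fewer than 2 polymorphic sites in region")
    g = gm.genotypes[np.ix_(keep, np.flatnonzero(smask))].astype(float)
    g[g < 0] = np.nan
    k = len(keep)
    r2 = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            ok = np.isfinite(g[a]) & np.isfinite(g[b])
            if ok.sum() < 2 or g[a][ok].std() == 0 or g[b][ok].std() == 0:
                r2[a, b] = r2[b, a] = np.nan
                continue
            r = np.corrcoef(g[a][ok], g[b][ok])[0, 1]
            r2[a, b] = r2[b, a] = r * r
    return r2, keep
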