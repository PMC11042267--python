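"""Synthetic two-species data with known ground truth.

A bespoke per-window structured coalescent drives everything: two diploid
populations of sizes N_A and N_B exchange migrants at a symmetric
per-lineage per-generation rate m, merge into an ancestral population of
size N_anc at t_split generations, and mutations fall on the genealogy as a
Poisson process at rate mu per bp per generation (infinite-sites: every
mutation is its own biallelic site).  Windows are unlinked; sites within a
window share one genealogy and no recombination.

On top of the neutral split model sit three window-level scenario
injectors -- neutral passthrough, a trans-specific balanced haplotype pair
(allelic classes older than the species split, shared class-defining
mutations in perfect linkage) and convergent same-site mutations (one
shared polymorphism arising independently within each species) -- plus a
read-depth/genotype-calling layer and an F1 AB x AB cross generator with
optional heterozygote viability advantage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, SampleInfo, SiteRecord
from .segregation import DEFAULT_CALLER, CrossObservation, GenotypeCaller

__all__ = [
    "DemographyConfig",
    "ScenarioSpec",
    "simulate_split",
    "split_windows",
    "inject_scenario",
    "add_reads",
    "simulate_cross",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class DemographyConfig:
    """Two-population split(+migration) model, in generations and diploid sizes.

    Defaults mirror the study system's relative scales (a larger "A"
    population vs a smaller "B" population) scaled down to desk size;
    scaling N and t together preserves theta and the split time in
    coalescent units.
    """

    N_anc: float = 1000.0
    N_A: float = 1000.0
    N_B: float = 1000.0
    t_split: float = 4000.0
    m: float = 0.0
    mu: float = 5.69e-9
    n_samples_A: int = 10
    n_samples_B: int = 10
    L: int = 100
    window_bp: int = 500
    seed: int = 1
    species_A: str = "NAm_pulex"
    species_B: str = "Euro_pulex"

    def __post_init__(self) -> None:
        if min(self.N_anc, self.N_A, self.N_B, self.mu) <= 0:
            raise ValueError("population sizes and mu must be positive")
        if not 0 <= self.m < 1:
            raise ValueError("m must be in [0, 1)")
        if min(self.n_samples_A, self.n_samples_B, self.L, self.window_bp) < 1:
            raise ValueError("sample counts, L and window_bp must be >= 1")
        if self.t_split < 0:
            raise ValueError("t_split must be non-negative")


@dataclass(slots=True)
class ScenarioSpec:
    """Window-level scenario: neutral, trans_specific or convergent.

    trans_specific: haplotypes are partitioned (exactly) into two allelic
    classes at ``class_frequency`` per species and ``n_class_mutations``
    shared class-defining mutations are placed on the class background; the
    classes are treated as older than the species split (t_balance >
    t_split), so window variants fixed between species are dropped -- a
    haplotype pair maintained through the split cannot carry post-split
    species-fixed differences on both backgrounds.

    convergent: one identical-state mutation is added independently within
    each species at ``convergent_frequency``; the species-structured
    background is untouched, so allele trees stay concordant.
    """

    kind: str = "neutral"
    t_balance: float | None = None
    class_frequency: float = 0.5
    n_class_mutations: int = 13
    convergent_frequency: float = 0.5
    het_advantage: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("neutral", "trans_specific", "convergent"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "trans_specific":
            if not 0 < self.class_frequency < 1:
                raise ValueError("class_frequency must be in (0, 1)")
            if self.n_class_mutations < 1:
                raise ValueError("n_class_mutations must be >= 1")


# ---------------------------------------------------------------------------
# the structured coalescent, one window at a time
# ---------------------------------------------------------------------------

def _simulate_genealogy(
    cfg: DemographyConfig, rng: random.Random
) -> tuple[list[float], list[int], list[list[int]]]:
    """One window genealogy: returns (node times, parent ids, tip sets).

    Lineages coalesce within their population at rate k*(k-1)/(4*N) per
    generation and migrate at rate m per lineage; at t_split all lineages
    join the ancestral population.  Times are in generations, tips first.
    """
    n_tips = 2 * (cfg.n_samples_A + cfg.n_samples_B)
    times = [0.0] * n_tips
    parents = [-1] * n_tips
    # active lineages per population: lists of node ids
    pops: list[list[int]] = [
        list(range(2 * cfg.n_samples_A)),
        list(range(2 * cfg.n_samples_A, n_tips)),
    ]
    sizes = [cfg.N_A, cfg.N_B]
    t = 0.0
    merged = cfg.t_split == 0.0
    if merged:
        pops = [pops[0] + pops[1], []]
        sizes = [cfg.N_anc, 0.0]

    def coal_rate(pop: int) -> float:
        k = len(pops[pop])
        return k * (k - 1) / (4.0 * sizes[pop]) if sizes[pop] > 0 else 0.0

    while len(pops[0]) + len(pops[1]) > 1:
        rates = [coal_rate(0), coal_rate(1)]
        n_active = len(pops[0]) + len(pops[1])
        mig = 0.0 if merged else cfg.m * n_active
        total = rates[0] + rates[1] + mig
        if total <= 0:
            # lone lineages in separate populations waiting for the merge
            t = cfg.t_split
        else:
            t += rng.expovariate(total)
        if not merged and t >= cfg.t_split:
            t = cfg.t_split
            pops = [pops[0] + pops[1], []]
            sizes = [cfg.N_anc, 0.0]
            merged = True
            continue
        if total <= 0:
            continue
        u = rng.random() * total
        if u < rates[0] or u < rates[0] + rates[1]:
            pop = 0 if u < rates[0] else 1
            group = pops[pop]
            i = rng.randrange(len(group))
            j = rng.randrange(len(group) - 1)
            if j >= i:
                j += 1
            a, b = group[i], group[j]
            node = len(times)
            times.append(t)
            parents.append(-1)
            parents[a] = node
            parents[b] = node
            group[:] = [x for x in group if x not in (a, b)] + [node]
        else:
            src = 0 if pops[0] and (not pops[1] or rng.random() < len(pops[0]) / n_active) else 1
            i = rng.randrange(len(pops[src]))
            lin = pops[src].pop(i)
            pops[1 - src].append(lin)

    # tip sets per node
    tipsets: list[list[int]] = [[i] for i in range(n_tips)] + [
        [] for _ in range(len(times) - n_tips)
    ]
    for node in range(len(times)):
        p = parents[node]
        if p >= 0:
            tipsets[p].extend(tipsets[node])
    return times, parents, tipsets


def simulate_split(cfg: DemographyConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate the split(+migration) model; phased matrix plus truth labels.

    Returns the genotype matrix (phased haplotypes, species labels) and a
    per-site provenance frame with columns window, pos, seg_A, seg_B (does
    the mutation segregate within each species' sample) and derived_count.
    Deterministic under the config seed.
    """
    rng = random.Random(cfg.seed)
    n_tips = 2 * (cfg.n_samples_A + cfg.n_samples_B)
    nA_h = 2 * cfg.n_samples_A

    hap_cols: list[np.ndarray] = []
    sites: list[SiteRecord] = []
    prov: list[dict] = []
    for w in range(cfg.L):
        times, parents, tipsets = _simulate_genealogy(cfg, rng)
        # branch lengths; root excluded (parent -1)
        lengths = [
            times[parents[v]] - times[v] if parents[v] >= 0 else 0.0
            for v in range(len(times))
        ]
        total = sum(lengths)
        lam = cfg.mu * cfg.window_bp * total
        n_mut = _poisson(lam, rng)
        if n_mut == 0:
            continue
        # infinite sites: every mutation is its own record; physical positions
        # may repeat in heavily scaled-down runs (mutation density > 1/bp)
        if n_mut <= cfg.window_bp:
            offsets = rng.sample(range(cfg.window_bp), n_mut)
        else:
            offsets = [rng.randrange(cfg.window_bp) for _ in range(n_mut)]
        offsets.sort()
        cum = np.cumsum(lengths)
        for off in offsets:
            u = rng.random() * total
            v = int(np.searchsorted(cum, u, side="right"))
            carriers = tipsets[v]
            col = np.zeros(n_tips, dtype=np.int8)
            col[carriers] = 1
            k = len(carriers)
            if k == 0 or k == n_tips:
                continue
            hap_cols.append(col)
            pos = w * cfg.window_bp + off + 1
            sites.append(SiteRecord(chrom="sim1", pos=pos, ref="A", alt="T"))
            kA = int(col[:nA_h].sum())
            kB = int(col[nA_h:].sum())
            prov.append(
                {
                    "window": w,
                    "pos": pos,
                    "seg_A": 0 < kA < nA_h,
                    "seg_B": 0 < kB < (n_tips - nA_h),
                    "derived_count": k,
                }
            )

    samples = [
        SampleInfo(sample_id=f"A{j:03d}", species=cfg.species_A, population="popA")
        for j in range(cfg.n_samples_A)
    ] + [
        SampleInfo(sample_id=f"B{j:03d}", species=cfg.species_B, population="popB")
        for j in range(cfg.n_samples_B)
    ]
    hap = (
        np.array(hap_cols, dtype=np.int8).reshape(len(sites), n_tips)
        if sites
        else np.zeros((0, n_tips), dtype=np.int8)
    )
    geno = hap[:, 0::2] + hap[:, 1::2]
    gm = GenotypeMatrix(
        sites=sites, samples=samples, genotypes=geno, phased_haplotypes=hap
    )
    provenance = pd.DataFrame(
        prov, columns=["window", "pos", "seg_A", "seg_B", "derived_count"]
    )
    return gm, provenance


def _poisson(lam: float, rng: random.Random) -> int:
    """Poisson draw from a python Random (Knuth below, normal approx above)."""
    if lam <= 0:
        return 0
    if lam > 500:
        return max(0, int(round(rng.gauss(lam, lam**0.5))))
    limit = np.exp(-lam)
    n = 0
    prod = rng.random()
    while prod > limit:
        n += 1
        prod *= rng.random()
    return n


def split_windows(
    gm: GenotypeMatrix, provenance: pd.DataFrame
) -> list[tuple[int, GenotypeMatrix]]:
    """Per-window views of a simulated matrix, as (window id, sub-matrix)."""
    out = []
    windows = provenance["window"].to_numpy()
    for w in np.unique(windows):
        idx = np.flatnonzero(windows == w)
        out.append((int(w), gm.subset(site_idx=idx)))
    return out


# ---------------------------------------------------------------------------
# scenario injection
# ---------------------------------------------------------------------------

def inject_scenario(
    base: GenotypeMatrix, spec: ScenarioSpec, seed: int = 0
) -> tuple[GenotypeMatrix, dict]:
    """Realize a scenario in one phased window; returns (window, truth labels).

    Truth contains the scenario kind, the injected site positions and (for
    trans_specific) the haplotype->class assignment.
    """
    if base.phased_haplotypes is None:
        raise ValueError("inject_scenario requires a phased window")
    if spec.kind == "neutral":
        return base, {"kind": "neutral", "injected_pos": []}

    rng = np.random.default_rng(seed)
    hap = base.phased_haplotypes
    species = np.repeat(base.species_labels, 2)
    uniq = list(dict.fromkeys(species))
    if len(uniq) != 2:
        raise ValueError("scenario injection expects exactly 2 species")
    positions = np.array([s.pos for s in base.sites])
    lo = int(positions.min()) if len(positions) else 1
    hi = int(positions.max()) if len(positions) else lo + spec.n_class_mutations + 1
    center = (lo + hi) // 2

    def fresh_positions(k: int) -> list[int]:
        # distinct positions near the window centre, avoiding existing sites
        used = set(int(p) for p in positions)
        out, p = [], center
        step = 0
        while len(out) < k:
            cand = center + step
            if cand >= 1 and cand not in used:
                out.append(cand)
                used.add(cand)
            step = -step + 1 if step <= 0 else -step
        return sorted(out)

    if spec.kind == "convergent":
        [pos] = fresh_positions(1)
        col = np.zeros(hap.shape[1], dtype=np.int8)
        for sp in uniq:
            idx = np.flatnonzero(species == sp)
            k = max(1, int(round(spec.convergent_frequency * len(idx))))
            k = min(k, len(idx) - 1)  # keep the site polymorphic within species
            col[rng.choice(idx, size=k, replace=False)] = 1
        new_sites = [SiteRecord(chrom=base.sites[0].chrom if base.sites else "sim1",
                                pos=pos, ref="A", alt="T", annotation="NS")]
        out = _append_sites(base, new_sites, col[None, :])
        return out, {"kind": "convergent", "injected_pos": [pos]}

    # trans_specific
    keep = np.ones(base.n_sites, dtype=bool)
    for i in range(base.n_sites):
        fA = hap[i, species == uniq[0]]
        fB = hap[i, species == uniq[1]]
        fA = fA[fA >= 0]
        fB = fB[fB >= 0]
        if len(fA) and len(fB):
            a, b = fA.mean(), fB.mean()
            if (a == 0 and b == 1) or (a == 1 and b == 0):
                keep[i] = False  # post-split fixed difference: incompatible
    trimmed = base.subset(site_idx=np.flatnonzero(keep))
    hap = trimmed.phased_haplotypes

    class1 = np.zeros(hap.shape[1], dtype=bool)
    assignment = {}
    for sp in uniq:
        idx = np.flatnonzero(species == sp)
        k = int(round(spec.class_frequency * len(idx)))
        k = min(max(k, 1), len(idx) - 1)
        pick = rng.choice(idx, size=k, replace=False)
        class1[pick] = True
    for h in range(hap.shape[1]):
        assignment[h] = 1 if class1[h] else 2

    pos_new = fresh_positions(spec.n_class_mutations)
    cols = np.tile(class1.astype(np.int8), (len(pos_new), 1))
    chrom = trimmed.sites[0].chrom if trimmed.sites else "sim1"
    new_sites = [
        SiteRecord(chrom=chrom, pos=p, ref="A", alt="T", annotation="NS")
        for p in pos_new
    ]
    out = _append_sites(trimmed, new_sites, cols)
    return out, {
        "kind": "trans_specific",
        "injected_pos": pos_new,
        "class_of_haplotype": assignment,
        "n_background_removed": int((~keep).sum()),
    }


def _append_sites(
    gm: GenotypeMatrix, new_sites: list[SiteRecord], hap_rows: np.ndarray
) -> GenotypeMatrix:
    """Append fully phased sites (haplotype rows) to a window, sorted by pos."""
    hap = (
        gm.phased_haplotypes
        if gm.phased_haplotypes is not None
        else np.zeros((0, 2 * gm.n_samples), dtype=np.int8)
    )
    all_sites = gm.sites + new_sites
    all_hap = np.vstack([hap, hap_rows.astype(np.int8)])
    order = np.argsort([s.pos for s in all_sites], kind="stable")
    all_sites = [all_sites[i] for i in order]
    all_hap = all_hap[order]
    geno = np.where(
        (all_hap[:, 0::2] >= 0) & (all_hap[:, 1::2] >= 0),
        all_hap[:, 0::2] + all_hap[:, 1::2],
        -1,
    ).astype(np.int8)
    return GenotypeMatrix(
        sites=all_sites,
        samples=[replace(s) for s in gm.samples],
        genotypes=geno,
        allele_depths=gm.allele_depths,
        phased_haplotypes=all_hap,
    )


# ---------------------------------------------------------------------------
# read layer
# ---------------------------------------------------------------------------

def add_reads(
    gm: GenotypeMatrix,
    depth_mean: float,
    depth_model: str | np.ndarray = "poisson",
    error_rate: float = 0.0,
    caller: GenotypeCaller = DEFAULT_CALLER,
    seed: int = 0,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Overlay finite-depth reads and called genotypes on true genotypes.

    Depths are Poisson(depth_mean) per call, or resampled from an empirical
    vector when ``depth_model`` is an array.  Returns the new matrix (called
    genotypes + AD, site mean depths filled in) and the true genotypes as a
    side channel.
    """
    if depth_mean < 0:
        raise ValueError("depth_mean must be non-negative")
    rng = np.random.default_rng(seed)
    truth = gm.genotypes.copy()
    shape = truth.shape
    if isinstance(depth_model, str):
        if depth_model != "poisson":
            raise ValueError(f"unknown depth model {depth_model!r}")
        depths = rng.poisson(depth_mean, size=shape)
    else:
        pool = np.asarray(depth_model, dtype=np.int64)
        depths = pool[rng.integers(0, len(pool), size=shape)]
    depths[truth < 0] = 0

    p_alt = np.select([truth == 0, truth == 1, truth == 2],
                      [error_rate, 0.5, 1 - error_rate], default=0.0)
    alt = rng.binomial(depths, p_alt)
    ref = depths - alt
    called = caller(ref, alt)
    ad = np.stack([ref, alt], axis=2).astype(np.int32)
    ad[truth < 0] = -1
    sites = [
        replace(s, mean_depth=float(d)) for s, d in zip(gm.sites, depths.mean(axis=1))
    ]
    out = GenotypeMatrix(
        sites=sites,
        samples=[replace(s) for s in gm.samples],
        genotypes=called.astype(np.int8),
        allele_depths=ad,
        phased_haplotypes=None,
    )
    return out, truth


# ---------------------------------------------------------------------------
# F1 cross
# ---------------------------------------------------------------------------

def simulate_cross(
    parents: tuple[np.ndarray, np.ndarray] | int,
    n_offspring: int = 400,
    het_advantage: float = 0.0,
    depth_mean: float | None = None,
    depths: np.ndarray | None = None,
    caller: GenotypeCaller = DEFAULT_CALLER,
    error_rate: float = 0.0,
    seed: int = 0,
    gene_id: str = "gene1",
) -> tuple[CrossObservation, np.ndarray]:
    """F1 offspring of an AB x AB cross at a linked block of SNPs.

    ``parents`` is either a pair of dosage vectors (all must be heterozygous
    at every SNP for the 1:2:1 contract) or an integer number of SNPs.  Each
    offspring inherits one haplotype block per parent; heterozygote viability
    1+s is applied as survival resampling, so the true genotype law is
    (1, 2*(1+s), 1) normalized.  If ``depth_mean`` (or an empirical depth
    vector) is given, reads are drawn and genotypes called; otherwise the
    true genotypes are reported.  Returns (observation, true genotype draws).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    if isinstance(parents, int):
        n_snps = parents
    else:
        p1, p2 = (np.asarray(p) for p in parents)
        if not ((p1 == 1).all() and (p2 == 1).all()):
            raise ValueError("both parents must be heterozygous at every SNP")
        if len(p1) != len(p2):
            raise ValueError("parent genotype lengths differ")
        n_snps = len(p1)
    s = het_advantage
    if s < -1:
        raise ValueError("het_advantage must be >= -1")
    w = np.array([1.0, 2.0 * (1.0 + s), 1.0])
    rng = np.random.default_rng(seed)
    true = rng.choice(3, size=n_offspring, p=w / w.sum())  # one linked block

    counts = np.zeros((n_snps, 3), dtype=np.int64)
    depth_lists: list[np.ndarray] = []
    if depth_mean is None and depths is None:
        for snp in range(n_snps):
            counts[snp] = np.bincount(true, minlength=3)
            # effectively infinite depth: het miscall probability 2^-999
            depth_lists.append(np.full(n_offspring, 1000, dtype=np.int64))
    else:
        for snp in range(n_snps):
            if depths is not None:
                pool = np.asarray(depths, dtype=np.int64)
                d = pool[rng.integers(0, len(pool), size=n_offspring)]
            else:
                d = rng.poisson(depth_mean, size=n_offspring)
            p_alt = np.select([true == 0, true == 1, true == 2],
                              [error_rate, 0.5, 1 - error_rate])
            alt = rng.binomial(d, p_alt)
            called = caller(d - alt, alt)
            counts[snp] = np.bincount(called[called >= 0], minlength=3)[:3]
            depth_lists.append(d)
    obs = CrossObservation(
        gene_id=gene_id,
        snp_ids=[f"{gene_id}_snp{i}" for i in range(n_snps)],
        genotype_counts=counts,
        depths=depth_lists,
    )
    return obs, true
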