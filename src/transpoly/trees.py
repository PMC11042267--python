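"""Allele-tree construction and the cophenetic concordance test.

To separate convergent same-site mutations from trans-specific haplotypes,
a distance tree is built from the phased haplotypes flanking each focal
shared polymorphism.  If the alleles predate the species split, haplotypes
cluster by allelic class rather than by species and the median pairwise
cophenetic distance (tip-to-tip path length) within species exceeds that
between species; CPD_within - CPD_between > 0 then flags a discordant
(allele-specific) topology, <= 0 a species-tree-concordant one.

Internal trees are neighbor joining on per-site-normalized mismatch
distances (deterministic, no external tools); externally computed Newick
trees can be ingested for fidelity to ML-based workflows.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .core import MISSING, GenotypeMatrix, SiteClassTable, SiteRecord

logger = logging.getLogger("transpoly")

__all__ = [
    "HaplotypeWindow",
    "LabeledTree",
    "CpdResult",
    "extract_window",
    "hap_distance_matrix",
    "nj_tree",
    "cophenetic",
    "cpd_statistic",
    "cpd_batch",
]


@dataclass
class HaplotypeWindow:
    """Phased haplotypes over the SNPs within +/- flank_bp of a focal site.

    Rows of ``haplotypes`` are haploid sequences over the window's SNP
    positions (0/1, -1 missing); each selected sample contributes two rows.
    """

    focal: SiteRecord
    flank_bp: int
    haplotypes: np.ndarray
    hap_ids: list[str]
    hap_species: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (len(self.hap_ids), len(self.positions)):
            raise ValueError("haplotype matrix shape mismatch")
        if len(self.hap_ids) % 2:
            raise ValueError("each sample must contribute exactly two haplotypes")


@dataclass
class LabeledTree:
    """A branch-length tree whose tips map to (haplotype, species)."""

    tree: TreeNode
    tip_species: dict[str, str]

    def __post_init__(self) -> None:
        tips = [t.name for t in self.tree.tips()]
        if len(tips) != len(set(tips)):
            raise ValueError("tip names must be unique")
        missing = [t for t in tips if t not in self.tip_species]
        if missing:
            raise ValueError(f"tips without species label: {missing[:5]}")

    @classmethod
    def from_newick(cls, newick: str, tip_species: dict[str, str]) -> "LabeledTree":
        tree = TreeNode.read(io.StringIO(newick), format="newick")
        return cls(tree=tree, tip_species=tip_species)

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()


@dataclass(slots=True)
class CpdResult:
    focal_id: str
    cpd_within: float
    cpd_between: float
    cpd_diff: float
    call: str
    per_species_within: dict


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def extract_window(
    gm: GenotypeMatrix,
    focal_index: int,
    flank_bp: int = 500,
    samples_per_species: int | None = 30,
    seed: int = 0,
    classes: SiteClassTable | None = None,
    maf_min: float = 0.25,
) -> HaplotypeWindow:
    """Haplotypes of the SNPs within +/- flank_bp of a focal shared SNP.

    Requires phased input.  Up to ``samples_per_species`` samples are chosen
    per species, highest mean depth first with a seeded tie-break.  A missing
    phase at one site leaves that haplotype position missing; the pair is
    retained.  When ``classes`` is given the focal site must be a shared
    polymorphism passing ``maf_min`` in both species.
    """
    if gm.phased_haplotypes is None:
        raise ValueError("extract_window requires phased haplotypes")
    focal = gm.sites[focal_index]
    if classes is not None:
        row = classes.frame.iloc[focal_index]
        if row["label"] != "shared_poly":
            raise ValueError(f"focal site {focal.chrom}:{focal.pos} is not a shared polymorphism")
        if not (row["maf_A"] > maf_min and row["maf_B"] > maf_min):
            raise ValueError(
                f"focal site {focal.chrom}:{focal.pos} fails the MAF>{maf_min} filter"
            )

    rng = np.random.default_rng(seed)
    depth = gm.sample_mean_depth()
    depth = np.where(np.isfinite(depth), depth, 0.0)
    chosen: list[int] = []
    for species in dict.fromkeys(s.species for s in gm.samples):
        idx = np.flatnonzero(gm.species_labels == species)
        order = np.lexsort((rng.random(len(idx)), -depth[idx]))
        take = idx[order] if samples_per_species is None else idx[order][:samples_per_species]
        chosen.extend(int(j) for j in np.sort(take))

    in_win = np.array(
        [
            s.chrom == focal.chrom and abs(s.pos - focal.pos) <= flank_bp
            for s in gm.sites
        ]
    )
    site_idx = np.flatnonzero(in_win)
    hap_ids, hap_species, rows = [], [], []
    for j in chosen:
        s = gm.samples[j]
        for h in (0, 1):
            hap_ids.append(f"{s.sample_id}_{h}")
            hap_species.append(s.species)
            rows.append(gm.phased_haplotypes[site_idx, 2 * j + h])
    return HaplotypeWindow(
        focal=focal,
        flank_bp=flank_bp,
        haplotypes=np.array(rows, dtype=np.int8),
        hap_ids=hap_ids,
        hap_species=hap_species,
        positions=np.array([gm.sites[i].pos for i in site_idx]),
    )


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def hap_distance_matrix(
    win: HaplotypeWindow,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Per-site-normalized mismatch distances between haplotypes.

    distance = mismatches / mutually non-missing positions; all-missing
    haplotypes are dropped (logged); pairs with zero overlap get NaN.
    Returns (matrix, haplotype ids, species labels) for the retained rows.
    """
    h = win.haplotypes
    keep = np.flatnonzero((h >= 0).any(axis=1)) if h.shape[1] else np.arange(len(h))
    dropped = len(h) - len(keep)
    if dropped:
        logger.info("hap_distance_matrix: dropped %d all-missing haplotypes", dropped)
    h = h[keep]
    if len(h) < 3:
        raise ValueError("need at least 3 haplotypes with data")
    valid = h >= 0
    n = len(h)
    d = np.zeros((n, n))
    for a in range(n):
        both = valid[a] & valid
        overlap = both.sum(axis=1)
        mism = ((h[a] != h) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(overlap > 0, mism / np.maximum(overlap, 1), np.nan)
        d[a] = row
    np.fill_diagonal(d, 0.0)
    ids = [win.hap_ids[i] for i in keep]
    species = [win.hap_species[i] for i in keep]
    return d, ids, species


def nj_tree(
    dm: np.ndarray, labels: dict[str, str] | list[tuple[str, str]]
) -> LabeledTree:
    """Neighbor-joining tree from a distance matrix (negative branches clamped).

    ``labels`` maps tip name -> species, in matrix row order when given as a
    list of (tip, species) pairs.  Missing (NaN) distances are an error:
    impute or drop the offending pairs first.
    """
    if not isinstance(labels, dict):
        labels = dict(labels)
    ids = list(labels.keys())
    dm = np.asarray(dm, dtype=float)
    if len(ids) != dm.shape[0]:
        raise ValueError("label count disagrees with matrix size")
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 tips")
    if not np.isfinite(dm).all():
        raise ValueError(
            "distance matrix has missing entries; impute them or remove the pairs"
        )
    tree = _skbio_nj(DistanceMatrix(dm, ids))
    return LabeledTree(tree=tree, tip_species=dict(labels))


def cophenetic(tree: LabeledTree) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length (cophenetic) distance matrix."""
    tips = [t.name for t in tree.tree.tips()]
    dm = tree.tree.tip_tip_distances(tips)
    return np.asarray(dm.data, dtype=float), tips


# ---------------------------------------------------------------------------
# the concordance statistic
# ---------------------------------------------------------------------------

def cpd_statistic(tree: LabeledTree, focal_id: str = "") -> CpdResult:
    """Median within- vs between-species cophenetic distance and the call.

    Within-species pairs are pooled across species before taking the median
    (per-species medians are reported alongside).  cpd_diff > 0 calls the
    tree discordant (allele-specific topology); <= 0 concordant.
    """
    d, tips = cophenetic(tree)
    species = np.array([tree.tip_species[t] for t in tips])
    uniq = list(dict.fromkeys(species))
    if len(uniq) < 2:
        raise ValueError("cpd_statistic needs tips from at least 2 species")
    for sp in uniq:
        if (species == sp).sum() < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 tips")
    iu, ju = np.triu_indices(len(tips), k=1)
    same = species[iu] == species[ju]
    within = d[iu[same], ju[same]]
    between = d[iu[~same], ju[~same]]
    per_species = {
        sp: float(np.median(d[iu, ju][same & (species[iu] == sp)]))
        for sp in uniq
    }
    cw = float(np.median(within))
    cb = float(np.median(between))
    diff = cw - cb
    return CpdResult(
        focal_id=focal_id,
        cpd_within=cw,
        cpd_between=cb,
        cpd_diff=diff,
        call="discordant" if diff > 0 else "concordant",
        per_species_within=per_species,
    )


def cpd_batch(
    gm: GenotypeMatrix,
    classes: SiteClassTable,
    maf_min: float = 0.25,
    annotations: tuple[str, ...] = ("NS",),
    flank_bp: int = 500,
    samples_per_species: int | None = 30,
    seed: int = 0,
    external_trees: dict[str, LabeledTree] | None = None,
) -> pd.DataFrame:
    """CPD statistic at every qualifying focal site, shared plus controls.

    Focal sites are shared polymorphisms with the requested annotation and
    within-species MAF > ``maf_min`` in both species; the control set is the
    non-shared (private) polymorphisms of the same annotation passing the MAF
    threshold in their polymorphic species.  ``external_trees`` (keyed by
    "chrom:pos") substitutes externally built trees for the internal NJ ones.
    """
    df = classes.frame
    is_ann = df["annotation"].isin(annotations)
    shared = (df["label"] == "shared_poly") & is_ann
    shared &= (df["maf_A"] > maf_min) & (df["maf_B"] > maf_min)
    control = df["label"].isin(["private_A", "private_B"]) & is_ann
    control &= np.maximum(df["maf_A"], df["maf_B"]) > maf_min

    focal_idx = np.concatenate([np.flatnonzero(shared), np.flatnonzero(control)])
    flags = [True] * int(shared.sum()) + [False] * int(control.sum())
    if len(focal_idx) == 0:
        logger.warning("cpd_batch: no qualifying focal sites")
        return pd.DataFrame(
            columns=["chrom", "pos", "shared", "cpd_within", "cpd_between", "cpd_diff", "call"]
        )

    rows = []
    for i, is_shared in zip(focal_idx, flags):
        site = gm.sites[int(i)]
        key = f"{site.chrom}:{site.pos}"
        try:
            if external_trees and key in external_trees:
                res = cpd_statistic(external_trees[key], focal_id=key)
            else:
                win = extract_window(
                    gm,
                    int(i),
                    flank_bp=flank_bp,
                    samples_per_species=samples_per_species,
                    seed=seed,
                )
                d, ids, species = hap_distance_matrix(win)
                tree = nj_tree(d, list(zip(ids, species)))
                res = cpd_statistic(tree, focal_id=key)
        except ValueError as exc:
            logger.info("cpd_batch: skipping %s (%s)", key, exc)
            continue
        rows.append(
            {
                "chrom": site.chrom,
                "pos": site.pos,
                "shared": is_shared,
                "cpd_within": res.cpd_within,
                "cpd_between": res.cpd_between,
                "cpd_diff": res.cpd_diff,
                "call": res.call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "shared", "cpd_within", "cpd_between", "cpd_diff", "call"],
    )
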