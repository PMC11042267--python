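"""Diversity, divergence, the neutral ILS expectation, and the folded joint SFS.

The neutral expectation for the number of shared polymorphisms between two
species descends from the classic ancestral-retention argument: a site is
polymorphic in both descendants either because the polymorphism predates the
split and survived drift in both lineages, or (excluded here) through
migration.  With within-species diversities pi_A, pi_B and between-species
divergence d_xy, the per-site probability is approximated by

    pi_A * pi_B * exp(-(2*d_xy - pi_A - pi_B) / max(pi_A, pi_B))

where the exponent is a proxy for the split time measured in within-species
coalescent units: E[2*d_xy - pi_A - pi_B] = 4*mu*T and max(pi_A, pi_B) =
4*mu*N for the larger population, so the exponent estimates T/N.

The two-dimensional folded SFS is projected to a smaller sample size by
hypergeometric expectation, the standard device for handling missing data,
and compared cell-wise between an empirical and a model spectrum via
standardized residuals (E - M) / sqrt(M).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import GenotypeMatrix

__all__ = [
    "DiversityStats",
    "JointSFS",
    "DemographicUnits",
    "diversity",
    "dxy",
    "diversity_stats",
    "IlsExpectation",
    "expected_shared_ils",
    "projection_weights",
    "joint_sfs",
    "count_shared_sfs",
    "sfs_residuals",
    "convert_units",
    "invert_units",
]


@dataclass(slots=True)
class DiversityStats:
    """Per-site diversities and divergence over a common site set."""

    pi_A: float
    pi_B: float
    dxy: float
    n_sites: int


@dataclass(slots=True)
class DemographicUnits:
    """Split-with-migration parameters in coalescent units.

    eta_A / eta_B are population sizes relative to the ancestral size, tau is
    the split time in units of 2*N_anc generations, M the scaled migration
    rate (2*N_anc*m), mu the per-site per-generation mutation rate.
    """

    eta_A: float
    eta_B: float
    tau: float
    M: float
    N_anc: float
    mu: float = 5.69e-9

    def __post_init__(self) -> None:
        for name in ("eta_A", "eta_B", "N_anc", "mu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau < 0 or self.M < 0:
            raise ValueError("tau and M must be non-negative")


# ---------------------------------------------------------------------------
# diversity and divergence
# ---------------------------------------------------------------------------

def diversity(gm: GenotypeMatrix, species: str) -> tuple[float, int]:
    """Average per-site nucleotide diversity pi within a species.

    Per site: 2*p*q * n/(n-1) with n the non-missing allele count (the
    unbiased pairwise estimator); averaged over all sites with n >= 2,
    monomorphic sites contributing zero.
    """
    alt, n = gm.allele_counts(species)
    use = n >= 2
    if not use.any():
        raise ValueError(f"no usable sites for species {species!r}")
    p = alt[use] / n[use]
    per_site = 2 * p * (1 - p) * n[use] / (n[use] - 1)
    return float(per_site.mean()), int(use.sum())


def dxy(gm: GenotypeMatrix, species_A: str, species_B: str) -> tuple[float, int]:
    """Average per-site pairwise divergence D_xy between two species."""
    alt_A, n_A = gm.allele_counts(species_A)
    alt_B, n_B = gm.allele_counts(species_B)
    use = (n_A >= 1) & (n_B >= 1)
    if not use.any():
        raise ValueError("no sites with calls in both species")
    pA = alt_A[use] / n_A[use]
    pB = alt_B[use] / n_B[use]
    per_site = pA * (1 - pB) + pB * (1 - pA)
    return float(per_site.mean()), int(use.sum())


def diversity_stats(
    gm: GenotypeMatrix,
    species_A: str,
    species_B: str,
    n_total_sites: int | None = None,
) -> DiversityStats:
    """pi_A, pi_B and d_xy computed over the common usable site set.

    When the matrix holds only the segregating sites of a longer surveyed
    sequence, pass the surveyed length as ``n_total_sites``: invariant sites
    contribute zero to every per-site sum, so the averages are rescaled to
    the per-bp values the ILS expectation needs.
    """
    alt_A, n_A = gm.allele_counts(species_A)
    alt_B, n_B = gm.allele_counts(species_B)
    use = (n_A >= 2) & (n_B >= 2)
    if not use.any():
        raise ValueError("no sites with >=2 alleles in both species")
    denom = int(use.sum()) if n_total_sites is None else int(n_total_sites)
    if denom <= 0:
        raise ValueError("n_total_sites must be positive")
    pA = alt_A[use] / n_A[use]
    pB = alt_B[use] / n_B[use]
    pi_A = float((2 * pA * (1 - pA) * n_A[use] / (n_A[use] - 1)).sum() / denom)
    pi_B = float((2 * pB * (1 - pB) * n_B[use] / (n_B[use] - 1)).sum() / denom)
    d = float((pA * (1 - pB) + pB * (1 - pA)).sum() / denom)
    return DiversityStats(pi_A=pi_A, pi_B=pi_B, dxy=d, n_sites=denom)


# ---------------------------------------------------------------------------
# neutral ILS expectation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class IlsExpectation:
    expected_count: float
    per_site_probability: float
    exponent: float
    retention_probability: float
    n_sites: int


def expected_shared_ils(div: DiversityStats) -> IlsExpectation:
    """Expected shared polymorphisms under neutrality without migration.

    Returns the count L * pi_A * pi_B * exp(-(2*dxy - pi_A - pi_B) /
    max(pi_A, pi_B)) together with the per-site probability and the exponent
    (split-time proxy in within-species coalescent units) for audit.
    """
    if max(div.pi_A, div.pi_B) <= 0:
        raise ValueError("expected_shared_ils requires positive diversity")
    if div.dxy < (div.pi_A + div.pi_B) / 2:
        warnings.warn(
            "dxy < (pi_A + pi_B)/2: negative split-time proxy; "
            "the ILS expectation is unreliable",
            stacklevel=2,
        )
    exponent = (2 * div.dxy - div.pi_A - div.pi_B) / max(div.pi_A, div.pi_B)
    retention = math.exp(-exponent)
    per_site = div.pi_A * div.pi_B * retention
    return IlsExpectation(
        expected_count=div.n_sites * per_site,
        per_site_probability=per_site,
        exponent=exponent,
        retention_probability=retention,
        n_sites=div.n_sites,
    )


# ---------------------------------------------------------------------------
# joint SFS
# ---------------------------------------------------------------------------

@dataclass
class JointSFS:
    """Folded two-dimensional site-frequency spectrum.

    ``data`` is a (n_A+1, n_B+1) matrix of (possibly fractional) site counts;
    ``mask`` flags cells excluded from analysis: the monomorphic corners and,
    when folded, the redundant majority-orientation half.
    """

    data: np.ndarray
    mask: np.ndarray
    n_proj_A: int
    n_proj_B: int
    folded: bool
    n_sites_used: int = 0
    n_sites_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != (self.n_proj_A + 1, self.n_proj_B + 1):
            raise ValueError("SFS shape inconsistent with projection sizes")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape mismatch")
        if (self.data[~self.mask] < -1e-9).any():
            raise ValueError("negative SFS entries")

    @property
    def segregating_mass(self) -> float:
        return float(self.data[~self.mask].sum())

    # dadi-style text layout: header "nA nB folded/unfolded", then the
    # row-major flattened values, then the flattened mask as 0/1.
    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"{self.n_proj_A + 1} {self.n_proj_B + 1} "
                f"{'folded' if self.folded else 'unfolded'}\n"
            )
            fh.write(" ".join(f"{v:.10g}" for v in self.data.ravel()) + "\n")
            fh.write(" ".join("1" if m else "0" for m in self.mask.ravel()) + "\n")

    @classmethod
    def from_file(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            shape = (int(header[0]), int(header[1]))
            folded = header[2] == "folded"
            data = np.array(fh.readline().split(), dtype=float).reshape(shape)
            mask = np.array(fh.readline().split(), dtype=int).astype(bool).reshape(shape)
        return cls(
            data=data,
            mask=mask,
            n_proj_A=shape[0] - 1,
            n_proj_B=shape[1] - 1,
            folded=folded,
        )


def projection_weights(k: int, n: int, n_proj: int) -> np.ndarray:
    """Hypergeometric projection of an allele count: exact subsampling law.

    Entry i is the probability that a random subsample of ``n_proj`` of the
    ``n`` alleles contains i copies of the allele observed ``k`` times:
    C(k, i) * C(n-k, n_proj-i) / C(n, n_proj).  Computed with exact integer
    binomials so the law agrees to the last float with exhaustive enumeration.
    """
    if not 0 <= k <= n or n_proj > n or n_proj < 0:
        raise ValueError("invalid projection configuration")
    denom = math.comb(n, n_proj)
    w = np.zeros(n_proj + 1)
    for i in range(max(0, n_proj - (n - k)), min(k, n_proj) + 1):
        w[i] = math.comb(k, i) * math.comb(n - k, n_proj - i) / denom
    return w


def _fold_joint(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fold a joint SFS on the globally minor allele (dadi convention)."""
    nA = data.shape[0] - 1
    nB = data.shape[1] - 1
    i = np.arange(nA + 1)[:, None]
    j = np.arange(nB + 1)[None, :]
    tot = 2 * (i + j)  # orientation by total count across both projections
    half = nA + nB
    rev = data[::-1, ::-1]
    folded = np.where(tot < half, data + rev, np.where(tot == half, (data + rev) / 2, 0.0))
    mask = tot > half
    return folded, mask


def joint_sfs(
    gm: GenotypeMatrix,
    species_A: str,
    species_B: str,
    proj: tuple[int, int] = (20, 20),
    folded: bool = True,
    mode: str = "expectation",
    seed: int | None = None,
) -> JointSFS:
    """Folded joint SFS of two species with hypergeometric projection.

    Sites where a species has fewer non-missing alleles than its projection
    size are dropped (counted).  In ``expectation`` mode each site deposits
    its exact subsampling probability mass (deterministic); ``sample`` mode
    draws one hypergeometric subsample per site (seeded).  The monomorphic
    corners are masked; for the folded spectrum the redundant half is too.
    """
    nA, nB = proj
    alt_A, tot_A = gm.allele_counts(species_A)
    alt_B, tot_B = gm.allele_counts(species_B)
    usable = (tot_A >= nA) & (tot_B >= nB)
    if not usable.any():
        raise ValueError("projection size exceeds every site's allele count")
    n_dropped = int((~usable).sum())

    data = np.zeros((nA + 1, nB + 1))
    if mode == "expectation":
        cache: dict[tuple[int, int, int], np.ndarray] = {}

        def weights(k: int, n: int, n_proj: int) -> np.ndarray:
            key = (k, n, n_proj)
            if key not in cache:
                cache[key] = projection_weights(k, n, n_proj)
            return cache[key]

        for k_a, n_a, k_b, n_b in zip(
            alt_A[usable], tot_A[usable], alt_B[usable], tot_B[usable]
        ):
            data += np.outer(weights(int(k_a), int(n_a), nA), weights(int(k_b), int(n_b), nB))
    elif mode == "sample":
        rng = np.random.default_rng(seed)
        i = rng.hypergeometric(alt_A[usable], tot_A[usable] - alt_A[usable], nA)
        j = rng.hypergeometric(alt_B[usable], tot_B[usable] - alt_B[usable], nB)
        np.add.at(data, (i, j), 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if folded:
        data, fold_mask = _fold_joint(data)
        mask = fold_mask
    else:
        mask = np.zeros_like(data, dtype=bool)
    mask = mask.copy()
    mask[0, 0] = True
    mask[-1, -1] = True
    return JointSFS(
        data=data,
        mask=mask,
        n_proj_A=nA,
        n_proj_B=nB,
        folded=folded,
        n_sites_used=int(usable.sum()),
        n_sites_dropped=n_dropped,
    )


def count_shared_sfs(sfs: JointSFS, min_count: int = 1) -> tuple[int, float]:
    """Shared-polymorphism cells of a folded joint SFS and their summed mass.

    A shared polymorphism is an allele at frequency strictly above
    ``min_count / n_proj`` in both species, i.e. projected count
    > ``min_count`` on each axis (the 1/20 rule with a 20-projection).
    Returns (number of contributing unmasked cells, summed mass).
    """
    if not sfs.folded:
        raise ValueError("count_shared_sfs expects a folded SFS")
    sel = np.zeros_like(sfs.mask)
    sel[min_count + 1 :, min_count + 1 :] = True
    sel &= ~sfs.mask
    cells = sel & (sfs.data > 0)
    return int(cells.sum()), float(sfs.data[sel].sum())


def sfs_residuals(empirical: JointSFS, model: JointSFS) -> np.ndarray:
    """Cell-wise standardized residuals (Empirical - Model) / sqrt(Model).

    Cells with Model = Empirical = 0 give 0; Model = 0 with Empirical > 0
    give +inf (flagged to the caller by the value itself).  Masked cells are
    NaN and excluded from any summary.
    """
    if empirical.data.shape != model.data.shape:
        raise ValueError("SFS shape mismatch")
    if not np.array_equal(empirical.mask, model.mask):
        raise ValueError("SFS mask mismatch")
    if (model.data[~model.mask] < 0).any():
        raise ValueError("model SFS has negative cells")
    e, m = empirical.data, model.data
    with np.errstate(invalid="ignore", divide="ignore"):
        res = (e - m) / np.sqrt(m)
    res[(m == 0) & (e == 0)] = 0.0
    res[(m == 0) & (e > 0)] = np.inf
    res[empirical.mask] = np.nan
    return res


# ---------------------------------------------------------------------------
# unit conversion
# ---------------------------------------------------------------------------

def convert_units(units: DemographicUnits) -> dict[str, float]:
    """Coalescent-unit parameters to physical sizes, generations and rates.

    N_A = N_anc*eta_A, N_B = N_anc*eta_B, t_split = 2*N_anc*tau generations,
    m = M / (2*N_anc) per generation.
    """
    return {
        "N_A": units.N_anc * units.eta_A,
        "N_B": units.N_anc * units.eta_B,
        "t_split_generations": 2 * units.N_anc * units.tau,
        "m_per_gen": units.M / (2 * units.N_anc),
    }


def invert_units(
    physical: dict[str, float], N_anc: float, mu: float = 5.69e-9
) -> DemographicUnits:
    """Inverse of :func:`convert_units`; convert -> invert round-trips."""
    if N_anc <= 0:
        raise ValueError("N_anc must be positive")
    return DemographicUnits(
        eta_A=physical["N_A"] / N_anc,
        eta_B=physical["N_B"] / N_anc,
        tau=physical["t_split_generations"] / (2 * N_anc),
        M=physical["m_per_gen"] * 2 * N_anc,
        N_anc=N_anc,
        mu=mu,
    )
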