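"""Data model, VCF round-trip, filtering, classification, MLG and QC stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transpoly import core
from transpoly.core import (
    GenotypeMatrix,
    assign_mlg,
    allele_balance_qc,
    classify_sites,
    filter_sites,
    genotype_mismatch,
    het_at_fixed_differences,
    mlg_representatives,
    pairwise_r2,
    read_vcf,
    write_sample_table,
    write_vcf,
)

from conftest import make_gm


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

VCF_TEXT = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##contig=<ID=chr1,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2
chr1\t100\t.\tA\tT\t.\t.\t.\tGT:AD\t0/0:9,0\t0/1:5,4
chr1\t200\t.\tC\tG\t.\t.\t.\tGT:AD\t0|1:6,6\t1/1:0,11
chr1\t300\t.\tG\tT,C\t.\t.\t.\tGT:AD\t0/1:3,3\t0/0:8,0
chr1\t400\t.\tT\tA\t.\t.\t.\tGT:AD\t1|0:4,5\t./.:.,.
"""


@pytest.fixture
def vcf_file(tmp_path):
    p = tmp_path / "test.vcf"
    p.write_text(VCF_TEXT)
    t = tmp_path / "samples.tsv"
    t.write_text("sample_id\tspecies\tpopulation\ns1\tA_sp\tp1\ns2\tB_sp\tp2\n")
    return p, t


def test_read_vcf_dosage_encoding_and_multiallelic_skip(vcf_file):
    vcf, table = vcf_file
    gm = read_vcf(vcf, str(table))
    # the multiallelic row chr1:300 is skipped
    assert gm.n_sites == 3
    assert gm.n_skipped_records == 1
    assert [s.pos for s in gm.sites] == [100, 200, 400]
    assert gm.genotypes.tolist() == [[0, 1], [1, 2], [1, -1]]
    # AD captured
    assert gm.allele_depths[0, 1].tolist() == [5, 4]
    # pipe-separated genotypes populate phased haplotypes; "/" calls stay missing
    assert gm.phased_haplotypes[1, 0:2].tolist() == [0, 1]
    assert gm.phased_haplotypes[0, 0:2].tolist() == [-1, -1]
    assert gm.phased_haplotypes[2, 0:2].tolist() == [1, 0]


def test_read_vcf_unknown_sample_is_hard_error(vcf_file, tmp_path):
    vcf, _ = vcf_file
    t = tmp_path / "bad.tsv"
    t.write_text("sample_id\tspecies\tpopulation\ns1\tA_sp\tp1\n")
    with pytest.raises(ValueError, match="s2"):
        read_vcf(vcf, str(t))


def test_vcf_round_trip_exact(vcf_file, tmp_path):
    vcf, table = vcf_file
    gm = read_vcf(vcf, str(table))
    out = tmp_path / "rt.vcf"
    write_vcf(gm, out)
    gm2 = read_vcf(out, str(table))
    assert np.array_equal(gm.genotypes, gm2.genotypes)
    assert np.array_equal(gm.phased_haplotypes, gm2.phased_haplotypes)
    assert np.array_equal(gm.allele_depths, gm2.allele_depths)
    assert [(s.chrom, s.pos, s.ref, s.alt) for s in gm.sites] == [
        (s.chrom, s.pos, s.ref, s.alt) for s in gm2.sites
    ]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def test_filter_sites_depth_and_missingness_bounds():
    # 20 samples, 30 sites: site 0 depth 40 (too high), site 2 depth 5 (too
    # low), site 3 has 3/20 calls missing (0.15 > 0.10); every sample's own
    # missingness stays low so the sample filter is inert
    g = np.ones((30, 20), dtype=np.int8)
    g[3, :3] = -1
    depths = [20.0] * 30
    depths[0], depths[2] = 40.0, 5.0
    gm = make_gm(g, species=["A_sp"] * 10 + ["B_sp"] * 10, mean_depths=depths)
    out, report = filter_sites(gm, max_missing=0.10, depth_lo=8, depth_hi=35)
    assert report.n_sites_removed_depth == 2
    assert report.n_sites_removed_missing == 1
    assert report.n_samples_removed == 0
    kept = [s.pos for s in out.sites]
    assert 1 not in kept and 3 not in kept and 4 not in kept
    assert out.n_sites == 27


def test_filter_sites_removes_high_missing_samples_first():
    g = np.zeros((10, 4), dtype=np.int8)
    g[:5, 0] = -1  # sample 0: 50% missing
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp"], mean_depths=[20.0] * 10)
    out, report = filter_sites(gm, max_missing=0.10)
    assert report.removed_samples == ["s000"]
    # with the bad sample gone, no site exceeds missingness
    assert out.n_sites == 10 and out.n_samples == 3


def test_filter_sites_idempotent():
    rng = np.random.default_rng(0)
    g = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
    g[rng.random(g.shape) < 0.05] = -1
    depths = rng.uniform(5, 40, size=200)
    gm = make_gm(g, species=["A_sp"] * 10 + ["B_sp"] * 10, mean_depths=depths)
    once, _ = filter_sites(gm)
    twice, rep2 = filter_sites(once)
    assert twice.n_sites == once.n_sites
    assert twice.n_samples == once.n_samples


def test_filter_sites_empty_result_warns_not_raises():
    gm = make_gm(np.ones((2, 4), dtype=np.int8),
                 species=["A_sp", "A_sp", "B_sp", "B_sp"], mean_depths=[50.0, 50.0])
    with pytest.warns(UserWarning, match="every site"):
        out, _ = filter_sites(gm)
    assert out.n_sites == 0


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _freq_gm(freq_pairs, n_per_species=100):
    """Sites with prescribed exact alt frequencies in two species."""
    rows = []
    for fA, fB in freq_pairs:
        row = []
        for f, n in ((fA, n_per_species), (fB, n_per_species)):
            alt = int(round(f * 2 * n))
            dosages = [2] * (alt // 2) + [1] * (alt % 2)
            dosages += [0] * (n - len(dosages))
            row.extend(dosages)
        rows.append(row)
    return make_gm(
        np.array(rows, dtype=np.int8),
        species=["A_sp"] * n_per_species + ["B_sp"] * n_per_species,
    )


@pytest.mark.parametrize(
    "fA,fB,label",
    [
        (0.3, 0.2, "shared_poly"),
        (1.0, 0.0, "fixed_diff"),
        (0.0, 1.0, "fixed_diff"),
        (0.005, 0.3, "private_B"),
        (0.5, 0.0, "private_A"),
        (0.0, 0.0, "monomorphic"),
        (1.0, 1.0, "monomorphic"),
        (0.995, 0.3, "private_B"),  # near-fixation is not a fixed difference
    ],
)
def test_classify_sites_examples(fA, fB, label):
    gm = _freq_gm([(fA, fB)])
    classes = classify_sites(gm, "A_sp", "B_sp", maf_min=0.01)
    assert classes.frame["label"].iloc[0] == label


def test_classify_unassessable_species_flagged():
    g = np.array([[1, 1, -1, -1]], dtype=np.int8)
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp"])
    classes = classify_sites(gm, "A_sp", "B_sp")
    assert classes.frame["label"].iloc[0] == "monomorphic"
    assert bool(classes.frame["unassessable"].iloc[0])


def test_classify_unknown_species_is_error(two_species_gm):
    with pytest.raises(ValueError, match="unknown species"):
        classify_sites(two_species_gm, "A_sp", "nope")


@given(
    st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=20), st.integers(min_value=0, max_value=20)
        ),
        min_size=1,
        max_size=30,
    )
)
def test_classify_partition_and_species_swap_symmetry(counts):
    """Labels partition sites; swapping species exchanges the private labels."""
    rows = []
    for kA, kB in counts:
        row = [2] * (kA // 2) + [1] * (kA % 2)
        row += [0] * (10 - len(row))
        rowB = [2] * (kB // 2) + [1] * (kB % 2)
        rowB += [0] * (10 - len(rowB))
        rows.append(row + rowB)
    gm = make_gm(np.array(rows, dtype=np.int8), species=["A_sp"] * 10 + ["B_sp"] * 10)
    fwd = classify_sites(gm, "A_sp", "B_sp")
    rev = classify_sites(gm, "B_sp", "A_sp")
    assert sum(fwd.counts().values()) == gm.n_sites
    swap = {"private_A": "private_B", "private_B": "private_A"}
    for lf, lr in zip(fwd.frame["label"], rev.frame["label"]):
        assert lr == swap.get(lf, lf)


# ---------------------------------------------------------------------------
# MLG
# ---------------------------------------------------------------------------

def test_assign_mlg_identity_classes():
    g = np.array(
        [[0, 0, 2, 1], [1, 1, 0, 2], [2, 2, 1, 0], [0, 0, 2, 2]], dtype=np.int8
    )
    gm = make_gm(g, species=["A_sp"] * 4)
    out = assign_mlg(gm, max_mismatch=0.0)
    ids = [s.mlg_id for s in out.samples]
    assert ids[0] == ids[1]
    assert len({ids[0], ids[2], ids[3]}) == 3


def test_mlg_representative_highest_depth_with_lexicographic_ties():
    g = np.zeros((4, 3), dtype=np.int8)
    ad = np.zeros((4, 3, 2), dtype=np.int32)
    ad[:, 0] = (4, 4)   # s000 depth 8
    ad[:, 1] = (10, 5)  # s001 depth 15 (highest)
    ad[:, 2] = (10, 5)  # s002 depth 15 (tie -> s001 by id)
    gm = make_gm(g, species=["A_sp"] * 3, allele_depths=ad)
    out = assign_mlg(gm)
    assert mlg_representatives(out) == ["s001"]


def test_genotype_mismatch_uses_mutual_overlap():
    g = np.array([[0, 0], [1, -1], [2, 0]], dtype=np.int8)
    gm = make_gm(g, species=["A_sp", "A_sp"])
    assert genotype_mismatch(gm, 0, 1) == pytest.approx(0.5)  # 2 shared sites, 1 differs


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------

def test_allele_balance_symmetric_and_biased():
    g = np.ones((50, 4), dtype=np.int8)  # all het
    ad = np.zeros((50, 4, 2), dtype=np.int32)
    ad[:, :2] = (10, 10)  # species A perfectly balanced
    ad[:, 2:] = (8, 2)    # species B ref-biased
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp"], allele_depths=ad)
    res = allele_balance_qc(gm, n_sites=50, n_boot=50, seed=0)
    assert res["A_sp"].mean_ref_fraction == pytest.approx(0.5)
    assert res["A_sp"].ci_low == pytest.approx(0.5)
    assert res["B_sp"].mean_ref_fraction == pytest.approx(0.8)
    # seeded determinism
    res2 = allele_balance_qc(gm, n_sites=50, n_boot=50, seed=0)
    assert res["B_sp"].ci_low == res2["B_sp"].ci_low


def test_het_at_fixed_differences_fraction():
    # 10 fixed differences; test sample heterozygous at 7
    g = np.zeros((10, 5), dtype=np.int8)
    g[:, :2] = 0      # species A fixed ref
    g[:, 2:4] = 2     # species B fixed alt
    g[:7, 4] = 1      # test sample het at 7, hom at 3
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp", "C_sp"])
    classes = classify_sites(gm, "A_sp", "B_sp")
    assert (classes.frame["label"] == "fixed_diff").all()
    assert het_at_fixed_differences(gm, classes, "s004") == pytest.approx(0.7)


def test_pairwise_r2_examples():
    # identical vectors, mirrored vectors, and a hand-computed pair
    g = np.array(
        [
            [0, 1, 2, 1],
            [0, 1, 2, 1],
            [2, 1, 0, 1],
            [0, 2, 1, 1],
        ],
        dtype=np.int8,
    )
    gm = make_gm(g, species=["A_sp"] * 4, positions=[10, 20, 30, 40])
    r2, kept = pairwise_r2(gm, "chr1", 1, 100, "A_sp", maf_min=0.01)
    assert np.allclose(np.diag(r2), 1.0)
    assert r2[0, 1] == pytest.approx(1.0)
    assert r2[0, 2] == pytest.approx(1.0)  # sign-invariance
    expected = np.corrcoef([0, 1, 2, 1], [0, 2, 1, 1])[0, 1] ** 2
    assert r2[0, 3] == pytest.approx(expected)


def test_pairwise_r2_excludes_monomorphic():
    g = np.array([[0, 1, 2, 1], [0, 0, 0, 0], [0, 1, 2, 1]], dtype=np.int8)
    gm = make_gm(g, species=["A_sp"] * 4, positions=[10, 20, 30])
    r2, kept = pairwise_r2(gm, "chr1", 1, 100, "A_sp")
    assert list(kept) == [0, 2]


def test_sample_table_round_trip(tmp_path, two_species_gm):
    p = tmp_path / "samples.tsv"
    write_sample_table(two_species_gm.samples, p)
    table = core.read_sample_table(p)
    assert set(table) == set(two_species_gm.sample_ids)
    assert table["s000"].species == "A_sp"
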