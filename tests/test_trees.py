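"""Haplotype windows, NJ trees, cophenetic distances, CPD concordance calls."""

import numpy as np
import pytest

from transpoly.core import classify_sites
from transpoly.trees import (
    HaplotypeWindow,
    LabeledTree,
    cophenetic,
    cpd_statistic,
    extract_window,
    hap_distance_matrix,
    nj_tree,
)
from transpoly.core import SiteRecord

from conftest import make_gm


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

def _phased_gm(n_per_species=3, positions=(100, 400, 700, 1400)):
    n_sites = len(positions)
    n = 2 * n_per_species
    rng = np.random.default_rng(0)
    hap = rng.integers(0, 2, size=(n_sites, 2 * n)).astype(np.int8)
    geno = hap[:, 0::2] + hap[:, 1::2]
    return make_gm(
        geno,
        species=["A_sp"] * n_per_species + ["B_sp"] * n_per_species,
        positions=positions,
        phased=hap,
    )


def test_extract_window_haplotype_counts_and_span():
    gm = _phased_gm()
    win = extract_window(gm, focal_index=1, flank_bp=500, samples_per_species=2, seed=0)
    assert len(win.hap_ids) == 8  # 2 samples/species x 2 haplotypes x 2 species
    # flank 500 around pos 400 keeps 100, 400, 700 but not 1400
    assert win.positions.tolist() == [100, 400, 700]


def test_extract_window_unphased_is_hard_error():
    gm = _phased_gm()
    gm.phased_haplotypes = None
    with pytest.raises(ValueError, match="phased"):
        extract_window(gm, 0)


def test_extract_window_rejects_non_shared_focal():
    g = np.array([[2, 2, 0, 0]], dtype=np.int8)
    hap = np.array([[1, 1, 1, 1, 0, 0, 0, 0]], dtype=np.int8)
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp"], phased=hap)
    classes = classify_sites(gm, "A_sp", "B_sp")
    with pytest.raises(ValueError, match="shared"):
        extract_window(gm, 0, classes=classes)


def test_extract_window_missing_phase_kept_as_missing():
    gm = _phased_gm()
    gm.phased_haplotypes[1, 0] = -1
    gm.genotypes[1, 0] = -1
    win = extract_window(gm, 1, flank_bp=500, samples_per_species=None, seed=0)
    col = win.positions.tolist().index(400)
    assert (win.haplotypes[:, col] == -1).sum() == 1


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _window_from_haps(haps, species):
    haps = np.asarray(haps, dtype=np.int8)
    return HaplotypeWindow(
        focal=SiteRecord(chrom="c", pos=1, ref="A", alt="T"),
        flank_bp=500,
        haplotypes=haps,
        hap_ids=[f"h{i}_{j}" for i in range(len(haps) // 2) for j in (0, 1)],
        hap_species=species,
        positions=np.arange(1, haps.shape[1] + 1),
    )


def test_hap_distances_mismatch_over_overlap():
    win = _window_from_haps(
        [[0, 0, 1], [0, 1, 1], [0, -1, 1], [1, 0, -1]],
        species=["A_sp", "A_sp", "B_sp", "B_sp"],
    )
    d, ids, sp = hap_distance_matrix(win)
    assert d[0, 1] == pytest.approx(1 / 3)
    assert d[1, 2] == pytest.approx(0.0)  # (0,.,1) vs (0,1,1): 0 of 2 overlapping
    assert d[0, 3] == pytest.approx(1 / 2)  # overlap 2, one mismatch
    assert np.allclose(np.diag(d), 0.0)


def test_hap_distances_drop_all_missing_and_flag_zero_overlap():
    win = _window_from_haps(
        [[-1, -1], [0, 1], [1, -1], [-1, 0]],
        species=["A_sp", "A_sp", "B_sp", "B_sp"],
    )
    d, ids, sp = hap_distance_matrix(win)
    assert len(ids) == 3  # the all-missing haplotype is dropped
    assert np.isnan(d[ids.index("h1_0"), ids.index("h1_1")])


# ---------------------------------------------------------------------------
# NJ and cophenetic oracles
# ---------------------------------------------------------------------------

def _random_tree_distances(rng, n_tips):
    """Random binary tree with branch lengths; returns (dist matrix, newick)."""
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]
    paths = {f"t{i}": {f"t{i}": 0.0} for i in range(n_tips)}
    # agglomerate randomly, tracking tip-to-tip path lengths
    dist = {}
    members = [[f"t{i}"] for i in range(n_tips)]
    depth = {f"t{i}": 0.0 for i in range(n_tips)}
    newick = [f"t{i}" for i in range(n_tips)]
    heights = [0.0] * n_tips
    while len(members) > 1:
        i, j = sorted(rng.choice(len(members), size=2, replace=False))
        bi, bj = rng.uniform(0.1, 2.0), rng.uniform(0.1, 2.0)
        for a in members[i]:
            for b in members[j]:
                dist[(a, b)] = dist[(b, a)] = depth[a] + bi + depth[b] + bj
        for a in members[i]:
            depth[a] += bi
        for b in members[j]:
            depth[b] += bj
        members[i] = members[i] + members[j]
        newick[i] = f"({newick[i]}:{bi},{newick[j]}:{bj})"
        del members[j], newick[j]
    ids = [f"t{i}" for i in range(n_tips)]
    m = np.zeros((n_tips, n_tips))
    for a in range(n_tips):
        for b in range(n_tips):
            if a != b:
                m[a, b] = dist[(ids[a], ids[b])]
    return m, newick[0] + ";"


def test_nj_recovers_additive_metrics_exactly():
    rng = np.random.default_rng(42)
    for _ in range(40):
        n = int(rng.integers(4, 9))
        m, _ = _random_tree_distances(rng, n)
        labels = {f"t{i}": "A_sp" for i in range(n)}
        tree = nj_tree(m, labels)
        d, tips = cophenetic(tree)
        order = [tips.index(f"t{i}") for i in range(n)]
        assert np.allclose(d[np.ix_(order, order)], m, atol=1e-10)


def test_nj_three_taxa_closed_form():
    # three-point formulas: b_a = (d_ab + d_ac - d_bc)/2 etc.
    m = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
    tree = nj_tree(m, {"a": "x", "b": "x", "c": "x"})
    d, tips = cophenetic(tree)
    order = [tips.index(t) for t in ("a", "b", "c")]
    assert np.allclose(d[np.ix_(order, order)], m, atol=1e-10)


def test_nj_star_distances_zero_internal_branches():
    m = np.full((4, 4), 2.0)
    np.fill_diagonal(m, 0.0)
    tree = nj_tree(m, {f"t{i}": "x" for i in range(4)})
    d, tips = cophenetic(tree)
    off = d[~np.eye(4, dtype=bool)]
    assert np.allclose(off, 2.0, atol=1e-10)


def test_nj_missing_distance_errors():
    m = np.full((3, 3), 1.0)
    np.fill_diagonal(m, 0.0)
    m[0, 1] = m[1, 0] = np.nan
    with pytest.raises(ValueError, match="missing"):
        nj_tree(m, {"a": "x", "b": "x", "c": "x"})


def test_cophenetic_path_sums_match_brute_force():
    """Path-length distances equal brute-force sums on random trees <= 8 tips."""
    rng = np.random.default_rng(7)
    for _ in range(30):
        n = int(rng.integers(4, 9))
        m, newick = _random_tree_distances(rng, n)
        tree = LabeledTree.from_newick(newick, {f"t{i}": "x" for i in range(n)})
        d, tips = cophenetic(tree)
        order = [tips.index(f"t{i}") for i in range(n)]
        assert np.allclose(d[np.ix_(order, order)], m, atol=1e-10)


def test_cophenetic_four_point_condition():
    rng = np.random.default_rng(9)
    for _ in range(20):
        m, newick = _random_tree_distances(rng, 6)
        tree = LabeledTree.from_newick(newick, {f"t{i}": "x" for i in range(6)})
        d, tips = cophenetic(tree)
        idx = rng.choice(6, size=4, replace=False)
        a, b, c, e = idx
        sums = sorted([d[a, b] + d[c, e], d[a, c] + d[b, e], d[a, e] + d[b, c]])
        assert sums[1] == pytest.approx(sums[2], abs=1e-9)


def test_cophenetic_simple_newick():
    tree = LabeledTree.from_newick(
        "((A1:1,A2:1):1,(B1:1,B2:1):1);",
        {"A1": "A_sp", "A2": "A_sp", "B1": "B_sp", "B2": "B_sp"},
    )
    d, tips = cophenetic(tree)
    g = lambda a, b: d[tips.index(a), tips.index(b)]
    assert g("A1", "A2") == pytest.approx(2.0)
    assert g("A1", "B1") == pytest.approx(4.0)


# ---------------------------------------------------------------------------
# CPD statistic
# ---------------------------------------------------------------------------

SPECIES_4 = {"A1": "A_sp", "A2": "A_sp", "B1": "B_sp", "B2": "B_sp"}


def test_cpd_concordant_worked_example():
    tree = LabeledTree.from_newick("((A1:1,A2:1):1,(B1:1,B2:1):1);", SPECIES_4)
    res = cpd_statistic(tree)
    assert res.cpd_within == pytest.approx(2.0)
    assert res.cpd_between == pytest.approx(4.0)
    assert res.cpd_diff == pytest.approx(-2.0)
    assert res.call == "concordant"


def test_cpd_discordant_worked_example():
    tree = LabeledTree.from_newick("((A1:1,B1:1):1,(A2:1,B2:1):1);", SPECIES_4)
    res = cpd_statistic(tree)
    assert res.cpd_within == pytest.approx(4.0)
    assert res.cpd_between == pytest.approx(3.0)
    assert res.cpd_diff == pytest.approx(1.0)
    assert res.call == "discordant"


def test_cpd_single_species_errors():
    tree = LabeledTree.from_newick(
        "((A1:1,A2:1):1,(A3:1,A4:1):1);", {f"A{i}": "A_sp" for i in range(1, 5)}
    )
    with pytest.raises(ValueError, match="2 species"):
        cpd_statistic(tree)


def test_cpd_invariant_to_tip_relabeling_within_species():
    t1 = LabeledTree.from_newick("((A1:1,B1:2):1,(A2:3,B2:1):2);", SPECIES_4)
    # exchange the names of the two A tips: same statistic
    t2 = LabeledTree.from_newick("((A2:1,B1:2):1,(A1:3,B2:1):2);", SPECIES_4)
    r1, r2 = cpd_statistic(t1), cpd_statistic(t2)
    assert r1.cpd_diff == pytest.approx(r2.cpd_diff)


def test_cpd_batch_runs_shared_and_control_sites():
    from transpoly.simulate import DemographyConfig, ScenarioSpec, inject_scenario, simulate_split
    from transpoly.trees import cpd_batch

    cfg = DemographyConfig(
        N_anc=500.0, N_A=500.0, N_B=500.0, t_split=3000.0, m=0.0, mu=2e-6,
        n_samples_A=6, n_samples_B=6, L=1, window_bp=1000, seed=31,
    )
    gm, _ = simulate_split(cfg)
    out, truth = inject_scenario(gm, ScenarioSpec(kind="trans_specific"), seed=2)
    classes = classify_sites(out, "NAm_pulex", "Euro_pulex")
    table = cpd_batch(out, classes, maf_min=0.25, annotations=("NS",),
                      flank_bp=1000, samples_per_species=None, seed=0)
    assert len(table) >= 13  # every injected class SNP qualifies as focal
    assert set(table.columns) >= {"shared", "cpd_diff", "call"}
    shared_rows = table[table["shared"]]
    assert (shared_rows["cpd_diff"] > 0).all()  # trans-specific window


def test_cpd_batch_empty_when_nothing_qualifies():
    from transpoly.trees import cpd_batch

    g = np.array([[1, 1, 1, 1]], dtype=np.int8)
    hap = np.array([[0, 1, 0, 1, 0, 1, 0, 1]], dtype=np.int8)
    gm = make_gm(g, species=["A_sp", "A_sp", "B_sp", "B_sp"],
                 annotations=["SYN"], phased=hap)
    classes = classify_sites(gm, "A_sp", "B_sp")
    table = cpd_batch(gm, classes, annotations=("NS",))
    assert len(table) == 0


def test_cpd_invariant_to_rerooting():
    t1 = LabeledTree.from_newick("((A1:1,B1:2):1,(A2:3,B2:1):2);", SPECIES_4)
    r1 = cpd_statistic(t1)
    rerooted = t1.tree.root_at(t1.tree.find("B2").parent)
    r2 = cpd_statistic(LabeledTree(tree=rerooted, tip_species=SPECIES_4))
    assert r2.cpd_diff == pytest.approx(r1.cpd_diff)
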