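"""PIC, window densities, subset selection, IBS distances, NJ, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import capsforge as cf
from capsforge.diversity_selection import (
    SelectionConfig,
    build_nj_tree,
    compute_pic,
    count_window_density,
    find_hotspots,
    ibs_distance,
    pca_genotypes,
    pic_from_counts,
    select_marker_subset,
)
from capsforge.genotype_io import GenotypeCall
from capsforge.variant_processing import LocationClass
from conftest import make_matrix


class TestPic:
    def test_monomorphic_is_zero(self):
        assert compute_pic([GenotypeCall("A", "A")] * 6) == 0.0

    def test_balanced_biallelic_maximum(self):
        # p = q = 0.5 attains the biallelic bound 0.375
        assert compute_pic([GenotypeCall("A", "A")] * 12
                           + [GenotypeCall("G", "G")] * 12) == pytest.approx(0.375)

    def test_nine_vs_fifteen_homozygotes(self):
        # p = 9/24 = 0.375: hand evaluation of the Botstein formula
        val = compute_pic([GenotypeCall("A", "A")] * 9 + [GenotypeCall("G", "G")] * 15)
        assert val == pytest.approx(0.358886, abs=1e-6)

    def test_all_missing_column_undefined(self):
        with pytest.raises(ValueError):
            compute_pic([GenotypeCall()] * 4)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(counts=st.lists(st.integers(0, 50), min_size=2, max_size=4).filter(sum))
    def test_bounded_by_allele_count(self, counts):
        k = sum(1 for c in counts if c > 0)
        pic = pic_from_counts(counts)
        assert 0.0 <= pic <= 1.0 - 1.0 / max(k, 1) + 1e-12


class TestWindows:
    def test_first_window_concentration(self):
        v = pd.DataFrame({"chrom": "Chr1", "pos": np.arange(1, 11) * 5000})
        dens = count_window_density(v, {"Chr1": 300_000}, 100_000)
        assert dens["snp_count"].tolist() == [10, 0, 0]

    def test_counts_match_direct_tally(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.integers(1, 1_000_001, size=500))
        v = pd.DataFrame({"chrom": "Chr2", "pos": pos})
        dens = count_window_density(v, {"Chr2": 1_000_000}, 100_000)
        for _, w in dens.iterrows():
            assert w["snp_count"] == ((pos >= w["start"]) & (pos <= w["end"])).sum()
        assert dens["snp_count"].sum() == 500

    def test_empty_chromosome_all_zero(self):
        v = pd.DataFrame({"chrom": [], "pos": []})
        dens = count_window_density(v, {"Chr3": 250_000}, 100_000)
        assert (dens["snp_count"] == 0).all() and len(dens) == 3

    def test_hotspot_region_sum_from_raw_positions(self):
        rng = np.random.default_rng(9)
        pos = np.concatenate([rng.integers(1, 1_000_001, 200),
                              rng.integers(830_000, 911_201, 300)])  # planted hotspot
        v = pd.DataFrame({"chrom": "Chr4", "pos": pos})
        dens = count_window_density(v, {"Chr4": 1_000_000}, 100_000)
        hs = find_hotspots(v, dens, ("Chr4", 830_000, 911_200))
        direct = int(((pos >= 830_000) & (pos <= 911_200)).sum())
        assert hs["snp_sum"] == direct
        assert hs["windows"].iloc[0]["snp_count"] == hs["windows"]["snp_count"].max()

    def test_region_outside_chromosome_rejected(self):
        v = pd.DataFrame({"chrom": "Chr1", "pos": [10]})
        dens = count_window_density(v, {"Chr1": 100_000}, 100_000)
        with pytest.raises(ValueError):
            find_hotspots(v, dens, ("Chr1", 1, 200_000))


def _candidates(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "pic", "mean_depth",
                                       "location_class"])


class TestSelection:
    def test_genic_preferred_within_interval(self):
        ann = _candidates([("Chr1", 1000, 0.2, 10, LocationClass.INTERGENIC),
                           ("Chr1", 2000, 0.1, 10, LocationClass.EXON)])
        out = select_marker_subset(ann, SelectionConfig(max_per_interval=1))
        assert out["pos"].tolist() == [2000]

    def test_empty_interval_contributes_nothing(self):
        ann = _candidates([("Chr1", 1000, 0.0, 10, LocationClass.EXON)])  # pic not > 0
        assert len(select_marker_subset(ann)) == 0

    def test_matches_brute_force_on_toy_chromosome(self):
        # 1.5 Mb, 9 candidates, 3 per 0.5-Mb interval, max 2 -> 6 selected
        rows = [("Chr1", 100_000 + i * 160_000, 0.1 + 0.02 * i, 10, LocationClass.INTRON)
                for i in range(9)]
        ann = _candidates(rows)
        cfg = SelectionConfig(max_per_interval=2)
        out = select_marker_subset(ann, cfg)
        assert len(out) == 6
        # brute force: per interval take the max_per_interval best by PIC
        expect = []
        for ivl, grp in itertools.groupby(rows, key=lambda r: (r[1] - 1) // 500_000):
            best = sorted(grp, key=lambda r: (-r[2], r[1]))[:2]
            expect.extend(p for _, p, *_ in best)
        assert sorted(out["pos"]) == sorted(expect)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(2)
        rows = [("Chr2", int(p), float(rng.uniform(0.01, 0.37)), 10,
                 LocationClass.EXON if rng.random() < 0.5 else LocationClass.INTERGENIC)
                for p in rng.choice(np.arange(1, 3_000_000), 60, replace=False)]
        a = select_marker_subset(_candidates(rows))
        b = select_marker_subset(_candidates(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)


class TestIbs:
    def test_identical_samples_distance_zero(self):
        m = make_matrix([["A/A", "A/A"], ["A/G", "A/G"]])
        assert ibs_distance(m)[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        m = make_matrix([["A/A", "G/G"], ["A/A", "G/G"]])
        assert ibs_distance(m)[0, 1] == 1.0

    def test_single_shared_allele_half(self):
        m = make_matrix([["A/A", "A/G"]])
        assert ibs_distance(m)[0, 1] == 0.5

    def test_symmetric_zero_diagonal_bounded(self, small_bundle):
        dm = ibs_distance(small_bundle["matrix"])
        d = dm.data
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        assert (d >= 0).all() and (d <= 1).all()

    def test_no_cocalled_loci_is_an_error(self):
        m = make_matrix([["A/A", "-/-"], ["-/-", "G/G"]])
        with pytest.raises(ValueError, match="s1.*s2"):
            ibs_distance(m)


def _random_additive_case(rng, n):
    """A random rooted binary tree over n leaves; returns its path-distance
    matrix (the oracle is plain shortest-path arithmetic, independent of any
    tree library)."""
    nodes = {i: None for i in range(n)}  # leaf -> parent
    lengths = {}
    parent = {}
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[i], active[j]
        p = next_id
        next_id += 1
        for child in (a, b):
            parent[child] = p
            lengths[child] = float(rng.uniform(0.05, 1.0))
        active = [x for x in active if x not in (a, b)] + [p]
    root = active[0]

    def path_to_root(x):
        out = {}
        d = 0.0
        while x != root:
            d += lengths[x]
            x = parent[x]
            out[x] = d
        return out

    d = np.zeros((n, n))
    paths = [path_to_root(i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            shared = set(paths[i]) & set(paths[j])
            lca_d = min(paths[i][s] + paths[j][s] for s in shared)
            d[i, j] = d[j, i] = lca_d
    return d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        from skbio import DistanceMatrix

        d_ab, d_ac, d_bc = 0.2, 0.5, 0.7
        dm = DistanceMatrix([[0, d_ab, d_ac], [d_ab, 0, d_bc], [d_ac, d_bc, 0]],
                            ids=list("abc"))
        tree = build_nj_tree(dm)
        get = lambda x: tree.find(x).length
        assert get("a") == pytest.approx((d_ab + d_ac - d_bc) / 2)
        assert get("b") == pytest.approx((d_ab + d_bc - d_ac) / 2)
        assert get("c") == pytest.approx((d_ac + d_bc - d_ab) / 2)

    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_exact_recovery_of_additive_distances(self, n, seed):
        from skbio import DistanceMatrix

        rng = np.random.default_rng(seed)
        d = _random_additive_case(rng, n)
        ids = [f"t{i}" for i in range(n)]
        tree = build_nj_tree(DistanceMatrix(d, ids=ids))
        for i in range(n):
            for j in range(i + 1, n):
                path = tree.find(ids[i]).distance(tree.find(ids[j]))
                assert path == pytest.approx(d[i, j], abs=1e-9)

    def test_identical_taxa_become_zero_length_siblings(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix([[0, 0, 0.6], [0, 0, 0.6], [0.6, 0.6, 0]], ids=list("abc"))
        tree = build_nj_tree(dm)
        assert tree.find("a").length == pytest.approx(0.0)
        assert tree.find("b").length == pytest.approx(0.0)

    def test_too_few_taxa(self):
        from skbio import DistanceMatrix

        with pytest.raises(ValueError):
            build_nj_tree(DistanceMatrix([[0, 1], [1, 0]], ids=list("ab")))


class TestPca:
    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(4)
        cols = []
        for _ in range(60):
            noise = lambda g: "A/G" if rng.random() < 0.05 else g
            cols.append([noise("A/A")] * 6 + [noise("G/G")] * 6)
        m = make_matrix(cols)
        coords, var = pca_genotypes(m)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:6].max() < pc1[6:].min()) or (pc1[:6].min() > pc1[6:].max())
        assert var[0] > 0.5

    def test_constant_matrix_zero_variance(self):
        m = make_matrix([["A/A"] * 5, ["A/A"] * 5])
        _, var = pca_genotypes(m)
        assert np.allclose(var, 0.0)

    def test_variance_fractions_normalized(self, small_bundle):
        coords, var = pca_genotypes(small_bundle["matrix"], n_components=5)
        assert (np.diff(var) <= 1e-12).all()
        assert var.sum() <= 1.0 + 1e-9
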