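"""Weir-Cockerham components, window scans, outliers, regions, gene sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sweepscan as sw
from sweepscan.errors import ComputationError, InputError
from sweepscan.sim import GeneModel

from conftest import build_table, random_table


def wc_two_pop_oracle(n1, p1, h1, n2, p2, h2):
    """Literal transcription of the Weir & Cockerham (1984) two-population
    variance components from sample sizes, allele frequencies and observed
    heterozygosity: returns (a, a + b + c)."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, a + b + c


def pop_stats(gt_site, idx):
    sub = gt_site[idx]
    ok = (sub >= 0).all(axis=1)
    n = ok.sum()
    p = sub[ok].sum() / (2 * n) if n else np.nan
    h = (sub[ok, 0] != sub[ok, 1]).mean() if n else np.nan
    return n, p, h


class TestPerSiteFst:
    def test_fixed_difference_gives_fst_one(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, :10] = 1  # focal fixed ALT, control fixed REF
        t = build_table(gt, pops=["focal"] * 10 + ["control"] * 10)
        num, den = sw.per_site_fst_components(t, ["focal", "control"])
        assert num[0] / den[0] == pytest.approx(1.0)

    def test_identical_frequencies_give_nonpositive_numerator(self):
        gt = np.zeros((1, 20, 2), dtype=np.int8)
        gt[0, ::2, 1] = 1  # same het pattern in both populations
        t = build_table(gt, pops=["focal"] * 10 + ["control"] * 10)
        num, _ = sw.per_site_fst_components(t, ["focal", "control"])
        assert num[0] <= 0

    def test_matches_textbook_formula_transcription(self, rng):
        t = random_table(rng, n_sites=100, n_samples=14, miss_frac=0.1)
        num, den = sw.per_site_fst_components(t, ["focal", "control"])
        f_idx = t.sample_indices("focal")
        c_idx = t.sample_indices("control")
        for i in range(t.n_sites):
            n1, p1, h1 = pop_stats(t.gt[i], f_idx)
            n2, p2, h2 = pop_stats(t.gt[i], c_idx)
            if n1 < 1 or n2 < 1 or (n1 + n2) / 2 <= 1:
                assert np.isnan(num[i]) and np.isnan(den[i])
                continue
            a, d = wc_two_pop_oracle(n1, p1, h1, n2, p2, h2)
            assert num[i] == pytest.approx(a, abs=1e-12)
            assert den[i] == pytest.approx(d, abs=1e-12)

    def test_requires_exactly_two_populations(self, rng):
        t = random_table(rng, n_sites=4, n_samples=6)
        with pytest.raises(InputError):
            sw.per_site_fst_components(t, ["focal", "control", "extra"])


class TestWindowedFst:
    def test_single_site_window_equals_site_ratio(self):
        pos = np.array([150])
        num, den = np.array([0.3]), np.array([0.5])
        df = sw.windowed_fst(pos, num, den, sw.WindowScheme(1000, 1000), 1000)
        assert df["fst"].iloc[0] == pytest.approx(0.6)

    def test_negative_window_fst_not_clamped(self):
        pos = np.array([100, 200])
        num, den = np.array([-0.1, -0.05]), np.array([0.5, 0.5])
        df = sw.windowed_fst(pos, num, den, sw.WindowScheme(1000, 1000), 1000)
        assert df["fst"].iloc[0] == pytest.approx(-0.15)

    def test_empty_window_flagged_nan(self):
        pos = np.array([100])
        df = sw.windowed_fst(pos, np.array([0.1]), np.array([0.2]),
                             sw.WindowScheme(500, 500), 1500)
        assert np.isnan(df["fst"].iloc[1]) and df["n_snps"].iloc[1] == 0

    def test_matches_brute_force_resummation(self, rng):
        n = 200
        pos = np.sort(rng.choice(np.arange(1, 50_000), size=n, replace=False))
        num = rng.normal(0, 0.1, n)
        den = rng.uniform(0.1, 1.0, n)
        scheme = sw.WindowScheme(5000, 2500)
        df = sw.windowed_fst(pos, num, den, scheme, 50_000)
        for _, row in df.iterrows():
            sel = (pos - 1 >= row["start"]) & (pos - 1 < row["end"])
            if sel.sum() == 0:
                assert np.isnan(row["fst"])
            else:
                assert row["fst"] == pytest.approx(
                    num[sel].sum() / den[sel].sum(), abs=1e-12
                )


class TestZTransform:
    def test_two_point_case(self):
        assert sw.z_transform(np.array([0.0, 1.0])).tolist() == [-1.0, 1.0]

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ComputationError):
            sw.z_transform(np.full(5, 2.0))

    def test_matches_elementwise_formula(self, rng):
        x = rng.normal(2, 3, 50)
        z = sw.z_transform(x)
        mu, sd = x.mean(), x.std(ddof=0)
        assert np.allclose(z, (x - mu) / sd, atol=1e-12)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=0) - 1) < 1e-12

    def test_invariant_under_affine_rescaling(self, rng):
        x = rng.normal(0, 1, 30)
        assert np.allclose(sw.z_transform(3.5 * x - 2.0), sw.z_transform(x))

    def test_nan_entries_are_preserved_not_ranked(self):
        z = sw.z_transform(np.array([0.0, np.nan, 1.0]))
        assert np.isnan(z[1]) and z[0] == -1.0


class TestLog2PiRatio:
    def test_reference_values(self):
        out = sw.log2_pi_ratio(np.array([0.002, 0.001]), np.array([0.001, 0.001]))
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(0.0)

    def test_zero_diversity_flagged_unusable(self):
        out = sw.log2_pi_ratio(np.array([0.002]), np.array([0.0]))
        assert np.isnan(out[0])

    def test_misaligned_windows_rejected(self):
        with pytest.raises(InputError):
            sw.log2_pi_ratio(np.zeros(3), np.zeros(4))


def windows_frame(z, ratio):
    return pd.DataFrame({
        "start": np.arange(len(z)) * 100,
        "end": np.arange(1, len(z) + 1) * 100,
        "z_fst": z,
        "log2_ratio": ratio,
    })


class TestJointOutliers:
    def test_identical_rank_order_gives_common_top_five(self):
        vals = np.arange(100, dtype=float)
        df, _, _ = sw.joint_outliers(windows_frame(vals, vals * 2 + 1))
        assert df["joint"].sum() == 5
        assert set(np.nonzero(df["joint"].to_numpy())[0]) == {95, 96, 97, 98, 99}

    def test_reversed_ranks_give_no_joint_outliers(self):
        vals = np.arange(100, dtype=float)
        df, _, _ = sw.joint_outliers(windows_frame(vals, vals[::-1].copy()))
        assert df["joint"].sum() == 0
        assert df["fst_top"].sum() == 5 and df["ratio_top"].sum() == 5

    def test_all_tied_values_all_flagged(self):
        vals = np.full(30, 1.5)
        ratio = np.full(30, 0.4)
        ratio_jitter = ratio.copy()
        df, _, _ = sw.joint_outliers(windows_frame(vals, ratio_jitter))
        assert df["joint"].all()

    def test_joint_never_exceeds_either_margin(self, rng):
        z = rng.normal(size=80)
        r = rng.normal(size=80)
        df, _, _ = sw.joint_outliers(windows_frame(z, r))
        assert df["joint"].sum() <= min(df["fst_top"].sum(), df["ratio_top"].sum())

    def test_cutoffs_match_sorting_oracle(self, rng):
        z = rng.normal(size=100)
        r = rng.normal(size=100)
        df, z_cut, r_cut = sw.joint_outliers(windows_frame(z, r))
        assert z_cut == sorted(z)[95]
        assert r_cut == sorted(r)[95]
        assert set(np.nonzero(df["fst_top"].to_numpy())[0]) == set(np.argsort(z)[95:])


def make_gene(gid, start, end):
    return GeneModel(gid, "chr1", start, end, "+", ((start, start + 2),))


class TestMergeAndMap:
    def test_overlapping_windows_merge(self):
        wins = pd.DataFrame({"start": [100_000, 120_000], "end": [140_000, 160_000]})
        regions = sw.merge_and_map(wins, [])
        assert [(r.start, r.end) for r in regions] == [(100_000, 160_000)]

    def test_one_bp_overlap_includes_gene(self):
        wins = pd.DataFrame({"start": [1000], "end": [2000]})
        gene = make_gene("g1", 2000, 2500)  # 1-based 2000 = last bp of region
        regions = sw.merge_and_map(wins, [gene])
        assert regions[0].genes == ("g1",)
        outside = make_gene("g2", 2001, 2500)
        assert sw.merge_and_map(wins, [outside])[0].genes == ()

    def test_matches_all_pairs_overlap_oracle(self, rng):
        for _ in range(20):
            starts = np.sort(rng.choice(np.arange(0, 100), size=8, replace=False)) * 100
            wins = pd.DataFrame({"start": starts, "end": starts + 250})
            genes = [
                make_gene(f"g{k}", int(s), int(s) + 120)
                for k, s in enumerate(rng.integers(1, 10_200, size=15))
            ]
            regions = sw.merge_and_map(wins, genes)
            # regions tile the union of windows
            covered = set()
            for s, e in zip(wins["start"], wins["end"]):
                covered |= set(range(s, e))
            got = set()
            for r in regions:
                got |= set(range(r.start, r.end))
            assert got == covered
            # gene assignment equals exhaustive interval overlap
            for r in regions:
                expect = sorted(
                    g.gene_id
                    for g in genes
                    if g.start - 1 < r.end and g.end > r.start
                )
                assert list(r.genes) == expect


class TestIntersectGeneSets:
    def test_three_way_partition(self):
        a_only, shared, b_only = sw.intersect_gene_sets(
            ["A", "B", "C"], ["B", "C", "D"]
        )
        assert (a_only, shared, b_only) == ({"A"}, {"B", "C"}, {"D"})

    def test_disjoint_sets(self):
        _, shared, _ = sw.intersect_gene_sets(["A"], ["B"])
        assert shared == set()

    def test_partition_sizes_sum_to_union(self, rng):
        a = {f"g{i}" for i in rng.choice(2000, size=300, replace=False)}
        b = {f"g{i}" for i in rng.choice(2000, size=900, replace=False)}
        a_only, shared, b_only = sw.intersect_gene_sets(a, b)
        assert len(a_only) + len(shared) + len(b_only) == len(a | b)


def test_window_fst_is_one_iff_all_fixed_differences():
    gt = np.zeros((3, 8, 2), dtype=np.int8)
    gt[:, :4] = 1
    t = build_table(gt, pos=[100, 200, 300], pops=["focal"] * 4 + ["control"] * 4)
    num, den = sw.per_site_fst_components(t, ["focal", "control"])
    df = sw.windowed_fst(t.pos, num, den, sw.WindowScheme(1000, 1000), 1000)
    assert df["fst"].iloc[0] == pytest.approx(1.0)
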