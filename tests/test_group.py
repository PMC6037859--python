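"""Mixed ANOVA, cluster formation, permutation cluster-FDR, report tables."""

import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synctoj.group import (
    Cluster,
    ClusterResult,
    GroupDesign,
    cluster_table,
    form_clusters,
    mixed_anova,
    permutation_cluster_fdr,
)

ALL_TERMS = ["group", "task", "coa", "group:task", "group:coa", "task:coa", "group:task:coa"]


def brute_force_anova_oracle(data, groups):
    """Independent split-plot sums-of-squares decomposition, written as
    literal nested loops over the model's mean contrasts."""
    N, a, b = data.shape[:3]
    y = data[..., 0]
    glabels = sorted(set(groups))
    grand = y.mean()
    mg = {g: y[groups == g].mean() for g in glabels}
    ng = {g: (groups == g).sum() for g in glabels}
    ms = y.mean(axis=(1, 2))
    mj = y.mean(axis=(0, 2))
    mk = y.mean(axis=(0, 1))
    mgj = {g: y[groups == g].mean(axis=(0, 2)) for g in glabels}
    mgk = {g: y[groups == g].mean(axis=(0, 1)) for g in glabels}
    mjk = y.mean(axis=0)
    mgjk = {g: y[groups == g].mean(axis=0) for g in glabels}
    msj = y.mean(axis=2)
    msk = y.mean(axis=1)

    ss = dict.fromkeys(
        ["g", "sg", "a", "ga", "asg", "b", "gb", "bsg", "ab", "gab", "absg"], 0.0
    )
    for g in glabels:
        ss["g"] += a * b * ng[g] * (mg[g] - grand) ** 2
        for j in range(a):
            ss["ga"] += b * ng[g] * (mgj[g][j] - mg[g] - mj[j] + grand) ** 2
        for k in range(b):
            ss["gb"] += a * ng[g] * (mgk[g][k] - mg[g] - mk[k] + grand) ** 2
        for j in range(a):
            for k in range(b):
                ss["gab"] += ng[g] * (
                    mgjk[g][j, k] - mgj[g][j] - mgk[g][k] + mg[g]
                    - mjk[j, k] + mj[j] + mk[k] - grand
                ) ** 2
    for s in range(N):
        g = groups[s]
        ss["sg"] += a * b * (ms[s] - mg[g]) ** 2
        for j in range(a):
            ss["asg"] += b * (msj[s, j] - ms[s] - mgj[g][j] + mg[g]) ** 2
        for k in range(b):
            ss["bsg"] += a * (msk[s, k] - ms[s] - mgk[g][k] + mg[g]) ** 2
        for j in range(a):
            for k in range(b):
                ss["absg"] += (
                    y[s, j, k] - msj[s, j] - msk[s, k] - mgjk[g][j, k]
                    + ms[s] + mgj[g][j] + mgk[g][k] - mg[g]
                ) ** 2
    for j in range(a):
        ss["a"] += N * b * (mj[j] - grand) ** 2
    for k in range(b):
        ss["b"] += N * a * (mk[k] - grand) ** 2
    for j in range(a):
        for k in range(b):
            ss["ab"] += N * (mjk[j, k] - mj[j] - mk[k] + grand) ** 2

    G = len(glabels)
    dfs = {
        "group": (G - 1, N - G, "g", "sg"),
        "task": (a - 1, (a - 1) * (N - G), "a", "asg"),
        "group:task": ((G - 1) * (a - 1), (a - 1) * (N - G), "ga", "asg"),
        "coa": (b - 1, (b - 1) * (N - G), "b", "bsg"),
        "group:coa": ((G - 1) * (b - 1), (b - 1) * (N - G), "gb", "bsg"),
        "task:coa": ((a - 1) * (b - 1), (a - 1) * (b - 1) * (N - G), "ab", "absg"),
        "group:task:coa": (
            (G - 1) * (a - 1) * (b - 1), (a - 1) * (b - 1) * (N - G), "gab", "absg"
        ),
    }
    out = {}
    for term, (d1, d2, num, den) in dfs.items():
        out[term] = (ss[num] / d1) / (ss[den] / d2), d1, d2
    return out


class TestMixedAnova:
    @pytest.mark.parametrize("seed,n_per_group,a,b", [(0, 4, 2, 4), (1, 6, 2, 3), (2, 3, 3, 2)])
    def test_matches_brute_force_oracle(self, seed, n_per_group, a, b):
        rng = np.random.default_rng(seed)
        N = 2 * n_per_group
        data = rng.standard_normal((N, a, b, 1))
        groups = np.array([0] * n_per_group + [1] * n_per_group)
        design = GroupDesign(data, groups)
        oracle = brute_force_anova_oracle(data, groups)
        for term in ALL_TERMS:
            F, d1, d2 = mixed_anova(design, term)
            oF, od1, od2 = oracle[term]
            assert (d1, d2) == (od1, od2), term
            assert F.ravel()[0] == pytest.approx(oF, abs=1e-8), term

    def test_matches_oracle_with_unequal_groups(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((10, 2, 4, 1))
        groups = np.array([0] * 4 + [1] * 6)
        design = GroupDesign(data, groups)
        oracle = brute_force_anova_oracle(data, groups)
        for term in ALL_TERMS:
            F, d1, d2 = mixed_anova(design, term)
            assert F.ravel()[0] == pytest.approx(oracle[term][0], abs=1e-8), term

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_r_aov_error_strata(self, tmp_path):
        """Full cross-check against R's aov with Error(subject/(A*B))."""
        rng = np.random.default_rng(42)
        N, a, b = 10, 2, 3
        data = rng.standard_normal((N, a, b, 1)) + 0.5 * np.arange(a)[None, :, None, None]
        groups = np.array([0] * 4 + [1] * 6)
        rows = [
            (s, groups[s], j, k, data[s, j, k, 0])
            for s in range(N) for j in range(a) for k in range(b)
        ]
        csv = tmp_path / "d.csv"
        pd.DataFrame(rows, columns=["subj", "grp", "A", "B", "y"]).to_csv(csv, index=False)
        r_code = f"""
        d <- read.csv("{csv}")
        for (c in c("subj","grp","A","B")) d[[c]] <- factor(d[[c]])
        m <- aov(y ~ grp*A*B + Error(subj/(A*B)), data=d)
        s <- summary(m)
        for (stratum in s) {{
          tab <- stratum[[1]]
          for (i in seq_len(nrow(tab))) {{
            nm <- trimws(rownames(tab)[i])
            if (nm != "Residuals") cat(nm, tab[i, "F value"], "\\n")
          }}
        }}
        """
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        ).stdout
        r_f = {}
        for line in out.strip().splitlines():
            name, val = line.split()
            r_f[name] = float(val)
        design = GroupDesign(data, groups, within_names=("A", "B"), between_name="grp")
        mapping = {
            "grp": "grp", "A": "A", "B": "B", "grp:A": "grp:A",
            "grp:B": "grp:B", "A:B": "A:B", "grp:A:B": "grp:A:B",
        }
        for r_name, term in mapping.items():
            F, _, _ = mixed_anova(design, term)
            assert F.ravel()[0] == pytest.approx(r_f[r_name], rel=1e-6), term

    def test_matches_pingouin_one_within_one_between(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        data = rng.standard_normal((12, 3, 1, 1))
        groups = np.array([0] * 6 + [1] * 6)
        design = GroupDesign(data, groups, within_names=("task", "coa"))
        rows = [
            (s, groups[s], j, data[s, j, 0, 0])
            for s in range(12) for j in range(3)
        ]
        df = pd.DataFrame(rows, columns=["subject", "group", "task", "y"])
        res = pg.mixed_anova(df, dv="y", within="task", subject="subject", between="group")
        for term, pg_row in [("group", "group"), ("task", "task"), ("group:task", "Interaction")]:
            F, _, _ = mixed_anova(design, term)
            expected = float(res.loc[res.Source == pg_row, "F"].iloc[0])
            assert F.ravel()[0] == pytest.approx(expected, rel=1e-8), term

    def test_zero_variance_voxels_get_f_zero(self):
        data = np.ones((6, 2, 2, 3))
        design = GroupDesign(data, np.array([0, 0, 0, 1, 1, 1]))
        F, _, _ = mixed_anova(design, "task")
        assert (F == 0).all()

    def test_injected_effect_peaks_in_its_region(self):
        rng = np.random.default_rng(7)
        data = rng.standard_normal((12, 2, 1, 6, 6, 6))
        data[:, 0, :, 2:4, 2:4, 2:4] += 3.0  # strong Task effect in one region
        design = GroupDesign(data, np.array([0] * 6 + [1] * 6))
        F, _, _ = mixed_anova(design, "task")
        peak = np.unravel_index(np.argmax(F), F.shape)
        assert all(2 <= p < 4 for p in peak)

    def test_invalid_term_rejected(self):
        design = GroupDesign(np.zeros((4, 2, 2, 1)), np.array([0, 0, 1, 1]))
        with pytest.raises(ValueError):
            mixed_anova(design, "time")

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            GroupDesign(np.zeros((3, 2, 2, 1)), np.array([0, 1, 1]))

    def test_null_false_positive_rate_is_nominal(self):
        """Voxelwise F exceeds the p=0.0001 threshold at close to the nominal
        rate under the global null (>= 10^6 voxel draws)."""
        rng = np.random.default_rng(8)
        n_draws = 0
        n_hits = 0
        thresh = None
        for rep in range(8):
            data = rng.standard_normal((16, 2, 1, 140_000))
            design = GroupDesign(data, np.array([0] * 8 + [1] * 8))
            F, d1, d2 = mixed_anova(design, "task")
            if thresh is None:
                thresh = stats.f.isf(1e-4, d1, d2)
            n_hits += int((F > thresh).sum())
            n_draws += F.size
        rate = n_hits / n_draws
        # 3 sigma Monte-Carlo band around 1e-4
        sigma = np.sqrt(1e-4 / n_draws)
        assert abs(rate - 1e-4) <= 3 * sigma + 1e-5


class TestFormClusters:
    def make_map(self, coords, value=100.0, shape=(8, 8, 8)):
        m = np.zeros(shape)
        for c in coords:
            m[c] = value
        return m

    def test_single_voxel_cluster(self):
        res = form_clusters(self.make_map([(2, 2, 2)]), dfs=(1, 20))
        assert len(res.clusters) == 1
        assert res.clusters[0].n_voxels == 1
        assert res.clusters[0].peak_coord == (2, 2, 2)

    def test_face_neighbours_merge_under_18_connectivity(self):
        res = form_clusters(self.make_map([(2, 2, 2), (2, 2, 3)]), dfs=(1, 20))
        assert len(res.clusters) == 1 and res.clusters[0].n_voxels == 2

    def test_edge_neighbours_merge_under_18_connectivity(self):
        res = form_clusters(self.make_map([(2, 2, 2), (2, 3, 3)]), dfs=(1, 20))
        assert len(res.clusters) == 1

    def test_corner_neighbours_stay_separate_under_18_connectivity(self):
        res = form_clusters(self.make_map([(2, 2, 2), (3, 3, 3)]), dfs=(1, 20))
        assert len(res.clusters) == 2

    def test_corner_neighbours_merge_under_26_connectivity(self):
        res = form_clusters(
            self.make_map([(2, 2, 2), (3, 3, 3)]), dfs=(1, 20), connectivity=26
        )
        assert len(res.clusters) == 1

    def test_threshold_respects_f_null(self):
        d1, d2 = 1, 20
        crit = stats.f.isf(1e-4, d1, d2)
        m = self.make_map([(1, 1, 1)], value=crit * 0.99)
        assert len(form_clusters(m, (d1, d2)).clusters) == 0

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            form_clusters(np.zeros((0, 0, 0)), (1, 10))


@pytest.fixture()
def effect_design():
    rng = np.random.default_rng(10)
    data = rng.standard_normal((20, 2, 1, 12, 12, 12))
    data[:, 0, :, 4:6, 4:6, 4:6] += 2.5  # 8-voxel Task effect
    return GroupDesign(data, np.array([0] * 10 + [1] * 10))


class TestPermutationClusterFdr:
    def test_deterministic_under_seed(self, effect_design):
        r1 = permutation_cluster_fdr(effect_design, "task", n_perm=100, seed=3)
        r2 = permutation_cluster_fdr(effect_design, "task", n_perm=100, seed=3)
        assert [c.p_cluster for c in r1.clusters] == [c.p_cluster for c in r2.clusters]

    def test_injected_effect_detected(self, effect_design):
        res = permutation_cluster_fdr(effect_design, "task", n_perm=150, seed=4)
        sig = [c for c in res.clusters if c.significant]
        assert sig and max(c.n_voxels for c in sig) >= 8

    def test_q_zero_never_significant(self, effect_design):
        res = permutation_cluster_fdr(effect_design, "task", n_perm=100, q=0.0, seed=5)
        assert not any(c.significant for c in res.clusters)

    def test_too_few_permutations_rejected(self, effect_design):
        with pytest.raises(ValueError):
            permutation_cluster_fdr(effect_design, "task", n_perm=10)


class TestClusterTable:
    def test_empty_table_has_header(self):
        res = ClusterResult(np.zeros((2, 2, 2), int), (), 1e-4, 18, 1, 10)
        table = cluster_table(res)
        assert table.empty and "peak_stat" in table.columns

    def test_equiv_z_probit_oracle_and_ordering(self):
        d1, d2 = 2, 30
        f_median = stats.f.isf(0.5, d1, d2)  # upper-tail p = 0.5 -> z = 0
        clusters = (
            Cluster(1, (1, 1, 1), 5, f_median, float(stats.norm.isf(stats.f.sf(f_median, d1, d2))), 0.2, 0.2, False),
            Cluster(2, (3, 3, 3), 9, 25.0, float(stats.norm.isf(stats.f.sf(25.0, d1, d2))), 0.01, 0.02, True),
        )
        res = ClusterResult(np.zeros((5, 5, 5), int), clusters, 1e-4, 18, d1, d2)
        table = cluster_table(res)
        assert list(table.cluster_id) == [2, 1]  # sorted by statistic desc
        assert table.equiv_z.iloc[1] == pytest.approx(0.0, abs=1e-9)
        expected_z = stats.norm.isf(stats.f.sf(25.0, d1, d2))
        assert table.equiv_z.iloc[0] == pytest.approx(expected_z)
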