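import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import mirscreen as ms
from mirscreen.cohort_stats import jonckheere_terpstra, to_newick
from mirscreen.io import ValidationError


def _tpm_like(values, samples, probes):
    return ms.ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=samples, columns=probes),
        "tpm",
    )


class TestVolcano:
    def test_identical_groups_have_zero_fold_change(self, rng):
        block = rng.uniform(1, 100, (4, 5))
        values = np.vstack([block, block])
        m = _tpm_like(values, [f"s{i}" for i in range(8)], [f"p{j}" for j in range(5)])
        labels = {f"s{i}": ("cancer" if i < 4 else "healthy") for i in range(8)}
        table = ms.univariate_volcano(m, labels, case="cancer")
        assert np.allclose(table["log2fc"], 0.0)

    def test_spiked_probe_attains_smallest_adjusted_p(self, rng):
        values = rng.lognormal(5, 0.3, (40, 10))
        values[:20, 0] *= 16  # +4 log2 units in the case group
        m = _tpm_like(values, [f"s{i}" for i in range(40)],
                      [f"p{j}" for j in range(10)])
        labels = {f"s{i}": ("cancer" if i < 20 else "healthy") for i in range(40)}
        table = ms.univariate_volcano(m, labels, case="cancer").set_index("probe")
        assert table["p_adj"].idxmin() == "p0"
        assert table.loc["p0", "log2fc"] > 3

    def test_adjusted_p_dominates_raw_and_is_monotone(self, small_human):
        cfg, tpm, meta = small_human
        mdf = ms.io.metadata_frame(meta)
        keep = mdf.index[mdf["group"].isin(["cancer", "healthy"])]
        sub = tpm.select_samples(list(keep))
        table = ms.univariate_volcano(sub, mdf.loc[keep, "group"], case="cancer")
        assert np.all(table["p_adj"] >= table["p"] - 1e-15)
        by_raw = table.sort_values("p")
        assert by_raw["p_adj"].is_monotonic_increasing

    def test_constant_probe_flagged_with_p_one(self):
        values = np.ones((8, 2))
        values[:, 1] = np.arange(8) + 1
        m = _tpm_like(values, [f"s{i}" for i in range(8)], ["const", "var"])
        labels = {f"s{i}": ("cancer" if i < 4 else "healthy") for i in range(8)}
        table = ms.univariate_volcano(m, labels, case="cancer").set_index("probe")
        assert table.loc["const", "p"] == 1.0
        assert table.loc["const", "flag"] == "constant"


def jt_enumeration_oracle(groups, observed):
    """Independent exact null: enumerate permutations of the pooled values."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    count = total = 0
    for perm in set(itertools.permutations(pooled)):
        arranged, start = [], 0
        for sz in sizes:
            arranged.append(np.array(perm[start:start + sz]))
            start += sz
        total += 1
        j = 0.0
        for a, b in itertools.combinations(arranged, 2):
            diff = b[None, :] - a[:, None]
            j += (diff > 0).sum() + 0.5 * (diff == 0).sum()
        if j >= observed - 1e-9:
            count += 1
    return count / total


class TestTrendTest:
    def test_strictly_increasing_design_attains_minimal_exact_p(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        j, p = jonckheere_terpstra(groups, method="exact")
        assert j == 12.0  # every cross-timepoint pair concordant
        assert p == pytest.approx(jt_enumeration_oracle(groups, j))
        # unique maximum -> minimal attainable p for this design
        assert p == pytest.approx(1 / 90)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 3, 2).astype(float) for _ in range(3)]
        j, p = jonckheere_terpstra(groups, method="exact")
        assert p == pytest.approx(jt_enumeration_oracle(groups, j))

    def test_constant_probe_gives_p_one(self):
        groups = [np.full(3, 2.0), np.full(3, 2.0)]
        _, p = jonckheere_terpstra(groups)
        assert p == 1.0

    def test_normal_approximation_is_calibrated_under_permutation(self, rng):
        pvals = []
        for _ in range(200):
            pooled = rng.normal(size=18)
            rng.shuffle(pooled)
            groups = [pooled[:6], pooled[6:12], pooled[12:]]
            pvals.append(jonckheere_terpstra(groups, method="normal")[1])
        assert 0.3 < np.mean(pvals) < 0.7
        assert np.mean(np.array(pvals) < 0.05) < 0.12

    def test_tumor_markers_trend_up_in_mouse_cohort(self, small_fireplex):
        cfg, matrix, meta, panel = small_fireplex
        specimen = [s for s in matrix.sample_ids if s not in set(panel.blanks)]
        table = ms.trend_test(
            matrix.select_samples(specimen), meta,
            group="tumor", probes=cfg.panel.predictive,
        ).set_index("probe")
        null_table = ms.trend_test(
            matrix.select_samples(specimen), meta,
            group="control", probes=cfg.panel.predictive,
        ).set_index("probe")
        # trend p-values among tumor animals stochastically smaller than controls
        assert table["p"].median() < null_table["p"].median()
        assert (table["p"] < 0.05).sum() >= 10

    def test_single_timepoint_rejected(self, small_fireplex):
        _, matrix, meta, panel = small_fireplex
        day28 = [m.sample_id for m in meta if m.timepoint_day == 28]
        with pytest.raises(ValidationError, match="timepoints"):
            ms.trend_test(matrix.select_samples(day28),
                          [m for m in meta if m.sample_id in set(day28)])


class TestHierarchicalClustering:
    def test_duplicated_samples_merge_at_height_zero(self, rng):
        row = rng.uniform(1, 10, 5)
        values = np.vstack([row, row, rng.uniform(1, 10, 5)])
        m = _tpm_like(values, ["a", "b", "c"], [f"p{j}" for j in range(5)])
        result = ms.hierarchical_cluster(m)
        assert result.linkage[0, 2] == pytest.approx(0.0)

    def test_two_separated_groups_recovered_at_k2(self, rng):
        n, p = 20, 6
        values = rng.normal(0, 0.5, (n, p))
        values[: n // 2] += 3.0
        m = ms.ExpressionMatrix(
            pd.DataFrame(values, index=[f"s{i}" for i in range(n)],
                         columns=[f"p{j}" for j in range(p)]),
            "normalized_log2",
        )
        labels = ms.hierarchical_cluster(m).cut(2)
        truth = np.array([1] * (n // 2) + [0] * (n // 2))
        assert adjusted_rand_score(truth, labels.to_numpy()) == 1.0

    def test_invariant_to_per_probe_affine_rescaling(self, rng):
        values = rng.normal(size=(10, 4))
        samples = [f"s{i}" for i in range(10)]
        probes = [f"p{j}" for j in range(4)]
        base = ms.ExpressionMatrix(
            pd.DataFrame(values, index=samples, columns=probes), "normalized_log2"
        )
        scaled = ms.ExpressionMatrix(
            pd.DataFrame(values * np.array([2, 5, 0.5, 10]) + np.array([1, -3, 0, 7]),
                         index=samples, columns=probes),
            "normalized_log2",
        )
        a, b = ms.hierarchical_cluster(base), ms.hierarchical_cluster(scaled)
        assert np.allclose(a.linkage, b.linkage)
        assert a.leaf_order == b.leaf_order

    def test_deterministic_leaf_order_places_denser_subtree_first(self):
        values = np.array([[0.0], [0.1], [0.2], [5.0]])
        m = ms.ExpressionMatrix(
            pd.DataFrame(values, index=["a", "b", "c", "d"], columns=["p"]),
            "normalized_log2",
        )
        result = ms.hierarchical_cluster(m)
        assert result.leaf_order[-1] == "d"  # singleton subtree goes right

    def test_mixed_dose_cohort_clusters_by_tumor_status_not_inoculum(self):
        """Saturated day-28 markers separate tumor vs control, not dose groups."""
        cfg = ms.ovcar8_validation_design(seed=17)
        matrix, meta, panel = ms.simulate_fireplex_cohort(cfg)
        corrected = ms.background_correct(matrix, panel)
        nm = ms.normalize(corrected, panel,
                          ms.rank_normalizer_stability(corrected, panel).top_pair)
        collapsed, meta_c = ms.collapse_replicates(
            nm.matrix, [m for m in meta if m.sample_id in set(nm.data.index)]
        )
        day28 = [m for m in meta_c if m.timepoint_day == 28]
        ids = [m.sample_id for m in day28]
        result = ms.hierarchical_cluster(collapsed.select_samples(ids))
        tumor = np.array([m.group == "tumor" for m in day28])
        dose = np.array([m.inoculum_cells for m in day28])
        two = result.cut(2).loc[ids].to_numpy()
        assert adjusted_rand_score(tumor, two) > 0.8
        three = result.cut(3).loc[ids].to_numpy()
        assert adjusted_rand_score(dose[tumor], three[tumor]) < 0.2

    def test_newick_export_is_well_formed(self, small_human):
        _, tpm, _ = small_human
        sub = tpm.select_samples(tpm.sample_ids[:12])
        result = ms.hierarchical_cluster(sub)
        tree = to_newick(result)
        assert tree.endswith(";")
        assert tree.count("(") == tree.count(")") == 11
        for sid in sub.sample_ids:
            assert sid in tree
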