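import numpy as np
import pandas as pd
import pytest

import mirscreen as ms
from mirscreen.io import ValidationError
from mirscreen.preprocess import (
    background_correct,
    collapse_replicates,
    counts_to_tpm,
    normalize,
    rank_normalizer_stability,
)


def _fluor(values, probes, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return ms.ExpressionMatrix(
        pd.DataFrame(np.asarray(values, float), index=samples, columns=probes),
        "fluorescence",
    )


@pytest.fixture()
def tiny_panel():
    return ms.PanelDefinition(
        predictive=["t1", "t2"],
        normalizers=["n1", "n2", "n3"],
        background_controls=["bg1", "bg2"],
        spike_ins=[],
    )


class TestBackgroundCorrect:
    def test_probe_at_background_level_floors_to_epsilon(self, tiny_panel):
        m = _fluor([[5, 5, 5, 5, 5, 5, 5]], ["t1", "t2", "n1", "n2", "n3", "bg1", "bg2"])
        out = background_correct(m, tiny_panel, epsilon=1.0)
        assert np.all(out.values == 1.0)
        assert set(out.probe_ids) == {"t1", "t2", "n1", "n2", "n3"}

    def test_zero_background_is_identity(self, tiny_panel):
        m = _fluor([[7, 9, 4, 4, 4, 0, 0]], ["t1", "t2", "n1", "n2", "n3", "bg1", "bg2"])
        out = background_correct(m, tiny_panel)
        assert list(out.data.iloc[0]) == [7, 9, 4, 4, 4]

    def test_missing_background_probes_error(self, tiny_panel):
        m = _fluor([[1, 2]], ["t1", "t2"])
        with pytest.raises(ValidationError, match="background"):
            background_correct(m, tiny_panel)

    def test_recovers_injected_signal_within_noise(self):
        """Correction removes the generator's known background offset."""
        cfg = ms.SyntheticConfig(
            n_control=6, n_tumor_per_group=6, groups=[("A", 1)], seed=5,
            biological_sd_log2=0.0, technical_cv=0.0,
            background_mean=200.0, background_sd=15.0,
        )
        matrix, meta, panel = ms.simulate_fireplex_cohort(cfg)
        out = background_correct(matrix, panel, epsilon=1.0)
        mdf = ms.io.metadata_frame(meta)
        probe = cfg.panel.predictive[0]
        ctrl = [s for s in out.sample_ids
                if mdf.loc[s, "group"] == "control"]
        truth = 2.0 ** cfg.baseline_log2_mean[probe]
        mae = np.abs(out.data.loc[ctrl, probe] - truth).mean()
        assert mae < 2 * cfg.background_sd


class TestStabilityRanking:
    def test_constant_normalizer_ranks_first_with_score_zero(self, tiny_panel):
        rng = np.random.default_rng(0)
        values = np.column_stack([
            rng.uniform(50, 150, 10), rng.uniform(50, 150, 10),
            np.full(10, 64.0), rng.uniform(50, 150, 10), rng.uniform(50, 150, 10),
        ])
        m = _fluor(values, ["t1", "t2", "n1", "n2", "n3"])
        ranking = rank_normalizer_stability(m, tiny_panel)
        assert ranking.ranking[0] == ("n1", 0.0)

    def test_cv_ordering_recovered_across_seeds(self, tiny_panel):
        """Noise-injected references rank by their configured dispersion."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cols = {
                "t1": rng.uniform(50, 150, 30), "t2": rng.uniform(50, 150, 30),
                "n1": 2 ** rng.normal(8, 0.08, 30),
                "n2": 2 ** rng.normal(8, 0.4, 30),
                "n3": 2 ** rng.normal(8, 1.6, 30),
            }
            m = _fluor(np.column_stack(list(cols.values())), list(cols))
            order = [p for p, _ in rank_normalizer_stability(m, tiny_panel).ranking]
            hits += order == ["n1", "n2", "n3"]
        assert hits >= 95

    def test_default_cohort_selects_the_canonical_pair(self):
        """miR-222/miR-181a carry the smallest dispersions by design."""
        matrix, meta, panel = ms.simulate_fireplex_cohort(ms.SyntheticConfig(seed=8))
        corrected = background_correct(matrix, panel)
        ranking = rank_normalizer_stability(corrected, panel)
        assert set(ranking.top_pair) == {"miR-222", "miR-181a"}

    def test_sample_order_invariance(self, tiny_panel):
        rng = np.random.default_rng(1)
        values = rng.uniform(20, 200, (12, 5))
        m = _fluor(values, ["t1", "t2", "n1", "n2", "n3"])
        shuffled = _fluor(values[::-1], ["t1", "t2", "n1", "n2", "n3"])
        a = rank_normalizer_stability(m, tiny_panel).ranking
        b = rank_normalizer_stability(shuffled, tiny_panel).ranking
        assert [p for p, _ in a] == [p for p, _ in b]
        assert np.allclose([s for _, s in a], [s for _, s in b])


class TestNormalize:
    def test_hand_case(self, tiny_panel):
        m = _fluor([[8, 3, 2, 8, 5]], ["t1", "t2", "n1", "n2", "n3"])
        nm = normalize(m, tiny_panel, ("n1", "n2"))
        assert nm.data.loc["s0", "t1"] == pytest.approx(1.0)  # log2(8/4)

    def test_probe_equal_to_geometric_mean_maps_to_zero(self, tiny_panel):
        m = _fluor([[4, 9, 2, 8, 5]], ["t1", "t2", "n1", "n2", "n3"])
        nm = normalize(m, tiny_panel, ("n1", "n2"))
        assert nm.data.loc["s0", "t1"] == pytest.approx(0.0)

    def test_per_sample_scale_invariance(self, tiny_panel, rng):
        values = rng.uniform(10, 500, (6, 5))
        probes = ["t1", "t2", "n1", "n2", "n3"]
        a = normalize(_fluor(values, probes), tiny_panel, ("n1", "n2"))
        b = normalize(_fluor(values * 10, probes), tiny_panel, ("n1", "n2"))
        assert np.allclose(a.data.to_numpy(), b.data.to_numpy())

    def test_non_positive_signal_rejected(self, tiny_panel):
        m = ms.ExpressionMatrix(
            pd.DataFrame([[0.0, 1, 2, 3, 4]], index=["s0"],
                         columns=["t1", "t2", "n1", "n2", "n3"]),
            "fluorescence",
        )
        with pytest.raises(ValidationError, match="non-positive"):
            normalize(m, tiny_panel, ("n1", "n2"))


class TestCountsToTpm:
    def test_arithmetic(self):
        m = ms.ExpressionMatrix(
            pd.DataFrame([[10, 90]], index=["s0"], columns=["a", "b"]), "counts"
        )
        out = counts_to_tpm(m)
        assert list(out.data.iloc[0]) == [100_000, 900_000]

    def test_rows_sum_to_a_million(self, rng):
        counts = rng.integers(0, 1000, (8, 20)).astype(float)
        counts[:, 0] += 1  # avoid all-zero rows
        m = ms.ExpressionMatrix(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(8)],
                         columns=[f"g{j}" for j in range(20)]), "counts"
        )
        assert np.allclose(counts_to_tpm(m).values.sum(axis=1), 1e6)

    def test_column_permutation_commutes(self, rng):
        counts = rng.integers(1, 1000, (5, 6)).astype(float)
        cols = [f"g{j}" for j in range(6)]
        m = ms.ExpressionMatrix(
            pd.DataFrame(counts, index=[f"s{i}" for i in range(5)], columns=cols),
            "counts",
        )
        perm = ["g3", "g0", "g5", "g1", "g4", "g2"]
        direct = counts_to_tpm(m).data[perm]
        permuted_first = counts_to_tpm(
            ms.ExpressionMatrix(m.data[perm], "counts")
        ).data
        assert np.allclose(direct.to_numpy(), permuted_first.to_numpy())

    def test_all_zero_sample_named(self):
        m = ms.ExpressionMatrix(
            pd.DataFrame([[1, 2], [0, 0]], index=["ok", "empty"],
                         columns=["a", "b"]), "counts"
        )
        with pytest.raises(ValidationError, match="empty"):
            counts_to_tpm(m)


class TestCollapseReplicates:
    @pytest.fixture()
    def triplicates(self):
        meta = [
            ms.SampleMeta(sample_id=f"m1_d0_r{r}", group="control",
                          subject_id="m1", timepoint_day=0, replicate_index=r)
            for r in (1, 2, 3)
        ]
        m = ms.ExpressionMatrix(
            pd.DataFrame([[1.0], [2.0], [3.0]],
                         index=[x.sample_id for x in meta], columns=["p"]),
            "fluorescence",
        )
        return m, meta

    def test_median_of_triplicate(self, triplicates):
        m, meta = triplicates
        out, out_meta = collapse_replicates(m, meta, policy="median")
        assert out.shape == (1, 1) and out.values[0, 0] == 2.0
        assert out_meta[0].sample_id == "m1_d0"

    def test_keep_is_identity(self, triplicates):
        m, meta = triplicates
        out, out_meta = collapse_replicates(m, meta, policy="keep")
        assert out is m and out_meta is meta

    def test_group_count_equals_distinct_subject_timepoints(self, small_fireplex):
        cfg, matrix, meta, panel = small_fireplex
        specimen = [s for s in matrix.sample_ids if s not in set(panel.blanks)]
        sub = matrix.select_samples(specimen)
        sub_meta = [m for m in meta if m.sample_id in set(specimen)]
        out, out_meta = collapse_replicates(sub, sub_meta, policy="mean")
        expected = len({(m.subject_id, m.timepoint_day) for m in sub_meta})
        assert out.shape[0] == expected == len(out_meta)
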