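"""Differential expression: size factors, Welch stages, filter rules."""

import numpy as np
import pandas as pd
import pytest

from mirpair.de import de_counts, de_proteins, size_factors
from mirpair.errors import NormalizationError, StatisticsError, ValidationError
from mirpair.synthetic import CohortDesign, EffectSpec, SimulationParams, simulate_study, with_seed


def sheet(groups):
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(groups))], "group": groups}
    )


class TestSizeFactors:
    def test_hand_computed_two_sample_case(self):
        counts = pd.DataFrame(
            {"s0": [10, 20, 30], "s1": [20, 40, 60]}, index=["a", "b", "c"]
        )
        sf = size_factors(counts)
        np.testing.assert_allclose(sf, [0.7071, 1.4142], atol=5e-5)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"s0": [5, 7, 9], "s1": [5, 7, 9], "s2": [5, 7, 9]})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"s0": [1, 2], "s1": [0, 0]})
        with pytest.raises(NormalizationError, match="s1"):
            size_factors(counts)

    def test_normalization_undoes_per_sample_scaling(self, rng):
        """Scaling one sample's counts leaves the normalized matrix
        unchanged up to a single global constant (the geometric-mean
        reference absorbs c^(1/n)), so all between-sample structure is
        invariant."""
        counts = pd.DataFrame(
            rng.poisson(100, size=(30, 4)), columns=[f"s{i}" for i in range(4)]
        )
        scaled = counts.copy()
        scaled["s2"] = scaled["s2"] * 3
        norm = (counts / size_factors(counts)).to_numpy()
        norm_scaled = (scaled / size_factors(scaled)).to_numpy()
        ratio = norm_scaled / norm
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)


class TestDeCounts:
    def test_small_group_rejected(self):
        counts = pd.DataFrame({"s0": [5], "s1": [5], "s2": [5]}, index=["a"])
        with pytest.raises(StatisticsError):
            de_counts(counts, sheet(["A", "B", "B"]), "A", "B")

    def test_duplicate_feature_ids_rejected(self):
        counts = pd.DataFrame(
            [[1, 2, 3, 4], [5, 6, 7, 8]], index=["a", "a"],
            columns=[f"s{i}" for i in range(4)],
        )
        with pytest.raises(ValidationError):
            de_counts(counts, sheet(["A", "A", "B", "B"]), "A", "B")

    def test_group_swap_negates_log2fc_keeps_p(self, rng):
        counts = pd.DataFrame(
            rng.poisson(200, size=(20, 6)), columns=[f"s{i}" for i in range(6)]
        )
        s = sheet(["A"] * 3 + ["B"] * 3)
        ab = de_counts(counts, s, "A", "B").table.set_index("feature")
        ba = de_counts(counts, s, "B", "A").table.set_index("feature")
        np.testing.assert_allclose(ab["log2_fc"], -ba.loc[ab.index, "log2_fc"])
        np.testing.assert_allclose(ab["p"], ba.loc[ab.index, "p"])

    def test_bh_is_monotone_in_p(self, rng):
        counts = pd.DataFrame(
            rng.poisson(150, size=(40, 8)), columns=[f"s{i}" for i in range(8)]
        )
        res = de_counts(counts, sheet(["A"] * 4 + ["B"] * 4), "A", "B").table
        assert (res["p_adjusted"] >= res["p"] - 1e-15).all()
        assert res["p_adjusted"].is_monotonic_increasing  # table sorted by p

    def test_direction_matches_log2fc_sign(self, small_study):
        res = de_counts(small_study.counts, small_study.sample_sheet, "CASE", "CTRL").table
        up = res["direction"] == "up"
        assert ((res.loc[up, "log2_fc"] > 0).all()
                and (res.loc[~up & (res["direction"] == "down"), "log2_fc"] < 0).all())

    def test_large_planted_effect_detected(self):
        """A count effect of Table-2 protein magnitude at n=3 vs 3 is
        BH-significant in nearly all replicates."""
        design = CohortDesign(("A", "B"), (3, 3))
        effects = [EffectSpec("hit", "counts", "A", -7.7, baseline=12.0)]
        # panel-scale family: Welch df ~2-4 at n=3 bounds attainable p near
        # 1e-3, so the BH penalty is what limits power here
        params = SimulationParams(n_background_counts=20)
        found = 0
        n_reps = 40
        for s in range(n_reps):
            study = simulate_study(
                with_seed(design, s), effects, params=params,
                layers=("counts",), n_decoy_links=0,
            )
            res = de_counts(study.counts, study.sample_sheet, "A", "B").table
            row = res.set_index("feature").loc["hit"]
            found += (row["p_adjusted"] < 0.05) and (row["direction"] == "down")
        assert found >= 0.9 * n_reps


class TestDeProteins:
    def test_min_present_filter_logs_dropped_feature(self):
        mat = pd.DataFrame(
            {
                "s0": [1000.0, np.nan], "s1": [1100.0, np.nan], "s2": [900.0, 500.0],
                "s3": [1000.0, 450.0], "s4": [1050.0, 500.0], "s5": [950.0, 480.0],
            },
            index=["kept", "sparse"],
        )
        res = de_proteins(mat, sheet(["A"] * 3 + ["B"] * 3), "A", "B", min_present=2)
        assert list(res.table["feature"]) == ["kept"]
        assert list(res.dropped["feature"]) == ["sparse"]
        assert "observed in <2" in res.dropped["reason"].iloc[0]

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            de_proteins(pd.DataFrame(), sheet(["A", "A", "B", "B"]), "A", "B")

    def test_planted_fold_change_recovered(self):
        """A planted log2FC of -2.15 (SD 0.3) at n=3 vs 3 is recovered
        within +/- 0.5 on average."""
        design = CohortDesign(("A", "B"), (3, 3))
        effects = [EffectSpec("hit", "protein", "A", -2.15, sd=0.3)]
        params = SimulationParams(n_background_proteins=20, protein_missing_rate=0.0)
        ests = []
        for s in range(30):
            study = simulate_study(
                with_seed(design, s), effects, params=params,
                layers=("protein",), n_decoy_links=0,
            )
            res = de_proteins(study.proteins, study.sample_sheet, "A", "B")
            ests.append(res.table.set_index("feature").at["hit", "log2_fc"])
        assert abs(np.median(ests) - (-2.15)) < 0.5

    def test_null_p_values_center_at_half(self):
        """Identical group distributions give a median p near 0.5."""
        design = CohortDesign(("A", "B"), (4, 4))
        params = SimulationParams(n_background_proteins=60, protein_missing_rate=0.0)
        medians = []
        for s in range(30):
            study = simulate_study(
                with_seed(design, s), [], params=params,
                layers=("protein",), n_decoy_links=0,
            )
            res = de_proteins(study.proteins, study.sample_sheet, "A", "B")
            medians.append(res.table["p"].median())
        assert 0.3 < np.mean(medians) < 0.7
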