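import math

import numpy as np
import pandas as pd
import pytest

from omicdiff.config import ThresholdConfig
from omicdiff.ptm import (
    RelativeQuantTable,
    aggregate_sites_to_proteins,
    call_differential_sites,
    centralize,
    cv_statistic,
    fold_change,
    protein_normalize,
)
from omicdiff.simulate import PtmSimConfig, simulate_ptm_experiment

from conftest import make_site_table
from _oracles import oracle_centralize, oracle_cv, oracle_fold_change

CONTRAST = ("CS", "control")


def relq_from(values, sample_ids=None) -> RelativeQuantTable:
    return centralize(make_site_table(values, sample_ids))


class TestCentralize:
    @pytest.mark.parametrize("row,expected", [
        ([10.0, 10.0], [1.0, 1.0]),
        ([2.0, 4.0], [2 / 3, 4 / 3]),
    ])
    def test_forced_values(self, row, expected):
        relq = relq_from([row])
        np.testing.assert_allclose(relq.values.iloc[0].to_numpy(), expected, rtol=1e-12)

    def test_row_means_are_one(self, rng):
        values = rng.lognormal(8, 1.5, (6, 4))
        values[1, 2] = np.nan
        relq = relq_from(values)
        means = relq.values.mean(axis=1, skipna=True)
        np.testing.assert_allclose(means.to_numpy(), 1.0, atol=1e-9)

    def test_idempotence(self, rng):
        values = rng.lognormal(8, 1.5, (5, 4))
        once = centralize(make_site_table(values))
        twice = centralize(once.values)
        pd.testing.assert_frame_equal(twice.values, once.values)

    def test_all_missing_row_dropped(self, caplog):
        values = [[1.0, 2.0], [np.nan, np.nan]]
        with caplog.at_level("INFO"):
            relq = relq_from(values)
        assert len(relq.values) == 1


class TestFoldChange:
    def test_identical_groups_give_one(self, sheet_2x2):
        relq = relq_from([[3.0, 5.0, 3.0, 5.0]],
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        assert fold_change(relq, CONTRAST, sheet_2x2).iloc[0] == pytest.approx(1.0)

    def test_ratio_of_group_means(self, sheet_2x2):
        # mean_CS(R)=0.2, mean_control(R)=2.0 -> fc 0.1 (up to row centering)
        raw = [[20.0, 20.0, 2.0, 2.0]]
        relq = relq_from(raw, sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        assert fold_change(relq, CONTRAST, sheet_2x2).iloc[0] == pytest.approx(0.1)

    def test_reciprocal_contrast(self, sheet_2x2, rng):
        relq = relq_from(rng.lognormal(5, 1, (8, 4)),
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        ab = fold_change(relq, CONTRAST, sheet_2x2)
        ba = fold_change(relq, ("control", "CS"), sheet_2x2)
        np.testing.assert_allclose((ab * ba).to_numpy(), 1.0, rtol=1e-12)

    def test_row_rescaling_invariance(self, sheet_2x2, rng):
        values = rng.lognormal(5, 1, (6, 4))
        base = relq_from(values, sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        scaled = relq_from(values * rng.lognormal(0, 2, (6, 1)),
                           sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        np.testing.assert_allclose(
            fold_change(base, CONTRAST, sheet_2x2).to_numpy(),
            fold_change(scaled, CONTRAST, sheet_2x2).to_numpy(),
            rtol=1e-12,
        )

    def test_group_without_values_is_undefined(self, sheet_2x2):
        relq = relq_from([[1.0, 2.0, np.nan, np.nan]],
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        assert math.isnan(fold_change(relq, CONTRAST, sheet_2x2).iloc[0])


class TestCvStatistic:
    def test_identical_ratios_give_zero(self, sheet_2x2):
        relq = relq_from([[1.0, 2.0, 2.0, 4.0]],
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        assert cv_statistic(relq, CONTRAST, sheet_2x2).iloc[0] == pytest.approx(0.0)

    def test_two_ratio_value(self, sheet_2x2):
        # paired ratios (1.0, 1.2): sample SD 0.2/sqrt(2), mean 1.1
        relq = relq_from([[1.0, 1.0, 1.0, 1.2]],
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        expected = (0.2 / math.sqrt(2)) / 1.1
        assert cv_statistic(relq, CONTRAST, sheet_2x2).iloc[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.12856, abs=5e-6)

    def test_single_usable_pair_is_undefined(self, sheet_2x2):
        relq = relq_from([[1.0, np.nan, 2.0, 3.0]],
                         sample_ids=["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        assert math.isnan(cv_statistic(relq, CONTRAST, sheet_2x2).iloc[0])


class TestBruteForceOracle:
    """Eq-by-eq agreement with a naive loop implementation."""

    def test_random_tables_match_oracle(self, sheet_2x2, rng):
        sample_ids = ["ctrl_1", "ctrl_2", "CS_1", "CS_2"]
        pairs = [(2, 0), (3, 1)]          # (CS_i, ctrl_i) column positions
        for _ in range(30):
            values = rng.lognormal(6, 1, (5, 4))
            values[rng.random((5, 4)) < 0.15] = np.nan
            values = values[~np.all(np.isnan(values), axis=1)]
            relq = relq_from(values, sample_ids)
            expected_r = oracle_centralize(values.tolist())
            np.testing.assert_allclose(relq.values.to_numpy(), expected_r,
                                       rtol=1e-12, equal_nan=True)
            fc = fold_change(relq, CONTRAST, sheet_2x2)
            cv = cv_statistic(relq, CONTRAST, sheet_2x2)
            for i, row in enumerate(expected_r):
                np.testing.assert_allclose(
                    fc.iloc[i], oracle_fold_change(row, [2, 3], [0, 1]),
                    rtol=1e-10, equal_nan=True)
                np.testing.assert_allclose(
                    cv.iloc[i], oracle_cv(row, pairs), rtol=1e-10, equal_nan=True)


class TestProteinNormalize:
    def test_perfect_cancellation(self, sheet_2x2):
        sample_ids = ["ctrl_1", "ctrl_2", "CS_1", "CS_2"]
        relq = relq_from([[1.0, 3.0, 1.0, 3.0]], sample_ids)
        proteins = pd.DataFrame([[1.0, 3.0, 1.0, 3.0]],
                                index=pd.Index(["P000"], name="protein_id"),
                                columns=sample_ids)
        out = protein_normalize(relq, proteins)
        np.testing.assert_allclose(out.values.iloc[0].to_numpy(), 1.0, rtol=1e-12)
        assert bool(out.protein_normalized.iloc[0])

    def test_absent_protein_falls_back(self, sheet_2x2):
        sample_ids = ["ctrl_1", "ctrl_2", "CS_1", "CS_2"]
        relq = relq_from([[1.0, 2.0, 3.0, 4.0]], sample_ids)
        proteins = pd.DataFrame([[1.0, 1.0, 1.0, 1.0]],
                                index=pd.Index(["OTHER"], name="protein_id"),
                                columns=sample_ids)
        out = protein_normalize(relq, proteins)
        pd.testing.assert_frame_equal(out.values, relq.values)
        assert not bool(out.protein_normalized.iloc[0])

    def test_coupled_effect_cancels_after_normalization(self):
        cfg = PtmSimConfig(n_proteins=30, sites_per_protein=1, noise_log_sd=0.0,
                           missing_rate=0.0, n_true_up=3, n_true_down=3,
                           effect_fold=4.0, coupled_protein_effect=True, seed=11)
        sites, proteins, sheet, truth = simulate_ptm_experiment(cfg)
        raw_fc = fold_change(centralize(sites), ("CS", "control"), sheet)
        norm_fc = fold_change(protein_normalize(centralize(sites), proteins),
                              ("CS", "control"), sheet)
        for key in truth.true_up | truth.true_down:
            assert raw_fc.loc[key] != pytest.approx(1.0)
            assert norm_fc.loc[key] == pytest.approx(1.0, rel=1e-9)


class TestCalling:
    def make_calls(self, raw_rows, mode):
        sample_ids = ["ctrl_1", "ctrl_2", "CS_1", "CS_2"]
        sheet = pd.DataFrame({
            "sample_id": sample_ids,
            "group": ["control", "control", "CS", "CS"],
            "replicate_index": [1, 2, 1, 2],
        })
        from omicdiff.io import SampleSheet
        relq = relq_from(raw_rows, sample_ids)
        return call_differential_sites(relq, CONTRAST, SampleSheet(sheet),
                                       ThresholdConfig.for_mode(mode))

    def test_strong_down_site_called(self):
        calls = self.make_calls([[10.0, 10.0, 1.0, 1.0]], "label_free")
        assert calls["direction"].iloc[0] == "down"
        assert calls["fc"].iloc[0] == pytest.approx(0.1)

    def test_boundary_fc_is_ns(self):
        # fc exactly 1.3 with cv 0: strict inequality keeps it ns
        calls = self.make_calls([[1.0, 1.0, 1.3, 1.3]], "label_free")
        assert calls["fc"].iloc[0] == pytest.approx(1.3)
        assert calls["direction"].iloc[0] == "ns"

    def test_regime_dependence(self):
        row = [[1.0, 1.0, 1.25, 1.25]]
        assert self.make_calls(row, "label_free")["direction"].iloc[0] == "ns"
        assert self.make_calls(row, "tmt")["direction"].iloc[0] == "up"

    def test_undetermined_with_single_pair(self):
        calls = self.make_calls([[1.0, np.nan, 5.0, 5.0]], "label_free")
        assert calls["direction"].iloc[0] == "undetermined"
        assert calls["n_ratio_pairs"].iloc[0] == 1

    def test_metabolite_mode_rejected(self, sheet_2x2):
        relq = relq_from([[1.0, 1.0, 1.0, 1.0]], ["ctrl_1", "ctrl_2", "CS_1", "CS_2"])
        with pytest.raises(ValueError, match="label_free or tmt"):
            call_differential_sites(relq, CONTRAST, sheet_2x2,
                                    ThresholdConfig.for_mode("metabolite"))


class TestAggregation:
    def make_calls_frame(self, rows):
        index = pd.MultiIndex.from_tuples(
            [(pid, "K", pos, "crotonyl") for pid, pos in
             [(r[0], 10 * i) for i, r in enumerate(rows)]],
            names=["protein_id", "residue", "position", "modification"],
        )
        return pd.DataFrame({"direction": [r[1] for r in rows]}, index=index)

    def test_two_down_sites_one_protein(self):
        out = aggregate_sites_to_proteins(
            self.make_calls_frame([("P1", "down"), ("P1", "down")]))
        assert out.loc["P1", "n_sites_down"] == 2
        assert bool(out.loc["P1", "protein_direction_down"])
        assert not bool(out.loc["P1", "protein_direction_up"])

    def test_protein_may_be_both_directions(self):
        out = aggregate_sites_to_proteins(
            self.make_calls_frame([("P1", "up"), ("P1", "down")]))
        assert bool(out.loc["P1", "protein_direction_up"])
        assert bool(out.loc["P1", "protein_direction_down"])

    def test_protein_counts_bounded_by_site_counts(self, rng):
        rows = [(f"P{rng.integers(5)}", rng.choice(["up", "down", "ns"]))
                for _ in range(40)]
        calls = self.make_calls_frame(rows)
        out = aggregate_sites_to_proteins(calls)
        n_sites_up = sum(1 for _, d in rows if d == "up")
        n_sites_down = sum(1 for _, d in rows if d == "down")
        assert out["protein_direction_up"].sum() <= n_sites_up
        assert out["protein_direction_down"].sum() <= n_sites_down
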