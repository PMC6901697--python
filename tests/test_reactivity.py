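"""GPR parsing, normalization, ComBat and reactivity calls."""

import numpy as np
import pandas as pd
import pytest

from igomeprof.reactivity import (
    ReactivityMatrix,
    SpotTable,
    balance_batches,
    call_reactivities,
    combat_adjust,
    normalize_set,
    preprocess_array,
    quantile_normalize,
    read_genepix,
    write_genepix,
)
from igomeprof.synthetic import (
    ReactivityConfig,
    reactivity_to_gpr,
    simulate_reactivity,
)


def _spot_table(rows):
    return SpotTable(
        data=pd.DataFrame(rows),
        header={"Type": "GenePix Results 3"},
    )


def _spot(block, row, col, pid, f, b=0.0, flag=0):
    return {
        "Block": block, "Row": row, "Column": col, "ID": pid,
        "F635 Median": f, "B635 Median": b, "Flags": flag,
    }


class TestGenepixIO:
    def test_minimal_fixture_parsed(self, tmp_path):
        p = tmp_path / "a.gpr"
        p.write_text(
            "ATF\t1.0\n"
            "2\t7\n"
            '"Type=GenePix Results 3"\n'
            '"Wavelengths=635"\n'
            "Block\tRow\tColumn\tID\tF635 Median\tB635 Median\tFlags\n"
            "1\t1\t1\tpepA\t100\t10\t0\n"
            "1\t1\t2\tpepB\t200\t10\t0\n"
            "1\t2\t1\tpepA\t110\t10\t0\n"
            "1\t2\t2\tpepC\t50\t10\t-100\n"
        )
        spots = read_genepix(p)
        assert len(spots.data) == 4
        assert spots.header["Type"] == "GenePix Results 3"
        assert spots.data["Flags"].tolist() == [0, 0, 0, -100]

    def test_missing_column_errors(self, tmp_path):
        p = tmp_path / "bad.gpr"
        p.write_text(
            "ATF\t1.0\n0\t3\nBlock\tRow\tColumn\n1\t1\t1\n"
        )
        with pytest.raises(ValueError, match="ID"):
            read_genepix(p)

    def test_roundtrip(self, tmp_path):
        table = _spot_table([_spot(1, 1, 1, "p1", 100.0), _spot(1, 1, 2, "p2", 64.0)])
        path = tmp_path / "rt.gpr"
        write_genepix(table, path)
        loaded = read_genepix(path)
        pd.testing.assert_frame_equal(
            loaded.data[table.data.columns], table.data, check_dtype=False
        )


class TestPreprocess:
    def test_duplicate_merge(self):
        spots = _spot_table([_spot(1, 1, 1, "p", 8.0), _spot(1, 2, 1, "p", 8.0)])
        values, _ = preprocess_array(spots)
        assert values["p"] == pytest.approx(3.0)

    def test_flagged_duplicate_ignored(self):
        spots = _spot_table(
            [_spot(1, 1, 1, "p", 8.0), _spot(1, 2, 1, "p", 900.0, flag=-100)]
        )
        values, report = preprocess_array(spots)
        assert values["p"] == pytest.approx(3.0)
        assert report.n_flagged == 1

    def test_fully_flagged_peptide_imputed(self):
        spots = _spot_table(
            [
                _spot(1, 1, 1, "p", 8.0, flag=-100),
                _spot(1, 1, 2, "q", 16.0),
                _spot(1, 2, 1, "r", 16.0),
            ]
        )
        values, report = preprocess_array(spots)
        assert report.imputed_peptides == ["p"]
        assert values["p"] == pytest.approx(4.0)

    def test_block_offset_removed(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(40):
            v = float(2 ** rng.normal(8, 0.3))
            rows.append(_spot(1, i + 1, 1, f"p{i}", v))
            rows.append(_spot(2, i + 1, 1, f"p{i}", v * 2.0))  # +1 log2 offset
        values, _ = preprocess_array(_spot_table(rows))
        # duplicates in the offset block agree after local centering
        per_spot = pd.DataFrame(rows)
        per_spot["signal"] = np.log2(per_spot["F635 Median"])
        gap = (
            per_spot.groupby("Block")["signal"].mean().diff().iloc[-1]
        )
        assert abs(gap) > 0.9  # offset present pre-centering
        spread = values - np.log2(
            per_spot[per_spot.Block == 1].set_index("ID")["F635 Median"]
        ).loc[values.index]
        assert spread.abs().median() < 0.05 + 0.51  # centered to array median


class TestNormalize:
    def test_hand_computed_quantiles(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_single_array_unchanged(self):
        s = pd.Series([1.0, 5.0, 2.0], index=["x", "y", "z"])
        mat = normalize_set({"only": s})
        assert mat.values["only"].tolist() == [1.0, 5.0, 2.0]

    def test_columns_identical_after(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (50, 4)))
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (30, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.allclose(once.to_numpy(), twice.to_numpy())

    def test_panel_mismatch_errors(self):
        a = pd.Series([1.0], index=["x"])
        b = pd.Series([1.0], index=["y"])
        with pytest.raises(ValueError):
            normalize_set({"a": a, "b": b})


class TestCombat:
    def test_single_batch_identity(self, small_matrix):
        values, meta = small_matrix
        meta = meta.assign(batch="G")
        mat = ReactivityMatrix(values, meta)
        out = combat_adjust(mat)
        assert np.allclose(out.values.to_numpy(), values.to_numpy())

    def test_planted_shift_removed(self):
        cfg = ReactivityConfig(
            panel=100, groups={"GBM": 6, "C": 6}, effect_size=0.0,
            n_discriminative=0, batch_offsets={"G": 0.0, "P": 2.0},
        )
        mat, _ = simulate_reactivity(cfg, seed=8)
        out = combat_adjust(mat)
        gaps = (
            out.values.T.groupby(mat.sample_meta["batch"]).mean().diff().iloc[-1]
        )
        assert gaps.abs().mean() < 0.1

    def test_orthogonal_effect_preserved(self):
        cfg = ReactivityConfig(
            panel=100, groups={"GBM": 6, "C": 6}, effect_size=1.5,
            n_discriminative=10, batch_offsets={"G": 0.0, "P": 2.0},
        )
        mat, truth = simulate_reactivity(cfg, seed=9)
        out = combat_adjust(mat, preserve_col="diagnosis")
        gbm = mat.sample_meta.index[mat.sample_meta["diagnosis"] == "GBM"]
        c = mat.sample_meta.index[mat.sample_meta["diagnosis"] == "C"]
        eff = (
            out.values.loc[truth.discriminative, gbm].mean(axis=1)
            - out.values.loc[truth.discriminative, c].mean(axis=1)
        ).mean()
        assert eff == pytest.approx(1.5, rel=0.2)

    def test_removes_planted_batch_variance(self):
        removed = []
        for s in range(20):
            cfg = ReactivityConfig(
                panel=60, groups={"GBM": 5, "C": 5}, effect_size=0.0,
                n_discriminative=0, batch_offsets={"G": 0.0, "P": 1.5},
            )
            mat, _ = simulate_reactivity(cfg, seed=100 + s)
            out = combat_adjust(mat)
            b = mat.sample_meta["batch"]

            def batch_var(df):
                means = df.T.groupby(b).mean()
                return float(((means.iloc[0] - means.iloc[1]) ** 2).mean())

            removed.append(1 - batch_var(out.values) / batch_var(mat.values))
        assert all(r >= 0.9 for r in removed)


class TestCalls:
    def test_value_at_rest_mean_not_significant(self):
        values = pd.DataFrame(
            np.tile([[1.0, 1.0, 1.0, 1.0]], (5, 1)) + np.eye(5, 4) * 0.0,
            index=[f"p{i}" for i in range(5)],
        )
        values.iloc[0] = [2.0, 2.0, 2.0, 2.0]
        values = values + np.random.default_rng(0).normal(0, 0.2, values.shape)
        calls = call_reactivities(values)
        # a cell exactly at the rest mean has z == 0
        row = values.iloc[1]
        assert calls.z.shape == values.shape

    def test_strong_outlier_significant(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.normal(8, 0.5, (30, 8)))
        values.iloc[0, 0] += 10 * 0.5
        calls = call_reactivities(values)
        assert calls.significant.iloc[0, 0]

    def test_zero_variance_marked_nonsignificant(self):
        values = pd.DataFrame(np.ones((4, 5)))
        values.iloc[0, 0] = 5.0
        calls = call_reactivities(values)
        assert not calls.significant.iloc[1:].any().any()

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(0, 1, (400, 10)))
        calls = call_reactivities(values, q=0.05)
        frac = calls.significant.to_numpy().mean()
        assert frac <= 0.07

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            call_reactivities(pd.DataFrame(np.ones((3, 2))))


class TestEndToEnd:
    def test_gpr_pipeline_recovers_matrix(self, tmp_path):
        cfg = ReactivityConfig(panel=40, groups={"GBM": 3, "C": 3}, n_discriminative=0,
                               effect_size=0.0)
        mat, _ = simulate_reactivity(cfg, seed=3)
        paths = reactivity_to_gpr(mat, tmp_path, duplicate_cv=0.05, seed=3)
        arrays = {p.stem: preprocess_array(read_genepix(p))[0] for p in paths}
        rebuilt = normalize_set(arrays, sample_meta=mat.sample_meta)
        # spot-level noise and quantile normalization allowed: values close
        common = rebuilt.values.loc[mat.values.index, mat.values.columns]
        corr = np.corrcoef(common.to_numpy().ravel(), mat.values.to_numpy().ravel())
        assert corr[0, 1] > 0.95


def test_balance_batches_caps_and_excludes():
    rows = []
    for diag, batch, n in [
        ("C", "G", 1), ("C", "P", 3), ("C", "R", 4),
        ("GBM", "G", 2), ("GBM", "P", 4), ("GBM", "R", 9),
        ("ML", "G", 2), ("ML", "P", 4), ("ML", "R", 3),
        ("MB", "R", 2),
    ]:
        for i in range(n):
            rows.append(
                {"sample": f"{diag}{batch}{i}", "diagnosis": diag, "batch": batch}
            )
    meta = pd.DataFrame(rows).set_index("sample")
    assert len(meta) == 34
    balanced = balance_batches(meta, caps={("GBM", "R"): 5}, exclude_groups=["MB"])
    assert len(balanced) == 28
    assert (balanced["diagnosis"] != "MB").all()
    gbm_r = balanced[(balanced.diagnosis == "GBM") & (balanced.batch == "R")]
    assert len(gbm_r) == 5
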