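"""Peak-list I/O, blank filtering, and the sample x formula matrix."""

import numpy as np
import pandas as pd
import pytest

import domdiv as dd
from domdiv.peaklists import (
    PeakList,
    assemble_matrix,
    blank_filter,
    normalize_intensities,
    read_environment,
    read_peaklist,
    replicate_qc,
    validate_environment,
    write_peaklist,
)


def _write(tmp_path, text, name="s1.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadPeaklist:
    def test_basic_ingest(self, tmp_path):
        p = read_peaklist(_write(tmp_path, "mz,intensity\n150.0,1e7\n300.0,2e7\n"))
        assert len(p) == 2 and p.sample_id == "s1"
        assert p.mz.tolist() == [150.0, 300.0]

    def test_rows_sorted_ascending(self, tmp_path):
        p = read_peaklist(_write(tmp_path, "mz,intensity\n300.0,2e7\n150.0,1e7\n"))
        assert p.mz.tolist() == [150.0, 300.0]
        assert p.intensity.tolist() == [1e7, 2e7]

    def test_zero_intensity_rejected_with_line(self, tmp_path):
        path = _write(tmp_path, "mz,intensity\n150.0,1e7\n200.0,0\n")
        with pytest.raises(ValueError, match="line 3"):
            read_peaklist(path)

    def test_unparseable_row_names_line(self, tmp_path):
        path = _write(tmp_path, "mz,intensity\n150.0,1e7\nbogus,1e6\n")
        with pytest.raises(ValueError, match="line 3"):
            read_peaklist(path)

    def test_empty_file_errors(self, tmp_path):
        with pytest.raises(ValueError):
            read_peaklist(_write(tmp_path, ""))

    def test_mass_window_drops_rows(self, tmp_path):
        path = _write(tmp_path, "mz,intensity\n50.0,1e7\n150.0,1e7\n1500.0,1e7\n")
        p = read_peaklist(path)
        assert p.mz.tolist() == [150.0]

    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        mz = np.sort(rng.uniform(100, 900, 50))
        inten = rng.lognormal(16, 1, 50)
        original = PeakList("ref", mz, inten)
        write_peaklist(original, tmp_path / "ref.csv")
        again = read_peaklist(tmp_path / "ref.csv")
        np.testing.assert_allclose(again.mz, original.mz, rtol=1e-6)
        np.testing.assert_allclose(again.intensity, original.intensity, rtol=1e-6)


def test_duplicate_mz_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        PeakList("s", np.array([200.0, 200.00005]), np.array([1.0, 2.0]))


class TestBlankFilter:
    def test_peak_well_above_blank_retained(self):
        sample = PeakList("s", np.array([250.0]), np.array([1e7]))
        blank = PeakList("b", np.array([250.0]), np.array([1e6]))
        filtered, report = blank_filter(sample, blank, ratio_min=5)
        assert len(filtered) == 1 and report.empty

    def test_peak_below_ratio_removed(self):
        sample = PeakList("s", np.array([250.0]), np.array([1e7]))
        blank = PeakList("b", np.array([250.0]), np.array([5e6]))
        filtered, report = blank_filter(sample, blank, ratio_min=5)
        assert len(filtered) == 0
        assert report["blank_intensity"].tolist() == [5e6]

    def test_no_overlap_leaves_sample_unchanged(self):
        sample = PeakList("s", np.array([250.0, 300.0]), np.array([1e7, 1e7]))
        blank = PeakList("b", np.array([500.0]), np.array([1e9]))
        filtered, report = blank_filter(sample, blank)
        assert len(filtered) == 2 and report.empty

    def test_ratio_min_must_exceed_one(self):
        sample = PeakList("s", np.array([250.0]), np.array([1e7]))
        with pytest.raises(ValueError):
            blank_filter(sample, sample, ratio_min=1.0)


class TestNormalize:
    def test_examples(self):
        m = pd.DataFrame([[2.0, 2.0], [1.0, 3.0]], index=["a", "b"], columns=["f1", "f2"])
        out = normalize_intensities(m)
        assert out.loc["a"].tolist() == [0.5, 0.5]
        assert out.loc["b"].tolist() == [0.25, 0.75]

    def test_zero_row_names_sample(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]], index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            normalize_intensities(m)

    def test_idempotent_and_zero_preserving(self):
        m = pd.DataFrame([[3.0, 0.0, 1.0], [0.0, 2.0, 2.0]], index=["a", "b"])
        once = normalize_intensities(m)
        twice = normalize_intensities(once)
        pd.testing.assert_frame_equal(once, twice)
        assert once.loc["a"].iloc[1] == 0.0


def _sample(sid, formulas, intensities):
    recs = [
        (200.0 + i, it, dd.MolecularFormula.parse(f), 0.0)
        for i, (f, it) in enumerate(zip(formulas, intensities))
    ]
    return dd.AssignedSample.from_records(sid, recs)


class TestAssembleMatrix:
    def test_union_semantics(self):
        a = _sample("a", ["C6H12O6", "C6H6"], [1.0, 2.0])
        b = _sample("b", ["C6H6", "C8H8O4"], [3.0, 4.0])
        m = assemble_matrix([a, b])
        assert m.shape == (2, 3)
        assert int((m.to_numpy() == 0).sum()) == 2

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            assemble_matrix([_sample("a", ["C6H6"], [1.0])])

    def test_duplicate_sample_id_rejected(self):
        s = _sample("a", ["C6H6"], [1.0])
        with pytest.raises(ValueError):
            assemble_matrix([s, s])

    def test_disjoint_sets_counting(self):
        groups = [["C5H10", "C6H12"], ["C7H14", "C8H16"], ["C9H18", "C10H20"]]
        samples = [_sample(f"s{i}", g, [1.0, 1.0]) for i, g in enumerate(groups)]
        m = assemble_matrix(samples)
        assert m.shape == (3, 6)
        assert int((m.to_numpy() == 0).sum()) == 12

    def test_sample_order_permutation_invariance(self):
        a = _sample("a", ["C6H12O6", "C6H6"], [1.0, 2.0])
        b = _sample("b", ["C6H6"], [3.0])
        c = _sample("c", ["C8H8O4"], [4.0])
        m1 = assemble_matrix([a, b, c]).sort_index()
        m2 = assemble_matrix([c, a, b]).sort_index()
        pd.testing.assert_frame_equal(m1, m2)

    def test_same_formula_peaks_summed(self):
        s = dd.AssignedSample.from_records(
            "a",
            [
                (200.0, 1.0, dd.MolecularFormula.parse("C6H6"), 0.0),
                (201.0, 2.0, dd.MolecularFormula.parse("C6H6"), 0.0),
            ],
        )
        m = assemble_matrix([s, _sample("b", ["C6H6"], [1.0])])
        assert m.loc["a"].tolist() == [3.0]

    def test_columns_sorted_by_exact_mass(self):
        a = _sample("a", ["C8H8O4", "C6H6"], [1.0, 1.0])
        b = _sample("b", ["C6H12O6"], [1.0])
        m = assemble_matrix([a, b])
        masses = [dd.MolecularFormula.parse(c).mass for c in m.columns]
        assert masses == sorted(masses)


def test_replicate_qc_flags_only_divergent_pairs():
    m = pd.DataFrame(
        [[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
        index=["r1", "r2", "weird"],
    )
    qc = replicate_qc(m, threshold=0.05)
    same = qc[(qc.sample_a == "r1") & (qc.sample_b == "r2")].iloc[0]
    assert same.bray_curtis == 0.0 and not same.flagged
    assert qc["flagged"].sum() == 2


class TestEnvironment:
    def _frame(self, **over):
        base = {
            "lake_id": ["a", "b"],
            "lake_type": ["saline", "freshwater"],
            "latitude": [-69.0, -70.0],
            "longitude": [39.0, 40.0],
            "EC": [1.0, 0.02],
            "pH": [8.0, 7.5],
        }
        base.update(over)
        return pd.DataFrame(base).set_index("lake_id")

    def test_valid_table_passes(self):
        validate_environment(self._frame())

    @pytest.mark.parametrize(
        "column, bad",
        [("lake_type", ["ocean", "freshwater"]), ("latitude", [-99.0, -70.0]), ("EC", [0.0, 0.02])],
    )
    def test_invalid_values_rejected(self, column, bad):
        with pytest.raises(ValueError):
            validate_environment(self._frame(**{column: bad}))

    def test_read_environment_csv(self, tmp_path):
        self._frame().reset_index().to_csv(tmp_path / "env.csv", index=False)
        env = read_environment(tmp_path / "env.csv")
        assert list(env.index) == ["a", "b"]
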