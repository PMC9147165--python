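import numpy as np
import pandas as pd
import pytest

from oilspec.exceptions import (
    InconsistentMetadataError,
    IrregularGridError,
    OilspecError,
    SpectraParseError,
)
from oilspec.spectra import (
    AcquisitionMeta,
    RESPONSES,
    SampleTable,
    SpectraMatrix,
    assign_split,
    average_replicates,
    read_spectra_table,
    validate_resolution,
    write_spectra_table,
)


def _meta(sid, rep=1, tech="TRANS", res=8):
    return AcquisitionMeta(sample_id=sid, technique=tech, resolution=res, replicate=rep)


def _matrix(values, axis=None, sids=None, tech="TRANS", res=8):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    p = values.shape[1]
    if axis is None:
        axis = 600.0 + 4.0 * np.arange(p)
    sids = sids or [f"s{i}" for i in range(values.shape[0])]
    return SpectraMatrix(
        axis=np.asarray(axis, float),
        values=values,
        meta=[_meta(s, tech=tech, res=res) for s in sids],
    )


class TestSpectraMatrix:
    def test_rejects_irregular_axis(self):
        with pytest.raises(IrregularGridError, match="irregular grid"):
            _matrix([[1, 2, 3]], axis=[600, 604, 612])

    def test_rejects_mixed_techniques(self):
        axis = np.array([600.0, 604.0])
        meta = [_meta("a", tech="TRANS"), _meta("b", tech="ATR")]
        with pytest.raises(InconsistentMetadataError):
            SpectraMatrix(axis=axis, values=np.ones((2, 2)), meta=meta)

    def test_rejects_axis_outside_technique_range(self):
        with pytest.raises(OilspecError, match="axis"):
            _matrix([[1, 2]], axis=[500.0, 504.0], tech="TRANS")

    def test_rejects_non_finite_values(self):
        with pytest.raises(OilspecError, match="finite"):
            _matrix([[1.0, np.nan, 2.0]])


class TestCsvRoundTrip:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        m = _matrix(rng.uniform(size=(3, 10)), sids=["a", "b", "c"])
        path = tmp_path / "spec.csv"
        write_spectra_table(m, path)
        back = read_spectra_table(path)
        assert np.array_equal(back.values, m.values)
        assert np.array_equal(back.axis, m.axis)
        assert back.meta == m.meta

    def test_shape_propagation(self, tmp_path):
        m = _matrix(np.ones((2, 5)))
        path = tmp_path / "two.csv"
        write_spectra_table(m, path)
        back = read_spectra_table(path)
        assert (back.n_spectra, back.n_points) == (2, 5)

    def test_empty_matrix_round_trip(self, tmp_path):
        m = SpectraMatrix(
            axis=np.array([600.0, 604.0, 608.0]), values=np.empty((0, 3)), meta=[]
        )
        path = tmp_path / "empty.csv"
        write_spectra_table(m, path)
        assert read_spectra_table(path).n_spectra == 0

    def test_descending_axis_normalised(self, tmp_path):
        path = tmp_path / "desc.csv"
        pd.DataFrame(
            {
                "wavenumber_cm-1": [616.0, 612.0, 608.0, 604.0, 600.0],
                "a|TRANS|R8|rep1": [5.0, 4.0, 3.0, 2.0, 1.0],
            }
        ).to_csv(path, index=False)
        m = read_spectra_table(path)
        assert np.array_equal(m.axis, [600, 604, 608, 612, 616])
        assert np.array_equal(m.values[0], [1, 2, 3, 4, 5])

    def test_irregular_file_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame(
            {"wavenumber_cm-1": [600.0, 604.0, 612.0], "a|TRANS|R8|rep1": [1.0, 2.0, 3.0]}
        ).to_csv(path, index=False)
        with pytest.raises(IrregularGridError, match="irregular grid"):
            read_spectra_table(path)

    def test_non_numeric_cell_names_location(self, tmp_path):
        path = tmp_path / "nn.csv"
        path.write_text("wavenumber_cm-1,a|TRANS|R8|rep1\n600,1.0\n604,oops\n")
        with pytest.raises(SpectraParseError, match=r"a\|TRANS\|R8\|rep1"):
            read_spectra_table(path)

    def test_refuses_nan_write(self, tmp_path):
        m = _matrix([[1.0, 2.0]])
        m.values[0, 0] = np.nan
        with pytest.raises(OilspecError):
            write_spectra_table(m, tmp_path / "nan.csv")


class TestAverageReplicates:
    def test_arithmetic_mean(self):
        m = _matrix([[1, 2, 3], [3, 2, 1], [2, 2, 2]], sids=["a", "a", "a"])
        avg = average_replicates(m)
        assert avg.n_spectra == 1
        assert np.allclose(avg.values[0], [2, 2, 2])
        assert avg.meta[0].replicate == 1

    def test_study_scale_collapse(self):
        rng = np.random.default_rng(1)
        sids = [f"s{i:02d}" for i in range(37) for _ in range(3)]
        m = _matrix(rng.uniform(size=(111, 4)), sids=sids)
        assert average_replicates(m).n_spectra == 37

    def test_single_replicate_identity(self):
        m = _matrix([[1.0, 2.0, 3.0]], sids=["only"])
        avg = average_replicates(m)
        assert np.array_equal(avg.values, m.values)


def _sample_table(oil_types, rng=None, responses=None):
    rng = rng or np.random.default_rng(3)
    n = len(oil_types)
    data = {
        "sample_id": [f"s{i:02d}" for i in range(n)],
        "oil_type": oil_types,
    }
    for j, r in enumerate(RESPONSES):
        data[r] = (
            responses[r]
            if responses and r in responses
            else rng.uniform(1, 50, size=n).round(3)
        )
    return SampleTable(pd.DataFrame(data))


TABLE5_COUNTS = (3, 2, 4, 2, 3, 3, 1, 2, 2, 4, 2, 2, 1, 1, 1, 1, 3)


class TestAssignSplit:
    def test_study_design_counts(self):
        oils = [f"oil{t}" for t, c in enumerate(TABLE5_COUNTS) for _ in range(c)]
        t = assign_split(_sample_table(oils), seed=0)
        counts = t.data["split"].value_counts()
        assert counts["calibration"] == 29
        assert counts["validation"] == 8

    def test_singleton_types_all_calibration(self):
        t = assign_split(_sample_table([f"oil{i}" for i in range(6)]), seed=1)
        assert (t.data["split"] == "calibration").all()

    def test_deterministic_and_conserving(self):
        oils = ["a"] * 4 + ["b"] * 3 + ["c"] * 1
        t1 = assign_split(_sample_table(oils), seed=42)
        t2 = assign_split(_sample_table(oils), seed=42)
        assert list(t1.data["split"]) == list(t2.data["split"])
        assert set(t1.data["split"]) <= {"calibration", "validation"}
        for oil, grp in t1.data.groupby("oil_type"):
            assert (grp["split"] == "calibration").sum() in (1, 2)

    def test_extreme_holder_never_in_validation(self):
        # sample 0 holds every maximum, sample 1 every minimum; only sample 2
        # is eligible, so it is always the validation member
        responses = {r: np.array([90.0, 1.0, 40.0]) for r in RESPONSES}
        t = _sample_table(["a", "a", "a"], responses=responses)
        for seed in range(100):
            out = assign_split(t, seed=seed)
            assert list(out.data["split"]) == ["calibration", "calibration", "validation"]

    def test_fallback_when_all_extreme(self):
        # two samples, both extreme in something, plus one more: with three
        # samples each holding an extreme the draw falls back to all of them
        responses = {
            r: np.array([1.0, 50.0, 25.0]) if i % 2 else np.array([50.0, 1.0, 25.0])
            for i, r in enumerate(RESPONSES)
        }
        responses[RESPONSES[0]] = np.array([1.0, 50.0, 99.0])  # third also extreme
        t = _sample_table(["a", "a", "a"], responses=responses)
        out = assign_split(t, seed=0)
        assert (out.data["split"] == "validation").sum() == 1


class TestSampleTableInvariants:
    def test_rejects_negative_reference_value(self):
        with pytest.raises(OilspecError, match="negative"):
            _sample_table(["a"], responses={"iodine_value": np.array([-1.0])})

    def test_rejects_bad_calibration_count(self):
        t = _sample_table(["a", "a", "a"])
        df = t.data.copy()
        df["split"] = ["calibration", "calibration", "calibration"]
        with pytest.raises(OilspecError, match="calibration"):
            SampleTable(df)

    def test_csv_round_trip(self, tmp_path):
        t = assign_split(_sample_table(["a", "a", "a", "b"]), seed=0)
        t.to_csv(tmp_path / "samples.csv")
        back = SampleTable.from_csv(tmp_path / "samples.csv")
        pd.testing.assert_frame_equal(back.data, t.data.reset_index(drop=True))


@pytest.mark.parametrize(
    "spacing,nominal,expected",
    [(4.0, 8, True), (8.0, 8, True), (32.0, 2, False), (1.0, 2, True), (2.0, 2, True)],
)
def test_validate_resolution(spacing, nominal, expected):
    axis = 600.0 + spacing * np.arange(10)
    m = _matrix(np.ones((1, 10)), axis=axis, res=nominal)
    assert validate_resolution(m) is expected
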