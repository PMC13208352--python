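"""Signal quantification: OLS slopes, QC partitioning, chip CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adipokinome as ak
from adipokinome.errors import (
    DegenerateDesignError,
    InsufficientDataError,
    IntegrityError,
    ReplicationError,
    SchemaError,
)
from adipokinome.signal import (
    STATUS_INCLUDED,
    STATUS_NONLINEAR,
    STATUS_SATURATED,
    STATUS_UNDETECTABLE,
    STATUSES,
    qc_filter,
)


def _normal_equation_slope(x, y):
    """Independent closed-form oracle: slope from the normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    A = np.array([[len(x), x.sum()], [x.sum(), (x * x).sum()]])
    b = np.array([y.sum(), (x * y).sum()])
    intercept, slope = np.linalg.solve(A, b)
    return slope


class TestExposureSlope:
    def test_exact_linear_case(self):
        assert ak.exposure_slope([10, 20, 50, 100], [20, 40, 100, 200]) == pytest.approx(200.0)

    def test_flat_intensities_give_zero(self):
        assert ak.exposure_slope([10, 20, 50, 100], [5, 5, 5, 5]) == pytest.approx(0.0)

    def test_matches_normal_equation_oracle(self):
        x, y = [10, 20, 50, 100], [25, 41, 98, 203]
        expected = _normal_equation_slope(x, y) * 100.0
        assert ak.exposure_slope(x, y) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            ak.exposure_slope([50, 50, 50], [1, 2, 3])


class TestKineticSlope:
    def test_exact_line(self):
        t = np.arange(0, 65, 5)
        slope, r2 = ak.kinetic_slope(t, 5 + 3 * t)
        assert slope == pytest.approx(3.0)
        assert r2 == pytest.approx(1.0)

    def test_constant_signal_flags_r2_undefined(self):
        slope, r2 = ak.kinetic_slope([0, 5, 10], [7.0, 7.0, 7.0])
        assert slope == pytest.approx(0.0)
        assert np.isnan(r2)

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            ak.kinetic_slope([0, 5], [1.0, 2.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=13),
           st.integers(0, 2**31 - 1))
    def test_matches_closed_form_on_random_instances(self, ys, seed):
        rng = np.random.default_rng(seed)
        t = np.sort(rng.choice(np.arange(100), size=len(ys), replace=False)).astype(float)
        ys = np.asarray(ys)
        if np.ptp(ys) < 1e-6:
            ys = ys + np.arange(len(ys))  # avoid the (near-)zero-variance branch
        slope, r2 = ak.kinetic_slope(t, ys)
        expected = _normal_equation_slope(t, ys)
        assert slope == pytest.approx(expected, rel=1e-10, abs=1e-10)
        assert 0.0 <= r2 <= 1.0 + 1e-12


class TestReadCycleReadings:
    def test_well_formed_single_row(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(
            "chip_id,array_id,group,assay,cycle_index,time_min,exposure_ms,peptide_id,intensity\n"
            "chip1,a1,control,PTK,1,0,10,pep1,5.5\n"
        )
        df = ak.read_cycle_readings(p)
        assert len(df) == 1
        assert df.loc[0, "intensity"] == 5.5
        assert df.loc[0, "exposure_ms"] == 10.0

    def test_tab_delimiter_autodetected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(
            "chip_id\tarray_id\tgroup\tassay\tcycle_index\ttime_min\texposure_ms\tpeptide_id\tintensity\n"
            "chip1\ta1\tcontrol\tPTK\t1\t0\t10\tpep1\t5.5\n"
        )
        assert len(ak.read_cycle_readings(p)) == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("chip_id,array_id,group,assay,cycle_index,time_min,peptide_id,intensity\n")
        with pytest.raises(SchemaError, match="exposure_ms"):
            ak.read_cycle_readings(p)

    def test_non_numeric_intensity_rows_dropped_with_diagnostics(self, tmp_path, caplog):
        p = tmp_path / "r.csv"
        p.write_text(
            "chip_id,array_id,group,assay,cycle_index,time_min,exposure_ms,peptide_id,intensity\n"
            "chip1,a1,control,PTK,1,0,10,pep1,5.5\n"
            "chip1,a1,control,PTK,1,0,20,pep1,oops\n"
        )
        with caplog.at_level("WARNING"):
            df = ak.read_cycle_readings(p)
        assert len(df) == 1
        assert "row" in caplog.text.lower()

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "r.csv"
        row = "chip1,a1,control,PTK,1,0,10,pep1,5.5\n"
        p.write_text(
            "chip_id,array_id,group,assay,cycle_index,time_min,exposure_ms,peptide_id,intensity\n"
            + row + row
        )
        with pytest.raises(IntegrityError):
            ak.read_cycle_readings(p)


def _signals(r2s, max_intensity=100.0):
    return pd.DataFrame({
        "chip_id": "chip1", "array_id": "a", "group": "g", "assay": "STK",
        "peptide_id": [f"p{i}" for i in range(len(r2s))],
        "slope": 1.0, "r_squared": r2s, "max_intensity": max_intensity,
    })


class TestQCFilter:
    def test_r2_strictly_below_threshold_excluded_boundary_included(self):
        out, parts = qc_filter(_signals([0.79, 0.80, 0.81]))
        assert out.status.tolist() == [STATUS_NONLINEAR, STATUS_INCLUDED, STATUS_INCLUDED]

    def test_undetectable_peptides(self):
        out, _ = qc_filter(_signals([np.nan, 0.9]), detect_min=2.0)
        assert out.status.tolist()[0] == STATUS_UNDETECTABLE
        low = _signals([0.95], max_intensity=1.0)
        assert qc_filter(low)[0].status.tolist() == [STATUS_UNDETECTABLE]

    def test_partition_exhaustive_and_mutually_exclusive(self):
        out, parts = qc_filter(_signals([0.1, 0.5, 0.85, np.nan, 1.0]))
        assert sum(len(v) for v in parts.values()) == len(out)
        assert set(out.status) <= set(STATUSES)

    def test_planted_pure_noise_peptides_are_excluded(self):
        """Flat (rate-0) peptides are undetectable; linear ones included."""
        peps = [f"pep{i:03d}" for i in range(1, 101)]
        noisy = set(peps[:10])
        kmap = ak.KinaseSubstrateMap({"K": (("pep050", 0),)}, frozenset(peps))
        rates = {p: (1e-9 if p in noisy else 50.0) for p in peps}
        truth = ak.PlantedTruth({"K": 1.0}, rates, noise_cv=0.0)
        exp = ak.simulate_experiment(truth, kmap, seed=0)
        sig = ak.quantify(exp.readings)
        excl = set(sig.loc[sig.status != STATUS_INCLUDED, "peptide_id"])
        assert excl == noisy


class TestQuantify:
    def test_noise_free_linear_data_all_r2_one_and_included(self, noise_free_experiment):
        sig = ak.quantify(noise_free_experiment.readings)
        assert (sig.status == STATUS_INCLUDED).all()
        assert sig.r_squared.to_numpy() == pytest.approx(1.0)

    def test_saturated_readings_dropped_slope_recovered(self):
        """Clipping distorts raw fits; dropping clipped points restores rate."""
        kmap = ak.KinaseSubstrateMap({"K": (("p", 0),)}, frozenset({"p"}))
        truth = ak.PlantedTruth(
            {"K": 1.0}, {"p": 100.0}, noise_cv=0.0, saturation_ceiling=3000.0
        )
        exp = ak.simulate_experiment(truth, kmap, seed=0)
        sig = ak.quantify(exp.readings, saturation_ceiling=3000.0)
        inc = sig[sig.group == "control"]
        assert inc.slope.to_numpy() == pytest.approx(100.0, rel=1e-9)

    def test_fully_saturated_peptide_flagged(self):
        kmap = ak.KinaseSubstrateMap({"K": (("p", 0),)}, frozenset({"p"}))
        truth = ak.PlantedTruth(
            {"K": 1.0}, {"p": 1000.0}, noise_cv=0.0, saturation_ceiling=10.0
        )
        exp = ak.simulate_experiment(truth, kmap, seed=0)
        sig = ak.quantify(exp.readings, saturation_ceiling=10.0)
        assert (sig.status == STATUS_SATURATED).all()


class TestChipCV:
    def test_direct_formula(self):
        df = pd.DataFrame({
            "chip_id": ["c1", "c2", "c3"], "array_id": ["a1", "a2", "a3"],
            "group": "g", "assay": "STK", "peptide_id": "p",
            "slope": [90.0, 100.0, 110.0], "r_squared": 1.0,
            "max_intensity": 100.0, "status": STATUS_INCLUDED,
        })
        tab, median_cv = ak.chip_cv(df, high_signal_quantile=0.0)
        assert tab.cv.iloc[0] == pytest.approx(0.10)
        assert median_cv == pytest.approx(0.10)

    def test_identical_signals_zero_cv_and_zero_mean_flagged(self):
        df = pd.DataFrame({
            "chip_id": ["c1", "c2", "c1", "c2"], "array_id": ["a"] * 4,
            "group": "g", "assay": "STK",
            "peptide_id": ["p", "p", "q", "q"],
            "slope": [5.0, 5.0, 0.0, 0.0], "r_squared": 1.0,
            "max_intensity": 100.0, "status": STATUS_INCLUDED,
        })
        tab, _ = ak.chip_cv(df, high_signal_quantile=0.0)
        assert tab.set_index("peptide_id").loc["p", "cv"] == pytest.approx(0.0)
        assert np.isnan(tab.set_index("peptide_id").loc["q", "cv"])

    def test_single_chip_rejected(self):
        df = pd.DataFrame({
            "chip_id": ["c1"], "array_id": ["a"], "group": "g", "assay": "STK",
            "peptide_id": ["p"], "slope": [5.0], "r_squared": 1.0,
            "max_intensity": 100.0, "status": STATUS_INCLUDED,
        })
        with pytest.raises(ReplicationError):
            ak.chip_cv(df)
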