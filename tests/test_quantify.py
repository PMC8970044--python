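"""XIC extraction/integration, normalization, ratios, filtering, profiling."""

import math

import numpy as np
import pandas as pd
import pytest

from glycoprm.io import PrmRun, TableValidationError
from glycoprm.quantify import (
    QuantRecord,
    XicTrace,
    aggregate_charge_states,
    extract_xic,
    filter_identifications,
    fucosylation_ratio,
    integrate_peak,
    normalize_sample,
    profile_distributions,
    replicate_correlation,
    run_set_comparison,
    y1_mz,
)


def trace(times, intensities, **kw):
    return XicTrace(
        target_key=kw.get("target_key", "t"),
        transition=kw.get("transition", "Y1, 2+"),
        times=np.asarray(times, dtype=float),
        intensities=np.asarray(intensities, dtype=float),
        mz_center=kw.get("mz_center", 1000.0),
        tolerance=kw.get("tolerance", 0.05),
    )


class TestExtractXic:
    def run_with_peaks(self, points, make_spectrum):
        spectra = [
            make_spectrum(peaks, scan_id=f"c{i}", rt=t)
            for i, (t, peaks) in enumerate(points)
        ]
        return PrmRun(sample_id="s", spectra=spectra)

    def test_planted_gaussian_reproduced_exactly(self, make_spectrum):
        times = np.arange(9.0, 11.0, 0.05)
        values = 100 * np.exp(-0.5 * ((times - 10.0) / 0.1) ** 2)
        run = self.run_with_peaks(
            [(t, [(1000.0, v)]) for t, v in zip(times, values)], make_spectrum
        )
        tr = extract_xic(run, 1000.0, 0.05)
        np.testing.assert_allclose(tr.intensities, values)

    def test_window_isolation_no_cross_talk(self, make_spectrum):
        run = self.run_with_peaks(
            [(10.0, [(1000.0, 100.0), (1000.2, 999.0)])], make_spectrum
        )
        tr = extract_xic(run, 1000.0, 0.05)
        assert tr.intensities[0] == pytest.approx(100.0)

    def test_off_mz_gives_zero_trace(self, make_spectrum):
        run = self.run_with_peaks([(10.0, [(500.0, 9.0)])], make_spectrum)
        tr = extract_xic(run, 1000.0, 0.05)
        assert np.all(tr.intensities == 0)

    def test_empty_rt_window_empty_trace(self, make_spectrum):
        run = self.run_with_peaks([(10.0, [(1000.0, 1.0)])], make_spectrum)
        tr = extract_xic(run, 1000.0, 0.05, rt_window=(50.0, 55.0))
        assert tr.times.size == 0
        assert integrate_peak(tr) == 0.0


class TestIntegratePeak:
    def test_unit_triangle_closed_form(self):
        tr = trace([0.0, 0.5, 1.0], [0.0, 1.0, 0.0])
        assert integrate_peak(tr) == pytest.approx(0.5)

    def test_gaussian_analytic_area_within_1pct(self):
        h, sd = 250.0, 0.1
        t = np.arange(8.0, 12.0, 0.01)
        y = h * np.exp(-0.5 * ((t - 10.0) / sd) ** 2)
        assert integrate_peak(trace(t, y)) == pytest.approx(
            h * sd * math.sqrt(2 * math.pi), rel=0.01
        )

    def test_all_zero_trace(self):
        assert integrate_peak(trace([0, 1, 2], [0, 0, 0])) == 0.0

    def test_short_trace_integrates_to_zero(self):
        assert integrate_peak(trace([0, 1], [5, 5])) == 0.0

    def test_boundaries_stop_at_local_minima(self):
        # two humps: integrating the taller one must not leak into the
        # neighbour across the valley
        t = np.arange(0, 4.0, 0.01)
        y = 100 * np.exp(-0.5 * ((t - 1.0) / 0.1) ** 2) + 40 * np.exp(
            -0.5 * ((t - 3.0) / 0.1) ** 2
        )
        area = integrate_peak(trace(t, y))
        assert area == pytest.approx(100 * 0.1 * math.sqrt(2 * math.pi), rel=0.01)


class TestNormalize:
    def rec(self, area, sid="s1", key="k"):
        return QuantRecord(sample_id=sid, target_key=key, y1_area=area)

    def test_two_targets(self):
        recs = normalize_sample([self.rec(1.0, key="a"), self.rec(3.0, key="b")])
        assert [r.relative_abundance for r in recs] == [0.25, 0.75]

    def test_single_target_is_unity(self):
        [r] = normalize_sample([self.rec(7.0)])
        assert r.relative_abundance == 1.0

    def test_all_zero_sample_flagged(self):
        recs = normalize_sample([self.rec(0.0, key=k) for k in "abc"])
        assert all(r.relative_abundance == 0.0 for r in recs)
        assert all(r.flagged for r in recs)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_sample([])


class TestAggregateChargeStates:
    def frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample", "peptide", "glycosite", "glycan", "charge", "xic_area"],
        )

    def test_charges_summed(self):
        ids = self.frame(
            [
                ("s1", "PEP", 1, "HexNAc(4)Hex(5)", 2, 10.0),
                ("s1", "PEP", 1, "HexNAc(4)Hex(5)", 3, 5.0),
            ]
        )
        out = aggregate_charge_states(ids)
        assert len(out) == 1
        assert out["xic_area"].iloc[0] == 15.0
        assert out["relative_abundance"].iloc[0] == 1.0

    def test_distinct_glycans_stay_separate(self):
        ids = self.frame(
            [
                ("s1", "PEP", 1, "HexNAc(4)Hex(5)", 2, 10.0),
                ("s1", "PEP", 1, "HexNAc(5)Hex(6)", 2, 5.0),
            ]
        )
        assert len(aggregate_charge_states(ids)) == 2

    def test_mixed_case_composition_strings_merge(self):
        ids = self.frame(
            [
                ("s1", "PEP", 1, "HexNAc(4)Hex(5)", 2, 10.0),
                ("s1", "PEP", 1, "HexNac(4)Gal(5)", 3, 5.0),
            ]
        )
        out = aggregate_charge_states(ids)
        assert len(out) == 1
        assert out["xic_area"].iloc[0] == 15.0


class TestFucosylationRatio:
    def test_arithmetic(self):
        ratio, nlr, defined = fucosylation_ratio(5.0, 10.0)
        assert ratio == 0.5
        assert nlr == pytest.approx(0.3010, abs=1e-4)
        assert defined

    def test_zero_numerator_flagged(self):
        ratio, nlr, defined = fucosylation_ratio(0.0, 10.0)
        assert ratio == 0.0
        assert math.isnan(nlr)
        assert not defined

    def test_zero_denominator_undefined(self):
        ratio, nlr, defined = fucosylation_ratio(10.0, 0.0)
        assert math.isnan(ratio)
        assert not defined

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            fucosylation_ratio(-1.0, 2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.uniform(0.1, 100, 2)
            c = rng.uniform(0.01, 1000)
            r1, _, _ = fucosylation_ratio(a, b)
            r2, _, _ = fucosylation_ratio(c * a, c * b)
            assert r2 == pytest.approx(r1, rel=1e-12)


class TestFilterIdentifications:
    @pytest.fixture()
    def toy(self):
        # hand-enumerated: rows 0 and 3 pass all four thresholds;
        # 1 fails byonic (=150, strict), 2 fails delta, 4 fails pep2d
        # (=0.05, strict), 5 fails fdr2d
        return pd.DataFrame(
            {
                "peptide": [f"P{i}" for i in range(6)],
                "byonic_score": [200.0, 150.0, 300.0, 151.0, 400.0, 250.0],
                "delta_mod_score": [15.0, 20.0, 10.0, 11.0, 30.0, 12.0],
                "pep2d": [0.01, 0.02, 0.03, 0.049, 0.05, 0.002],
                "fdr2d": [0.005, 0.001, 0.009, 0.0099, 0.004, 0.01],
            }
        )

    def test_hand_enumerated_rows_retained(self, toy):
        out = filter_identifications(toy)
        assert list(out["peptide"]) == ["P0", "P3"]
        assert out.attrs["filter_counts"]["removed_total"] == 4

    def test_boundary_score_150_removed(self, toy):
        out = filter_identifications(toy)
        assert "P1" not in set(out["peptide"])

    def test_idempotent(self, toy):
        once = filter_identifications(toy)
        twice = filter_identifications(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_empty_table_passes_through(self, toy):
        out = filter_identifications(toy.iloc[0:0])
        assert len(out) == 0

    def test_missing_column_rejected(self, toy):
        with pytest.raises(TableValidationError, match="pep2d"):
            filter_identifications(toy.drop(columns=["pep2d"]))


class TestProfileDistributions:
    def ids(self, glycans):
        return pd.DataFrame(
            {
                "peptide": [f"P{i}" for i in range(len(glycans))],
                "glycosite": range(len(glycans)),
                "glycan": glycans,
            }
        )

    def test_antennarity_percentages(self):
        out = profile_distributions(
            self.ids(
                [
                    "HexNAc(4)Hex(5)",
                    "HexNAc(4)Hex(4)",
                    "HexNAc(5)Hex(6)",
                    "HexNAc(6)Hex(7)",
                ]
            )
        )
        ant = out["antennarity"]
        assert ant["bi"]["percent"] == 50.0
        assert ant["tri"]["percent"] == 25.0
        assert ant["tetra"]["percent"] == 25.0

    def test_monofucosylated_fraction_among_fucosylated(self):
        out = profile_distributions(
            self.ids(
                [
                    "HexNAc(4)Hex(5)",
                    "HexNAc(4)Hex(5)Fuc(1)",
                    "HexNAc(5)Hex(6)Fuc(1)",
                    "HexNAc(5)Hex(6)Fuc(3)",
                ]
            )
        )
        assert out["n_fucosylated"] == 3
        assert out["fucose_count"][1]["percent"] == pytest.approx(100 * 2 / 3)

    def test_run_set_comparison(self):
        out = run_set_comparison({"A": {"x", "y"}, "B": {"y", "z"}})
        assert out["A|B"]["union"] == 3
        assert out["A|B"]["intersection"] == 1


class TestReplicateCorrelation:
    def test_identical_replicates_r2_one(self):
        v = pd.DataFrame({"r1": [1.0, 2, 3], "r2": [1.0, 2, 3]})
        m = replicate_correlation(v)
        assert m.loc["r1", "r2"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        v = pd.DataFrame({"r1": [1.0, 2, 3], "r2": [2.0, 4, 6]})
        assert replicate_correlation(v).loc["r1", "r2"] == pytest.approx(1.0)

    def test_three_point_hand_value(self):
        # r = 3/sqrt(2 * 42/9) => r^2 = 27/28
        v = pd.DataFrame({"r1": [1.0, 2, 3], "r2": [2.0, 3, 5]})
        assert replicate_correlation(v).loc["r1", "r2"] == pytest.approx(
            27 / 28, abs=1e-12
        )

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(pd.DataFrame({"r1": [1.0, 2]}))


def test_y1_mz_matches_manual_formula():
    # ELHHLQEQNVSNAFLDK: (2020.9966 + 203.0794 + 2*1.007276)/2
    assert y1_mz("ELHHLQEQNVSNAFLDK", 2) == pytest.approx(1113.045, abs=1e-3)
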