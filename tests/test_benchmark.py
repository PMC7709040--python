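"""Reference-table integrity and the comparison statistics."""

import numpy as np
import pytest

from stokesrad.benchmark import (
    DataIntegrityError,
    bias_corrected_stats,
    calibrate_shift,
    deviation_stats,
    load_reference_table,
    preferred_channel,
    ratio_report,
    reference_frame,
    relative_deviation_report,
)
from stokesrad.chem_input import InputError
from stokesrad.diffusion import WATER_298K, round_half_up, stokes_einstein


@pytest.fixture(scope="module")
def table():
    return reference_frame()


class TestLoad:
    def test_eighteen_validated_entries(self):
        entries = load_reference_table()
        assert len(entries) == 18

    def test_class_composition(self, table):
        counts = table.compound_class.value_counts()
        assert counts["sugar"] == 8
        assert counts["amino acid"] == 6
        assert counts["drug"] == 4

    def test_xylose_row(self, table):
        row = table.set_index("name").loc["xylose"]
        assert row.r_s == 3.09
        assert row.d_s == 7.94

    def test_corrupted_frame_rejected(self, table):
        bad = table.copy()
        bad.loc[0, "dev_s"] = 99.0
        from stokesrad.benchmark import _validate

        with pytest.raises(DataIntegrityError, match="xylose"):
            _validate(bad)

    def test_deviation_columns_consistent(self, table):
        # every printed deviation equals the difference of its D columns
        assert np.all(np.abs(table.dev_s - (table.d_s - table.d0)) <= 0.005)
        assert np.all(np.abs(table.dev_e - (table.d_e - table.d0)) <= 0.005)

    def test_printed_d_consistent_with_printed_radii(self, table):
        # r -> D via Stokes-Einstein round-trips the reference columns.
        # The simple-radius channel is tight: |dD/dr| * 0.005 (radius
        # stored to 2 decimals) plus 0.005 for the rounding of D itself.
        for _, row in table.iterrows():
            est = stokes_einstein(row.r_s, WATER_298K)
            tol = est / row.r_s * 0.005 + 0.005
            assert est == pytest.approx(row.d_s, abs=tol)
        # The effective-radius channel carries transcription noise in the
        # source data: a few D_e cells sit ~0.03 from their r_e cells, and
        # the leucine r_e (3.51) is inconsistent with its D_e (6.75, which
        # back-solves to r_e = 3.63).  The D_e column, not r_e, is the one
        # the deviation statistics are built on, so it is authoritative.
        for _, row in table.iterrows():
            est = stokes_einstein(row.r_e, WATER_298K)
            if row["name"] == "leucine":
                assert est == pytest.approx(row.d_e, abs=0.25)
            else:
                assert est == pytest.approx(row.d_e, abs=0.03)


class TestShiftCalibration:
    def test_sugar_shift(self, table):
        assert round_half_up(calibrate_shift(table), 2) == 0.65

    def test_six_sugars_qualify(self, table):
        qual = table[table.d0_source == "experimental"]
        assert len(qual) == 6
        assert set(qual.compound_class) == {"sugar"}

    def test_derived_d0_reproduced_exactly(self, table):
        shift = round_half_up(calibrate_shift(table), 2)
        derived = table[table.d0_source == "derived"]
        for _, row in derived.iterrows():
            assert round_half_up(row.d_c + shift, 2) == row.d0

    def test_single_entry_shift(self):
        df = reference_frame().iloc[:1].copy()
        df["d0"] = df["d_c"] + 0.5
        assert calibrate_shift(df) == pytest.approx(0.5)

    def test_no_experimental_entries_rejected(self, table):
        df = table.copy()
        df["d0_source"] = "derived"
        with pytest.raises(InputError):
            calibrate_shift(df)


class TestDeviationStats:
    def test_sugar_effective_channel(self, table):
        sugars = table[table.compound_class == "sugar"]
        assert deviation_stats(sugars.d_e, sugars.d0)["summary"] == 0.27

    def test_non_sugar_simple_channel(self, table):
        others = table[table.compound_class != "sugar"]
        assert len(others) == 10
        assert deviation_stats(others.d_s, others.d0)["summary"] == 0.30

    def test_non_sugar_excluding_alanine(self, table):
        others = table[(table.compound_class != "sugar") & (table.name != "alanine")]
        assert deviation_stats(others.d_s, others.d0)["summary"] == 0.24

    def test_identical_vectors_zero(self):
        out = deviation_stats([1.0, 2.0], [1.0, 2.0])
        assert np.all(out["deviations"] == 0)
        assert out["summary"] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            deviation_stats([1.0], [1.0, 2.0])


class TestBiasCorrection:
    def test_correction_025_gives_017(self, table):
        assert round_half_up(bias_corrected_stats(table, 0.25), 2) == 0.17

    def test_zero_correction_pools_both_channels(self, table):
        # with no shift the statistic is the weighted pool of the sugar
        # 0.27 average (8 rows) and the non-sugar 0.30 average (10 rows)
        expected = (
            np.abs(table[table.compound_class == "sugar"].dev_e).sum()
            + np.abs(table[table.compound_class != "sugar"].dev_s).sum()
        ) / 18.0
        assert bias_corrected_stats(table, 0.0) == pytest.approx(expected)
        assert round_half_up(bias_corrected_stats(table, 0.0), 2) == 0.29

    def test_not_idempotent(self, table):
        once = bias_corrected_stats(table, 0.25)
        twice = bias_corrected_stats(table, 0.50)
        assert once != pytest.approx(twice)

    def test_channel_rule(self, table):
        est = preferred_channel(table)
        sugars = table.compound_class == "sugar"
        assert np.all(est[sugars.to_numpy()] == table.d_e[sugars].to_numpy())
        assert np.all(est[~sugars.to_numpy()] == table.d_s[~sugars].to_numpy())


class TestRatioAndRelativeReports:
    def test_ratios_at_least_one(self, table):
        report = ratio_report(table)
        assert np.all(report.ratio >= 1.0)

    def test_xylose_ratio(self, table):
        report = ratio_report(table).set_index("name")
        assert round_half_up(report.loc["xylose", "ratio"], 1) == 1.1

    def test_fast_green_exceeds_nominal_range(self, table):
        # the dye's anisometry pushes D_s/D_e to ~1.35, just past the
        # 1.1-1.3 span of the other 17 compounds; reported unclamped
        report = ratio_report(table).set_index("name")
        assert report.loc["fast green fcf", "ratio"] == pytest.approx(
            4.54 / 3.36, rel=1e-9
        )
        rest = report.drop("fast green fcf")
        for ratio in rest.ratio:
            assert 1.1 <= round_half_up(ratio, 1) <= 1.3

    def test_relative_deviations(self, table):
        report = relative_deviation_report(table).set_index("name")
        assert report.loc["fructose", "rel_dev_e_pct"] == pytest.approx(
            100 * -0.09 / 6.93, rel=1e-9
        )
        # signs follow the deviation columns
        merged = report.join(table.set_index("name")[["dev_s", "dev_e"]])
        assert np.all(np.sign(merged.rel_dev_s_pct) == np.sign(merged.dev_s))
        assert np.all(np.sign(merged.rel_dev_e_pct) == np.sign(merged.dev_e))
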