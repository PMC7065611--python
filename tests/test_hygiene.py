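"""ATP/TPC guideline classification and survey aggregation arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stainscan import (
    HygieneSample,
    REFERENCE_SURVEY,
    VISUAL_INSPECTION,
    classify_atp,
    classify_tpc,
    overall_positive_rate,
    read_samples_csv,
    summarize,
    survey_totals,
    verdict,
)
from stainscan.errors import DataQualityWarning, InputError

SEVERITY = {"pass": 0, "exceeds_benchmark": 1, "heavy_growth": 2}


@pytest.mark.parametrize(
    "atp,expected",
    [
        (1.9, "dirty"),   # dirty armrest reading
        (0.2, "clean"),   # same surface after cleaning
        (1.0, "dirty"),   # guideline boundary is inclusive
        (0.99, "clean"),
    ],
)
def test_atp_guideline(atp, expected):
    assert classify_atp(atp) == expected


@pytest.mark.parametrize(
    "tpc,expected",
    [
        (191.0, "heavy_growth"),  # toilet door lock knob
        (85.0, "heavy_growth"),   # chair armrest
        (51.0, "heavy_growth"),   # second lock knob
        (40.0, "heavy_growth"),   # heavy-growth boundary, inclusive
        (2.5, "exceeds_benchmark"),
        (0.5, "pass"),            # half the detection limit
    ],
)
def test_tpc_benchmark(tpc, expected):
    assert classify_tpc(tpc) == expected


def test_negative_values_rejected():
    with pytest.raises(InputError):
        classify_atp(-0.1)
    with pytest.raises(InputError):
        classify_tpc(-1.0)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.lists(st.floats(0.0, 500.0), min_size=2, max_size=10))
def test_tpc_severity_is_monotone(values):
    ranked = [SEVERITY[classify_tpc(v)] for v in sorted(values)]
    assert ranked == sorted(ranked)


class TestSample:
    def test_requires_at_least_one_assay(self):
        with pytest.raises(InputError):
            HygieneSample(location="table", surface_area=100.0)

    def test_inconsistent_per_surface_atp_warns(self):
        # 109 RLU over 50 cm² implies 2.18, >10% off the stated 1.9
        with pytest.warns(DataQualityWarning):
            HygieneSample(location="armrest", surface_area=50.0, atp=1.9, atp_surface=109.0)

    def test_verdict_combines_both_assays(self):
        s = HygieneSample(location="lock", surface_area=37.0, atp=0.4, tpc=51.0)
        v = verdict(s)
        assert (v.atp_status, v.tpc_status) == ("clean", "heavy_growth")

    def test_verdict_not_applicable_without_assay(self):
        s = HygieneSample(location="lock", surface_area=37.0, tpc=1.0)
        assert verdict(s).atp_status == "n/a"


def _synthetic_samples():
    rng = np.random.default_rng(0)
    samples = []
    for loc, n in (("table", 5), ("handle", 3)):
        for _ in range(n):
            samples.append(
                HygieneSample(
                    location=loc,
                    surface_area=100.0,
                    atp=float(rng.uniform(0, 5)),
                    tpc=float(rng.uniform(0, 50)),
                    indicators={"s_aureus": bool(rng.integers(0, 2))},
                )
            )
    return samples


class TestSummarize:
    def test_matches_direct_computation(self):
        samples = _synthetic_samples()
        rows = {s.location: s for s in summarize(samples)}
        table_atp = [s.atp for s in samples if s.location == "table"]
        assert rows["table"].n_atp == 5
        assert rows["table"].atp_mean == pytest.approx(np.mean(table_atp))
        assert rows["table"].atp_sd == pytest.approx(np.std(table_atp, ddof=1))
        assert rows["table"].atp_min == pytest.approx(min(table_atp))
        assert rows["table"].atp_max == pytest.approx(max(table_atp))
        # overall row pools every sample
        assert rows["Total"].n_atp == 8
        assert rows["Total"].atp_mean == pytest.approx(np.mean([s.atp for s in samples]))

    def test_single_sample_location_reports_zero_sd_with_flag(self):
        only = [HygieneSample(location="lock", surface_area=37.0, atp=2.0, tpc=3.0)]
        row = summarize(only)[0]
        assert row.atp_sd == 0.0
        assert not row.sd_defined

    def test_per_location_counts_sum_to_total(self):
        samples = _synthetic_samples()
        rows = summarize(samples)
        total = rows[-1]
        assert sum(r.n_atp for r in rows[:-1]) == total.n_atp
        assert sum(r.n_tpc for r in rows[:-1]) == total.n_tpc


class TestOverallPositiveRate:
    def test_reconstructs_pooled_rate_from_rows(self):
        rows = [(7.1, 14), (8.3, 24), (2.9, 34), (33.3, 6), (20.0, 10), (35.7, 14)]
        # 1+2+1+2+2+5 = 13 positives over 102 row-attributed samples
        assert overall_positive_rate(rows) == pytest.approx(100 * 13 / 102)

    def test_all_zero_percentages(self):
        assert overall_positive_rate([(0.0, 10), (0.0, 5)]) == 0.0

    def test_single_location_identity(self):
        assert overall_positive_rate([(50.0, 10)]) == pytest.approx(50.0)

    def test_ambiguous_rounding_warns(self):
        with pytest.warns(DataQualityWarning):
            overall_positive_rate([(25.0, 2)])  # 0.5 positives is not a count

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InputError):
            overall_positive_rate([(50.0, 0)])
        with pytest.raises(InputError):
            overall_positive_rate([(120.0, 10)])


class TestReferenceSurvey:
    def test_assay_totals(self):
        totals = survey_totals()
        assert totals["n_atp"] == 44
        assert totals["n_tpc"] == 112
        assert totals["n_total"] == 156
        # the published per-location rows only attribute 102 TPC samples
        assert totals["n_tpc_rows"] == 102

    def test_pooled_indicator_rates(self):
        totals = survey_totals()
        assert totals["overall_pct"]["s_aureus"] == pytest.approx(11.6, abs=0.05)
        assert totals["overall_pct"]["enterococci"] == pytest.approx(5.0, abs=0.5)
        assert totals["overall_pct"]["gram_negatives"] == 0.0

    def test_visually_clean_surface_count(self):
        assert VISUAL_INSPECTION["n_inspected"] - VISUAL_INSPECTION["n_visibly_dirty"] == 38


def test_csv_round_trip(tmp_path):
    path = tmp_path / "samples.csv"
    path.write_text(
        "location,surface_area_cm2,atp_rlu_cm2,atp_rlu_surface,tpc_cfu_cm2,"
        "s_aureus,enterococci,gram_negatives\n"
        "table,100,1.2,,3.6,1,0,0\n"
        "lock,37,,,51.0,,,\n"
    )
    samples = read_samples_csv(path)
    assert len(samples) == 2
    assert samples[0].indicators == {"s_aureus": True, "enterococci": False, "gram_negatives": False}
    assert samples[1].atp is None
    assert verdict(samples[1]).tpc_status == "heavy_growth"
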