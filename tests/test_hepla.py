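"""The %HEPLA index, PRP validation, interpretation and aggregation."""

import itertools
from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hitfca import (
    AssayRun,
    DataError,
    HeplaResult,
    ReferenceLimits,
    TubeActivation,
    aggregate,
    classify,
    check_stability,
    compute_hepla,
    interpret,
    validate_prp,
)
from hitfca.hepla import INDETERMINATE, NEGATIVE, POSITIVE, VERDICT_INCONCLUSIVE, VERDICT_REPEAT


def make_run(neg, pos, h03, h100, age_min=None):
    tubes = {
        role: TubeActivation(tube_role=role, percent_activated=val, n_events=10_000)
        for role, val in zip(("NEG", "POS", "H03", "H100"), (neg, pos, h03, h100))
    }
    prepared = measured = None
    if age_min is not None:
        prepared = datetime(2021, 3, 1, 9, 0)
        measured = prepared + timedelta(minutes=age_min)
    return AssayRun(tubes=tubes, prp_prepared_at=prepared, measured_at=measured)


def make_result(hepla, pct_h100, **kw):
    return HeplaResult(pct_neg=10, pct_pos=90, pct_h03=50, pct_h100=pct_h100, hepla=hepla, **kw)


class TestComputeHepla:
    @pytest.mark.parametrize(
        "neg,pos,h03,h100,expected",
        [
            (10, 90, 90, 10, 100.0),  # numerator equals denominator
            (10, 90, 40, 40, 0.0),  # null numerator
            (10, 90, 58, 14, 55.0),  # (58-14)/(90-10)
            (10, 90, 14, 58, -55.0),  # negative values preserved
        ],
    )
    def test_index(self, neg, pos, h03, h100, expected):
        assert compute_hepla(make_run(neg, pos, h03, h100)) == pytest.approx(expected)

    def test_denominator_error_when_pos_not_above_neg(self):
        with pytest.raises(DataError, match="PRP unusable"):
            compute_hepla(make_run(50, 50, 30, 10))

    @settings(deadline=None, derandomize=True)
    @given(
        neg=st.floats(0, 80),
        span=st.floats(2, 20),
        h03=st.floats(0, 100),
        h100=st.floats(0, 100),
        a=st.floats(0, 10),
        b=st.floats(0.1, 0.9),
    )
    def test_affine_invariance(self, neg, span, h03, h100, a, b):
        """hepla is invariant under pct -> a + b*pct applied to all tubes."""
        pos = neg + span
        base = compute_hepla(make_run(neg, pos, h03, h100))
        shifted = compute_hepla(make_run(*(a + b * v for v in (neg, pos, h03, h100))))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestValidatePrp:
    def test_midpoint_controls_valid(self):
        valid, reasons = validate_prp(make_run(11.1, 90, 40, 10, age_min=120))
        assert valid and reasons == []

    @pytest.mark.parametrize(
        "neg,pos,phrase",
        [
            (1.0, 90, "poorly reactive"),
            (25.0, 90, "over-reactive"),
            (11.1, 80, "weak positive"),
        ],
    )
    def test_violations_named(self, neg, pos, phrase):
        valid, reasons = validate_prp(make_run(neg, pos, 40, 10))
        assert not valid
        assert any(phrase in r for r in reasons)

    def test_stale_prp(self):
        valid, reasons = validate_prp(make_run(11.1, 90, 40, 10, age_min=200))
        assert not valid
        assert any("stale" in r for r in reasons)

    def test_boundaries_are_inclusive(self):
        valid, _ = validate_prp(make_run(2.9, 84.9, 40, 10, age_min=180))
        assert valid


class TestStability:
    @pytest.mark.parametrize("age,status", [(120, "pass"), (180, "pass"), (200, "fail")])
    def test_window(self, age, status):
        assert check_stability(make_run(11, 90, 40, 10, age_min=age))["status"] == status

    def test_missing_timestamps_warn(self):
        assert check_stability(make_run(11, 90, 40, 10))["status"] == "warn"


class TestInterpret:
    @pytest.mark.parametrize(
        "hepla,h100,expected,flag",
        [
            (92.6, 8, POSITIVE, False),
            (2.6, 10, NEGATIVE, False),
            (-5, 40, INDETERMINATE, True),  # low index with uninhibited H100
            (11, 10, INDETERMINATE, False),  # gray zone
            (13.0, 10, INDETERMINATE, False),  # boundary falls in gray zone
            (9.6, 10, INDETERMINATE, False),
            (13.1, 90, POSITIVE, False),  # positive regardless of %H100
        ],
    )
    def test_decision_branches(self, hepla, h100, expected, flag):
        res = make_result(hepla, h100)
        assert interpret(res) == expected
        assert res.h100_high_flag == flag

    def test_invalid_prp_refused_with_reasons(self):
        res = make_result(50, 10, prp_valid=False, validity_reasons=["stale PRP"])
        with pytest.raises(DataError, match="stale PRP"):
            interpret(res)

    @settings(deadline=None, derandomize=True)
    @given(hepla=st.floats(-100, 200), h100=st.floats(0, 100))
    def test_total_and_deterministic(self, hepla, h100):
        out1 = classify(hepla, h100)
        out2 = classify(hepla, h100)
        assert out1 == out2
        assert out1[0] in (POSITIVE, NEGATIVE, INDETERMINATE)


class TestAggregate:
    def _res(self, call):
        r = make_result(50, 10)
        r.interpretation = call
        return r

    def test_believe_the_positive(self):
        final = aggregate([self._res(POSITIVE), self._res(NEGATIVE)])
        assert final.verdict == POSITIVE

    def test_unanimous_negative(self):
        assert aggregate([self._res(NEGATIVE), self._res(NEGATIVE)]).verdict == NEGATIVE

    def test_indeterminate_routes_by_round(self):
        assert aggregate([self._res(INDETERMINATE)], round="initial").verdict == VERDICT_REPEAT
        assert aggregate([self._res(INDETERMINATE)], round="repeat").verdict == VERDICT_INCONCLUSIVE

    def test_permutation_invariant(self):
        calls = [POSITIVE, NEGATIVE, INDETERMINATE]
        verdicts = {
            aggregate([self._res(c) for c in perm]).verdict
            for perm in itertools.permutations(calls)
        }
        assert verdicts == {POSITIVE}

    def test_empty_or_all_invalid_rejected(self):
        with pytest.raises(DataError):
            aggregate([])
        invalid = make_result(50, 10, prp_valid=False)
        with pytest.raises(DataError):
            aggregate([invalid])


class TestReferenceLimits:
    def test_defaults_are_the_published_constants(self):
        lim = ReferenceLimits()
        assert (lim.neg_low, lim.neg_high, lim.pos_low) == (2.9, 19.3, 84.9)
        assert (lim.hepla_negative, lim.hepla_positive, lim.h100_high) == (9.6, 13.0, 23.0)

    def test_gray_zone_lower_bound_is_overridable(self):
        # the alternative 9.0 lower bound remains configurable
        lim = ReferenceLimits(hepla_negative=9.0)
        assert classify(9.3, 10, lim)[0] == INDETERMINATE
        assert classify(8.9, 10, lim)[0] == NEGATIVE
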