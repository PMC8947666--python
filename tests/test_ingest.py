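"""Reading, preprocessing rules and daily aggregation."""

import datetime
import random

import numpy as np
import pytest

from metalrisk.ingest import (
    preprocess,
    read_detection_table,
    summarize_daily,
)
from metalrisk.records import DetectionRecord, Metal, parse_metal

D = datetime.date(2020, 3, 1)


def _rec(metal=Metal.CADMIUM, raw="0.1", value=0.1, censored=False, lod=None, date=D):
    return DetectionRecord(
        metal=metal, date=date, raw_result=raw, value=value, censored=censored, lod=lod
    )


class TestReadTable:
    def test_reads_numeric_censored_and_rejects_bad_rows(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(
            "Heavy Metal Elements,Date of Inspection,Inspection Result,Province\n"
            "Cadmium(Cd),9/9/2020,0.071,Henan\n"
            "Inorganic arsenic(As),6/24/2020,Not detected,Zhejiang\n"
            "Unobtainium,6/24/2020,0.2,Hebei\n"
            "Chromium(Cr),not-a-date,0.3,Hebei\n"
        )
        records, report = read_detection_table(p)
        assert report.n_parsed == 2 and report.n_rejected == 2
        assert report.reasons == {"unparseable metal": 1, "unparseable date": 1}
        cd, ars = records
        assert cd.metal is Metal.CADMIUM and cd.value == pytest.approx(0.071)
        assert not cd.censored
        assert ars.metal is Metal.ARSENIC and ars.censored and ars.value is None

    def test_zero_parseable_rows_is_an_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("Heavy Metal Elements,Date of Inspection,Inspection Result\n")
        with pytest.raises(ValueError, match="zero parseable rows"):
            read_detection_table(p)

    def test_missing_column_and_missing_file(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("foo,bar\n1,2\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            read_detection_table(p)
        with pytest.raises(FileNotFoundError):
            read_detection_table(tmp_path / "nope.csv")

    def test_metal_aliases(self):
        assert parse_metal("Chromium(Cr)") is Metal.CHROMIUM
        assert parse_metal(" inorganic arsenic(As) ") is Metal.ARSENIC
        with pytest.raises(ValueError):
            parse_metal("lead")


class TestPreprocess:
    def test_half_lod_substitution(self):
        out = preprocess([_rec(raw="Not detected", value=None, censored=True, lod=0.01)])
        assert out[0].value == pytest.approx(0.005)
        assert not out[0].censored

    def test_lod_table_fallback_and_missing_lod_error(self):
        rec = _rec(raw="Not detected", value=None, censored=True)
        out = preprocess([rec], lod_table={Metal.CADMIUM: 0.02})
        assert out[0].value == pytest.approx(0.01)
        with pytest.raises(ValueError, match="no resolvable LOD"):
            preprocess([rec])

    def test_symbol_stripping_keeps_value(self):
        out = preprocess([_rec(raw="<0.05", value=None)])
        assert out[0].value == pytest.approx(0.05)
        assert not out[0].censored

    def test_arsenic_ratio_applied_exactly_once(self):
        rec = _rec(metal=Metal.ARSENIC, raw="0.10", value=0.10)
        once = preprocess([rec], inorganic_as_ratio=0.70)
        assert once[0].value == pytest.approx(0.07)
        twice = preprocess(once, inorganic_as_ratio=0.70)
        assert twice[0].value == pytest.approx(0.07)  # guarded by processed flag

    def test_idempotent_on_processed_records(self):
        recs = [
            _rec(raw="Not detected", value=None, censored=True, lod=0.01),
            _rec(metal=Metal.ARSENIC, raw="0.2", value=0.2),
            _rec(raw="<0.05", value=None),
        ]
        once = preprocess(recs)
        again = preprocess(once)
        assert [r.value for r in again] == [r.value for r in once]

    def test_censored_arsenic_gets_half_lod_then_ratio(self):
        out = preprocess(
            [_rec(metal=Metal.ARSENIC, raw="Not detected", value=None, censored=True, lod=0.02)]
        )
        assert out[0].value == pytest.approx(0.01 * 0.70)


class TestSummarizeDaily:
    def test_three_point_group_hand_oracle(self):
        recs = preprocess(
            [_rec(raw=str(v), value=v) for v in (0.1, 0.2, 0.3)]
        )
        (s,) = summarize_daily(recs, {Metal.CADMIUM: 0.2})
        assert s.p_max == pytest.approx(1.5)
        assert s.p_avg == pytest.approx(1.0)
        assert s.x_q50 == pytest.approx(0.2)
        assert s.x_q95 == pytest.approx(0.29)  # linear-interpolation quantile

    def test_single_record_degenerate(self):
        recs = preprocess([_rec(raw="0.2", value=0.2)])
        (s,) = summarize_daily(recs, {Metal.CADMIUM: 0.2})
        assert s.p_max == s.p_avg == 1.0
        assert s.x_q50 == s.x_q95 == pytest.approx(0.2)

    def test_missing_limit_errors(self):
        recs = preprocess([_rec(raw="0.2", value=0.2)])
        with pytest.raises(KeyError, match="cadmium"):
            summarize_daily(recs, {Metal.CHROMIUM: 1.0})

    def test_permutation_invariance_and_quantile_order(self):
        rng = np.random.default_rng(3)
        recs = []
        for day in range(4):
            date = D + datetime.timedelta(days=day)
            for metal in Metal:
                for v in rng.lognormal(-2.5, 0.6, size=8):
                    recs.append(_rec(metal=metal, raw=f"{v}", value=float(v), date=date))
        recs = preprocess(recs)
        limits = {Metal.CADMIUM: 0.2, Metal.CHROMIUM: 1.0, Metal.ARSENIC: 0.2}
        base = summarize_daily(recs, limits)
        shuffled = list(recs)
        random.Random(0).shuffle(shuffled)
        assert summarize_daily(shuffled, limits) == base
        for s in base:
            assert s.x_q95 >= s.x_q50 >= 0
            assert s.p_max >= s.p_avg >= 0
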