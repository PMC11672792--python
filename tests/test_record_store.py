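"""Record store: round trips, occupancy queries and QR payloads."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from healthpass.record_store import (CheckinRecord, ParseError,
                                     RecordStoreError, Venue, Visitor,
                                     decode_qr_payload, encode_qr_payload,
                                     occupancy, read_checkins, read_venues,
                                     write_checkins, write_venues)

HEADER = "visitor_id,venue_id,check_in_time,check_out_time,reason,liability\n"


def _random_records(rng, n, open_fraction=0.2):
    records = []
    for i in range(n):
        t_in = float(rng.integers(0, 10_000)) * 60.0
        is_open = rng.random() < open_fraction
        records.append(CheckinRecord(
            visitor=f"u{rng.integers(0, 50):03d}",
            venue=f"v{rng.integers(0, 5)}",
            t_in=t_in,
            t_out=None if is_open else t_in + float(rng.integers(1, 500)) * 60.0,
            reason="errand" if rng.random() < 0.3 else None,
            liability=round(float(rng.random()), 4) if rng.random() < 0.8 else None,
        ))
    return records


def test_domain_type_invariants():
    with pytest.raises(RecordStoreError):
        Visitor("")
    with pytest.raises(RecordStoreError):
        Venue("lib", 0)
    with pytest.raises(RecordStoreError):
        CheckinRecord("u1", "v1", t_in=100.0, t_out=50.0)
    with pytest.raises(RecordStoreError):
        CheckinRecord("u1", "v1", t_in=0.0, liability=1.5)


@pytest.mark.parametrize("fmt", ["csv", "jsonl"])
def test_round_trip_identity(tmp_path, rng, fmt):
    records = _random_records(rng, 60)
    path = tmp_path / f"checkins.{fmt}"
    write_checkins(records, path, format=fmt)
    back = read_checkins(path, format=fmt)
    assert sorted(back, key=lambda r: (r.t_in, r.visitor, r.venue)) == \
        sorted(records, key=lambda r: (r.t_in, r.visitor, r.venue))


def test_read_returns_records_in_checkin_order(tmp_path, rng):
    records = _random_records(rng, 30)
    path = tmp_path / "c.csv"
    write_checkins(records, path)
    back = read_checkins(path)
    assert [r.t_in for r in back] == sorted(r.t_in for r in back)


def test_empty_file_with_header(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(HEADER)
    assert read_checkins(path) == []


def test_write_empty_collection_gives_header_only(tmp_path):
    path = tmp_path / "c.csv"
    write_checkins([], path)
    assert path.read_text() == HEADER


def test_open_session_serialized_with_empty_exit(tmp_path):
    rec = CheckinRecord("u1", "lib", t_in=0.0)
    path = tmp_path / "c.csv"
    write_checkins([rec], path)
    line = path.read_text().splitlines()[1]
    assert line.split(",")[3] == ""
    assert read_checkins(path)[0].t_out is None


def test_parse_error_names_line(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(
        HEADER
        + "u1,lib,2020-05-01T09:00:00+00:00,2020-05-01T10:00:00+00:00,,\n"
        + "u2,lib,2020-05-01T09:00:00+00:00,2020-05-01T08:00:00+00:00,,\n")
    with pytest.raises(ParseError, match="line 3"):
        read_checkins(path)


def test_malformed_timestamp_names_line(tmp_path):
    path = tmp_path / "c.csv"
    path.write_text(HEADER + "u1,lib,yesterday,,,\n")
    with pytest.raises(ParseError, match="line 2"):
        read_checkins(path)


def test_byte_stable_output(tmp_path, rng):
    records = _random_records(rng, 100)
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_checkins(records, p1)
    write_checkins(list(reversed(records)), p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_venues_round_trip(tmp_path):
    venues = [Venue("lib-01", 20), Venue("gym", 35)]
    path = tmp_path / "venues.csv"
    write_venues(venues, path)
    assert read_venues(path) == venues


# --------------------------------------------------------------------------
# occupancy


def test_occupancy_empty_and_unknown_venue():
    assert occupancy([], "lib", 0.0) == 0
    recs = [CheckinRecord("u1", "lib", 0.0, 3600.0)]
    assert occupancy(recs, "gym", 100.0) == 0


def test_occupancy_half_open_boundary():
    rec = CheckinRecord("u1", "lib", t_in=9 * 3600.0, t_out=10 * 3600.0)
    assert occupancy([rec], "lib", 9 * 3600.0) == 1   # present at entry
    assert occupancy([rec], "lib", 10 * 3600.0) == 0  # departed at exit


def test_occupancy_matches_brute_force_interval_scan(rng):
    records = _random_records(rng, 50, open_fraction=0.1)
    for t in rng.uniform(0, 10_000 * 60, size=20):
        for venue in {r.venue for r in records}:
            expected = 0
            for r in records:
                inside = r.t_in <= t and (r.t_out is None or r.t_out > t)
                expected += r.venue == venue and inside
            assert occupancy(records, venue, float(t)) == expected


def test_occupancy_sums_to_open_sessions(rng):
    records = _random_records(rng, 80, open_fraction=0.15)
    t = 5_000 * 60.0
    total = sum(occupancy(records, v, t) for v in {r.venue for r in records})
    open_now = sum(1 for r in records
                   if r.t_in <= t and (r.t_out is None or r.t_out > t))
    assert total == open_now


# --------------------------------------------------------------------------
# QR payloads


def test_qr_round_trip_simple():
    assert encode_qr_payload("lib-01") == "healthpass://venue/lib-01"
    assert decode_qr_payload("healthpass://venue/lib-01") == "lib-01"


def test_qr_empty_and_bad_scheme():
    with pytest.raises(RecordStoreError):
        encode_qr_payload("")
    with pytest.raises(RecordStoreError):
        decode_qr_payload("https://venue/lib-01")


@given(st.text(min_size=1, max_size=30))
def test_qr_round_trip_arbitrary_ids(venue_id):
    assert decode_qr_payload(encode_qr_payload(venue_id)) == venue_id
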