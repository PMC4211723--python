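"""Migration phenology: date arithmetic, distance matrices, MCP extraction."""

import numpy as np
import pandas as pd
import pytest

import hetmig as hm
from hetmig.migration import (
    GpsTrack,
    RangeCentroids,
    SeasonWindows,
    centroid_distance_matrix,
    correct_to_earliest,
    extract_migration_dates,
    timing_distance_matrix,
)


# -- Julian-date correction --------------------------------------------------

def test_correct_to_earliest_spring_window():
    """Initiation spanning April 11 to June 1 becomes counts 0..51."""
    out = correct_to_earliest({"a": 101, "b": 152, "c": 120})
    assert out == {"a": 0, "b": 51, "c": 19}


def test_correct_to_earliest_all_equal_and_missing():
    out = correct_to_earliest({"a": 290, "b": 290, "c": None})
    assert out == {"a": 0, "b": 0, "c": None}
    with pytest.raises(ValueError):
        correct_to_earliest({"a": None})


def test_correction_preserves_pairwise_differences():
    rng = np.random.default_rng(1)
    dates = {f"i{k}": int(v) for k, v in enumerate(rng.integers(100, 160, 20))}
    out = correct_to_earliest(dates)
    assert min(out.values()) == 0
    for a in dates:
        for b in dates:
            assert out[a] - out[b] == dates[a] - dates[b]


# -- timing distance matrix --------------------------------------------------

def test_timing_distance_basic_and_shift_invariance():
    m = timing_distance_matrix({"a": 0, "b": 51})
    assert m.values[0, 1] == 51
    assert m.units == "days"
    m2 = timing_distance_matrix({"a": 10, "b": 61})
    assert np.array_equal(m.values, m2.values)


def test_timing_distance_matches_brute_force():
    rng = np.random.default_rng(2)
    dates = {f"i{k}": float(v) for k, v in enumerate(rng.integers(100, 160, 5))}
    m = timing_distance_matrix(dates)
    for i, a in enumerate(m.ids):
        for j, b in enumerate(m.ids):
            assert m.values[i, j] == abs(dates[a] - dates[b])


def test_timing_distance_drops_missing_with_warning():
    with pytest.warns(UserWarning, match="dropping"):
        m = timing_distance_matrix({"a": 1, "b": None, "c": 5})
    assert m.ids == ["a", "c"]
    with pytest.raises(ValueError):
        timing_distance_matrix({"a": 1, "b": None})


def test_correction_commutes_with_distance_matrix():
    rng = np.random.default_rng(3)
    dates = {f"i{k}": float(v) for k, v in enumerate(rng.integers(100, 160, 8))}
    raw = timing_distance_matrix(dates)
    corr = timing_distance_matrix(
        {k: float(v) for k, v in correct_to_earliest(dates).items()}
    )
    assert np.array_equal(raw.values, corr.values)


# -- centroid distances ------------------------------------------------------

def test_centroid_pythagorean_distance():
    c = RangeCentroids(winter={"a": (0.0, 0.0), "b": (3000.0, 4000.0)},
                       summer={"a": (0.0, 0.0), "b": (0.0, 0.0)})
    m = centroid_distance_matrix(c, "winter")
    assert m.values[m.ids.index("a"), m.ids.index("b")] == pytest.approx(5000.0)
    s = centroid_distance_matrix(c, "summer")
    assert s.values.max() == 0.0


def test_centroid_matrix_matches_brute_force():
    rng = np.random.default_rng(4)
    pts = {f"i{k}": tuple(rng.normal(0, 1000, 2)) for k in range(6)}
    c = RangeCentroids(winter=pts, summer=pts)
    m = centroid_distance_matrix(c, "winter")
    for i, a in enumerate(m.ids):
        for j, b in enumerate(m.ids):
            expected = np.hypot(pts[a][0] - pts[b][0], pts[a][1] - pts[b][1])
            assert m.values[i, j] == pytest.approx(expected)


# -- MCP extraction ----------------------------------------------------------

def _build_track(ind, day_xy, fixes_per_day=4, year=2011):
    """Track from [(day_of_year, x, y), ...] anchor positions, linearly
    interpolated at the requested fix rate."""
    days = np.array([d for d, _, _ in day_xy], dtype=float)
    xs = np.array([x for _, x, _ in day_xy], dtype=float)
    ys = np.array([y for _, _, y in day_xy], dtype=float)
    t = np.arange(days[0], days[-1], 1.0 / fixes_per_day)
    x = np.interp(t, days, xs)
    y = np.interp(t, days, ys)
    base = np.datetime64(f"{year}-01-01").astype("datetime64[s]")
    times = base + ((t - 1) * 86400).astype("timedelta64[s]")
    return GpsTrack(ind, times, np.column_stack([x, y]))


def _winter_cluster(rng, start, end, centre=(0.0, 0.0), sd=150.0):
    out = []
    for d in range(start, end):
        out.append((d, centre[0] + rng.normal(0, sd), centre[1] + rng.normal(0, sd)))
    return out


def test_extraction_recovers_planted_dates():
    rng = np.random.default_rng(5)
    anchors = _winter_cluster(rng, 20, 110)                      # winter until day 110
    anchors += [(115, 0.0, 30_000.0)]                            # 5-day transit
    anchors += _winter_cluster(rng, 116, 210, centre=(0.0, 30_000.0))
    track = _build_track("d1", anchors)
    rec, cents = extract_migration_dates(track, "spring")
    assert rec.spring_start is not None
    assert abs(rec.spring_start - 110) <= 1
    assert abs(rec.spring_end - 115) <= 1
    assert cents.winter["d1"][1] < 1000 and cents.summer["d1"][1] > 29_000


def test_stationary_track_flagged_no_migration():
    rng = np.random.default_rng(6)
    track = _build_track("d2", _winter_cluster(rng, 20, 210))
    rec, _ = extract_migration_dates(track, "spring")
    assert rec.spring_start is None
    # jitter may push single fixes over the hull edge, so either the strict
    # "never left" flag or the "never left permanently" flag is acceptable
    assert any("no_migration" in f or "no_permanent_departure" in f for f in rec.flags)


def test_excursion_with_return_not_scored_as_migration():
    """A brief trip away that returns before the final departure must not
    set the initiation date ('without return' rule)."""
    rng = np.random.default_rng(7)
    anchors = _winter_cluster(rng, 20, 90)
    anchors += [(92, 0.0, 15_000.0), (94, 0.0, 0.0)]             # out and back
    anchors += _winter_cluster(rng, 95, 120)
    anchors += [(125, 0.0, 30_000.0)]
    anchors += _winter_cluster(rng, 126, 210, centre=(0.0, 30_000.0))
    track = _build_track("d3", anchors)
    rec, _ = extract_migration_dates(track, "spring")
    assert abs(rec.spring_start - 120) <= 1
    assert abs(rec.spring_end - 125) <= 1


def test_extraction_invariant_to_thinning():
    rng = np.random.default_rng(8)
    anchors = _winter_cluster(rng, 20, 100)
    anchors += [(105, 0.0, 30_000.0)]
    anchors += _winter_cluster(rng, 106, 210, centre=(0.0, 30_000.0))
    track = _build_track("d4", anchors, fixes_per_day=8)
    thinned = GpsTrack("d4", track.times[::2], track.xy[::2])
    r1, _ = extract_migration_dates(track, "spring")
    r2, _ = extract_migration_dates(thinned, "spring")
    assert abs(r1.spring_start - r2.spring_start) <= 1
    assert abs(r1.spring_end - r2.spring_end) <= 1


def test_hull_contains_its_builders():
    from hetmig.migration import _covers, _hull

    rng = np.random.default_rng(9)
    pts = rng.normal(0, 500, (40, 2))
    hull = _hull(pts)
    assert _covers(hull, pts).all()


def test_degenerate_hull_errors():
    from hetmig.migration import _hull

    with pytest.raises(ValueError, match="degenerate"):
        _hull(np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]]))


def test_track_validation():
    times = np.array(["2011-03-01T00:00:00", "2011-03-01T00:00:00"], dtype="datetime64[s]")
    with pytest.raises(ValueError, match="increasing"):
        GpsTrack("x", times, np.zeros((2, 2)))


def test_migration_record_order_invariant():
    with pytest.raises(ValueError, match="initiation after termination"):
        hm.MigrationRecord("x", 2011, spring_start=150, spring_end=120)


def test_closed_loop_recovery_on_simulated_tracks():
    """Extraction recovers the simulator's planted dates within one fix
    interval for both seasons."""
    cfg = hm.SimConfig(seed=31, n_individuals=12, group_sizes=(3, 3, 3, 3))
    _, truth = hm.simulate_genotypes(cfg)
    mig = hm.simulate_migration_dates(truth, cfg).set_index("id")
    for season, cols in [("spring", ("spring_start", "spring_end")),
                         ("fall", ("fall_start", "fall_end"))]:
        tracks = hm.simulate_gps_tracks(truth, cfg, season=season)
        for tr in tracks:
            rec, _ = extract_migration_dates(tr, season)
            got = (getattr(rec, cols[0]), getattr(rec, cols[1]))
            if got[0] is None:
                continue
            want = (mig.loc[tr.individual_id, cols[0]], mig.loc[tr.individual_id, cols[1]])
            dt_days = (tr.times[1] - tr.times[0]).astype(int) / 86400
            tol = max(1.0, dt_days)
            assert abs(got[0] - want[0]) <= tol
            assert abs(got[1] - want[1]) <= tol


def test_gps_csv_roundtrip(tmp_path):
    cfg = hm.SimConfig(seed=32, n_individuals=4, group_sizes=(1, 1, 1, 1),
                       fix_hours=(5.0,))
    _, truth = hm.simulate_genotypes(cfg)
    hm.simulate_migration_dates(truth, cfg)
    tracks = hm.simulate_gps_tracks(truth, cfg, season="spring")
    rows = []
    for tr in tracks:
        for t, (x, y) in zip(tr.times, tr.xy):
            rows.append({"id": tr.individual_id, "timestamp": str(t), "x": x, "y": y})
    path = tmp_path / "gps.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    from hetmig.migration import read_gps_csv

    back = read_gps_csv(path)
    assert len(back) == len(tracks)
    assert np.allclose(back[0].xy, tracks[0].xy)
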