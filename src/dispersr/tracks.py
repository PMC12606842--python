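"""GPS track construction, cleaning and displacement summaries.

A *track* is the ordered fix series of one individual in a planar
projected CRS (meters, x east / y north).  Steps connect consecutive
fixes within a *segment*; segments are contiguous runs split wherever a
sampling gap exceeds the configured maximum.  The cleaning chain is

    trim -> speed-outlier removal -> gap split -> regularization

Headings are degrees clockwise from north in [0, 360); turn angles are
the signed heading change wrapped to (-180, 180].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0

FIX_COLUMNS = ["t", "x", "y", "imputed", "segment"]

STEP_COLUMNS = [
    "segment", "i0", "i1", "t0", "t1", "dt_s",
    "x0", "y0", "x1", "y1",
    "length_m", "heading_deg", "turn_angle_deg", "speed_kmph",
]


@dataclass(frozen=True)
class FilterConfig:
    """Cleaning thresholds.

    max_speed_kmph : steps strictly faster than this are GPS errors
        (biologically implausible sustained speed).
    max_gap_days : steps spanning strictly more than this are treated
        as data gaps (e.g. winter-sleep transmitter silence) and the
        track is split there.
    trim_steps : number of fixes dropped from each end of a raw track
        (collaring / retrieval artefacts).
    regular_interval_h : target fix interval after regularization.
    """

    max_speed_kmph: float = 40.0
    max_gap_days: float = 7.0
    trim_steps: int = 3
    regular_interval_h: float = 3.0

    def __post_init__(self) -> None:
        if min(self.max_speed_kmph, self.max_gap_days,
               self.trim_steps, self.regular_interval_h) <= 0:
            raise ValueError("FilterConfig fields must be strictly positive")


@dataclass
class Track:
    """One individual's fix series plus derived steps.

    ``fixes`` columns: t (UTC datetime), x, y (m), imputed (bool),
    segment (int).  ``steps`` is built lazily by :func:`build_steps`.
    """

    individual_id: str
    fixes: pd.DataFrame
    steps: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        f = self.fixes.reset_index(drop=True).copy()
        if "imputed" not in f:
            f["imputed"] = False
        if "segment" not in f:
            f["segment"] = 0
        f = f[FIX_COLUMNS]
        if not f["t"].is_monotonic_increasing:
            raise ValueError(f"fixes of {self.individual_id!r} not time-ordered")
        if not np.isfinite(f[["x", "y"]].to_numpy()).all():
            raise ValueError("non-finite coordinates")
        self.fixes = f

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def n_segments(self) -> int:
        return self.fixes["segment"].nunique() if len(self.fixes) else 0

    def with_fixes(self, fixes: pd.DataFrame) -> "Track":
        return Track(self.individual_id, fixes)


def _wrap_signed(deg: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (-180, 180]."""
    w = np.mod(deg, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return w


def lonlat_to_local_xy(lon, lat, lon0: float | None = None,
                       lat0: float | None = None):
    """Project lon/lat (degrees) to local planar meters.

    Equirectangular projection about a reference point (defaults to the
    data centroid): adequate over tracking-study extents of a few
    hundred km.  Returns (x, y, lon0, lat0).
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if lon0 is None:
        lon0 = float(np.mean(lon))
    if lat0 is None:
        lat0 = float(np.mean(lat))
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y, lon0, lat0


def read_gps_csv(path, column_map: dict | None = None) -> list[Track]:
    """Read a Movebank-style relocation CSV into one Track per individual.

    ``column_map`` binds logical names to CSV columns; recognized keys
    are ``id``, ``t`` and either ``x``/``y`` (projected meters) or
    ``lon``/``lat`` (projected locally at read time).  Defaults follow
    the Movebank dialect.  Duplicate timestamps within an individual
    keep the first occurrence (warned); rows are sorted by time.
    """
    cmap = {
        "id": "individual-local-identifier",
        "t": "timestamp",
        "lon": "location-long",
        "lat": "location-lat",
        "x": "x",
        "y": "y",
    }
    cmap.update(column_map or {})
    df = pd.read_csv(path, comment="#")

    for key in ("id", "t"):
        if cmap[key] not in df.columns:
            raise ValueError(f"missing required column {cmap[key]!r} for {key!r}")
    has_xy = cmap["x"] in df.columns and cmap["y"] in df.columns
    has_ll = cmap["lon"] in df.columns and cmap["lat"] in df.columns
    if not (has_xy or has_ll):
        raise ValueError(
            f"need coordinate columns {cmap['x']!r}/{cmap['y']!r} "
            f"or {cmap['lon']!r}/{cmap['lat']!r}")

    t = pd.to_datetime(df[cmap["t"]], utc=True, errors="coerce", format="mixed")
    bad = np.flatnonzero(t.isna().to_numpy())
    if bad.size:
        raise ValueError(
            "unparseable timestamps at CSV data rows: "
            + ", ".join(str(i + 2) for i in bad[:20]))

    if has_xy:
        x = df[cmap["x"]].to_numpy(dtype=float)
        y = df[cmap["y"]].to_numpy(dtype=float)
    else:
        x, y, lon0, lat0 = lonlat_to_local_xy(df[cmap["lon"]], df[cmap["lat"]])
        log.info("projected lon/lat to local planar CRS about (%.4f, %.4f)",
                 lon0, lat0)

    frame = pd.DataFrame({"id": df[cmap["id"]].astype(str), "t": t,
                          "x": x, "y": y})
    tracks = []
    for ind, grp in frame.groupby("id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        dup = grp["t"].duplicated(keep="first")
        if dup.any():
            log.warning("%s: dropped %d duplicate-timestamp fixes",
                        ind, int(dup.sum()))
            grp = grp[~dup]
        fixes = pd.DataFrame({"t": grp["t"].to_numpy(), "x": grp["x"].to_numpy(),
                              "y": grp["y"].to_numpy(), "imputed": False,
                              "segment": 0})
        tracks.append(Track(str(ind), fixes))
    return tracks


def build_steps(track: Track) -> Track:
    """Derive the step table (per consecutive fix pair within a segment).

    Length is Euclidean; heading is degrees clockwise from north; the
    turn angle is defined from the second step of each segment onward.
    Zero-length steps have undefined (NaN) heading.
    """
    f = track.fixes
    rows = []
    for seg, grp in f.groupby("segment", sort=True):
        n = len(grp)
        if n < 2:
            continue
        idx = grp.index.to_numpy()
        x = grp["x"].to_numpy()
        y = grp["y"].to_numpy()
        t = pd.DatetimeIndex(grp["t"])
        dt = np.diff(t.asi8) / 1e9
        if np.any(dt <= 0):
            raise ValueError(f"non-positive dt in segment {seg}")
        dx = np.diff(x)
        dy = np.diff(y)
        length = np.hypot(dx, dy)
        heading = np.degrees(np.arctan2(dx, dy)) % 360.0
        heading = np.where(length == 0, np.nan, heading)
        ta = np.full(n - 1, np.nan)
        if n > 2:
            ta[1:] = _wrap_signed(heading[1:] - heading[:-1])
        speed = (length / 1000.0) / (dt / 3600.0)
        rows.append(pd.DataFrame({
            "segment": seg, "i0": idx[:-1], "i1": idx[1:],
            "t0": t[:-1], "t1": t[1:], "dt_s": dt,
            "x0": x[:-1], "y0": y[:-1], "x1": x[1:], "y1": y[1:],
            "length_m": length, "heading_deg": heading,
            "turn_angle_deg": ta, "speed_kmph": speed,
        }))
    steps = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=STEP_COLUMNS))
    return replace(track, steps=steps)


def trim_track(track: Track, cfg: FilterConfig, first_day: bool = False) -> Track:
    """Drop collaring/retrieval artefacts from the track ends.

    Removes the first and last ``trim_steps`` fixes (hence the first
    and last ``trim_steps`` steps).  With ``first_day`` the leading cut
    extends to the whole first 24 h when that covers more fixes than
    the step trim does.
    """
    n = track.n_fixes
    k = cfg.trim_steps
    if n < 2 * k + 2:
        raise ValueError(
            f"track {track.individual_id!r} too short to trim "
            f"({n} fixes, need >= {2 * k + 2})")
    front = k
    if first_day:
        t0 = track.fixes["t"].iloc[0]
        within_day = int((track.fixes["t"] <= t0 + pd.Timedelta(hours=24)).sum())
        front = max(front, within_day)
        if n - front - k < 2:
            raise ValueError("track too short after first-day trim")
    fixes = track.fixes.iloc[front: n - k]
    return track.with_fixes(fixes)


def filter_speed_outliers(track: Track, cfg: FilterConfig
                          ) -> tuple[Track, list[dict]]:
    """Iteratively remove GPS-error fixes implied by implausible speeds.

    While any step is strictly faster than ``max_speed_kmph``, the end
    fix of the fastest offending step is removed and steps are rebuilt.
    Terminates because the fix count strictly decreases.  Returns the
    filtered track and a removal log.
    """
    removed: list[dict] = []
    tr = build_steps(track)
    while len(tr.steps):
        speeds = tr.steps["speed_kmph"].to_numpy()
        over = speeds > cfg.max_speed_kmph
        if not over.any():
            break
        worst = tr.steps.iloc[int(np.argmax(np.where(over, speeds, -np.inf)))]
        removed.append({"t": worst["t1"], "x": worst["x1"], "y": worst["y1"],
                        "speed_kmph": float(worst["speed_kmph"])})
        fixes = tr.fixes.drop(index=int(worst["i1"]))
        tr = build_steps(tr.with_fixes(fixes))
    if removed:
        log.info("%s: removed %d speed-outlier fixes",
                 track.individual_id, len(removed))
    return tr, removed


def split_on_gaps(track: Track, cfg: FilterConfig) -> Track:
    """Split the track into segments at sampling gaps.

    Steps with dt strictly greater than ``max_gap_days`` are deleted;
    no step or turn angle ever spans a declared gap.
    """
    tr = build_steps(track)
    max_s = cfg.max_gap_days * 86400.0
    f = tr.fixes
    dt = f["t"].diff().dt.total_seconds().to_numpy()
    new_seg = np.zeros(len(f), dtype=int)
    breaks = (dt > max_s) | (f["segment"].to_numpy()
                             != np.r_[f["segment"].iloc[:1], f["segment"].iloc[:-1]])
    new_seg = np.cumsum(breaks)
    fixes = f.copy()
    fixes["segment"] = new_seg
    return build_steps(track.with_fixes(fixes))


def regularize(track: Track, cfg: FilterConfig) -> Track:
    """Resample each segment onto a regular time grid.

    The grid is anchored at the segment's first fix with spacing
    ``regular_interval_h``.  Positions are linearly interpolated
    between bracketing raw fixes; grid fixes not coinciding with a raw
    fix (to 1 s) are flagged ``imputed``.  Raw fixes off the grid are
    dropped; segments shorter than one interval are dropped (warned).
    """
    step_s = cfg.regular_interval_h * 3600.0
    out = []
    seg_id = 0
    for seg, grp in track.fixes.groupby("segment", sort=True):
        t0 = grp["t"].iloc[0]
        sec = (grp["t"] - t0).dt.total_seconds().to_numpy()
        if sec[-1] < step_s:
            log.warning("%s: dropped segment %s shorter than one interval",
                        track.individual_id, seg)
            continue
        grid = np.arange(0.0, sec[-1] + 0.5, step_s)
        grid = grid[grid <= sec[-1] + 1.0]
        gx = np.interp(grid, sec, grp["x"].to_numpy())
        gy = np.interp(grid, sec, grp["y"].to_numpy())
        on_raw = np.abs(grid[:, None] - sec[None, :]).min(axis=1) <= 1.0
        out.append(pd.DataFrame({
            "t": t0 + pd.to_timedelta(grid, unit="s"),
            "x": gx, "y": gy, "imputed": ~on_raw, "segment": seg_id,
        }))
        seg_id += 1
    if not out:
        raise ValueError(f"{track.individual_id!r}: no segment long enough "
                         "to regularize")
    return build_steps(track.with_fixes(pd.concat(out, ignore_index=True)))


def process_track(track: Track, cfg: FilterConfig, first_day: bool = False
                  ) -> tuple[Track, dict]:
    """Full cleaning chain: trim, speed filter, gap split, regularize."""
    n0 = track.n_fixes
    tr = trim_track(track, cfg, first_day=first_day)
    n_trim = n0 - tr.n_fixes
    tr, removed = filter_speed_outliers(tr, cfg)
    tr = split_on_gaps(tr, cfg)
    n_seg = tr.n_segments
    tr = regularize(tr, cfg)
    report = {"n_raw": n0, "n_trimmed": n_trim, "n_speed_outliers": len(removed),
              "n_segments": n_seg, "n_final": tr.n_fixes,
              "n_imputed": int(tr.fixes["imputed"].sum())}
    log.info("%s: %s", track.individual_id, report)
    return tr, report


def displacement(track: Track) -> float:
    """Straight-line distance (m) between first and last fix."""
    if track.n_fixes < 2:
        raise ValueError("displacement needs at least two fixes")
    f = track.fixes
    return float(np.hypot(f["x"].iloc[-1] - f["x"].iloc[0],
                          f["y"].iloc[-1] - f["y"].iloc[0]))


def total_distance(track: Track) -> float:
    """Sum of step lengths (m) over all segments."""
    tr = track if track.steps is not None else build_steps(track)
    return float(tr.steps["length_m"].sum())


def monthly_distance(track: Track) -> pd.Series:
    """Distance travelled (m) per calendar month of the step's start fix.

    Months without steps in the track's time span report 0.
    """
    tr = track if track.steps is not None else build_steps(track)
    s = tr.steps
    if not len(s):
        return pd.Series(dtype=float)
    per = pd.PeriodIndex(pd.DatetimeIndex(s["t0"]), freq="M")
    summed = pd.Series(s["length_m"].to_numpy()).groupby(per).sum()
    full = pd.period_range(per.min(), per.max(), freq="M")
    return summed.reindex(full, fill_value=0.0)


def welch_t(a, b) -> dict:
    """Welch's unequal-variance t-test (two-sided).

    Returns ``{"t", "df", "p"}`` with Satterthwaite degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both samples degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df),
            "p": float(res.pvalue)}
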