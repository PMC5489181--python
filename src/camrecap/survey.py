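"""Ingestion of camera-trap detection events and robust-design capture histories.

A *detection event* is one time-stamped identification of a known individual at
a camera station.  Events are thinned to independence (consecutive detections of
the same individual must be at least 24 h apart), then binned into a robust
design layout: annual *primary* survey seasons, each cut into week-long
*secondary* occasions across which the population is assumed closed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, EmptyInputError, SchemaError

logger = logging.getLogger("camrecap")

SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("adult", "cub")
ERAS = ("film", "digital")

#: default independence gap between consecutive detections of one individual
DEFAULT_MIN_GAP = timedelta(hours=24)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class DetectionEvent:
    """One identification of one individual at one station.

    Timestamps are naive local time; the independence rule is a 24-hour
    duration, so day boundaries and time zones play no role.
    """

    individual_id: str
    timestamp: datetime
    station_id: str = ""
    sex: str = "unknown"
    age_class: str = "adult"

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("individual_id must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(
                f"age_class must be one of {AGE_CLASSES}, got {self.age_class!r}"
            )


@dataclass(frozen=True)
class Primary:
    """One annual survey season (a primary occasion)."""

    year: int
    start_date: date
    end_date: date
    n_secondary: int
    era: str

    def __post_init__(self) -> None:
        if self.era not in ERAS:
            raise DesignError(f"era must be one of {ERAS}, got {self.era!r}")
        if self.n_secondary < 1:
            raise DesignError("each primary needs at least one secondary occasion")
        if self.end_date <= self.start_date:
            raise DesignError(f"primary {self.year}: end_date before start_date")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days

    def secondary_windows(self) -> list[tuple[datetime, datetime]]:
        """Contiguous 7-day windows from the start; a short remainder
        (< 7 days) is absorbed into the last window."""
        t0 = datetime.combine(self.start_date, datetime.min.time())
        t_end = datetime.combine(self.end_date, datetime.min.time())
        wins = []
        for k in range(self.n_secondary):
            a = t0 + timedelta(days=7 * k)
            b = t0 + timedelta(days=7 * (k + 1))
            if k == self.n_secondary - 1:
                b = t_end
            wins.append((a, b))
        return wins


@dataclass(frozen=True)
class SurveyDesign:
    """The primary/secondary layout of a multi-year robust-design survey."""

    primaries: tuple[Primary, ...]
    n_stations: int = 19

    def __post_init__(self) -> None:
        if not self.primaries:
            raise DesignError("design must contain at least one primary")
        years = [p.year for p in self.primaries]
        if years != sorted(set(years)):
            raise DesignError("primary years must be strictly increasing")
        for a, b in zip(self.primaries, self.primaries[1:]):
            if b.start_date <= a.end_date:
                raise DesignError(
                    f"primaries {a.year} and {b.year} overlap or touch"
                )
        if self.n_stations < 1:
            raise DesignError("n_stations must be >= 1")

    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(p.year for p in self.primaries)

    @property
    def intervals(self) -> tuple[int, ...]:
        """Whole-year gaps between consecutive primaries (>= 1)."""
        ys = self.years
        return tuple(b - a for a, b in zip(ys, ys[1:]))

    @property
    def K(self) -> np.ndarray:
        return np.array([p.n_secondary for p in self.primaries], dtype=int)

    @property
    def eras(self) -> tuple[str, ...]:
        return tuple(p.era for p in self.primaries)

    def to_dict(self) -> dict:
        return {
            "n_stations": self.n_stations,
            "primaries": [
                {
                    "year": p.year,
                    "start_date": p.start_date.isoformat(),
                    "end_date": p.end_date.isoformat(),
                    "n_secondary": p.n_secondary,
                    "era": p.era,
                }
                for p in self.primaries
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SurveyDesign":
        prim = tuple(
            Primary(
                year=int(q["year"]),
                start_date=date.fromisoformat(q["start_date"]),
                end_date=date.fromisoformat(q["end_date"]),
                n_secondary=int(q["n_secondary"]),
                era=q["era"],
            )
            for q in d["primaries"]
        )
        return cls(primaries=prim, n_stations=int(d.get("n_stations", 19)))


@dataclass
class CaptureHistory:
    """Binary individual x primary x secondary detection array.

    ``detections`` has shape (n_individuals, n_primaries, max K); columns past a
    primary's own K are structurally zero.
    """

    individual_ids: list[str]
    sexes: list[str]
    detections: np.ndarray
    design: SurveyDesign

    def __post_init__(self) -> None:
        det = np.asarray(self.detections)
        if det.ndim != 3:
            raise ValueError("detections must be 3-dimensional")
        if not np.isin(det, (0, 1)).all():
            raise ValueError("detections must be binary")
        K = self.design.K
        for t, k in enumerate(K):
            if det[:, t, k:].any():
                raise ValueError(f"primary {t} has detections past its K={k}")
        if det.shape[0] and not det.reshape(det.shape[0], -1).any(axis=1).all():
            raise ValueError("every individual must have at least one detection")
        self.detections = det.astype(np.int8)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def counts(self) -> np.ndarray:
        """Detections per (individual, primary): shape (N, T)."""
        return self.detections.sum(axis=2)

    @property
    def first_primary(self) -> np.ndarray:
        """Index of each individual's first primary with >= 1 detection."""
        seen = self.counts > 0
        return np.argmax(seen, axis=1)

    def subset(self, mask: np.ndarray) -> "CaptureHistory":
        idx = np.flatnonzero(mask)
        return CaptureHistory(
            [self.individual_ids[i] for i in idx],
            [self.sexes[i] for i in idx],
            self.detections[idx],
            self.design,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """One row per individual, one column per secondary occasion."""
        cols, blocks = [], []
        for t, p in enumerate(self.design.primaries):
            for k in range(p.n_secondary):
                cols.append(f"y{p.year}_s{k + 1}")
                blocks.append(self.detections[:, t, k])
        df = pd.DataFrame(
            dict(zip(cols, blocks)) if blocks else {},
            index=pd.Index(self.individual_ids, name="individual_id"),
        )
        df.insert(0, "sex", self.sexes)
        return df

    def yearly_matrix(self) -> pd.DataFrame:
        """Individual x survey-year binary detection table."""
        return pd.DataFrame(
            (self.counts > 0).astype(int),
            index=pd.Index(self.individual_ids, name="individual_id"),
            columns=list(self.design.years),
        )


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

REQUIRED_COLUMNS = ("individual_id", "sex", "station_id", "timestamp")


def parse_events(
    source,
    schema: Mapping[str, str] | None = None,
) -> tuple[list[DetectionEvent], list[int]]:
    """Read detection events from a delimited text source.

    Parameters
    ----------
    source : path, file-like or str of CSV content
    schema : optional mapping from required column name to the actual column
        name in the file, e.g. ``{"individual_id": "animal"}``.

    Returns
    -------
    (events, rejected_rows) : events sorted by (individual_id, timestamp) and
        the 1-based data row numbers whose timestamps could not be parsed.
    """
    try:
        df = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        raise EmptyInputError("event file contains no data") from None
    if df.empty:
        raise EmptyInputError("event file contains no data rows")

    colmap = {c: c for c in REQUIRED_COLUMNS}
    colmap["age_class"] = "age_class"
    if schema:
        colmap.update(schema)
    for want in REQUIRED_COLUMNS:
        if colmap[want] not in df.columns:
            raise SchemaError(f"missing required column: {colmap[want]!r}")

    # ISO8601 parsing accepts mixed precision (with/without seconds or
    # fractional seconds) instead of locking onto the first row's format
    ts = pd.to_datetime(df[colmap["timestamp"]], errors="coerce", format="ISO8601")
    bad = ts.isna()
    rejected = [int(i) + 1 for i in np.flatnonzero(bad.to_numpy())]
    if rejected:
        logger.warning("rejected %d rows with unparseable timestamps", len(rejected))

    has_age = colmap["age_class"] in df.columns
    events = []
    for i in np.flatnonzero(~bad.to_numpy()):
        row = df.iloc[i]
        events.append(
            DetectionEvent(
                individual_id=str(row[colmap["individual_id"]]),
                timestamp=ts.iloc[i].to_pydatetime(),
                station_id=str(row[colmap["station_id"]]),
                sex=str(row[colmap["sex"]]),
                age_class=str(row[colmap["age_class"]]) if has_age else "adult",
            )
        )
    events.sort(key=lambda e: (e.individual_id, e.timestamp))
    return events, rejected


def filter_independent(
    events: Iterable[DetectionEvent],
    min_gap: timedelta = DEFAULT_MIN_GAP,
) -> list[DetectionEvent]:
    """Thin each individual's events to independent detections.

    Greedy forward scan per individual: an event is kept iff it is at least
    ``min_gap`` after the previously *kept* event of the same individual; the
    first event is always kept.  Individuals never interact.
    """
    if min_gap < timedelta(0):
        raise ValueError("min_gap must be non-negative")
    last_kept: dict[str, datetime] = {}
    kept = []
    for ev in sorted(events, key=lambda e: (e.individual_id, e.timestamp)):
        prev = last_kept.get(ev.individual_id)
        if prev is None or ev.timestamp - prev >= min_gap:
            kept.append(ev)
            last_kept[ev.individual_id] = ev.timestamp
    return kept


def build_capture_histories(
    events: Sequence[DetectionEvent],
    design: SurveyDesign,
    adults_only: bool = True,
    drop_unknown_sex: bool = False,
) -> tuple[CaptureHistory, dict]:
    """Bin independence-filtered events into a robust-design capture history.

    Each primary's span is cut into its K consecutive secondary windows; an
    entry is 1 iff at least one event of the individual falls in the window.
    Events outside all primaries are ignored but counted in the report.

    Returns the history and a report dict with counts of out-of-window events,
    excluded cubs, and unknown-sex individuals (flagged; excluded only when
    ``drop_unknown_sex``).
    """
    windows = []  # (t, k, start, end)
    for t, p in enumerate(design.primaries):
        for k, (a, b) in enumerate(p.secondary_windows()):
            windows.append((t, k, a, b))

    report = {"n_outside": 0, "n_cubs_excluded": 0, "unknown_sex_ids": []}
    rows: dict[str, np.ndarray] = {}
    sexes: dict[str, str] = {}
    Kmax = int(design.K.max())
    T = design.n_primaries

    first_start = datetime.combine(
        design.primaries[0].start_date, datetime.min.time()
    )
    for ev in events:
        if adults_only and ev.age_class == "cub":
            report["n_cubs_excluded"] += 1
            continue
        hit = None
        for t, k, a, b in windows:
            if a <= ev.timestamp < b:
                hit = (t, k)
                break
        if hit is None:
            report["n_outside"] += 1
            if ev.timestamp < first_start:
                logger.warning(
                    "event before first primary start ignored: %s at %s",
                    ev.individual_id,
                    ev.timestamp,
                )
            continue
        if ev.individual_id not in rows:
            rows[ev.individual_id] = np.zeros((T, Kmax), dtype=np.int8)
            sexes[ev.individual_id] = ev.sex
        rows[ev.individual_id][hit] = 1

    ids = sorted(rows)
    report["unknown_sex_ids"] = [i for i in ids if sexes[i] == "unknown"]
    if drop_unknown_sex:
        ids = [i for i in ids if sexes[i] != "unknown"]
    det = (
        np.stack([rows[i] for i in ids])
        if ids
        else np.zeros((0, T, Kmax), dtype=np.int8)
    )
    hist = CaptureHistory(ids, [sexes[i] for i in ids], det, design)
    return hist, report


def detection_summary(
    events: Sequence[DetectionEvent],
    design: SurveyDesign,
) -> dict[str, pd.DataFrame]:
    """Per-individual and per-survey summaries of independent detections.

    Returns a dict with:

    ``per_individual``
        one row per (individual, survey year): independent detection count and
        detections per station per survey-year (count / n_stations).
    ``per_survey``
        one row per survey year: individuals and detections by sex.
    """
    recs = []
    for ev in events:
        for p in design.primaries:
            a = datetime.combine(p.start_date, datetime.min.time())
            b = datetime.combine(p.end_date, datetime.min.time())
            if a <= ev.timestamp < b:
                recs.append((ev.individual_id, ev.sex, p.year))
                break
    if not recs:
        per_ind = pd.DataFrame(
            columns=["individual_id", "sex", "year", "n_detections",
                     "detections_per_location"]
        )
        per_survey = pd.DataFrame(
            columns=["year", "sex", "n_individuals", "n_detections"]
        )
        return {"per_individual": per_ind, "per_survey": per_survey}

    df = pd.DataFrame(recs, columns=["individual_id", "sex", "year"])
    per_ind = (
        df.groupby(["individual_id", "sex", "year"], as_index=False)
        .size()
        .rename(columns={"size": "n_detections"})
    )
    per_ind["detections_per_location"] = (
        per_ind["n_detections"] / design.n_stations
    )
    per_survey = (
        df.groupby(["year", "sex"], as_index=False)
        .agg(
            n_individuals=("individual_id", "nunique"),
            n_detections=("individual_id", "size"),
        )
    )
    return {"per_individual": per_ind, "per_survey": per_survey}


def export_mark_inp(history: CaptureHistory) -> str:
    """Render a capture history as MARK-style encounter-file text.

    One line per individual: the concatenated 0/1 string over all secondary
    occasions in primary order, then one frequency column per group in the
    order (male, female, unknown), terminated ``;``.  A header comment records
    the per-primary secondary counts.
    """
    design = history.design
    kline = " ".join(str(p.n_secondary) for p in design.primaries)
    lines = [f"/* robust design; secondary occasions per primary: {kline} */",
             "/* groups: male female unknown */"]
    for i in range(history.n_individuals):
        bits = []
        for t, p in enumerate(design.primaries):
            bits.append(
                "".join(str(int(v)) for v in history.detections[i, t, : p.n_secondary])
            )
        freq = {s: 0 for s in SEXES}
        freq[history.sexes[i]] = 1
        lines.append(
            "".join(bits)
            + " "
            + " ".join(str(freq[s]) for s in SEXES)
            + ";"
        )
    return "\n".join(lines) + "\n"


def import_mark_inp(text: str, design: SurveyDesign) -> CaptureHistory:
    """Parse MARK-style encounter text written by :func:`export_mark_inp`."""
    T = design.n_primaries
    Kmax = int(design.K.max())
    ids, sexes, rows = [], [], []
    n = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("/*"):
            continue
        body = line.rstrip(";").split()
        enc, freqs = body[0], [int(x) for x in body[1:]]
        sex = SEXES[freqs.index(1)]
        arr = np.zeros((T, Kmax), dtype=np.int8)
        pos = 0
        for t, p in enumerate(design.primaries):
            k = p.n_secondary
            arr[t, :k] = [int(c) for c in enc[pos : pos + k]]
            pos += k
        n += 1
        ids.append(f"ind{n:04d}")
        sexes.append(sex)
        rows.append(arr)
    det = np.stack(rows) if rows else np.zeros((0, T, Kmax), dtype=np.int8)
    return CaptureHistory(ids, sexes, det, design)


def write_history_csv(history: CaptureHistory, path) -> None:
    history.to_dataframe().to_csv(path)


def events_to_dataframe(events: Sequence[DetectionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [e.individual_id for e in events],
            "sex": [e.sex for e in events],
            "station_id": [e.station_id for e in events],
            "timestamp": [e.timestamp.isoformat(sep=" ") for e in events],
            "age_class": [e.age_class for e in events],
        }
    )
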