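"""Synthetic camera-trap event generator with a ground-truth ledger.

The generator emulates the statistical structure the robust-design analysis
assumes: an open population with constant annual apparent survival, temporary
emigration (random or Markovian), Poisson per-capita recruitment, sex- and
era-specific per-occasion detection, an optional resident/transient entry
stream, and the study layout of 12 annual dry-season primaries (2002-2008 and
2011-2015, with the 2009-2010 survey gap) cut into week-long secondary
occasions at 19 camera stations.

Event timing: each individual is assigned a fixed daily "passage hour"
(06:00-16:00); a detected secondary occasion yields one event at that hour on
a uniformly chosen day of the window, plus a Poisson number of clustered
duplicate events within the following six hours.  Regular passage times are a
reasonable caricature of trail-patrolling cats, and they make the 24-hour
independence filter recover exactly the true week-level detection matrix, so
the ledger is an exact oracle for the ingestion pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .survey import (
    CaptureHistory,
    DetectionEvent,
    Primary,
    SurveyDesign,
    events_to_dataframe,
)

STATE_NOT_RECRUITED = "not-yet-recruited"
STATE_ONGRID = "on-grid"
STATE_OFFGRID = "off-grid"
STATE_DEAD = "dead"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    design: SurveyDesign
    n_initial: dict = field(default_factory=lambda: {"male": 16, "female": 16})
    recruitment_rate: float = 0.22    # per-capita, per year; 1 - phi keeps N stationary
    phi: float = 0.78
    gamma_mode: str = "random"
    gamma_pp: float = 0.20            # on-grid -> off-grid
    gamma_p: float = 0.20             # off-grid -> off-grid (= gamma_pp when random)
    p_film: dict = field(default_factory=lambda: {"male": 0.36, "female": 0.07})
    p_digital: dict = field(default_factory=lambda: {"male": 0.40, "female": 0.10})
    transient_entry_rate: float = 0.0  # expected new transients per year
    transient_dwell: tuple = (1, 2)    # years on-grid before leaving for good
    transient_p_multiplier: float = 0.5
    event_clustering: float = 0.5      # mean extra events per detection
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recruitment_rate", "phi", "gamma_pp", "gamma_p",
                     "transient_p_multiplier"):
            v = getattr(self, name)
            if name != "recruitment_rate" and not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.gamma_mode not in ("random", "markovian"):
            raise ValueError("gamma_mode must be 'random' or 'markovian'")
        if sum(self.n_initial.values()) < 1:
            raise ValueError("initial population must be non-empty")

    def detection_prob(self, sex: str, year: int, era: str) -> float:
        table = self.p_film if era == "film" else self.p_digital
        v = table[sex]
        return float(v[year]) if isinstance(v, dict) else float(v)


def paper_design() -> SurveyDesign:
    """The study's survey layout: 12 annual dry-season primaries, 2002-2008
    film era and 2011-2015 digital era, weekly secondaries (K = floor(days/7),
    short remainders merged into the last week; the 2013 year-long survey is
    represented by its 100-day dry-season subsample, K = 14)."""
    spans = [
        (2002, 20, 77), (2003, 18, 91), (2004, 24, 70), (2005, 22, 84),
        (2006, 21, 98), (2007, 20, 77), (2008, 19, 70),
        (2011, 22, 84), (2012, 21, 77), (2013, 19, 100), (2014, 18, 91),
        (2015, 17, 84),
    ]
    prim = []
    for year, day, dur in spans:
        start = date(year, 2, day)
        prim.append(
            Primary(
                year=year,
                start_date=start,
                end_date=start + timedelta(days=dur),
                n_secondary=dur // 7,
                era="film" if year <= 2008 else "digital",
            )
        )
    return SurveyDesign(primaries=tuple(prim), n_stations=19)


def paper_preset(seed: int = 0, transients: bool = False) -> SimulationConfig:
    """Default configuration mirroring the study's scale and the published
    model-averaged rates: phi = 0.78, random temporary emigration 0.20, film
    detection 0.36 (males) / 0.07 (females), year-specific digital detection.

    ``transients=True`` adds the transient entry stream (dwell 1-2 years, half
    the resident detection rate) used by the population-structure analyses; it
    is off by default because transients leave permanently, which by design
    depresses pooled apparent survival below the resident rate.
    """
    return SimulationConfig(
        design=paper_design(),
        p_digital={
            "male": {2011: 0.47, 2012: 0.27, 2013: 0.40, 2014: 0.33, 2015: 0.37},
            "female": {2011: 0.05, 2012: 0.06, 2013: 0.12, 2014: 0.16, 2015: 0.16},
        },
        transient_entry_rate=2.5 if transients else 0.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Ground truth of a simulation run.

    ``states``: per (individual, calendar year) latent state; ``detections``:
    dict individual -> (T, Kmax) binary true detection array over the design's
    primaries; ``sexes``/``kinds``: per-individual labels.
    """

    states: pd.DataFrame
    detections: dict
    sexes: dict
    kinds: dict
    design: SurveyDesign

    def detected_ids(self) -> list[str]:
        return sorted(i for i, m in self.detections.items() if m.any())

    def detection_history(self) -> CaptureHistory:
        """The true week-level capture history of all detected individuals."""
        ids = self.detected_ids()
        Kmax = int(self.design.K.max())
        T = self.design.n_primaries
        det = (
            np.stack([self.detections[i] for i in ids])
            if ids
            else np.zeros((0, T, Kmax), dtype=np.int8)
        )
        return CaptureHistory(ids, [self.sexes[i] for i in ids], det, self.design)

    def yearly_counts(self) -> pd.DataFrame:
        """Realized per-year totals: alive, available (on-grid), detected."""
        years = self.design.years
        yidx = {y: t for t, y in enumerate(years)}
        rows = []
        for y in sorted(self.states["year"].unique()):
            sub = self.states[self.states["year"] == y]
            alive = int(sub["state"].isin([STATE_ONGRID, STATE_OFFGRID]).sum())
            avail = int((sub["state"] == STATE_ONGRID).sum())
            det = 0
            if y in yidx:
                det = sum(int(self.detections[i][yidx[y]].any()) for i in self.detections)
            rows.append((y, alive, avail, det))
        return pd.DataFrame(rows, columns=["year", "alive", "available", "detected"])


def simulate_population(
    config: SimulationConfig, seed: int | None = None
) -> tuple[TruthLedger, list[DetectionEvent]]:
    """Simulate an open population and its camera-trap event record.

    Dynamics run over every calendar year spanned by the design (survey gap
    years included).  Each year, survivors are retained with probability phi,
    then move between on- and off-grid according to the emigration mode; new
    recruits enter on-grid at the per-capita rate; transients enter on-grid,
    dwell 1-2 years, then leave permanently.
    """
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    rng_demog, rng_detect = (np.random.default_rng(s) for s in ss.spawn(2))

    design = config.design
    years = list(range(design.years[0], design.years[-1] + 1))
    T = design.n_primaries
    Kmax = int(design.K.max())
    yidx = {p.year: t for t, p in enumerate(design.primaries)}

    sexes: dict[str, str] = {}
    kinds: dict[str, str] = {}
    passage: dict[str, int] = {}
    state: dict[str, str] = {}
    entry: dict[str, int] = {}
    dwell_left: dict[str, int] = {}
    counter = 0

    def new_individual(sex, kind, year):
        nonlocal counter
        counter += 1
        iid = f"{'t' if kind == 'transient' else 'j'}{counter:04d}"
        sexes[iid] = sex
        kinds[iid] = kind
        passage[iid] = int(rng_detect.integers(6, 17))
        state[iid] = STATE_ONGRID
        entry[iid] = year
        return iid

    for sex, n in config.n_initial.items():
        for _ in range(int(n)):
            new_individual(sex, "resident", years[0])

    state_rows = []
    detections: dict[str, np.ndarray] = {}

    def record_states(year):
        for iid in sexes:
            st = state[iid] if entry[iid] <= year else STATE_NOT_RECRUITED
            state_rows.append((iid, sexes[iid], year, st))

    def detect(year):
        if year not in yidx:
            return
        t = yidx[year]
        prim = design.primaries[t]
        windows = prim.secondary_windows()
        p_era = prim.era
        for iid in sexes:
            if entry[iid] > year or state[iid] != STATE_ONGRID:
                continue
            p = config.detection_prob(sexes[iid], year, p_era)
            if kinds[iid] == "transient":
                p *= config.transient_p_multiplier
            hits = rng_detect.random(prim.n_secondary) < p
            if hits.any() and iid not in detections:
                detections[iid] = np.zeros((T, Kmax), dtype=np.int8)
            if iid in detections:
                detections[iid][t, : prim.n_secondary] |= hits.astype(np.int8)
            for k in np.flatnonzero(hits):
                a, b = windows[k]
                day = int(rng_detect.integers((b - a).days))
                ts = a + timedelta(days=day, hours=passage[iid])
                yield_events.append(
                    DetectionEvent(
                        individual_id=iid,
                        timestamp=ts,
                        station_id=f"st{int(rng_detect.integers(design.n_stations)) + 1:02d}",
                        sex=sexes[iid],
                    )
                )
                for _ in range(int(rng_detect.poisson(config.event_clustering))):
                    dt_h = float(rng_detect.uniform(0.1, 6.0))
                    yield_events.append(
                        DetectionEvent(
                            individual_id=iid,
                            timestamp=ts + timedelta(hours=dt_h),
                            station_id=f"st{int(rng_detect.integers(design.n_stations)) + 1:02d}",
                            sex=sexes[iid],
                        )
                    )

    yield_events: list[DetectionEvent] = []
    record_states(years[0])
    detect(years[0])

    for year in years[1:]:
        # survival and movement of existing individuals
        for iid in list(sexes):
            if entry[iid] > year or state[iid] == STATE_DEAD:
                continue
            if kinds[iid] == "transient":
                dwell_left[iid] -= 1
                if dwell_left[iid] <= 0:
                    state[iid] = STATE_DEAD  # left the area for good
                continue
            if rng_demog.random() > config.phi:
                state[iid] = STATE_DEAD
                continue
            if state[iid] == STATE_ONGRID:
                if rng_demog.random() < config.gamma_pp:
                    state[iid] = STATE_OFFGRID
            else:
                if rng_demog.random() >= config.gamma_p:
                    state[iid] = STATE_ONGRID
        # recruitment (per-capita on the living resident population)
        n_alive = sum(
            1
            for iid in sexes
            if kinds[iid] == "resident"
            and entry[iid] <= year
            and state[iid] != STATE_DEAD
        )
        for _ in range(int(rng_demog.poisson(config.recruitment_rate * n_alive))):
            sex = "male" if rng_demog.random() < 0.5 else "female"
            new_individual(sex, "resident", year)
        # transient entries
        for _ in range(int(rng_demog.poisson(config.transient_entry_rate))):
            sex = "male" if rng_demog.random() < 0.5 else "female"
            iid = new_individual(sex, "transient", year)
            lo, hi = config.transient_dwell
            dwell_left[iid] = int(rng_demog.integers(lo, hi + 1))
        record_states(year)
        detect(year)

    states = pd.DataFrame(state_rows, columns=["individual_id", "sex", "year", "state"])
    yield_events.sort(key=lambda e: (e.individual_id, e.timestamp))
    ledger = TruthLedger(states, detections, sexes, kinds, design)
    return ledger, yield_events


def simulate_year_survey(
    n_males: int = 17,
    n_females: int = 12,
    weekly_p: dict | None = None,
    start: date = date(2013, 1, 15),
    n_weeks: int = 52,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[DetectionEvent]]:
    """Simulate a single year-long continuous survey (weekly occasions).

    Returns a truth table (individual_id, sex, week, detected) and the event
    list; used to exercise quarterly subsampling of a 12-month record.
    Default weekly rates give quarterly detection fractions near those seen in
    year-round trail monitoring of jaguars (males high, females sporadic).
    """
    weekly_p = weekly_p or {"male": 0.12, "female": 0.045}
    rng = np.random.default_rng(seed)
    t0 = datetime.combine(start, datetime.min.time())
    rows, events = [], []
    inds = [("male", f"m{i + 1:03d}") for i in range(n_males)] + [
        ("female", f"f{i + 1:03d}") for i in range(n_females)
    ]
    for sex, iid in inds:
        hour = int(rng.integers(6, 17))
        for w in range(n_weeks):
            hit = rng.random() < weekly_p[sex]
            rows.append((iid, sex, w, int(hit)))
            if hit:
                day = int(rng.integers(7))
                events.append(
                    DetectionEvent(
                        individual_id=iid,
                        timestamp=t0 + timedelta(days=7 * w + day, hours=hour),
                        station_id=f"st{int(rng.integers(19)) + 1:02d}",
                        sex=sex,
                    )
                )
    truth = pd.DataFrame(rows, columns=["individual_id", "sex", "week", "detected"])
    events.sort(key=lambda e: (e.individual_id, e.timestamp))
    return truth, events


def write_events(events, path) -> None:
    """Write events as CSV matching the ingestion schema (round-trips through
    :func:`camrecap.survey.parse_events`)."""
    events_to_dataframe(list(events)).to_csv(path, index=False)
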