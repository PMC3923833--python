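"""Tidal and sea-level forcing.

Tidal datums (MSL, MHHW) are computed from a water-level record; accelerating
sea-level-rise (SLR) curves are quadratic with a prescribed initial rate and a
prescribed total rise after one century, in the style of the NRC scenario
curves.  Scenarios pair one SLR curve with one suspended-sediment level.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: length of a tidal day (two semidiurnal cycles) in hours
TIDAL_DAY_HOURS = 24.84

#: minimum record length for datum computation: one lunar month
MIN_RECORD_DAYS = 29.0


class ForcingError(ValueError):
    """Invalid water-level record or forcing parameters."""


@dataclass(frozen=True)
class TidalDatums:
    """Mean sea level and mean higher high water, cm NAVD88."""

    msl: float
    mhhw: float

    def __post_init__(self) -> None:
        if not self.mhhw > self.msl:
            raise ForcingError(
                f"MHHW ({self.mhhw}) must exceed MSL ({self.msl})"
            )

    @property
    def range(self) -> float:
        """MHHW − MSL in cm: the denominator of the z* normalization."""
        return self.mhhw - self.msl

    def at_year(self, rise_cm: float) -> "TidalDatums":
        """Datums after a rise of *rise_cm*; the MSL–MHHW offset is constant."""
        return TidalDatums(self.msl + rise_cm, self.mhhw + rise_cm)


@dataclass
class WaterLevelSeries:
    """Uniformly sampled stage record.

    Parameters
    ----------
    times : array of numpy.datetime64
        Strictly increasing, uniformly spaced timestamps.
    stage_cm : array of float
        Water surface elevation, cm NAVD88.
    """

    times: np.ndarray
    stage_cm: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[s]")
        self.stage_cm = np.asarray(self.stage_cm, dtype=float)
        if self.times.shape != self.stage_cm.shape or self.times.ndim != 1:
            raise ForcingError("times and stage must be 1-D of equal length")
        if len(self.times) < 2:
            raise ForcingError("record needs at least two samples")
        dt = np.diff(self.times.astype("int64"))
        if np.any(dt <= 0):
            raise ForcingError("timestamps must be strictly increasing")
        if np.any(dt != dt[0]):
            raise ForcingError("non-uniform sampling interval")

    @property
    def interval_s(self) -> float:
        return float(
            (self.times[1] - self.times[0]) / np.timedelta64(1, "s")
        )

    @property
    def duration_days(self) -> float:
        span = (self.times[-1] - self.times[0]) / np.timedelta64(1, "s")
        return float(span) / 86400.0

    @classmethod
    def from_csv(cls, path) -> "WaterLevelSeries":
        """Read a CSV with columns ``timestamp`` (ISO-8601) and
        ``stage_m_navd88`` (metres); stage is converted to cm."""
        df = pd.read_csv(path)
        missing = {"timestamp", "stage_m_navd88"} - set(df.columns)
        if missing:
            raise ForcingError(f"water-level CSV missing columns: {missing}")
        t = pd.to_datetime(df["timestamp"]).to_numpy(dtype="datetime64[s]")
        return cls(t, df["stage_m_navd88"].to_numpy(dtype=float) * 100.0)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "timestamp": pd.DatetimeIndex(self.times).strftime(
                    "%Y-%m-%dT%H:%M:%S"
                ),
                "stage_m_navd88": self.stage_cm / 100.0,
            }
        ).to_csv(path, index=False)


def compute_tidal_datums(series: WaterLevelSeries) -> TidalDatums:
    """Tidal datums from a water-level record.

    MSL is the arithmetic mean of stage.  MHHW is the mean of the
    higher-high water of each tidal day, where tidal days are consecutive
    24.84 h windows anchored at the first timestamp; a day with a single
    high water contributes that high water (the window maximum covers both
    cases).  Only complete windows are used.
    """
    if series.duration_days < MIN_RECORD_DAYS:
        raise ForcingError(
            f"record of {series.duration_days:.1f} d is shorter than the "
            f"{MIN_RECORD_DAYS:.0f} d (one lunar month) minimum"
        )
    stage = series.stage_cm
    if np.ptp(stage) == 0.0:
        raise ForcingError("no tidal oscillation: stage is constant")

    window_s = TIDAL_DAY_HOURS * 3600.0
    elapsed = (series.times - series.times[0]) / np.timedelta64(1, "s")
    idx = np.floor(elapsed.astype(float) / window_s).astype(int)
    n_complete = int(np.floor((elapsed[-1] + series.interval_s) / window_s))
    keep = idx < n_complete
    if n_complete < 1:
        raise ForcingError("record shorter than one tidal day")
    hh = np.full(n_complete, -np.inf)
    np.maximum.at(hh, idx[keep], stage[keep])
    return TidalDatums(msl=float(stage.mean()), mhhw=float(hh.mean()))


@dataclass(frozen=True)
class SLRScenario:
    """Accelerating sea-level-rise curve.

    s(t) = r0·t + b·t² with b chosen so s(100) = s100 exactly:
    b = (s100 − 100·r0)/10000.  r0 in cm/yr, s100 in cm.
    """

    r0: float
    s100: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.s100 < 0:
            raise ForcingError("s100 must be nonnegative")
        if self.s100 < 100.0 * self.r0:
            warnings.warn(
                f"SLR scenario {self.label or self.s100}: century total "
                f"{self.s100} cm implies deceleration below the initial "
                f"rate {self.r0} cm/yr",
                stacklevel=2,
            )
        if not self.label:
            object.__setattr__(self, "label", f"{self.s100:g}cm")

    @property
    def accel(self) -> float:
        """Quadratic coefficient b in cm/yr²."""
        return (self.s100 - 100.0 * self.r0) / 1.0e4


def sea_level(t_years: float, slr: SLRScenario) -> float:
    """Cumulative rise (cm above initial MSL) at time *t_years* ∈ [0, 100]."""
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0) or np.any(t > 100):
        raise ForcingError("t must lie in [0, 100] years")
    # algebraically r0·t + b·t²; written so s(100) = s100 exactly in
    # floating point (u = t/100 is exactly 1.0 at the endpoint)
    u = t / 100.0
    out = slr.r0 * t + (slr.s100 - 100.0 * slr.r0) * u * u
    return float(out) if out.ndim == 0 else out


#: fraction of the site's current SSC used at each level
SSC_LEVEL_FRACTIONS = {"high": 1.0, "mid": 0.5, "low": 0.25}

#: the five century totals examined in the study, cm (24 is the historic
#: hindcast rate; 180 the maximum published estimate)
DEFAULT_S100_CM = (24.0, 52.0, 100.0, 165.0, 180.0)

#: historic rate of sea-level rise, cm/yr, also used as the initial rate of
#: every accelerating curve
HISTORIC_RATE_CM_YR = 0.24


def hindcast_scenario() -> SLRScenario:
    """Constant-rate 24 cm/century curve used for the historic hindcast."""
    return SLRScenario(r0=HISTORIC_RATE_CM_YR, s100=24.0, label="24cm")


def default_slr_scenarios(r0: float = HISTORIC_RATE_CM_YR) -> list[SLRScenario]:
    return [SLRScenario(r0=r0, s100=s, label=f"{s:g}cm") for s in DEFAULT_S100_CM]


@dataclass(frozen=True)
class Scenario:
    """One SLR curve paired with one suspended-sediment level."""

    slr: SLRScenario
    ssc_level: str
    ssc_mg_l: float

    def __post_init__(self) -> None:
        if self.ssc_level not in SSC_LEVEL_FRACTIONS:
            raise ForcingError(f"unknown SSC level {self.ssc_level!r}")
        if self.ssc_mg_l <= 0:
            raise ForcingError("ssc must be positive")

    @property
    def label(self) -> str:
        return f"{self.slr.label}|{self.ssc_level}"


def enumerate_scenarios(
    slr_scenarios: list[SLRScenario],
    ssc_levels: list[str],
    site_ssc_mg_l: float,
) -> list[Scenario]:
    """Cartesian product of SLR curves and SSC levels.

    Ordering is deterministic: SLR ascending by century total, then SSC
    high → mid → low.  Each level's concentration is the stated fraction of
    the site's current SSC.
    """
    if not slr_scenarios or not ssc_levels:
        raise ForcingError("scenario lists must be non-empty")
    level_order = sorted(
        ssc_levels, key=lambda lv: -SSC_LEVEL_FRACTIONS[lv]
    )
    slr_order = sorted(slr_scenarios, key=lambda s: s.s100)
    return [
        Scenario(slr, lv, SSC_LEVEL_FRACTIONS[lv] * site_ssc_mg_l)
        for slr, lv in itertools.product(slr_order, level_order)
    ]


def scenario_table(scenarios: list[Scenario], site: str = "") -> pd.DataFrame:
    """Tabular form of a scenario list (CSV-ready)."""
    return pd.DataFrame(
        {
            "site": site,
            "slr_label": [s.slr.label for s in scenarios],
            "s100_cm": [s.slr.s100 for s in scenarios],
            "ssc_level": [s.ssc_level for s in scenarios],
            "ssc_mg_per_l": [s.ssc_mg_l for s in scenarios],
        }
    )
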