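"""Indirect-calorimetry (CLAMS-style) trace analysis.

A trace is a time series of mass-specific gas exchange rates (VO2, VCO2 in
mL/kg/h), locomotor activity counts and cumulative food intake.  Samples
are partitioned into the diurnal (lights-on) and nocturnal (lights-off)
phases of the light schedule; per-phase summaries report mean VO2, VCO2,
respiratory exchange ratio (RER = VCO2/VO2) and energy expenditure, plus
total activity and food intake.

Energy expenditure uses the Lusk-type thermal equivalents by default,

    EE (kcal/h) = 3.815 * VO2 + 1.232 * VCO2          (VO2, VCO2 in L/h)

with the abbreviated Weir equation (3.941 * VO2 + 1.106 * VCO2) as an
alternative; the formula name travels with the result.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidScheduleError

EE_COEFFICIENTS = {
    "lusk": (3.815, 1.232),
    "weir": (3.941, 1.106),
}

DIURNAL = "diurnal"
NOCTURNAL = "nocturnal"


@dataclass
class CalorimetryTrace:
    """An ordered respirometry recording for one animal.

    ``samples`` columns: timestamp (datetime64), vo2, vco2 (mL/kg/h unless
    ``vo2_units`` says otherwise), activity_counts, food_g (cumulative).
    """

    samples: pd.DataFrame
    light_schedule: tuple[dt.time, dt.time]  # (lights_on, lights_off)
    body_mass_g: float
    vo2_units: str = "ml/kg/h"  # or "l/h" for absolute rates

    def __post_init__(self) -> None:
        req = {"timestamp", "vo2", "vco2"}
        missing = req - set(self.samples.columns)
        if missing:
            raise ValueError(f"trace is missing columns: {sorted(missing)}")
        ts = pd.to_datetime(self.samples["timestamp"])
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError("timestamps must be strictly increasing")
        self.samples = self.samples.assign(timestamp=ts).reset_index(drop=True)
        if (self.samples["vo2"] < 0).any() or (self.samples["vco2"] < 0).any():
            raise ValueError("vo2 and vco2 must be nonnegative")

    @classmethod
    def from_csv(cls, csv_path, meta: dict) -> "CalorimetryTrace":
        """Load from a CSV and a metadata dict with keys lights_on,
        lights_off ("HH:MM"), body_mass_g and optionally vo2_units."""
        df = pd.read_csv(csv_path, parse_dates=["timestamp"])
        on = dt.time.fromisoformat(meta["lights_on"])
        off = dt.time.fromisoformat(meta["lights_off"])
        return cls(
            samples=df,
            light_schedule=(on, off),
            body_mass_g=float(meta["body_mass_g"]),
            vo2_units=meta.get("vo2_units", "ml/kg/h"),
        )


@dataclass(frozen=True)
class CycleSummary:
    phase: str
    n_samples: int
    mean_vo2: float
    mean_vco2: float
    mean_rer: float
    mean_ee_kcal_h: float
    total_activity: float
    total_food_g: float
    ee_formula: str = "lusk"


def _seconds_of_day(timestamps: pd.Series) -> np.ndarray:
    t = pd.to_datetime(timestamps)
    return (
        t.dt.hour.to_numpy() * 3600
        + t.dt.minute.to_numpy() * 60
        + t.dt.second.to_numpy()
        + t.dt.microsecond.to_numpy() / 1e6
    )


def partition_cycles(trace: CalorimetryTrace) -> np.ndarray:
    """Label each sample diurnal iff its clock time lies in [lights_on,
    lights_off), else nocturnal; wrap-around schedules are supported."""
    on, off = trace.light_schedule
    s_on = on.hour * 3600 + on.minute * 60 + on.second
    s_off = off.hour * 3600 + off.minute * 60 + off.second
    if s_on == s_off:
        raise InvalidScheduleError("lights_on equals lights_off")
    sec = _seconds_of_day(trace.samples["timestamp"])
    if s_on < s_off:
        diurnal = (sec >= s_on) & (sec < s_off)
    else:
        diurnal = (sec >= s_on) | (sec < s_off)
    return np.where(diurnal, DIURNAL, NOCTURNAL)


def compute_rer(vo2, vco2):
    """Respiratory exchange ratio VCO2/VO2 (units cancel)."""
    vo2 = np.asarray(vo2, dtype=np.float64)
    vco2 = np.asarray(vco2, dtype=np.float64)
    if np.any(vo2 <= 0):
        raise ZeroDivisionError("RER undefined where VO2 <= 0")
    return vco2 / vo2


def compute_ee(vo2, vco2, body_mass_g: float, formula: str = "lusk",
               vo2_units: str = "ml/kg/h"):
    """Energy expenditure in kcal/h from gas exchange rates.

    Mass-specific rates (mL/kg/h) are converted to absolute L/h using the
    body mass; absolute rates ("l/h") are used as-is.
    """
    try:
        a, b = EE_COEFFICIENTS[formula]
    except KeyError:
        raise ValueError(f"unknown EE formula {formula!r}") from None
    vo2 = np.asarray(vo2, dtype=np.float64)
    vco2 = np.asarray(vco2, dtype=np.float64)
    if np.any(vo2 <= 0):
        raise ZeroDivisionError("EE undefined where VO2 <= 0")
    if vo2_units == "ml/kg/h":
        scale = body_mass_g / 1000.0 / 1000.0  # mL/kg/h -> L/h
    elif vo2_units == "l/h":
        scale = 1.0
    else:
        raise ValueError(f"unknown vo2 units {vo2_units!r}")
    return a * vo2 * scale + b * vco2 * scale


def summarize_cycles(
    trace: CalorimetryTrace,
    labels: np.ndarray | None = None,
    ee_formula: str = "lusk",
    drop_acclimation_h: float = 0.0,
) -> list[CycleSummary]:
    """Per-phase arithmetic means and totals.

    ``drop_acclimation_h`` discards the leading hours of the recording
    (chamber acclimatization) before summarising.
    """
    df = trace.samples
    if labels is None:
        labels = partition_cycles(trace)
    labels = np.asarray(labels)
    if drop_acclimation_h > 0:
        t0 = df["timestamp"].iloc[0] + pd.Timedelta(hours=drop_acclimation_h)
        keep = (df["timestamp"] >= t0).to_numpy()
        df = df.loc[keep]
        labels = labels[keep]
    out: list[CycleSummary] = []
    for phase in (DIURNAL, NOCTURNAL):
        sel = df.loc[labels == phase]
        if sel.empty:
            warnings.warn(f"no samples in the {phase} phase; omitted", stacklevel=2)
            continue
        vo2 = sel["vo2"].to_numpy()
        vco2 = sel["vco2"].to_numpy()
        rer = compute_rer(vo2, vco2)
        ee = compute_ee(vo2, vco2, trace.body_mass_g, ee_formula, trace.vo2_units)
        activity = sel["activity_counts"].sum() if "activity_counts" in sel else float("nan")
        if "food_g" in sel:
            food = float(sel["food_g"].iloc[-1] - sel["food_g"].iloc[0])
        else:
            food = float("nan")
        out.append(
            CycleSummary(
                phase=phase,
                n_samples=len(sel),
                mean_vo2=float(vo2.mean()),
                mean_vco2=float(vco2.mean()),
                mean_rer=float(rer.mean()),
                mean_ee_kcal_h=float(np.mean(ee)),
                total_activity=float(activity),
                total_food_g=food,
                ee_formula=ee_formula,
            )
        )
    return out
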