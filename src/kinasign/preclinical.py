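"""Tumor volume and tumor-growth-inhibition (TGI) computation.

Caliper measurements give the largest (D) and shortest (d) tumor diameter
in mm; volume uses the standard ellipsoid approximation V = D·d²/2 (mm³).
Treatment efficacy is summarised as

    TGI = [1 − (T_F/T_0)_treated / (T_F/T_0)_vehicle] × 100

where T_0 and T_F are arm mean volumes at the initial and final time
points; by convention T_F is the last day at which the first-terminated
treated arm still has measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def tumor_volume(D: float, d: float) -> float:
    """Ellipsoid tumor volume in mm³ from caliper diameters (mm)."""
    if d <= 0 or D < d:
        raise ValidationError(f"need D >= d > 0, got D={D}, d={d}")
    return D * d * d / 2.0


@dataclass
class TgiResult:
    arm: str
    t0: float
    tf: float
    tgi: float  # percent
    treated_ratio: float
    vehicle_ratio: float
    n_treated: int
    n_vehicle: int


def _arm_mean_volume(growth: pd.DataFrame, day: float) -> tuple:
    rows = growth[growth["day"] == day]
    if rows.empty:
        missing = sorted(growth["animal_id"].unique())
        raise ValidationError(
            f"no measurement at day {day} for animals {missing}"
        )
    if "volume" in rows.columns and rows["volume"].notna().all():
        vols = rows["volume"].to_numpy(float)
    else:
        vols = np.array([tumor_volume(D, d)
                         for D, d in zip(rows["D"], rows["d"])])
    return float(vols.mean()), len(rows)


def tgi(treated: pd.DataFrame, vehicle: pd.DataFrame,
        t0: float | None = None, tf: float | None = None) -> TgiResult:
    """Tumor growth inhibition of one treated arm versus vehicle.

    Both frames are tidy growth tables (``animal_id``, ``arm``, ``day``,
    and ``volume`` or ``D``/``d``).  Growth ratios are ratios of arm mean
    volumes at ``tf`` versus ``t0``.  ``t0`` defaults to the earliest
    shared day; ``tf`` to the last day present in both arms (the last time
    point of whichever arm was terminated first).
    """
    days_t = set(treated["day"])
    days_v = set(vehicle["day"])
    shared = sorted(days_t & days_v)
    if not shared:
        raise ValidationError("arms share no measurement days")
    if t0 is None:
        t0 = shared[0]
    if tf is None:
        tf = shared[-1]
    if tf <= t0:
        raise ValidationError(f"need tf > t0, got t0={t0}, tf={tf}")
    m_t0, n_t = _arm_mean_volume(treated, t0)
    m_tf, _ = _arm_mean_volume(treated, tf)
    v_t0, n_v = _arm_mean_volume(vehicle, t0)
    v_tf, _ = _arm_mean_volume(vehicle, tf)
    if m_t0 <= 0 or v_t0 <= 0:
        raise ValidationError("initial mean volumes must be positive")
    vehicle_ratio = v_tf / v_t0
    if vehicle_ratio <= 0:
        raise ValidationError("vehicle growth ratio must be positive")
    treated_ratio = m_tf / m_t0
    value = (1.0 - treated_ratio / vehicle_ratio) * 100.0
    arm = treated["arm"].iloc[0] if "arm" in treated.columns else "treated"
    return TgiResult(arm=str(arm), t0=float(t0), tf=float(tf), tgi=float(value),
                     treated_ratio=float(treated_ratio),
                     vehicle_ratio=float(vehicle_ratio),
                     n_treated=n_t, n_vehicle=n_v)


def arm_compare(burdens_a, burdens_b) -> tuple:
    """Welch two-sample t-test on per-tumor burdens; returns (t, p)."""
    a = np.asarray(burdens_a, dtype=float)
    b = np.asarray(burdens_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 tumors per arm")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
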