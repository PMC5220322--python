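"""Time-integrated activity coefficients (TIACs, "residence times").

A TIAC tau is the integral over time of a region's activity divided by
the administered activity, in MBq.h/MBq.  This module covers the four
steps that produce the tau inputs of the dose model:

* numerical integration of a sampled time-activity curve (trapezoid over
  the observed, decay-included points plus an analytic physical-decay
  tail beyond the last sample -- standard MIRD practice);
* rescaling a curve measured with one nuclide to another nuclide with
  identical biology (divide out one physical decay, multiply in the
  other);
* rat-to-human translation by relative organ mass (Kirschner scaling:
  tau scales with the organ-to-body mass fraction);
* partitioning the whole-pancreas tau into per-islet and exocrine shares
  from the islet area fraction, the islet:exocrine uptake ratio per
  pixel, and the representative islet diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "TimeActivityCurve",
    "TiacSet",
    "BodyCompositionPair",
    "PancreasPartition",
    "RAT_HUMAN_DEFAULTS",
    "integrate_tac",
    "rescale_to_nuclide",
    "kirschner_translate",
    "partition_pancreas",
    "calibrate_uptake_ratio",
    "select_kidney_tau",
    "read_tac",
    "write_tac",
]


@dataclass(frozen=True)
class TimeActivityCurve:
    """Fraction of injected activity in a region at sampled times (hours)."""

    times_h: np.ndarray
    activity_fraction: np.ndarray
    includes_physical_decay: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        f = np.asarray(self.activity_fraction, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "activity_fraction", f)
        if t.ndim != 1 or t.shape != f.shape:
            raise ValueError("times and fractions must be 1-D arrays of equal length")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("activity fractions must lie in [0, 1]")


@dataclass(frozen=True)
class TiacSet:
    """The three TIACs feeding the islet dose model, with their context."""

    tau_kidneys: float
    tau_pancreas: float
    tau_one_islet: float
    islet_diameter_um: float
    islet_fraction: float

    def __post_init__(self) -> None:
        if min(self.tau_kidneys, self.tau_pancreas, self.tau_one_islet) <= 0:
            raise ValueError("all TIACs must be positive")
        if self.tau_one_islet >= self.tau_pancreas:
            raise ValueError("per-islet TIAC must be far smaller than the pancreas TIAC")


@dataclass(frozen=True)
class BodyCompositionPair:
    """Organ and total-body masses for rat-to-human TIAC translation."""

    organ_mass_rat_g: float
    body_mass_rat_g: float
    organ_mass_human_g: float
    body_mass_human_g: float

    def __post_init__(self) -> None:
        for m in (
            self.organ_mass_rat_g,
            self.body_mass_rat_g,
            self.organ_mass_human_g,
            self.body_mass_human_g,
        ):
            if m <= 0:
                raise ValueError("masses must be positive")
        if not (
            self.organ_mass_rat_g < self.body_mass_rat_g
            and self.organ_mass_human_g < self.body_mass_human_g
        ):
            raise ValueError("organ mass must be smaller than body mass")


#: default pancreas/body masses: rat 1 g / 150 g; human male 94.3 g / 70.0 kg,
#: female 85 g / 56.9 kg (standard reference-adult values)
RAT_HUMAN_DEFAULTS = {
    "male": BodyCompositionPair(1.0, 150.0, 94.3, 70_000.0),
    "female": BodyCompositionPair(1.0, 150.0, 85.0, 56_900.0),
}


def integrate_tac(
    tac: TimeActivityCurve, lambda_phys_per_h: float, tail: str = "physical_decay"
) -> float:
    """TIAC in MBq.h/MBq: trapezoid over the samples plus an optional tail.

    The curve must include physical decay.  With ``tail="physical_decay"``
    the integral beyond the last sample assumes physical decay only
    (A_last / lambda), the conservative MIRD convention; ``tail="none"``
    truncates at the last sample.
    """
    if tail not in ("physical_decay", "none"):
        raise ValueError("tail must be 'physical_decay' or 'none'")
    n_min = 1 if tail == "physical_decay" else 2
    if tac.times_h.size < n_min:
        raise ValueError(f"need at least {n_min} samples for tail={tail!r}")
    tau = float(np.trapezoid(tac.activity_fraction, tac.times_h))
    if tail == "physical_decay":
        if lambda_phys_per_h <= 0:
            raise ValueError("physical decay constant must be positive")
        tau += float(tac.activity_fraction[-1]) / lambda_phys_per_h
    return tau


def rescale_to_nuclide(
    tac: TimeActivityCurve, lambda_a_per_h: float, lambda_b_per_h: float
) -> TimeActivityCurve:
    """Re-express a decay-included curve measured with nuclide A for nuclide B.

    Divides out exp(-lambda_A t) and multiplies by exp(-lambda_B t),
    assuming identical biological behaviour of the two radiotracers.
    """
    if not tac.includes_physical_decay:
        raise ValueError("curve must include physical decay to rescale between nuclides")
    if lambda_a_per_h <= 0 or lambda_b_per_h <= 0:
        raise ValueError("decay constants must be positive")
    f = tac.activity_fraction * np.exp((lambda_a_per_h - lambda_b_per_h) * tac.times_h)
    return TimeActivityCurve(tac.times_h.copy(), np.clip(f, 0.0, 1.0), True)


def kirschner_translate(tau_rat: float, masses: BodyCompositionPair) -> float:
    """Translate a rat TIAC to human by relative organ mass.

    tau_human = tau_rat * (m_organ/m_body)_human / (m_organ/m_body)_rat.
    """
    if tau_rat <= 0:
        raise ValueError("tau must be positive")
    frac_h = masses.organ_mass_human_g / masses.body_mass_human_g
    frac_r = masses.organ_mass_rat_g / masses.body_mass_rat_g
    return tau_rat * frac_h / frac_r


@dataclass(frozen=True)
class PancreasPartition:
    tau_one_islet: float
    tau_exocrine_total: float
    n_islets: float
    islet_share: float


def _islet_volume_cm3(diameter_um: float) -> float:
    return math.pi / 6.0 * (diameter_um * 1e-4) ** 3


def partition_pancreas(
    tau_pancreas: float,
    islet_fraction: float,
    uptake_ratio: float,
    islet_diameter_um: float,
    pancreas_mass_g: float = 94.3,
    density_g_cm3: float = 1.04,
) -> PancreasPartition:
    """Split the whole-pancreas TIAC into per-islet and exocrine shares.

    With islet volume fraction f and per-pixel islet:exocrine activity
    concentration ratio r, the islet compartment holds a share
    r*f / (r*f + (1-f)) of the pancreas TIAC; dividing by the islet count
    N = f*M / (rho * pi d^3/6) gives the TIAC of a single islet of
    diameter d.  Shares conserve activity:
    tau_one_islet*N + tau_exocrine_total = tau_pancreas.
    """
    if tau_pancreas <= 0:
        raise ValueError("tau_pancreas must be positive")
    if not 0.0 < islet_fraction < 1.0:
        raise ValueError("islet fraction must lie in (0, 1)")
    if uptake_ratio <= 0:
        raise ValueError("uptake ratio must be positive")
    if not 10.0 < islet_diameter_um < 2000.0:
        raise ValueError("islet diameter must lie in (10, 2000) um")
    if pancreas_mass_g <= 0 or density_g_cm3 <= 0:
        raise ValueError("mass and density must be positive")
    f, r = islet_fraction, uptake_ratio
    share = r * f / (r * f + (1.0 - f))
    n_islets = f * pancreas_mass_g / (density_g_cm3 * _islet_volume_cm3(islet_diameter_um))
    tau_one = share * tau_pancreas / n_islets
    tau_exo = (1.0 - share) * tau_pancreas
    return PancreasPartition(tau_one, tau_exo, n_islets, share)


def calibrate_uptake_ratio(
    tau_pancreas: float,
    islet_fraction: float,
    islet_diameter_um: float,
    tau_one_islet_target: float,
    pancreas_mass_g: float = 94.3,
    density_g_cm3: float = 1.04,
) -> float:
    """Uptake ratio r for which ``partition_pancreas`` hits a per-islet TIAC."""
    def miss(r: float) -> float:
        part = partition_pancreas(
            tau_pancreas, islet_fraction, r, islet_diameter_um, pancreas_mass_g, density_g_cm3
        )
        return part.tau_one_islet - tau_one_islet_target

    return float(brentq(miss, 1e-6, 1e8, xtol=1e-12, rtol=1e-13))


def select_kidney_tau(taus: Sequence[float], mode: str = "mean") -> float:
    """Cohort summary of per-subject kidney TIACs: mean, min or max."""
    taus = list(taus)
    if not taus:
        raise ValueError("need at least one subject TIAC")
    if mode == "mean":
        return float(np.mean(taus))
    if mode == "min":
        return float(np.min(taus))
    if mode == "max":
        return float(np.max(taus))
    raise ValueError("mode must be 'mean', 'min' or 'max'")


def read_tac(path) -> TimeActivityCurve:
    """Read a curve from CSV with columns time_h, fraction and an
    includes_decay column (constant 0/1)."""
    df = pd.read_csv(path)
    return TimeActivityCurve(
        df["time_h"].to_numpy(float),
        df["fraction"].to_numpy(float),
        bool(df["includes_decay"].iloc[0]) if "includes_decay" in df else True,
    )


def write_tac(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "time_h": tac.times_h,
            "fraction": tac.activity_fraction,
            "includes_decay": int(tac.includes_physical_decay),
        }
    ).to_csv(path, index=False)
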