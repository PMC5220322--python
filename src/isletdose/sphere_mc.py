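"""Monte Carlo self-dose S-values for activity-filled soft-tissue microspheres.

The islet of Langerhans is modelled as a homogeneous sphere (50-400 um
diameter, ICRU-44-like soft tissue, density 1.04 g/cm3) with activity
distributed uniformly through its volume.  Electrons and positrons above
a 1 keV cutoff are transported in the continuous-slowing-down
approximation (CSDA) along straight tracks: the energy deposited by a
track is the initial energy minus the residual energy carried across the
sphere boundary, obtained from a packaged collisional stopping-power
tabulation (Moller formula, log-log interpolated).  Sub-keV Auger
electrons are deposited locally.  Photon self-absorption is treated
analytically via mass energy-absorption coefficients over the mean chord;
for spheres below 400 um it contributes well under 0.1% of the S-value.

Multiple-scattering deflection, energy-loss straggling and backscatter
from the surrounding tissue are deliberately not modelled; at these
sphere sizes escape-versus-containment is governed by the range/chord
geometry, which the straight-track CSDA captures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay_data import (
    LOCAL_ABSORPTION_CUTOFF_KEV,
    RadionuclideSpectrum,
    _beta_sampler,
)

__all__ = [
    "SphereGeometry",
    "SValueResult",
    "stopping_power",
    "csda_range",
    "energy_at_range",
    "transport_electron",
    "photon_absorbed_fraction",
    "compute_sphere_svalue",
]

_ELECTRON_MASS_KEV = 510.99895
_KEV_TO_J = 1.602176634e-16
#: decays per MBq.h divided by Gy->mGy: S[mGy/(MBq.h)] = (J/decay)/kg * 3.6e12
_S_UNIT_FACTOR = 3.6e12

_E_MIN_KEV, _E_MAX_KEV = 1.0, 3000.0


@dataclass(frozen=True)
class Medium:
    """Electron-transport medium: mean Z/A, mean excitation energy, density."""

    name: str
    z_over_a: float
    i_ev: float
    density_g_cm3: float


# ICRU-44 adult soft tissue and pancreas differ by <1% in Z/A, I and
# density; a single medium is used for both labels.
MEDIA = {
    "soft_tissue": Medium("soft_tissue", z_over_a=0.550, i_ev=74.7, density_g_cm3=1.04),
    "pancreas": Medium("pancreas", z_over_a=0.550, i_ev=74.7, density_g_cm3=1.04),
}


@dataclass(frozen=True)
class SphereGeometry:
    diameter_um: float
    density_g_cm3: float = 1.04
    medium: str = "soft_tissue"

    def __post_init__(self) -> None:
        if not 10.0 < self.diameter_um < 2000.0:
            raise ValueError("sphere diameter must lie in (10, 2000) um")
        if not 0.9 < self.density_g_cm3 < 1.1:
            raise ValueError("density must lie in (0.9, 1.1) g/cm3")
        if self.medium not in MEDIA:
            raise ValueError(f"unknown medium {self.medium!r}; available: {sorted(MEDIA)}")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    @property
    def mass_kg(self) -> float:
        volume_cm3 = np.pi / 6.0 * (self.diameter_um * 1e-4) ** 3
        return self.density_g_cm3 * volume_cm3 * 1e-3


@dataclass(frozen=True)
class SValueResult:
    """Self-dose S-value of one microsphere with its MC bookkeeping."""

    nuclide_id: str
    diameter_um: float
    s_mgy_per_mbqh: float
    absorbed_fraction_by_kind: dict[str, float]
    rel_stderr: float
    n_histories: int
    seed: int
    mean_energy_absorbed_kev: float


# ---------------------------------------------------------------------------
# stopping power / range tabulation


def _moller_stopping_power_mev_cm2_g(e_kev: np.ndarray, medium: Medium) -> np.ndarray:
    """Collisional (Moller) stopping power for electrons, MeV cm2/g."""
    tau = e_kev / _ELECTRON_MASS_KEV
    beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
    i_rel = medium.i_ev * 1e-3 / _ELECTRON_MASS_KEV
    log_term = np.log(tau**2 * (tau + 2.0) / (2.0 * i_rel**2))
    f_tau = 1.0 - beta2 + (tau**2 / 8.0 - (2.0 * tau + 1.0) * np.log(2.0)) / (tau + 1.0) ** 2
    return 0.1535 * medium.z_over_a / beta2 * (log_term + f_tau)


class _TransportTable:
    """Packaged stopping-power/CSDA-range tabulation for one medium.

    600-point log grid from 1 keV to 3 MeV; stopping power in keV/um,
    range in um (density included).  Lookup is log-log interpolated.
    """

    def __init__(self, medium: Medium):
        e = np.logspace(np.log10(_E_MIN_KEV), np.log10(_E_MAX_KEV), 600)
        sp = _moller_stopping_power_mev_cm2_g(e, medium)  # MeV cm2/g
        sp_kev_um = sp * 1e3 * medium.density_g_cm3 * 1e-4  # keV/um
        # CSDA range: integral of dE/S from the cutoff, plus the linear
        # remainder below 1 keV (~0.08 um, deposited locally anyway)
        inv = 1.0 / sp_kev_um
        r = np.concatenate([[0.0], np.cumsum((inv[1:] + inv[:-1]) * np.diff(e) / 2.0)])
        r += e[0] / sp_kev_um[0]
        self._log_e = np.log(e)
        self._log_sp = np.log(sp_kev_um)
        self._log_r = np.log(r)

    def stopping_power(self, e_kev):
        e = np.asarray(e_kev, dtype=float)
        if np.any(e < _E_MIN_KEV) or np.any(e > _E_MAX_KEV):
            raise ValueError(f"energy outside tabulated range [{_E_MIN_KEV}, {_E_MAX_KEV}] keV")
        return np.exp(np.interp(np.log(e), self._log_e, self._log_sp))

    def csda_range(self, e_kev):
        e = np.asarray(e_kev, dtype=float)
        if np.any(e < _E_MIN_KEV) or np.any(e > _E_MAX_KEV):
            raise ValueError(f"energy outside tabulated range [{_E_MIN_KEV}, {_E_MAX_KEV}] keV")
        return np.exp(np.interp(np.log(e), self._log_e, self._log_r))

    def energy_at_range(self, r_um):
        """Inverse of csda_range; residual energies below 1 keV map to 0."""
        r = np.asarray(r_um, dtype=float)
        out = np.exp(np.interp(np.log(np.maximum(r, 1e-12)), self._log_r, self._log_e))
        return np.where(r < np.exp(self._log_r[0]), 0.0, out)


_TABLES: dict[str, _TransportTable] = {}


def _table(medium: str) -> _TransportTable:
    if medium not in MEDIA:
        raise ValueError(f"unknown medium {medium!r}; available: {sorted(MEDIA)}")
    if medium not in _TABLES:
        _TABLES[medium] = _TransportTable(MEDIA[medium])
    return _TABLES[medium]


def stopping_power(energy_kev, medium: str = "soft_tissue"):
    """Collisional electron stopping power in keV/um (1 keV - 3 MeV)."""
    return _table(medium).stopping_power(energy_kev)


def csda_range(energy_kev, medium: str = "soft_tissue"):
    """CSDA range in um, integrated from the 1 keV transport cutoff."""
    return _table(medium).csda_range(energy_kev)


def energy_at_range(range_um, medium: str = "soft_tissue"):
    """Electron energy (keV) whose CSDA range equals ``range_um``."""
    return _table(medium).energy_at_range(range_um)


# ---------------------------------------------------------------------------
# photon self-absorption

# Mass energy-absorption coefficients mu_en/rho for soft tissue (cm2/g),
# log-log interpolated; values follow the standard NIST water tabulation,
# which matches ICRU-44 soft tissue to within a few percent -- far below
# the <0.1% photon contribution to S at these sphere sizes.
_MU_EN_E_KEV = np.array(
    [1, 2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 40, 50, 60, 80, 100,
     150, 200, 300, 400, 500, 600, 800, 1000, 1250, 1500, 2000, 3000],
    dtype=float,
)
_MU_EN_CM2_G = np.array(
    [4065, 617, 191.7, 81.9, 41.9, 24.1, 9.92, 4.944, 1.374, 0.5503,
     0.1557, 0.0695, 0.04223, 0.0319, 0.02597, 0.02546, 0.02764, 0.02967,
     0.03192, 0.03279, 0.03299, 0.03284, 0.03206, 0.03103, 0.02965,
     0.02833, 0.02608, 0.02281],
    dtype=float,
)


def photon_absorbed_fraction(energy_kev: float, geometry: SphereGeometry) -> float:
    """Self-absorbed fraction for photons emitted uniformly in the sphere.

    Analytic estimate 1 - exp(-mu_en * <chord>) with the mean path from a
    uniform interior source to the boundary, <chord> = 3R/4.  For spheres
    up to 400 um this is well below 1e-2.
    """
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    e = np.clip(energy_kev, _MU_EN_E_KEV[0], _MU_EN_E_KEV[-1])
    mu_en = np.exp(
        np.interp(np.log(e), np.log(_MU_EN_E_KEV), np.log(_MU_EN_CM2_G))
    ) * geometry.density_g_cm3  # 1/cm
    mean_path_cm = 0.75 * geometry.radius_um * 1e-4
    return float(1.0 - np.exp(-mu_en * mean_path_cm))


# ---------------------------------------------------------------------------
# electron transport


def _chord_lengths(radius_um: float, r_um: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Distance to the sphere surface from radius r along a direction whose
    cosine with the outward radial vector is mu."""
    return -r_um * mu + np.sqrt(radius_um**2 - r_um**2 * (1.0 - mu**2))


def _deposit_csda(
    energy_kev: np.ndarray, path_um: np.ndarray, medium: str
) -> np.ndarray:
    """Energy deposited along straight CSDA tracks truncated at ``path_um``."""
    tbl = _table(medium)
    full_range = tbl.csda_range(energy_kev)
    residual_range = np.maximum(full_range - path_um, 0.0)
    e_res = tbl.energy_at_range(residual_range)
    # residuals at/below the cutoff are deposited locally
    e_res = np.where(e_res <= LOCAL_ABSORPTION_CUTOFF_KEV, 0.0, e_res)
    return energy_kev - e_res


def transport_electron(
    energy_kev: float,
    origin_um: np.ndarray,
    direction: np.ndarray,
    geometry: SphereGeometry,
    rng: np.random.Generator | None = None,
) -> float:
    """Deposited energy (keV) of one electron track.

    Straight-track CSDA: deposition stops when the track leaves the
    sphere or the residual energy falls to the 1 keV cutoff (then the
    residual is deposited locally).  ``rng`` is accepted for interface
    symmetry; the straight-track model is deterministic.
    """
    if energy_kev <= LOCAL_ABSORPTION_CUTOFF_KEV:
        raise ValueError("transport requires energy above the 1 keV cutoff")
    origin = np.asarray(origin_um, dtype=float)
    r = float(np.linalg.norm(origin))
    radius = geometry.radius_um
    if r > radius * (1.0 + 1e-12):
        raise ValueError("electron origin lies outside the sphere")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    mu = float(origin @ d) / r if r > 0 else 1.0
    path = _chord_lengths(radius, np.array([min(r, radius)]), np.array([mu]))[0]
    dep = _deposit_csda(np.array([energy_kev]), np.array([path]), geometry.medium)[0]
    return float(dep)


# ---------------------------------------------------------------------------
# S-value Monte Carlo


def compute_sphere_svalue(
    spectrum: RadionuclideSpectrum,
    geometry: SphereGeometry,
    n_histories: int = 1_000_000,
    seed: int = 0,
) -> SValueResult:
    """Self-dose S-value (mGy per MBq.h) of a uniformly active sphere.

    Each history is one decay at a position sampled uniformly in the
    sphere volume.  Every electron line of the spectrum contributes its
    yield-weighted track deposit from that position along an isotropic
    direction; positron energies are drawn per history from the branch
    spectrum.  Sub-keV Auger electrons deposit locally and photons are
    handled with the analytic absorbed fraction -- both enter as
    per-decay constants with zero MC variance.  Identical seeds give
    bit-identical results.
    """
    if n_histories < 1000:
        raise ValueError("need at least 1000 histories")
    rng = np.random.default_rng(seed)

    radius = geometry.radius_um
    # uniform positions in the sphere: r = R * u^(1/3); mu relative to the
    # radial direction is uniform for isotropic emission
    r_pos = radius * np.cbrt(rng.random(n_histories))

    emitted = {k: 0.0 for k in ("gamma", "auger_electron", "ic_electron", "beta_plus")}
    absorbed = dict(emitted)

    deterministic_kev = 0.0  # per-decay deposit with no MC variance
    stochastic = np.zeros(n_histories)

    for line in spectrum.lines:
        e_emitted = line.energy_kev * line.yield_per_decay
        emitted[line.kind] += e_emitted
        if line.kind == "gamma":
            frac = photon_absorbed_fraction(line.energy_kev, geometry)
            deterministic_kev += e_emitted * frac
            absorbed[line.kind] += e_emitted * frac
            continue
        if line.locally_absorbed:
            deterministic_kev += e_emitted
            absorbed[line.kind] += e_emitted
            continue
        mu = rng.uniform(-1.0, 1.0, n_histories)
        if line.kind == "beta_plus":
            energies = _beta_sampler(line).sample(rng, n_histories)
        else:
            energies = np.full(n_histories, line.energy_kev)
        path = _chord_lengths(radius, r_pos, mu)
        dep = _deposit_csda(energies, path, geometry.medium) * line.yield_per_decay
        stochastic += dep
        absorbed[line.kind] += float(dep.mean())

    mean_kev = deterministic_kev + float(stochastic.mean())
    if n_histories > 1 and stochastic.any():
        stderr = float(stochastic.std(ddof=1)) / np.sqrt(n_histories)
    else:
        stderr = 0.0
    rel_stderr = stderr / mean_kev if mean_kev > 0 else 0.0

    s_value = mean_kev * _KEV_TO_J / geometry.mass_kg * _S_UNIT_FACTOR
    af = {
        k: (absorbed[k] / emitted[k] if emitted[k] > 0 else 0.0) for k in emitted
    }
    return SValueResult(
        nuclide_id=spectrum.nuclide_id,
        diameter_um=geometry.diameter_um,
        s_mgy_per_mbqh=float(s_value),
        absorbed_fraction_by_kind=af,
        rel_stderr=rel_stderr,
        n_histories=n_histories,
        seed=seed,
        mean_energy_absorbed_kev=mean_kev,
    )
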