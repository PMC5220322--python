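"""Radionuclide decay data for In-111 and Ga-68.

The package ships a condensed, machine-readable emission line list per
nuclide (YAML, schema version 1) holding the gamma lines, the Auger and
internal-conversion electron groups (In-111) and the positron branches
(Ga-68), together with the physical half-life.  The line lists are the
source term of every S-value computed elsewhere in the package: what
matters dosimetrically is the energy emitted per decay per radiation
kind, which the condensed lists preserve exactly.

Positron energies are continuous; they are sampled from an
allowed-transition beta spectrum shape (including a positron Coulomb
factor) whose mean is calibrated to the tabulated mean energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "EmissionLine",
    "RadionuclideSpectrum",
    "LINE_KINDS",
    "ELECTRON_KINDS",
    "available_nuclides",
    "load_spectrum",
    "decay_constant",
    "mean_energy_per_decay",
    "sample_emission",
    "sample_emissions",
    "BetaPlusSpectrum",
]

LINE_KINDS = frozenset({"gamma", "auger_electron", "ic_electron", "beta_plus"})
#: kinds transported as charged particles
ELECTRON_KINDS = frozenset({"auger_electron", "ic_electron", "beta_plus"})

#: electrons at or below this energy are assumed fully locally absorbed
LOCAL_ABSORPTION_CUTOFF_KEV = 1.0

_ELECTRON_MASS_KEV = 510.99895
_ALPHA = 1.0 / 137.035999

_DATA_FILES = {"In-111": "in111.yaml", "Ga-68": "ga68.yaml"}


@dataclass(frozen=True)
class EmissionLine:
    """One discrete emission (or one continuous beta-plus branch).

    For ``beta_plus`` lines ``energy_kev`` is the branch *mean* energy and
    ``endpoint_kev`` the spectrum endpoint; for all other kinds the line is
    monoenergetic and ``endpoint_kev`` is ``None``.
    """

    kind: str
    energy_kev: float
    yield_per_decay: float
    endpoint_kev: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in LINE_KINDS:
            raise ValueError(f"unknown emission kind {self.kind!r}; expected one of {sorted(LINE_KINDS)}")
        if self.energy_kev <= 0:
            raise ValueError("emission energy must be positive")
        if self.yield_per_decay <= 0:
            raise ValueError("emission yield must be positive")
        if self.kind == "beta_plus":
            if self.endpoint_kev is None:
                raise ValueError("beta_plus lines need an endpoint energy")
            if not self.energy_kev < self.endpoint_kev:
                raise ValueError("beta_plus mean energy must lie below the endpoint")
        elif self.endpoint_kev is not None:
            raise ValueError("endpoint_kev only applies to beta_plus lines")

    @property
    def locally_absorbed(self) -> bool:
        """True for sub-keV electrons, deposited where they are emitted."""
        return self.kind in ELECTRON_KINDS and self.energy_kev <= LOCAL_ABSORPTION_CUTOFF_KEV


@dataclass(frozen=True)
class RadionuclideSpectrum:
    """Half-life plus emission line list for one nuclide."""

    nuclide_id: str
    half_life_h: float
    lines: tuple[EmissionLine, ...]

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        if not self.lines:
            raise ValueError("spectrum must contain at least one line")

    def lines_of_kind(self, kinds: Iterable[str]) -> tuple[EmissionLine, ...]:
        kinds = set(kinds)
        unknown = kinds - LINE_KINDS
        if unknown:
            raise ValueError(f"unknown emission kinds {sorted(unknown)}")
        return tuple(ln for ln in self.lines if ln.kind in kinds)


def available_nuclides() -> tuple[str, ...]:
    return tuple(sorted(_DATA_FILES))


def load_spectrum(nuclide_id: str) -> RadionuclideSpectrum:
    """Load the packaged emission spectrum for ``nuclide_id``.

    Raises ``KeyError`` naming the packaged nuclides when the id is
    unknown.  Half-lives are expressed in hours.
    """
    try:
        fname = _DATA_FILES[nuclide_id]
    except KeyError:
        raise KeyError(
            f"no packaged decay data for {nuclide_id!r}; available nuclides: "
            f"{sorted(_DATA_FILES)}"
        ) from None
    text = resources.files("isletdose.data.decay").joinpath(fname).read_text()
    raw = yaml.safe_load(text)
    lines = tuple(
        EmissionLine(
            kind=ln["kind"],
            energy_kev=float(ln["energy_keV"]),
            yield_per_decay=float(ln["yield"]),
            endpoint_kev=float(ln["endpoint_keV"]) if "endpoint_keV" in ln else None,
        )
        for ln in raw["lines"]
    )
    spec = RadionuclideSpectrum(
        nuclide_id=raw["nuclide"], half_life_h=float(raw["half_life_h"]), lines=lines
    )
    _validate_nuclide_specific(spec)
    return spec


def _validate_nuclide_specific(spec: RadionuclideSpectrum) -> None:
    kinds = {ln.kind for ln in spec.lines}
    if spec.nuclide_id == "In-111" and "beta_plus" in kinds:
        raise ValueError("In-111 decays by electron capture; beta_plus lines are inconsistent")
    if spec.nuclide_id == "Ga-68" and kinds & {"auger_electron", "ic_electron"}:
        raise ValueError("Ga-68 line list must not contain Auger/IC electron groups")


def decay_constant(spectrum: RadionuclideSpectrum) -> float:
    """Physical decay constant in h^-1 (ln 2 / half-life)."""
    return math.log(2.0) / spectrum.half_life_h


def mean_energy_per_decay(
    spectrum: RadionuclideSpectrum, kinds: Iterable[str] | None = None
) -> float:
    """Energy emitted per decay (keV) summed over the selected line kinds.

    Beta-plus branches contribute mean energy x yield.  An empty
    selection returns 0.
    """
    if kinds is None:
        kinds = LINE_KINDS
    selected = spectrum.lines_of_kind(kinds)
    return sum(ln.energy_kev * ln.yield_per_decay for ln in selected)


class BetaPlusSpectrum:
    """Continuous positron energy sampler for one beta-plus branch.

    Uses the allowed-transition shape p*W*(Q-E)^2 times a positron
    Coulomb (Fermi) factor, tabulated on a fine grid, then linearly
    rescaled in energy so the distribution mean equals the tabulated
    branch mean.  The rescale factor for both Ga-68 branches is < 1, so
    sampled energies never exceed the endpoint.
    """

    _N_GRID = 4000

    def __init__(self, endpoint_kev: float, mean_kev: float, daughter_z: int = 30):
        self.endpoint_kev = float(endpoint_kev)
        self.mean_kev = float(mean_kev)
        e = np.linspace(endpoint_kev * 1e-5, endpoint_kev * (1 - 1e-9), self._N_GRID)
        w = e / _ELECTRON_MASS_KEV + 1.0
        p = np.sqrt(w * w - 1.0)
        shape = p * w * (endpoint_kev - e) ** 2
        # positron Coulomb factor: eta < 0 suppresses slow positrons
        eta = -_ALPHA * daughter_z * w / p
        shape *= 2 * np.pi * eta / (1.0 - np.exp(-2 * np.pi * eta))
        cdf = np.concatenate([[0.0], np.cumsum((shape[1:] + shape[:-1]) * np.diff(e) / 2)])
        cdf /= cdf[-1]
        raw_mean = np.trapezoid(shape * e, e) / np.trapezoid(shape, e)
        scale = mean_kev / raw_mean
        if abs(scale - 1.0) > 0.02:
            raise ValueError(
                f"allowed shape mean {raw_mean:.1f} keV deviates >2% from tabulated "
                f"{mean_kev} keV"
            )
        self._grid = e
        self._cdf = cdf
        self._scale = scale

    def sample(self, rng: np.random.Generator, n: int | None = None) -> np.ndarray | float:
        u = rng.random(n)
        e = np.interp(u, self._cdf, self._grid) * self._scale
        return e


_BETA_SAMPLERS: dict[tuple[float, float], BetaPlusSpectrum] = {}


def _beta_sampler(line: EmissionLine) -> BetaPlusSpectrum:
    key = (line.endpoint_kev, line.energy_kev)
    if key not in _BETA_SAMPLERS:
        _BETA_SAMPLERS[key] = BetaPlusSpectrum(line.endpoint_kev, line.energy_kev)
    return _BETA_SAMPLERS[key]


def sample_emission(
    spectrum: RadionuclideSpectrum, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw one emission: the line with probability proportional to yield,
    then (for beta_plus) an energy from the continuous branch spectrum."""
    kinds, energies = sample_emissions(spectrum, 1, rng)
    return kinds[0], float(energies[0])


def sample_emissions(
    spectrum: RadionuclideSpectrum, n: int, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    """Vectorised form of :func:`sample_emission`; returns (kinds, energies)."""
    yields = np.array([ln.yield_per_decay for ln in spectrum.lines])
    idx = rng.choice(len(spectrum.lines), size=n, p=yields / yields.sum())
    energies = np.empty(n)
    kinds: list[str] = []
    for i, line in enumerate(spectrum.lines):
        sel = idx == i
        if line.kind == "beta_plus":
            m = int(sel.sum())
            if m:
                energies[sel] = _beta_sampler(line).sample(rng, m)
        else:
            energies[sel] = line.energy_kev
    lut = [ln.kind for ln in spectrum.lines]
    kinds = [lut[i] for i in idx]
    return kinds, energies
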