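"""Wet-lab arithmetic: Beer–Lambert quantification, encapsulation efficiency,
and withdrawal-corrected cumulative release.

A dissolution study repeatedly withdraws medium for UV–vis measurement, which
removes already-released drug from the vessel.  Cumulative release at sampling
k must therefore add back the drug carried away by every earlier withdrawal:

    M_k = V_k·c_k + Σ_{i<k} w_i·c_i        (as mass, via the analyte's MW)

where c_i is the vessel concentration at sampling i (from absorbance through
Beer–Lambert, including any dilution of the measured supernatant), V_k the
vessel volume at sampling k, and w_i the withdrawn volumes.  With replacement
of withdrawn medium V stays at the initial volume; without, it shrinks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .kinetics import ReleaseCurve

__all__ = [
    "OpticalProtocol",
    "SamplingEvent",
    "absorbance_to_concentration",
    "concentration_to_mass",
    "encapsulation_efficiency",
    "cumulative_release",
    "release_percent_of_loaded",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OpticalProtocol:
    """UV–vis quantification constants.

    epsilon : molar extinction coefficient, dm³·mol⁻¹·cm⁻¹
        (e.g. 58 547 for curcumin in DMSO at 426 nm, 28 648 in PBS/ethanol).
    path_cm : cuvette path length, cm.
    dilution_factor : ≥ 1; 2 for a 1:1 dilution of the withdrawn supernatant.
    mw : analyte molar mass, g·mol⁻¹ (curcumin: 368.38).
    """

    epsilon: float
    mw: float
    path_cm: float = 1.0
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be > 0")
        if self.path_cm <= 0:
            raise ValueError("path length must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        if self.mw <= 0:
            raise ValueError("molar mass must be > 0")


@dataclass(frozen=True)
class SamplingEvent:
    """One withdrawal: time (h), measured absorbance (AU, of the possibly
    diluted supernatant), withdrawn volume (mL), and whether the volume was
    replaced with fresh medium."""

    time: float
    absorbance: float
    withdrawn_volume: float
    replaced: bool = True

    def __post_init__(self) -> None:
        if self.absorbance < 0:
            raise ValueError("absorbance must be non-negative")
        if self.withdrawn_volume < 0:
            raise ValueError("withdrawn volume must be non-negative")


def absorbance_to_concentration(
    A: float, proto: OpticalProtocol, *, blank_threshold: float = 0.0
) -> float:
    """Molar concentration in the vessel from a measured absorbance.

    Inverts Beer–Lambert (A = ε·c·l) on the measured sample and multiplies by
    the dilution factor to recover the vessel concentration.  Absorbances at
    or below ``blank_threshold`` are clamped to 0 (logged) — blank-level
    readings carry no analyte signal.
    """
    if A < 0:
        raise ValueError("absorbance must be non-negative")
    if A <= blank_threshold and A > 0:
        logger.warning("absorbance %.4g at/below blank threshold %.4g; clamped to 0",
                       A, blank_threshold)
        A = 0.0
    return A * proto.dilution_factor / (proto.epsilon * proto.path_cm)


def concentration_to_mass(c: float, volume_ml: float, mw: float) -> float:
    """µg of analyte in ``volume_ml`` mL of solution at molar concentration c."""
    if c < 0:
        raise ValueError("concentration must be non-negative")
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    return c * (volume_ml / 1000.0) * mw * 1e6


def encapsulation_efficiency(measured_drug_ug: float, theoretical_drug_ug: float) -> float:
    """Percent of the offered drug actually encapsulated: 100·measured/theoretical.

    May legitimately fall below 100 or, through measurement error, slightly
    above it; the value is reported untruncated.
    """
    if theoretical_drug_ug <= 0:
        raise ValueError("theoretical drug amount must be > 0")
    if measured_drug_ug < 0:
        raise ValueError("measured drug amount must be non-negative")
    return 100.0 * measured_drug_ug / theoretical_drug_ug


def cumulative_release(
    events: Sequence[SamplingEvent],
    initial_volume_ml: float,
    proto: OpticalProtocol,
    *,
    blank_threshold: float = 0.0,
    label: str = "",
) -> ReleaseCurve:
    """Assemble a µg-scale cumulative release curve from sampling events.

    Applies the mass-balance correction for withdrawn medium (see module
    docstring).  Events must be time-ordered and no withdrawal may exceed the
    current vessel volume.
    """
    if initial_volume_ml <= 0:
        raise ValueError("initial volume must be > 0")
    times = [ev.time for ev in events]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("sampling events must be strictly time-ordered")

    volume = initial_volume_ml
    carried_ug = 0.0  # drug removed from the vessel by earlier withdrawals
    masses = []
    for ev in events:
        if ev.withdrawn_volume > volume + 1e-12:
            raise ValueError(
                f"withdrawal of {ev.withdrawn_volume} mL at t={ev.time} h exceeds "
                f"vessel volume {volume} mL"
            )
        c = absorbance_to_concentration(ev.absorbance, proto, blank_threshold=blank_threshold)
        masses.append(concentration_to_mass(c, volume, proto.mw) + carried_ug)
        if ev.withdrawn_volume > 0:
            carried_ug += concentration_to_mass(c, ev.withdrawn_volume, proto.mw)
            if not ev.replaced:
                volume -= ev.withdrawn_volume
    return ReleaseCurve(
        times=np.asarray(times, dtype=float),
        values=np.asarray(masses, dtype=float),
        scale="mass_ug",
        label=label,
    )


def release_percent_of_loaded(
    curve: ReleaseCurve, aliquot_mass_mg: float, loading_ug_per_mg: float
) -> ReleaseCurve:
    """Convert a µg-scale curve to percent of the drug loaded in the aliquot.

    The loading basis (µg drug per mg particles) is explicit.  Values above
    100% are reported untruncated with a logged flag — measurement error can
    push apparent release past the loaded amount.
    """
    if curve.scale != "mass_ug":
        raise ValueError("expected a mass-scale (µg) curve")
    if aliquot_mass_mg <= 0 or loading_ug_per_mg <= 0:
        raise ValueError("aliquot mass and loading must be > 0")
    loaded_ug = aliquot_mass_mg * loading_ug_per_mg
    values = 100.0 * curve.values / loaded_ug
    if np.any(values > 100.0):
        logger.warning(
            "curve %r: cumulative release exceeds 100%% of loaded drug "
            "(max %.1f%%); reported untruncated", curve.label, values.max()
        )
    return ReleaseCurve(times=curve.times.copy(), values=values, scale="percent",
                        label=curve.label)
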