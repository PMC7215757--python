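"""Synthetic data with known ground truth: release curves, formulation sets,
and full UV–vis sampling protocols.

Every generator is a pure function of its inputs and seed, so pipeline stages
can be tested round-trip against exact ground truth.  Defaults mimic a
72-hour microparticle dissolution study: sampling at {1, 2, 4, 8, 24, 48, 72}
hours spans the burst and plateau phases, parameter ranges bracket both
slow-releasing (lower asymptote, small rate constant) and fast-releasing
(asymptote near or slightly above 100%, larger rate constant) formulations,
and proportional noise of 5% reflects typical replicate scatter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .kinetics import FirstOrderParams, ReleaseCurve, eval_first_order
from .mixtures import Formulation
from .quantify import OpticalProtocol, SamplingEvent

__all__ = [
    "NoiseModel",
    "DEFAULT_TIMES_H",
    "generate_release_curve",
    "generate_formulation_set",
    "simulate_sampling_protocol",
]

#: Default sampling schedule (hours) of a release study.
DEFAULT_TIMES_H = (1.0, 2.0, 4.0, 8.0, 24.0, 48.0, 72.0)

_NOISE_KINDS = ("none", "additive_gaussian", "proportional_gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise applied to generated curves.

    kind : 'none', 'additive_gaussian' (sigma in curve units) or
        'proportional_gaussian' (sigma as a fraction of the signal, e.g. 0.05).
    seed : RNG seed; the same (inputs, seed) always produce the same data.
    """

    kind: str = "none"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise ValueError(f"noise kind must be one of {_NOISE_KINDS}, got {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def generate_release_curve(
    params: FirstOrderParams,
    times: Sequence[float],
    noise: NoiseModel = NoiseModel(),
    *,
    scale: str = "percent",
    label: str = "",
) -> ReleaseCurve:
    """First-order curve a(1 - e^(-bt)) sampled at ``times``, plus noise.

    Values are clamped at 0 from below, and a t=0 point is pinned to 0 so the
    model's initial condition survives additive noise.
    """
    t = np.asarray(times, dtype=float)
    clean = eval_first_order(params, t)
    clean = np.atleast_1d(clean)
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "none" or noise.sigma == 0:
        values = clean.copy()
    elif noise.kind == "additive_gaussian":
        values = clean + rng.normal(0.0, noise.sigma, size=clean.shape)
    else:
        values = clean * (1.0 + rng.normal(0.0, noise.sigma, size=clean.shape))
    values = np.clip(values, 0.0, None)
    values[t == 0] = 0.0
    return ReleaseCurve(times=t, values=values, scale=scale, label=label)


def generate_formulation_set(
    n: int,
    *,
    a_range: Tuple[float, float] = (60.0, 110.0),
    b_range: Tuple[float, float] = (0.02, 0.4),
    loading_range: Optional[Tuple[float, float]] = (5.0, 60.0),
    seed: int = 0,
) -> list:
    """``n`` reproducible formulations with parameters drawn uniformly from
    the given ranges (collapsed ranges yield identical parameters).

    Defaults span slow-releasing and fast-releasing regimes so that blends
    exhibit intermediate profiles.
    """
    if n < 1:
        raise ValueError("need n >= 1 formulations")
    for name, rng_ in (("a_range", a_range), ("b_range", b_range)):
        if rng_[1] < rng_[0] or rng_[0] <= 0:
            raise ValueError(f"invalid {name}: {rng_}")
    if loading_range is not None and (loading_range[1] < loading_range[0] or loading_range[0] <= 0):
        raise ValueError(f"invalid loading_range: {loading_range}")

    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        a = float(rng.uniform(*a_range))
        b = float(rng.uniform(*b_range))
        loading = float(rng.uniform(*loading_range)) if loading_range is not None else None
        out.append(
            Formulation(name=f"F{i + 1}", params=FirstOrderParams(a=a, b=b), loading=loading)
        )
    return out


def simulate_sampling_protocol(
    params_mass: FirstOrderParams,
    schedule: Sequence[float],
    proto: OpticalProtocol,
    *,
    initial_volume_ml: float = 1.5,
    withdrawn_ml: float = 1.0,
    replaced: bool = True,
) -> Tuple[list, np.ndarray]:
    """Forward-simulate a dissolution sampling protocol.

    ``params_mass`` is the true dissolution curve in µg (total drug that has
    left the particles).  At each scheduled time the newly released drug is
    added to the vessel, the absorbance an instrument would read on the
    (possibly diluted) supernatant is computed through Beer–Lambert, and
    ``withdrawn_ml`` of medium is removed — with or without replacement by
    fresh medium.

    Returns the ordered ``SamplingEvent`` list and the ground-truth cumulative
    dissolved mass (µg) at each scheduled time, for oracle tests of
    :func:`releasekit.quantify.cumulative_release`.
    """
    sched = np.asarray(schedule, dtype=float)
    if len(sched) and not np.all(np.diff(sched) > 0):
        raise ValueError("schedule times must be strictly increasing")
    if withdrawn_ml < 0 or withdrawn_ml > initial_volume_ml:
        raise ValueError("withdrawn volume must lie within the vessel volume")

    volume = initial_volume_ml
    vessel_ug = 0.0
    prev_true = 0.0
    events = []
    truth = []
    for t in sched:
        true_cum = float(eval_first_order(params_mass, t))
        vessel_ug += true_cum - prev_true
        prev_true = true_cum
        if withdrawn_ml > volume + 1e-12:
            raise ValueError(
                f"withdrawal of {withdrawn_ml} mL at t={t} h exceeds vessel volume {volume} mL"
            )
        # vessel molar concentration -> absorbance of the diluted sample
        c_molar = (vessel_ug / 1e6) / proto.mw / (volume / 1000.0)
        absorbance = c_molar * proto.epsilon * proto.path_cm / proto.dilution_factor
        events.append(
            SamplingEvent(time=float(t), absorbance=absorbance,
                          withdrawn_volume=withdrawn_ml, replaced=replaced)
        )
        truth.append(true_cum)
        if withdrawn_ml > 0:
            vessel_ug -= vessel_ug * withdrawn_ml / volume
            if not replaced:
                volume -= withdrawn_ml
    return events, np.asarray(truth)
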