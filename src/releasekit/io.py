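"""File I/O, run configuration, and the fit → predict pipeline.

Release curves travel as CSV with columns ``time_h,value``; sampling events
as CSV with columns ``time_h,absorbance,withdrawn_ml,replaced``; formulation
registries and run configs as YAML (or JSON, which YAML subsumes).  Machine
reports are JSON at full double precision; human summaries round to 4
significant figures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .kinetics import (
    FirstOrderParams,
    FitResult,
    ReleaseCurve,
    fit_first_order,
)
from .mixtures import Formulation, MixtureSpec, predict_mixture_mass, predict_mixture_percent

__all__ = [
    "read_release_csv",
    "write_release_csv",
    "read_events_csv",
    "read_formulation_registry",
    "RunConfig",
    "run_pipeline",
    "sig4",
]

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """A delimited input file violates its expected schema."""


def sig4(x: float) -> str:
    """Render a number at 4 significant figures for human reports."""
    return f"{x:.4g}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def read_release_csv(path, *, scale: str = "percent", label: str = "") -> ReleaseCurve:
    """Read a ``time_h,value`` CSV into a validated, time-sorted ReleaseCurve.

    Raises :class:`ParseError` naming the offending line for missing columns,
    non-numeric cells, or duplicate times.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = {"time_h", "value"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("time_h", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((coerced.isna()).idxmax()) + 2  # header is line 1
        else:
            row = None
        if row is not None:
            raise ParseError(f"{path}: non-numeric or empty {col!r} at line {row}")
        df[col] = coerced
    dup = df["time_h"].duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise ParseError(f"{path}: duplicate time at line {row}")
    df = df.sort_values("time_h", kind="mergesort")
    return ReleaseCurve(
        times=df["time_h"].to_numpy(),
        values=df["value"].to_numpy(),
        scale=scale,
        label=label or path.stem,
    )


def write_release_csv(curve: ReleaseCurve, path) -> None:
    """Write a ReleaseCurve as ``time_h,value`` CSV at full double precision."""
    df = pd.DataFrame({"time_h": curve.times, "value": curve.values})
    df.to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path):
    """Read sampling events (``time_h,absorbance,withdrawn_ml,replaced``)."""
    from .quantify import SamplingEvent

    path = Path(path)
    df = pd.read_csv(path)
    missing = {"time_h", "absorbance", "withdrawn_ml", "replaced"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    events = []
    for i, row in df.iterrows():
        try:
            events.append(
                SamplingEvent(
                    time=float(row["time_h"]),
                    absorbance=float(row["absorbance"]),
                    withdrawn_volume=float(row["withdrawn_ml"]),
                    replaced=bool(int(row["replaced"])),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad event at line {i + 2}: {exc}") from exc
    return events


def read_formulation_registry(path) -> dict:
    """Read a YAML/JSON registry: list of {name, a, b, scale, loading, ee_percent}.

    Returns an ordered name → :class:`Formulation` mapping.
    """
    path = Path(path)
    entries = yaml.safe_load(path.read_text())
    if not isinstance(entries, list):
        raise ParseError(f"{path}: registry must be a list of formulation entries")
    registry: dict = {}
    for i, e in enumerate(entries):
        try:
            form = Formulation(
                name=str(e["name"]),
                params=FirstOrderParams(a=float(e["a"]), b=float(e["b"])),
                scale=e.get("scale", "percent"),
                loading=float(e["loading"]) if e.get("loading") is not None else None,
                ee_percent=float(e["ee_percent"]) if e.get("ee_percent") is not None else None,
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: entry {i}: {exc}") from exc
        if form.name in registry:
            raise ParseError(f"{path}: duplicate formulation name {form.name!r}")
        registry[form.name] = form
    return registry


@dataclass
class RunConfig:
    """Configuration for a full fit → predict run.

    curves : name → CSV path of observed release curves to fit.
    registry : optional path to a pre-parameterized formulation registry
        (entries are merged with, and overridden by, freshly fitted ones).
    mixtures : list of {name, weights: {component: percent}, times: [h], and
        optional total_mp_mass for µg-scale prediction}.
    """

    curves: dict = field(default_factory=dict)
    registry: Optional[str] = None
    mixtures: list = field(default_factory=list)
    scale: str = "percent"
    output_dir: str = "releasekit_out"
    seed: int = 0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {"curves", "registry", "mixtures", "scale", "output_dir", "seed"}
        if unknown:
            raise ParseError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.scale not in ("percent", "mass_ug"):
            raise ValueError(f"scale must be 'percent' or 'mass_ug', got {self.scale!r}")
        for name, p in self.curves.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"curve {name!r}: no such file {p}")
        if self.registry is not None and not Path(self.registry).exists():
            raise FileNotFoundError(f"registry: no such file {self.registry}")


def _fit_table(fits: dict) -> pd.DataFrame:
    rows = [
        {
            "formulation": name,
            "a": fr.params.a,
            "b": fr.params.b,
            "r2": fr.r2,
            "r2_adj": fr.r2_adj,
            "rss": fr.rss,
            "n_obs": fr.n_obs,
            "converged": fr.converged,
        }
        for name, fr in fits.items()
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Fit every configured curve, evaluate every requested mixture, and write
    machine- (JSON/CSV) and human-readable outputs under ``config.output_dir``.

    Deterministic for fixed inputs and seed: reruns produce byte-identical
    machine outputs.  Any stage failure is re-raised with the stage name.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    provenance = {
        "seed": config.seed,
        "scale": config.scale,
        "input_sha256": {
            name: _sha256(p) for name, p in sorted(config.curves.items())
        },
    }
    if config.registry:
        provenance["registry_sha256"] = _sha256(config.registry)
    logger.info("run: %s", json.dumps(provenance, sort_keys=True))

    registry: dict = {}
    if config.registry:
        try:
            registry.update(read_formulation_registry(config.registry))
        except Exception as exc:
            raise RuntimeError(f"stage 'registry': {exc}") from exc

    fits: dict = {}
    for name, path in config.curves.items():
        try:
            curve = read_release_csv(path, scale=config.scale, label=name)
            fr = fit_first_order(curve)
            fits[name] = fr
            registry[name] = Formulation(name=name, params=fr.params, scale=config.scale)
        except Exception as exc:
            raise RuntimeError(f"stage 'fit' ({name}): {exc}") from exc

    predictions = []
    for req in config.mixtures:
        try:
            comps = tuple(registry[n] for n in req["weights"])
            weights = tuple(float(w) for w in req["weights"].values())
            mix = MixtureSpec(components=comps, weights=weights)
            times = np.asarray(req["times"], dtype=float)
            if req.get("total_mp_mass") is not None or any(
                c.scale == "mass_ug" for c in comps
            ):
                values = predict_mixture_mass(mix, times, total_mp_mass=req.get("total_mp_mass"))
                pred_scale = "mass_ug"
            else:
                values = predict_mixture_percent(mix, times)
                pred_scale = "percent"
            predictions.append(
                {
                    "name": req.get("name", "+".join(req["weights"])),
                    "weights": dict(zip(req["weights"], weights)),
                    "scale": pred_scale,
                    "times_h": times.tolist(),
                    "predicted": np.atleast_1d(values).tolist(),
                }
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'predict' ({req.get('name', '?')}): {exc}") from exc

    report = {
        "provenance": provenance,
        "fits": {
            name: {
                "a": fr.params.a,
                "b": fr.params.b,
                "r2": fr.r2,
                "r2_adj": fr.r2_adj,
                "rss": fr.rss,
                "n_obs": fr.n_obs,
                "converged": fr.converged,
                "n_iter": fr.n_iter,
            }
            for name, fr in fits.items()
        },
        "predictions": predictions,
    }
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=1, allow_nan=True) + "\n"
    )
    if fits:
        _fit_table(fits).to_csv(outdir / "fits.csv", index=False, float_format="%.17g")
    if predictions:
        rows = [
            {"mixture": p["name"], "time_h": t, "scale": p["scale"], "predicted": v}
            for p in predictions
            for t, v in zip(p["times_h"], p["predicted"])
        ]
        pd.DataFrame(rows).to_csv(outdir / "predictions.csv", index=False, float_format="%.17g")

    # human-readable summary at 4 significant figures
    lines = []
    for name, fr in fits.items():
        lines.append(
            f"{name}: a={sig4(fr.params.a)} b={sig4(fr.params.b)} /h "
            f"R2={sig4(fr.r2)} adjR2={sig4(fr.r2_adj)}"
        )
    for p in predictions:
        w = ", ".join(f"{k}:{sig4(v)}" for k, v in p["weights"].items())
        vals = ", ".join(
            f"t={sig4(t)}h -> {sig4(v)}" for t, v in zip(p["times_h"], p["predicted"])
        )
        unit = "%" if p["scale"] == "percent" else " µg"
        lines.append(f"mixture {p['name']} ({w}): {vals}{unit}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report
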