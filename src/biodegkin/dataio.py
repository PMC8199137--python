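"""Reading, writing and synthesising weight-loss series.

CSV dialect: two columns with header ``t,w``, '#'-prefixed comment lines,
'.' decimal separator, times in days and weight loss in %.  Reading is
strict — rows out of time order, duplicate times, non-numeric cells or a
missing header are parse errors naming the offending line, never silently
repaired.

Three reference datasets ship with the package (under ``datasets/``), each
a measured weight-loss table together with the reference parameters of the
double-exponential dead-time model fitted to it and, where available, the
published indicator panel:

* ``bioreactor_wastewater`` — glycopolymer in a bioreactor fed with
  beer-fabrication wastewater (17 points).
* ``bioreactor_bega`` — glycopolymer in a bioreactor fed with Bega River
  water (16 points).
* ``gordon_tropical`` — cornstarch/PHBV blend in tropical coastal water
  (9 points, two of them flagged as visually interpolated).

:func:`generate_synthetic` draws noiseless or Gaussian-noise-corrupted
realisations of any model on an arbitrary sampling schedule, with a seed
for exact reproducibility; it is the workhorse behind the parameter
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import numpy as np

from .indicators import GoodnessOfFit
from .models import DoubleExpDelayParams, get_model
from .series import WeightLossSeries

__all__ = [
    "SeriesParseError",
    "SyntheticSpec",
    "Fixture",
    "FIXTURE_NAMES",
    "BACTERIAL_GROWTH_PARAMS",
    "read_series",
    "write_series",
    "load_fixture",
    "generate_synthetic",
]

FIXTURE_NAMES = ("bioreactor_wastewater", "bioreactor_bega", "gordon_tropical")

#: Reference double-exponential parameters for a Salmonella spp. growth
#: curve (log CFU/mL in tryptic soy broth at 30 degC), with the baseline
#: offset w0 = log b(0) = 2.8.  The underlying time series is not bundled;
#: these parameters exercise the nonzero-baseline form of the model.
BACTERIAL_GROWTH_PARAMS = DoubleExpDelayParams(
    w1_inf=1.2596, T1=8.1116, tau=7.4524, w2_inf=4.6819, T2=6.7336, w0=2.8
)


class SeriesParseError(ValueError):
    """A CSV series file violates the expected dialect; names the line."""


def read_series(path, label: Optional[str] = None) -> WeightLossSeries:
    """Read a two-column ``t,w`` CSV file into a validated series."""
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                cols = [c.strip().lower() for c in line.split(",")]
                if cols[:2] != ["t", "w"]:
                    raise SeriesParseError(
                        f"{path}:{lineno}: expected header 't,w', got {line!r}"
                    )
                header_seen = True
                continue
            cells = line.split(",")
            if len(cells) < 2:
                raise SeriesParseError(
                    f"{path}:{lineno}: expected two comma-separated columns"
                )
            try:
                t = float(cells[0])
                w = float(cells[1])
            except ValueError:
                raise SeriesParseError(
                    f"{path}:{lineno}: non-numeric cell in {line!r}"
                ) from None
            if times:
                if t == times[-1]:
                    raise SeriesParseError(
                        f"{path}:{lineno}: duplicate time t = {t}"
                    )
                if t < times[-1]:
                    raise SeriesParseError(
                        f"{path}:{lineno}: times out of order "
                        f"({t} after {times[-1]})"
                    )
            times.append(t)
            values.append(w)
    if not header_seen:
        raise SeriesParseError(f"{path}: missing 't,w' header")
    if len(times) < 2:
        raise SeriesParseError(
            f"{path}: data section has {len(times)} row(s); need at least 2"
        )
    return WeightLossSeries(
        np.array(times), np.array(values),
        label=label if label is not None else str(path),
    )


def write_series(series: WeightLossSeries, path, comments: Sequence[str] = ()) -> None:
    """Write a series as ``t,w`` CSV at 6 significant digits."""
    with open(path, "w") as fh:
        if series.label:
            fh.write(f"# label: {series.label}\n")
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("t,w\n")
        for t, w in zip(series.times, series.values):
            fh.write(f"{t:.6g},{w:.6g}\n")


@dataclass(frozen=True)
class Fixture:
    """A bundled reference dataset.

    Attributes
    ----------
    series : WeightLossSeries
        The measured series exactly as published (interpolated points
        flagged where applicable).
    series_corrected : WeightLossSeries or None
        The measured series with known typesetting defects repaired,
        where any exist (see ``notes``); this is the series consistent
        with the published residual row and fitted parameters.
    reference_params : DoubleExpDelayParams
        Published fitted parameters of the double-exponential model.
    initial_guess : DoubleExpDelayParams or None
        The published hand-derived starting vector, where one was stated.
    reference_cw, reference_dw : ndarray or None
        Published model values and residuals at the sample times
        (``*_corrected`` variants fix a known typesetting duplication).
    reference_panel : GoodnessOfFit or None
        Published indicator panel, where it is reproducible.
    """

    name: str
    series: WeightLossSeries
    series_corrected: Optional[WeightLossSeries]
    reference_params: DoubleExpDelayParams
    initial_guess: Optional[DoubleExpDelayParams]
    reference_cw: Optional[np.ndarray]
    reference_dw: Optional[np.ndarray]
    reference_cw_corrected: Optional[np.ndarray]
    reference_dw_corrected: Optional[np.ndarray]
    reference_panel: Optional[GoodnessOfFit]
    notes: str = ""


def _opt_array(x):
    return None if x is None else np.asarray(x, dtype=float)


def load_fixture(name: str) -> Fixture:
    """Load a bundled reference dataset by name (see :data:`FIXTURE_NAMES`)."""
    if name not in FIXTURE_NAMES:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {list(FIXTURE_NAMES)}"
        )
    ref = resources.files("biodegkin.datasets").joinpath(f"{name}.json")
    data = json.loads(ref.read_text())
    series = WeightLossSeries(
        np.array(data["times"], dtype=float),
        np.array(data["values"], dtype=float),
        label=data["name"],
        interpolated=np.array(data["interpolated"], dtype=bool),
    )
    panel = None
    if data.get("reference_panel"):
        p = data["reference_panel"]
        panel = GoodnessOfFit(rmse=p["rmse"], mse=p["mse"], r2=p["r2"],
                              r=p["r"], rae=p["rae"], n=len(series))
    vp = data.get("initial_guess")
    init = None
    if vp is not None:
        init = DoubleExpDelayParams(w1_inf=vp[0], T1=vp[1], tau=vp[2],
                                    w2_inf=vp[3], T2=vp[4])
    corrected = None
    if data.get("values_corrected") is not None:
        corrected = WeightLossSeries(
            np.array(data["times"], dtype=float),
            np.array(data["values_corrected"], dtype=float),
            label=data["name"] + ":corrected",
            interpolated=np.array(data["interpolated"], dtype=bool),
        )
    return Fixture(
        name=data["name"],
        series=series,
        series_corrected=corrected,
        reference_params=DoubleExpDelayParams.from_dict(
            data["reference_params"]),
        initial_guess=init,
        reference_cw=_opt_array(data.get("reference_cw")),
        reference_dw=_opt_array(data.get("reference_dw")),
        reference_cw_corrected=_opt_array(data.get("reference_cw_corrected")),
        reference_dw_corrected=_opt_array(data.get("reference_dw_corrected")),
        reference_panel=panel,
        notes=data.get("notes", ""),
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic weight-loss series.

    ``values = model(times; true_params) + eps`` with
    ``eps ~ Normal(0, noise_sd^2)`` drawn from a generator seeded with
    ``seed``; the noise is additive and untruncated, so high-noise series
    may dip below zero near t = 0 — fitting must tolerate that.
    """

    model_name: str
    true_params: object
    times: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "times", t)


def generate_synthetic(spec: SyntheticSpec) -> WeightLossSeries:
    """Draw one realisation of a synthetic series from its spec."""
    model = get_model(spec.model_name)
    params = spec.true_params
    if isinstance(params, dict):
        params = model.params_cls.from_dict(params)
    if not isinstance(params, model.params_cls):
        raise TypeError(
            f"true_params must be {model.params_cls.__name__} for model "
            f"{spec.model_name!r}"
        )
    clean = np.asarray(model.evaluate(params, spec.times), dtype=float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        clean = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    return WeightLossSeries(
        spec.times, clean,
        label=f"synthetic:{spec.model_name}:seed={spec.seed}",
    )
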