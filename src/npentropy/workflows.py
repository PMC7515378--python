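"""Drivers: sliding-window profiles, parameter sweeps and file I/O.

These are the user-facing entry points that iterate the entropies over
windows of one signal or over freshly generated signals on a parameter
grid. Every result echoes the configuration it was computed with,
because all the entropies depend on it (the NPE in particular on the
weight tolerance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import dynamics
from .baselines import ipe, pe, wpe
from .embedding import as_signal
from .npe import DEFAULT_ERROR, npe_value

__all__ = [
    "compute_entropy",
    "sliding_profile",
    "sweep_1d",
    "sweep_2d",
    "read_signal",
    "write_results",
    "WindowProfile",
    "SweepResult",
    "METHODS",
]

METHODS = ("pe", "wpe", "ipe", "npe")

#: Default quantization levels for IPE when unspecified.
DEFAULT_L = 4


def compute_entropy(x, method: str, d: int, error: float = None, L: int = None) -> float:
    """Dispatch one entropy computation by method tag."""
    method = method.lower()
    if method == "pe":
        return pe(x, d)
    if method == "wpe":
        return wpe(x, d)
    if method == "ipe":
        return ipe(x, d, DEFAULT_L if L is None else L)
    if method == "npe":
        return npe_value(x, d, DEFAULT_ERROR if error is None else error).value
    raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")


@dataclass(frozen=True)
class WindowProfile:
    """Entropy values on consecutive sliding windows of one signal."""

    method: str
    window_length: int
    step: int
    offsets: np.ndarray  # 1-based window start indices
    values: np.ndarray
    config: dict = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return len(self.values)

    def to_dict(self) -> dict:
        return {
            "kind": "window_profile",
            "method": self.method,
            "window_length": self.window_length,
            "step": self.step,
            "offsets": [int(o) for o in self.offsets],
            "values": [float(v) for v in self.values],
            "config": dict(self.config),
        }


def sliding_profile(
    x,
    method: str,
    window_length: int,
    step: int,
    d: int,
    error: float = None,
    L: int = None,
) -> WindowProfile:
    """Entropy computed independently on each sliding window.

    Windows start at samples 1, 1+step, 1+2*step, ... and must fit
    entirely inside the signal, so the count is
    floor((N - window_length)/step) + 1. NPE networks are built per
    window; no connections cross window boundaries.
    """
    x = as_signal(x)
    if step < 1:
        raise ValueError("step must be >= 1")
    if window_length < d + 1:
        raise ValueError(f"window_length={window_length} must be >= d+1={d + 1}")
    if x.size < window_length:
        raise ValueError(f"window_length={window_length} exceeds signal length {x.size}")
    starts = np.arange(0, x.size - window_length + 1, step)
    values = np.array(
        [compute_entropy(x[s : s + window_length], method, d, error=error, L=L) for s in starts]
    )
    return WindowProfile(
        method=method,
        window_length=window_length,
        step=step,
        offsets=starts + 1,
        values=values,
        config={"d": d, "error": error, "L": L},
    )


@dataclass(frozen=True)
class SweepResult:
    """Entropy values over a 1-D parameter axis or 2-D parameter grid.

    ``values`` has shape (len(axis),) for 1-D sweeps and
    (len(axis_x), len(axis_y)) for 2-D sweeps; cells whose signal
    generation or entropy computation failed (e.g. diverged
    trajectories) hold NaN.
    """

    method: str
    generator: str
    axes: dict  # parameter name -> grid values
    values: np.ndarray
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kind": "sweep",
            "method": self.method,
            "generator": self.generator,
            "axes": {k: [float(v) for v in vals] for k, vals in self.axes.items()},
            "values": self.values.tolist(),
            "config": dict(self.config),
        }


_GENERATORS = {
    "periodic": dynamics.periodic_signal,
    "random": dynamics.uniform_random_signal,
    "logistic": dynamics.logistic_series,
    "simplified_lorenz": dynamics.simplified_lorenz_series,
    "fractional_henon": dynamics.fractional_henon_series,
}


def _resolve_generator(generator: str):
    try:
        return _GENERATORS[generator]
    except KeyError:
        raise ValueError(
            f"unknown generator {generator!r}; choose one of {sorted(_GENERATORS)}"
        ) from None


def grid_values(start: float, stop: float, step: float = None, n_points: int = None) -> np.ndarray:
    """Inclusive-endpoint parameter grid from a step size or point count."""
    if stop < start:
        raise ValueError("stop must be >= start")
    if n_points is not None:
        if n_points < 1:
            raise ValueError("n_points must be >= 1")
        return np.linspace(start, stop, n_points)
    if step is None or step <= 0:
        raise ValueError("provide a positive step or an explicit n_points")
    count = int(math.floor((stop - start) / step + 1e-9)) + 1
    return start + step * np.arange(count)


def sweep_1d(
    generator: str,
    param: str,
    start: float,
    stop: float,
    step: float = None,
    n_points: int = None,
    method: str = "npe",
    d: int = 5,
    error: float = None,
    L: int = None,
    n: int = 1000,
    **gen_kwargs,
) -> SweepResult:
    """Entropy along a 1-D parameter grid of a signal generator.

    A fresh series of length ``n`` is generated at every grid value;
    grid endpoints are inclusive. Failed cells become NaN rather than
    aborting the sweep.
    """
    fn = _resolve_generator(generator)
    axis = grid_values(start, stop, step=step, n_points=n_points)
    values = np.empty(axis.size)
    for k, val in enumerate(axis):
        params = dict(gen_kwargs)
        params[param] = float(val)
        try:
            values[k] = compute_entropy(fn(n=n, **params), method, d, error=error, L=L)
        except (ValueError, FloatingPointError, OverflowError):
            values[k] = np.nan
    return SweepResult(
        method=method,
        generator=generator,
        axes={param: axis},
        values=values,
        config={"d": d, "error": error, "L": L, "n": n, **gen_kwargs},
    )


def sweep_2d(
    generator: str,
    param_x: str,
    x_range: tuple,
    param_y: str,
    y_range: tuple,
    method: str = "npe",
    d: int = 5,
    error: float = None,
    L: int = None,
    n: int = 1000,
    **gen_kwargs,
) -> SweepResult:
    """Entropy over a 2-D parameter plane.

    ``x_range``/``y_range`` are (start, stop, step) or
    (start, stop, None, n_points). values[i, j] corresponds to
    (axis_x[i], axis_y[j]); failed cells are NaN.
    """
    fn = _resolve_generator(generator)
    ax = grid_values(*x_range)
    ay = grid_values(*y_range)
    values = np.empty((ax.size, ay.size))
    for i, xv in enumerate(ax):
        for j, yv in enumerate(ay):
            params = dict(gen_kwargs)
            params[param_x] = float(xv)
            params[param_y] = float(yv)
            try:
                values[i, j] = compute_entropy(
                    fn(n=n, **params), method, d, error=error, L=L
                )
            except (ValueError, FloatingPointError, OverflowError):
                values[i, j] = np.nan
    return SweepResult(
        method=method,
        generator=generator,
        axes={param_x: ax, param_y: ay},
        values=values,
        config={"d": d, "error": error, "L": L, "n": n, **gen_kwargs},
    )


def read_signal(path, format: str = None, column: int = 1, delimiter: str = ",") -> np.ndarray:
    """Read a univariate signal from single-column ASCII or CSV text.

    Lines starting with '#' and blank lines are skipped. For CSV,
    ``column`` selects the 1-based column. The single-column ASCII
    dialect (one sample per line) matches common EEG archive exports.
    """
    if format is None:
        format = "csv" if str(path).lower().endswith(".csv") else "ascii"
    samples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            if format == "csv":
                fields = text.split(delimiter)
                if column < 1 or column > len(fields):
                    raise ValueError(f"line {lineno}: column {column} out of range")
                text = fields[column - 1].strip()
            try:
                samples.append(float(text))
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric value {text!r}") from None
    if not samples:
        raise ValueError(f"no data found in {path}")
    return as_signal(samples)


def write_signal(x, path, header: str = None) -> None:
    """Write a signal as single-column ASCII with a '#' comment header."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for v in as_signal(x):
            fh.write(f"{v:.12g}\n")


def _result_dict(result) -> dict:
    if hasattr(result, "to_dict"):
        return result.to_dict()
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def write_results(result, path, format: str = "tsv") -> None:
    """Write a WindowProfile, SweepResult or NpeResult to disk.

    TSV output carries the full configuration in '#' comment lines;
    JSON output is the ``to_dict()`` structure and round-trips with
    ``json.load``.
    """
    payload = _result_dict(result)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
        return
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; choose 'tsv' or 'json'")
    with open(path, "w") as fh:
        kind = payload.get("kind", payload.get("method", "result"))
        config = {
            k: v for k, v in payload.items() if not isinstance(v, (list, dict))
        }
        config.update(payload.get("config", {}))
        echo = "\t".join(f"{k}={v}" for k, v in config.items() if v is not None)
        fh.write(f"# {kind}\t{echo}\n")
        if payload.get("kind") == "window_profile":
            fh.write("offset\tvalue\n")
            for off, val in zip(payload["offsets"], payload["values"]):
                fh.write(f"{off}\t{val:.10g}\n")
        elif payload.get("kind") == "sweep":
            axes = payload["axes"]
            names = list(axes)
            if len(names) == 1:
                fh.write(f"{names[0]}\tvalue\n")
                for v, val in zip(axes[names[0]], payload["values"]):
                    fh.write(f"{v:.10g}\t{val:.10g}\n")
            else:
                ay = axes[names[1]]
                fh.write(f"{names[0]}\\{names[1]}\t" + "\t".join(f"{v:.10g}" for v in ay) + "\n")
                for v, row in zip(axes[names[0]], payload["values"]):
                    fh.write(f"{v:.10g}\t" + "\t".join(f"{c:.10g}" for c in row) + "\n")
        else:  # single-value result (e.g. NPE)
            fh.write("value\n")
            fh.write(f"{payload['value']:.10g}\n")
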