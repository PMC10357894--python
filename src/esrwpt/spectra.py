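"""Reading, validation and regularization of field-swept cw ESR spectra.

A cw ESR spectrometer records the field-modulated first derivative of the
microwave absorption against the swept magnetic field.  Everything downstream
(wavelet decomposition, peak analysis) assumes a uniformly sampled,
dyadic-length signal, which experimental sweeps rarely are; :func:`to_uniform`
bridges that gap with median-step resampling and symmetric padding to the next
power of two.

Field values and couplings are in gauss throughout.  Intensities are in
arbitrary units and are never normalized on read; normalization is an explicit
choice at the mixing stage (:mod:`esrwpt.mixtures`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "UniformSpectrum",
    "SpectrumError",
    "ParseError",
    "read_spectrum",
    "to_uniform",
    "strip_pads",
    "crop",
    "write_spectrum",
    "write_result",
    "read_result",
]

MIN_POINTS = 16


class SpectrumError(ValueError):
    """A spectrum failed validation."""


class ParseError(SpectrumError):
    """A spectrum file could not be parsed."""


@dataclass
class Spectrum:
    """A field-swept first-derivative cw ESR spectrum.

    Parameters
    ----------
    field
        Magnetic-field axis in gauss, strictly increasing, >= 16 points.
    intensity
        First-derivative absorption, arbitrary units, same length as `field`.
    mw_frequency_ghz
        Microwave frequency in GHz; required only when g values are extracted.
    label
        Free-text sample label.
    meta
        String-keyed metadata (temperature, modulation amplitude, source file,
        simulator ground truth, ...).
    """

    field: np.ndarray
    intensity: np.ndarray
    mw_frequency_ghz: float | None = None
    label: str = ""
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumError("field and intensity must be 1-D")
        if self.field.size != self.intensity.size:
            raise SpectrumError(
                f"field ({self.field.size}) and intensity "
                f"({self.intensity.size}) differ in length"
            )
        if self.field.size < MIN_POINTS:
            raise SpectrumError(
                f"spectrum has {self.field.size} points; at least "
                f"{MIN_POINTS} are required"
            )
        if not np.all(np.diff(self.field) > 0):
            raise SpectrumError("field axis must be strictly increasing")
        if self.mw_frequency_ghz is not None and not self.mw_frequency_ghz > 0:
            raise SpectrumError("mw_frequency_ghz must be positive")

    @property
    def n_points(self) -> int:
        return self.field.size

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.field.copy(),
            self.intensity.copy(),
            self.mw_frequency_ghz,
            self.label,
            dict(self.meta),
        )


@dataclass
class UniformSpectrum(Spectrum):
    """A spectrum resampled to a constant step and padded to 2**k points.

    ``field``/``intensity`` include the padding; ``original_range`` records
    the field interval covered by real (resampled) data and ``pad_left`` /
    ``pad_right`` how many samples were appended on each side.
    """

    step_gauss: float = 0.0
    pad_left: int = 0
    pad_right: int = 0
    original_range: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        super().__post_init__()
        steps = np.diff(self.field)
        if self.step_gauss <= 0:
            raise SpectrumError("step_gauss must be positive")
        if np.max(np.abs(steps - self.step_gauss)) > 1e-6 * self.step_gauss:
            raise SpectrumError("field axis is not uniform to 1e-6 relative")
        n = self.field.size
        if n & (n - 1):
            raise SpectrumError(f"length {n} is not a power of two")


def _parse_row(raw: str) -> tuple[float, float] | None:
    """Parse one data line; return None for comments/blank lines."""
    stripped = raw.strip()
    if not stripped or stripped[0] in "#;":
        return None
    parts = stripped.replace(",", " ").split()
    if len(parts) < 2:
        raise ValueError("expected two columns")
    return float(parts[0]), float(parts[1])


def read_spectrum(
    path: str | Path,
    mw_frequency_ghz: float | None = None,
    dialect: str = "auto",
    label: str | None = None,
) -> Spectrum:
    """Read a two-column (field [G], intensity) text or CSV spectrum.

    Comment lines starting with ``#`` or ``;`` and a ``field_g,intensity``
    CSV header are skipped.  A strictly decreasing field axis is reversed
    (both columns) and noted in ``meta['reversed']``.

    Raises
    ------
    ParseError
        Naming the offending line when a row is non-numeric.
    SpectrumError
        When the field axis is not monotone after reversal or the file has
        fewer than 16 points.
    """
    if dialect not in ("auto", "two_column_ascii", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such spectrum file: {path}")
    fields, intens = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not fields and raw.strip().lower().replace(" ", "") in (
                "field_g,intensity",
                "field_g\tintensity",
            ):
                continue
            try:
                row = _parse_row(raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: could not parse {raw.strip()!r} "
                    f"({exc})"
                ) from exc
            if row is not None:
                fields.append(row[0])
                intens.append(row[1])
    field = np.array(fields)
    intensity = np.array(intens)
    meta = {"source_file": str(path)}
    if field.size >= 2 and np.all(np.diff(field) < 0):
        field = field[::-1].copy()
        intensity = intensity[::-1].copy()
        meta["reversed"] = "true"
    return Spectrum(
        field,
        intensity,
        mw_frequency_ghz=mw_frequency_ghz,
        label=label if label is not None else path.stem,
        meta=meta,
    )


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as ``field_g,intensity`` CSV (full float precision)."""
    path = Path(path)
    with open(path, "w") as fh:
        if s.mw_frequency_ghz is not None:
            fh.write(f"# mw_frequency_ghz = {s.mw_frequency_ghz!r}\n")
        if s.label:
            fh.write(f"# label = {s.label}\n")
        fh.write("field_g,intensity\n")
        for b, y in zip(s.field, s.intensity):
            fh.write(f"{float(b)!r},{float(y)!r}\n")


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p *= 2
    return p


_PAD_MODES = {"symmetric": "symmetric", "zero": "constant", "edge": "edge"}


def to_uniform(s: Spectrum, pad_mode: str = "symmetric") -> UniformSpectrum:
    """Resample onto a uniform grid and pad to the next power of two.

    The step is the median of the input field steps; intensities are linearly
    interpolated.  Padding samples are split as evenly as possible between the
    two ends and recorded so that :func:`strip_pads` can undo them.  An
    already-uniform dyadic-length input passes through unchanged.
    """
    if pad_mode not in _PAD_MODES:
        raise ValueError(f"unknown pad_mode {pad_mode!r}")
    step = float(np.median(np.diff(s.field)))
    span = float(s.field[-1] - s.field[0])
    n = int(round(span / step)) + 1
    grid = s.field[0] + step * np.arange(n)
    # keep the grid inside the data range so no extrapolation occurs
    if grid[-1] > s.field[-1] + 1e-9 * step:
        n -= 1
        grid = grid[:n]
    y = np.interp(grid, s.field, s.intensity)
    p = _next_pow2(n)
    extra = p - n
    pad_left = extra // 2
    pad_right = extra - pad_left
    y_padded = np.pad(y, (pad_left, pad_right), mode=_PAD_MODES[pad_mode])
    full_field = grid[0] + step * (np.arange(p) - pad_left)
    return UniformSpectrum(
        field=full_field,
        intensity=y_padded,
        mw_frequency_ghz=s.mw_frequency_ghz,
        label=s.label,
        meta=dict(s.meta),
        step_gauss=step,
        pad_left=pad_left,
        pad_right=pad_right,
        original_range=(float(grid[0]), float(grid[-1])),
    )


def strip_pads(u: UniformSpectrum, signal: np.ndarray | None = None):
    """Return (field, values) restricted to the unpadded region of `u`.

    `signal` defaults to ``u.intensity`` but may be any full-length array
    aligned with ``u.field`` (e.g. a wavelet component reconstruction).
    """
    values = u.intensity if signal is None else np.asarray(signal)
    hi = u.field.size - u.pad_right
    return u.field[u.pad_left:hi], values[u.pad_left:hi]


def crop(s: Spectrum, lo: float, hi: float, min_points: int = MIN_POINTS) -> Spectrum:
    """Restrict a spectrum to the field interval [lo, hi] gauss."""
    if hi <= lo:
        raise ValueError("crop interval must have hi > lo")
    mask = (s.field >= lo) & (s.field <= hi)
    if int(mask.sum()) < min_points:
        raise SpectrumError(
            f"crop [{lo}, {hi}] G keeps {int(mask.sum())} points "
            f"(< {min_points})"
        )
    out = Spectrum(
        s.field[mask].copy(),
        s.intensity[mask].copy(),
        s.mw_frequency_ghz,
        s.label,
        dict(s.meta),
    )
    out.meta["crop"] = f"{lo}:{hi}"
    return out


# ---------------------------------------------------------------------------
# result serialization


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def _group_row(g, extra=None):
    row = {
        "n_lines": g.n_lines,
        "mean_spacing_g": g.mean_spacing,
        "spacing_cv": g.spacing_cv,
        "span_g": g.span,
        "center_g": g.center,
        "line_positions_g": ";".join(repr(float(x)) for x in g.line_positions),
    }
    if extra:
        row.update(extra)
    return row


def write_result(result, path: str | Path, format: str = "json") -> None:
    """Serialize a HyperfineResult or MixtureReport to JSON or CSV.

    JSON keeps the full nested structure (the authoritative round-trip
    format); CSV is a flat table with one row per multiplet group.
    """
    from .peaks import HyperfineResult  # local import: avoid cycle
    from .mixtures import MixtureReport

    path = Path(path)
    if format == "json":
        payload = _to_jsonable(result)
        payload["_kind"] = type(result).__name__
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return
    if format != "csv":
        raise ValueError(f"unknown format {format!r}")

    rows: list[dict] = []
    if isinstance(result, HyperfineResult):
        for g in result.groups:
            rows.append(
                _group_row(
                    g,
                    {
                        "A_fine_g": result.A_fine,
                        "A_cu_g": result.A_cu,
                        "g_value": result.g_value,
                        "region": result.region,
                    },
                )
            )
        if not rows:  # keep the scalar summary even with no groups
            rows = []
        header = [
            "n_lines", "mean_spacing_g", "spacing_cv", "span_g", "center_g",
            "line_positions_g", "A_fine_g", "A_cu_g", "g_value", "region",
        ]
    elif isinstance(result, MixtureReport):
        for g, label in result.groups:
            rows.append(
                _group_row(
                    g,
                    {
                        "assigned_component": label,
                        "window_lo_g": result.window[0],
                        "window_hi_g": result.window[1],
                        "minor_detected": result.minor_detected,
                        "minor_fraction": result.minor_fraction,
                    },
                )
            )
        header = [
            "n_lines", "mean_spacing_g", "spacing_cv", "span_g", "center_g",
            "line_positions_g", "assigned_component", "window_lo_g",
            "window_hi_g", "minor_detected", "minor_fraction",
        ]
    else:
        raise TypeError(f"cannot serialize {type(result).__name__}")
    df = pd.DataFrame(rows, columns=header)
    df.to_csv(path, index=False)


def read_result(path: str | Path):
    """Read back a JSON result written by :func:`write_result`."""
    from .peaks import HyperfineResult, MultipletGroup
    from .mixtures import MixtureReport

    with open(path) as fh:
        payload = json.load(fh)
    kind = payload.pop("_kind")

    def mk_group(d):
        return MultipletGroup(
            line_positions=np.array(d["line_positions"]),
            mean_spacing=d["mean_spacing"],
            spacing_cv=d["spacing_cv"],
            span=d["span"],
            center=d["center"],
            n_lines=d["n_lines"],
        )

    if kind == "HyperfineResult":
        payload["groups"] = [mk_group(d) for d in payload["groups"]]
        if payload.get("quartet_positions") is not None:
            payload["quartet_positions"] = [
                float(v) for v in payload["quartet_positions"]
            ]
        return HyperfineResult(**payload)
    if kind == "MixtureReport":
        payload["window"] = tuple(payload["window"])
        payload["groups"] = [
            (mk_group(d), label) for d, label in payload["groups"]
        ]
        return MixtureReport(**payload)
    raise ValueError(f"unknown result kind {kind!r}")
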