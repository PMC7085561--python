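"""Gravity-sensor time series: in-memory model plus CSV round-trip.

An Android gravity sensor emits a three-component vector (x, y, z) in m/s²
whose magnitude is nominally g ≈ 9.81 m/s²; the device orientation during an
exercise is read off the y component.  Traces are stored as a plain CSV with
columns ``t,x,y,z`` (seconds, m/s²) and optional ``#key=value`` metadata
comment lines.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import TraceOrderingError, TraceParseError, ValidationError

STANDARD_GRAVITY = 9.81
#: plausibility band for the gravity-vector magnitude (±10% around g);
#: samples outside it are flagged in metadata, never rejected — the fused
#: software sensor is noisy but a wildly wrong norm usually means a bad
#: mounting or a unit mix-up.
NORM_BAND = (8.8, 10.8)

CANONICAL_COLUMNS = ("t", "x", "y", "z")


@dataclass(frozen=True)
class GravitySample:
    """One timestamped gravity vector (seconds since trace start, m/s²)."""

    t: float
    gx: float
    gy: float
    gz: float

    @property
    def norm(self) -> float:
        return math.sqrt(self.gx**2 + self.gy**2 + self.gz**2)

    def is_physical(self) -> bool:
        lo, hi = NORM_BAND
        return lo <= self.norm <= hi


@dataclass
class GravityTrace:
    """Ordered gravity samples with nominal rate and free-form metadata.

    ``t`` and ``g`` are parallel arrays: ``t`` of shape (n,) strictly
    increasing, ``g`` of shape (n, 3) holding (gx, gy, gz) rows.
    ``sample_rate_hz`` is advisory metadata; algorithms use actual timestamps.
    """

    t: np.ndarray
    g: np.ndarray
    sample_rate_hz: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.t.ndim != 1 or self.g.shape != (self.t.size, 3):
            raise ValidationError(
                f"trace arrays malformed: t{self.t.shape}, g{self.g.shape}"
            )
        if self.t.size == 0:
            raise ValidationError("no samples")
        if not np.all(np.isfinite(self.t)) or self.t[0] < 0:
            raise ValidationError("timestamps must be finite and non-negative")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise TraceOrderingError("timestamps must be strictly increasing")
        if self.sample_rate_hz is not None and self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")

    def __len__(self) -> int:
        return self.t.size

    def __iter__(self) -> Iterator[GravitySample]:
        for ti, (gx, gy, gz) in zip(self.t, self.g):
            yield GravitySample(float(ti), float(gx), float(gy), float(gz))

    @property
    def samples(self) -> list[GravitySample]:
        return list(self)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def y(self) -> np.ndarray:
        """The y gravity component — the channel every detector operates on."""
        return self.g[:, 1]

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.g, axis=1)

    def flag_norm_outliers(self) -> int:
        """Record out-of-band |g| samples in ``meta``; returns the count."""
        lo, hi = NORM_BAND
        norms = self.norms()
        bad = np.flatnonzero((norms < lo) | (norms > hi))
        self.meta["norm_warnings"] = int(bad.size)
        if bad.size:
            self.meta["norm_warning_first_index"] = int(bad[0])
        return int(bad.size)

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[GravitySample],
        sample_rate_hz: float | None = None,
        meta: Mapping | None = None,
    ) -> "GravityTrace":
        if not samples:
            raise ValidationError("no samples")
        t = np.array([s.t for s in samples])
        g = np.array([[s.gx, s.gy, s.gz] for s in samples])
        return cls(t, g, sample_rate_hz, dict(meta or {}))


def read_trace(
    path: str | os.PathLike,
    columns: Sequence[str] = CANONICAL_COLUMNS,
) -> GravityTrace:
    """Read a trace CSV (``t,x,y,z`` header, ``#key=value`` meta lines).

    ``columns`` remaps the header: a 4-tuple naming the time and x/y/z axis
    columns as they appear in the file (device mountings differ, so an axis
    swap can be expressed here rather than by rewriting files).

    Raises :class:`TraceParseError` naming the offending line on malformed
    rows, :class:`TraceOrderingError` on non-monotone timestamps, and
    :class:`ValidationError` for an empty data section.  Out-of-band gravity
    norms are flagged in ``meta`` (see :data:`NORM_BAND`), not rejected.
    """
    if len(columns) != 4:
        raise ValidationError("columns must name (time, x, y, z)")
    meta: dict = {}
    data_lines: list[tuple[int, str]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            data_lines.append((lineno, line))
    if not data_lines:
        raise ValidationError("no samples")
    header_line = data_lines[0][1]
    header = next(csv.reader(io.StringIO(header_line)))
    header = [h.strip() for h in header]
    try:
        idx = [header.index(c) for c in columns]
    except ValueError as exc:
        raise TraceParseError(
            f"header {header!r} lacks required columns {tuple(columns)!r}"
        ) from exc
    rows = []
    for lineno, line in data_lines[1:]:
        fields = next(csv.reader(io.StringIO(line)))
        try:
            rows.append([float(fields[i]) for i in idx])
        except (ValueError, IndexError) as exc:
            raise TraceParseError(f"malformed row at line {lineno}: {line!r}") from exc
    if not rows:
        raise ValidationError("no samples")
    arr = np.asarray(rows, dtype=float)
    rate = float(meta["sample_rate_hz"]) if "sample_rate_hz" in meta else None
    trace = GravityTrace(arr[:, 0], arr[:, 1:4], sample_rate_hz=rate, meta=meta)
    trace.flag_norm_outliers()
    return trace


def write_trace(trace: GravityTrace, path: str | os.PathLike) -> str:
    """Write a trace as canonical CSV; round-trips to 6 decimal places."""
    if len(trace) == 0:  # pragma: no cover - constructor forbids empty traces
        raise ValidationError("no samples")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if trace.sample_rate_hz is not None:
            fh.write(f"#sample_rate_hz={trace.sample_rate_hz:g}\n")
        for key, value in trace.meta.items():
            if key == "sample_rate_hz":
                continue
            fh.write(f"#{key}={value}\n")
        fh.write(",".join(CANONICAL_COLUMNS) + "\n")
        for ti, (gx, gy, gz) in zip(trace.t, trace.g):
            fh.write(f"{ti:.6f},{gx:.6f},{gy:.6f},{gz:.6f}\n")
    return os.fspath(path)


def smooth(trace: GravityTrace, window: int) -> GravityTrace:
    """Centred moving average per axis; edges use shrunken windows.

    Length-preserving and linear; a window of 1 is the identity.  The
    shrunken-edge policy keeps the mean of each axis exact for signals that
    are constant near both ends (the plateau lead-in/out of every test item).
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if window == 1:
        return GravityTrace(
            trace.t.copy(), trace.g.copy(), trace.sample_rate_hz, dict(trace.meta)
        )
    kernel = np.ones(window)
    counts = np.convolve(np.ones(len(trace)), kernel, mode="same")
    smoothed = np.column_stack(
        [np.convolve(trace.g[:, k], kernel, mode="same") / counts for k in range(3)]
    )
    return GravityTrace(trace.t.copy(), smoothed, trace.sample_rate_hz, dict(trace.meta))


def smooth_channel(y: np.ndarray, window: int) -> np.ndarray:
    """Moving average of a single channel with the same edge policy as smooth."""
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be a positive odd integer, got {window}")
    if window == 1:
        return np.asarray(y, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    kernel = np.ones(window)
    counts = np.convolve(np.ones(y.size), kernel, mode="same")
    return np.convolve(y, kernel, mode="same") / counts
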