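"""Recording container and plain-CSV persistence.

A :class:`Recording` is the common in-memory form for every signal the
glove produces: finger bend angles (degrees), palm/finger contact force
(arbitrary force units) and triaxial acceleration (g).  On disk a
recording is a comma-separated file with ``#``-prefixed metadata lines
before the header row, so the files stay greppable and language-neutral.
Time is implicit: row ``i`` is sample ``i / fs`` seconds.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ACCEL_CHANNELS = ("ax", "ay", "az")
BEND_CHANNELS = ("thumb", "index", "middle", "ring", "little")
KINDS = ("bend", "pressure", "accel")

DEFAULT_ACCEL_RANGE_G = 4.0  # acquisition range of the IMU, +/- g
BEND_RANGE_DEG = (0.0, 180.0)


class RecordingError(ValueError):
    """Raised when a recording violates its structural invariants."""


@dataclass
class Recording:
    """A timestamped multichannel signal block with sampling metadata.

    Parameters
    ----------
    kind : {'bend', 'pressure', 'accel'}
        Signal family.  ``accel`` recordings must have exactly the three
        channels ``ax, ay, az`` and values within the acquisition range;
        ``bend`` recordings have the five finger channels with angles in
        [0, 180] degrees.
    channels : list of str
        Channel names, one per data column.
    data : ndarray of shape (n_samples, n_channels)
    fs : float
        Sampling frequency in Hz.
    units : str
        'degrees', 'force units' or 'g'.
    meta : dict
        Free-form key/value metadata (subject id, gesture name, label...).
    """

    kind: str
    channels: list[str]
    data: np.ndarray
    fs: float
    units: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = list(self.channels)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self, accel_range: float = DEFAULT_ACCEL_RANGE_G) -> None:
        if self.kind not in KINDS:
            raise RecordingError(f"unknown recording kind {self.kind!r}")
        if self.data.ndim != 2:
            raise RecordingError("data must be a 2-D (n_samples, n_channels) array")
        n_samples, n_channels = self.data.shape
        if n_samples < 1:
            raise RecordingError("recording must contain at least one sample")
        if n_channels != len(self.channels) or n_channels == 0:
            raise RecordingError(
                f"{n_channels} data columns but {len(self.channels)} channel names"
            )
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise RecordingError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise RecordingError("recording contains non-finite samples")
        if self.kind == "accel":
            if tuple(self.channels) != ACCEL_CHANNELS:
                raise RecordingError(
                    f"accel recordings need channels {ACCEL_CHANNELS}, got {tuple(self.channels)}"
                )
            amax = float(np.abs(self.data).max())
            if amax > accel_range:
                raise RecordingError(
                    f"acceleration {amax:.3f} g exceeds acquisition range +/-{accel_range} g"
                )
        if self.kind == "bend":
            if len(self.channels) != 5:
                raise RecordingError(
                    f"bend recordings need 5 finger channels, got {len(self.channels)}"
                )
            lo, hi = BEND_RANGE_DEG
            if self.data.min() < lo or self.data.max() > hi:
                raise RecordingError("bend angles must lie in [0, 180] degrees")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return the 1-D series for a named channel."""
        return self.data[:, self.channels.index(name)]


def _parse_meta_value(text: str):
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def write_recording(rec: Recording, path) -> Path:
    """Write ``rec`` to CSV, lossless to >= 9 significant digits.

    Layout: ``#`` metadata lines (kind, fs, units, ``meta.*``), then a
    header row of channel names, then one row per sample.
    """
    rec.validate()
    path = Path(path)
    lines = [
        f"# kind: {rec.kind}",
        f"# fs: {rec.fs!r}",
        f"# units: {rec.units}",
    ]
    for key, value in rec.meta.items():
        lines.append(f"# meta.{key}: {value}")
    buf = _stdio.StringIO()
    pd.DataFrame(rec.data, columns=rec.channels).to_csv(
        buf, index=False, float_format="%.17g"
    )
    path.write_text("\n".join(lines) + "\n" + buf.getvalue())
    return path


def read_recording(path, kind: str | None = None, fs: float | None = None) -> Recording:
    """Read a Recording CSV written by :func:`write_recording`.

    ``kind``/``fs`` override the file's metadata when given (and are
    required if the file carries none, e.g. a bare CSV from another tool).
    """
    path = Path(path)
    header: dict[str, str] = {}
    meta: dict = {}
    body_lines: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            if ":" not in text:
                raise RecordingError(f"{path}:{lineno}: malformed metadata line {line!r}")
            key, _, value = text.partition(":")
            key, value = key.strip(), value.strip()
            if key.startswith("meta."):
                meta[key[5:]] = _parse_meta_value(value)
            else:
                header[key] = value
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise RecordingError(f"{path}: no header/data rows found")
    try:
        frame = pd.read_csv(
            _stdio.StringIO("\n".join(body_lines)), float_precision="round_trip"
        )
        data = frame.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise RecordingError(f"{path}: malformed CSV body: {exc}") from exc
    kind = kind or header.get("kind")
    if kind is None:
        raise RecordingError(f"{path}: recording kind not in file metadata; pass kind=")
    fs = fs if fs is not None else float(header.get("fs", "nan"))
    if not np.isfinite(fs):
        raise RecordingError(f"{path}: sampling frequency not in file metadata; pass fs=")
    return Recording(
        kind=kind,
        channels=list(frame.columns),
        data=data,
        fs=fs,
        units=header.get("units", ""),
        meta=meta,
    )
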