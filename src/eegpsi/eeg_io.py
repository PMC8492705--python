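"""Reading and writing EEG recordings and tabular results.

Recordings are kept as channels x samples matrices in microvolts with a
single sampling rate; samples are columns because every pipeline stage
normalizes or sums across channels at fixed time points.

Two on-disk formats are supported: EDF (European Data Format; read via mne,
written by a minimal built-in writer using the standard 16-bit encoding) and
plain delimited text with one row per channel.  Result tables go out as CSV
at full float precision so reruns are diffable.
"""

from __future__ import annotations

import datetime
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "EEGRecording",
    "read_edf",
    "write_edf",
    "read_matrix",
    "write_matrix",
    "write_table",
    "read_table",
]

DEFAULT_FS = 250.0  # Hz, the conventional high-density EEG rate used here


@dataclass
class EEGRecording:
    """A multichannel EEG recording: channels x samples, microvolts."""

    data: np.ndarray
    fs: float
    labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.labels)} labels"
            )
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        _reject_nonfinite(self.data, self.labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs


def _reject_nonfinite(data: np.ndarray, labels: list[str]) -> None:
    bad = ~np.isfinite(data)
    if bad.any():
        ch, sm = np.argwhere(bad)[0]
        raise ValueError(
            f"non-finite value at channel {labels[ch]!r} (row {ch}), "
            f"sample {sm}"
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_samples_per_record(path) -> tuple[list[int], float, int]:
    """Header scan: per-signal samples per record, record duration, n signals.

    mne silently resamples EDF files whose channels carry different rates, so
    the uniformity check has to look at the raw header fields directly.
    """
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise ValueError(f"truncated EDF header in {path}")
        try:
            duration = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError) as exc:
            raise ValueError(f"unreadable EDF header in {path}: {exc}") from exc
        sig = f.read(256 * ns)
    if len(sig) < 256 * ns:
        raise ValueError(f"truncated EDF signal header in {path}")
    # field-major layout: samples-per-record starts at offset 216*ns
    off = (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80) * ns
    spr = [
        int(sig[off + 8 * i: off + 8 * (i + 1)].decode("ascii").strip())
        for i in range(ns)
    ]
    return spr, duration, ns


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an EEGRecording (microvolts).

    All channels must share one sampling rate; annotation channels are not
    supported.  Raises ValueError on mixed rates or a malformed header.
    """
    import mne

    spr, duration, _ = _edf_samples_per_record(path)
    if len(set(spr)) > 1:
        rates = sorted({s / duration for s in spr})
        raise ValueError(
            f"mixed sampling rates in {path}: {rates} Hz; resample upstream"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts for EEG channels
    rec = EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    return rec


def _edf_str(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(path, rec: EEGRecording) -> None:
    """Write an EEGRecording as a single-data-record EDF file.

    Samples are quantized to the standard 16-bit digital range against
    per-channel physical extrema, so a round trip is exact only to
    (phys_max - phys_min) / 65535 per channel.
    """
    data = rec.data
    n_ch, n_samp = data.shape
    duration = n_samp / rec.fs
    dur_s = f"{duration:.6g}"
    if len(dur_s) > 8:
        raise ValueError(f"record duration {duration} does not fit EDF header")

    pmins, pmaxs, digital = [], [], []
    dmin, dmax = -32768, 32767
    for row in data:
        lo, hi = float(row.min()), float(row.max())
        if hi <= lo:  # constant channel: open a token range around it
            lo, hi = lo - 1.0, hi + 1.0
        scale = (dmax - dmin) / (hi - lo)
        dig = np.round((row - lo) * scale + dmin).astype("<i2")
        pmins.append(lo)
        pmaxs.append(hi)
        digital.append(dig)

    now = datetime.datetime(2000, 1, 1)
    header = b"".join([
        _edf_str("0", 8),
        _edf_str("X X X X", 80),
        _edf_str("Startdate X X X X", 80),
        _edf_str(now.strftime("%d.%m.%y"), 8),
        _edf_str(now.strftime("%H.%M.%S"), 8),
        _edf_str(256 * (1 + n_ch), 8),
        _edf_str("", 44),
        _edf_str(1, 8),
        _edf_str(dur_s, 8),
        _edf_str(n_ch, 4),
    ])
    fields = [
        [_edf_str(lab[:16], 16) for lab in rec.labels],
        [_edf_str("", 80)] * n_ch,
        [_edf_str("uV", 8)] * n_ch,
        [_edf_str(f"{p:.6g}"[:8], 8) for p in pmins],
        [_edf_str(f"{p:.6g}"[:8], 8) for p in pmaxs],
        [_edf_str(dmin, 8)] * n_ch,
        [_edf_str(dmax, 8)] * n_ch,
        [_edf_str("", 80)] * n_ch,
        [_edf_str(n_samp, 8)] * n_ch,
        [_edf_str("", 32)] * n_ch,
    ]
    with open(path, "wb") as f:
        f.write(header)
        for fld in fields:
            f.writelines(fld)
        for dig in digital:
            f.write(dig.tobytes())


def edf_quantization_bound(rec: EEGRecording) -> np.ndarray:
    """Per-channel worst-case EDF 16-bit round-trip error (microvolts)."""
    lo = rec.data.min(axis=1)
    hi = rec.data.max(axis=1)
    span = np.where(hi > lo, hi - lo, 2.0)
    return span / 65535.0


# ---------------------------------------------------------------------------
# Delimited text
# ---------------------------------------------------------------------------

def read_matrix(path, fs: float | None = None) -> EEGRecording:
    """Read a delimited channels-x-samples matrix; first column is the label.

    If *fs* is omitted the conventional 250 Hz is assumed (with a warning).
    """
    if fs is None:
        logger.warning("no sampling rate given; assuming %g Hz", DEFAULT_FS)
        fs = DEFAULT_FS
    labels: list[str] = []
    rows: list[np.ndarray] = []
    width = None
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if width is None:
                width = len(parts)
            elif len(parts) != width:
                raise ValueError(
                    f"ragged row at line {lineno}: {len(parts)} fields, "
                    f"expected {width}"
                )
            labels.append(parts[0])
            try:
                rows.append(np.array([float(v) for v in parts[1:]]))
            except ValueError:
                raise ValueError(
                    f"non-numeric sample value at line {lineno}"
                ) from None
    if not rows:
        raise ValueError(f"empty matrix file: {path}")
    return EEGRecording(np.vstack(rows), fs, labels)


def write_matrix(path, rec: EEGRecording) -> None:
    """Write a recording as delimited text, full precision (round-trippable)."""
    with open(path, "w") as f:
        for lab, row in zip(rec.labels, rec.data):
            f.write(lab + "," + ",".join(repr(float(v)) for v in row) + "\n")


def write_table(path, table: dict[str, np.ndarray] | pd.DataFrame) -> None:
    """Write named columns as CSV with header, deterministic column order,
    full float precision."""
    if not isinstance(table, pd.DataFrame):
        table = pd.DataFrame(dict(table))
    table.to_csv(path, index=False, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
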