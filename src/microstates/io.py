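"""Readers, writers and domain containers for EEG microstate analysis.

The on-disk formats are deliberately plain:

* recordings — either EDF (16-bit European Data Format, one data record)
  or a tab-separated channels × samples matrix preceded by ``#``-prefixed
  ``key = value`` header lines (sampling rate, units, channel names,
  montage coordinates);
* template sets, label series and parameter tables — tab-separated text;
* covariate tables — CSV via pandas.

Channel order is authoritative from the file; downstream code matches
channels by *name* and raises on mismatch instead of silently reordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "TemplateSet",
    "LabelSeries",
    "FormatError",
    "build_spherical_montage",
    "read_recording",
    "write_recording",
    "read_templates",
    "write_templates",
    "read_labels",
    "write_labels",
    "read_parameters",
    "write_parameters",
    "read_covariates",
    "write_covariates",
]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates the expected structure."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class EEGRecording:
    """Multichannel EEG voltages with montage and reference state.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltages in microvolts.
    sfreq : float
        Sampling rate in Hz.
    channel_names : list of str
    montage : ndarray, shape (n_channels, 3)
        Unit-sphere sensor coordinates (right-handed, head-centred:
        +x right, +y anterior, +z superior).
    reference : {"original", "average"}
    subject_id : str
    group : str or None
        Optional cohort label, e.g. ``"patient"`` / ``"control"``.
    """

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    montage: np.ndarray
    reference: str = "original"
    subject_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.montage = np.asarray(self.montage, dtype=float)
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise FormatError("recording data must be 2-D (channels x samples)")
        if self.n_channels < 3:
            raise FormatError("need at least 3 channels")
        if not self.sfreq > 0:
            raise FormatError("sampling rate must be positive")
        if len(self.channel_names) != self.n_channels:
            raise FormatError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} data rows"
            )
        if self.montage.shape != (self.n_channels, 3):
            raise FormatError(
                f"montage shape {self.montage.shape} does not match "
                f"{self.n_channels} channels"
            )
        norms = np.linalg.norm(self.montage, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise FormatError("montage coordinates must lie on the unit sphere")
        _reject_nonfinite(self.data, self.channel_names)
        if self.reference not in ("original", "average"):
            raise FormatError(f"unknown reference state {self.reference!r}")

    def copy_with(self, **kwargs) -> "EEGRecording":
        return replace(self, **kwargs)


@dataclass
class TemplateSet:
    """K microstate template topographies, each zero-mean and unit L2 norm."""

    maps: np.ndarray  # (K, n_channels)
    class_labels: list[str]
    channel_names: list[str]
    level: str = "individual"  # individual | group | population

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        self.validate()

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]

    def validate(self) -> None:
        if self.maps.shape[0] < 1:
            raise FormatError("template set needs at least one map")
        if len(self.class_labels) != self.maps.shape[0]:
            raise FormatError("class label count does not match map count")
        if len(self.channel_names) != self.maps.shape[1]:
            raise FormatError("channel name count does not match map width")
        if not np.allclose(self.maps.mean(axis=1), 0.0, atol=1e-9):
            raise FormatError("template maps must be zero-mean across channels")
        if not np.allclose(np.linalg.norm(self.maps, axis=1), 1.0, atol=1e-9):
            raise FormatError("template maps must have unit L2 norm")
        if self.level not in ("individual", "group", "population"):
            raise FormatError(f"unknown template level {self.level!r}")
        if self.maps.shape[0] > 1:
            c = self.maps @ self.maps.T
            off = c[~np.eye(self.maps.shape[0], dtype=bool)]
            if np.any(np.isclose(np.abs(off), 1.0, atol=1e-12)):
                raise FormatError("two template maps are perfectly correlated")


@dataclass
class LabelSeries:
    """Per-sample microstate class assignment from back-fitting.

    ``corr`` is the absolute spatial correlation with the winning template;
    ``corr_all`` (optional, K × n_samples) keeps the full correlation matrix
    so that temporal smoothing can re-assign samples to runner-up classes.
    """

    labels: np.ndarray  # (n_samples,) int
    corr: np.ndarray  # (n_samples,) float in [0, 1]
    sfreq: float
    class_labels: list[str]
    corr_all: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.labels.shape != self.corr.shape:
            raise FormatError("labels and corr must have equal length")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_labels)
        ):
            raise FormatError("label outside class range")

    @property
    def n_samples(self) -> int:
        return self.labels.size


def _reject_nonfinite(data: np.ndarray, channel_names: list[str]) -> None:
    bad = ~np.isfinite(data)
    if bad.any():
        ch, smp = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite value at channel {channel_names[ch]!r}, sample {smp}"
        )


# ---------------------------------------------------------------------------
# Synthetic montage
# ---------------------------------------------------------------------------


def build_spherical_montage(
    n_channels: int, seed: int = 0, jitter: float = 0.0
) -> np.ndarray:
    """Quasi-uniform unit-sphere sensor layout (Fibonacci lattice).

    Deterministic for fixed arguments; ``seed`` only matters when
    ``jitter > 0`` (small tangential Gaussian perturbation, radians).
    """
    if n_channels < 3:
        raise ValueError("a montage needs at least 3 channels")
    i = np.arange(n_channels)
    z = 1.0 - 2.0 * (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * i
    r = np.sqrt(1.0 - z**2)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    if jitter > 0:
        rng = np.random.default_rng(seed)
        pts = pts + jitter * rng.standard_normal(pts.shape)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def default_channel_names(n_channels: int) -> list[str]:
    width = max(3, len(str(n_channels)))
    return [f"E{i + 1:0{width}d}" for i in range(n_channels)]


# ---------------------------------------------------------------------------
# Delimited recording format
# ---------------------------------------------------------------------------

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def _parse_header(path: Path) -> tuple[dict, list[str], int]:
    """Return (key→value dict, montage lines, number of header lines)."""
    meta: dict[str, str] = {}
    montage_lines: list[str] = []
    n_header = 0
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if body.startswith("montage "):
                montage_lines.append(body)
            elif "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta, montage_lines, n_header


def _read_delimited_recording(path: Path) -> EEGRecording:
    meta, montage_lines, n_header = _parse_header(path)
    for required in ("sfreq", "channels"):
        if required not in meta:
            raise FormatError(f"missing required header key {required!r} in {path}")
    channel_names = meta["channels"].split("\t")
    if len(channel_names) == 1:
        channel_names = meta["channels"].split(",")
    channel_names = [c.strip() for c in channel_names if c.strip()]
    sfreq = float(meta["sfreq"])
    units = meta.get("units", "uV")
    if units not in _UNIT_TO_UV:
        raise FormatError(f"unknown units {units!r}")
    scale = _UNIT_TO_UV[units]

    coords = {}
    for line in montage_lines:
        parts = line.split()
        if len(parts) != 5:
            raise FormatError(f"malformed montage line: {line!r}")
        coords[parts[1]] = [float(v) for v in parts[2:]]
    if set(coords) != set(channel_names):
        raise FormatError("montage channel set does not match 'channels' header")
    montage = np.array([coords[c] for c in channel_names])

    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            row = []
            for col, cell in enumerate(cells):
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"non-numeric cell at line {lineno}, column {col + 1}: "
                        f"{cell!r}"
                    ) from None
            rows.append(row)
    if len(rows) != len(channel_names):
        raise FormatError(
            f"{len(rows)} data rows but {len(channel_names)} channels declared"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError("ragged data rows (unequal sample counts)")
    data = np.asarray(rows, dtype=float) * scale
    return EEGRecording(
        data=data,
        sfreq=sfreq,
        channel_names=channel_names,
        montage=montage,
        reference=meta.get("reference", "original"),
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group") or None,
    )


def _write_delimited_recording(rec: EEGRecording, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# microstates recording v1\n")
        fh.write(f"# subject_id = {rec.subject_id}\n")
        if rec.group is not None:
            fh.write(f"# group = {rec.group}\n")
        fh.write(f"# sfreq = {rec.sfreq!r}\n")
        fh.write("# units = uV\n")
        fh.write(f"# reference = {rec.reference}\n")
        fh.write("# channels = " + "\t".join(rec.channel_names) + "\n")
        for name, (x, y, z) in zip(rec.channel_names, rec.montage):
            fh.write(f"# montage {name} {float(x)!r} {float(y)!r} {float(z)!r}\n")
        for row in rec.data:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# EDF (European Data Format), minimal single-record implementation
# ---------------------------------------------------------------------------
# EDF cannot carry sensor coordinates, so the writer emits a
# "<path>.montage.tsv" sidecar that the reader picks up when present.


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt8(v: float) -> str:
    """Format a float into ≤8 ASCII chars without corrupting its magnitude."""
    for spec in (".6g", ".4g", ".2g", ".1e", ".0e"):
        s = format(v, spec)
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot represent {v} in 8 characters")


def _write_edf(rec: EEGRecording, path: Path) -> None:
    n_ch = rec.n_channels
    n_samp = rec.n_samples
    # per-channel physical range ±8×max|x| bounds quantization error
    phys_max = 8.0 * np.maximum(np.abs(rec.data).max(axis=1), 1e-6)
    dig_min, dig_max = -32768, 32767
    duration = n_samp / rec.sfreq
    dur_str = f"{duration:.6g}"
    if len(dur_str) > 8:
        dur_str = f"{duration:.2f}"[:8]

    with open(path, "wb") as fh:
        fh.write(_edf_field("0", 8))
        fh.write(_edf_field(rec.subject_id or "X", 80))
        fh.write(_edf_field(f"group={rec.group or ''} ref={rec.reference}", 80))
        fh.write(_edf_field("01.01.00", 8))
        fh.write(_edf_field("00.00.00", 8))
        fh.write(_edf_field(str(256 * (n_ch + 1)), 8))
        fh.write(_edf_field("", 44))
        fh.write(_edf_field("1", 8))  # one data record
        fh.write(_edf_field(dur_str, 8))
        fh.write(_edf_field(str(n_ch), 4))
        for name in rec.channel_names:
            fh.write(_edf_field(name, 16))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field("uV", 8))
        for pm in phys_max:
            fh.write(_edf_field(_fmt8(-pm), 8))
        for pm in phys_max:
            fh.write(_edf_field(_fmt8(pm), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_edf_field(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 80))
        for _ in range(n_ch):
            fh.write(_edf_field(str(n_samp), 8))
        for _ in range(n_ch):
            fh.write(_edf_field("", 32))
        # data: channel-sequential within the single record
        # re-parse the truncated physical range exactly as a reader would
        pm_written = np.array([float(_fmt8(pm)) for pm in phys_max])
        scale = (2.0 * pm_written) / (dig_max - dig_min)
        for ch in range(n_ch):
            dig = np.round(
                (rec.data[ch] + pm_written[ch]) / scale[ch] + dig_min
            ).astype(np.int16)
            fh.write(dig.astype("<i2").tobytes())

    side = Path(str(path) + ".montage.tsv")
    with open(side, "w", encoding="utf-8") as fh:
        for name, (x, y, z) in zip(rec.channel_names, rec.montage):
            fh.write(f"{name}\t{float(x)!r}\t{float(y)!r}\t{float(z)!r}\n")


def _read_edf(path: Path) -> EEGRecording:
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise FormatError("truncated EDF header")
        subject_id = header[8:88].decode("ascii", "replace").strip()
        recording_id = header[88:168].decode("ascii", "replace").strip()
        n_records = int(header[236:244].decode().strip())
        duration = float(header[244:252].decode().strip())
        n_ch = int(header[252:256].decode().strip())
        sig = fh.read(256 * n_ch)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode().strip()
                for i in range(n_ch)
            ]

        names = fields(0, 16)
        phys_min = np.array([float(v) for v in fields(16 + 80 + 8, 8)], dtype=float)
        phys_max = np.array(
            [float(v) for v in fields(16 + 80 + 8 + 8, 8)], dtype=float
        )
        dig_min = np.array(
            [float(v) for v in fields(16 + 80 + 8 + 16, 8)], dtype=float
        )
        dig_max = np.array(
            [float(v) for v in fields(16 + 80 + 8 + 24, 8)], dtype=float
        )
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise FormatError("mixed sampling rates across EDF channels")
        n_samp_rec = spr[0]

        data = np.empty((n_ch, n_records * n_samp_rec))
        for rec_i in range(n_records):
            for ch in range(n_ch):
                raw = fh.read(2 * n_samp_rec)
                if len(raw) < 2 * n_samp_rec:
                    raise FormatError("truncated EDF data record")
                dig = np.frombuffer(raw, dtype="<i2").astype(float)
                scale = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
                data[ch, rec_i * n_samp_rec : (rec_i + 1) * n_samp_rec] = (
                    dig - dig_min[ch]
                ) * scale + phys_min[ch]

    sfreq = n_samp_rec / duration * 1.0 if n_records == 1 else n_samp_rec / duration
    group = None
    reference = "original"
    for token in recording_id.split():
        if token.startswith("group="):
            group = token[6:] or None
        elif token.startswith("ref="):
            reference = token[4:] or "original"

    side = Path(str(path) + ".montage.tsv")
    if side.exists():
        rows = [ln.split("\t") for ln in side.read_text().splitlines() if ln]
        coords = {r[0]: [float(v) for v in r[1:4]] for r in rows}
        if set(coords) != set(names):
            raise FormatError("montage sidecar channels do not match EDF labels")
        montage = np.array([coords[c] for c in names])
    else:
        warnings.warn(
            f"no montage sidecar next to {path}; using a synthetic spherical layout"
        )
        montage = build_spherical_montage(n_ch)

    return EEGRecording(
        data=data,
        sfreq=sfreq,
        channel_names=names,
        montage=montage,
        reference=reference,
        subject_id=subject_id if subject_id != "X" else "",
        group=group,
    )


# ---------------------------------------------------------------------------
# Public recording API
# ---------------------------------------------------------------------------


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a recording from EDF or the delimited text format.

    ``format`` is inferred from the suffix (``.edf`` → EDF) when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        return _read_edf(path)
    if format == "delimited":
        return _read_delimited_recording(path)
    raise ValueError(f"unknown format {format!r}")


def write_recording(
    rec: EEGRecording, path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    rec.validate()
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        _write_edf(rec, path)
    elif format == "delimited":
        _write_delimited_recording(rec, path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


# ---------------------------------------------------------------------------
# Templates, labels, parameter and covariate tables
# ---------------------------------------------------------------------------


def write_templates(tset: TemplateSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# microstates templates v1\n")
        fh.write(f"# level = {tset.level}\n")
        fh.write("# class_labels = " + "\t".join(tset.class_labels) + "\n")
        fh.write("# channels = " + "\t".join(tset.channel_names) + "\n")
        for row in tset.maps:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")
    return path


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    meta, _, _ = _parse_header(path)
    labels = [c for c in meta.get("class_labels", "").split("\t") if c]
    channels = [c for c in meta.get("channels", "").split("\t") if c]
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append([float(v) for v in line.split("\t")])
    maps = np.asarray(rows)
    if maps.shape != (len(labels), len(channels)):
        raise FormatError(
            f"template matrix {maps.shape} does not match header "
            f"({len(labels)} classes, {len(channels)} channels)"
        )
    return TemplateSet(
        maps=maps,
        class_labels=labels,
        channel_names=channels,
        level=meta.get("level", "individual"),
    )


def write_labels(series: LabelSeries, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# microstates labels v1\n")
        fh.write(f"# sfreq = {series.sfreq!r}\n")
        fh.write("# class_labels = " + "\t".join(series.class_labels) + "\n")
        for lab, c in zip(series.labels, series.corr):
            fh.write(f"{int(lab)}\t{float(c)!r}\n")
    return path


def read_labels(path: str | Path) -> LabelSeries:
    path = Path(path)
    meta, _, _ = _parse_header(path)
    class_labels = [c for c in meta.get("class_labels", "").split("\t") if c]
    labels, corr = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            a, b = line.split("\t")
            labels.append(int(a))
            corr.append(float(b))
    return LabelSeries(
        labels=np.array(labels),
        corr=np.array(corr),
        sfreq=float(meta["sfreq"]),
        class_labels=class_labels,
    )


PARAMETER_COLUMNS = [
    "subject_id",
    "group",
    "class",
    "gev",
    "mean_duration_ms",
    "time_coverage_pct",
    "occurrence_per_min",
]


def write_parameters(table: pd.DataFrame, path: str | Path) -> Path:
    missing = [c for c in PARAMETER_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"parameter table missing columns {missing}")
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_parameters(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PARAMETER_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"parameter table missing columns {missing}")
    return table


def write_covariates(table: pd.DataFrame, path: str | Path) -> Path:
    if "subject_id" not in table.columns or "group" not in table.columns:
        raise FormatError("covariate table needs subject_id and group columns")
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_covariates(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if "subject_id" not in table.columns or "group" not in table.columns:
        raise FormatError("covariate table needs subject_id and group columns")
    if table["group"].isna().any():
        raise FormatError("covariate table has missing group labels")
    if not table["subject_id"].is_unique:
        raise FormatError("duplicate subject_id in covariate table")
    return table
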