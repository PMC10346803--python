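"""Reading and writing EHG records and feature tables.

Records follow the PhysioNet WFDB convention used by the Term-Preterm
ElectroHysteroGram database (TPEHG): a text header (``.hea``) describing the
signals plus gestational metadata in comment lines, and a binary ``.dat``
file holding interleaved 16-bit samples.  Only the subset of WFDB needed for
TPEHG-style records is supported (format 16, one segment, shared sampling
frequency).

A *feature table* is a :class:`pandas.DataFrame` whose first four columns are
``record_id, label, group, provenance`` followed by one column per feature.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ehgpreterm")

#: delivery strictly before this gestational week counts as preterm labor
PRETERM_WEEK = 37.0
#: recording strictly before this gestational week puts a subject in the
#: "early" (PE-TE) cohort, otherwise "late" (PL-TL)
EARLY_WEEK = 26.0

#: leading metadata columns of a feature table
META_COLUMNS = ["record_id", "label", "group", "provenance"]

#: raw (unfiltered) signal indices for the three bipolar channels in a
#: 12-signal TPEHG header, where each channel is stored as the raw trace
#: followed by three pre-filtered versions
TPEHG_RAW_CHANNELS = (0, 4, 8)


class EHGFormatError(ValueError):
    """Malformed WFDB header/signal file or feature-table CSV."""


class EHGChannelError(ValueError):
    """Fewer than three usable signals in a record."""


class EHGMetadataError(ValueError):
    """Gestational-age metadata missing from a header."""


def label_from_weeks(gestation_at_delivery: float,
                     preterm_week: float = PRETERM_WEEK) -> str:
    """Term/preterm label from the gestational week at delivery."""
    return "preterm" if gestation_at_delivery < preterm_week else "term"


def group_from_weeks(gestation_at_recording: float,
                     early_week: float = EARLY_WEEK) -> str:
    """Early/late cohort from the gestational week at recording."""
    return "early" if gestation_at_recording < early_week else "late"


@dataclass
class EHGRecord:
    """One subject's three-channel EHG recording with gestational metadata.

    ``channels`` is a ``(3, n)`` float array (bipolar CH1, CH2, CH3).  The
    term/preterm label and early/late group are pure functions of the two
    gestational weeks and are derived, never stored independently.
    """

    record_id: str
    fs: float
    channels: np.ndarray
    gestation_at_recording: float
    gestation_at_delivery: float
    provenance: str = "real"

    def __post_init__(self) -> None:
        self.channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        if self.channels.shape[0] != 3:
            raise EHGChannelError(
                f"{self.record_id}: expected 3 channels, "
                f"got {self.channels.shape[0]}")
        if not np.all(np.isfinite(self.channels)):
            raise EHGFormatError(f"{self.record_id}: non-finite samples")

    @property
    def label(self) -> str:
        return label_from_weeks(self.gestation_at_delivery)

    @property
    def group(self) -> str:
        return group_from_weeks(self.gestation_at_recording)

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def replace_channels(self, channels: np.ndarray) -> "EHGRecord":
        """Copy of this record with new signal content (same metadata)."""
        return EHGRecord(self.record_id, self.fs, channels,
                         self.gestation_at_recording,
                         self.gestation_at_delivery, self.provenance)


# ---------------------------------------------------------------------------
# WFDB header / signal parsing (format-16 subset)
# ---------------------------------------------------------------------------

_GAIN_RE = re.compile(r"([-+0-9.eE]+)(?:\(([-+0-9]+)\))?(?:/(\S+))?")


@dataclass
class _SignalSpec:
    file_name: str
    fmt: str
    gain: float
    baseline: int
    description: str = ""


@dataclass
class _Header:
    record_name: str
    n_sig: int
    fs: float
    n_samples: int
    signals: list[_SignalSpec] = field(default_factory=list)
    comments: dict[str, str] = field(default_factory=dict)


def _parse_header(path: Path) -> _Header:
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EHGFormatError(f"{path}: empty header")
    first = lines[0].split()
    if len(first) < 3:
        raise EHGFormatError(f"{path}: record line needs name/n_sig/fs, "
                             f"got {lines[0]!r}")
    try:
        n_sig = int(first[1])
        fs = float(first[2].split("/")[0])
        n_samples = int(first[3]) if len(first) > 3 else -1
    except ValueError as exc:
        raise EHGFormatError(f"{path}: bad record line field: {exc}") from exc

    header = _Header(first[0], n_sig, fs, n_samples)
    for ln in lines[1:]:
        if ln.startswith("#"):
            parts = ln.lstrip("# \t").split(None, 1)
            if len(parts) == 2:
                header.comments[parts[0].lower()] = parts[1].strip()
            continue
        if len(header.signals) >= n_sig:
            continue
        fields = ln.split()
        if len(fields) < 2:
            raise EHGFormatError(f"{path}: bad signal line {ln!r}")
        fmt = fields[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline = 200.0, 0
        if len(fields) >= 3:
            m = _GAIN_RE.match(fields[2])
            if m is None:
                raise EHGFormatError(f"{path}: bad gain field {fields[2]!r}")
            gain = float(m.group(1))
            if m.group(2) is not None:
                baseline = int(m.group(2))
            elif len(fields) >= 5:
                # baseline defaults to adc_zero when not given explicitly
                try:
                    baseline = int(fields[4])
                except ValueError:
                    baseline = 0
        if gain == 0:
            gain = 200.0
        desc = " ".join(fields[9:]) if len(fields) > 9 else ""
        header.signals.append(
            _SignalSpec(fields[0], fmt, gain, baseline, desc))
    if len(header.signals) != n_sig:
        raise EHGFormatError(
            f"{path}: header declares {n_sig} signals, "
            f"found {len(header.signals)} signal lines")
    return header


def _parse_week(header: _Header, key: str, path: Path) -> float:
    raw = header.comments.get(key)
    if raw is None:
        raise EHGMetadataError(f"{path}: missing '{key}' metadata comment")
    token = raw.split()[0]
    try:
        week = float(token)
    except ValueError:
        raise EHGMetadataError(
            f"{path}: '{key}' value {token!r} is not a number") from None
    return week


def read_record(path: str | Path,
                channel_indices: Sequence[int] | None = None) -> EHGRecord:
    """Read one WFDB record (header + format-16 signal file).

    Parameters
    ----------
    path
        Path to the ``.hea`` file (the extension may be omitted).
    channel_indices
        Which of the header's signals are the three raw bipolar channels.
        Defaults to ``(0, 4, 8)`` for 12-signal TPEHG headers (raw CH1/CH2/
        CH3, skipping the database's pre-filtered versions) and ``(0, 1, 2)``
        otherwise.
    """
    path = Path(path)
    if path.suffix != ".hea":
        path = path.with_suffix(".hea")
    if not path.exists():
        raise FileNotFoundError(path)
    header = _parse_header(path)

    if channel_indices is None:
        channel_indices = (TPEHG_RAW_CHANNELS if header.n_sig >= 12
                           else (0, 1, 2))
    if len(channel_indices) != 3:
        raise EHGChannelError(f"{path}: need exactly 3 channel indices")
    if max(channel_indices) >= header.n_sig:
        raise EHGChannelError(
            f"{path}: channel index {max(channel_indices)} out of range "
            f"for {header.n_sig} signals")
    for spec in header.signals:
        if spec.fmt != "16":
            raise EHGFormatError(
                f"{path}: unsupported signal format {spec.fmt!r} "
                "(only format 16 is supported)")

    rec_week = _parse_week(header, "rectime", path)
    del_week = _parse_week(header, "gestation", path)

    dat_path = path.with_name(header.signals[0].file_name)
    raw = np.fromfile(dat_path, dtype="<i2")
    if header.n_samples > 0:
        expected = header.n_samples * header.n_sig
        if raw.size < expected:
            raise EHGFormatError(
                f"{dat_path}: expected {expected} samples, got {raw.size}")
        raw = raw[:expected]
    if raw.size % header.n_sig:
        raise EHGFormatError(
            f"{dat_path}: sample count {raw.size} not divisible by "
            f"{header.n_sig} signals")
    frames = raw.reshape(-1, header.n_sig)

    channels = np.empty((3, frames.shape[0]))
    for row, idx in enumerate(channel_indices):
        spec = header.signals[idx]
        channels[row] = (frames[:, idx] - spec.baseline) / spec.gain

    return EHGRecord(header.record_name, header.fs, channels,
                     rec_week, del_week, provenance="real")


def write_record(record: EHGRecord, out_dir: str | Path,
                 gain: float = 1000.0) -> Path:
    """Write a record as a WFDB header + format-16 signal file pair.

    Values are quantised to ``round(x * gain)`` 16-bit integers; the gain
    default keeps sub-millivolt resolution for unit-scale synthetic signals.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = record.record_id
    ints = np.round(record.channels * gain)
    if np.abs(ints).max() > 32767:
        raise EHGFormatError(
            f"{name}: signal exceeds 16-bit range at gain {gain}")
    frames = ints.T.astype("<i2")
    (out_dir / f"{name}.dat").write_bytes(frames.tobytes())

    lines = [f"{name} 3 {record.fs:g} {record.n_samples}"]
    for c in range(3):
        lines.append(f"{name}.dat 16 {gain:g}(0)/mV 16 0 0 0 0 CH{c + 1}")
    lines.append(f"#RecTime {record.gestation_at_recording:g}")
    lines.append(f"#Gestation {record.gestation_at_delivery:g}")
    lines.append(f"#Provenance {record.provenance}")
    hea = out_dir / f"{name}.hea"
    hea.write_text("\n".join(lines) + "\n")
    return hea


def read_cohort(directory: str | Path,
                channel_indices: Sequence[int] | None = None,
                ) -> list[EHGRecord]:
    """Read every WFDB record in a directory, skipping records whose
    gestational metadata is missing (with a logged warning)."""
    directory = Path(directory)
    records = []
    for hea in sorted(directory.glob("*.hea")):
        try:
            records.append(read_record(hea, channel_indices))
        except EHGMetadataError as exc:
            logger.warning("skipping %s: %s", hea.name, exc)
    return records


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def group_counts(records: Iterable[EHGRecord]) -> pd.DataFrame:
    """Count records by (group, label); a 2x2 table as in cohort summaries."""
    records = list(records)
    if not records:
        raise ValueError("group_counts requires a non-empty record list")
    counts = pd.DataFrame(0, index=pd.Index(["early", "late"], name="group"),
                          columns=pd.Index(["term", "preterm"], name="label"))
    for rec in records:
        counts.loc[rec.group, rec.label] += 1
    assert int(counts.to_numpy().sum()) == len(records)
    return counts


# ---------------------------------------------------------------------------
# Feature-table CSV round trip
# ---------------------------------------------------------------------------

def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns (everything after the metadata block)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def validate_feature_table(table: pd.DataFrame) -> None:
    missing = [c for c in META_COLUMNS if c not in table.columns]
    if missing:
        raise EHGFormatError(f"feature table missing columns {missing}")
    feats = feature_columns(table)
    if len(set(feats)) != len(feats):
        raise EHGFormatError("duplicate feature names")
    values = table[feats].to_numpy()
    if values.size and not np.all(np.isfinite(values.astype(float))):
        raise EHGFormatError("non-finite feature values")


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table as UTF-8 CSV with full float precision."""
    validate_feature_table(table)
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise EHGFormatError(f"{path}: {exc}") from exc
    if table.isna().any().any():
        raise EHGFormatError(f"{path}: missing values (ragged rows?)")
    validate_feature_table(table)
    return table
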