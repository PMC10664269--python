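"""Readers/writers for the file shapes the pipeline touches.

Two plain-text tab-separated dialects are pinned here so that round trips are
bit-exact and fixtures stay human-readable:

Marker TSV
    Header lines are ``KEY<TAB>value...`` pairs.  ``FREQUENCY`` (Hz) and
    ``MARKER_NAMES`` (tab-separated labels) are mandatory; ``UNITS`` (``m`` or
    ``mm``, default ``m``), ``GAP_ZERO`` (``1`` if an all-zero coordinate
    triple means "marker lost", the common optical-capture convention, default
    ``1``) and the trial metadata keys ``PARTICIPANT``, ``TRIAL_TYPE``,
    ``TRIAL_NUMBER`` are optional.  Each subsequent line is one frame with
    three columns (x, y, z) per marker; an empty cell marks a gap.
    Coordinates are normalised to metres in memory; the vertical axis is z.

Force TSV
    ``FREQUENCY`` mandatory, ``CHANNELS`` (subset of fz, fx, fy; fz required)
    mandatory, ``PLATE_DIMS`` (metres) optional.  One sample per line, newtons.

The genotype table is an ordinary headed CSV (columns ``id``, ``actn3``,
``ace`` plus free covariates) read with pandas and vocabulary-validated here.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ValidationError

#: Canonical eleven-marker set: fifth metatarsal (A), lateral malleolus (B),
#: lateral femoral condyle (C), greater trochanter (D), anterior superior
#: iliac spine (E) on both sides, plus the sacrum (F).
CANONICAL_MARKERS = (
    "A5thMet_L", "A5thMet_R",
    "Bmalleolus_L", "Bmalleolus_R",
    "Ccondyle_L", "Ccondyle_R",
    "Dtrochanter_L", "Dtrochanter_R",
    "E_ASIS_L", "E_ASIS_R",
    "F_sacrum",
)

ACTN3_GENOTYPES = ("RR", "RX", "XX")
ACE_GENOTYPES = ("II", "ID", "DD")

_TRIAL_TYPES = ("SJ", "CMJ", "DJ", "SPRINT")


@dataclass
class TrialMeta:
    participant_id: str = ""
    trial_type: str = ""
    trial_number: int = 0


@dataclass
class MarkerTrajectories:
    """Time-indexed 3D positions for a labelled marker set.

    ``positions`` has shape ``(n_markers, n_frames, 3)`` in metres, lab frame,
    vertical axis z.  Gaps (lost markers) are NaN.
    """

    marker_ids: list[str]
    positions: np.ndarray
    frequency: float
    trial_meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise InputError("positions must have shape (n_markers, n_frames, 3)")
        if self.positions.shape[0] != len(self.marker_ids):
            raise InputError("marker_ids length does not match positions")
        if not self.frequency > 0:
            raise InputError("sampling frequency must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frequency

    def get(self, marker_id: str) -> np.ndarray:
        """Return the ``(n_frames, 3)`` trajectory of one marker."""
        try:
            idx = self.marker_ids.index(marker_id)
        except ValueError:
            raise InputError(f"marker {marker_id!r} not present") from None
        return self.positions[idx]

    def has_gaps(self) -> bool:
        return bool(np.isnan(self.positions).any())

    def is_complete(self) -> bool:
        """True when all eleven canonical markers are present."""
        return set(CANONICAL_MARKERS) <= set(self.marker_ids)


def fill_gaps(markers: MarkerTrajectories, max_run: int = 10) -> MarkerTrajectories:
    """Linearly interpolate NaN gaps per marker coordinate.

    A gap run longer than ``max_run`` frames, or a gap touching either end of
    the trial, rejects the trial (InputError): extrapolating marker positions
    would silently corrupt downstream kinematics.
    """
    pos = markers.positions.copy()
    n = markers.n_frames
    t = np.arange(n)
    for m, mid in enumerate(markers.marker_ids):
        bad = np.isnan(pos[m]).any(axis=1)
        if not bad.any():
            continue
        if bad[0] or bad[-1]:
            raise InputError(f"marker {mid}: gap at trial boundary cannot be interpolated")
        # longest run of consecutive gap frames
        runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])).reshape(-1, 2), axis=1)
        if runs.size and runs.max() > max_run:
            raise InputError(
                f"marker {mid}: gap of {int(runs.max())} frames exceeds max_run={max_run}"
            )
        good = ~bad
        for c in range(3):
            pos[m, bad, c] = np.interp(t[bad], t[good], pos[m, good, c])
    return MarkerTrajectories(list(markers.marker_ids), pos, markers.frequency, markers.trial_meta)


@dataclass
class ForcePlateSeries:
    """Ground-reaction force components (newtons) sampled at ``frequency`` Hz."""

    fz: np.ndarray
    frequency: float
    fx: np.ndarray | None = None
    fy: np.ndarray | None = None
    plate_dims: tuple[float, float] = (0.9, 0.9)

    def __post_init__(self) -> None:
        self.fz = np.asarray(self.fz, dtype=float)
        if not self.frequency > 0:
            raise InputError("sampling frequency must be positive")
        for name in ("fx", "fy"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.shape != self.fz.shape:
                    raise InputError(f"channel {name} length differs from fz")
                setattr(self, name, ch)

    @property
    def n_samples(self) -> int:
        return self.fz.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.frequency


@dataclass
class ParticipantRecord:
    """One row of cohort metadata; BMI is checked against mass/height**2."""

    id: str
    sex: str = "F"
    age: float = math.nan
    body_mass_kg: float = math.nan
    height_m: float = math.nan
    bmi: float = math.nan
    parq_positive: bool = False
    power_sport: bool = False

    def __post_init__(self) -> None:
        if not math.isnan(self.body_mass_kg) and not self.body_mass_kg > 0:
            raise ValidationError(f"participant {self.id}: body mass must be positive")
        if not (math.isnan(self.bmi) or math.isnan(self.body_mass_kg) or math.isnan(self.height_m)):
            implied = self.body_mass_kg / self.height_m**2
            if abs(implied - self.bmi) > 0.01 * implied:
                raise ValidationError(
                    f"participant {self.id}: BMI {self.bmi:.2f} inconsistent with "
                    f"mass/height^2 = {implied:.2f}"
                )


# ---------------------------------------------------------------------------
# marker TSV


def _open(source, mode: str):
    if isinstance(source, (str, Path)):
        return open(source, mode, newline=""), True
    return source, False


def _parse_header(lines: list[str], known: set[str]):
    header: dict[str, list[str]] = {}
    i = 0
    for i, line in enumerate(lines):
        fields = line.rstrip("\n").split("\t")
        if fields[0] in known:
            header[fields[0]] = fields[1:]
        else:
            break
    else:
        i = len(lines)
    return header, i


def read_marker_tsv(source, gap_zero: bool | None = None) -> MarkerTrajectories:
    """Parse the pinned marker TSV dialect into :class:`MarkerTrajectories`.

    ``gap_zero`` overrides the file's GAP_ZERO flag (whether an exact (0,0,0)
    triple is to be read as a lost marker).
    """
    fh, owned = _open(source, "r")
    try:
        lines = [ln for ln in fh.read().splitlines() if ln.strip() != ""]
    finally:
        if owned:
            fh.close()
    known = {"FREQUENCY", "UNITS", "GAP_ZERO", "MARKER_NAMES",
             "PARTICIPANT", "TRIAL_TYPE", "TRIAL_NUMBER"}
    header, first_data = _parse_header(lines, known)
    if "FREQUENCY" not in header:
        raise FormatError("marker TSV: missing FREQUENCY header line")
    if "MARKER_NAMES" not in header:
        raise FormatError("marker TSV: missing MARKER_NAMES header line")
    try:
        frequency = float(header["FREQUENCY"][0])
    except (IndexError, ValueError):
        raise FormatError("marker TSV: FREQUENCY value is not numeric") from None
    units = (header.get("UNITS", ["m"]) or ["m"])[0].lower()
    if units not in ("m", "mm"):
        raise FormatError(f"marker TSV: unknown UNITS {units!r}")
    scale = 0.001 if units == "mm" else 1.0
    if gap_zero is None:
        gap_zero = (header.get("GAP_ZERO", ["1"]) or ["1"])[0] != "0"
    marker_ids = [m for m in header["MARKER_NAMES"] if m != ""]
    if not marker_ids:
        raise FormatError("marker TSV: MARKER_NAMES lists no markers")
    ncol = 3 * len(marker_ids)

    rows = []
    for lineno, line in enumerate(lines[first_data:], start=first_data + 1):
        fields = line.split("\t")
        if len(fields) != ncol:
            raise FormatError(
                f"marker TSV line {lineno}: expected {ncol} columns, got {len(fields)}"
            )
        row = np.empty(ncol)
        for j, cell in enumerate(fields):
            if cell.strip() == "":
                row[j] = np.nan
            else:
                try:
                    row[j] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"marker TSV line {lineno}: non-numeric cell {cell!r}"
                    ) from None
        rows.append(row)
    if not rows:
        raise FormatError("marker TSV: no data rows")
    data = np.asarray(rows) * scale
    pos = data.reshape(len(rows), len(marker_ids), 3).transpose(1, 0, 2)
    # a triple that is exactly zero in the raw file is a lost marker under the
    # optical-capture convention
    if gap_zero:
        raw = np.asarray(rows).reshape(len(rows), len(marker_ids), 3).transpose(1, 0, 2)
        lost = (raw == 0.0).all(axis=2)
        pos[lost] = np.nan
    # any NaN coordinate voids the whole marker-frame triple
    pos[np.isnan(pos).any(axis=2)] = np.nan
    meta = TrialMeta(
        participant_id=(header.get("PARTICIPANT", [""]) or [""])[0],
        trial_type=(header.get("TRIAL_TYPE", [""]) or [""])[0],
        trial_number=int((header.get("TRIAL_NUMBER", ["0"]) or ["0"])[0]),
    )
    return MarkerTrajectories(marker_ids, pos, frequency, meta)


def write_marker_tsv(markers: MarkerTrajectories, dest) -> None:
    """Write in metres with GAP_ZERO disabled so NaN gaps stay empty cells."""
    fh, owned = _open(dest, "w")
    try:
        fh.write(f"FREQUENCY\t{markers.frequency:.12g}\n")
        fh.write("UNITS\tm\nGAP_ZERO\t0\n")
        meta = markers.trial_meta
        if meta.participant_id:
            fh.write(f"PARTICIPANT\t{meta.participant_id}\n")
        if meta.trial_type:
            fh.write(f"TRIAL_TYPE\t{meta.trial_type}\n")
        if meta.trial_number:
            fh.write(f"TRIAL_NUMBER\t{meta.trial_number}\n")
        fh.write("MARKER_NAMES\t" + "\t".join(markers.marker_ids) + "\n")
        flat = markers.positions.transpose(1, 0, 2).reshape(markers.n_frames, -1)
        for row in flat:
            cells = ["" if np.isnan(v) else f"{v:.12g}" for v in row]
            fh.write("\t".join(cells) + "\n")
    finally:
        if owned:
            fh.close()


# ---------------------------------------------------------------------------
# force-plate TSV


def read_forceplate_tsv(source) -> ForcePlateSeries:
    fh, owned = _open(source, "r")
    try:
        lines = [ln for ln in fh.read().splitlines() if ln.strip() != ""]
    finally:
        if owned:
            fh.close()
    header, first_data = _parse_header(lines, {"FREQUENCY", "CHANNELS", "PLATE_DIMS"})
    if "FREQUENCY" not in header:
        raise FormatError("force TSV: missing FREQUENCY header line")
    if "CHANNELS" not in header:
        raise FormatError("force TSV: missing CHANNELS header line")
    try:
        frequency = float(header["FREQUENCY"][0])
    except (IndexError, ValueError):
        raise FormatError("force TSV: FREQUENCY value is not numeric") from None
    channels = [c for c in header["CHANNELS"] if c != ""]
    if "fz" not in channels:
        raise FormatError("force TSV: CHANNELS must include fz")
    bad = set(channels) - {"fz", "fx", "fy"}
    if bad:
        raise FormatError(f"force TSV: unknown channels {sorted(bad)}")
    dims = (0.9, 0.9)
    if "PLATE_DIMS" in header:
        try:
            dims = (float(header["PLATE_DIMS"][0]), float(header["PLATE_DIMS"][1]))
        except (IndexError, ValueError):
            raise FormatError("force TSV: PLATE_DIMS needs two numeric values") from None
    data = np.empty((len(lines) - first_data, len(channels)))
    for i, (lineno, line) in enumerate(
        zip(range(first_data + 1, len(lines) + 1), lines[first_data:])
    ):
        fields = line.split("\t")
        if len(fields) != len(channels):
            raise FormatError(
                f"force TSV line {lineno}: expected {len(channels)} columns, got {len(fields)}"
            )
        for j, cell in enumerate(fields):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise FormatError(
                    f"force TSV line {lineno}: non-numeric cell {cell!r}"
                ) from None
    if data.shape[0] == 0:
        raise FormatError("force TSV: no data rows")
    cols = {c: data[:, j] for j, c in enumerate(channels)}
    return ForcePlateSeries(
        fz=cols["fz"], frequency=frequency,
        fx=cols.get("fx"), fy=cols.get("fy"), plate_dims=dims,
    )


def write_forceplate_tsv(fp: ForcePlateSeries, dest) -> None:
    channels = ["fz"] + [c for c in ("fx", "fy") if getattr(fp, c) is not None]
    fh, owned = _open(dest, "w")
    try:
        fh.write(f"FREQUENCY\t{fp.frequency:.12g}\n")
        fh.write("CHANNELS\t" + "\t".join(channels) + "\n")
        fh.write(f"PLATE_DIMS\t{fp.plate_dims[0]:.12g}\t{fp.plate_dims[1]:.12g}\n")
        mat = np.column_stack([getattr(fp, c) for c in channels])
        for row in mat:
            fh.write("\t".join(f"{v:.12g}" for v in row) + "\n")
    finally:
        if owned:
            fh.close()


# ---------------------------------------------------------------------------
# genotype CSV


def read_genotype_table(source) -> pd.DataFrame:
    """Read and vocabulary-validate the cohort genotype/covariate CSV.

    Requires columns ``id``, ``actn3`` (RR|RX|XX) and ``ace`` (II|ID|DD); any
    further columns (body_mass_kg, age, sex, ...) pass through untouched.
    """
    df = pd.read_csv(source, dtype={"id": str})
    for col in ("id", "actn3", "ace"):
        if col not in df.columns:
            raise ValidationError(f"genotype table: missing column {col!r}")
    dupes = df["id"][df["id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"genotype table: duplicate participant id(s) {dupes}")
    for col, vocab in (("actn3", ACTN3_GENOTYPES), ("ace", ACE_GENOTYPES)):
        bad = ~df[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"genotype table row {row}: invalid {col} genotype {df[col].iloc[row]!r}"
            )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# results tables


def write_results_table(results, dest) -> None:
    """Write a results collection as CSV, deterministically.

    ``results`` may be a DataFrame or an iterable of mappings (dict rows).
    Column order is preserved from the input (first-seen order for dict rows);
    floats are printed with 12 significant digits so write -> read round-trips
    to that precision and repeated writes are byte-identical.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = list(results)
        df = pd.DataFrame(rows)
    buf = io.StringIO()
    df.to_csv(buf, index=False, float_format="%.12g", lineterminator="\n")
    text = buf.getvalue()
    fh, owned = _open(dest, "w")
    try:
        fh.write(text)
    finally:
        if owned:
            fh.close()


def read_results_table(source) -> pd.DataFrame:
    return pd.read_csv(source)
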