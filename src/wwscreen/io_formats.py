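"""Readers and writers for spectral (msp, mgf) and tabular pipeline files.

The msp dialect is NIST-style ``Name:`` / ``PrecursorMZ:`` / ``Num Peaks:``
blocks; mgf follows Mascot ``BEGIN IONS``/``END IONS`` conventions.  Both are
written so that reading back reproduces the in-memory object field by field,
including free-form header keys, which are kept verbatim in ``annotations``.

Tables (features, suspect list, calibration series, internal standards,
excretion records) are UTF-8 comma- or tab-delimited files with a mandatory
header row; the delimiter is sniffed.  Unknown extra columns are preserved.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .registry import SuspectEntry

MZ_MIN, MZ_MAX = 0.0, 10000.0


class SpectrumFormatError(ValueError):
    """Raised for malformed spectral files; names the record and line."""


class TableSchemaError(ValueError):
    """Raised when a delimited table does not match its declared schema."""


@dataclass
class Spectrum:
    """A centroided MS2 spectrum.

    Peaks are kept sorted ascending by m/z; intensities are arbitrary counts.
    """

    identifier: str
    precursor_mz: float
    polarity: str = "positive"
    rt: float | None = None  # minutes
    peaks: list[tuple[float, float]] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise ValueError(f"{self.identifier}: precursor_mz must be positive")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"{self.identifier}: unknown polarity {self.polarity!r}")
        for mz, inten in self.peaks:
            if not (MZ_MIN < mz < MZ_MAX):
                raise ValueError(f"{self.identifier}: peak m/z {mz} out of range")
            if inten < 0:
                raise ValueError(f"{self.identifier}: negative intensity {inten}")
        self.peaks = sorted(self.peaks, key=lambda p: (p[0], p[1]))

    @property
    def mz(self) -> list[float]:
        return [p[0] for p in self.peaks]

    @property
    def intensity(self) -> list[float]:
        return [p[1] for p in self.peaks]


@dataclass(frozen=True)
class FeatureRecord:
    """One MS1 peak in one sample: m/z, RT (min), intensity, quality rating."""

    mz: float
    rt: float
    sample_id: str
    intensity: float
    peak_rating: float = 10.0

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.intensity < 0:
            raise ValueError("feature intensity must be nonnegative")
        if not (0.0 <= self.peak_rating <= 10.0):
            raise ValueError("peak_rating must be in [0, 10]")


def _fmt_mz(value: float) -> str:
    """Shortest exact decimal, padded to at least 5 decimal places."""
    s = repr(float(value))
    if "e" in s or "E" in s:
        return f"{value:.6f}"
    decimals = len(s.split(".")[1]) if "." in s else 0
    return s if decimals >= 5 else f"{value:.5f}"


def _fmt_num(value: float) -> str:
    s = repr(float(value))
    return s[:-2] if s.endswith(".0") else s


# ---------------------------------------------------------------------------
# msp (NIST-style)

_MSP_RESERVED = ("name", "precursormz", "precursor_mz", "ion_mode",
                 "ionmode", "retentiontime", "rt", "num peaks")


def _polarity_from_text(text: str) -> str:
    t = text.strip().lower()
    if t in ("positive", "pos", "p", "+", "1"):
        return "positive"
    if t in ("negative", "neg", "n", "-", "-1"):
        return "negative"
    raise ValueError(f"cannot interpret ion mode {text!r}")


def _parse_msp_blocks(lines: list[str], source: str) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    n_expected: int | None = None
    record_index = 0

    def flush(lineno: int) -> None:
        nonlocal header, peaks, n_expected, record_index
        if not header and not peaks:
            return
        if "Name" not in header:
            raise SpectrumFormatError(
                f"{source}: record {record_index} ending at line {lineno} has no Name"
            )
        if "PrecursorMZ" not in header:
            raise SpectrumFormatError(
                f"{source}: record {record_index} ({header.get('Name')}) "
                "has no PrecursorMZ"
            )
        if n_expected is not None and n_expected != len(peaks):
            raise SpectrumFormatError(
                f"{source}: record {record_index} declares {n_expected} peaks "
                f"but {len(peaks)} were read (line {lineno})"
            )
        ann = {
            k: v
            for k, v in header.items()
            if k.lower() not in _MSP_RESERVED
        }
        spectra.append(
            Spectrum(
                identifier=header["Name"],
                precursor_mz=float(header["PrecursorMZ"]),
                polarity=_polarity_from_text(header.get("Ion_mode", "positive")),
                rt=float(header["RetentionTime"]) if "RetentionTime" in header else None,
                peaks=peaks,
                annotations=ann,
            )
        )
        header, peaks, n_expected = {}, [], None
        record_index += 1

    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if ":" in line and not line.split(":", 1)[0].strip().replace(".", "").isdigit():
            key, value = line.split(":", 1)
            key, value = key.strip(), value.strip()
            if key.lower() == "num peaks":
                try:
                    n_expected = int(value)
                except ValueError as exc:
                    raise SpectrumFormatError(
                        f"{source}: record {record_index}, line {lineno}: "
                        f"bad Num Peaks value {value!r}"
                    ) from exc
            else:
                header[key] = value
        else:
            parts = line.replace("\t", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{source}: record {record_index}, line {lineno}: "
                    f"cannot parse peak line {line!r}"
                )
            try:
                peaks.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{source}: record {record_index}, line {lineno}: "
                    f"non-numeric peak {line!r}"
                ) from exc
    flush(len(lines) + 1)
    return spectra


def _write_msp(spectra: list[Spectrum], handle: io.TextIOBase) -> None:
    for sp in spectra:
        handle.write(f"Name: {sp.identifier}\n")
        handle.write(f"PrecursorMZ: {_fmt_mz(sp.precursor_mz)}\n")
        handle.write(f"Ion_mode: {sp.polarity}\n")
        if sp.rt is not None:
            handle.write(f"RetentionTime: {_fmt_num(sp.rt)}\n")
        for key, value in sp.annotations.items():
            handle.write(f"{key}: {value}\n")
        handle.write(f"Num Peaks: {len(sp.peaks)}\n")
        for mz, inten in sp.peaks:
            handle.write(f"{_fmt_mz(mz)} {_fmt_num(inten)}\n")
        handle.write("\n")


# ---------------------------------------------------------------------------
# mgf (Mascot generic format)

_MGF_RESERVED = ("title", "pepmass", "rtinseconds", "charge", "ion_mode", "ionmode")


def _parse_mgf(lines: list[str], source: str) -> list[Spectrum]:
    spectra: list[Spectrum] = []
    in_block = False
    header: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    record_index = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line == "BEGIN IONS":
            if in_block:
                raise SpectrumFormatError(
                    f"{source}: record {record_index}, line {lineno}: "
                    "nested BEGIN IONS"
                )
            in_block, header, peaks = True, {}, []
            continue
        if line == "END IONS":
            if not in_block:
                raise SpectrumFormatError(
                    f"{source}: line {lineno}: END IONS without BEGIN IONS"
                )
            if "PEPMASS" not in header:
                raise SpectrumFormatError(
                    f"{source}: record {record_index} has no PEPMASS"
                )
            charge = header.get("CHARGE", "1+")
            polarity = "negative" if charge.strip().endswith("-") else "positive"
            if "ION_MODE" in header:
                polarity = _polarity_from_text(header["ION_MODE"])
            ann = {k: v for k, v in header.items() if k.upper() not in
                   (r.upper() for r in _MGF_RESERVED)}
            # mgf stores RT in seconds; round to 1e-6 min so the
            # minutes -> seconds -> minutes conversion is exact
            rt = (
                round(float(header["RTINSECONDS"]) / 60.0, 6)
                if "RTINSECONDS" in header
                else None
            )
            spectra.append(
                Spectrum(
                    identifier=header.get("TITLE", f"spectrum_{record_index}"),
                    precursor_mz=float(header["PEPMASS"].split()[0]),
                    polarity=polarity,
                    rt=rt,
                    peaks=peaks,
                    annotations=ann,
                )
            )
            in_block = False
            record_index += 1
            continue
        if not in_block:
            raise SpectrumFormatError(
                f"{source}: line {lineno}: content outside BEGIN IONS block: {line!r}"
            )
        if "=" in line and not line.split("=", 1)[0].strip().replace(".", "").isdigit():
            key, value = line.split("=", 1)
            header[key.strip()] = value.strip()
        else:
            parts = line.replace("\t", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{source}: record {record_index}, line {lineno}: "
                    f"cannot parse peak line {line!r}"
                )
            try:
                peaks.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumFormatError(
                    f"{source}: record {record_index}, line {lineno}: "
                    f"non-numeric peak {line!r}"
                ) from exc
    if in_block:
        raise SpectrumFormatError(
            f"{source}: record {record_index}: unterminated BEGIN IONS block"
        )
    return spectra


def _write_mgf(spectra: list[Spectrum], handle: io.TextIOBase) -> None:
    for sp in spectra:
        handle.write("BEGIN IONS\n")
        handle.write(f"TITLE={sp.identifier}\n")
        handle.write(f"PEPMASS={_fmt_mz(sp.precursor_mz)}\n")
        handle.write(f"CHARGE=1{'+' if sp.polarity == 'positive' else '-'}\n")
        handle.write(f"ION_MODE={sp.polarity}\n")
        if sp.rt is not None:
            handle.write(f"RTINSECONDS={_fmt_num(sp.rt * 60.0)}\n")
        for key, value in sp.annotations.items():
            handle.write(f"{key}={value}\n")
        for mz, inten in sp.peaks:
            handle.write(f"{_fmt_mz(mz)} {_fmt_num(inten)}\n")
        handle.write("END IONS\n")


# ---------------------------------------------------------------------------
# public spectral API

def read_spectra(path: str | os.PathLike, format: str | None = None) -> list[Spectrum]:
    """Read a spectral library file; ``format`` in {"msp", "mgf"} (inferred
    from the extension when omitted).  Peak lists are normalized to ascending
    m/z order; unknown header keys survive in ``annotations``."""
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt not in ("msp", "mgf"):
        raise ValueError(f"unknown spectral format {fmt!r}")
    with open(path, encoding="utf-8") as handle:
        lines = handle.readlines()
    if not any(line.strip() for line in lines):
        warnings.warn(f"{path}: empty spectral file", stacklevel=2)
        return []
    if fmt == "msp":
        return _parse_msp_blocks(lines, str(path))
    return _parse_mgf(lines, str(path))


def write_spectra(
    spectra: list[Spectrum], path: str | os.PathLike, format: str | None = None
) -> None:
    """Write spectra such that :func:`read_spectra` reproduces them exactly."""
    fmt = format or os.path.splitext(str(path))[1].lstrip(".").lower()
    if fmt not in ("msp", "mgf"):
        raise ValueError(f"unknown spectral format {fmt!r}")
    with open(path, "w", encoding="utf-8") as handle:
        if fmt == "msp":
            _write_msp(spectra, handle)
        else:
            _write_mgf(spectra, handle)


# ---------------------------------------------------------------------------
# delimited tables

#: schema name -> (required columns, {optional column: default})
TABLE_SCHEMAS: dict[str, tuple[list[str], dict[str, object]]] = {
    "features": (
        ["sample_id", "mz", "rt", "intensity"],
        {"peak_rating": 10.0},
    ),
    "suspects": (
        ["name", "formula", "parent_name", "phase"],
        {
            "biotransformation": None,
            "logD_pos": None,
            "logD_neg": None,
            "excretion_fraction": None,
        },
    ),
    "calibration": (
        ["analyte", "level_conc", "analyte_area"],
        {"ilis_area": None},
    ),
    "ilis": (
        ["ilis_id", "mz", "rt", "spike_conc"],
        {"target": None, "relative_recovery": None},
    ),
    "excretion": (
        ["parent", "compound", "phase", "molar_fraction", "mw"],
        {"back_cleavable": False},
    ),
}

_NUMERIC_COLUMNS = {
    "mz", "rt", "intensity", "peak_rating", "logD_pos", "logD_neg",
    "excretion_fraction", "level_conc", "analyte_area", "ilis_area",
    "spike_conc", "relative_recovery", "molar_fraction", "mw",
}


def read_table(path: str | os.PathLike, schema: str) -> pd.DataFrame:
    """Read a delimited table and validate it against a named schema.

    The delimiter (comma or tab) is sniffed from the header line.  Missing
    optional columns are filled with their declared defaults; extra columns
    are preserved.  Raises :class:`TableSchemaError` naming the first missing
    required column or the first non-numeric cell in a numeric column.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown table schema {schema!r}")
    required, optional = TABLE_SCHEMAS[schema]
    with open(path, encoding="utf-8") as handle:
        header_line = handle.readline()
    sep = "\t" if header_line.count("\t") >= header_line.count(",") and "\t" in header_line else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise TableSchemaError(
                f"{path}: schema {schema!r} requires column {col!r}"
            )
    for col, default in optional.items():
        if col not in df.columns:
            df[col] = default
    for col in df.columns:
        if col in _NUMERIC_COLUMNS and df[col].dtype == object:
            values = df[col].map(lambda v: v.strip() if isinstance(v, str) else v)
            values = values.replace("", None)

            def to_float(v):
                # full-precision parse (pandas' fast path rounds the last ULP)
                if v is None:
                    return float("nan")
                try:
                    return float(v)
                except (TypeError, ValueError):
                    return float("nan")

            converted = values.map(to_float).astype(float)
            bad = converted.isna() & values.notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based, plus header
                raise TableSchemaError(
                    f"{path}: non-numeric value {values[bad.idxmax()]!r} in "
                    f"numeric column {col!r} at line {row}"
                )
            df[col] = converted
        elif col == "back_cleavable" and df[col].dtype == object:
            df[col] = df[col].map(
                lambda v: str(v).strip().lower() in ("true", "1", "yes")
            )
    return df


def write_table(df: pd.DataFrame, path: str | os.PathLike, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def features_from_table(df: pd.DataFrame) -> list[FeatureRecord]:
    rating = df["peak_rating"].fillna(10.0)
    return [
        FeatureRecord(
            mz=float(row.mz),
            rt=float(row.rt),
            sample_id=str(row.sample_id),
            intensity=float(row.intensity),
            peak_rating=float(rating.iloc[i]),
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def suspects_from_table(df: pd.DataFrame) -> list[SuspectEntry]:
    entries = []
    known = {"name", "formula", "parent_name", "phase", "biotransformation",
             "logD_pos", "logD_neg", "excretion_fraction"}
    extra_cols = [c for c in df.columns if c not in known]
    for _, row in df.iterrows():

        def opt_num(col: str) -> float | None:
            v = row[col]
            return None if pd.isna(v) else float(v)

        parent = row["parent_name"] if row["parent_name"] not in ("", None) else None
        biot = row["biotransformation"]
        entries.append(
            SuspectEntry(
                name=str(row["name"]),
                formula=str(row["formula"]),
                parent_name=parent,
                phase=str(row["phase"]),
                biotransformation=None if biot in ("", None) else str(biot),
                logD_pos=opt_num("logD_pos"),
                logD_neg=opt_num("logD_neg"),
                excretion_fraction=opt_num("excretion_fraction"),
                annotations={c: row[c] for c in extra_cols},
            )
        )
    return entries


def suspects_to_table(entries: list[SuspectEntry]) -> pd.DataFrame:
    rows = []
    for e in entries:
        rows.append(
            {
                "name": e.name,
                "formula": e.formula,
                "parent_name": e.parent_name or "",
                "phase": e.phase,
                "biotransformation": e.biotransformation or "",
                "logD_pos": e.logD_pos,
                "logD_neg": e.logD_neg,
                "excretion_fraction": e.excretion_fraction,
                **e.annotations,
            }
        )
    return pd.DataFrame(rows)
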