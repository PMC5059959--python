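"""Reading and writing peak lists, peak tables and sample manifests.

A *peak list* is one centroided MALDI-TOF measurement of one serum sample:
paired (m/z, intensity) values.  A *peak table* is the aligned matrix form —
one row per reference ion, one intensity column per sample-measurement —
with per-column metadata (sample id, class label, training-set assignment,
replicate index).

Supported on-disk forms are delimited text (``tsv``/``csv``) and read-only
centroided mzML (a minimal built-in decoder for the standard binary data
arrays).  Peak tables serialize to a wide
CSV with a leading ``mz`` column, one column per measurement, and the column
metadata in ``#``-prefixed header lines so a round trip is lossless.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RawSpectrum",
    "PeakTable",
    "PeakListError",
    "PeakTableFormatError",
    "read_peaklist",
    "write_peaklist",
    "apply_import_filters",
    "read_peak_table",
    "write_peak_table",
    "read_manifest",
    "write_manifest",
]

#: Metadata fields attached to every peak-table column.
COLUMN_FIELDS = ("sample_id", "label", "set", "replicate")

#: Valid training-set assignments ("none" = unassigned).
SET_LABELS = ("A1", "A2", "B", "none")


class PeakListError(ValueError):
    """Malformed or empty peak-list input."""


class PeakTableFormatError(ValueError):
    """Peak-table file does not match the expected schema."""


@dataclass(frozen=True)
class RawSpectrum:
    """One measurement of one sample: ascending m/z with intensities.

    Invariants (enforced at construction): ``mz`` strictly ascending and
    positive, ``intensity`` non-negative, equal lengths.  Use
    :meth:`from_unsorted` for raw inputs that may be unsorted or contain
    duplicate m/z entries (duplicates are merged by intensity sum).
    """

    sample_id: str
    replicate_index: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise PeakListError(
                f"{self.sample_id}: m/z and intensity lengths differ "
                f"({mz.size} vs {inten.size})"
            )
        if mz.size and np.any(np.diff(mz) <= 0):
            raise PeakListError(f"{self.sample_id}: m/z values not strictly ascending")
        if mz.size and mz[0] <= 0:
            raise PeakListError(f"{self.sample_id}: non-positive m/z value")
        if np.any(inten < 0):
            raise PeakListError(f"{self.sample_id}: negative intensity")

    def __len__(self) -> int:
        return int(self.mz.size)

    @classmethod
    def from_unsorted(
        cls, sample_id: str, replicate_index: int, mz, intensity
    ) -> "RawSpectrum":
        """Build a spectrum from possibly unsorted peaks, merging duplicate m/z."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        if mz.size:
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, intensity)
            mz, intensity = uniq, summed
        return cls(sample_id, replicate_index, mz, intensity)


@dataclass
class PeakTable:
    """Aligned intensity matrix on a common reference m/z axis.

    ``intensities`` has shape ``(len(axis_mz), n_columns)``; ``columns`` is a
    DataFrame with one row per intensity column carrying ``sample_id``,
    ``label`` (class), ``set`` (A1/A2/B/none) and ``replicate``.
    """

    axis_mz: np.ndarray
    intensities: np.ndarray
    columns: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.axis_mz = np.asarray(self.axis_mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise PeakTableFormatError("intensities must be a 2-D matrix")
        if self.intensities.shape[0] != self.axis_mz.size:
            raise PeakTableFormatError(
                f"matrix has {self.intensities.shape[0]} rows but axis has "
                f"{self.axis_mz.size} ions"
            )
        if self.axis_mz.size and np.any(np.diff(self.axis_mz) <= 0):
            raise PeakTableFormatError("axis m/z not strictly ascending")
        if len(self.columns) != self.intensities.shape[1]:
            raise PeakTableFormatError(
                f"{len(self.columns)} metadata rows for "
                f"{self.intensities.shape[1]} columns"
            )
        missing = [f for f in COLUMN_FIELDS if f not in self.columns.columns]
        if missing and self.n_columns:
            raise PeakTableFormatError(f"column metadata missing fields {missing}")
        if self.columns.index.size and not (
            self.columns.index == np.arange(len(self.columns))
        ).all():
            self.columns = self.columns.reset_index(drop=True)

    @property
    def n_ions(self) -> int:
        return int(self.axis_mz.size)

    @property
    def n_columns(self) -> int:
        return int(self.intensities.shape[1])

    def select(self, mask) -> "PeakTable":
        """Sub-table with the columns selected by a boolean mask / index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return PeakTable(
            self.axis_mz.copy(),
            self.intensities[:, idx].copy(),
            self.columns.iloc[idx].reset_index(drop=True),
        )

    def copy(self) -> "PeakTable":
        return PeakTable(
            self.axis_mz.copy(), self.intensities.copy(), self.columns.copy()
        )

    def equals(self, other: "PeakTable", rtol: float = 0.0) -> bool:
        return (
            np.array_equal(self.axis_mz, other.axis_mz)
            if rtol == 0.0
            else np.allclose(self.axis_mz, other.axis_mz, rtol=rtol)
        ) and (
            np.array_equal(self.intensities, other.intensities)
            if rtol == 0.0
            else np.allclose(self.intensities, other.intensities, rtol=rtol)
        ) and self.columns[list(COLUMN_FIELDS)].equals(
            other.columns[list(COLUMN_FIELDS)]
        )


# ---------------------------------------------------------------------------
# Peak lists


def read_peaklist(
    path,
    dialect: str = "tsv",
    sample_id: str | None = None,
    replicate_index: int = 1,
) -> RawSpectrum:
    """Read one centroided peak list.

    ``dialect`` is ``tsv``, ``csv`` or ``mzml``.  Text dialects expect two
    numeric columns (m/z, intensity); a ``mz``/``m/z`` header line is allowed
    and skipped.  Peaks are returned sorted ascending by m/z with duplicate
    m/z entries merged by intensity sum.
    """
    path = str(path)
    if sample_id is None:
        sample_id = path.rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if dialect == "mzml":
        return _read_mzml(path, sample_id, replicate_index)
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    mzs: list[float] = []
    intens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep)
            if lineno == 1 and parts and parts[0].lower().lstrip('"') .rstrip('"') in (
                "mz",
                "m/z",
                "mass",
            ):
                continue
            if len(parts) < 2:
                raise PeakListError(f"{path}:{lineno}: expected two columns")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: {exc}") from None
    if not mzs:
        raise PeakListError(f"{path}: empty peak list")
    return RawSpectrum.from_unsorted(sample_id, replicate_index, mzs, intens)


def _read_mzml(path: str, sample_id: str, replicate_index: int) -> RawSpectrum:
    """Minimal reader for centroided mzML: binary data arrays only.

    Decodes the m/z and intensity ``binaryDataArray`` elements (64/32-bit
    floats, no compression or zlib) of every spectrum and pools the peaks.
    Deliberately small in scope: no chromatograms, no indexed wrappers
    beyond tag stripping, no numpress codecs.
    """
    import base64
    import xml.etree.ElementTree as ET
    import zlib

    def local(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for _, elem in ET.iterparse(path, events=("end",)):
        if local(elem.tag) != "spectrum":
            continue
        arrays: dict[str, np.ndarray] = {}
        for bda in elem.iter():
            if local(bda.tag) != "binaryDataArray":
                continue
            accessions = {
                child.get("accession")
                for child in bda.iter()
                if local(child.tag) == "cvParam"
            }
            kind = (
                "mz"
                if "MS:1000514" in accessions
                else "intensity"
                if "MS:1000515" in accessions
                else None
            )
            if kind is None:
                continue
            binary = next(
                (c for c in bda.iter() if local(c.tag) == "binary"), None
            )
            raw = base64.b64decode(binary.text or "") if binary is not None else b""
            if "MS:1000574" in accessions:  # zlib compression
                raw = zlib.decompress(raw)
            dtype = "<f4" if "MS:1000521" in accessions else "<f8"
            arrays[kind] = np.frombuffer(raw, dtype=dtype).astype(float)
        if "mz" in arrays and "intensity" in arrays:
            mzs.append(arrays["mz"])
            intens.append(arrays["intensity"])
        elem.clear()
    if not mzs or sum(a.size for a in mzs) == 0:
        raise PeakListError(f"{path}: no centroided peaks found")
    return RawSpectrum.from_unsorted(
        sample_id, replicate_index, np.concatenate(mzs), np.concatenate(intens)
    )


def write_peaklist(spectrum: RawSpectrum, path, dialect: str = "tsv") -> None:
    """Write a two-column delimited peak list (full float64 precision)."""
    sep = "\t" if dialect == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"mz{sep}intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r}{sep}{float(i)!r}\n")


def apply_import_filters(
    spectrum: RawSpectrum, min_response: float = 10.0, max_peaks: int = 10000
) -> RawSpectrum:
    """Apply the two import filters: response threshold and peak-count cap.

    Peaks with intensity >= ``min_response`` are kept (threshold inclusive);
    if more than ``max_peaks`` survive, the most intense are retained, with
    ties at the boundary broken toward lower m/z.  The output stays sorted by
    m/z.  The operation is idempotent.
    """
    if min_response < 0:
        raise ValueError("min_response must be >= 0")
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    keep = spectrum.intensity >= min_response
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size > max_peaks:
        # Sort by (-intensity, mz): stable preference for lower m/z at ties.
        order = np.lexsort((mz, -inten))[:max_peaks]
        order.sort()  # restore m/z ordering
        mz, inten = mz[order], inten[order]
    return replace(spectrum, mz=mz, intensity=inten)


# ---------------------------------------------------------------------------
# Peak tables


def write_peak_table(table: PeakTable, path) -> None:
    """Serialize a peak table to wide CSV.

    Layout: four ``#`` metadata lines (sample_id, label, set, replicate), a
    header line ``mz,<col ids>``, then one row per reference ion.  Floats are
    written with ``repr`` so the round trip is exact for float64.
    """
    buf = io.StringIO()
    n = table.n_columns
    for fname in COLUMN_FIELDS:
        vals = (
            [str(v) for v in table.columns[fname]] if n else []
        )
        buf.write("#" + fname + "," + ",".join(vals) + "\n")
    ids = [
        f"{sid}:{rep}"
        for sid, rep in zip(
            table.columns.get("sample_id", []), table.columns.get("replicate", [])
        )
    ]
    buf.write("mz," + ",".join(ids) + "\n")
    for i in range(table.n_ions):
        row = ",".join(repr(float(v)) for v in table.intensities[i])
        buf.write(repr(float(table.axis_mz[i])) + ("," + row if n else row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_peak_table(path) -> PeakTable:
    """Read a peak table written by :func:`write_peak_table`."""
    meta: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines) and lines[pos].startswith("#"):
        key, _, rest = lines[pos][1:].partition(",")
        meta[key] = rest.split(",") if rest else []
        pos += 1
    missing = [f for f in COLUMN_FIELDS if f not in meta]
    if missing:
        raise PeakTableFormatError(f"{path}: missing metadata lines {missing}")
    if pos >= len(lines) or not lines[pos].startswith("mz"):
        raise PeakTableFormatError(f"{path}: missing 'mz' header line")
    pos += 1
    n_cols = len(meta["sample_id"]) if meta["sample_id"] != [""] else 0
    if meta["sample_id"] == [""]:
        n_cols = 0
    axis: list[float] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[pos:], start=pos + 1):
        if not line:
            continue
        parts = line.split(",")
        if len(parts) != n_cols + 1:
            raise PeakTableFormatError(
                f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(parts)}"
            )
        axis.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    columns = pd.DataFrame(
        {
            "sample_id": meta["sample_id"][:n_cols],
            "label": meta["label"][:n_cols],
            "set": meta["set"][:n_cols],
            "replicate": [int(v) for v in meta["replicate"][:n_cols]],
        }
    )
    matrix = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, n_cols))
    )
    if matrix.size == 0 and rows:
        matrix = matrix.reshape(len(rows), n_cols)
    return PeakTable(np.asarray(axis, dtype=float), matrix.reshape(len(axis), n_cols), columns)


# ---------------------------------------------------------------------------
# Manifests


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Write the sample manifest (sample_id, label, replicate, set, path)."""
    cols = [c for c in ("sample_id", "label", "replicate", "set", "path", "stage") if c in manifest.columns]
    manifest[cols].to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    manifest = pd.read_csv(path, dtype={"sample_id": str, "label": str})
    required = {"sample_id", "label", "replicate"}
    missing = required - set(manifest.columns)
    if missing:
        raise PeakTableFormatError(f"{path}: manifest missing columns {sorted(missing)}")
    if "set" not in manifest.columns:
        manifest["set"] = "none"
    return manifest
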