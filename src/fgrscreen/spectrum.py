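"""Profile mass-spectrum container and file I/O.

A :class:`Spectrum` holds one linear-mode MALDI-ToF profile spectrum —
paired m/z (Da) and intensity (arbitrary units) arrays — together with the
patient / measurement-series / cohort annotations the cohort analysis needs.

Two on-disk formats are supported:

* two-column whitespace-delimited text (``m/z intensity``), annotations
  encoded in the filename as ``<patient>_<series>_<cohort>.txt``;
* mzML, written by :func:`write_mzml` (uncompressed 64-bit float binary
  arrays, annotations as userParams) and read by an lxml-based reader that
  handles 32/64-bit float arrays with or without zlib compression.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import numpy as np
from lxml import etree

from .errors import FormatError

__all__ = [
    "Spectrum",
    "read_spectrum",
    "write_spectrum",
    "read_mzml",
    "write_mzml",
]


@dataclass
class Spectrum:
    """One profile mass spectrum with optional cohort annotations.

    Invariants (checked on construction): equal-length arrays of at least
    two points, strictly increasing m/z, non-negative intensities.
    """

    mz: np.ndarray
    intensity: np.ndarray
    patient_id: str | None = None
    series_id: str | None = None
    cohort: str | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("m/z and intensity must be one-dimensional arrays")
        if len(self.mz) != len(self.intensity):
            raise FormatError(
                f"length mismatch: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.mz) < 2:
            raise FormatError("a spectrum needs at least two data points")
        if not np.all(np.diff(self.mz) > 0):
            raise FormatError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise FormatError("intensities must be non-negative")

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def spectrum_id(self) -> str:
        """Stable identifier ``<patient>/<series>`` used in output tables."""
        return f"{self.patient_id or 'NA'}/{self.series_id or 'NA'}"

    def with_mz(self, new_mz: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with a replaced (e.g. recalibrated) m/z axis."""
        return replace(self, mz=np.asarray(new_mz, dtype=float))

    def scaled(self, k: float) -> "Spectrum":
        """Copy with all intensities multiplied by ``k`` (k > 0)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        return replace(self, intensity=self.intensity * k)


def _annotations_from_filename(path: Path) -> dict:
    """Parse ``<patient>_<series>_<cohort>`` from a file stem; missing parts
    stay None. This is the convention the simulator uses when writing."""
    parts = path.stem.split("_")
    keys = ("patient_id", "series_id", "cohort")
    return {k: (parts[i] if i < len(parts) else None) for i, k in enumerate(keys)}


# ---------------------------------------------------------------------------
# two-column text
# ---------------------------------------------------------------------------

def _read_xy(path: Path) -> Spectrum:
    try:
        data = np.loadtxt(path, dtype=float, ndmin=2)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse two-column text file {path}: {exc}") from exc
    if data.shape[1] != 2:
        raise FormatError(f"{path}: expected two columns, got {data.shape[1]}")
    return Spectrum(data[:, 0], data[:, 1], **_annotations_from_filename(path))


def _write_xy(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, i in zip(spectrum.mz.tolist(), spectrum.intensity.tolist()):
            fh.write(f"{m!r} {i!r}\n")


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_MZML_HEADER = (
    '<?xml version="1.0" encoding="utf-8"?>\n'
    '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
    '  <cvList count="1">\n'
    '    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
    ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
    "  </cvList>\n"
    '  <run id="run">\n'
)


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


def _binary_array_xml(values: np.ndarray, array_cv: tuple[str, str]) -> str:
    b64 = _encode_array(values)
    accession, name = array_cv
    return (
        f'        <binaryDataArray encodedLength="{len(b64)}">\n'
        '          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f'          <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>\n'
        f"          <binary>{b64}</binary>\n"
        "        </binaryDataArray>\n"
    )


def write_mzml(spectra: list[Spectrum] | Spectrum, path) -> None:
    """Write one or several spectra to a minimal mzML 1.1.0 document.

    Arrays are stored as uncompressed little-endian 64-bit floats;
    annotations are stored as userParams so that generic readers surface
    them by name.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    path = Path(path)
    chunks = [_MZML_HEADER, f'    <spectrumList count="{len(spectra)}">\n']
    for idx, sp in enumerate(spectra):
        chunks.append(
            f'      <spectrum index="{idx}" id={quoteattr(f"scan={idx + 1}")}'
            f' defaultArrayLength="{len(sp)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>\n'
        )
        for key in ("patient_id", "series_id", "cohort"):
            value = getattr(sp, key)
            if value is not None:
                chunks.append(
                    f'        <userParam name="{key}" value="{escape(str(value))}"/>\n'
                )
        chunks.append('        <binaryDataArrayList count="2">\n')
        chunks.append(_binary_array_xml(sp.mz, ("MS:1000514", "m/z array")))
        chunks.append(_binary_array_xml(sp.intensity, ("MS:1000515", "intensity array")))
        chunks.append("        </binaryDataArrayList>\n      </spectrum>\n")
    chunks.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(chunks), encoding="utf-8")


def _decode_binary_array(node) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>; returns (array kind, values)."""
    accessions = {
        cv.get("accession") for cv in node.iter("{*}cvParam")
    }
    kind = None
    if "MS:1000514" in accessions:
        kind = "mz"
    elif "MS:1000515" in accessions:
        kind = "intensity"
    binary = node.find("{*}binary")
    raw = base64.b64decode((binary.text or "").encode("ascii"))
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[Spectrum]:
    """Read all spectra from an mzML file."""
    try:
        tree = etree.parse(str(path))
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse mzML file {path}: {exc}") from exc
    spectra = []
    for node in tree.iter("{*}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for bda in node.iter("{*}binaryDataArray"):
            kind, values = _decode_binary_array(bda)
            if kind is not None:
                arrays[kind] = values
        if "mz" not in arrays or "intensity" not in arrays:
            raise FormatError(
                f"{path}: spectrum {node.get('id')!r} lacks m/z or intensity array"
            )
        annotations = {
            up.get("name"): up.get("value")
            for up in node.iter("{*}userParam")
            if up.get("name") in ("patient_id", "series_id", "cohort")
        }
        spectra.append(Spectrum(arrays["mz"], arrays["intensity"], **annotations))
    if not spectra:
        raise FormatError(f"{path}: no spectra found")
    return spectra


# ---------------------------------------------------------------------------
# format dispatch
# ---------------------------------------------------------------------------

def read_spectrum(path, format: str = "auto") -> Spectrum:
    """Read a single spectrum from ``path``.

    ``format`` is one of ``mzml``, ``xy_text`` or ``auto`` (by extension:
    ``.mzml`` → mzML, anything else → two-column text). For multi-spectrum
    mzML files the first spectrum is returned; use :func:`read_mzml` for all.
    """
    path = Path(path)
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy_text"
    if format == "mzml":
        return read_mzml(path)[0]
    if format == "xy_text":
        return _read_xy(path)
    raise ValueError(f"unknown spectrum format: {format!r}")


def write_spectrum(spectrum: Spectrum, path, format: str = "auto") -> None:
    """Write one spectrum; format resolution mirrors :func:`read_spectrum`."""
    path = Path(path)
    if format == "auto":
        format = "mzml" if path.suffix.lower() == ".mzml" else "xy_text"
    if format == "mzml":
        write_mzml(spectrum, path)
    elif format == "xy_text":
        _write_xy(spectrum, path)
    else:
        raise ValueError(f"unknown spectrum format: {format!r}")
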