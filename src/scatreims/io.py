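"""Readers, writers and pipeline configuration.

Scan series travel as centroided mzML (one file per acquisition, readable
by any MS toolchain) or as a compact JSON-lines format; feature matrices
and label tables are plain CSV; pipeline configuration is YAML with an
exact read -> write -> read round trip.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd
import yaml

from .classify import FeatureMatrix
from .spectra import BinGrid, PeakList, ScanSeries

# ---------------------------------------------------------------------------
# mzML

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
"""


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def _binary_array_xml(values: np.ndarray, kind: str) -> str:
    if kind == "mz":
        name_param = (
            '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        )
    else:
        name_param = (
            '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
        )
    payload = _b64_doubles(values)
    return (
        f'<binaryDataArray encodedLength="{len(payload)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f"{name_param}<binary>{payload}</binary></binaryDataArray>"
    )


def write_mzml(series: ScanSeries, path: str | Path) -> None:
    """Write one acquisition as centroided negative-mode mzML."""
    path = Path(path)
    mode_acc, mode_name = (
        ("MS:1000129", "negative scan")
        if series.polarity == "negative"
        else ("MS:1000130", "positive scan")
    )
    parts = [_MZML_HEADER]
    run_id = str(series.meta.get("pellet_id", series.meta.get("sample_id", "run")))
    parts.append(f"  <run id={quoteattr(run_id)}>\n")
    parts.append(f'    <spectrumList count="{len(series)}">\n')
    for i, (t, scan) in enumerate(zip(series.times, series.scans)):
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{len(scan)}">\n'
            '        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>\n'
            f'        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>\n'
            '        <scanList count="1">\n'
            '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(t)!r}" '
            'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <binaryDataArrayList count="2">'
            f"{_binary_array_xml(scan.mz, 'mz')}"
            f"{_binary_array_xml(scan.intensity, 'intensity')}"
            "</binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append("    </spectrumList>\n  </run>\n</mzML>\n")
    path.write_text("".join(parts))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element) -> np.ndarray:
    dtype, decompress = np.float64, False
    payload = ""
    for child in bda.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession")
            if acc == "MS:1000521":  # 32-bit float
                dtype = np.float32
            elif acc == "MS:1000574":  # zlib compression
                decompress = True
        elif tag == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload)
    if decompress:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> ScanSeries:
    """Read a centroided mzML acquisition into a ScanSeries.

    A deliberately small reader for single-run MS1 mzML: scan times,
    polarity, and uncompressed or zlib base64 m/z / intensity arrays
    (32- or 64-bit). Profile-mode spectra are rejected — peak picking
    from raw profiles is outside this package's scope and must happen
    upstream.
    """
    path = Path(path)
    times, scans = [], []
    polarity = "negative"
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(
            f"failed to parse mzML file {path} at line/column {exc.position}: {exc}"
        ) from exc
    for spectrum in root.iter():
        if _local(spectrum.tag) != "spectrum":
            continue
        accessions = {
            el.get("accession"): el
            for el in spectrum.iter()
            if _local(el.tag) == "cvParam"
        }
        if "MS:1000128" in accessions:
            raise ValueError(
                f"{path}: profile-mode spectra are not supported; "
                "centroid the data upstream"
            )
        if "MS:1000130" in accessions:
            polarity = "positive"
        t = float(len(times))
        if "MS:1000016" in accessions:
            el = accessions["MS:1000016"]
            t = float(el.get("value"))
            if el.get("unitName") == "minute":
                t *= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spectrum.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            accs = {
                el.get("accession")
                for el in bda.iter()
                if _local(el.tag) == "cvParam"
            }
            try:
                values = _decode_binary_array(bda)
            except Exception as exc:
                raise ValueError(
                    f"{path}: undecodable binary data array: {exc}"
                ) from exc
            if "MS:1000514" in accs:
                arrays["mz"] = values
            elif "MS:1000515" in accs:
                arrays["intensity"] = values
        times.append(t)
        scans.append(
            PeakList(
                arrays.get("mz", np.empty(0)),
                arrays.get("intensity", np.empty(0)),
            )
        )
    return ScanSeries(
        times=np.asarray(times), scans=scans, polarity=polarity,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# JSON-lines scan format

def write_scans_jsonl(series: ScanSeries, path: str | Path) -> None:
    """Compact internal format: one header line, then one line per scan."""
    path = Path(path)
    header = {
        "format": "scatreims-scans",
        "polarity": series.polarity,
        "mz_range": list(series.mz_range),
        "meta": series.meta,
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for t, scan in zip(series.times, series.scans):
            fh.write(
                json.dumps(
                    {"t": float(t), "mz": scan.mz.tolist(), "i": scan.intensity.tolist()}
                )
                + "\n"
            )


def read_scans_jsonl(path: str | Path) -> ScanSeries:
    path = Path(path)
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("format") != "scatreims-scans":
            raise ValueError(f"{path} is not a scatreims scan file")
        times, scans = [], []
        for line in fh:
            rec = json.loads(line)
            times.append(rec["t"])
            scans.append(PeakList(np.asarray(rec["mz"]), np.asarray(rec["i"])))
    return ScanSeries(
        times=np.asarray(times),
        scans=scans,
        polarity=header["polarity"],
        mz_range=tuple(header["mz_range"]),
        meta=header.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# Feature matrix / labels CSV

def write_feature_matrix(matrix: FeatureMatrix, matrix_csv: str | Path,
                         labels_csv: str | Path) -> None:
    matrix.intensities.to_csv(matrix_csv, index_label="sample_id")
    matrix.labels.to_csv(labels_csv, index_label="sample_id")


def read_feature_matrix(matrix_csv: str | Path, labels_csv: str | Path) -> FeatureMatrix:
    """Rebuild a FeatureMatrix from CSV; the bin grid is inferred from columns."""
    intensities = pd.read_csv(matrix_csv, index_col="sample_id")
    labels = pd.read_csv(labels_csv, index_col="sample_id")
    if "sample_id" in labels.columns:
        labels = labels.drop(columns="sample_id")
    centers = np.array([float(c) for c in intensities.columns])
    if len(centers) < 2:
        raise ValueError("feature matrix must have at least two bins")
    width = round(float(np.median(np.diff(centers))), 6)
    grid = BinGrid(float(centers[0]), float(centers[-1]), width)
    if grid.n_points != len(centers):
        raise ValueError("matrix columns do not form a regular bin grid")
    return FeatureMatrix(intensities, labels.loc[intensities.index], grid)


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Parameters for the end-to-end synthetic experiment.

    Simulation settings feed the generator, preprocessing settings the
    vendor-equivalent chain, and classification/diagnostics settings the
    two analysis tracks. All randomness derives from ``seed``.
    """

    seed: int = 0
    # simulation
    classes: list[str] = field(
        default_factory=lambda: ["BV", "FV", "HM", "WM", "R"]
    )
    n_individuals_per_class: int = 20
    pellets_per_individual: int = 3
    # preprocessing
    lockmass: float = 554.26
    intensity_threshold: float = 3e5
    mz_start: float = 400.0
    mz_end: float = 1100.0
    bin_width: float = 0.1
    # classification
    target: str = "class"
    mode: str = "all_data"
    n_trees: int = 500
    # diagnostics
    top_k: int = 5
    r_min: float = 0.9
    n_shuffles: int = 0

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("classes must be non-empty")
        if self.bin_width <= 0 or self.mz_end <= self.mz_start:
            raise ValueError("invalid bin grid parameters")
        if self.intensity_threshold < 0 or self.n_trees < 1 or self.top_k < 1:
            raise ValueError("invalid numeric parameter")
        if self.mode not in ("all_data", "split_70_30"):
            raise ValueError(f"unknown classification mode {self.mode!r}")

    def grid(self) -> BinGrid:
        return BinGrid(self.mz_start, self.mz_end, self.bin_width)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
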