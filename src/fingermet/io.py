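"""Reading and writing spectra and feature matrices.

Two on-disk spectrum formats are supported:

* **mzML** (MS1, profile mode): a minimal, self-contained reader/writer
  pair.  The writer emits 64-bit uncompressed binary arrays with the
  standard CV terms; the reader decodes 32/64-bit float arrays with or
  without zlib compression, so it also accepts conformant files from
  other producers.  (Bioconductor's mzR serves as the cross-validation
  oracle for the writer in the test suite.)
* **CSV dialect**: a header column ``mz`` followed by one intensity
  column per sample; all samples share the m/z grid.

Feature matrices are CSVs whose first column is ``sample_id`` and whose
remaining columns are named by feature m/z to four decimals; a JSON
sidecar carries processing parameters and the seed.
"""

from __future__ import annotations

import base64
import json
import struct
import xml.etree.ElementTree as ET
import zlib
from pathlib import Path

import numpy as np

import pandas as pd

from .containers import MZ_WINDOW, FeatureMatrix, Spectrum


def read_spectra(path: str | Path, format: str | None = None,
                 window: tuple[float, float] = MZ_WINDOW) -> list[Spectrum]:
    """Read spectra from mzML or the CSV dialect; the m/z window is applied on read."""
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "mzml":
        spectra = _read_mzml(path)
    elif fmt == "csv":
        spectra = _read_csv(path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")
    return [s.windowed(*window) for s in spectra]


def write_spectra(spectra: list[Spectrum], path: str | Path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or ("mzml" if path.suffix.lower() == ".mzml" else "csv")
    if fmt == "mzml":
        _write_mzml(spectra, path)
    elif fmt == "csv":
        _write_csv(spectra, path)
    else:
        raise ValueError(f"unknown spectrum format {fmt!r}")


def _read_csv(path: Path) -> list[Spectrum]:
    df = pd.read_csv(path)
    if df.columns[0] != "mz":
        raise ValueError(f"{path}: first column must be 'mz', got {df.columns[0]!r}")
    mz = df["mz"].to_numpy(dtype=float)
    if mz.size >= 2 and not np.all(np.diff(mz) > 0):
        raise ValueError(f"{path}: mz column must be strictly increasing")
    out = []
    for col in df.columns[1:]:
        try:
            out.append(Spectrum(mz, df[col].to_numpy(dtype=float), sample_id=str(col)))
        except ValueError as e:
            raise ValueError(f"{path}: sample {col!r}: {e}") from e
    return out


def _write_csv(spectra: list[Spectrum], path: Path) -> None:
    if not spectra:
        raise ValueError("no spectra to write")
    mz = spectra[0].mz
    for s in spectra[1:]:
        if s.mz.shape != mz.shape or not np.allclose(s.mz, mz):
            raise ValueError("CSV dialect requires a shared m/z grid across samples")
    data = {"mz": mz}
    for s in spectra:
        data[s.sample_id or f"sample_{len(data)}"] = s.intensity
    pd.DataFrame(data).to_csv(path, index=False)


_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr)).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "") -> None:
    ET.SubElement(parent, "cvParam", cvRef="MS", accession=accession, name=name, value=value)


def _write_mzml(spectra: list[Spectrum], path: Path) -> None:
    """Minimal MS1 profile-mode mzML with 64-bit uncompressed arrays."""
    if not spectra:
        raise ValueError("no spectra to write")
    root = ET.Element("mzML", xmlns=_MZML_NS, version="1.1.0")
    ET.SubElement(root, "cvList", count="1")
    run = ET.SubElement(root, "run", id="run1")
    slist = ET.SubElement(run, "spectrumList", count=str(len(spectra)))
    for i, s in enumerate(spectra):
        sp = ET.SubElement(slist, "spectrum", index=str(i),
                           id=f"sample={s.sample_id or i}",
                           defaultArrayLength=str(s.mz.size))
        _cv(sp, "MS:1000511", "ms level", "1")
        _cv(sp, "MS:1000128", "profile spectrum")
        bdal = ET.SubElement(sp, "binaryDataArrayList", count="2")
        for arr, acc, name in ((s.mz, "MS:1000514", "m/z array"),
                               (s.intensity, "MS:1000515", "intensity array")):
            payload = _b64(arr)
            bda = ET.SubElement(bdal, "binaryDataArray", encodedLength=str(len(payload)))
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, acc, name)
            ET.SubElement(bda, "binary").text = payload
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: ET.Element, path: Path) -> tuple[str, np.ndarray]:
    dtype, compressed, kind, payload = "<d", False, None, ""
    for el in bda.iter():
        name = _local(el.tag)
        if name == "cvParam":
            acc = el.get("accession", "")
            if acc == "MS:1000523":
                dtype = "<d"
            elif acc == "MS:1000521":
                dtype = "<f"
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514":
                kind = "mz"
            elif acc == "MS:1000515":
                kind = "intensity"
        elif name == "binary":
            payload = el.text or ""
    raw = base64.b64decode(payload)
    if compressed:
        raw = zlib.decompress(raw)
    if kind is None:
        raise ValueError(f"{path}: binaryDataArray without an array-type cvParam")
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: Path) -> list[Spectrum]:
    """Minimal mzML reader: MS1 spectra, 32/64-bit float arrays, zlib or none."""
    out = []
    for _, el in ET.iterparse(str(path), events=("end",)):
        if _local(el.tag) != "spectrum":
            continue
        sid = el.get("id", "")
        if sid.startswith("sample="):
            sid = sid[len("sample="):]
        arrays: dict[str, np.ndarray] = {}
        for bda in el.iter():
            if _local(bda.tag) == "binaryDataArray":
                kind, arr = _decode_binary_array(bda, path)
                arrays[kind] = arr
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum {sid!r} lacks m/z or intensity array")
        mz, inten = arrays["mz"], arrays["intensity"]
        if mz.size >= 2 and not np.all(np.diff(mz) > 0):
            raise ValueError(f"{path}: spectrum {sid!r}: mz not strictly increasing")
        out.append(Spectrum(mz, np.clip(inten, 0, None), sample_id=sid))
        el.clear()
    if not out:
        raise ValueError(f"{path}: no spectra found")
    return out


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path,
                         params: dict | None = None) -> None:
    """Write a feature matrix CSV plus a JSON sidecar of processing parameters."""
    path = Path(path)
    df = matrix.to_dataframe()
    if matrix.labels is not None:
        df.insert(0, "group", matrix.labels)
    df.to_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(params or {}, indent=2, sort_keys=True))


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = None
    if "group" in df.columns:
        labels = df.pop("group").astype(str).tolist()
    feature_mz = np.array([float(c) for c in df.columns])
    return FeatureMatrix(feature_mz, df.to_numpy(dtype=float),
                         [str(i) for i in df.index], labels)


def write_ground_truth(truth, path: str | Path) -> None:
    rows = [{"name": n, "mz": mz, "direction": d, "effect": e}
            for n, mz, d, e in truth.differential_features]
    pd.DataFrame(rows, columns=["name", "mz", "direction", "effect"]).to_csv(path, index=False)
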