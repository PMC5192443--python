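"""Minimal mzML I/O for centroided raw maps.

The writer emits a minimal, uncompressed (64-bit float, base64) mzML
document; the reader handles the common MS1 centroid subset of mzML
1.1 (32/64-bit floats, zlib or no compression, scan start times in
seconds or minutes) via the standard-library XML parser.
"""

from __future__ import annotations

import base64
import struct
import zlib
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

from .peaks import RawMap

__all__ = ["write_mzml", "read_mzml"]

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_SCAN_START = "MS:1000016"
_ACC_MS_LEVEL = "MS:1000511"


def _encode(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *np.asarray(values, dtype=float))
    return base64.b64encode(raw).decode("ascii")


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_SPECTRUM = """      <spectrum index="{index}" id="scan={index}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(raw: RawMap, path, run_id: str = "synthetic") -> None:
    """Write a centroided raw map as a minimal mzML document."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_HEADER.format(run_id=escape(run_id), count=len(raw)))
        for index, rt in enumerate(raw.scan_rts):
            mz_b64 = _encode(raw.scan_mzs[index])
            int_b64 = _encode(raw.scan_intensities[index])
            fh.write(
                _SPECTRUM.format(
                    index=index,
                    n=len(raw.scan_mzs[index]),
                    rt=float(rt),
                    mz_len=len(mz_b64),
                    mz_b64=mz_b64,
                    int_len=len(int_b64),
                    int_b64=int_b64,
                )
            )
        fh.write(_FOOTER)


def _decode_binary_array(elem: ElementTree.Element) -> np.ndarray:
    accessions = {
        cv.get("accession") for cv in elem.iter(f"{_NS}cvParam")
    }
    binary = elem.find(f"{_NS}binary")
    data = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in accessions:
        data = zlib.decompress(data)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    return np.frombuffer(data, dtype=dtype).astype(float)


def _spectrum_arrays(spectrum: ElementTree.Element):
    ms_level = 1
    rt = None
    for cv in spectrum.iter(f"{_NS}cvParam"):
        acc = cv.get("accession")
        if acc == _ACC_MS_LEVEL:
            ms_level = int(cv.get("value"))
        elif acc == _ACC_SCAN_START:
            value = float(cv.get("value"))
            unit = (cv.get("unitName") or "").lower()
            rt = value * 60.0 if "minute" in unit else value
    mz = intensity = None
    for arr in spectrum.iter(f"{_NS}binaryDataArray"):
        accessions = {cv.get("accession") for cv in arr.iter(f"{_NS}cvParam")}
        if _ACC_MZ_ARRAY in accessions:
            mz = _decode_binary_array(arr)
        elif _ACC_INT_ARRAY in accessions:
            intensity = _decode_binary_array(arr)
    return ms_level, rt, mz, intensity


def read_mzml(path) -> RawMap:
    """Read centroided MS1 spectra from an mzML file into a RawMap."""
    rts: list[float] = []
    mzs: list[np.ndarray] = []
    intens: list[np.ndarray] = []
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if elem.tag != f"{_NS}spectrum":
            continue
        ms_level, rt, mz, intensity = _spectrum_arrays(elem)
        elem.clear()
        if ms_level != 1 or mz is None or intensity is None:
            continue
        if rt is None:
            rt = float(len(rts))
        order = np.argsort(mz, kind="stable")
        rts.append(rt)
        mzs.append(mz[order])
        intens.append(intensity[order])
    if not rts:
        raise ValueError(f"no MS1 spectra found in {path}")
    order = np.argsort(rts, kind="stable")
    return RawMap(
        scan_rts=np.asarray(rts, dtype=float)[order],
        scan_mzs=[mzs[i] for i in order],
        scan_intensities=[intens[i] for i in order],
    )
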