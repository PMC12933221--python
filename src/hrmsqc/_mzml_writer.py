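"""Minimal mzML 1.1 writer for simulated runs.

Only what the package's own reader needs: centroided MS1/MS2 spectra with
retention times in seconds, polarity, DDA precursor annotation and
uncompressed 64-bit base64 binary arrays. Real acquisitions should be
converted with a full-featured converter; this writer exists so simulated
batches can exercise the file-based pipeline end to end.
"""

from __future__ import annotations

import base64
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .raw_io import Run, Spectrum

__all__ = ["write_mzml"]


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    unit_attr = ""
    if unit == "second":
        unit_attr = (
            ' unitCvRef="UO" unitAccession="UO:0000010" unitName="second"'
        )
    elif unit == "mz":
        unit_attr = ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'
    return (
        f'<cvParam cvRef="MS" accession="{accession}" name="{escape(name)}"'
        f' value="{escape(str(value))}"{unit_attr}/>'
    )


def _binary_array(arr: np.ndarray, kind: str) -> list[str]:
    encoded = _b64(arr)
    name, acc = (
        ("m/z array", "MS:1000514") if kind == "mz" else ("intensity array", "MS:1000515")
    )
    return [
        f'<binaryDataArray encodedLength="{len(encoded)}">',
        _cv("MS:1000523", "64-bit float"),
        _cv("MS:1000576", "no compression"),
        _cv(acc, name, unit="mz" if kind == "mz" else ""),
        f"<binary>{encoded}</binary>",
        "</binaryDataArray>",
    ]


def _spectrum_xml(s: Spectrum, index: int) -> str:
    lines = [
        f'<spectrum index="{index}" id="scan={index + 1}" '
        f'defaultArrayLength="{s.mz.size}">',
        _cv("MS:1000511", "ms level", str(s.ms_level)),
        _cv("MS:1000127", "centroid spectrum"),
    ]
    if s.polarity == "negative":
        lines.append(_cv("MS:1000129", "negative scan"))
    else:
        lines.append(_cv("MS:1000130", "positive scan"))
    lines += [
        '<scanList count="1">',
        _cv("MS:1000795", "no combination"),
        "<scan>",
        _cv("MS:1000016", "scan start time", f"{s.rt:.6f}", unit="second"),
        "</scan>",
        "</scanList>",
    ]
    if s.ms_level >= 2 and s.precursor_mz is not None:
        width = 2.5 if s.acquisition_mode == "DIA" else 0.5
        lines += [
            '<precursorList count="1">',
            "<precursor>",
            "<isolationWindow>",
            _cv("MS:1000827", "isolation window target m/z", f"{s.precursor_mz:.6f}", unit="mz"),
            _cv("MS:1000828", "isolation window lower offset", f"{width:.3f}", unit="mz"),
            _cv("MS:1000829", "isolation window upper offset", f"{width:.3f}", unit="mz"),
            "</isolationWindow>",
            '<selectedIonList count="1">',
            "<selectedIon>",
            _cv("MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}", unit="mz"),
            "</selectedIon>",
            "</selectedIonList>",
            "<activation>",
            _cv("MS:1000133", "collision-induced dissociation"),
            "</activation>",
            "</precursor>",
            "</precursorList>",
        ]
    lines.append('<binaryDataArrayList count="2">')
    lines += _binary_array(s.mz, "mz")
    lines += _binary_array(s.intensity, "intensity")
    lines += ["</binaryDataArrayList>", "</spectrum>"]
    return "\n".join(lines)


def write_mzml(run: Run, path: str | Path) -> Path:
    """Serialise a Run to a (non-indexed) mzML 1.1 file readable by pyteomics."""
    path = Path(path)
    stamp = run.acquired_at.isoformat()
    head = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry '
        'Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="Unit Ontology" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        f'<run id="{escape(Path(run.path).stem or "run")}" startTimeStamp="{stamp}">',
        f'<spectrumList count="{len(run.spectra)}">',
    ]
    body = [_spectrum_xml(s, i) for i, s in enumerate(run.spectra)]
    tail = ["</spectrumList>", "</run>", "</mzML>"]
    path.write_text("\n".join(head + body + tail))
    return path
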