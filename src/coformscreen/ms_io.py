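"""Read and write centroided LC-MS runs as mzML.

A deliberately small, standards-conformant mzML 1.1 subset: centroid
spectra, MS1/MS2 levels, scan start times, precursor isolation windows and
collision energies, 64-bit little-endian uncompressed binary arrays. The
subset round-trips every (rt, m/z, intensity) at float64 precision, which
is all the screening pipeline needs; profile-mode data are rejected.

Retention time is minutes everywhere in the package; files recorded in
seconds are converted on read.
"""

from __future__ import annotations

import base64
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CentroidSpectrum",
    "MsRun",
    "read_run",
    "write_run",
    "ms2_events_near",
    "run_to_table",
    "run_from_table",
]

logger = logging.getLogger(__name__)

_NS = "http://psi.hupo.org/ms/mzml"

# PSI-MS controlled-vocabulary accessions used by the subset
_CV = {
    "ms_level": "MS:1000511",
    "ms1": "MS:1000579",
    "msn": "MS:1000580",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "positive": "MS:1000130",
    "negative": "MS:1000129",
    "scan_start": "MS:1000016",
    "selected_mz": "MS:1000744",
    "iso_target": "MS:1000827",
    "iso_lower": "MS:1000828",
    "iso_upper": "MS:1000829",
    "ce": "MS:1000045",
    "mz_array": "MS:1000514",
    "int_array": "MS:1000515",
    "f64": "MS:1000523",
    "no_compress": "MS:1000576",
    "minute": "UO:0000031",
    "second": "UO:0000010",
}


@dataclass
class CentroidSpectrum:
    """One centroided scan: peaks plus acquisition metadata.

    ``mz`` values are strictly increasing and intensities positive; MS2
    scans carry their precursor m/z, isolation half-width and collision
    energy. ``rt`` is in minutes.
    """

    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    polarity: str = "+"
    precursor_mz: Optional[float] = None
    isolation_half_width: Optional[float] = None
    collision_energy: Optional[float] = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity <= 0):
            raise ValueError("intensities must be positive")
        if self.ms_level >= 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")
        if self.polarity not in ("+", "-"):
            raise ValueError("polarity must be '+' or '-'")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    def base_peak(self) -> Tuple[float, float]:
        if not self.mz.size:
            raise ValueError("empty spectrum")
        i = int(np.argmax(self.intensity))
        return float(self.mz[i]), float(self.intensity[i])


@dataclass
class MsRun:
    """An ordered centroided LC-MS run with its acquisition role.

    ``role`` distinguishes sample, blank, solvent-standard and
    spiked-sample injections; ``dilution_factor`` is the sample
    preparation dilution (e.g. 10000 for a 1:10,000 v/v dilution) used to
    back-calculate formulation concentrations.
    """

    run_id: str
    spectra: List[CentroidSpectrum] = field(default_factory=list)
    role: str = "sample"
    dilution_factor: float = 1.0
    metadata: Dict[str, str] = field(default_factory=dict)

    _ROLES = ("sample", "blank", "solvent-standard", "spiked-sample")

    def __post_init__(self) -> None:
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}")
        if self.dilution_factor < 1:
            raise ValueError("dilution factor must be >= 1")
        rts = [s.rt for s in self.spectra]
        if rts != sorted(rts):
            raise ValueError("spectra must be ordered by retention time")

    def ms1_spectra(self) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2_spectra(self) -> List[CentroidSpectrum]:
        return [s for s in self.spectra if s.ms_level == 2]

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# mzML writing
# ---------------------------------------------------------------------------


def _b64(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f8").tobytes()).decode("ascii")


def _cv(parent: ET.Element, accession: str, name: str, value: str = "", **extra) -> None:
    attrs = {"cvRef": accession.split(":")[0], "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    ET.SubElement(parent, "cvParam", attrs)


def _binary_array(parent: ET.Element, arr: np.ndarray, kind: str) -> None:
    payload = _b64(arr)
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(payload))})
    _cv(bda, _CV["f64"], "64-bit float")
    _cv(bda, _CV["no_compress"], "no compression")
    if kind == "mz":
        _cv(bda, _CV["mz_array"], "m/z array", unitCvRef="MS",
            unitAccession="MS:1000040", unitName="m/z")
    else:
        _cv(bda, _CV["int_array"], "intensity array", unitCvRef="MS",
            unitAccession="MS:1000131", unitName="number of detector counts")
    ET.SubElement(bda, "binary").text = payload


def write_run(run: MsRun, path) -> None:
    """Serialize a run to mzML with the centroid-spectrum flag set."""
    root = ET.Element("mzML", {
        "xmlns": _NS,
        "version": "1.1.0",
        "id": run.run_id,
    })
    cvlist = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cvlist, "cv", {"id": "MS", "fullName": "PSI-MS controlled vocabulary",
                                 "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"})
    ET.SubElement(cvlist, "cv", {"id": "UO", "fullName": "Unit Ontology",
                                 "URI": "http://ontologies.berkeleybop.org/uo.obo"})
    run_el = ET.SubElement(root, "run", {
        "id": run.run_id,
        "sampleRole": run.role,
        "dilutionFactor": repr(run.dilution_factor),
    })
    for k, v in run.metadata.items():
        ET.SubElement(run_el, "userParam", {"name": str(k), "value": str(v)})
    slist = ET.SubElement(run_el, "spectrumList", {"count": str(len(run.spectra))})
    for i, s in enumerate(run.spectra):
        sp = ET.SubElement(slist, "spectrum", {
            "index": str(i),
            "id": f"scan={i + 1}",
            "defaultArrayLength": str(s.n_peaks),
        })
        _cv(sp, _CV["ms_level"], "ms level", str(s.ms_level))
        _cv(sp, _CV["ms1"] if s.ms_level == 1 else _CV["msn"],
            "MS1 spectrum" if s.ms_level == 1 else "MSn spectrum")
        _cv(sp, _CV["centroid"], "centroid spectrum")
        _cv(sp, _CV["positive" if s.polarity == "+" else "negative"],
            "positive scan" if s.polarity == "+" else "negative scan")
        scans = ET.SubElement(sp, "scanList", {"count": "1"})
        scan = ET.SubElement(scans, "scan")
        _cv(scan, _CV["scan_start"], "scan start time", repr(float(s.rt)),
            unitCvRef="UO", unitAccession=_CV["minute"], unitName="minute")
        if s.ms_level >= 2:
            plist = ET.SubElement(sp, "precursorList", {"count": "1"})
            prec = ET.SubElement(plist, "precursor")
            if s.isolation_half_width is not None:
                iso = ET.SubElement(prec, "isolationWindow")
                _cv(iso, _CV["iso_target"], "isolation window target m/z", repr(float(s.precursor_mz)))
                _cv(iso, _CV["iso_lower"], "isolation window lower offset", repr(float(s.isolation_half_width)))
                _cv(iso, _CV["iso_upper"], "isolation window upper offset", repr(float(s.isolation_half_width)))
            ions = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            ion = ET.SubElement(ions, "selectedIon")
            _cv(ion, _CV["selected_mz"], "selected ion m/z", repr(float(s.precursor_mz)))
            act = ET.SubElement(prec, "activation")
            if s.collision_energy is not None:
                _cv(act, _CV["ce"], "collision energy", repr(float(s.collision_energy)),
                    unitCvRef="UO", unitAccession="UO:0000266", unitName="electronvolt")
        arrays = ET.SubElement(sp, "binaryDataArrayList", {"count": "2"})
        _binary_array(arrays, s.mz, "mz")
        _binary_array(arrays, s.intensity, "intensity")
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# mzML reading
# ---------------------------------------------------------------------------


def _tag(el: ET.Element) -> str:
    return el.tag.split("}")[-1]

def _iter(el: ET.Element, name: str):
    yield from el.iter(f"{{{_NS}}}{name}")
    if not el.tag.startswith("{"):  # un-namespaced files
        yield from el.iter(name)


def _cvparams(el: ET.Element) -> Dict[str, Dict[str, str]]:
    out = {}
    for cv in _iter(el, "cvParam"):
        out[cv.get("accession", "")] = dict(cv.attrib)
    return out


def _decode_arrays(sp: ET.Element) -> Tuple[np.ndarray, np.ndarray]:
    mz = inten = None
    for bda in _iter(sp, "binaryDataArray"):
        params = _cvparams(bda)
        if _CV["f64"] not in params:
            raise ValueError("only 64-bit float arrays are supported")
        if _CV["no_compress"] not in params:
            raise ValueError("only uncompressed binary arrays are supported")
        binary = next(_iter(bda, "binary"), None)
        text = (binary.text or "") if binary is not None else ""
        arr = np.frombuffer(base64.b64decode(text), dtype="<f8")
        if _CV["mz_array"] in params:
            mz = arr
        elif _CV["int_array"] in params:
            inten = arr
    if mz is None or inten is None:
        raise ValueError("spectrum is missing an m/z or intensity array")
    return mz.copy(), inten.copy()


def read_run(path, role: str = "sample", dilution_factor: float = 1.0) -> MsRun:
    """Load an mzML file into an :class:`MsRun`.

    Profile-mode spectra are rejected; retention times in seconds are
    converted to minutes. ``role`` and ``dilution_factor`` default to the
    values stored in the file (written by :func:`write_run`) when present.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    run_el = next(_iter(root, "run"), None)
    if run_el is None:
        raise ValueError(f"{path}: no <run> element found")
    run_id = run_el.get("id", "run")
    role = run_el.get("sampleRole", role)
    dilution_factor = float(run_el.get("dilutionFactor", dilution_factor))
    metadata = {up.get("name"): up.get("value")
                for up in run_el.findall(f"{{{_NS}}}userParam") + run_el.findall("userParam")}

    spectra: List[CentroidSpectrum] = []
    for sp in _iter(root, "spectrum"):
        params = _cvparams(sp)
        if _CV["profile"] in params:
            raise ValueError(f"{path}: profile-mode spectra are not supported; centroid first")
        ms_level = int(params.get(_CV["ms_level"], {}).get("value", 1))
        polarity = "-" if _CV["negative"] in params else "+"
        rt = None
        for scan in _iter(sp, "scan"):
            sparams = _cvparams(scan)
            if _CV["scan_start"] in sparams:
                p = sparams[_CV["scan_start"]]
                rt = float(p["value"])
                if p.get("unitAccession") == _CV["second"] or p.get("unitName") == "second":
                    rt /= 60.0
        if rt is None:
            raise ValueError(f"{path}: spectrum without a scan start time")
        precursor_mz = half_width = ce = None
        for prec in _iter(sp, "precursor"):
            pparams = _cvparams(prec)
            if _CV["selected_mz"] in pparams:
                precursor_mz = float(pparams[_CV["selected_mz"]]["value"])
            elif _CV["iso_target"] in pparams:
                precursor_mz = float(pparams[_CV["iso_target"]]["value"])
            if _CV["iso_lower"] in pparams:
                half_width = float(pparams[_CV["iso_lower"]]["value"])
            if _CV["ce"] in pparams:
                ce = float(pparams[_CV["ce"]]["value"])
        mz, inten = _decode_arrays(sp)
        spectra.append(CentroidSpectrum(
            rt=rt, mz=mz, intensity=inten, ms_level=ms_level, polarity=polarity,
            precursor_mz=precursor_mz, isolation_half_width=half_width,
            collision_energy=ce,
        ))
    if not spectra:
        logger.warning("%s: mzML file contains no spectra", path)
    return MsRun(run_id=run_id, spectra=spectra, role=role,
                 dilution_factor=dilution_factor, metadata=metadata)


# ---------------------------------------------------------------------------
# ddMS2 lookup and tabular serialization
# ---------------------------------------------------------------------------


def ms2_events_near(
    run: MsRun,
    mz: float,
    rt: float,
    mz_tol: float = 2.5,
    rt_tol: float = 0.2,
) -> List[CentroidSpectrum]:
    """All MS2 scans whose precursor lies near (mz, rt), ordered by rt.

    ``mz_tol`` is in Da (default 2.5, half a 5.0-wide isolation window);
    ``rt_tol`` in minutes.
    """
    if mz_tol < 0 or rt_tol < 0:
        raise ValueError("tolerances must be >= 0")
    hits = [s for s in run.ms2_spectra()
            if s.precursor_mz is not None
            and abs(s.precursor_mz - mz) <= mz_tol
            and abs(s.rt - rt) <= rt_tol]
    return sorted(hits, key=lambda s: s.rt)


_TABLE_COLUMNS = ["scan", "rt_min", "ms_level", "polarity",
                  "precursor_mz", "mz", "intensity"]


def run_to_table(run: MsRun) -> pd.DataFrame:
    """One row per centroid; a plain-text fixture format for small runs."""
    rows = []
    for i, s in enumerate(run.spectra):
        for m, inten in zip(s.mz, s.intensity):
            rows.append((i, s.rt, s.ms_level, s.polarity,
                         s.precursor_mz if s.precursor_mz is not None else np.nan,
                         m, inten))
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def run_from_table(df: pd.DataFrame, run_id: str = "run", **run_kwargs) -> MsRun:
    """Inverse of :func:`run_to_table` (scan metadata of empty scans is lost)."""
    spectra = []
    for scan, grp in df.groupby("scan", sort=True):
        first = grp.iloc[0]
        order = np.argsort(grp["mz"].to_numpy())
        prec = first["precursor_mz"]
        spectra.append(CentroidSpectrum(
            rt=float(first["rt_min"]),
            mz=grp["mz"].to_numpy()[order],
            intensity=grp["intensity"].to_numpy()[order],
            ms_level=int(first["ms_level"]),
            polarity=str(first["polarity"]),
            precursor_mz=None if pd.isna(prec) else float(prec),
        ))
    spectra.sort(key=lambda s: s.rt)
    return MsRun(run_id=run_id, spectra=spectra, **run_kwargs)
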