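"""Spectrum and table I/O: MGF, a read-only mzML subset, and the CSV
tables (PRM targets, identifications, patient cohorts).

Readers validate rather than coerce: any violation of the documented
contracts surfaces as a structured error.  Retention time is stored in
minutes throughout; MGF RTINSECONDS is converted on read.

Note the shipped 18-target ceruloplasmin fixture
(:func:`default_target_list`): the site-762 peptide ELHHLQEQNVSNAFLDK
is the real tryptic peptide; the peptides for sites 138/358/397 are
synthetic stand-ins with valid N-glycosylation sequons, as the original
target table is not public.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _pt_mgf

from .chem import GlycanComposition

__all__ = [
    "Spectrum",
    "PrmRun",
    "SpectrumIOError",
    "TableValidationError",
    "read_mgf",
    "write_mgf",
    "read_mzml_subset",
    "read_target_list",
    "read_identifications",
    "read_cohort",
    "default_target_list",
    "COHORT_GROUPS",
]

logger = logging.getLogger(__name__)

#: Fixed vocabulary of cohort group labels.
COHORT_GROUPS = ("cirrhosis", "early_hcc", "late_hcc")

#: Tolerance below which adjacent peaks are merged on read (Th).
PEAK_MERGE_TOL = 1e-5

_ID_SCORE_COLUMNS = ("byonic_score", "delta_mod_score", "pep2d", "fdr2d")


class SpectrumIOError(ValueError):
    """Malformed spectrum file (bad MGF block, corrupt mzML, ...)."""


class TableValidationError(ValueError):
    """A CSV table violated its documented contract."""


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum with precursor metadata.

    ``precursor_charge`` may be None when the source file carried no
    charge assignment; downstream consumers must treat such spectra as
    flagged.  Peaks are kept sorted ascending by m/z.
    """

    scan_id: str
    precursor_mz: float
    precursor_charge: int | None
    retention_time_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectrumIOError(
                f"scan {self.scan_id}: mz and intensity lengths differ"
            )
        if self.mz.size and np.any(self.mz <= 0):
            raise SpectrumIOError(f"scan {self.scan_id}: non-positive m/z value")
        if self.intensity.size and np.any(self.intensity < 0):
            raise SpectrumIOError(f"scan {self.scan_id}: negative intensity")
        if self.precursor_charge is not None and not 1 <= self.precursor_charge <= 6:
            raise SpectrumIOError(
                f"scan {self.scan_id}: precursor charge {self.precursor_charge} "
                "outside 1..6"
            )
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        self._merge_close_peaks()

    def _merge_close_peaks(self) -> None:
        # merge peaks closer than PEAK_MERGE_TOL, summing intensity
        if self.mz.size < 2:
            return
        close = np.diff(self.mz) < PEAK_MERGE_TOL
        if not np.any(close):
            return
        group = np.concatenate([[0], np.cumsum(~close)])
        n = group[-1] + 1
        mz_out = np.zeros(n)
        int_out = np.zeros(n)
        np.add.at(int_out, group, self.intensity)
        # first member's m/z represents the merged peak
        first = np.concatenate([[True], ~close])
        mz_out[:] = self.mz[first]
        self.mz, self.intensity = mz_out, int_out

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass
class PrmRun:
    """A time-ordered targeted acquisition for one sample."""

    sample_id: str
    spectra: list[Spectrum]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rts = [s.retention_time_min for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise SpectrumIOError(
                f"run {self.sample_id}: retention times not non-decreasing"
            )


def _check_mgf_blocks(path: str) -> None:
    """Pre-scan for unbalanced BEGIN IONS/END IONS, reporting line numbers."""
    open_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().upper()
            if token == "BEGIN IONS":
                if open_line is not None:
                    raise SpectrumIOError(
                        f"{path}:{lineno}: BEGIN IONS inside an open block "
                        f"started at line {open_line}"
                    )
                open_line = lineno
            elif token == "END IONS":
                if open_line is None:
                    raise SpectrumIOError(
                        f"{path}:{lineno}: END IONS without matching BEGIN IONS"
                    )
                open_line = None
    if open_line is not None:
        raise SpectrumIOError(
            f"{path}:{open_line}: BEGIN IONS block never closed"
        )


def read_mgf(path: str) -> list[Spectrum]:
    """Read centroided spectra from an MGF file.

    RTINSECONDS is converted to minutes.  A spectrum without a CHARGE
    line gets ``precursor_charge=None`` (flagged downstream).  An empty
    file yields an empty list with a warning.
    """
    _check_mgf_blocks(path)
    spectra: list[Spectrum] = []
    with _pt_mgf.MGF(path) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            pepmass = params.get("pepmass", (0.0,))[0]
            rt_s = params.get("rtinseconds")
            rt_min = float(rt_s) / 60.0 if rt_s is not None else 0.0
            spectra.append(
                Spectrum(
                    scan_id=str(params.get("title", f"index={len(spectra)}")),
                    precursor_mz=float(pepmass),
                    precursor_charge=charge,
                    retention_time_min=rt_min,
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                )
            )
    if not spectra:
        warnings.warn(f"no spectra found in {path}", stacklevel=2)
    return spectra


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    """Write spectra to MGF (TITLE, PEPMASS, CHARGE, RTINSECONDS)."""
    entries = []
    for s in spectra:
        params: dict = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time_min * 60.0,
        }
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {
                "params": params,
                "m/z array": s.mz,
                "intensity array": s.intensity,
            }
        )
    _pt_mgf.write(entries, path, file_mode="w")


_MZML_ACCESSIONS = {
    "ms_level": "MS:1000511",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "scan_start_time": "MS:1000016",
    "selected_ion_mz": "MS:1000744",
    "charge_state": "MS:1000041",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "float64": "MS:1000523",
    "float32": "MS:1000521",
    "zlib": "MS:1000574",
    "no_compression": "MS:1000576",
}


def _cv(elem, accession) -> str | None:
    for cv in elem.iter("{*}cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value", "")
    return None


def _cv_unit(elem, accession) -> tuple[str | None, str | None]:
    for cv in elem.iter("{*}cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value", ""), cv.get("unitName")
    return None, None


def _decode_binary_array(array_elem) -> np.ndarray:
    import base64
    import zlib

    acc = _MZML_ACCESSIONS
    binary = array_elem.findtext("{*}binary") or ""
    raw = base64.b64decode(binary)
    if _cv(array_elem, acc["zlib"]) is not None:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _cv(array_elem, acc["float32"]) is not None else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_subset(path: str) -> list[Spectrum]:
    """Read centroided MS2 spectra from an mzML document.

    A deliberately minimal reader (lxml over the PSI schema): only scan
    id, precursor m/z and charge, retention time, and peak arrays are
    extracted; vendor extras are ignored.  MS1 scans are skipped (count
    logged), spectra without precursor metadata are skipped with a
    warning, and profile-mode spectra are rejected with advice to
    centroid first.
    """
    acc = _MZML_ACCESSIONS
    spectra: list[Spectrum] = []
    skipped_ms1 = 0
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise SpectrumIOError(
            f"{path}: corrupt mzML XML at line {exc.lineno}: {exc.msg}"
        ) from exc
    for elem in tree.iter("{*}spectrum"):
        level = _cv(elem, acc["ms_level"])
        if level is None or int(level) != 2:
            skipped_ms1 += 1
            continue
        if _cv(elem, acc["profile"]) is not None:
            raise SpectrumIOError(
                f"{path}: profile-mode spectrum {elem.get('id')!r}; "
                "centroid the data before loading"
            )
        ion = next(iter(elem.iter("{*}selectedIon")), None)
        if ion is None or _cv(ion, acc["selected_ion_mz"]) is None:
            warnings.warn(
                f"{path}: MS2 scan {elem.get('id')!r} lacks precursor "
                "metadata; skipped",
                stacklevel=2,
            )
            continue
        charge = _cv(ion, acc["charge_state"])
        scan = next(iter(elem.iter("{*}scan")), elem)
        rt_val, rt_unit = _cv_unit(scan, acc["scan_start_time"])
        rt_min = float(rt_val) if rt_val else 0.0
        if rt_unit == "second":
            rt_min /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for array_elem in elem.iter("{*}binaryDataArray"):
            for key in ("mz_array", "intensity_array"):
                if _cv(array_elem, acc[key]) is not None:
                    arrays[key] = _decode_binary_array(array_elem)
        if set(arrays) != {"mz_array", "intensity_array"}:
            raise SpectrumIOError(
                f"{path}: spectrum {elem.get('id')!r} lacks m/z or "
                "intensity binary array"
            )
        spectra.append(
            Spectrum(
                scan_id=str(elem.get("id")),
                precursor_mz=float(_cv(ion, acc["selected_ion_mz"])),
                precursor_charge=int(float(charge)) if charge else None,
                retention_time_min=rt_min,
                mz=arrays["mz_array"],
                intensity=arrays["intensity_array"],
            )
        )
    if skipped_ms1:
        logger.info("%s: skipped %d non-MS2 scans", path, skipped_ms1)
    return spectra


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(f"{what}: missing required columns {missing}")


def read_target_list(path: str) -> pd.DataFrame:
    """Load a PRM target table.

    Required columns: peptide, glycan, charge, expected_rt_min, protein,
    glycosite.  Glycan composition strings are canonicalised through
    :class:`~glycoprm.chem.GlycanComposition`; duplicate
    (peptide, glycan, charge) triples are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("peptide", "glycan", "charge", "expected_rt_min", "protein", "glycosite"),
        "target list",
    )
    df = df.copy()
    df["glycan"] = [str(GlycanComposition.parse(g)) for g in df["glycan"]]
    df["charge"] = df["charge"].astype(int)
    dup = df.duplicated(subset=["peptide", "glycan", "charge"], keep=False)
    if dup.any():
        dups = df.loc[dup, ["peptide", "glycan", "charge"]].drop_duplicates()
        raise TableValidationError(
            f"target list: duplicate (peptide, glycan, charge) triples:\n{dups}"
        )
    if not df["charge"].between(1, 6).all():
        raise TableValidationError("target list: precursor charge outside 1..6")
    return df


def default_target_list() -> pd.DataFrame:
    """The shipped 18-target ceruloplasmin fixture (4 glycosites)."""
    with resources.as_file(
        resources.files("glycoprm.data") / "ceru_targets.csv"
    ) as p:
        return read_target_list(str(p))


def read_identifications(path: str) -> pd.DataFrame:
    """Load a glycopeptide identification table (search-engine export).

    Required columns: peptide, glycosite, glycan, charge, scan_id,
    xic_area, byonic_score, delta_mod_score, pep2d, fdr2d, sample.
    An absent/empty ``variable_mods`` column defaults to none.
    """
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("peptide", "glycosite", "glycan", "charge", "scan_id", "xic_area", "sample")
        + _ID_SCORE_COLUMNS,
        "identification table",
    )
    df = df.copy()
    df["glycan"] = [str(GlycanComposition.parse(g)) for g in df["glycan"]]
    if "variable_mods" not in df.columns:
        df["variable_mods"] = ""
    df["variable_mods"] = df["variable_mods"].fillna("")
    for col in _ID_SCORE_COLUMNS:
        if not np.isfinite(df[col]).all():
            raise TableValidationError(f"identification table: non-finite {col}")
    for col in ("pep2d", "fdr2d"):
        if not df[col].between(0, 1).all():
            raise TableValidationError(
                f"identification table: {col} outside [0, 1]"
            )
    return df


def read_cohort(path: str) -> pd.DataFrame:
    """Load a patient cohort table.

    Required columns: patient_id, group, afp_ng_ml; groups must come
    from the fixed vocabulary (cirrhosis, early_hcc, late_hcc) and AFP
    must be strictly positive.  Per-target quantity columns pass
    through unchanged.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("patient_id", "group", "afp_ng_ml"), "cohort table")
    bad = set(df["group"]) - set(COHORT_GROUPS)
    if bad:
        raise TableValidationError(
            f"cohort table: unknown group labels {sorted(bad)}; "
            f"allowed: {COHORT_GROUPS}"
        )
    if not (df["afp_ng_ml"] > 0).all():
        raise TableValidationError("cohort table: AFP values must be > 0")
    return df
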