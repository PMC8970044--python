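"""DDA profiling and PRM Y1-ion quantification.

The PRM side extracts Y1 (peptide+HexNAc) extracted-ion chromatograms
from targeted runs within an absolute m/z window (Skyline-style, 0.05
m/z default), integrates the elution peak with apex-anchored
trapezoidal boundaries, normalizes each target's area to the summed
area of all targets in the sample, and forms the fucosylation-ratio
statistic

    ratio = area(fucosylated glycopeptide) / area(non-fucosylated partner)

reported alongside −log10(ratio) (ratios are mostly < 1, so the minus
log puts the informative direction upward).  Undefined ratios (zero
denominator) are flagged and excluded from group statistics rather
than imputed.

The DDA side filters identification tables on the four search-engine
confidence thresholds, aggregates XIC areas over precursor charge
states, profiles antennarity / fucosylation / sialylation
distributions over unique glycopeptides, and computes replicate
Pearson R² matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    MONOSACCHARIDE_MASSES,
    PROTON,
    GlycanComposition,
    classify_glycoform,
    glycan_mass,
    peptide_mass,
)
from .io import PrmRun, TableValidationError

__all__ = [
    "XicTrace",
    "QuantRecord",
    "RatioRecord",
    "XIC_TOL_MZ",
    "y1_mz",
    "extract_xic",
    "integrate_peak",
    "quantify_run",
    "normalize_sample",
    "aggregate_charge_states",
    "fucosylation_ratio",
    "filter_identifications",
    "profile_distributions",
    "replicate_correlation",
]

#: Default absolute XIC extraction tolerance (m/z), the targeted-mode
#: ion match tolerance.
XIC_TOL_MZ = 0.05
#: Integration window half-width around the expected retention time (min).
RT_HALF_WINDOW_MIN = 1.5
#: Y1 charge states considered for quantification.
Y1_CHARGES = (1, 2)
#: Half-width of the precursor isolation window (m/z) used to assign
#: targeted MS2 spectra to their analyte.
ISOLATION_HALF_WIDTH = 0.7

FILTER_THRESHOLDS = {
    "byonic_score": 150.0,  # strictly greater
    "delta_mod_score": 10.0,  # strictly greater
    "pep2d": 0.05,  # strictly less
    "fdr2d": 0.01,  # strictly less
}


@dataclass
class XicTrace:
    """An extracted-ion chromatogram for one transition."""

    target_key: str
    transition: str  # e.g. "Y1, 2+"
    times: np.ndarray  # retention time, min, strictly increasing
    intensities: np.ndarray
    mz_center: float
    tolerance: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size != self.intensities.size:
            raise ValueError("trace time/intensity lengths differ")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("trace intensities must be >= 0")


@dataclass
class QuantRecord:
    """Integrated, normalized Y1 area for one target in one sample."""

    sample_id: str
    target_key: str
    y1_area: float
    y1_charge: int | None = None
    relative_abundance: float = math.nan
    flagged: bool = False


@dataclass
class RatioRecord:
    """Fucosylation ratio for one (sample, glycosite) target pair."""

    sample_id: str
    glycosite: int
    fucosylated_key: str
    nonfucosylated_key: str
    fucosylation_ratio: float = math.nan
    neg_log10_ratio: float = math.nan
    defined: bool = True


def y1_mz(peptide: str, charge: int, fixed_mods: dict[str, float] | None = None,
          extra_hexnac: int = 1, extra_fuc: int = 0) -> float:
    """m/z of the Y1 (pep+HexNAc) transition at a given charge.

    ``extra_hexnac``/``extra_fuc`` generalise to the other small
    glycosidic Y transitions when needed.
    """
    neutral = (
        peptide_mass(peptide, fixed_mods if fixed_mods is not None else {"C": 57.021464})
        + extra_hexnac * MONOSACCHARIDE_MASSES["HexNAc"]
        + extra_fuc * MONOSACCHARIDE_MASSES["Fuc"]
    )
    return (neutral + charge * PROTON) / charge


def _precursor_mz(peptide: str, glycan: str, charge: int) -> float:
    neutral = peptide_mass(peptide, {"C": 57.021464}) + glycan_mass(
        GlycanComposition.parse(glycan)
    )
    return (neutral + charge * PROTON) / charge


def extract_xic(
    run: PrmRun,
    mz_center: float,
    tolerance: float = XIC_TOL_MZ,
    rt_window: tuple[float, float] | None = None,
    target_key: str = "",
    transition: str = "",
) -> XicTrace:
    """Sum peak intensity within ``mz_center ± tolerance`` per spectrum.

    Only spectra inside ``rt_window`` (inclusive) contribute; an empty
    window yields an empty trace.  Spectra sharing a retention time are
    collapsed by summing (keeps times strictly increasing).
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    times: list[float] = []
    values: list[float] = []
    for s in run.spectra:
        rt = s.retention_time_min
        if rt_window is not None and not rt_window[0] <= rt <= rt_window[1]:
            continue
        lo = np.searchsorted(s.mz, mz_center - tolerance, side="left")
        hi = np.searchsorted(s.mz, mz_center + tolerance, side="right")
        inten = float(s.intensity[lo:hi].sum())
        if times and rt == times[-1]:
            values[-1] += inten
        else:
            times.append(rt)
            values.append(inten)
    return XicTrace(
        target_key=target_key,
        transition=transition,
        times=np.array(times),
        intensities=np.array(values),
        mz_center=mz_center,
        tolerance=tolerance,
    )


def integrate_peak(trace: XicTrace) -> float:
    """Trapezoidal area under the apex-anchored elution peak.

    Integration boundaries are the local minima on either side of the
    apex (the maximum-intensity point); the area between them is
    computed by the trapezoid rule in intensity·min.  Traces shorter
    than 3 points integrate to 0.
    """
    t, y = trace.times, trace.intensities
    if t.size < 3 or not np.any(y > 0):
        return 0.0
    # boundaries are found on a lightly smoothed copy so that sampling
    # noise near the apex does not truncate the peak; a minimum only
    # counts as a boundary once the signal has genuinely come down
    # (below half the apex) or reached the noise floor (1% of apex)
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same")
    apex = int(np.argmax(ys))
    floor = 0.01 * ys[apex]
    half = 0.5 * ys[apex]

    def walk(step: int) -> int:
        i = apex
        edge = 0 if step < 0 else ys.size - 1
        while i != edge:
            nxt = i + step
            if ys[nxt] < floor:
                return nxt
            if ys[nxt] > ys[i] and ys[i] < half:
                return i  # rising again after a real valley
            i = nxt
        return edge

    left, right = walk(-1), walk(+1)
    if right - left < 1:
        return 0.0
    return float(np.trapezoid(y[left : right + 1], t[left : right + 1]))


def quantify_run(
    run: PrmRun,
    targets: pd.DataFrame,
    tolerance: float = XIC_TOL_MZ,
    rt_half_window: float = RT_HALF_WINDOW_MIN,
) -> list[QuantRecord]:
    """Quantify every target of a PRM run by its Y1 transition.

    For each target analyte, Y1 XICs are extracted at charges 1 and 2
    within expected RT ± ``rt_half_window``; the charge with maximal
    integrated area is quantified (recorded per record).  Target rows
    listing the same (peptide, glycosite, glycan) at several precursor
    charges share one Y1 transition and collapse to one record.
    Records are then sample-normalized.
    """
    unique = targets.drop_duplicates(subset=["peptide", "glycosite", "glycan"])
    # PRM isolation: each targeted MS2 belongs to one precursor, so the
    # Y1 XIC of an analyte is read only from spectra whose precursor
    # matches one of its listed charge states (glycoforms of the same
    # peptide share the Y1 m/z and are separated by isolation, not RT)
    precursors: dict[str, list[float]] = {}
    for _, row in targets.iterrows():
        key = f"{row.peptide}|{row.glycosite}|{row.glycan}"
        gp_mz = _precursor_mz(row.peptide, row.glycan, int(row.charge))
        precursors.setdefault(key, []).append(gp_mz)

    records: list[QuantRecord] = []
    for _, row in unique.iterrows():
        key = f"{row.peptide}|{row.glycosite}|{row.glycan}"
        mzs = precursors[key]
        sub = PrmRun(
            sample_id=run.sample_id,
            spectra=[
                s
                for s in run.spectra
                if any(abs(s.precursor_mz - m) <= ISOLATION_HALF_WIDTH for m in mzs)
            ],
            metadata=run.metadata,
        )
        window = (
            row.expected_rt_min - rt_half_window,
            row.expected_rt_min + rt_half_window,
        )
        best_area, best_charge = 0.0, None
        for z in Y1_CHARGES:
            trace = extract_xic(
                sub,
                y1_mz(row.peptide, z),
                tolerance=tolerance,
                rt_window=window,
                target_key=key,
                transition=f"Y1, {z}+",
            )
            area = integrate_peak(trace)
            if area > best_area:
                best_area, best_charge = area, z
        records.append(
            QuantRecord(
                sample_id=run.sample_id,
                target_key=key,
                y1_area=best_area,
                y1_charge=best_charge,
            )
        )
    return normalize_sample(records)


def normalize_sample(records: list[QuantRecord]) -> list[QuantRecord]:
    """Set relative_abundance = area / Σ areas within the sample.

    Relative abundances sum to 1 whenever the total area is positive.
    An all-zero sample is flagged and left at zero abundance.  Missing
    targets should enter as zero-area records so denominators stay
    comparable across samples.
    """
    if not records:
        raise ValueError("normalize_sample requires at least one record")
    total = sum(r.y1_area for r in records)
    for r in records:
        if total > 0:
            r.relative_abundance = r.y1_area / total
        else:
            r.relative_abundance = 0.0
            r.flagged = True
    return records


def aggregate_charge_states(ids: pd.DataFrame) -> pd.DataFrame:
    """Sum XIC areas over precursor charge states, then sample-normalize.

    The unique-glycopeptide key is (peptide, glycosite, canonical
    glycan composition); charge is collapsed.  Returns one row per
    (sample, key) with ``xic_area`` and ``relative_abundance``.
    """
    df = ids.copy()
    df["glycan"] = [str(GlycanComposition.parse(g)) for g in df["glycan"]]
    agg = (
        df.groupby(["sample", "peptide", "glycosite", "glycan"], as_index=False)[
            "xic_area"
        ].sum()
    )
    totals = agg.groupby("sample")["xic_area"].transform("sum")
    agg["relative_abundance"] = np.where(
        totals > 0, agg["xic_area"] / totals, 0.0
    )
    return agg


def fucosylation_ratio(fuc_area: float, nonfuc_area: float) -> tuple[float, float, bool]:
    """The fucosylation-ratio statistic and its −log10.

    Returns ``(ratio, neg_log10_ratio, defined)``.  A zero denominator
    makes the ratio undefined (``defined=False``, NaNs); a zero
    numerator gives ratio 0 with an undefined −log10, also flagged so
    the record is excluded from group statistics.
    """
    if fuc_area < 0 or nonfuc_area < 0:
        raise ValueError("areas must be >= 0")
    if nonfuc_area == 0:
        return math.nan, math.nan, False
    ratio = fuc_area / nonfuc_area
    if ratio == 0:
        return 0.0, math.nan, False
    return ratio, -math.log10(ratio), True


def filter_identifications(ids: pd.DataFrame) -> pd.DataFrame:
    """Apply the four-threshold identification confidence filter.

    Keeps rows with byonic_score > 150, delta_mod_score > 10,
    pep2d < 0.05 and fdr2d < 0.01 — all strict inequalities; a row
    failing any one is removed.  Removal counts per criterion are
    attached as ``DataFrame.attrs['filter_counts']``.  Idempotent.
    """
    missing = [c for c in FILTER_THRESHOLDS if c not in ids.columns]
    if missing:
        raise TableValidationError(
            f"identification filter: missing score columns {missing}"
        )
    keep = (
        (ids["byonic_score"] > FILTER_THRESHOLDS["byonic_score"])
        & (ids["delta_mod_score"] > FILTER_THRESHOLDS["delta_mod_score"])
        & (ids["pep2d"] < FILTER_THRESHOLDS["pep2d"])
        & (ids["fdr2d"] < FILTER_THRESHOLDS["fdr2d"])
    )
    counts = {
        "byonic_score": int((~(ids["byonic_score"] > 150)).sum()),
        "delta_mod_score": int((~(ids["delta_mod_score"] > 10)).sum()),
        "pep2d": int((~(ids["pep2d"] < 0.05)).sum()),
        "fdr2d": int((~(ids["fdr2d"] < 0.01)).sum()),
        "removed_total": int((~keep).sum()),
    }
    out = ids.loc[keep].reset_index(drop=True)
    out.attrs["filter_counts"] = counts
    return out


def _unique_glycopeptides(ids: pd.DataFrame) -> pd.DataFrame:
    df = ids.copy()
    df["glycan"] = [str(GlycanComposition.parse(g)) for g in df["glycan"]]
    return df.drop_duplicates(subset=["peptide", "glycosite", "glycan"])


def profile_distributions(ids: pd.DataFrame) -> dict:
    """Glycoform distribution summary over unique glycopeptides.

    Counts and percentages by antennarity class, by fucose count
    (percentages among the fucosylated subset, the pie-chart
    convention), and by sialic-acid count (among the sialylated
    subset); plus totals of fucosylated and sialylated unique
    glycopeptides.
    """
    uniq = _unique_glycopeptides(ids)
    classes = [classify_glycoform(GlycanComposition.parse(g)) for g in uniq["glycan"]]
    n = len(classes)

    def dist(keys):
        counts: dict = {}
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
        total = sum(counts.values())
        return {
            k: {"count": v, "percent": 100.0 * v / total if total else 0.0}
            for k, v in sorted(counts.items(), key=lambda kv: str(kv[0]))
        }

    fuc_counts = [c.fucose_count for c in classes if c.fucose_count > 0]
    sia_counts = [c.sialyl_count for c in classes if c.sialyl_count > 0]
    return {
        "n_unique_glycopeptides": n,
        "n_fucosylated": len(fuc_counts),
        "n_sialylated": len(sia_counts),
        "antennarity": dist([c.antennarity for c in classes]),
        "fucose_count": dist(fuc_counts),
        "sialyl_count": dist(sia_counts),
    }


def run_set_comparison(groups: dict[str, set]) -> dict:
    """Pairwise union/intersection sizes across run groups."""
    out = {}
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            out[f"{a}|{b}"] = {
                "union": len(groups[a] | groups[b]),
                "intersection": len(groups[a] & groups[b]),
                "only_" + a: len(groups[a] - groups[b]),
                "only_" + b: len(groups[b] - groups[a]),
            }
    return out


def replicate_correlation(abundances: pd.DataFrame) -> pd.DataFrame:
    """Pairwise squared Pearson correlations of replicate profiles.

    ``abundances`` has one column per replicate over a shared
    glycopeptide index (missing values treated as 0).  Returns the
    symmetric R² matrix; entries against a constant replicate are NaN
    (flagged by a warning-free NaN rather than an error).
    """
    if abundances.shape[1] < 2:
        raise ValueError("need at least two replicates")
    mat = abundances.fillna(0.0)
    r = np.corrcoef(mat.to_numpy().T)
    r2 = r**2
    return pd.DataFrame(r2, index=mat.columns, columns=mat.columns)
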