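"""Fragment-ion matching and fucosylation-topology calling.

Matches theoretical oxonium, glycosidic Y, and peptide b/y ions against
centroided spectra within a ppm (or absolute m/z) tolerance, and turns
the matched evidence into a core / outer-arm fucosylation verdict:

* core fucosylation — the fucose rides on the reducing-end HexNAc and
  survives in small glycosidic Y ions, so evidence is a matched
  pep+HexNAc+Fuc or pep+2HexNAc+Fuc ion (any allowed charge);
* outer-arm (antennary) fucosylation — the fucose decorates an antenna
  and shows up in the HexNAc+Hex+Fuc oxonium at m/z 512.20.

Larger fucosylated Y ions are annotated but deliberately not used as
topology evidence: by the time most of the glycan is retained, the
fucose position is ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import FragmentIon, Glycopeptide, b_y_ladders, oxonium_ions, y_ion_series
from .io import Spectrum

__all__ = [
    "MatchedIon",
    "TopologyCall",
    "screen_oxonium",
    "match_fragments",
    "call_fucose_topology",
    "DEFAULT_TOL_PPM",
    "MIN_RELATIVE_INTENSITY",
]

DEFAULT_TOL_PPM = 20.0  # MS2 fragment tolerance
#: Evidence peaks below this fraction of the base peak are ignored.
MIN_RELATIVE_INTENSITY = 0.01

_CORE_EVIDENCE_LABELS = ("pep+HexNAc+Fuc", "pep+2HexNAc+Fuc")
_OUTER_ARM_LABEL = "HexNAcHexFuc"


@dataclass(frozen=True)
class MatchedIon:
    """A theoretical ion assigned to an observed peak."""

    fragment: FragmentIon
    observed_mz: float
    observed_intensity: float
    error_ppm: float


@dataclass(frozen=True)
class TopologyCall:
    """Core/outer-arm fucosylation verdict with its spectral evidence.

    ``verdict`` is one of core, outer_arm, both, undetermined,
    non_fucosylated.  "both" requires at least two fucoses in the
    composition; a mono-fucosylated target with both evidence kinds is
    "undetermined" with ``conflict=True`` (one fucose cannot occupy two
    positions).
    """

    core_fucosylated: bool
    outer_arm_fucosylated: bool
    evidence: tuple[str, ...]
    verdict: str
    conflict: bool = False


def _match(
    spectrum: Spectrum,
    ions: list[FragmentIon],
    tol_ppm: float | None,
    tol_mz: float | None,
    min_rel_intensity: float,
) -> list[MatchedIon]:
    """Assign each observed peak to at most one theoretical ion.

    For each ion the nearest in-tolerance peak is found; when two ions
    claim one peak, the smaller |ppm error| wins, ties going to the
    lower-mass ion.  Matching is deterministic.
    """
    if (tol_ppm is None) == (tol_mz is None):
        raise ValueError("specify exactly one of tol_ppm / tol_mz")
    if (tol_ppm is not None and tol_ppm <= 0) or (tol_mz is not None and tol_mz <= 0):
        raise ValueError("tolerance must be > 0")
    if spectrum.mz.size == 0:
        return []

    floor = min_rel_intensity * spectrum.base_peak_intensity
    candidates: list[tuple[float, float, int, FragmentIon, int]] = []
    for ion in ions:
        mz = ion.mz
        tol = mz * tol_ppm * 1e-6 if tol_ppm is not None else tol_mz
        idx = np.searchsorted(spectrum.mz, mz)
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < spectrum.mz.size:
                delta = abs(spectrum.mz[j] - mz)
                if delta <= tol and spectrum.intensity[j] >= floor:
                    if best is None or delta < best[0]:
                        best = (delta, j)
        if best is not None:
            _, j = best
            err_ppm = (spectrum.mz[j] - mz) / mz * 1e6
            candidates.append((abs(err_ppm), mz, j, ion, int(j)))

    # resolve peak collisions: smaller |ppm| wins, tie -> lower-mass ion
    candidates.sort(key=lambda c: (c[0], c[1]))
    taken: set[int] = set()
    matches: list[MatchedIon] = []
    for abs_err, mz, j, ion, peak_idx in candidates:
        if peak_idx in taken:
            continue
        taken.add(peak_idx)
        matches.append(
            MatchedIon(
                fragment=ion,
                observed_mz=float(spectrum.mz[peak_idx]),
                observed_intensity=float(spectrum.intensity[peak_idx]),
                error_ppm=float((spectrum.mz[peak_idx] - ion.mz) / ion.mz * 1e6),
            )
        )
    matches.sort(key=lambda m: m.fragment.mz)
    return matches


def screen_oxonium(
    spectrum: Spectrum,
    glycan,
    tol_ppm: float = DEFAULT_TOL_PPM,
    min_rel_intensity: float = MIN_RELATIVE_INTENSITY,
) -> list[MatchedIon]:
    """Match the diagnostic oxonium ions of a composition to a spectrum.

    Each diagnostic from :func:`glycoprm.chem.oxonium_ions` is matched
    to the nearest peak within ``tol_ppm``; unmatched ions are absent
    from the output.  An empty spectrum yields an empty list.
    """
    return _match(spectrum, oxonium_ions(glycan), tol_ppm, None, min_rel_intensity)


def match_fragments(
    spectrum: Spectrum,
    gp: Glycopeptide,
    tol_ppm: float | None = DEFAULT_TOL_PPM,
    tol_mz: float | None = None,
    ion_types: tuple[str, ...] = ("oxonium", "Y", "b", "y"),
    max_charge: int = 2,
    min_rel_intensity: float = MIN_RELATIVE_INTENSITY,
) -> list[MatchedIon]:
    """Annotate a glycopeptide spectrum with all requested ion series.

    Generates oxonium diagnostics, the glycosidic Y series, and b/y
    backbone ladders (charges 1..max_charge, the targeted-transition
    convention) and assigns each observed peak to at most one
    theoretical ion (nearest-ppm wins; ties to the lower-mass ion).
    """
    ions: list[FragmentIon] = []
    if "oxonium" in ion_types:
        ions.extend(oxonium_ions(gp.glycan))
    if "Y" in ion_types:
        ions.extend(y_ion_series(gp, max_charge=max_charge))
    if "b" in ion_types or "y" in ion_types:
        ladder = b_y_ladders(gp, max_charge=max_charge)
        ions.extend(i for i in ladder if i.kind in ion_types)
    return _match(spectrum, ions, tol_ppm, tol_mz, min_rel_intensity)


def call_fucose_topology(
    spectrum: Spectrum,
    gp: Glycopeptide,
    tol_ppm: float = DEFAULT_TOL_PPM,
    max_charge: int = 2,
    min_rel_intensity: float = MIN_RELATIVE_INTENSITY,
) -> TopologyCall:
    """Call core / outer-arm fucosylation for one target spectrum.

    A composition without fucose is non_fucosylated regardless of any
    spurious matches.  Otherwise core evidence is a matched
    pep+HexNAc+Fuc or pep+2HexNAc+Fuc Y ion, outer-arm evidence the
    HexNAc+Hex+Fuc oxonium; the verdict combines the two, demanding
    fuc >= 2 for "both".
    """
    if gp.glycan.fuc == 0:
        return TopologyCall(False, False, (), "non_fucosylated")

    matches = match_fragments(
        spectrum,
        gp,
        tol_ppm=tol_ppm,
        ion_types=("oxonium", "Y"),
        max_charge=max_charge,
        min_rel_intensity=min_rel_intensity,
    )
    labels = tuple(
        f"{m.fragment.label}({m.fragment.charge}+)"
        if m.fragment.kind == "Y"
        else m.fragment.label
        for m in matches
    )
    core = any(m.fragment.label in _CORE_EVIDENCE_LABELS for m in matches)
    outer = any(m.fragment.label == _OUTER_ARM_LABEL for m in matches)

    evidence = tuple(
        lab
        for lab, m in zip(labels, matches)
        if m.fragment.label in _CORE_EVIDENCE_LABELS
        or m.fragment.label == _OUTER_ARM_LABEL
    )
    conflict = False
    if core and outer:
        if gp.glycan.fuc >= 2:
            verdict = "both"
        else:
            # one fucose cannot occupy two positions: demote to
            # undetermined and clear both flags so that "both" remains
            # equivalent to (core and outer)
            verdict = "undetermined"
            conflict = True
            core = outer = False
    elif core:
        verdict = "core"
    elif outer:
        verdict = "outer_arm"
    else:
        verdict = "undetermined"
    return TopologyCall(core, outer, evidence, verdict, conflict)
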