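"""Monoisotopic mass engine for glycopeptides and their fragment ions.

Covers the four-monosaccharide alphabet of serum N-glycoproteomics
(HexNAc, Hex, Fuc, NeuAc), peptide masses with fixed/variable
modifications, glycosidic Y ions, the diagnostic oxonium ions used to
screen glycopeptide spectra, and composition-level glycoform
classification (antennarity, fucose and sialic-acid counts).

All masses are monoisotopic, in Da.  m/z values are computed as
``(neutral_mass + z * PROTON) / z``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

from pyteomics import mass as _pt_mass

__all__ = [
    "PROTON",
    "WATER",
    "RESIDUE_MASSES",
    "MONOSACCHARIDE_MASSES",
    "CARBAMIDOMETHYL",
    "GlycanComposition",
    "Glycopeptide",
    "FragmentIon",
    "GlycoformClass",
    "peptide_mass",
    "glycan_mass",
    "oxonium_ions",
    "y_ion_series",
    "b_y_ladders",
    "classify_glycoform",
    "constants_table_path",
]

PROTON = 1.007276  # Da, mass of H+
WATER = 18.010565  # Da, monoisotopic H2O

#: Monoisotopic residue masses of the 20 canonical amino acids
#: (standard table, via pyteomics).
RESIDUE_MASSES: dict[str, float] = {
    aa: _pt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Monoisotopic residue masses of the four monosaccharides that make up
#: complex-type serum N-glycans.  Lookups of any other name fail.
MONOSACCHARIDE_MASSES: dict[str, float] = {
    "HexNAc": 203.079373,
    "Hex": 162.052824,
    "Fuc": 146.057909,
    "NeuAc": 291.095417,
}

CARBAMIDOMETHYL = 57.021464  # Da, fixed Cys modification

#: HexNAc secondary oxonium fragments (dehydration / cross-ring
#: products).  These have no simple residue-sum form and are stored as
#: the published m/z values; every other diagnostic ion below is
#: computed from residue masses.  Note the 168.05 entry: the common
#: literature value is 168.066 — the published table value is kept and
#: flagged in the shipped constants CSV.
_HEXNAC_SECONDARY_MZ = (138.05, 168.05)

# Synonyms seen in figure captions: Glc/Gal/Man are Hex isomers and
# indistinguishable by mass; HexNac is a casing variant.
_MONO_SYNONYMS = {
    "hexnac": "HexNAc",
    "hex": "Hex",
    "gal": "Hex",
    "glc": "Hex",
    "man": "Hex",
    "fuc": "Fuc",
    "neuac": "NeuAc",
}

_COMPOSITION_TOKEN = re.compile(r"([A-Za-z]+)\((\d+)\)")


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Counts of HexNAc/Hex/Fuc/NeuAc; the unit of all glycan logic.

    String form follows the ``HexNAc(a)Hex(b)Fuc(c)NeuAc(d)`` field
    convention; zero-count terms are omitted on formatting and optional
    on parsing.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neuac"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(
                    f"monosaccharide count {name}={v!r} must be a non-negative integer"
                )

    @classmethod
    def parse(cls, text: str) -> "GlycanComposition":
        """Parse ``HexNAc(5)Hex(6)Fuc(2)NeuAc(3)``-style strings.

        Accepts ``HexNac``/``Gal``/``Glc``/``Man`` synonyms (Hex
        isomers) and any term order; unknown monosaccharide names are
        rejected.
        """
        text = text.strip()
        counts = {"HexNAc": 0, "Hex": 0, "Fuc": 0, "NeuAc": 0}
        consumed = 0
        for m in _COMPOSITION_TOKEN.finditer(text):
            name = _MONO_SYNONYMS.get(m.group(1).lower())
            if name is None:
                raise ValueError(
                    f"unknown monosaccharide {m.group(1)!r} in composition {text!r}"
                )
            counts[name] += int(m.group(2))
            consumed += len(m.group(0))
        if consumed != len(re.sub(r"\s+", "", text)):
            raise ValueError(f"malformed glycan composition string: {text!r}")
        return cls(counts["HexNAc"], counts["Hex"], counts["Fuc"], counts["NeuAc"])

    def __str__(self) -> str:
        parts = []
        for name, count in (
            ("HexNAc", self.hexnac),
            ("Hex", self.hex),
            ("Fuc", self.fuc),
            ("NeuAc", self.neuac),
        ):
            if count:
                parts.append(f"{name}({count})")
        return "".join(parts)

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac,
            self.hex + other.hex,
            self.fuc + other.fuc,
            self.neuac + other.neuac,
        )

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.fuc + self.neuac


@dataclass(frozen=True)
class Glycopeptide:
    """A peptide backbone carrying one N-glycan at a labelled site.

    ``glycosite`` is a 1-based protein coordinate used only as a label;
    it does not enter the mass computation.  ``fixed_mods`` maps a
    residue symbol to a mass addition applied at every occurrence
    (default: carbamidomethyl on C, the standard alkylation).
    ``variable_mods`` lists explicit ``(position, delta)`` pairs
    (1-based within the peptide), e.g. oxidised Met or deamidated
    Asn/Gln.
    """

    sequence: str
    glycosite: int
    glycan: GlycanComposition
    fixed_mods: dict[str, float] = field(
        default_factory=lambda: {"C": CARBAMIDOMETHYL}
    )
    variable_mods: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for i, aa in enumerate(self.sequence):
            if aa not in RESIDUE_MASSES:
                raise ValueError(
                    f"unknown residue symbol {aa!r} at position {i + 1} "
                    f"in sequence {self.sequence!r}"
                )
        for pos, _ in self.variable_mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"variable modification position {pos} outside peptide "
                    f"of length {len(self.sequence)}"
                )

    @property
    def peptide_mass(self) -> float:
        return peptide_mass(self.sequence, self.fixed_mods, self.variable_mods)

    @property
    def neutral_mass(self) -> float:
        """Intact glycopeptide monoisotopic mass (peptide + glycan)."""
        return self.peptide_mass + glycan_mass(self.glycan)

    def precursor_mz(self, charge: int) -> float:
        if charge < 1:
            raise ValueError("charge must be >= 1")
        return (self.neutral_mass + charge * PROTON) / charge


@dataclass(frozen=True)
class FragmentIon:
    """A theoretical fragment: oxonium, glycosidic Y, or peptide b/y."""

    kind: str  # one of {"oxonium", "Y", "b", "y"}
    label: str  # e.g. "pep+2HexNAc+Fuc", "HexNAcHexFuc", "b3"
    neutral_mass: float
    charge: int

    def __post_init__(self) -> None:
        if self.kind not in ("oxonium", "Y", "b", "y"):
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")
        if self.kind == "oxonium" and self.charge != 1:
            raise ValueError("oxonium ions are singly charged")

    @property
    def mz(self) -> float:
        return (self.neutral_mass + self.charge * PROTON) / self.charge


@dataclass(frozen=True)
class GlycoformClass:
    """Composition-level classification: antennarity + Fuc/NeuAc counts.

    Antennarity follows the chitobiose-core convention for non-bisected
    complex-type glycans: antenna count = HexNAc − 2, so HexNAc 4/5/6
    map to bi/tri/tetra.  Anything else (including high-mannose-like
    compositions with HexNAc < 2, which are flagged) is "other".
    Core vs outer-arm fucose position is not inferable from composition
    and is decided spectrally (see :mod:`glycoprm.annotate`).
    """

    antennarity: str  # {"bi", "tri", "tetra", "other"}
    fucose_count: int
    sialyl_count: int
    below_complex_type: bool = False


def peptide_mass(
    sequence: str,
    fixed_mods: dict[str, float] | None = None,
    variable_mods: tuple[tuple[int, float], ...] | list[tuple[int, float]] = (),
) -> float:
    """Monoisotopic peptide mass: residues + water + modification deltas.

    Parameters
    ----------
    sequence:
        Amino-acid string over the 20 canonical residues.
    fixed_mods:
        Mapping residue symbol -> mass delta applied at every occurrence.
    variable_mods:
        Explicit ``(1-based position, mass delta)`` pairs.
    """
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    total = WATER
    for i, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue symbol {aa!r} at position {i + 1} "
                f"in sequence {sequence!r}"
            ) from None
        if fixed_mods and aa in fixed_mods:
            total += fixed_mods[aa]
    for pos, delta in variable_mods:
        if not 1 <= pos <= len(sequence):
            raise ValueError(
                f"variable modification position {pos} outside peptide "
                f"of length {len(sequence)}"
            )
        total += delta
    return total


def glycan_mass(glycan: GlycanComposition) -> float:
    """Sum of monosaccharide residue masses (0 for the empty composition)."""
    return (
        glycan.hexnac * MONOSACCHARIDE_MASSES["HexNAc"]
        + glycan.hex * MONOSACCHARIDE_MASSES["Hex"]
        + glycan.fuc * MONOSACCHARIDE_MASSES["Fuc"]
        + glycan.neuac * MONOSACCHARIDE_MASSES["NeuAc"]
    )


def _oxonium(label: str, residue_sum: float) -> FragmentIon:
    # oxonium neutral mass chosen so mz = residue_sum + proton
    return FragmentIon("oxonium", label, residue_sum, 1)


def oxonium_ions(glycan: GlycanComposition) -> list[FragmentIon]:
    """Diagnostic oxonium ions expected from a glycan composition.

    Returns the subset of the eight standard diagnostics whose
    constituent monosaccharides are present: HexNAc (m/z 138.05, 168.05,
    204.09), NeuAc (274.09, 292.10), HexNAc+Hex (366.14),
    HexNAc+Hex+Fuc (512.20, the outer-arm fucosylation diagnostic) and
    HexNAc+Hex+NeuAc (657.23).  All are singly charged.  The two HexNAc
    secondary fragments come from a fixed published-value table; the
    rest are residue-mass sums plus a proton.
    """
    hexnac = MONOSACCHARIDE_MASSES["HexNAc"]
    hex_ = MONOSACCHARIDE_MASSES["Hex"]
    fuc = MONOSACCHARIDE_MASSES["Fuc"]
    neuac = MONOSACCHARIDE_MASSES["NeuAc"]

    ions: list[FragmentIon] = []
    if glycan.hexnac >= 1:
        for mz in _HEXNAC_SECONDARY_MZ:
            ions.append(FragmentIon("oxonium", f"HexNAc-frag({mz})", mz - PROTON, 1))
        ions.append(_oxonium("HexNAc", hexnac))
    if glycan.neuac >= 1:
        ions.append(_oxonium("NeuAc-H2O", neuac - WATER))
        ions.append(_oxonium("NeuAc", neuac))
    if glycan.hexnac >= 1 and glycan.hex >= 1:
        ions.append(_oxonium("HexNAcHex", hexnac + hex_))
        if glycan.fuc >= 1:
            ions.append(_oxonium("HexNAcHexFuc", hexnac + hex_ + fuc))
        if glycan.neuac >= 1:
            ions.append(_oxonium("HexNAcHexNeuAc", hexnac + hex_ + neuac))
    return ions


def y_ion_series(gp: Glycopeptide, max_charge: int = 2) -> list[FragmentIon]:
    """Glycosidic Y ions retaining the peptide backbone.

    Emits Y0 (bare peptide), Y1 (pep+HexNAc — the quantification
    transition), pep+HexNAc+Fuc, pep+2HexNAc and pep+2HexNAc+Fuc, each
    only when the composition permits, at every charge 1..max_charge.
    The fucose-retaining small Y ions are the core-fucosylation
    diagnostics.
    """
    if max_charge < 1:
        raise ValueError("max_charge must be >= 1")
    pep = gp.peptide_mass
    hexnac = MONOSACCHARIDE_MASSES["HexNAc"]
    fuc = MONOSACCHARIDE_MASSES["Fuc"]

    species: list[tuple[str, float]] = [("pep", pep)]
    if gp.glycan.hexnac >= 1:
        species.append(("pep+HexNAc", pep + hexnac))
        if gp.glycan.fuc >= 1:
            species.append(("pep+HexNAc+Fuc", pep + hexnac + fuc))
    if gp.glycan.hexnac >= 2:
        species.append(("pep+2HexNAc", pep + 2 * hexnac))
        if gp.glycan.fuc >= 1:
            species.append(("pep+2HexNAc+Fuc", pep + 2 * hexnac + fuc))

    return [
        FragmentIon("Y", label, neutral, z)
        for label, neutral in species
        for z in range(1, max_charge + 1)
    ]


def b_y_ladders(
    gp: Glycopeptide | None = None,
    sequence: str | None = None,
    max_charge: int = 2,
    fixed_mods: dict[str, float] | None = None,
) -> list[FragmentIon]:
    """Peptide-backbone b/y fragment ladders at charges 1..max_charge.

    Standard monoisotopic conventions: neutral b_i = Σ first-i residue
    masses (+mods); neutral y_j = Σ last-j residue masses (+mods) +
    water.  Ladders run from length 1 to len−1.  Variable modifications
    of the parent are applied at their residue positions.
    """
    if gp is not None:
        sequence = gp.sequence
        fixed_mods = gp.fixed_mods
        varmods = dict(gp.variable_mods)
    else:
        varmods = {}
    if sequence is None:
        raise ValueError("either gp or sequence must be given")
    if fixed_mods is None:
        fixed_mods = {"C": CARBAMIDOMETHYL}

    n = len(sequence)
    res = []
    for i, aa in enumerate(sequence, start=1):
        m = RESIDUE_MASSES[aa] + fixed_mods.get(aa, 0.0)
        m += varmods.get(i, 0.0)
        res.append(m)

    ions: list[FragmentIon] = []
    total = sum(res)
    prefix = 0.0
    for i in range(1, n):
        prefix += res[i - 1]
        suffix = total - prefix
        for z in range(1, max_charge + 1):
            # b ion neutral mass = Σ residues; y ion = Σ residues + H2O
            ions.append(FragmentIon("b", f"b{i}", prefix, z))
            ions.append(FragmentIon("y", f"y{n - i}", suffix + WATER, z))
    return ions


def classify_glycoform(glycan: GlycanComposition) -> GlycoformClass:
    """Classify a composition by antennarity and Fuc/NeuAc counts.

    HexNAc 4/5/6 → bi/tri/tetra-antennary (antenna = HexNAc − 2 under
    the chitobiose-core convention); everything else is "other".
    Compositions with HexNAc < 2 fall below the complex-type threshold
    and are additionally flagged.
    """
    # <= 2 HexNAc is core-only (high-mannose-like): no antennae to count
    flag = glycan.hexnac <= 2
    antennarity = {4: "bi", 5: "tri", 6: "tetra"}.get(glycan.hexnac, "other")
    if flag:
        antennarity = "other"
    return GlycoformClass(
        antennarity=antennarity,
        fucose_count=glycan.fuc,
        sialyl_count=glycan.neuac,
        below_complex_type=flag,
    )


def constants_table_path() -> str:
    """Path of the shipped machine-readable constants CSV."""
    return str(resources.files("glycoprm.data") / "constants.csv")
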