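"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: stepped-HCD
style MS2 spectra of glycopeptides (oxonium + glycosidic Y + b/y ions
plus noise), PRM runs with Gaussian Y1 elution peaks, search-engine
style identification tables, and two-group patient cohorts in which
the −log10 fucosylation ratio differs by a configurable standardized
effect size with log-normal AFP.

The default cohort parameters are the study design itself: 35
cirrhosis vs 27 early-HCC patients, effect size d = 0.8 (α = 0.05
gives power 0.87), AFP log-normal medians 3.7 and 32.4 ng/mL.  Noise
peaks in MS2 spectra are placed at least 3× the match tolerance away
from every theoretical ion of the target, so annotation tests have
exact expected outcomes; an adversarial mode drops that guarantee.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import (
    GlycanComposition,
    Glycopeptide,
    b_y_ladders,
    oxonium_ions,
    y_ion_series,
)
from .io import PrmRun, Spectrum, default_target_list
from .quantify import y1_mz

__all__ = [
    "SpectrumSpec",
    "PrmRunSpec",
    "CohortSpec",
    "make_ms2",
    "make_prm_run",
    "make_cohort",
    "make_identifications",
    "default_ratio_pairs",
    "glycopeptide_from_target_row",
]

# Study-design defaults (cohort)
DEFAULT_N1 = 35  # cirrhosis
DEFAULT_N2 = 27  # early-stage HCC
DEFAULT_EFFECT_SIZE = 0.8
DEFAULT_AFP_MEDIANS = (3.7, 32.4)  # ng/mL, cirrhosis vs early HCC
DEFAULT_AFP_LOG_SD = 1.2  # sd of ln(AFP); spread chosen to emulate the
# wide clinical AFP ranges while keeping both groups overlapping


@dataclass
class SpectrumSpec:
    """Recipe for one synthetic glycopeptide MS2 spectrum."""

    target: Glycopeptide
    precursor_charge: int = 3
    planted_kinds: tuple[str, ...] = ("oxonium", "Y", "b", "y")
    planted_intensity: float = 1000.0
    n_noise_peaks: int = 50
    noise_intensity_scale: float = 100.0
    mz_jitter_ppm_sd: float = 0.0
    tol_ppm: float = 20.0  # noise exclusion zone = 3 × this
    adversarial: bool = False
    retention_time_min: float = 30.0
    max_fragment_charge: int = 2
    drop_labels: tuple[str, ...] = ()  # theoretical ions left unplanted
    #: fucosylation topology the planted evidence should support:
    #: "core", "outer_arm", "both", or None to pick the composition's
    #: natural default (fuc=0 → non-fucosylated, fuc=1 → core,
    #: fuc>=2 → both)
    planted_topology: str | None = None


@dataclass
class PrmRunSpec:
    """Recipe for one synthetic PRM acquisition.

    ``targets`` is a target-list DataFrame; ``true_areas`` maps
    positionally to its rows (intensity·min under each Y1 Gaussian).
    """

    targets: pd.DataFrame
    true_areas: np.ndarray
    sample_id: str = "sample"
    y1_charge: int = 2
    peak_sd_min: float = 0.1
    sampling_interval_min: float = 0.02
    run_length_min: float = 65.0
    baseline: float = 0.0
    multiplicative_noise: float = 0.0
    metadata: dict = field(
        default_factory=lambda: {
            "gradient_min": 65,
            "stepped_collision_energies": (19, 26, 33),
        }
    )


@dataclass
class CohortSpec:
    """Recipe for a two-group patient cohort."""

    n_per_group: tuple[int, int] = (DEFAULT_N1, DEFAULT_N2)
    effect_size_d: float = DEFAULT_EFFECT_SIZE
    ratio_mu: float = 0.5  # mean −log10 ratio, reference (cirrhosis) group
    ratio_sigma: float = 0.15
    afp_medians: tuple[float, float] = DEFAULT_AFP_MEDIANS
    afp_log_sd: float = DEFAULT_AFP_LOG_SD
    groups: tuple[str, str] = ("cirrhosis", "early_hcc")

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.ratio_sigma <= 0 or self.afp_log_sd <= 0:
            raise ValueError("scales must be > 0")


def glycopeptide_from_target_row(row) -> Glycopeptide:
    """Build a Glycopeptide from one target-list row."""
    return Glycopeptide(
        sequence=row.peptide,
        glycosite=int(row.glycosite),
        glycan=GlycanComposition.parse(row.glycan),
    )


def _theoretical_ions(spec: SpectrumSpec):
    gp = spec.target
    ions = []
    ions.extend(oxonium_ions(gp.glycan))
    ions.extend(y_ion_series(gp, max_charge=spec.max_fragment_charge))
    ions.extend(b_y_ladders(gp, max_charge=spec.max_fragment_charge))
    return ions


def make_ms2(spec: SpectrumSpec, seed: int | np.random.Generator = 0) -> Spectrum:
    """Generate one centroided MS2 spectrum from a recipe.

    Peaks are planted at the theoretical m/z of the requested ion
    kinds (minus ``drop_labels``), perturbed by Gaussian ppm jitter;
    noise peaks are drawn uniformly over the m/z range but rejected
    within 3 × ``tol_ppm`` of any theoretical ion of the target
    (unless ``adversarial``).  Reproducible given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    all_ions = _theoretical_ions(spec)

    topology = spec.planted_topology
    fuc = spec.target.glycan.fuc
    if topology is None:
        topology = "non_fucosylated" if fuc == 0 else ("core" if fuc == 1 else "both")
    if topology == "both" and fuc < 2:
        raise ValueError("'both' topology needs at least two fucoses")
    if topology != "non_fucosylated" and fuc == 0:
        raise ValueError(f"topology {topology!r} needs fucose in the composition")
    # evidence ions incompatible with the planted topology are dropped
    drop = set(spec.drop_labels)
    if topology in ("core", "non_fucosylated"):
        drop.add("HexNAcHexFuc")
    if topology in ("outer_arm", "non_fucosylated"):
        drop.update(("pep+HexNAc+Fuc", "pep+2HexNAc+Fuc"))

    planted = [
        i
        for i in all_ions
        if i.kind in spec.planted_kinds and i.label not in drop
    ]

    mzs, intens = [], []
    for ion in planted:
        jitter = (
            rng.normal(0.0, spec.mz_jitter_ppm_sd) * 1e-6 * ion.mz
            if spec.mz_jitter_ppm_sd > 0
            else 0.0
        )
        mzs.append(ion.mz + jitter)
        intens.append(spec.planted_intensity * (0.5 + rng.random()))

    # noise peaks away from every theoretical ion (3x tolerance guard)
    theo_mz = np.array([i.mz for i in all_ions])
    lo, hi = 120.0, max(2000.0, float(theo_mz.max()) + 100.0)
    guard = 3.0 * spec.tol_ppm * 1e-6
    n_placed = 0
    while n_placed < spec.n_noise_peaks:
        cand = rng.uniform(lo, hi)
        if not spec.adversarial and np.any(
            np.abs(cand - theo_mz) <= guard * theo_mz
        ):
            continue
        mzs.append(cand)
        intens.append(rng.exponential(spec.noise_intensity_scale))
        n_placed += 1

    return Spectrum(
        scan_id=f"synthetic|{spec.target.sequence}|{spec.target.glycan}",
        precursor_mz=spec.target.precursor_mz(spec.precursor_charge),
        precursor_charge=spec.precursor_charge,
        retention_time_min=spec.retention_time_min,
        mz=np.array(mzs),
        intensity=np.array(intens),
    )


def make_prm_run(spec: PrmRunSpec, seed: int | np.random.Generator = 0) -> tuple[PrmRun, pd.DataFrame]:
    """Generate a PRM run whose Y1 XICs trace Gaussians of known area.

    Each target elutes as a Gaussian centred on its expected retention
    time with sd ``peak_sd_min`` and total area ``true_areas[i]``; the
    run samples every target's precursor at a fixed cycle time.
    Returns the run plus a ground-truth table (target key, Y1 m/z,
    true area).  Overlapping elution windows are allowed (flagged in
    the truth table).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    areas = np.asarray(spec.true_areas, dtype=float)
    if areas.size != len(spec.targets):
        raise ValueError("true_areas must align with target rows")
    if spec.peak_sd_min <= 0 or spec.sampling_interval_min <= 0:
        raise ValueError("peak width and sampling interval must be > 0")

    # rows listing one analyte at several precursor charges share a Y1
    # transition: collapse to unique analytes, summing their areas
    frame = spec.targets.copy()
    frame["__area"] = areas
    frame = frame.groupby(
        ["peptide", "glycosite", "glycan"], as_index=False, sort=False
    ).agg({"charge": "first", "expected_rt_min": "first", "protein": "first",
           "__area": "sum"})
    areas = frame.pop("__area").to_numpy()
    rows = list(frame.itertuples(index=False))
    y1 = np.array([y1_mz(r.peptide, spec.y1_charge) for r in rows])
    centers = np.array([float(r.expected_rt_min) for r in rows])
    heights = areas / (spec.peak_sd_min * np.sqrt(2 * np.pi))

    truth = pd.DataFrame(
        {
            "target_key": [
                f"{r.peptide}|{r.glycosite}|{r.glycan}" for r in rows
            ],
            "y1_mz": y1,
            "y1_charge": spec.y1_charge,
            "true_area": areas,
            "rt_center_min": centers,
            "rt_sd_min": spec.peak_sd_min,
        }
    )
    truth["overlapping_window"] = [
        bool(
            np.any(
                (np.abs(centers - c) < 6 * spec.peak_sd_min)
                & (np.abs(y1 - m) < 0.2)
                & (truth["target_key"] != k)
            )
        )
        for k, m, c in zip(truth["target_key"], y1, centers)
    ]

    times = np.arange(0.0, spec.run_length_min, spec.sampling_interval_min)
    spectra: list[Spectrum] = []
    for t in times:
        # one targeted MS2 per target per cycle; skip far-from-elution cycles
        for i, r in enumerate(rows):
            if abs(t - centers[i]) > 5 * spec.peak_sd_min and spec.baseline == 0:
                continue
            signal = heights[i] * np.exp(
                -0.5 * ((t - centers[i]) / spec.peak_sd_min) ** 2
            )
            if spec.multiplicative_noise > 0:
                signal *= max(0.0, 1.0 + spec.multiplicative_noise * rng.normal())
            signal += spec.baseline
            if signal <= 0:
                continue
            spectra.append(
                Spectrum(
                    scan_id=f"{spec.sample_id}|cycle{len(spectra)}",
                    precursor_mz=float(
                        glycopeptide_from_target_row(r).precursor_mz(int(r.charge))
                    ),
                    precursor_charge=int(r.charge),
                    retention_time_min=float(t),
                    mz=np.array([y1[i]]),
                    intensity=np.array([signal]),
                )
            )
    run = PrmRun(sample_id=spec.sample_id, spectra=spectra, metadata=dict(spec.metadata))
    return run, truth


def make_cohort(spec: CohortSpec = CohortSpec(), seed: int | np.random.Generator = 0) -> tuple[pd.DataFrame, dict]:
    """Generate a two-group cohort table with known generative truth.

    Per-patient −log10 fucosylation ratios are Normal(μ_g, σ²) with a
    between-group mean difference of d·σ (the disease group shifted
    downward: higher fucosylation ⇒ smaller −log10 ratio); AFP is
    log-normal with group-specific medians.  Returns (table, truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1, n2 = spec.n_per_group
    mu1 = spec.ratio_mu
    mu2 = spec.ratio_mu - spec.effect_size_d * spec.ratio_sigma

    nlr = np.concatenate(
        [
            rng.normal(mu1, spec.ratio_sigma, n1),
            rng.normal(mu2, spec.ratio_sigma, n2),
        ]
    )
    afp = np.concatenate(
        [
            np.exp(rng.normal(np.log(spec.afp_medians[0]), spec.afp_log_sd, n1)),
            np.exp(rng.normal(np.log(spec.afp_medians[1]), spec.afp_log_sd, n2)),
        ]
    )
    groups = [spec.groups[0]] * n1 + [spec.groups[1]] * n2
    table = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n1 + n2)],
            "group": groups,
            "afp_ng_ml": afp,
            "neg_log10_ratio": nlr,
            "fucosylation_ratio": 10.0 ** (-nlr),
        }
    )
    truth = {
        "mu_neg_log10_ratio": (mu1, mu2),
        "sigma": spec.ratio_sigma,
        "effect_size_d": spec.effect_size_d,
        "afp_medians": spec.afp_medians,
        "afp_log_sd": spec.afp_log_sd,
        "n_per_group": (n1, n2),
    }
    return table, truth


def make_identifications(
    n_rows: int = 200,
    n_samples: int = 3,
    pass_fraction: float = 0.6,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Generate a search-engine-style identification table.

    Glycans are drawn over bi/tri/tetra-antennary complex-type
    compositions with random fucosylation/sialylation; roughly
    ``pass_fraction`` of rows pass the four confidence thresholds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = default_target_list()
    peptides = targets[["peptide", "glycosite"]].drop_duplicates().to_numpy()
    rows = []
    for i in range(n_rows):
        pep, site = peptides[rng.integers(len(peptides))]
        hexnac = int(rng.choice([2, 4, 5, 6], p=[0.1, 0.5, 0.3, 0.1]))
        glycan = GlycanComposition(
            hexnac=hexnac,
            hex=hexnac + 1,
            fuc=int(rng.choice([0, 1, 2, 3, 4], p=[0.55, 0.33, 0.08, 0.03, 0.01])),
            neuac=int(rng.integers(0, max(1, hexnac - 1)) if rng.random() < 0.8 else 0),
        )
        passing = rng.random() < pass_fraction
        rows.append(
            {
                "peptide": pep,
                "glycosite": int(site),
                "glycan": str(glycan),
                "charge": int(rng.integers(2, 5)),
                "scan_id": f"scan{i}",
                "xic_area": float(rng.lognormal(10, 1)),
                "byonic_score": float(rng.uniform(151, 600) if passing else rng.uniform(0, 150)),
                "delta_mod_score": float(rng.uniform(10.5, 100) if passing else rng.uniform(0, 10)),
                "pep2d": float(rng.uniform(0, 0.049) if passing else rng.uniform(0.05, 1)),
                "fdr2d": float(rng.uniform(0, 0.0099) if passing else rng.uniform(0.01, 0.2)),
                "sample": f"rep{1 + i % n_samples}",
            }
        )
    return pd.DataFrame(rows)


def default_ratio_pairs(targets: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fucosylated / non-fucosylated target pairs per glycosite.

    For every fucosylated target, the partner is the same peptide and
    glycosite with the identical composition minus all fucoses, when
    that composition is itself in the target list.  In the shipped
    fixture site 358 carries no fucosylated target, so it contributes
    no pair (its ratio is undefined by construction).
    """
    if targets is None:
        targets = default_target_list()
    keys = {
        (r.peptide, int(r.glycosite), r.glycan) for r in targets.itertuples()
    }
    pairs = []
    for r in targets.itertuples():
        comp = GlycanComposition.parse(r.glycan)
        if comp.fuc == 0:
            continue
        partner = GlycanComposition(comp.hexnac, comp.hex, 0, comp.neuac)
        if (r.peptide, int(r.glycosite), str(partner)) in keys:
            pairs.append(
                {
                    "peptide": r.peptide,
                    "glycosite": int(r.glycosite),
                    "fucosylated_glycan": r.glycan,
                    "nonfucosylated_glycan": str(partner),
                    "fucosylated_key": f"{r.peptide}|{r.glycosite}|{r.glycan}",
                    "nonfucosylated_key": f"{r.peptide}|{r.glycosite}|{partner}",
                }
            )
    return pd.DataFrame(pairs).drop_duplicates().reset_index(drop=True)
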