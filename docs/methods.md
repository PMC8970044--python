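# Methods

## Scope and model

The package models the quantitative path of a targeted serum
glycoproteomics biomarker experiment. An intact N-glycopeptide is a
peptide backbone carrying one glycan described only by its
monosaccharide composition over HexNAc, Hex, Fuc and NeuAc; topology
(branch placement, isomers) is never enumerated. Three layers of
inference sit on top of that representation:

1. **Spectral annotation.** Under stepped-HCD fragmentation a
   glycopeptide yields low-mass oxonium ions (glycan fragments),
   glycosidic Y ions (peptide + residual glycan), and b/y backbone
   fragments. All are predicted as monoisotopic residue-mass sums;
   observed peaks are assigned to at most one theoretical ion by
   nearest relative (ppm) error, ties broken toward the lower-mass
   ion, so annotation is deterministic.
2. **Fucosylation topology.** Composition alone cannot place a fucose.
   The spectral rule used: a fucose retained on a small Y ion
   (pep+HexNAc+Fuc or pep+2HexNAc+Fuc) must sit on the reducing-end
   core HexNAc → core fucosylation; the HexNAc+Hex+Fuc oxonium
   (m/z 512.20) is an antenna fragment → outer-arm fucosylation.
   Larger fucose-bearing Y ions are annotated but carry no topological
   weight (position ambiguous). A composition without fucose is
   non-fucosylated regardless of spurious matches; "both" requires at
   least two fucoses, and a mono-fucosylated spectrum showing both
   evidence kinds is reported "undetermined" with a conflict flag —
   one fucose cannot occupy two positions.
3. **Quantification and cohort statistics.** The Y1 ion (peptide +
   one HexNAc) is the quantification transition: it is common to all
   glycoforms of a peptide and intense under stepped HCD. Because all
   glycoforms of a peptide share the same Y1 m/z, extraction respects
   PRM precursor isolation: a target's chromatogram is read only from
   MS2 spectra whose precursor matches one of its listed charge
   states (isolation half-width 0.7 m/z). The fucosylation ratio —
   fucosylated area over composition-matched non-fucosylated area
   within one sample — cancels between-patient abundance differences;
   −log10(ratio) is the analysis scale since ratios are mostly < 1.

## Parameters and defaults

| Parameter | Default | Why |
|---|---|---|
| MS2 fragment tolerance | 20 ppm | discovery-mode fragment accuracy on Orbitrap-class instruments |
| XIC extraction tolerance | 0.05 m/z absolute | targeted-mode (Skyline-style) ion match window |
| Y1 charge states | 1+, 2+ | the transition-list convention; the charge with the larger integrated area is quantified and recorded |
| RT integration window | expected RT ± 1.5 min | brackets elution drift without swallowing neighbours |
| Evidence intensity floor | 1% of base peak | guards topology calls against noise-level matches; no documented floor exists, so it is configurable |
| Identification filter | Byonic > 150, Delta mod > 10, PEP2D < 0.05, FDR2D < 0.01 | the published confidence thresholds, strict inequalities exactly as printed |
| Cohort design | n = 35 vs 27, d = 0.8, α = 0.05 | the study design; gives power 0.867 |
| AFP model | log-normal, medians 3.7 / 32.4 ng/mL, σ(ln) = 1.2 | group medians from the clinical table; σ chosen so the groups overlap realistically (clinical AFP ranges span orders of magnitude) |
| −log10 ratio model | Normal(0.5, 0.15²), disease shifted by −d·σ | keeps ratios in the sub-unity regime typical of fucosylated/non-fucosylated pairs |

Atomic constants: proton 1.007276 Da, water 18.010565 Da; residue
masses from the standard monoisotopic table (via pyteomics). The two
HexNAc secondary oxonium fragments (m/z 138.05 and 168.05) have no
residue-sum form and ship as published literals in
`glycoprm/data/constants.csv`; the 168.05 entry is flagged there
because the common literature value is 168.066. All other diagnostics
are computed.

## Antennarity

Antenna count = HexNAc − 2 under the chitobiose-core convention, so
HexNAc 4/5/6 → bi/tri/tetra-antennary. This holds for non-bisected
complex-type glycans only; bisecting GlcNAc is not modelled, and
compositions with HexNAc ≤ 2 (high-mannose-like) are classed "other"
with an explicit flag.

## Numerical choices

- **Peak integration**: trapezoidal, between apex-anchored boundaries.
  Boundaries are located on a 3-point moving average of the trace and
  a local minimum only terminates the peak once the smoothed signal is
  below half the apex (or below a 1% noise floor) — raw
  nearest-local-minimum walking truncates noisy peaks at sampling
  jitter and biased areas low by ~25% at 5% multiplicative noise.
- **Peak-list hygiene**: peaks closer than 1e-5 m/z are merged on
  read (summing intensity); peak lists are kept m/z-sorted.
- **Degenerate t-tests**: groups whose standard deviations are ≤1e-12
  of the data magnitude are treated as constant — identical means give
  (t = 0, p = 1), distinct means perfect separation — instead of
  propagating floating-point noise through a 0/0.
- **Undefined ratios**: a zero denominator (or zero numerator, whose
  −log10 is undefined) flags the record; flagged records are excluded
  from group statistics and counted, never imputed.
- **Missing targets** enter normalization as zero-area records so the
  per-sample denominator stays comparable across samples.
- **Logistic combination**: maximum likelihood on (log10 AFP,
  −log10 ratio) with ridge λ = 1e-6 so separable cohorts converge;
  in-sample ROC, no cross-validation. AUC is the trapezoid over the
  empirical curve, identical to Mann–Whitney U/(n⁺n⁻) with ties
  counted 0.5.
- **Power**: noncentral-t with δ = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2
  (statsmodels' independent-samples engine), cross-checked in the
  tests by direct cohort simulation.
- **Seeds**: every generator accepts a seed or Generator; the pipeline
  derives per-stage streams from one root seed via
  `SeedSequence.spawn`, making reruns bit-identical.

## What the synthetic data does and does not show

The generators emulate: planted fragment ions with Gaussian ppm
jitter; uniform-m/z noise peaks excluded from ±3× tolerance around
every theoretical ion of the target (an adversarial mode lifts this
exclusion); Gaussian elution peaks of specified area sampled on a
fixed cycle time; log-normal AFP; Normal −log10 ratios with a
standardized group shift. They do not model chromatographic tailing,
isotope envelopes, co-isolation interference, missing-value structure,
or retention-time drift between runs. Passing the closed-loop tests
therefore demonstrates correctness of the computational chain —
mass arithmetic, matching, integration, normalization, statistics —
not robustness to every artefact of real acquisitions; the clinical
performance numbers of any real cohort depend on the sera and search
engine and are outside what desk-scale simulation can certify.

## Shipped fixtures

`glycoprm/data/ceru_targets.csv` lists 18 PRM targets across
ceruloplasmin glycosites 138, 358, 397 and 762 with one
fucosylated/non-fucosylated ratio pair per site except 358, which
deliberately ships without a fucosylated partner to exercise the
undefined-ratio path. The site-762 peptide ELHHLQEQNVSNAFLDK is the
real tryptic peptide; the other three peptides are synthetic
stand-ins with valid N-glycosylation sequons (the original target
table is not public). Expected retention times are synthetic-run
coordinates, not measured values.

## Problem sizes

The default end-to-end demo simulates 62 patients × 17 unique
analytes at a 0.02 min PRM cycle and finishes in well under five
minutes on one CPU. Test-suite simulation sizes (50,000 Monte-Carlo
power cohorts; 20,000 null and 5,000 powered calibration cohorts;
1,000 topology spectra; 200 ROC instances) were chosen as the
smallest sets whose sampling error is comfortably below the
tolerances being asserted.

## Known limitations

- Composition strings treat Gal/Glc/Man as indistinguishable Hex
  isomers; the 512.20 diagnostic is labelled HexNAc+Hex+Fuc
  accordingly.
- O-glycans, hybrid/bisected types, and glycan structure elucidation
  are out of scope; "other" is a catch-all antennarity class.
- The mzML reader is a centroided-MS2 subset (no vendor extras, no
  write support); synthetic runs are persisted as MGF.
- Retention-time alignment and match-between-runs are not provided;
  targets are located by their declared expected RT.
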