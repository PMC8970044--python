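"""End-to-end orchestration: simulate → annotate → quantify → stats.

Drives a complete synthetic experiment shaped like the targeted
glycoproteomics study: a two-group patient cohort is generated with a
planted effect on the −log10 fucosylation ratio of the site-762
tri-antennary target; per-patient PRM runs encode each patient's true
ratio in their Y1 elution peaks; the quantification stage recovers
ratios from the runs; and the statistics stage compares groups,
corrects across targets, and evaluates ROC/AUC for the ratio, AFP,
and their logistic combination.

Every stage derives its random stream from one root seed
(``numpy.random.SeedSequence.spawn``), so a rerun with the same config
is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import call_fucose_topology
from .io import read_mgf, write_mgf
from .quantify import fucosylation_ratio, quantify_run
from .simulate import (
    CohortSpec,
    PrmRunSpec,
    SpectrumSpec,
    default_ratio_pairs,
    glycopeptide_from_target_row,
    make_cohort,
    make_ms2,
    make_prm_run,
)
from .io import default_target_list
from .stats import bh_qvalues, combine_with_afp, compare_groups, t_test_power

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`run_pipeline`.

    Unknown keys in a YAML config are rejected; all tolerances must be
    positive.
    """

    out_dir: str = "glycoprm_out"
    seed: int = 0
    n1: int = 35
    n2: int = 27
    effect_size_d: float = 0.8
    ratio_mu: float = 0.5
    ratio_sigma: float = 0.15
    ms2_tol_ppm: float = 20.0
    xic_tol_mz: float = 0.05
    rt_half_window_min: float = 1.5
    prm_sampling_interval_min: float = 0.02
    prm_peak_sd_min: float = 0.1
    prm_noise: float = 0.0
    equal_var: bool = True
    alpha: float = 0.05
    stages: tuple[str, ...] = ("simulate", "annotate", "quantify", "stats")

    def __post_init__(self) -> None:
        for name in ("ms2_tol_ppm", "xic_tol_mz", "rt_half_window_min",
                     "prm_sampling_interval_min", "prm_peak_sd_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        unknown = set(self.stages) - {"simulate", "annotate", "quantify", "stats"}
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"allowed: {sorted(allowed)}"
            )
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _simulate_stage(cfg: PipelineConfig, rng_children, out: Path) -> dict:
    targets = default_target_list()
    pairs = default_ratio_pairs(targets)
    cohort, truth = make_cohort(
        CohortSpec(
            n_per_group=(cfg.n1, cfg.n2),
            effect_size_d=cfg.effect_size_d,
            ratio_mu=cfg.ratio_mu,
            ratio_sigma=cfg.ratio_sigma,
        ),
        seed=np.random.default_rng(rng_children["cohort"]),
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    pairs.to_csv(out / "pairs.csv", index=False)
    targets.to_csv(out / "targets.csv", index=False)

    # Per-patient PRM run: the site-762 tri-antennary pair encodes the
    # patient's true ratio; remaining targets get fixed reference areas.
    headline_fuc = "ELHHLQEQNVSNAFLDK|762|HexNAc(5)Hex(6)Fuc(2)NeuAc(3)"
    headline_non = "ELHHLQEQNVSNAFLDK|762|HexNAc(5)Hex(6)NeuAc(3)"
    keys = [
        f"{r.peptide}|{r.glycosite}|{r.glycan}" for r in targets.itertuples()
    ]
    base = 1000.0
    runs = []
    run_rng = np.random.default_rng(rng_children["prm"])
    for row in cohort.itertuples():
        areas = np.full(len(targets), base * 0.5)
        for i, k in enumerate(keys):
            if k == headline_non:
                areas[i] = base
            elif k == headline_fuc:
                areas[i] = base * row.fucosylation_ratio
        run, run_truth = make_prm_run(
            PrmRunSpec(
                targets=targets,
                true_areas=areas,
                sample_id=row.patient_id,
                sampling_interval_min=cfg.prm_sampling_interval_min,
                peak_sd_min=cfg.prm_peak_sd_min,
                multiplicative_noise=cfg.prm_noise,
            ),
            seed=run_rng,
        )
        runs.append(run)
    # one run exercises the MGF round-trip path as a format check
    mgf_path = out / f"{runs[0].sample_id}.mgf"
    write_mgf(runs[0].spectra, str(mgf_path))
    reread = read_mgf(str(mgf_path))
    assert len(reread) == len(runs[0].spectra)
    return {"targets": targets, "pairs": pairs, "cohort": cohort, "runs": runs,
            "truth": truth}


def _annotate_stage(cfg: PipelineConfig, rng_children, state: dict, out: Path) -> pd.DataFrame:
    rng = np.random.default_rng(rng_children["annotate"])
    rows = []
    for row in state["targets"].itertuples():
        gp = glycopeptide_from_target_row(row)
        spectrum = make_ms2(
            SpectrumSpec(target=gp, precursor_charge=int(row.charge),
                         tol_ppm=cfg.ms2_tol_ppm),
            seed=rng,
        )
        call = call_fucose_topology(spectrum, gp, tol_ppm=cfg.ms2_tol_ppm)
        rows.append(
            {
                "peptide": row.peptide,
                "glycosite": row.glycosite,
                "glycan": row.glycan,
                "scan_id": spectrum.scan_id,
                "verdict": call.verdict,
                "core_fucosylated": call.core_fucosylated,
                "outer_arm_fucosylated": call.outer_arm_fucosylated,
                "evidence": ";".join(call.evidence),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "annotations.csv", index=False)
    return df


def _quantify_stage(cfg: PipelineConfig, state: dict, out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    quant_rows = []
    for run in state["runs"]:
        for rec in quantify_run(
            run,
            state["targets"],
            tolerance=cfg.xic_tol_mz,
            rt_half_window=cfg.rt_half_window_min,
        ):
            quant_rows.append(dataclasses.asdict(rec))
    quant = pd.DataFrame(quant_rows)
    quant.to_csv(out / "quant.csv", index=False)

    ratio_rows = []
    for sample_id, sub in quant.groupby("sample_id"):
        areas = dict(zip(sub["target_key"], sub["y1_area"]))
        for pair in state["pairs"].itertuples():
            ratio, nlr, defined = fucosylation_ratio(
                areas.get(pair.fucosylated_key, 0.0),
                areas.get(pair.nonfucosylated_key, 0.0),
            )
            ratio_rows.append(
                {
                    "sample_id": sample_id,
                    "glycosite": pair.glycosite,
                    "fucosylated_key": pair.fucosylated_key,
                    "nonfucosylated_key": pair.nonfucosylated_key,
                    "fucosylation_ratio": ratio,
                    "neg_log10_ratio": nlr,
                    "defined": defined,
                }
            )
    ratios = pd.DataFrame(ratio_rows)
    ratios.to_csv(out / "ratios.csv", index=False)
    return quant, ratios


def _stats_stage(cfg: PipelineConfig, state: dict, ratios: pd.DataFrame, out: Path) -> pd.DataFrame:
    cohort = state["cohort"]
    grp = dict(zip(cohort["patient_id"], cohort["group"]))
    afp = dict(zip(cohort["patient_id"], cohort["afp_ng_ml"]))
    g1, g2 = "cirrhosis", "early_hcc"

    report = []
    for pair_key, sub in ratios.groupby("fucosylated_key"):
        sub = sub[sub["defined"]]
        x = sub.loc[[grp[s] == g1 for s in sub["sample_id"]], "neg_log10_ratio"]
        y = sub.loc[[grp[s] == g2 for s in sub["sample_id"]], "neg_log10_ratio"]
        if len(x) < 2 or len(y) < 2:
            continue
        test = compare_groups(x, y, equal_var=cfg.equal_var)
        labels = [1 if grp[s] == g2 else 0 for s in sub["sample_id"]]
        combo = combine_with_afp(
            sub["neg_log10_ratio"].to_numpy(),
            np.array([afp[s] for s in sub["sample_id"]]),
            labels,
        )
        report.append(
            {
                "target": pair_key,
                "n_excluded_undefined": int(
                    (~ratios.loc[ratios["fucosylated_key"] == pair_key, "defined"]).sum()
                ),
                "p_raw": test["p"],
                "t": test["t"],
                "scale": test["scale"],
                "auc_ratio": combo["roc_ratio"].auc,
                "auc_afp": combo["roc_afp"].auc,
                "auc_combined": combo["roc_combined"].auc,
                "sens_at_spec90_combined": combo["roc_combined"].sensitivity_at_spec90,
            }
        )
    rep = pd.DataFrame(report)
    if len(rep):
        rep["q_bh"] = bh_qvalues(rep["p_raw"])
    rep.to_csv(out / "report.csv", index=False)
    return rep


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the report bundle.

    Writes per-stage CSVs plus ``run_log.json`` (version, seed,
    parameters, design power) under ``config.out_dir``.  Raises on the
    first failing stage, naming it; partial outputs are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(config.seed).spawn(4)
    rng_children = dict(zip(("cohort", "prm", "annotate", "stats"), children))

    state: dict = {}
    results: dict = {"config": dataclasses.asdict(config)}
    current = "setup"
    try:
        if "simulate" in config.stages:
            current = "simulate"
            state = _simulate_stage(config, rng_children, out)
            results["n_runs"] = len(state["runs"])
        if "annotate" in config.stages:
            current = "annotate"
            results["annotations"] = _annotate_stage(config, rng_children, state, out)
        if "quantify" in config.stages:
            current = "quantify"
            quant, ratios = _quantify_stage(config, state, out)
            results["quant"] = quant
            results["ratios"] = ratios
        if "stats" in config.stages:
            current = "stats"
            results["report"] = _stats_stage(config, state, results["ratios"], out)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    log = {
        "glycoprm_version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "design_power": t_test_power(config.n1, config.n2, config.effect_size_d,
                                     config.alpha),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return results
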