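"""Configuration-driven orchestration of the extrapolation pipeline.

Stages (in order): virtual population, synthetic biomonitoring study,
calibration, global sensitivity analysis, in vitro free-concentration
transformation, ABC reverse dosimetry, benchmark-dose derivation.  Each
stage persists its tables under the output directory and the run manifest
records seeds, configuration hash, runtimes and output paths.  The master
seed spawns independent per-stage streams.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import HierarchicalCalibration, summarize
from .errors import ConfigError, DomainError
from .bmd import DoseResponseSet, bootstrap_bmdl
from .gsa import efast, lowry_bounds, morris_rank
from .params import default_parameters
from .reverse_dosimetry import (AbcConfig, assemble_dose_response,
                                make_pbk_summary_fn, preprocess_response,
                                reverse_dosimetry)
from .study import (ASSAY_PLATE, ASSAY_TISSUE, TOP10, load_assay_table,
                    posterior_ranges, tissue_auc_model_fn)
from .synthetic import SyntheticStudySpec, generate_hbm, sample_population
from .vcba import default_setup, load_bpa_physchem, transform_assay_table

STAGES = ("population", "hbm", "calibrate", "gsa", "vcba", "qivive", "bmd")


@dataclass
class RunConfig:
    """Pipeline settings; every field has a scaled-down default so a full run
    completes on a workstation."""

    outdir: str = "results/pipeline"
    seed: int = 0
    stages: tuple = STAGES
    assay: str = "ATG_PXR_TRANS_up"
    population_n: int = 200
    hbm: dict = field(default_factory=lambda: {"n_individuals": 4,
                                               "iterations": 200})
    gsa: dict = field(default_factory=lambda: {"output": "CVli",
                                               "trajectories": 10,
                                               "repeats": 3,
                                               "samples_per_param": 129,
                                               "top_k": 6})
    abc: dict = field(default_factory=lambda: {"phase1_n": 300,
                                               "phase2_iters": 500,
                                               "phase2_chains": 2,
                                               "n_targets": 3})
    bmd: dict = field(default_factory=lambda: {"replicates": 300})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def read_assay_csv(path) -> pd.DataFrame:
    """Validated dashboard-style assay table from CSV."""
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise DomainError(f"empty assay table: {path}")
    required = {"response", "response_type"}
    if not required <= set(df.columns):
        raise DomainError(f"assay table missing columns {required - set(df.columns)}")
    if "conc_um" not in df.columns and "log10_conc_um" not in df.columns:
        raise DomainError("assay table needs conc_um or log10_conc_um")
    if "conc_um" not in df.columns:
        df["conc_um"] = 10.0 ** df["log10_conc_um"].astype(float)
    return df


def write_results(tables: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Persist named tables as CSV; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    streams = {s: np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31)
               for i, s in enumerate(STAGES)}
    manifest = {"seed": config.seed, "config_hash": config.digest(),
                "stages": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}

    def record(stage, t0, paths, **extra):
        manifest["stages"][stage] = {"seed": int(streams[stage]),
                                     "runtime_s": round(time.time() - t0, 2),
                                     "outputs": paths, **extra}

    try:
        if "population" in config.stages:
            t0 = time.time()
            pop = sample_population(config.population_n, seed=streams["population"])
            paths = write_results({"population": pop}, out)
            record("population", t0, paths, n=len(pop))

        hbm = truth = None
        if "hbm" in config.stages:
            t0 = time.time()
            spec = SyntheticStudySpec(n_individuals=config.hbm["n_individuals"],
                                      seed=streams["hbm"])
            hbm, truth = generate_hbm(spec)
            hbm.to_csv(out / "hbm.csv")
            truth.to_csv(out / "hbm_true_parameters.csv", index=False)
            record("hbm", t0, {"hbm": str(out / "hbm.csv")})

        if "calibrate" in config.stages:
            t0 = time.time()
            if hbm is None:
                raise ConfigError("calibrate stage needs the hbm stage")
            cal = HierarchicalCalibration(
                hbm, global_params=["FB_BPA", "KM_liv_BPA_in_vitro"],
                individual_params=["MPY", "FracDOSEHep"], solver_step=0.02)
            chains = cal.run_mcmc(chains=2, iterations=config.hbm["iterations"],
                                  seed=int(streams["calibrate"]))
            chains.to_tsv(out / "chains.tsv", out / "chains_meta.json")
            summ = summarize(chains)
            summ.to_csv(out / "posterior_summary.csv")
            record("calibrate", t0, {"chains": str(out / "chains.tsv")})

        if "gsa" in config.stages:
            t0 = time.time()
            g = config.gsa
            output = g["output"]
            names = TOP10[output]
            ranges = posterior_ranges(names)
            fn = tissue_auc_model_fn(output)
            ranks = morris_rank(fn, ranges, trajectories=g["trajectories"],
                                repeats=g["repeats"], seed=int(streams["gsa"]),
                                top_k=g["top_k"])
            res = efast(fn, ranges, samples_per_param=g["samples_per_param"],
                        seed=int(streams["gsa"]))
            ribbon = lowry_bounds(res)
            paths = write_results({"morris_rank": ranks,
                                   "efast_indices": res.to_frame(),
                                   "lowry_ribbon": ribbon}, out)
            record("gsa", t0, paths)

        assay_tab = None
        if "vcba" in config.stages:
            t0 = time.time()
            chem = load_bpa_physchem()
            setup = default_setup(ASSAY_PLATE[config.assay], 0.05)
            assay_tab = transform_assay_table(load_assay_table(config.assay),
                                              chem, setup)
            paths = write_results({f"vcba_{config.assay}": assay_tab}, out)
            record("vcba", t0, paths)

        dr = None
        if "qivive" in config.stages:
            t0 = time.time()
            if assay_tab is None:
                raise ConfigError("qivive stage needs the vcba stage")
            a = config.abc
            tissue = ASSAY_TISSUE[config.assay]
            sens = TOP10[tissue][:8]
            ranges = posterior_ranges(sens)
            base = default_parameters()
            summary_fn = make_pbk_summary_fn(base, tissue, solver_step=0.02)
            targets = assay_tab["free_mgL"].to_numpy()[: a["n_targets"]]
            responses = preprocess_response(
                assay_tab["response"].to_numpy()[: a["n_targets"]],
                assay_tab["response_type"].iloc[0])
            posts = []
            for j, tgt in enumerate(targets):
                cfg = AbcConfig(target_tissue=tissue, phase1_n=a["phase1_n"],
                                phase2_iters=a["phase2_iters"],
                                phase2_chains=a["phase2_chains"],
                                sensitive_params=tuple(sens),
                                seed=int(streams["qivive"]) + j)
                posts.append(reverse_dosimetry(float(tgt), cfg, ranges, summary_fn))
            dr = assemble_dose_response(posts, list(responses))
            table = pd.DataFrame({
                "free_conc_mgL": [p.target for p in posts],
                "dose_mean": [p.mean for p in posts],
                "dose_lo": [p.q2_5 for p in posts],
                "dose_hi": [p.q97_5 for p in posts],
                "acc_phase1": [p.acceptance_phase1 for p in posts],
                "acc_phase2": [p.acceptance_phase2 for p in posts]})
            paths = write_results({f"poraldose_{config.assay}": table}, out)
            record("qivive", t0, paths)

        if "bmd" in config.stages:
            t0 = time.time()
            if dr is not None:
                mean_set = dr["mean"]
                ds = DoseResponseSet(dose=mean_set["dose"].to_numpy(),
                                     response=mean_set["response"].to_numpy())
            else:   # fall back to the published dose table for this assay
                from .study import load_poraldose_table
                tab = load_poraldose_table(config.assay)
                raw = load_assay_table(config.assay)
                resp = preprocess_response(raw["response"].to_numpy(),
                                           raw["response_type"].iloc[0])
                ds = DoseResponseSet(dose=tab["dose_mean"].to_numpy(), response=resp)
            res = bootstrap_bmdl(ds, replicates=config.bmd["replicates"],
                                 seed=int(streams["bmd"]))
            bmd_tab = pd.DataFrame([{"assay": config.assay, "bmd": res.bmd,
                                     "bmdl10": res.bmdl10, "bmdu10": res.bmdu10,
                                     "flags": ";".join(res.flags)}])
            paths = write_results({f"bmd_{config.assay}": bmd_tab}, out)
            record("bmd", t0, paths)
    except Exception as exc:
        manifest["failed"] = repr(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    manifest["completed"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
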