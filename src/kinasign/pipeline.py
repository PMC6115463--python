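"""Pipeline orchestration: simulate → differential → KSEA → stratify →
survival → TGI, with config handling, seeding, logging and machine-readable
outputs.

Every run writes its results, a config snapshot and SHA-256 checksums of
its input files into a run directory; with a fixed seed the result files
are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import differential, io, ksea, preclinical, simulate, stratify, survival
from .errors import KinasignError, ValidationError
from .stratify import SIGNATURE_KINASES

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-level configuration; thresholds default to the study settings."""

    seed: int = 0
    outdir: str = "kinasign_run"
    simulate: bool = True
    diff_fdr: float = 0.15
    ksea_fdr: float = 0.05
    ksea_fdr_relaxed: float = 0.25
    quantile: float = 0.75
    kinases: tuple = SIGNATURE_KINASES
    metric: str = "signed_t"
    weight_p: float = 1.0
    n_perm: int = 200
    min_set_size: int = 5
    max_set_size: int = 500
    stages: tuple = ("diff", "ksea", "stratify", "survival", "tgi")
    # input paths (used when simulate is False)
    sites_path: str | None = None
    motifs_path: str | None = None
    clinical_path: str | None = None
    growth_path: str | None = None
    sim: simulate.SimulationConfig = field(default=None)

    def __post_init__(self):
        if self.sim is None:
            self.sim = simulate.SimulationConfig(seed=self.seed)


def validate_config(config: PipelineConfig) -> PipelineConfig:
    """Check thresholds, kinase list and referenced paths; return config."""
    errors = []
    for name in ("diff_fdr", "ksea_fdr", "ksea_fdr_relaxed", "quantile"):
        v = getattr(config, name)
        if not 0.0 < v < 1.0:
            errors.append(f"{name} must be in (0, 1), got {v}")
    if not config.kinases:
        errors.append("kinase list must not be empty")
    if config.n_perm <= 0:
        errors.append("n_perm must be positive")
    if not config.simulate:
        for name in ("sites_path", "motifs_path", "clinical_path"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                errors.append(f"{name} missing or does not exist: {p}")
    if errors:
        raise ValidationError("invalid config: " + "; ".join(errors))
    return config


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", None)
    cfg = PipelineConfig(**raw)
    if sim_raw:
        cfg.sim = simulate.SimulationConfig(**sim_raw)
    return validate_config(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the run directory.

    Stage failures abort with the stage name attached to the error.
    """
    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    snapshot = dataclasses.asdict(config)
    snapshot["sim"] = dataclasses.asdict(config.sim)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)

    stage = "inputs"
    try:
        if config.simulate:
            inputs_dir = outdir / "inputs"
            sim = simulate.simulate_all(config.sim, inputs_dir)
            sites = sim["sites"]
            library = sim["library"]
            cohort = sim["clinical"]
            growth = sim["growth"]
        else:
            sites = io.read_site_table(config.sites_path)
            library = io.read_motifs(config.motifs_path)
            cohort = io.read_clinical(config.clinical_path)
            growth = (io.read_growth(config.growth_path)
                      if config.growth_path else None)
            inputs_dir = None
        checksums = {}
        paths = ([p for p in (inputs_dir or Path(".")).glob("*")]
                 if inputs_dir else
                 [Path(p) for p in (config.sites_path, config.motifs_path,
                                    config.clinical_path, config.growth_path)
                  if p])
        for p in sorted(paths):
            if p.is_file():
                checksums[p.name] = _sha256(p)
        with open(outdir / "input_checksums.json", "w") as fh:
            json.dump(checksums, fh, indent=1, sort_keys=True)

        summary = {"seed": config.seed}
        logged = differential.log_transform(sites)

        diff = None
        if "diff" in config.stages:
            stage = "diff"
            diff = differential.moderated_two_group_test(
                logged, fdr_threshold=config.diff_fdr
            )
            out = diff.copy()
            out.to_csv(outdir / "differential.tsv", sep="\t")
            summary["n_sites_tested"] = int(diff["tested"].sum())
            summary["n_sites_selected"] = int(diff["selected"].sum())

        if "ksea" in config.stages:
            stage = "ksea"
            kcfg = ksea.KseaConfig(
                metric=config.metric, weight_p=config.weight_p,
                n_perm=config.n_perm, seed=config.seed,
                min_size=config.min_set_size, max_size=config.max_set_size,
                fdr_significant=config.ksea_fdr,
                fdr_relaxed=config.ksea_fdr_relaxed,
            )
            run = ksea.ksea_run(logged, None, library, kcfg)
            res = run.results.copy()
            res["leading_edge"] = res["leading_edge"].map(";".join)
            res.to_csv(outdir / "ksea.tsv", sep="\t")
            rs = pd.DataFrame(
                {k: pd.Series(v) for k, v in run.running_sums.items()}
            )
            rs.insert(0, "rank", range(1, len(run.ranked) + 1))
            rs.to_csv(outdir / "ksea_running_sums.tsv", sep="\t", index=False)
            summary["n_kinase_sets"] = int(len(res))
            summary["n_ksea_significant"] = int(res["significant"].sum())
            summary["n_ksea_relaxed"] = int(res["relaxed"].sum())
            summary["top_nes_kinase"] = str(res["nes"].idxmax())

        status = None
        if "stratify" in config.stages:
            stage = "stratify"
            hs = cohort[[f"hscore_{k}" for k in config.kinases]].rename(
                columns=lambda c: c[len("hscore_"):]
            )
            status = stratify.binarize_quartile(hs, config.quantile)
            khigh = stratify.k_high(status, config.kinases)
            patterns = stratify.enumerate_patterns(status, cohort["event"])
            status.status.to_csv(outdir / "kinase_status.tsv", sep="\t")
            patterns.to_csv(outdir / "patterns.tsv", sep="\t", index=False)
            stratify.colinearity(hs).to_csv(outdir / "colinearity.tsv", sep="\t")
            summary["n_patterns_observed"] = int(len(patterns))
            summary["n_patterns_possible"] = int(patterns.attrs["max_patterns"])
            summary["n_khigh"] = int(khigh.sum())

        if "survival" in config.stages:
            stage = "survival"
            if status is None:
                hs = cohort[[f"hscore_{k}" for k in config.kinases]].rename(
                    columns=lambda c: c[len("hscore_"):]
                )
                status = stratify.binarize_quartile(hs, config.quantile)
            indicators = status.status.copy()
            indicators["K-high"] = stratify.k_high(status, config.kinases)
            report = survival.kinase_survival_report(cohort, indicators)
            report.to_csv(outdir / "survival.tsv", sep="\t")
            summary["khigh_hr"] = float(report.loc["K-high", "cox_hr"])
            summary["khigh_logrank_p"] = float(report.loc["K-high", "logrank_p"])

        if "tgi" in config.stages and growth is not None:
            stage = "tgi"
            vehicle = growth[growth["arm"] == "vehicle"]
            rows = []
            for arm in growth["arm"].unique():
                if arm == "vehicle":
                    continue
                res = preclinical.tgi(growth[growth["arm"] == arm], vehicle)
                rows.append(dataclasses.asdict(res))
            if rows:
                pd.DataFrame(rows).to_csv(outdir / "tgi.tsv", sep="\t",
                                          index=False)
                summary["tgi_by_arm"] = {r["arm"]: r["tgi"] for r in rows}

        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
    except KinasignError as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    return outdir
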