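"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates, at desk scale, the five inputs of the analysis:

* a motif library (by default 224 kinase + 23 phosphatase + 80 SH2 linear
  motifs, mirroring the 327-motif annotation used for kinase prediction);
* a synthetic proteome whose phosphosite flanking windows are constructed
  to satisfy chosen motifs, so every site carries a known planted motif
  membership;
* a phosphosite × sample intensity matrix: log2 intensities are normal
  around a per-site baseline, substrates of the configured *active*
  kinases are shifted up by ``effect_log2fc`` in the "relapsed" group, and
  intensity-dependent (MNAR-lite) dropout removes values preferentially at
  low abundance;
* a clinical cohort: per-patient H-scores for the six signature kinases,
  T/N/G/age covariates, and exponential relapse times whose hazard is
  multiplied by planted per-kinase hazard ratios (and optionally a K-high
  level hazard ratio), with independent uniform censoring;
* xenograft growth curves, exponential with per-arm rate multipliers and
  lognormal measurement noise.

Every generator is a pure function of the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import ValidationError
from .io import (
    SiteMatrix,
    write_clinical,
    write_fasta,
    write_growth,
    write_motifs,
    write_site_table,
)
from .motifs import AMINO_ACIDS, HALF, WINDOW, Motif, MotifLibrary
from .stratify import SIGNATURE_KINASES

BASE_LOG2_INTENSITY = 25.0  # typical log2 MS1 intensity midpoint
SITE_BASELINE_SD = 2.0      # between-site spread of baseline abundance
MISSING_SLOPE = 0.5         # dropout steepness per log2 unit below baseline
ANIMALS_PER_ARM = 6
GROWTH_DAYS = tuple(range(0, 22, 3))
V0_MM3 = 500.0              # randomisation threshold volume
ASPECT = 1.25               # D/d caliper aspect ratio for emitted diameters


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions."""

    seed: int = 0
    n_samples_per_group: int = 10
    n_proteins: int = 100
    n_sites: int = 1635
    n_kinase_motifs: int = 224
    n_phosphatase_motifs: int = 23
    n_sh2_motifs: int = 80
    active_kinases: list = field(default_factory=list)
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    missing_rate_base: float = 0.1
    n_patients: int = 113
    kinase_hr: dict = field(default_factory=dict)
    khigh_hr: float | None = None
    censor_rate: float = 0.6
    growth_rate_vehicle: float = 0.1
    growth_effect: dict = field(default_factory=lambda: {"vehicle": 1.0})
    growth_noise_sd: float = 0.1
    baseline_median_months: float = 60.0

    def __post_init__(self):
        for name in ("missing_rate_base", "censor_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_kinase_motifs", "n_phosphatase_motifs", "n_sh2_motifs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        bad = set(self.kinase_hr) - set(SIGNATURE_KINASES)
        if bad:
            raise ValidationError(
                f"kinase_hr keys must be signature kinases; unknown {sorted(bad)}"
            )
        if any(v <= 0 for v in self.kinase_hr.values()):
            raise ValidationError("hazard ratios must be positive")
        if self.khigh_hr is not None and self.khigh_hr <= 0:
            raise ValidationError("khigh_hr must be positive")


def _motif_names(cfg: SimulationConfig):
    kin = [f"KIN_{i + 1:03d}" for i in range(cfg.n_kinase_motifs)]
    pho = [f"PHOS_{i + 1:03d}" for i in range(cfg.n_phosphatase_motifs)]
    sh2 = [f"SH2_{i + 1:03d}" for i in range(cfg.n_sh2_motifs)]
    return kin, pho, sh2


def generate_motif_library(cfg: SimulationConfig) -> MotifLibrary:
    """Random position-specific motifs over the 15-residue window.

    Each motif fixes the centre residue (S/T/Y for kinase and phosphatase
    motifs, Y for SH2 motifs) and constrains three further positions to
    one or two residues — specific enough that incidental matches to
    random windows are rare.
    """
    rng = np.random.default_rng(cfg.seed)
    kin, pho, sh2 = _motif_names(cfg)
    motifs = []
    for names, category in ((kin, "kinase"), (pho, "phosphatase"), (sh2, "sh2")):
        for name in names:
            slots = [None] * WINDOW
            if category == "sh2":
                center = "Y"
            else:
                center = str(rng.choice(list("STY"), p=[0.5, 0.3, 0.2]))
            slots[HALF] = frozenset(center)
            positions = rng.choice(
                [i for i in range(WINDOW) if i != HALF], size=3, replace=False
            )
            for pos in positions:
                k = int(rng.integers(1, 3))
                residues = rng.choice(list(AMINO_ACIDS), size=k, replace=False)
                slots[pos] = frozenset(residues)
            motifs.append(Motif(name=name, category=category, slots=tuple(slots)))
    return MotifLibrary(motifs)


def _window_for_motif(motif: Motif, rng) -> str:
    chars = []
    for slot in motif.slots:
        if slot is None:
            chars.append(str(rng.choice(list(AMINO_ACIDS))))
        else:
            chars.append(str(rng.choice(sorted(slot))))
    return "".join(chars)


def generate_proteome_and_sites(cfg: SimulationConfig, lib: MotifLibrary):
    """Synthesise proteins whose phosphosites match known motifs.

    Sites are assigned to motifs round-robin (active kinases first, so
    each active kinase is guaranteed substrates); each site's 15-residue
    window is drawn to satisfy its motif and the windows are concatenated
    into protein sequences.  Returns ``(proteins, annotations)`` where
    ``annotations`` records, per site, the protein, residue, position,
    flank and the planted motif name (the generator's truth table).
    """
    if cfg.n_sites > 0 and cfg.n_proteins <= 0:
        raise ValidationError("n_sites > 0 requires n_proteins > 0")
    missing = [k for k in cfg.active_kinases if k not in lib]
    if missing:
        raise ValidationError(f"active kinases not in library: {missing}")
    if cfg.active_kinases and cfg.n_sites < len(cfg.active_kinases):
        raise ValidationError("need at least one site per active kinase")
    rng = np.random.default_rng(cfg.seed + 1)
    order = list(cfg.active_kinases) + [
        n for n in lib.names() if n not in cfg.active_kinases
    ]
    sites_per_protein = int(np.ceil(cfg.n_sites / cfg.n_proteins))
    proteins: dict = {}
    rows = []
    for i in range(cfg.n_sites):
        motif_name = order[i % len(order)] if order else None
        prot_idx = i // sites_per_protein
        protein_id = f"PROT{prot_idx + 1:04d}"
        if motif_name is None:
            window = "".join(rng.choice(list(AMINO_ACIDS), size=WINDOW))
            mid = window[:HALF] + str(rng.choice(list("STY"))) + window[HALF + 1:]
            window = mid
        else:
            window = _window_for_motif(lib[motif_name], rng)
        seq = proteins.get(protein_id, "")
        position = len(seq) + HALF + 1  # 1-based centre of the appended window
        proteins[protein_id] = seq + window
        residue = window[HALF]
        rows.append({
            "site_id": f"{protein_id}_{residue}{position}",
            "protein_id": protein_id,
            "residue": residue,
            "position": position,
            "flank": window,
            "planted_motif": motif_name or "",
        })
    annotations = pd.DataFrame(rows).set_index("site_id")
    return proteins, annotations


def generate_site_matrix(cfg: SimulationConfig,
                         annotations: pd.DataFrame) -> SiteMatrix:
    """Log-normal intensity matrix with planted group effect and dropout.

    Substrate sites of the configured active kinases are shifted up by
    ``effect_log2fc`` (log2 units) in the "relapsed" group.  Dropout
    probability follows a logistic curve in the true log2 intensity
    anchored at ``missing_rate_base`` for a baseline-abundance value.
    Intensities are returned on the raw (linear) scale.
    """
    if cfg.noise_sd <= 0:
        raise ValidationError("noise_sd must be > 0")
    rng = np.random.default_rng(cfg.seed + 2)
    n = cfg.n_samples_per_group
    samples = [f"R{i + 1:02d}" for i in range(n)] + \
              [f"N{i + 1:02d}" for i in range(n)]
    groups = pd.Series(
        ["relapsed"] * n + ["non-relapsed"] * n, index=samples, name="group"
    )
    n_sites = len(annotations)
    baseline = rng.normal(BASE_LOG2_INTENSITY, SITE_BASELINE_SD, size=n_sites)
    log2x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_sites, 2 * n))
    if "planted_motif" in annotations.columns:
        is_active = annotations["planted_motif"].isin(cfg.active_kinases).to_numpy()
    else:
        is_active = np.zeros(n_sites, dtype=bool)
    log2x[np.ix_(is_active, np.arange(n))] += cfg.effect_log2fc
    if cfg.missing_rate_base > 0:
        logit_base = np.log(cfg.missing_rate_base / (1 - cfg.missing_rate_base))
        p_miss = expit(logit_base - MISSING_SLOPE * (log2x - BASE_LOG2_INTENSITY))
        drop = rng.random(log2x.shape) < p_miss
        log2x[drop] = np.nan
    intensities = pd.DataFrame(
        np.exp2(log2x), index=annotations.index, columns=samples
    )
    ann = annotations.drop(columns=["planted_motif"], errors="ignore")
    matrix = SiteMatrix(ann, intensities, groups)
    return matrix


def generate_clinical_cohort(cfg: SimulationConfig):
    """Cohort of patients with planted prognostic kinase effects.

    H-scores per signature kinase are continuous on [0, 3], so roughly a
    quarter of patients land strictly above each cohort 75th percentile.
    The relapse hazard is exponential: baseline rate ``log 2 /
    baseline_median_months``, multiplied per patient by ``kinase_hr[k]``
    for every kinase whose H-score exceeds its quartile threshold and by
    ``khigh_hr`` when any does.  Censoring times are uniform on
    ``(0, c_max)`` with ``c_max`` chosen so the expected censored fraction
    is ``censor_rate``.

    Returns ``(cohort, truth)``: the clinical frame (indexed by
    patient id) and the planted per-kinase status table with its K-high
    column.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n = cfg.n_patients
    ids = [f"P{i + 1:04d}" for i in range(n)]
    hs = pd.DataFrame(
        {k: 3.0 * rng.beta(2.0, 2.0, size=n) for k in SIGNATURE_KINASES},
        index=ids,
    )
    thresholds = hs.quantile(0.75)
    status = (hs > thresholds).astype(int)
    khigh = status.max(axis=1)
    lam0 = np.log(2.0) / cfg.baseline_median_months
    lam = np.full(n, lam0)
    for k, hr in cfg.kinase_hr.items():
        lam = lam * np.power(hr, status[k].to_numpy())
    if cfg.khigh_hr is not None:
        lam = lam * np.power(cfg.khigh_hr, khigh.to_numpy())
    t_event = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        lam_bar = lam.mean()

        def _cens_frac(cmax):
            return (1.0 - np.exp(-lam_bar * cmax)) / (lam_bar * cmax)

        c_max = brentq(lambda c: _cens_frac(c) - cfg.censor_rate,
                       1e-9, 1e7)
        c_time = rng.uniform(0.0, c_max, size=n)
        time = np.minimum(t_event, c_time)
        event = (t_event <= c_time).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-6)
    cohort = pd.DataFrame({
        "T": rng.choice([1, 2, 3, 4], size=n, p=[0.3, 0.4, 0.2, 0.1]),
        "N": rng.choice([0, 1, 2, 3], size=n, p=[0.5, 0.25, 0.15, 0.1]),
        "G": rng.choice([1, 2, 3], size=n, p=[0.15, 0.35, 0.5]),
        "age": np.clip(rng.normal(56.0, 12.0, size=n), 25, 90).round(1),
        "event": event,
        "time": time,
    }, index=pd.Index(ids, name="patient_id"))
    for k in SIGNATURE_KINASES:
        cohort[f"hscore_{k}"] = hs[k]
    truth = status.copy()
    truth["k_high"] = khigh
    return cohort, truth


def generate_growth_curves(cfg: SimulationConfig) -> pd.DataFrame:
    """Exponential xenograft growth with per-arm rate multipliers.

    ``V(t) = V0 · exp(r · multiplier · t) · exp(ε)`` with lognormal noise
    ``ε ~ N(0, growth_noise_sd)``; emits caliper diameters consistent with
    the ellipsoid volume formula as well as the volume itself.
    """
    if "vehicle" not in cfg.growth_effect:
        raise ValidationError('growth_effect must include a "vehicle" arm')
    rng = np.random.default_rng(cfg.seed + 4)
    rows = []
    for arm, mult in cfg.growth_effect.items():
        for a in range(ANIMALS_PER_ARM):
            animal = f"{arm}_{a + 1:02d}"
            for day in GROWTH_DAYS:
                v = V0_MM3 * np.exp(cfg.growth_rate_vehicle * mult * day)
                if cfg.growth_noise_sd > 0:
                    v *= np.exp(rng.normal(0.0, cfg.growth_noise_sd))
                d_short = (2.0 * v / ASPECT) ** (1.0 / 3.0)
                rows.append({
                    "animal_id": animal,
                    "arm": arm,
                    "day": day,
                    "D": ASPECT * d_short,
                    "d": d_short,
                    "volume": v,
                })
    return pd.DataFrame(rows)


def simulate_all(cfg: SimulationConfig, outdir) -> dict:
    """Generate and write every pipeline input plus a JSON truth sidecar.

    Returns the in-memory objects: library, proteins, site matrix,
    clinical cohort, growth table and the truth dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib = generate_motif_library(cfg)
    proteins, annotations = generate_proteome_and_sites(cfg, lib)
    matrix = generate_site_matrix(cfg, annotations)
    cohort, clinical_truth = generate_clinical_cohort(cfg)
    growth = generate_growth_curves(cfg)
    write_motifs(lib, outdir / "motifs.tsv")
    write_fasta(proteins, outdir / "proteome.fasta")
    write_site_table(matrix, outdir / "sites.tsv")
    write_clinical(cohort, outdir / "clinical.csv")
    write_growth(growth, outdir / "growth.csv")
    truth = {
        "seed": cfg.seed,
        "config": {
            k: (v if not isinstance(v, dict) else dict(v))
            for k, v in dataclasses.asdict(cfg).items()
        },
        "planted_motif_by_site": annotations["planted_motif"].to_dict(),
        "active_kinases": list(cfg.active_kinases),
        "clinical_status": {
            c: clinical_truth[c].to_dict() for c in clinical_truth.columns
        },
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return {
        "library": lib,
        "proteins": proteins,
        "annotations": annotations,
        "sites": matrix,
        "clinical": cohort,
        "clinical_truth": clinical_truth,
        "growth": growth,
        "truth": truth,
    }
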