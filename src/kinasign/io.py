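"""Readers and writers for every format the pipeline touches.

Formats
-------
* **Site table** — tab-separated, UTF-8, ``.`` decimal.  Fixed columns
  ``site_id``, ``protein_id``, ``residue``, ``position``, ``flank`` followed
  by one intensity column per sample named ``intensity:<sample>:<group>``.
  Missing intensities are empty cells (never 0).  Unknown extra columns are
  preserved as annotation passthrough.
* **Motif library** — TSV with ``name``, ``category`` and 15 slot columns
  ``p-7`` … ``p+7``; each slot is ``X`` (any residue) or a string of
  allowed one-letter residues.
* **Clinical table** — CSV with ``patient_id``, ``T``, ``N``, ``G``,
  ``age``, ``event``, ``time``, one ``hscore_<kinase>`` column per kinase,
  optional ``area_<kinase>_{high,med,low}`` triples and ``mut_<gene>``
  booleans.
* **Growth table** — CSV with ``animal_id``, ``arm``, ``day`` and either
  caliper diameters ``D``/``d`` (mm) or a precomputed ``volume`` (mm³).
* **FASTA** — standard, via Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError
from .motifs import (
    AMINO_ACIDS,
    CENTER_RESIDUES,
    HALF,
    WINDOW,
    Motif,
    MotifLibrary,
)

SITE_COLUMNS = ["site_id", "protein_id", "residue", "position", "flank"]
INTENSITY_PREFIX = "intensity:"
CLINICAL_COLUMNS = ["patient_id", "T", "N", "G", "age", "event", "time"]
_SLOT_NAMES = [f"p{i:+d}" if i else "p0" for i in range(-HALF, HALF + 1)]


@dataclass
class SiteMatrix:
    """Phosphosite × sample intensity matrix with site annotations.

    Attributes
    ----------
    annotations:
        Frame indexed by unique ``site_id`` with columns ``protein_id``,
        ``residue`` (one of S/T/Y), ``position`` (1-based) and ``flank``
        (15-char window); extra columns are carried through untouched.
    intensities:
        Frame indexed like ``annotations`` with one float column per
        sample; ``NaN`` marks a missing (undetected) value.
    sample_groups:
        Series mapping sample name to its group label (by convention
        ``relapsed`` / ``non-relapsed``).
    """

    annotations: pd.DataFrame
    intensities: pd.DataFrame
    sample_groups: pd.Series = field(default=None)

    def __post_init__(self):
        ann = self.annotations
        if not ann.index.is_unique:
            dup = ann.index[ann.index.duplicated()][:5].tolist()
            raise ValidationError(f"duplicate site_id: {dup}")
        for col in ("protein_id", "residue", "position", "flank"):
            if col not in ann.columns:
                raise ValidationError(f"annotations missing column {col!r}")
        bad = ann.index[~ann["residue"].isin(list(CENTER_RESIDUES))]
        if len(bad):
            raise ValidationError(f"residue not S/T/Y for sites {bad[:5].tolist()}")
        if (ann["position"] < 1).any():
            raise ValidationError("positions must be 1-based (>= 1)")
        badflank = ann.index[
            (ann["flank"].str.len() != WINDOW)
            | (~ann["flank"].str[HALF].isin(list(CENTER_RESIDUES)))
        ]
        if len(badflank):
            raise ValidationError(
                f"flank must be {WINDOW} chars centred on S/T/Y; bad sites "
                f"{badflank[:5].tolist()}"
            )
        if not self.intensities.index.equals(ann.index):
            raise ValidationError("intensities index must equal annotations index")
        if (self.intensities < 0).any().any():
            raise ValidationError("intensities must be nonnegative")
        if self.sample_groups is None:
            self.sample_groups = pd.Series(
                "", index=self.intensities.columns, name="group"
            )
        missing = set(self.intensities.columns) - set(self.sample_groups.index)
        if missing:
            raise ValidationError(f"samples without group label: {sorted(missing)}")

    @property
    def samples(self):
        return list(self.intensities.columns)

    @property
    def site_ids(self):
        return list(self.annotations.index)

    def copy(self) -> "SiteMatrix":
        return SiteMatrix(
            self.annotations.copy(),
            self.intensities.copy(),
            self.sample_groups.copy(),
        )


def write_site_table(matrix: SiteMatrix, path) -> None:
    ann = matrix.annotations.reset_index()
    ann = ann.rename(columns={ann.columns[0]: "site_id"})
    out = ann.copy()
    for sample in matrix.intensities.columns:
        group = matrix.sample_groups[sample]
        out[f"{INTENSITY_PREFIX}{sample}:{group}"] = matrix.intensities[sample].values
    out.to_csv(path, sep="\t", index=False, na_rep="")


def read_site_table(path) -> SiteMatrix:
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot read site table: {exc}", path=path)
    for col in SITE_COLUMNS:
        if col not in raw.columns:
            raise ParseError("missing required column", path=path, field=col)
    if raw["site_id"].duplicated().any():
        row = int(raw.index[raw["site_id"].duplicated()][0]) + 2
        raise ParseError("duplicate site_id", path=path, line=row, field="site_id")
    for idx, flank in raw["flank"].items():
        if len(flank) != WINDOW:
            raise ParseError(
                f"flank has length {len(flank)}, expected {WINDOW}",
                path=path, line=int(idx) + 2, field="flank",
            )
    intensity_cols = [c for c in raw.columns if c.startswith(INTENSITY_PREFIX)]
    samples, groups = [], {}
    for col in intensity_cols:
        parts = col[len(INTENSITY_PREFIX):].rsplit(":", 1)
        sample = parts[0]
        samples.append((col, sample))
        groups[sample] = parts[1] if len(parts) == 2 else ""
    ann = raw.drop(columns=intensity_cols).set_index("site_id")
    ann["position"] = pd.to_numeric(ann["position"]).astype(int)
    intens = {}
    for col, sample in samples:
        vals = raw[col].replace("", np.nan)
        try:
            intens[sample] = pd.to_numeric(vals).astype(float)
        except (ValueError, TypeError):
            bad = vals[pd.to_numeric(vals, errors="coerce").isna() & vals.notna()]
            raise ParseError(
                f"non-numeric intensity {bad.iloc[0]!r}",
                path=path, line=int(bad.index[0]) + 2, field=col,
            )
    intensities = pd.DataFrame(intens)
    intensities.index = ann.index  # row order is preserved by the parser
    sample_groups = pd.Series(groups, name="group")
    return SiteMatrix(ann, intensities, sample_groups)


def read_fasta(path) -> dict:
    """Read protein records into an ``{id: sequence}`` dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError("duplicate FASTA id", path=path, field=rec.id)
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(records: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_motifs(library: MotifLibrary, path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tcategory\t" + "\t".join(_SLOT_NAMES) + "\n")
        for m in library:
            fh.write(f"{m.name}\t{m.category}\t{m.pattern_string()}\n")


def read_motifs(path) -> MotifLibrary:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["name", "category"] + _SLOT_NAMES
    for col in needed:
        if col not in raw.columns:
            raise ParseError("missing required column", path=path, field=col)
    motifs = []
    for idx, row in raw.iterrows():
        slots = []
        for col in _SLOT_NAMES:
            cell = row[col]
            if cell == "X":
                slots.append(None)
                continue
            bad = set(cell) - set(AMINO_ACIDS)
            if bad:
                raise ParseError(
                    f"invalid residue {''.join(sorted(bad))!r} in motif "
                    f"{row['name']!r}",
                    path=path, line=int(idx) + 2, field=col,
                )
            slots.append(frozenset(cell))
        try:
            motifs.append(Motif(row["name"], row["category"], tuple(slots)))
        except ValidationError as exc:
            raise ParseError(str(exc), path=path, line=int(idx) + 2)
    try:
        return MotifLibrary(motifs)
    except ValidationError as exc:
        raise ParseError(str(exc), path=path)


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical cohort table; returns a frame indexed by patient_id.

    Validates event coding, positive follow-up time, H-scores in [0, 3] and
    per-kinase area fractions summing to at most 100.
    """
    raw = pd.read_csv(path)
    for col in CLINICAL_COLUMNS:
        if col not in raw.columns:
            raise ParseError("missing required column", path=path, field=col)
    if raw["patient_id"].duplicated().any():
        row = int(raw.index[raw["patient_id"].duplicated()][0]) + 2
        raise ParseError("duplicate patient_id", path=path, line=row,
                         field="patient_id")
    bad_time = raw.index[raw["time"] <= 0]
    if len(bad_time):
        raise ParseError("time must be > 0", path=path,
                         line=int(bad_time[0]) + 2, field="time")
    if not raw["event"].isin([0, 1]).all():
        row = int(raw.index[~raw["event"].isin([0, 1])][0]) + 2
        raise ParseError("event must be 0 or 1", path=path, line=row,
                         field="event")
    for col in raw.columns:
        if col.startswith("hscore_"):
            bad = raw.index[(raw[col] < 0) | (raw[col] > 3)]
            if len(bad):
                raise ParseError("hscore outside [0, 3]", path=path,
                                 line=int(bad[0]) + 2, field=col)
    area_kinases = {
        c[len("area_"):-len("_high")]
        for c in raw.columns if c.startswith("area_") and c.endswith("_high")
    }
    for kin in area_kinases:
        cols = [f"area_{kin}_{lvl}" for lvl in ("high", "med", "low")]
        if not all(c in raw.columns for c in cols):
            raise ParseError(f"incomplete area triple for kinase {kin!r}",
                             path=path, field=f"area_{kin}_*")
        total = raw[cols].sum(axis=1)
        if (raw[cols] < 0).any().any() or (total > 100 + 1e-9).any():
            raise ParseError(
                f"area percentages for {kin!r} must be >= 0 and sum <= 100",
                path=path, field=f"area_{kin}_*",
            )
    return raw.set_index("patient_id")


def write_clinical(cohort: pd.DataFrame, path) -> None:
    cohort.reset_index().to_csv(path, index=False)


def read_growth(path) -> pd.DataFrame:
    """Read per-animal tumor measurements; returns a tidy frame."""
    raw = pd.read_csv(path)
    for col in ("animal_id", "arm", "day"):
        if col not in raw.columns:
            raise ParseError("missing required column", path=path, field=col)
    has_diam = "D" in raw.columns and "d" in raw.columns
    if not has_diam and "volume" not in raw.columns:
        raise ParseError("need either D/d diameters or a volume column",
                         path=path, field="volume")
    if has_diam:
        bad = raw.index[(raw["d"] <= 0) | (raw["D"] < raw["d"])]
        if len(bad):
            raise ParseError("need D >= d > 0", path=path,
                             line=int(bad[0]) + 2, field="D/d")
    if "volume" in raw.columns and (raw["volume"] <= 0).any():
        row = int(raw.index[raw["volume"] <= 0][0]) + 2
        raise ParseError("volume must be positive", path=path, line=row,
                         field="volume")
    if raw.duplicated(["animal_id", "day"]).any():
        row = int(raw.index[raw.duplicated(["animal_id", "day"])][0]) + 2
        raise ParseError("duplicate animal_id/day measurement", path=path,
                         line=row, field="animal_id")
    return raw


def write_growth(growth: pd.DataFrame, path) -> None:
    growth.to_csv(path, index=False)
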