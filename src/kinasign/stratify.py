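"""H-score computation, quartile binarisation and kinase-activation patterns.

Immunohistochemistry H-scores weight the high / medium / low staining area
fractions 3 / 2 / 1, giving a value in [0, 3] per patient and kinase.
Per kinase, patients strictly above the cohort's 75th percentile are coded
as "high" (1); the per-patient OR across the six signature kinases defines
K-high.  Each patient's 6-bit high/low vector is an activation pattern;
with k kinases there are 2^k theoretically possible patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

#: The six signature kinases in the fixed display/pattern-bit order.
SIGNATURE_KINASES = ("PRKCE", "c-Kit", "p-ERK", "p-P70S6K", "p-PNKP", "CDK6")

QUANTILE = 0.75


def h_score(area_pct_high: float, area_pct_med: float, area_pct_low: float) -> float:
    """IHC H-score: (high·3 + med·2 + low·1) / 100, in [0, 3].

    Inputs are area percentages of the whole tissue; they must be
    nonnegative and sum to at most 100.
    """
    areas = (area_pct_high, area_pct_med, area_pct_low)
    if any(a < 0 for a in areas):
        raise ValidationError(f"negative area percentage in {areas}")
    if sum(areas) > 100 + 1e-9:
        raise ValidationError(f"area percentages sum to {sum(areas)} > 100")
    return (area_pct_high * 3 + area_pct_med * 2 + area_pct_low * 1) / 100.0


@dataclass
class KinaseStatusMatrix:
    """Patient × kinase binary activation status with derivation metadata."""

    status: pd.DataFrame  # patients × kinases, values in {0, 1}
    thresholds: pd.Series  # per-kinase 75th-percentile cut
    quantile: float = QUANTILE
    rule: str = "strictly above (linear-interpolation quantile)"

    @property
    def kinases(self):
        return list(self.status.columns)

    @property
    def patients(self):
        return list(self.status.index)


def binarize_quartile(hscores: pd.DataFrame, quantile: float = QUANTILE) -> KinaseStatusMatrix:
    """Encode each patient 1 iff strictly above the per-kinase cohort quantile.

    ``hscores`` is a patient × kinase frame.  The threshold is the
    linear-interpolation quantile of the cohort (per kinase); ties at the
    threshold are coded 0.
    """
    if len(hscores) < 4:
        raise ValidationError("need at least 4 patients to define quartiles")
    thresholds = hscores.quantile(quantile, interpolation="linear")
    status = (hscores > thresholds).astype(int)
    return KinaseStatusMatrix(status=status, thresholds=thresholds,
                              quantile=quantile)


def k_high(status: KinaseStatusMatrix,
           kinases=SIGNATURE_KINASES) -> pd.Series:
    """Per-patient K-high: 1 iff any of the given kinases is high."""
    missing = [k for k in kinases if k not in status.status.columns]
    if missing:
        raise ValidationError(f"status matrix lacks kinases {missing}")
    return status.status[list(kinases)].max(axis=1).rename("k_high")


def k_test_variables(status: KinaseStatusMatrix, combos: dict) -> pd.DataFrame:
    """Indicator variables from kinase subsets (OR over each subset).

    ``combos`` maps a variable name (e.g. ``K-test_1``) to a nonempty
    subset of the kinase columns.
    """
    out = {}
    for name, subset in combos.items():
        subset = list(subset)
        if not subset:
            raise ValidationError(f"empty kinase subset for {name!r}")
        missing = [k for k in subset if k not in status.status.columns]
        if missing:
            raise ValidationError(f"{name!r} references unknown kinases {missing}")
        out[name] = status.status[subset].max(axis=1)
    return pd.DataFrame(out, index=status.status.index)


def enumerate_patterns(status: KinaseStatusMatrix,
                       events: pd.Series | None = None,
                       kinase_order=None) -> pd.DataFrame:
    """Tabulate observed activation patterns.

    Each pattern id is the k-bit string of per-kinase statuses in
    ``kinase_order`` (default: the matrix column order, or the fixed
    signature order when those six kinases are present).  Returns one row
    per observed pattern with patient counts, relapse counts (if
    ``events`` given) and an exclusivity flag; the frame's
    ``attrs["max_patterns"]`` records the theoretical maximum 2^k.
    """
    cols = list(status.status.columns)
    if kinase_order is None:
        kinase_order = [k for k in SIGNATURE_KINASES if k in cols] \
            if set(SIGNATURE_KINASES) <= set(cols) else cols
    mat = status.status[list(kinase_order)]
    patterns = mat.apply(lambda row: "".join(str(int(v)) for v in row), axis=1)
    rows = []
    for pat, members in patterns.groupby(patterns).groups.items():
        n = len(members)
        n_relapse = int(events.loc[members].sum()) if events is not None else 0
        rows.append({
            "pattern": pat,
            "n_patients": n,
            "n_relapse": n_relapse,
            "exclusive_to_relapsed": events is not None and n_relapse == n,
        })
    table = pd.DataFrame(rows).sort_values(
        ["n_patients", "pattern"], ascending=[False, True]
    ).reset_index(drop=True)
    table.attrs["max_patterns"] = 2 ** len(kinase_order)
    table.attrs["kinase_order"] = list(kinase_order)
    return table


def colinearity(hscores: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of kinase H-scores."""
    corr = hscores.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def overlay_mutations(patterns: pd.DataFrame, status: KinaseStatusMatrix,
                      mutations: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate activation patterns against mutation profiles.

    ``mutations`` is a patient × gene boolean frame.  For every observed
    pattern, lists each distinct mutation profile among its patients with
    its count — pure tabulation, no inference.
    """
    if mutations.shape[1] == 0:
        raise ValidationError("empty mutation table")
    order = patterns.attrs.get("kinase_order", list(status.status.columns))
    mat = status.status[list(order)]
    pat_per_patient = mat.apply(
        lambda row: "".join(str(int(v)) for v in row), axis=1
    )
    genes = list(mutations.columns)
    rows = []
    for pat in patterns["pattern"]:
        members = pat_per_patient.index[pat_per_patient == pat]
        profiles = mutations.loc[members].astype(int).apply(
            lambda row: "".join(str(v) for v in row), axis=1
        )
        for profile, count in profiles.value_counts().items():
            rows.append({
                "pattern": pat,
                "mutation_profile": profile,
                "n_patients": int(count),
            })
    out = pd.DataFrame(rows)
    out.attrs["genes"] = genes
    return out
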