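"""Kinase-set enrichment analysis (KSEA).

Asks, per kinase (or phosphatase / SH2 domain), whether the kinase's
putative substrates — phosphosites whose flanking windows match its linear
motif — concentrate at one end of a ranked phosphosite list.  The statistic
is the weighted Kolmogorov–Smirnov running sum of gene-set enrichment
analysis: walking down the ranked list, substrate hits increment the sum by
``|metric|^p`` (normalised by the set total) and misses decrement it by
``1/(N − set size)``; the enrichment score (ES) is the signed supremum.
Significance comes from a permutation null (phenotype relabelling when
group sizes allow, otherwise random same-size site sets), ES is normalised
to NES by the mean same-sign null magnitude, and a pooled signed-NES
procedure yields FDR q-values across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import moderated_two_group_test
from .errors import ValidationError
from .io import SiteMatrix
from .motifs import KinaseSet, MotifLibrary, build_kinase_sets

logger = logging.getLogger(__name__)

RANK_METRICS = ("signed_t", "log2fc", "mean_intensity_diff")
PHENOTYPE_MIN_PER_GROUP = 7


@dataclass(frozen=True)
class RankedList:
    """Sites in descending metric order with deterministic tie-breaking."""

    ids: tuple
    metric: np.ndarray

    def __post_init__(self):
        if len(self.ids) != len(self.metric):
            raise ValidationError("ids and metric lengths differ")

    def __len__(self):
        return len(self.ids)

    def position(self) -> dict:
        return {sid: i for i, sid in enumerate(self.ids)}


@dataclass
class EnrichmentScore:
    """ES with its running sum, leading edge and degeneracy flag."""

    es: float
    running_sum: np.ndarray
    leading_edge: list
    degenerate: bool = False


@dataclass
class KseaConfig:
    metric: str = "signed_t"
    weight_p: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    mode: str = "auto"  # phenotype | set | auto
    min_size: int = 5
    max_size: int = 500
    fdr_significant: float = 0.05
    fdr_relaxed: float = 0.25


@dataclass
class KseaRun:
    """Full KSEA output: the results table plus plotting material."""

    results: pd.DataFrame
    ranked: RankedList
    running_sums: dict = field(default_factory=dict)
    mode: str = "phenotype"


def _metric_vector(sites: SiteMatrix, groups: pd.Series, metric: str,
                   group_order=None) -> pd.Series:
    diff = moderated_two_group_test(sites, groups, group_order=group_order)
    if metric == "signed_t":
        vals = diff["t_mod"]
    elif metric == "log2fc":
        vals = diff["log2fc"]
    elif metric == "mean_intensity_diff":
        g1, g2 = diff.attrs["group_order"]
        cols1 = [s for s in sites.intensities.columns if groups[s] == g1]
        cols2 = [s for s in sites.intensities.columns if groups[s] == g2]
        vals = sites.intensities[cols1].mean(axis=1) - \
            sites.intensities[cols2].mean(axis=1)
    else:
        raise ValidationError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    return vals[diff["tested"]]


def rank_sites(diff: pd.DataFrame, metric: str = "signed_t",
               sites: SiteMatrix | None = None,
               groups: pd.Series | None = None) -> RankedList:
    """Rank tested sites by a signed metric, descending.

    ``diff`` is the differential-test frame.  Ties are broken by site id
    (lexicographic), so the ordering is invariant to input row order.
    ``mean_intensity_diff`` additionally needs the site matrix.
    """
    if metric == "signed_t":
        vals = diff.loc[diff["tested"], "t_mod"]
    elif metric == "log2fc":
        vals = diff.loc[diff["tested"], "log2fc"]
    elif metric == "mean_intensity_diff":
        if sites is None:
            raise ValidationError("mean_intensity_diff ranking needs the site matrix")
        if groups is None:
            groups = sites.sample_groups
        vals = _metric_vector(sites, groups, "mean_intensity_diff")
    else:
        raise ValidationError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    frame = pd.DataFrame({"metric": vals.astype(float)})
    frame["sid"] = frame.index.astype(str)
    frame = frame.sort_values(["metric", "sid"], ascending=[False, True],
                              kind="mergesort")
    return RankedList(ids=tuple(frame.index), metric=frame["metric"].to_numpy())


def _es_from_membership(metric: np.ndarray, member: np.ndarray,
                        weight_p: float) -> tuple:
    """Running-sum ES for one set given an already-ordered metric vector."""
    n = len(metric)
    nh = int(member.sum())
    if nh == 0 or nh == n:
        return 0.0, np.zeros(n), True
    w = np.abs(metric) ** weight_p
    wr = np.where(member, w, 0.0)
    total = wr[member].sum()
    if total > 0:
        hit = wr / total
    else:  # all member metrics are zero: fall back to unweighted hits
        hit = np.where(member, 1.0 / nh, 0.0)
    miss = np.where(member, 0.0, 1.0 / (n - nh))
    running = np.cumsum(hit - miss)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running, False


def enrichment_score(ranked: RankedList, kset: KinaseSet,
                     weight_p: float = 1.0) -> EnrichmentScore:
    """ES of one kinase set against a ranked list.

    The leading edge comprises the set members at or before the running-sum
    extremum for positive ES, and at or after it for negative ES.  A set
    covering the entire list is degenerate (miss decrement undefined) and
    reported as ES = 0 with the flag raised.
    """
    pos = ranked.position()
    members_present = kset.substrates & set(ranked.ids)
    if not members_present:
        raise ValidationError(f"set {kset.kinase!r} has no member in the ranked list")
    member = np.zeros(len(ranked), dtype=bool)
    for sid in members_present:
        member[pos[sid]] = True
    es, running, degenerate = _es_from_membership(ranked.metric, member, weight_p)
    if degenerate:
        return EnrichmentScore(0.0, running, [], True)
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        lead_idx = np.flatnonzero(member[: idx + 1])
    else:
        member_idx = np.flatnonzero(member)
        lead_idx = member_idx[member_idx >= idx]
    leading = [ranked.ids[i] for i in lead_idx]
    return EnrichmentScore(es, running, leading, False)


def permutation_null(sites: SiteMatrix, groups: pd.Series, kset: KinaseSet,
                     n_perm: int = 1000, mode: str = "auto", seed: int = 0,
                     metric: str = "signed_t",
                     weight_p: float = 1.0) -> np.ndarray:
    """Null ES sample for a single kinase set (see :func:`ksea_run`)."""
    if n_perm <= 0:
        raise ValidationError("n_perm must be positive")
    null, _, mode = _null_es(sites, groups, [kset], n_perm, mode, seed,
                             metric, weight_p)
    return null[:, 0]


def _resolve_mode(mode: str, groups: pd.Series) -> str:
    counts = groups.value_counts()
    if mode == "auto":
        mode = "phenotype" if (counts >= PHENOTYPE_MIN_PER_GROUP).all() else "set"
    if mode == "phenotype" and (counts < PHENOTYPE_MIN_PER_GROUP).any():
        logger.warning(
            "phenotype permutation needs >= %d samples per group (have %s); "
            "falling back to set permutation",
            PHENOTYPE_MIN_PER_GROUP, counts.to_dict(),
        )
        mode = "set"
    return mode


def _null_es(sites, groups, ksets, n_perm, mode, seed, metric, weight_p):
    """(n_perm × n_sets) null ES matrix shared across sets."""
    mode = _resolve_mode(mode, groups)
    rng = np.random.default_rng(seed)
    obs_metric = _metric_vector(sites, groups, metric)
    ranked = _rank_series(obs_metric)
    pos = {sid: i for i, sid in enumerate(ranked.ids)}
    n = len(ranked)
    membership = np.zeros((len(ksets), n), dtype=bool)
    for j, ks in enumerate(ksets):
        for sid in ks.substrates:
            if sid in pos:
                membership[j, pos[sid]] = True
    null = np.zeros((n_perm, len(ksets)))
    if mode == "phenotype":
        sample_names = np.array(sites.intensities.columns)
        labels = groups.loc[sample_names].to_numpy()
        id_index = pd.Index(ranked.ids)
        for b in range(n_perm):
            perm = rng.permutation(labels)
            perm_groups = pd.Series(perm, index=sample_names)
            vals = _metric_vector(sites, perm_groups, metric,
                                  group_order=tuple(dict.fromkeys(labels)))
            vals = vals.reindex(id_index).fillna(0.0)
            rperm = _rank_series(vals)
            ppos = {sid: i for i, sid in enumerate(rperm.ids)}
            pmember = np.zeros((len(ksets), n), dtype=bool)
            for j, ks in enumerate(ksets):
                for sid in ks.substrates:
                    if sid in ppos:
                        pmember[j, ppos[sid]] = True
            for j in range(len(ksets)):
                es, _, _ = _es_from_membership(rperm.metric, pmember[j], weight_p)
                null[b, j] = es
    else:
        sizes = membership.sum(axis=1)
        for b in range(n_perm):
            for j, size in enumerate(sizes):
                rand = np.zeros(n, dtype=bool)
                rand[rng.choice(n, size=size, replace=False)] = True
                es, _, _ = _es_from_membership(ranked.metric, rand, weight_p)
                null[b, j] = es
    return null, (ranked, membership), mode


def _rank_series(vals: pd.Series) -> RankedList:
    frame = pd.DataFrame({"metric": vals.astype(float)})
    frame["sid"] = frame.index.astype(str)
    frame = frame.sort_values(["metric", "sid"], ascending=[False, True],
                              kind="mergesort")
    return RankedList(ids=tuple(frame.index), metric=frame["metric"].to_numpy())


def _nes(es, null_col):
    """ES normalised by the mean magnitude of same-sign null scores."""
    if es >= 0:
        same = null_col[null_col > 0]
    else:
        same = null_col[null_col < 0]
    denom = np.abs(same).mean() if same.size else np.abs(null_col).mean()
    if not denom:
        return 0.0
    return float(es / denom)


def ksea_run(sites: SiteMatrix, groups: pd.Series | None,
             library: MotifLibrary, cfg: KseaConfig | None = None) -> KseaRun:
    """End-to-end KSEA over all motif sets of a library.

    Builds substrate sets by motif matching, scores each against the ranked
    site list, draws a shared permutation null, and reports ES, NES,
    nominal p, FDR q (pooled signed-NES procedure), direction and leading
    edge per set, sorted by NES descending.
    """
    cfg = cfg or KseaConfig()
    if groups is None:
        groups = sites.sample_groups
    ksets = build_kinase_sets(sites, library, cfg.min_size, cfg.max_size)
    if not ksets:
        raise ValidationError("no kinase set within size bounds")
    null, (ranked, membership), mode = _null_es(
        sites, groups, ksets, cfg.n_perm, cfg.mode, cfg.seed,
        cfg.metric, cfg.weight_p,
    )
    g1, g2 = moderated_two_group_test(sites, groups).attrs["group_order"]
    rows = []
    running_sums = {}
    nes_null = np.zeros_like(null)
    nes_obs = np.zeros(len(ksets))
    for j, ks in enumerate(ksets):
        score = enrichment_score(ranked, ks, cfg.weight_p)
        running_sums[ks.kinase] = score.running_sum
        null_j = null[:, j]
        nes_obs[j] = _nes(score.es, null_j)
        pos_mean = np.abs(null_j[null_j > 0]).mean() if (null_j > 0).any() else np.nan
        neg_mean = np.abs(null_j[null_j < 0]).mean() if (null_j < 0).any() else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[:, j] = np.where(
                null_j >= 0,
                null_j / (pos_mean if np.isfinite(pos_mean) else 1.0),
                null_j / (neg_mean if np.isfinite(neg_mean) else 1.0),
            )
        if score.es >= 0:
            same = null_j[null_j >= 0]
            p_nom = float((same >= score.es).sum() / max(1, same.size))
        else:
            same = null_j[null_j <= 0]
            p_nom = float((same <= score.es).sum() / max(1, same.size))
        category = library[ks.kinase].category if ks.kinase in library else ""
        rows.append({
            "kinase": ks.kinase,
            "category": category,
            "size": ks.size,
            "es": score.es,
            "nes": nes_obs[j],
            "p_nominal": p_nom,
            "leading_edge": score.leading_edge,
            "degenerate": score.degenerate,
            "direction": f"{g1}-enriched" if score.es >= 0 else f"{g2}-enriched",
        })
    fdr = _gsea_fdr(nes_obs, nes_null)
    res = pd.DataFrame(rows).set_index("kinase")
    res["fdr_q"] = fdr
    res["significant"] = res["fdr_q"] < cfg.fdr_significant
    res["relaxed"] = res["fdr_q"] < cfg.fdr_relaxed
    res = res.sort_values("nes", ascending=False)
    return KseaRun(results=res, ranked=ranked, running_sums=running_sums,
                   mode=mode)


def _gsea_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """FDR q-values from the pooled signed-NES permutation procedure.

    For a set with NES* ≥ 0, q is the ratio of the null tail fraction
    ``P(NES_null ≥ NES* | NES_null ≥ 0)`` to the observed tail fraction
    ``P(NES_obs ≥ NES* | NES_obs ≥ 0)`` (mirrored for negative scores),
    clipped to [0, 1] and made monotone in |NES| within each sign.
    For a single set the q-value reduces to the nominal tail probability.
    """
    pool = nes_null.ravel()
    pool = pool[np.isfinite(pool)]
    m = len(nes_obs)
    q = np.ones(m)
    pos_pool = pool[pool >= 0]
    neg_pool = pool[pool <= 0]
    n_pos_obs = (nes_obs >= 0).sum()
    n_neg_obs = (nes_obs < 0).sum()
    for j, nes in enumerate(nes_obs):
        if nes >= 0:
            num = (pos_pool >= nes).sum() / max(1, pos_pool.size)
            den = (nes_obs >= nes).sum() / max(1, n_pos_obs)
        else:
            num = (neg_pool <= nes).sum() / max(1, neg_pool.size)
            den = (nes_obs <= nes).sum() / max(1, n_neg_obs)
        q[j] = min(1.0, num / den) if den > 0 else 1.0
    # monotone: a more extreme NES never has a larger q than a less extreme one
    for sign in (1, -1):
        idx = np.flatnonzero((nes_obs >= 0) if sign > 0 else (nes_obs < 0))
        if idx.size:
            order = idx[np.argsort(-np.abs(nes_obs[idx]), kind="mergesort")]
            q[order] = np.minimum.accumulate(q[order][::-1])[::-1]
    return q
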