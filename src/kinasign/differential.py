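"""Differential phosphorylation analysis between relapse groups.

The central test is a two-group linear-model contrast with empirical-Bayes
variance moderation: per-site residual variances are shrunk toward a pooled
prior variance ``s0²`` whose weight (prior degrees of freedom ``d0``) is
estimated by moment matching on the observed distribution of log residual
variances — the same scaled-inverse-chi-square hierarchy used by standard
microarray linear-model software.  P-values use a t reference with
``residual + prior`` degrees of freedom and are corrected across sites by
Benjamini–Hochberg; sites at FDR q < 0.15 are flagged as differentially
phosphorylated.

Sites with fewer than two observed values in either group are reported but
not tested (no imputation).  Intensities are assumed to be on the log2
scale (see :func:`log_transform`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import cut_tree, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .io import SiteMatrix

logger = logging.getLogger(__name__)

DEFAULT_FDR = 0.15


def normalize_by_protein(sites: SiteMatrix, protein_abundance: pd.DataFrame) -> SiteMatrix:
    """Divide each site's intensity by its protein's abundance per sample.

    ``protein_abundance`` is a protein × sample frame of positive values.
    A missing protein abundance leaves the site value missing, with a
    logged warning naming the protein.
    """
    if (protein_abundance <= 0).any().any():
        raise ValidationError("protein abundances must be positive where present")
    out = sites.copy()
    warned = set()
    proteins = sites.annotations["protein_id"]
    for sample in out.intensities.columns:
        if sample not in protein_abundance.columns:
            raise ValidationError(f"no protein abundance for sample {sample!r}")
        ab = proteins.map(protein_abundance[sample])
        missing = ab.isna() & out.intensities[sample].notna()
        for prot in proteins[missing].unique():
            if prot not in warned:
                logger.warning("no abundance for protein %s; site values left missing", prot)
                warned.add(prot)
        out.intensities[sample] = out.intensities[sample] / ab
    return out


def log_transform(sites: SiteMatrix) -> SiteMatrix:
    """Base-2 log of positive intensities; zeros and missing stay missing."""
    out = sites.copy()
    vals = out.intensities.where(out.intensities > 0)
    out.intensities = np.log2(vals)
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (plain BH, pi0 = 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) < 1e-8 * y):
            break
    return y


def estimate_prior_variance(s2: np.ndarray, df: np.ndarray):
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    Returns ``(d0, s0_sq)``: the prior degrees of freedom (possibly ``inf``)
    and the prior variance, obtained by matching the mean and variance of
    ``log(s²)`` against its theoretical digamma/trigamma moments.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        return np.inf, float(np.nanmedian(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2) + np.log(df[ok] / 2)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df[ok] / 2).mean()
    if evar > 0:
        d0 = float(2 * _trigamma_inverse(np.array([evar]))[0])
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    else:
        # variances are under-dispersed relative to chi-square sampling
        # noise: infinitely strong prior located at the mean variance
        d0 = np.inf
        s0_sq = float(s2[ok].mean())
    return d0, s0_sq


def moderated_two_group_test(
    sites: SiteMatrix,
    groups: pd.Series | None = None,
    group_order: tuple | None = None,
    prior_df: float | None = None,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Moderated two-group test on log2 intensities, site by site.

    Parameters
    ----------
    sites:
        Log2-scale site matrix (missing = NaN).
    groups:
        Sample → group labels; defaults to ``sites.sample_groups``.
    group_order:
        ``(test, reference)`` pair; the log2 fold change is
        ``mean(test) − mean(reference)``.  Defaults to
        ``("relapsed", "non-relapsed")`` when those labels are present,
        otherwise the two labels in order of appearance.
    prior_df:
        Override the estimated prior degrees of freedom; 0 recovers the
        ordinary pooled-variance two-sample t-test.
    fdr_threshold:
        BH q cut-off for the ``selected`` flag (default 0.15).

    Returns
    -------
    DataFrame indexed by site id with columns ``log2fc``, ``t_mod``, ``p``,
    ``q``, ``selected``, ``tested`` and per-group observation counts.
    Untested sites (fewer than 2 observations in either group) carry NaN
    statistics.
    """
    if groups is None:
        groups = sites.sample_groups
    labels = list(dict.fromkeys(groups))
    if len(labels) != 2:
        raise ValidationError(f"need exactly two groups, got {labels}")
    if group_order is None:
        if "relapsed" in labels and "non-relapsed" in labels:
            group_order = ("relapsed", "non-relapsed")
        else:
            group_order = tuple(labels)
    g1, g2 = group_order
    cols1 = [s for s in sites.intensities.columns if groups[s] == g1]
    cols2 = [s for s in sites.intensities.columns if groups[s] == g2]
    if len(cols1) < 2 or len(cols2) < 2:
        raise ValidationError(
            f"need >= 2 samples per group ({g1}: {len(cols1)}, {g2}: {len(cols2)})"
        )
    x1 = sites.intensities[cols1].to_numpy(float)
    x2 = sites.intensities[cols2].to_numpy(float)
    ok1, ok2 = np.isfinite(x1), np.isfinite(x2)
    n1 = ok1.sum(axis=1)
    n2 = ok2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.where(ok1, x1, 0.0).sum(axis=1) / n1
        m2 = np.where(ok2, x2, 0.0).sum(axis=1) / n2
        ss1 = np.where(ok1, (x1 - m1[:, None]) ** 2, 0.0).sum(axis=1)
        ss2 = np.where(ok2, (x2 - m2[:, None]) ** 2, 0.0).sum(axis=1)
    tested = (n1 >= 2) & (n2 >= 2)
    df = np.where(tested, n1 + n2 - 2, np.nan)
    s2 = np.where(tested, (ss1 + ss2) / df, np.nan)

    if prior_df is None:
        d0, s0_sq = estimate_prior_variance(s2[tested], df[tested])
    else:
        d0, s0_sq = float(prior_df), float(
            np.nanmedian(s2[tested]) if np.isfinite(s2[tested]).any() else 1.0
        )
        if d0 > 0:
            d0_est, s0_sq = estimate_prior_variance(s2[tested], df[tested])
            del d0_est  # keep the caller's d0, moment-matched s0²
    df_sum = np.nansum(df[tested])
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.full_like(df, df_sum)
    elif d0 == 0:
        s2_post = s2
        df_total = df
    else:
        # total df capped at the summed residual df across sites
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = np.minimum(df + d0, df_sum)
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = diff / se
    p = np.where(
        np.isinf(df_total),
        2 * stats.norm.sf(np.abs(t)),
        2 * stats.t.sf(np.abs(t), np.where(tested, df_total, 1)),
    )
    p = np.where(tested, p, np.nan)
    # degenerate zero-variance sites: se == 0 -> p = 0 if means differ else 1
    zero_se = tested & (se == 0)
    p[zero_se] = np.where(diff[zero_se] != 0, 0.0, 1.0)
    t[zero_se & (diff == 0)] = 0.0

    q = np.full_like(p, np.nan)
    q[tested] = bh_adjust(p[tested])
    res = pd.DataFrame(
        {
            "log2fc": diff,
            "t_mod": t,
            "p": p,
            "q": q,
            "selected": np.where(tested, q < fdr_threshold, False).astype(bool),
            "tested": tested,
            f"n_obs_{g1}": n1,
            f"n_obs_{g2}": n2,
        },
        index=sites.annotations.index,
    )
    res.attrs["prior_df"] = d0
    res.attrs["prior_var"] = s0_sq
    res.attrs["group_order"] = (g1, g2)
    return res


@dataclass
class ConsensusResult:
    """Consensus matrix and final assignment for one value of k."""

    k: int
    consensus: pd.DataFrame
    assignments: pd.Series


def consensus_cluster(
    sites: SiteMatrix,
    k_range,
    n_iter: int = 1000,
    subsample_frac: float = 0.8,
    seed: int = 0,
    linkage: str = "average",
) -> dict:
    """Consensus clustering of samples by their phosphoprofiles.

    Repeatedly subsamples the samples, hierarchically clusters the subset
    using ``1 − Pearson correlation`` distance, and records how often each
    co-sampled pair lands in the same cluster.  The final assignment for
    each k cuts an average-linkage tree built on ``1 − consensus``.

    Samples with constant profiles (zero variance) are excluded with a
    warning.  Returns ``{k: ConsensusResult}``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValidationError("empty k_range")
    profiles = sites.intensities
    variances = profiles.var(axis=0, skipna=True)
    constant = variances.index[(variances == 0) | variances.isna()]
    if len(constant):
        logger.warning("excluding %d constant-profile samples: %s",
                       len(constant), list(constant[:5]))
        profiles = profiles.drop(columns=constant)
    samples = list(profiles.columns)
    n = len(samples)
    if n < 2 * max(k_range):
        raise ValidationError(
            f"need >= {2 * max(k_range)} samples for max k, have {n}"
        )
    rng = np.random.default_rng(seed)
    n_sub = max(2, int(round(subsample_frac * n)))
    results = {}
    for k in k_range:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for _ in range(n_iter):
            idx = np.sort(rng.choice(n, size=n_sub, replace=False))
            sub = profiles.iloc[:, idx]
            corr = sub.corr(method="pearson").to_numpy()
            dist = squareform(1.0 - corr, checks=False)
            tree = scipy_linkage(dist, method=linkage)
            labels = cut_tree(tree, n_clusters=min(k, len(idx))).ravel()
            co[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            consensus = np.where(co > 0, together / np.maximum(co, 1), 0.0)
        np.fill_diagonal(consensus, np.where(np.diag(co) > 0, 1.0, 0.0))
        cons_df = pd.DataFrame(consensus, index=samples, columns=samples)
        dist = squareform(1.0 - consensus, checks=False)
        tree = scipy_linkage(dist, method=linkage)
        labels = cut_tree(tree, n_clusters=k).ravel()
        results[k] = ConsensusResult(
            k=k,
            consensus=cons_df,
            assignments=pd.Series(labels, index=samples, name="cluster"),
        )
    return results
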