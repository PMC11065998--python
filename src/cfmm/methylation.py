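"""Methylation markers: tissue DMR discovery and cfDNA malignant ratios.

A DMR (differentially methylated region) is carried as one row of a region
frame with columns ``chrom, start, end, direction, tumor_beta, normal_beta``
(direction ``hyper`` = tumor-higher, ``hypo`` = tumor-lower).

Per-fragment malignant calls use a nearest-reference rule: a fragment with
enough CpGs is called malignant when its methylated fraction is strictly
closer to the region's tumor reference level than to the normal level
(ties break to normal).  The per-sample, per-region malignant ratio —
malignant / (malignant + normal) over informative fragments — estimates
local ctDNA content.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import regions_mean_methylation

MALIGNANT, NORMAL, UNINFORMATIVE = 1, 0, -1


def call_tissue_dmrs(pairs: Sequence[dict], candidate_regions: pd.DataFrame,
                     min_delta: float = 0.2, fdr: float = 0.05,
                     min_pair_coverage: float = 0.5) -> pd.DataFrame:
    """Discover DMRs from paired tumor/normal CpG tracks.

    Per candidate region, computes each pair's tumor-minus-normal mean
    methylation difference, tests the paired differences with a Wilcoxon
    signed-rank test, applies Benjamini-Hochberg control at ``fdr`` and an
    effect filter ``|mean delta| >= min_delta``.  Regions covered in fewer
    than ``min_pair_coverage`` of pairs are excluded.

    Each pair is a dict with ``tumor_sites`` / ``normal_sites`` CpG frames.
    Returns the retained regions with ``direction``, ``tumor_beta``,
    ``normal_beta`` (cohort means), ``mean_delta``, ``p`` and ``p_adj``.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 tumor/normal pairs")
    regions = candidate_regions.reset_index(drop=True)
    n_reg = len(regions)
    tmeans = np.full((len(pairs), n_reg), np.nan)
    nmeans = np.full((len(pairs), n_reg), np.nan)
    for i, pair in enumerate(pairs):
        tmeans[i] = regions_mean_methylation(pair["tumor_sites"], regions)
        nmeans[i] = regions_mean_methylation(pair["normal_sites"], regions)
    deltas = tmeans - nmeans
    covered = ~np.isnan(deltas)
    testable = covered.mean(axis=0) >= min_pair_coverage

    pvals = np.ones(n_reg)
    for j in np.flatnonzero(testable):
        d = deltas[covered[:, j], j]
        if len(d) < 3 or np.allclose(d, 0.0):
            pvals[j] = 1.0
            continue
        pvals[j] = stats.wilcoxon(d, zero_method="zsplit").pvalue
    p_adj = np.ones(n_reg)
    if testable.any():
        p_adj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]

    with np.errstate(invalid="ignore"):
        mean_delta = np.nanmean(np.where(covered, deltas, np.nan), axis=0)
        mean_t = np.nanmean(np.where(covered, tmeans, np.nan), axis=0)
        mean_n = np.nanmean(np.where(covered, nmeans, np.nan), axis=0)
    keep = testable & (p_adj < fdr) & (np.abs(mean_delta) >= min_delta)

    out = regions.loc[keep, ["chrom", "start", "end"]].copy()
    out["direction"] = np.where(mean_delta[keep] > 0, "hyper", "hypo")
    out["tumor_beta"] = mean_t[keep]
    out["normal_beta"] = mean_n[keep]
    out["mean_delta"] = mean_delta[keep]
    out["p"] = pvals[keep]
    out["p_adj"] = p_adj[keep]
    return out.reset_index(drop=True)


def fragment_malignant_call(n_cpg: int, n_meth: int, tumor_beta: float,
                            normal_beta: float, min_cpg: int = 3) -> int:
    """Classify one fragment against a region's reference levels.

    Returns ``MALIGNANT`` (1), ``NORMAL`` (0) or ``UNINFORMATIVE`` (-1).
    """
    if n_cpg < min_cpg:
        return UNINFORMATIVE
    frac = n_meth / n_cpg
    if abs(frac - tumor_beta) < abs(frac - normal_beta):
        return MALIGNANT
    return NORMAL


def classify_fragments(frags: pd.DataFrame, regions: pd.DataFrame,
                       min_cpg: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised malignant calls for all fragments against all regions.

    Fragments are matched to the (at most one) overlapping region; regions
    must be sorted and non-overlapping per chromosome.  Returns
    ``(region_index, call)`` per fragment, region_index -1 when no overlap.
    """
    regions = regions.reset_index(drop=True)
    n = len(frags)
    region_idx = np.full(n, -1, dtype=np.int64)
    call = np.full(n, UNINFORMATIVE, dtype=np.int8)
    fr_chrom = frags["chrom"].astype(str).to_numpy()
    fr_start = frags["start"].to_numpy()
    fr_end = frags["end"].to_numpy()
    for chrom, reg in regions.groupby("chrom", sort=False, observed=True):
        reg = reg.sort_values("start")
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        ridx = reg.index.to_numpy()
        sel = np.flatnonzero(fr_chrom == str(chrom))
        if len(sel) == 0:
            continue
        j = np.searchsorted(starts, fr_end[sel], side="left") - 1
        ok = (j >= 0) & (fr_start[sel] < ends[np.maximum(j, 0)])
        region_idx[sel[ok]] = ridx[j[ok]]

    matched = region_idx >= 0
    n_cpg = frags["n_cpg"].to_numpy()[matched]
    n_meth = frags["n_meth"].to_numpy()[matched]
    tb = regions["tumor_beta"].to_numpy()[region_idx[matched]]
    nb = regions["normal_beta"].to_numpy()[region_idx[matched]]
    informative = n_cpg >= min_cpg
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(informative, n_meth / np.maximum(n_cpg, 1), np.nan)
    res = np.full(matched.sum(), UNINFORMATIVE, dtype=np.int8)
    res[informative] = np.where(
        np.abs(frac[informative] - tb[informative])
        < np.abs(frac[informative] - nb[informative]),
        MALIGNANT, NORMAL)
    call[matched] = res
    return region_idx, call


def malignant_ratio(frags: pd.DataFrame, region: pd.Series | dict,
                    min_cpg: int = 3, min_fragments: int = 5) -> float:
    """Malignant / (malignant + normal) among informative fragments in a region.

    Missing (NaN) when fewer than ``min_fragments`` informative fragments.
    """
    reg = pd.DataFrame([dict(region)])
    _, call = classify_fragments(frags, reg, min_cpg=min_cpg)
    informative = call != UNINFORMATIVE
    n_inf = int(informative.sum())
    if n_inf < min_fragments:
        return float("nan")
    return float((call == MALIGNANT).sum() / n_inf)


def malignant_ratio_matrix(sample_fragments: Iterable[tuple[str, pd.DataFrame]],
                           regions: pd.DataFrame, min_cpg: int = 3,
                           min_fragments: int = 5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Samples x regions malignant-ratio matrix plus informative-fragment counts."""
    regions = regions.reset_index(drop=True)
    names = [f"{r.chrom}:{r.start}-{r.end}" for r in regions.itertuples()]
    ratios, counts, ids = [], [], []
    for sample_id, frags in sample_fragments:
        ridx, call = classify_fragments(frags, regions, min_cpg=min_cpg)
        informative = call != UNINFORMATIVE
        n_inf = np.bincount(ridx[informative], minlength=len(regions))
        n_mal = np.bincount(ridx[informative & (call == MALIGNANT)],
                            minlength=len(regions))
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(n_inf >= min_fragments, n_mal / np.maximum(n_inf, 1), np.nan)
        ratios.append(row)
        counts.append(n_inf)
        ids.append(sample_id)
    return (pd.DataFrame(ratios, index=ids, columns=names),
            pd.DataFrame(counts, index=ids, columns=names))


def select_cfdna_dmrs(matrix: pd.DataFrame, labels: np.ndarray,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Rank-sum screen of malignant ratios for case-elevated regions.

    Two-sided Mann-Whitney per region on case vs control ratios,
    Benjamini-Hochberg adjusted p < ``fdr``, and the direction filter
    ``case mean > control mean``.  Regions all-missing in either class are
    excluded.  Returns a frame ordered by adjusted p with columns
    ``region, p, p_adj, case_mean, control_mean``.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    cases = matrix.loc[labels.tolist()] if len(labels) == len(matrix) else None
    if cases is None:
        raise ValueError("labels length must match matrix rows")
    ctrls = matrix.loc[(~labels).tolist()]
    rows = []
    for col in matrix.columns:
        x = cases[col].dropna().to_numpy()
        y = ctrls[col].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            continue
        if np.all(x == x[0]) and np.all(y == x[0]):
            p = 1.0
        else:
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        rows.append((col, p, float(x.mean()), float(y.mean())))
    if not rows:
        return pd.DataFrame(columns=["region", "p", "p_adj", "case_mean", "control_mean"])
    df = pd.DataFrame(rows, columns=["region", "p", "case_mean", "control_mean"])
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    keep = (df["p_adj"] < fdr) & (df["case_mean"] > df["control_mean"])
    out = df.loc[keep].sort_values(["p_adj", "p", "region"], ignore_index=True)
    return out[["region", "p", "p_adj", "case_mean", "control_mean"]]
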