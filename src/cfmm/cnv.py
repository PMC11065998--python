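"""Copy-number calling from bisulfite fragment coverage.

Pipeline: depth-standardised fragment counts per genomic bin → robust
local (LOESS) regression of count on GC fraction, with tricube distance
weights

    W(u) = (1 - u^3)^3   for |u| < 1, else 0

in the first pass and bisquare robustness weights

    B(r) = (1 - r^2)^2   for |r| < 1, else 0

on scaled residuals in subsequent passes → per-bin log2 ratio of
GC-corrected test vs reference counts, ``log2(Ft / Fn)`` → Gaussian
mixture clustering of the log2 ratios refined by a 3-state (DEL / NEUT /
AMP) hidden Markov model decoded per chromosome → segments, recurrent
regions across a cohort, and baseline-relative event calls in cfDNA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from scipy import stats
from sklearn.mixture import GaussianMixture
from statsmodels.stats.multitest import multipletests

STATES = ("DEL", "NEUT", "AMP")
GC_RANGE = (0.3, 0.6)
VAR_FLOOR = 1e-4


def tricube_weight(u: np.ndarray) -> np.ndarray:
    """Distance kernel W(u) = (1 - |u|^3)^3 on |u| < 1, else 0."""
    u = np.abs(np.asarray(u, dtype=float))
    return np.where(u < 1.0, (1.0 - u ** 3) ** 3, 0.0)


def bisquare_weight(r: np.ndarray) -> np.ndarray:
    """Robustness kernel B(r) = (1 - r^2)^2 on |r| < 1, else 0."""
    r = np.abs(np.asarray(r, dtype=float))
    return np.where(r < 1.0, (1.0 - r ** 2) ** 2, 0.0)


@dataclass
class BinCounts:
    """Per-bin fragment counts with GC annotation."""

    bins: pd.DataFrame          # bin frame (chrom, start, end, gc, partial)
    y: np.ndarray               # depth-standardised fragment count per bin

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.y) != len(self.bins):
            raise ValueError("count vector length must match bins")
        if np.any(self.y < 0):
            raise ValueError("counts must be non-negative")

    @property
    def gc(self) -> np.ndarray:
        return self.bins["gc"].to_numpy(dtype=float)


def count_fragments_per_bin(frags: pd.DataFrame, bins: pd.DataFrame,
                            target_depth: float = 1e6) -> BinCounts:
    """Assign fragments to bins by midpoint and rescale to a uniform depth.

    The genome-wide total is standardised to ``target_depth`` so samples
    of different sequencing depth are comparable.
    """
    if len(frags) == 0:
        raise ValueError("no fragments to count")
    counts = np.zeros(len(bins), dtype=float)
    mid = (frags["start"].to_numpy() + frags["end"].to_numpy()) // 2
    fr_chrom = frags["chrom"].astype(str).to_numpy()
    for chrom, b in bins.groupby("chrom", sort=False, observed=True):
        starts = b["start"].to_numpy()
        ends = b["end"].to_numpy()
        sel = fr_chrom == str(chrom)
        pos = mid[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.maximum(j, 0)])
        counts[b.index.to_numpy()] += np.bincount(j[ok], minlength=len(b))
    total = counts.sum()
    if total == 0:
        raise ValueError("no fragments fell inside the bins")
    return BinCounts(bins.reset_index(drop=True), counts * (target_depth / total))


def _loess_fit(x: np.ndarray, y: np.ndarray, span: float,
               iterations: int) -> np.ndarray:
    """Robust local weighted linear regression, evaluated at the data points."""
    m = len(x)
    k = max(2, int(np.ceil(span * m)))
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]

    # nearest-k windows on the sorted axis (two-pointer)
    lo = np.empty(m, dtype=np.int64)
    j = 0
    for i in range(m):
        j = min(max(j, i - k + 1), m - k)
        while j + k < m and xs[j + k] - xs[i] < xs[i] - xs[j]:
            j += 1
        lo[i] = j
    idx = lo[:, None] + np.arange(k)[None, :]
    xw = xs[idx]                      # (m, k)
    yw = ys[idx]
    d = np.abs(xw - xs[:, None])
    dmax = d.max(axis=1, keepdims=True)
    dmax[dmax == 0] = 1.0
    wdist = tricube_weight(d / dmax)

    rob = np.ones((m, k))
    yhat_s = np.empty(m)
    for it in range(max(1, iterations + 1)):
        w = wdist * rob
        sw = w.sum(axis=1)
        swx = (w * xw).sum(axis=1)
        swx2 = (w * xw * xw).sum(axis=1)
        swy = (w * yw).sum(axis=1)
        swxy = (w * xw * yw).sum(axis=1)
        denom = sw * swx2 - swx * swx
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(np.abs(denom) > 1e-12, (sw * swxy - swx * swy) / denom, 0.0)
            a = np.where(sw > 0, (swy - b * swx) / sw, yw.mean(axis=1))
        yhat_s = a + b * xs
        if it == iterations:
            break
        resid = ys - yhat_s
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        rob = bisquare_weight(resid[idx] / (6.0 * s))
        # guard against all-zero weight rows
        dead = (wdist * rob).sum(axis=1) <= 0
        rob[dead] = 1.0

    yhat = np.empty(m)
    yhat[order] = yhat_s
    return yhat


def loess_gc_correct(counts: BinCounts, span: float = 0.3, iterations: int = 2,
                     gc_range: tuple[float, float] = GC_RANGE,
                     ) -> tuple[dict, np.ndarray]:
    """GC-bias correction of bin counts by robust LOESS of count on GC.

    Bins with GC outside ``gc_range`` (or missing GC) are masked (NaN in
    the corrected vector).  Corrected count = y * median(yhat) / yhat, so
    the count scale is preserved while the GC trend is flattened.

    Returns ``(model, corrected)``; the model dict carries the fit
    (``yhat``, ``mask``, ``span``, ``iterations``).
    """
    gc = counts.gc
    y = counts.y
    mask = np.isfinite(gc) & (gc >= gc_range[0]) & (gc <= gc_range[1]) & np.isfinite(y)
    if "partial" in counts.bins:
        widths = counts.bins["end"] - counts.bins["start"]
        mask &= (widths >= 0.5 * widths.max()).to_numpy()
    if mask.sum() < 30:
        raise ValueError("need at least 30 bins with GC in the admissible range")
    yhat_m = _loess_fit(gc[mask], y[mask], span=span, iterations=iterations)
    yhat_m = np.maximum(yhat_m, 1e-8)
    med = np.median(yhat_m)
    corrected = np.full(len(y), np.nan)
    corrected[mask] = y[mask] * (med / yhat_m)
    yhat = np.full(len(y), np.nan)
    yhat[mask] = yhat_m
    model = {"yhat": yhat, "mask": mask, "span": span, "iterations": iterations,
             "median_yhat": float(med)}
    return model, corrected


def log2_ratio(test: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-bin log2(Ft / Fn); NaN where either side is missing or non-positive."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("test and reference must cover the same bins")
    ok = np.isfinite(test) & np.isfinite(reference) & (test > 0) & (reference > 0)
    out = np.full(test.shape, np.nan)
    out[ok] = np.log2(test[ok] / reference[ok])
    return out


def viterbi_decode(values: np.ndarray, means: np.ndarray, variances: np.ndarray,
                   self_transition: float = 0.99) -> np.ndarray:
    """Maximum-probability state path for Gaussian emissions.

    Symmetric transitions (``self_transition`` on the diagonal, the
    remainder split evenly), uniform start probabilities.
    """
    values = np.asarray(values, dtype=float)
    k = len(means)
    model = GaussianHMM(n_components=k, covariance_type="diag",
                        init_params="", params="")
    model.startprob_ = np.full(k, 1.0 / k)
    off = (1.0 - self_transition) / (k - 1) if k > 1 else 0.0
    model.transmat_ = np.full((k, k), off) + np.eye(k) * (self_transition - off)
    model.means_ = np.asarray(means, dtype=float).reshape(-1, 1)
    model.covars_ = np.maximum(np.asarray(variances, dtype=float), VAR_FLOOR).reshape(-1, 1)
    _, path = model.decode(values.reshape(-1, 1), algorithm="viterbi")
    return path


def _mixture_state_params(values: np.ndarray, max_states: int,
                          alt_mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Fit Gaussian mixtures (1..max_states, BIC-selected) and map the
    components onto (DEL, NEUT, AMP) means/variances.

    The component nearest 0 anchors NEUT; components below/above it pool
    into DEL/AMP.  Absent sides fall back to ``neut_mean -/+ alt_mean``.
    """
    x = values.reshape(-1, 1)
    best, best_bic = None, np.inf
    for k in range(1, max_states + 1):
        if len(values) <= k:
            break
        gm = GaussianMixture(n_components=k, random_state=0, n_init=1,
                             reg_covar=1e-6).fit(x)
        bic = gm.bic(x)
        if bic < best_bic:
            best, best_bic = gm, bic
    mu = best.means_.ravel()
    var = best.covariances_.ravel()
    w = best.weights_.ravel()
    neut_i = int(np.argmin(np.abs(mu)))
    neut_mean, neut_var = mu[neut_i], var[neut_i]

    def _pool(side: np.ndarray, fallback_mean: float) -> tuple[float, float]:
        if side.any():
            ww = w[side] / w[side].sum()
            return float(np.sum(ww * mu[side])), float(np.sum(ww * var[side]))
        return fallback_mean, float(neut_var)

    del_mean, del_var = _pool(mu < neut_mean, float(neut_mean) - alt_mean)
    amp_mean, amp_var = _pool(mu > neut_mean, float(neut_mean) + alt_mean)
    means = np.array([del_mean, neut_mean, amp_mean])
    variances = np.maximum(np.array([del_var, neut_var, amp_var]), VAR_FLOOR)
    return means, variances


def segment_gmm_hmm(values: np.ndarray, bins: pd.DataFrame, max_states: int = 3,
                    self_transition: float = 0.99,
                    alt_mean: float = 0.5) -> pd.DataFrame:
    """Segment a log2-ratio track into DEL/NEUT/AMP runs.

    Gaussian-mixture clustering (model order by BIC) initialises a 3-state
    HMM whose maximum-probability path is decoded per chromosome; missing
    bins are skipped.  Consecutive same-state bins merge into segments.

    Returns segments with ``chrom, start, end, state, mean_log2, n_bins,
    first_bin, last_bin`` (bin indices into ``bins``).
    """
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 20:
        raise ValueError("need at least 20 non-missing bins to segment")
    means, variances = _mixture_state_params(values[ok], max_states, alt_mean)

    state = np.full(len(values), -1, dtype=np.int64)
    chroms = bins["chrom"].astype(str).to_numpy()
    for chrom in pd.unique(chroms):
        sel = np.flatnonzero((chroms == chrom) & ok)
        if len(sel) == 0:
            continue
        state[sel] = viterbi_decode(values[sel], means, variances, self_transition)

    rows = []
    called = np.flatnonzero(state >= 0)
    if len(called) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "state", "mean_log2",
                                     "n_bins", "first_bin", "last_bin"])
    run_start = called[0]
    prev = called[0]
    for i in list(called[1:]) + [None]:
        boundary = (i is None or state[i] != state[prev]
                    or chroms[i] != chroms[prev])
        if boundary:
            members = called[(called >= run_start) & (called <= prev)]
            rows.append((chroms[run_start], int(bins["start"].iloc[run_start]),
                         int(bins["end"].iloc[prev]), STATES[state[run_start]],
                         float(np.nanmean(values[members])), len(members),
                         int(run_start), int(prev)))
            run_start = i
        prev = i
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                       "mean_log2", "n_bins", "first_bin", "last_bin"])


def segments_to_bin_states(segments: pd.DataFrame, n_bins: int) -> np.ndarray:
    """Per-bin state codes (-1 uncalled, 0 DEL, 1 NEUT, 2 AMP) from segments."""
    out = np.full(n_bins, -1, dtype=np.int64)
    for seg in segments.itertuples():
        out[seg.first_bin:seg.last_bin + 1] = STATES.index(seg.state)
    return out


def recurrent_regions(per_sample_segments: Sequence[pd.DataFrame],
                      bins: pd.DataFrame, min_recurrence: int = 3) -> pd.DataFrame:
    """Bins recurrently non-neutral across samples, merged into regions.

    Per bin and per state (AMP, DEL), counts samples calling that state;
    bins with count >= ``min_recurrence`` are kept and adjacent kept bins
    of the same state merge.  Returns ``chrom, start, end, state, support,
    first_bin, last_bin``.
    """
    if len(per_sample_segments) < min_recurrence:
        raise ValueError("fewer samples than min_recurrence")
    n = len(bins)
    amp = np.zeros(n, dtype=np.int64)
    dele = np.zeros(n, dtype=np.int64)
    for segs in per_sample_segments:
        st = segments_to_bin_states(segs, n)
        amp += st == STATES.index("AMP")
        dele += st == STATES.index("DEL")
    chroms = bins["chrom"].astype(str).to_numpy()
    rows = []
    for state, count in (("AMP", amp), ("DEL", dele)):
        kept = count >= min_recurrence
        i = 0
        while i < n:
            if not kept[i]:
                i += 1
                continue
            j = i
            while (j + 1 < n and kept[j + 1] and chroms[j + 1] == chroms[i]):
                j += 1
            rows.append((chroms[i], int(bins["start"].iloc[i]),
                         int(bins["end"].iloc[j]), state,
                         int(count[i:j + 1].max()), i, j))
            i = j + 1
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "state", "support",
                                      "first_bin", "last_bin"])
    return out.sort_values(["first_bin", "state"], ignore_index=True)


def build_control_baseline(control_counts: Sequence[BinCounts], span: float = 0.3,
                           iterations: int = 2) -> np.ndarray:
    """Per-bin median of GC-corrected control counts (the cfDNA reference Fn)."""
    if len(control_counts) < 1:
        raise ValueError("need at least one control sample")
    corrected = []
    for bc in control_counts:
        _, c = loess_gc_correct(bc, span=span, iterations=iterations)
        corrected.append(c)
    arr = np.vstack(corrected)
    out = np.full(arr.shape[1], np.nan)
    ok = np.isfinite(arr).any(axis=0)
    if ok.any():
        out[ok] = np.nanmedian(arr[:, ok], axis=0)
    return out


def call_cfdna_events(sample_counts: BinCounts, baseline: np.ndarray,
                      regions: pd.DataFrame, span: float = 0.3,
                      iterations: int = 2, self_transition: float = 0.99,
                      alt_mean: float = 0.15) -> pd.DataFrame:
    """Baseline-relative event calls for a cfDNA sample in recurrent regions.

    GC-corrects the sample, takes log2 ratios against the control-median
    baseline, segments with a low-amplitude state prior (``alt_mean``)
    suited to low tumor fraction, and reports an event in a region only
    when a non-neutral segment overlaps it *with matching direction*.

    Returns one row per region: ``state`` (the region's expected
    direction), ``event`` in {AMP, DEL, none}, ``testable``.
    """
    _, corrected = loess_gc_correct(sample_counts, span=span, iterations=iterations)
    track = log2_ratio(corrected, baseline)
    segments = segment_gmm_hmm(track, sample_counts.bins,
                               self_transition=self_transition, alt_mean=alt_mean)
    states = segments_to_bin_states(segments, len(sample_counts.bins))
    rows = []
    for reg in regions.itertuples():
        span_states = states[reg.first_bin:reg.last_bin + 1]
        testable = bool(np.any(span_states >= 0))
        want = STATES.index(reg.state)
        hit = bool(np.any(span_states == want)) and reg.state != "NEUT"
        rows.append((reg.chrom, reg.start, reg.end, reg.state,
                     reg.state if hit else "none", testable))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "state",
                                       "event", "testable"])


def select_differential_cnv_regions(event_matrix: pd.DataFrame, labels: np.ndarray,
                                    alpha: float = 0.05,
                                    adjust: bool = False) -> pd.DataFrame:
    """Case-enriched recurrent regions by rank-sum test on event indicators.

    ``event_matrix`` is samples x regions with 0/1 indicators.  Default is
    the unadjusted two-sided test at ``alpha``; ``adjust=True`` switches to
    Benjamini-Hochberg control.
    """
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    x = event_matrix.to_numpy(dtype=float)
    rows = []
    for j, col in enumerate(event_matrix.columns):
        a, b = x[labels, j], x[~labels, j]
        if np.all(a == a[0] if len(a) else True) and np.all(b == (a[0] if len(a) else 0)):
            p = 1.0
        else:
            p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append((col, float(p), float(a.mean()), float(b.mean())))
    df = pd.DataFrame(rows, columns=["region", "p", "case_rate", "control_rate"])
    if adjust:
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        keep = (df["p_adj"] < alpha) & (df["case_rate"] > df["control_rate"])
    else:
        keep = (df["p"] < alpha) & (df["case_rate"] > df["control_rate"])
    return df.loc[keep].reset_index(drop=True)


def score_segmentation(called: pd.DataFrame, truth: pd.DataFrame,
                       tol_bins: int = 1) -> dict:
    """Recall/precision of non-neutral segments against a truth table.

    A truth segment is recalled when a called segment of the same state
    has both boundaries within ``tol_bins``; a called segment is correct
    when it matches a truth segment the same way.  Both frames need
    ``state, first_bin, last_bin`` columns.
    """
    called_nn = called[called["state"] != "NEUT"]

    def _matches(a, b) -> bool:
        return (a.state == b.state
                and abs(int(a.first_bin) - int(b.first_bin)) <= tol_bins
                and abs(int(a.last_bin) - int(b.last_bin)) <= tol_bins)

    recalled = sum(any(_matches(t, c) for c in called_nn.itertuples())
                   for t in truth.itertuples())
    correct = sum(any(_matches(c, t) for t in truth.itertuples())
                  for c in called_nn.itertuples())
    return {"recall": recalled / len(truth) if len(truth) else float("nan"),
            "precision": correct / len(called_nn) if len(called_nn) else float("nan"),
            "n_called": int(len(called_nn)), "n_truth": int(len(truth))}


def region_key(df: pd.DataFrame) -> pd.Series:
    """Canonical region identifier ``chrom:start-end:state``."""
    return (df["chrom"].astype(str) + ":" + df["start"].astype(str) + "-"
            + df["end"].astype(str) + ":" + df["state"].astype(str))


def cnv_positive(event_calls: pd.DataFrame,
                 selected_regions: pd.DataFrame | None = None) -> bool:
    """True iff the sample has >= 1 event call inside the selected regions."""
    calls = event_calls[event_calls["event"] != "none"]
    if len(calls) == 0:
        return False
    if selected_regions is None:
        return True
    if len(selected_regions) == 0:
        return False
    if "region" in selected_regions.columns:
        keys = set(selected_regions["region"])
    else:
        keys = set(region_key(selected_regions))
    return bool(region_key(calls).isin(keys).any())
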