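"""End-to-end orchestration on a synthetic cohort.

Mirrors the tissue-informed cfDNA workflow: discover DMRs and recurrent
CNV regions in simulated tissue pairs, extract malignant ratios, CNV
event calls and fragment-size ratios from the cfDNA cohort, select
cfDNA-informative features, and train/evaluate the three diagnostic
models (``meth``, ``meth_cnv``, ``full``) with out-of-fold scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cnv, fragmentomics, methylation, models
from .simulate import (Cohort, SimulationConfig, SimulatedGenome, build_genome,
                       iter_cfdna_samples, simulate_tissue_cohort)


@dataclass
class TissueReference:
    """Tissue-derived priors: DMR panel and recurrent CNV regions."""

    dmrs: pd.DataFrame
    recurrent_regions: pd.DataFrame


def derive_tissue_reference(config: SimulationConfig, genome: SimulatedGenome,
                            n_pairs: int = 30, min_delta: float = 0.2,
                            fdr: float = 0.05,
                            min_recurrence: int = 3) -> TissueReference:
    """Run the tissue arm: DMR discovery and recurrent CNV regions."""
    pairs = simulate_tissue_cohort(config, genome, n_pairs)
    candidates = genome.dmr_truth[["chrom", "start", "end"]]
    dmrs = methylation.call_tissue_dmrs(pairs, candidates, min_delta=min_delta,
                                        fdr=fdr)
    seg_lists = []
    for pair in pairs:
        t = cnv.BinCounts(genome.cnv_bins, pair["tumor_counts"])
        n = cnv.BinCounts(genome.cnv_bins, pair["normal_counts"])
        _, ct = cnv.loess_gc_correct(t)
        _, cn = cnv.loess_gc_correct(n)
        track = cnv.log2_ratio(ct, cn)
        seg_lists.append(cnv.segment_gmm_hmm(track, genome.cnv_bins))
    recurrent = cnv.recurrent_regions(seg_lists, genome.cnv_bins,
                                      min_recurrence=min_recurrence)
    return TissueReference(dmrs, recurrent)


@dataclass
class CohortFeatures:
    """Per-sample modality tables extracted in one pass over the cohort."""

    manifest: pd.DataFrame
    labels: np.ndarray
    dmr_matrix: pd.DataFrame       # samples x DMR malignant ratios
    fsr_matrix: pd.DataFrame       # samples x 5'-bin short-fragment ratios
    bin_counts: pd.DataFrame       # samples x CNV-bin fragment counts (standardised)


def extract_cohort_features(config: SimulationConfig, genome: SimulatedGenome,
                            reference: TissueReference,
                            min_cpg: int = 3, min_fragments: int = 5,
                            fsr_min_total: int = 100) -> CohortFeatures:
    """Stream the cfDNA cohort once, extracting all three modalities."""
    dmr_rows, fsr_rows, count_rows = [], [], []
    manifest_rows = []
    regions = reference.dmrs.reset_index(drop=True)
    names = [f"{r.chrom}:{r.start}-{r.end}" for r in regions.itertuples()]
    fsr_names = [f"{b.chrom}:{b.start}-{b.end}" for b in genome.fsr_bins.itertuples()]
    for sample in iter_cfdna_samples(config, genome):
        frags = sample.fragments
        ridx, call = methylation.classify_fragments(frags, regions, min_cpg=min_cpg)
        informative = call != methylation.UNINFORMATIVE
        n_inf = np.bincount(ridx[informative], minlength=len(regions))
        n_mal = np.bincount(ridx[informative & (call == methylation.MALIGNANT)],
                            minlength=len(regions))
        with np.errstate(invalid="ignore", divide="ignore"):
            dmr_rows.append(np.where(n_inf >= min_fragments,
                                     n_mal / np.maximum(n_inf, 1), np.nan))
        fsr = fragmentomics.fsr_per_bin(frags, genome.fsr_bins,
                                        short_band=config.short_band,
                                        min_total=fsr_min_total)
        fsr_rows.append(fsr["ratio"].to_numpy())
        bc = cnv.count_fragments_per_bin(frags, genome.cnv_bins,
                                         target_depth=config.n_fragments)
        count_rows.append(bc.y)
        manifest_rows.append((sample.sample_id, sample.label,
                              sample.tumor_fraction, sample.has_cnv))
    manifest = pd.DataFrame(manifest_rows, columns=["sample_id", "label",
                                                    "tumor_fraction", "has_cnv"])
    ids = manifest["sample_id"]
    labels = (manifest["label"] == "case").to_numpy().astype(int)
    return CohortFeatures(
        manifest=manifest, labels=labels,
        dmr_matrix=pd.DataFrame(dmr_rows, index=ids, columns=names),
        fsr_matrix=pd.DataFrame(fsr_rows, index=ids, columns=fsr_names),
        bin_counts=pd.DataFrame(count_rows, index=ids,
                                columns=range(len(genome.cnv_bins))))


def call_cohort_cnv_events(features: CohortFeatures, genome: SimulatedGenome,
                           reference: TissueReference,
                           alt_mean: float = 0.15) -> pd.DataFrame:
    """Baseline-relative CNV event indicators for every sample.

    The reference Fn is the per-bin median of the GC-corrected control
    samples (a panel-of-normals baseline).  Returns a samples x regions
    0/1 frame keyed by canonical region ids.
    """
    ctrl_ids = features.manifest.loc[features.labels == 0, "sample_id"]
    controls = [cnv.BinCounts(genome.cnv_bins,
                              features.bin_counts.loc[sid].to_numpy())
                for sid in ctrl_ids]
    baseline = cnv.build_control_baseline(controls)
    regions = reference.recurrent_regions
    keys = list(cnv.region_key(regions)) if len(regions) else []
    rows = []
    for sid in features.manifest["sample_id"]:
        bc = cnv.BinCounts(genome.cnv_bins, features.bin_counts.loc[sid].to_numpy())
        calls = cnv.call_cfdna_events(bc, baseline, regions, alt_mean=alt_mean)
        rows.append((calls["event"] != "none").astype(int).to_numpy())
    return pd.DataFrame(rows, index=features.manifest["sample_id"], columns=keys)


@dataclass
class PipelineResult:
    config: SimulationConfig
    genome: SimulatedGenome = field(repr=False)
    reference: TissueReference = field(repr=False)
    features: CohortFeatures = field(repr=False)
    selected_dmrs: pd.DataFrame
    selected_fsr_bins: pd.DataFrame
    event_matrix: pd.DataFrame
    selected_cnv_regions: pd.DataFrame
    cnv_positive: pd.Series
    bundles: dict[str, models.ModelBundle]
    metrics: dict[str, dict]


def run_pipeline(config: SimulationConfig, n_tissue_pairs: int = 30,
                 n_dmr_panel: int = 50, modes=("meth", "meth_cnv", "full"),
                 n_trees: int = 500, k_folds: int = 10,
                 use_rfe: bool = False, eval_boot: int = 2000,
                 dmr_fdr: float = 0.05) -> PipelineResult:
    """Full synthetic run: simulate, extract, select, train, evaluate."""
    genome = build_genome(config)
    reference = derive_tissue_reference(config, genome, n_pairs=n_tissue_pairs)
    features = extract_cohort_features(config, genome, reference)
    labels = features.labels

    selected = methylation.select_cfdna_dmrs(features.dmr_matrix, labels,
                                             fdr=dmr_fdr)
    panel_cols = list(selected["region"].head(n_dmr_panel))
    if not panel_cols:
        raise ValueError(
            "no DMR survived the cfDNA screen; the cohort (or the tissue "
            "pair count) is too small for the FDR level — enlarge the cohort "
            "or relax the screen")
    if use_rfe and len(panel_cols) > n_dmr_panel // 2:
        sizes = sorted({len(panel_cols), max(2, n_dmr_panel // 2), n_dmr_panel})
        sizes = [s for s in sizes if s <= len(panel_cols)]
        panel_cols, _ = models.rfe_select(features.dmr_matrix[panel_cols], labels,
                                          sizes, seed=config.seed,
                                          n_trees=min(n_trees, 200),
                                          n_select=min(n_dmr_panel, len(panel_cols)))
    dmr_panel = features.dmr_matrix[panel_cols]

    event_matrix = call_cohort_cnv_events(features, genome, reference)
    selected_cnv = cnv.select_differential_cnv_regions(event_matrix, labels) \
        if event_matrix.shape[1] else pd.DataFrame(columns=["region", "p"])
    cnv_cols = list(selected_cnv["region"]) if len(selected_cnv) else \
        list(event_matrix.columns)
    positive = event_matrix[cnv_cols].sum(axis=1) > 0 if cnv_cols else \
        pd.Series(False, index=event_matrix.index)

    selected_fsr = fragmentomics.select_differential_fsr_bins(
        features.fsr_matrix, labels)
    fsr_cols = list(selected_fsr["bin"]) if len(selected_fsr) else \
        list(features.fsr_matrix.columns)

    bundles, metrics = {}, {}
    for mode in modes:
        X, builder = models.build_model_inputs(
            dmr_panel, labels,
            cnv_events=event_matrix[cnv_cols] if mode != "meth" else None,
            fsr_matrix=features.fsr_matrix[fsr_cols] if mode == "full" else None,
            mode=mode, seed=config.seed)
        bundle = models.train_rf_cv(X, labels, n_trees=n_trees, k_folds=k_folds,
                                    seed=config.seed, mode=mode, builder=builder)
        bundles[mode] = bundle
        metrics[mode] = models.evaluate(bundle.oof_scores, labels,
                                        cutoff=bundle.threshold,
                                        n_boot=eval_boot, seed=config.seed)
    return PipelineResult(config, genome, reference, features, selected,
                          selected_fsr, event_matrix, selected_cnv, positive,
                          bundles, metrics)
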