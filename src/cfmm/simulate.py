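"""Synthetic cfDNA WGBS cohort simulator.

Generates tissue pairs and plasma cfDNA samples with the statistical
structure the downstream pipeline assumes, on a scaled toy genome:

* per-fragment CpG methylation drawn from region-specific tumor/normal
  beta levels (differentially methylated regions, DMRs);
* bin-level coverage modulated by copy-number state, GC content and
  tumor fraction;
* a two-component fragment-length mixture — healthy fragments modal at
  166 bp, tumor-derived fragments shorter (modal ~145 bp) and enriched in
  the 100–150 bp band.

Every latent variable (tumor fraction, fragment origin, truth regions) is
recorded so recovery tests can score the pipeline against ground truth.
All randomness flows through one seeded :class:`numpy.random.Generator`
per object; same seed ⇒ byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .genome import GenomeLayout, make_bins


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Length scales are deliberately smaller than a human genome (two
    chromosomes of 25 Mb each, 100-kb copy-number bins, 500-kb
    fragmentation bins) so that a full cohort runs on a laptop; signal
    amplitudes (beta contrasts, copy ratios, fragment-length modes) are
    kept at realistic values.
    """

    seed: int = 0
    n_cases: int = 100
    n_controls: int = 100
    tumor_fraction_range: tuple[float, float] = (0.01, 0.15)

    # genome geometry
    n_chromosomes: int = 2
    chrom_length: int = 25_000_000
    cnv_bin_size: int = 100_000
    fsr_bin_size: int = 500_000

    # fragment-length mixture (lognormal, parameterised by mode)
    healthy_length_mode: int = 166
    tumor_length_mode: int = 145
    length_sigma: float = 0.18
    short_band: tuple[int, int] = (100, 150)

    # methylation truth
    n_dmrs: int = 60              # half hyper, half hypo
    n_null_regions: int = 140     # candidate regions with no contrast
    dmr_width: int = 3_000
    hyper_tumor_beta: float = 0.85
    hyper_normal_beta: float = 0.15
    background_beta: float = 0.75
    region_cpg_rate: float = 0.04   # CpG per bp inside candidate regions
    background_cpg_rate: float = 0.008
    beta_concentration: float = 30.0  # tissue Beta noise
    pair_beta_sd: float = 0.03        # pair-level beta wobble

    # copy-number truth
    n_amp: int = 5
    n_del: int = 5
    cnv_segment_bins: int = 20
    amp_copy_ratio: float = 1.75
    del_copy_ratio: float = 0.5
    cnv_prevalence: float = 0.3   # fraction of cases carrying the CNV profile
    tissue_purity: float = 1.0

    # fragmentation truth: bins where tumor-derived coverage is enriched
    n_fsr_truth_bins: int = 20
    fsr_enrichment: float = 5.0
    tumor_spatial_background: float = 1.0  # tumor weight outside enriched bins

    # coverage
    n_fragments: int = 150_000      # per cfDNA sample
    tissue_mean_depth: float = 100.0  # fragments per CNV bin in tissue counts
    gc_bias_linear: float = 0.8
    gc_bias_quad: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.tumor_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("tumor_fraction_range must satisfy 0 <= lo <= hi <= 1")
        for b in (self.hyper_tumor_beta, self.hyper_normal_beta, self.background_beta):
            if not 0.0 <= b <= 1.0:
                raise ValueError("beta levels must lie in [0, 1]")
        if self.amp_copy_ratio <= 0 or self.del_copy_ratio <= 0:
            raise ValueError("copy ratios must be positive")
        if self.short_band[0] >= self.short_band[1]:
            raise ValueError("short_band must be an increasing pair")

    def gc_bias(self, gc: np.ndarray) -> np.ndarray:
        """Multiplicative coverage weight as a smooth function of GC."""
        d = np.asarray(gc, dtype=float) - 0.45
        return 1.0 + self.gc_bias_linear * d + self.gc_bias_quad * d * d


@dataclass
class SimulatedGenome:
    """Toy genome with truth annotations, derived deterministically from config."""

    layout: GenomeLayout
    cnv_bins: pd.DataFrame        # bin frame + gc column filled
    fsr_bins: pd.DataFrame
    dmr_truth: pd.DataFrame       # chrom,start,end,tumor_beta,normal_beta,direction,is_true
    cnv_truth: pd.DataFrame       # chrom,start,end,state,copy_ratio,first_bin,last_bin
    fsr_truth_bins: np.ndarray    # indices into fsr_bins

    def copy_ratio_per_cnv_bin(self) -> np.ndarray:
        r = np.ones(len(self.cnv_bins))
        for _, seg in self.cnv_truth.iterrows():
            r[int(seg.first_bin):int(seg.last_bin) + 1] = seg.copy_ratio
        return r


@dataclass
class SimulatedSample:
    sample_id: str
    label: str                    # "case" | "control"
    tumor_fraction: float
    has_cnv: bool
    fragments: pd.DataFrame       # chrom,start,end,n_cpg,n_meth
    is_tumor: np.ndarray          # per-fragment origin tag (truth)


def _lognormal_mode_params(mode: float, sigma: float) -> float:
    # lognormal mode = exp(mu - sigma^2)  =>  mu = ln(mode) + sigma^2
    return float(np.log(mode) + sigma * sigma)


def build_genome(config: SimulationConfig) -> SimulatedGenome:
    """Lay out the toy genome and place truth regions (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0FFEE]))
    layout = GenomeLayout(tuple(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)))
    cnv_bins = make_bins(layout, config.cnv_bin_size)
    fsr_bins = make_bins(layout, config.fsr_bin_size)

    # synthetic per-bin GC fractions, mostly inside the admissible 0.3-0.6 range
    gc = np.clip(rng.normal(0.45, 0.05, size=len(cnv_bins)), 0.28, 0.62)
    cnv_bins = cnv_bins.copy()
    cnv_bins["gc"] = gc

    # candidate methylation regions: non-overlapping windows on a coarse grid
    n_regions = config.n_dmrs + config.n_null_regions
    grid = 10_000  # candidate slots every 10 kb keep regions disjoint
    slots_per_chrom = (config.chrom_length - config.dmr_width) // grid
    all_slots = [(c, s) for c in layout.names for s in range(1, slots_per_chrom)]
    chosen = rng.choice(len(all_slots), size=n_regions, replace=False)
    chosen.sort()
    # true DMRs carry a genuine tumor/normal contrast; null candidates keep a
    # nominal reference contrast (a tissue lead that does not replicate) but
    # both cfDNA components are simulated at the normal level.
    rows = []
    n_hyper = config.n_dmrs // 2
    for k, idx in enumerate(chosen):
        chrom, slot = all_slots[idx]
        start = slot * grid
        end = start + config.dmr_width
        if k < n_hyper:
            tb, nb = config.hyper_tumor_beta, config.hyper_normal_beta
            stb, snb, direction, is_true = tb, nb, "hyper", True
        elif k < config.n_dmrs:
            tb, nb = config.hyper_normal_beta, config.hyper_tumor_beta
            stb, snb, direction, is_true = tb, nb, "hypo", True
        else:
            nb = float(rng.uniform(0.15, 0.55))
            tb = nb + 0.3
            stb = snb = nb
            direction, is_true = "none", False
        rows.append((chrom, start, end, tb, nb, stb, snb, direction, is_true))
    dmr_truth = pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "tumor_beta", "normal_beta",
        "sim_tumor_beta", "sim_normal_beta", "direction", "is_true"])
    dmr_truth = dmr_truth.sort_values(["chrom", "start"], ignore_index=True)

    # copy-number truth segments on the CNV bin grid, non-overlapping
    n_seg = config.n_amp + config.n_del
    seg_bins = config.cnv_segment_bins
    bins_per_chrom = config.chrom_length // config.cnv_bin_size
    # candidate segment start bins, leaving a 2-bin gap between segments
    placed: list[tuple[int, int]] = []
    seg_rows = []
    states = ["AMP"] * config.n_amp + ["DEL"] * config.n_del
    attempt = 0
    while len(seg_rows) < n_seg:
        attempt += 1
        if attempt > 10_000:
            raise RuntimeError("could not place CNV truth segments; genome too small")
        chrom_idx = int(rng.integers(0, config.n_chromosomes))
        b0 = int(rng.integers(2, bins_per_chrom - seg_bins - 2))
        first = chrom_idx * bins_per_chrom + b0
        last = first + seg_bins - 1
        if any(f - 2 <= last and first <= l + 2 for f, l in placed):
            continue
        placed.append((first, last))
        state = states[len(seg_rows)]
        ratio = config.amp_copy_ratio if state == "AMP" else config.del_copy_ratio
        chrom = layout.names[chrom_idx]
        seg_rows.append((chrom, b0 * config.cnv_bin_size,
                         (b0 + seg_bins) * config.cnv_bin_size,
                         state, ratio, first, last))
    cnv_truth = pd.DataFrame(seg_rows, columns=[
        "chrom", "start", "end", "state", "copy_ratio", "first_bin", "last_bin"])
    cnv_truth = cnv_truth.sort_values(["first_bin"], ignore_index=True)

    fsr_truth = rng.choice(len(fsr_bins), size=config.n_fsr_truth_bins, replace=False)
    fsr_truth.sort()
    return SimulatedGenome(layout, cnv_bins, fsr_bins, dmr_truth, cnv_truth, fsr_truth)


# ---------------------------------------------------------------------------
# Tissue pairs
# ---------------------------------------------------------------------------

def simulate_tissue_pair(config: SimulationConfig, genome: SimulatedGenome,
                         rng: np.random.Generator) -> dict:
    """One tumor/normal tissue pair: CpG tracks plus per-bin fragment counts.

    CpG sites are laid every 50 bp inside candidate regions; site betas are
    Beta-distributed around the region's (pair-perturbed) reference level.
    Tumor bin counts scale with copy ratio (diluted by ``tissue_purity``)
    and GC bias; counts are Poisson.
    """
    conc = config.beta_concentration
    spacing = 50
    site_rows_t, site_rows_n = [], []
    for _, reg in genome.dmr_truth.iterrows():
        pos = np.arange(reg.start, reg.end, spacing, dtype=np.int64)
        mu_t = float(np.clip(reg.sim_tumor_beta + rng.normal(0, config.pair_beta_sd), 1e-3, 1 - 1e-3))
        mu_n = float(np.clip(reg.sim_normal_beta + rng.normal(0, config.pair_beta_sd), 1e-3, 1 - 1e-3))
        bt = rng.beta(mu_t * conc, (1 - mu_t) * conc, size=len(pos))
        bn = rng.beta(mu_n * conc, (1 - mu_n) * conc, size=len(pos))
        depth = rng.poisson(30, size=len(pos)) + 1
        site_rows_t.append(pd.DataFrame({"chrom": reg.chrom, "pos": pos, "beta": bt,
                                         "depth": depth}))
        site_rows_n.append(pd.DataFrame({"chrom": reg.chrom, "pos": pos, "beta": bn,
                                         "depth": depth}))
    tumor_sites = pd.concat(site_rows_t, ignore_index=True)
    normal_sites = pd.concat(site_rows_n, ignore_index=True)

    gc_w = config.gc_bias(genome.cnv_bins["gc"].to_numpy())
    ratio = genome.copy_ratio_per_cnv_bin()
    eff_ratio = 1.0 + config.tissue_purity * (ratio - 1.0)
    lam_n = config.tissue_mean_depth * gc_w
    lam_t = config.tissue_mean_depth * gc_w * eff_ratio
    tumor_counts = rng.poisson(lam_t).astype(np.int64)
    normal_counts = rng.poisson(lam_n).astype(np.int64)
    return {"tumor_sites": tumor_sites, "normal_sites": normal_sites,
            "tumor_counts": tumor_counts, "normal_counts": normal_counts}


def simulate_tissue_cohort(config: SimulationConfig, genome: SimulatedGenome,
                           n_pairs: int, seed_key: int = 1) -> list[dict]:
    seqs = np.random.SeedSequence([config.seed, seed_key]).spawn(n_pairs)
    return [simulate_tissue_pair(config, genome, np.random.default_rng(s)) for s in seqs]


# ---------------------------------------------------------------------------
# cfDNA samples
# ---------------------------------------------------------------------------

def _assign_regions(genome: SimulatedGenome, chrom_idx: np.ndarray,
                    mid: np.ndarray) -> np.ndarray:
    """Index of the candidate methylation region containing each midpoint (-1 if none)."""
    out = np.full(len(mid), -1, dtype=np.int64)
    truth = genome.dmr_truth
    for ci, chrom in enumerate(genome.layout.names):
        reg = truth[truth["chrom"] == chrom]
        if reg.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        ridx = reg.index.to_numpy()
        sel = chrom_idx == ci
        pos = mid[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.maximum(j, 0)])
        res = np.where(ok, ridx[np.maximum(j, 0)], -1)
        out[sel] = res
    return out


def simulate_cfdna_sample(config: SimulationConfig, genome: SimulatedGenome,
                          tumor_fraction: float, rng: np.random.Generator,
                          has_cnv: bool = True,
                          sample_id: str = "s0") -> SimulatedSample:
    """Draw one plasma sample as a fragment table.

    Each fragment is tumor-derived with probability ``tumor_fraction``;
    tumor fragments are placed with spatial weight ``copy_ratio × fsr
    enrichment × GC bias`` (so amplified and ctDNA-enriched bins receive
    proportionally more tumor fragments), healthy fragments with weight
    ``GC bias``.  Per-fragment CpG totals are Poisson in the local CpG
    density; methylated counts are binomial in the component's beta at the
    overlapped region (background beta elsewhere).
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor_fraction must lie in [0, 1]")
    n = config.n_fragments
    bins = genome.cnv_bins
    bin_size = config.cnv_bin_size
    bins_per_chrom = config.chrom_length // bin_size
    gc_w = config.gc_bias(bins["gc"].to_numpy())

    # spatial weights at CNV-bin resolution
    healthy_w = gc_w.copy()
    copy_ratio = genome.copy_ratio_per_cnv_bin() if has_cnv else np.ones(len(bins))
    fsr_w = np.full(len(bins), config.tumor_spatial_background)
    scale = config.fsr_bin_size // bin_size
    for fb in genome.fsr_truth_bins:
        fsr_w[fb * scale:(fb + 1) * scale] = config.fsr_enrichment
    tumor_w = gc_w * copy_ratio * fsr_w

    is_tumor = rng.random(n) < tumor_fraction
    n_t = int(is_tumor.sum())

    bin_idx = np.empty(n, dtype=np.int64)
    for mask, w in ((~is_tumor, healthy_w), (is_tumor, tumor_w)):
        k = int(mask.sum())
        if k == 0:
            continue
        cdf = np.cumsum(w / w.sum())
        bin_idx[mask] = np.searchsorted(cdf, rng.random(k), side="right")

    sigma = config.length_sigma
    lengths = np.empty(n, dtype=np.int64)
    mu_h = _lognormal_mode_params(config.healthy_length_mode, sigma)
    mu_t = _lognormal_mode_params(config.tumor_length_mode, sigma)
    lengths[~is_tumor] = np.round(rng.lognormal(mu_h, sigma, size=n - n_t)).astype(np.int64)
    lengths[is_tumor] = np.round(rng.lognormal(mu_t, sigma, size=n_t)).astype(np.int64)
    lengths = np.clip(lengths, 30, bin_size - 1)

    chrom_idx = bin_idx // bins_per_chrom
    bin_start = (bin_idx % bins_per_chrom) * bin_size
    offset = (rng.random(n) * (bin_size - lengths)).astype(np.int64)
    start = bin_start + offset
    end = start + lengths
    mid = start + lengths // 2

    region = _assign_regions(genome, chrom_idx, mid)
    in_region = region >= 0
    cpg_rate = np.where(in_region, config.region_cpg_rate, config.background_cpg_rate)
    n_cpg = rng.poisson(cpg_rate * lengths)

    beta = np.full(n, config.background_beta)
    tb = genome.dmr_truth["sim_tumor_beta"].to_numpy()
    nb = genome.dmr_truth["sim_normal_beta"].to_numpy()
    ri = np.maximum(region, 0)
    beta[in_region & is_tumor] = tb[ri[in_region & is_tumor]]
    beta[in_region & ~is_tumor] = nb[ri[in_region & ~is_tumor]]
    n_meth = rng.binomial(n_cpg, beta)

    order = np.lexsort((start, chrom_idx))
    frags = pd.DataFrame({
        "chrom": pd.Categorical.from_codes(chrom_idx[order].astype(np.int8),
                                           categories=genome.layout.names),
        "start": start[order].astype(np.int64),
        "end": end[order].astype(np.int64),
        "n_cpg": n_cpg[order].astype(np.int32),
        "n_meth": n_meth[order].astype(np.int32),
    })
    label = "case" if tumor_fraction > 0 else "control"
    return SimulatedSample(sample_id, label, float(tumor_fraction),
                           bool(has_cnv), frags, is_tumor[order])


@dataclass
class Cohort:
    config: SimulationConfig
    genome: SimulatedGenome
    samples: list[SimulatedSample]

    @property
    def manifest(self) -> pd.DataFrame:
        """Truth manifest: one row per sample with every latent variable."""
        return pd.DataFrame({
            "sample_id": [s.sample_id for s in self.samples],
            "label": [s.label for s in self.samples],
            "tumor_fraction": [s.tumor_fraction for s in self.samples],
            "has_cnv": [s.has_cnv for s in self.samples],
        })

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label == "case" for s in self.samples], dtype=int)


def iter_cfdna_samples(config: SimulationConfig,
                       genome: SimulatedGenome) -> Iterator[SimulatedSample]:
    """Yield the cohort's samples one at a time (memory-friendly).

    Cases first, then controls; each sample has its own generator spawned
    from the cohort seed, so the stream is reproducible and any prefix of
    it is independent of how many samples are consumed.
    """
    n_total = config.n_cases + config.n_controls
    root = np.random.SeedSequence([config.seed, 2])
    seqs = root.spawn(n_total + 1)
    head = np.random.default_rng(seqs[0])
    lo, hi = config.tumor_fraction_range
    tfs = head.uniform(lo, hi, size=config.n_cases)
    carries = head.random(config.n_cases) < config.cnv_prevalence
    for i in range(config.n_cases):
        rng = np.random.default_rng(seqs[i + 1])
        yield simulate_cfdna_sample(config, genome, float(tfs[i]), rng,
                                    has_cnv=bool(carries[i]),
                                    sample_id=f"case_{i:03d}")
    for i in range(config.n_controls):
        rng = np.random.default_rng(seqs[config.n_cases + i + 1])
        yield simulate_cfdna_sample(config, genome, 0.0, rng, has_cnv=False,
                                    sample_id=f"control_{i:03d}")


def simulate_cohort(config: SimulationConfig,
                    genome: SimulatedGenome | None = None) -> Cohort:
    """Materialise the full labelled cohort plus truth manifest."""
    if config.n_cases < 0 or config.n_controls < 0:
        raise ValueError("cohort sizes must be non-negative")
    if genome is None:
        genome = build_genome(config)
    samples = list(iter_cfdna_samples(config, genome))
    return Cohort(config, genome, samples)
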