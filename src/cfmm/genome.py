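"""Genome partitioning, GC annotation and region-level methylation.

All coordinates are 0-based half-open internally.  BED input/output is
native; bedGraph and Bismark cytosine-coverage positions are converted on
read.  Bins, CpG tracks and region tables are plain :class:`pandas.DataFrame`
objects with fixed column schemas:

* bins:    ``chrom, start, end, gc, partial``
* CpGs:    ``chrom, pos, beta, depth``
* regions: ``chrom, start, end`` (+ optional extra columns)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BIN_COLUMNS = ["chrom", "start", "end", "gc", "partial"]
CPG_COLUMNS = ["chrom", "pos", "beta", "depth"]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome table with an inclusion set.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs; lengths in bp.
    included
        Names participating in binning.  Defaults to every chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    included: frozenset[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(names) != len(set(names)):
            raise ValueError("duplicate chromosome names")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.included is None:
            object.__setattr__(self, "included", frozenset(names))
        else:
            object.__setattr__(self, "included", frozenset(self.included))
            unknown = self.included - set(names)
            if unknown:
                raise ValueError(f"included chromosomes not in layout: {sorted(unknown)}")

    @classmethod
    def from_items(cls, items: Mapping[str, int] | Iterable[tuple[str, int]],
                   included: Iterable[str] | None = None) -> "GenomeLayout":
        if isinstance(items, Mapping):
            pairs = tuple(sorted(items.items()))
        else:
            pairs = tuple(items)
        return cls(pairs, None if included is None else frozenset(included))

    @classmethod
    def from_chrom_sizes(cls, path: str | Path,
                         included: Iterable[str] | None = None) -> "GenomeLayout":
        """Read a two-column ``chrom<TAB>length`` file (FASTA-index style)."""
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1],
                         names=["chrom", "length"], dtype={"chrom": str})
        return cls(tuple(zip(df["chrom"], df["length"].astype(int))),
                   None if included is None else frozenset(included))

    @classmethod
    def from_fasta(cls, path: str | Path,
                   included: Iterable[str] | None = None) -> "GenomeLayout":
        from pyfaidx import Fasta

        fa = Fasta(str(path))
        return cls(tuple((name, len(fa[name])) for name in fa.keys()),
                   None if included is None else frozenset(included))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def included_chromosomes(self) -> list[tuple[str, int]]:
        """Included (name, length) pairs in layout order."""
        return [(n, s) for n, s in self.chromosomes if n in self.included]

    def total_included_length(self) -> int:
        return sum(s for _, s in self.included_chromosomes())


def make_bins(layout: GenomeLayout, bin_size: int) -> pd.DataFrame:
    """Tile every included chromosome with non-overlapping ``bin_size`` bins.

    Terminal partial bins are retained and flagged ``partial=True``.
    Deterministic: bins follow the layout's chromosome order.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    chroms = layout.included_chromosomes()
    if not chroms:
        raise ValueError("layout has no included chromosomes")
    rows = []
    for name, length in chroms:
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({
            "chrom": name, "start": starts, "end": ends,
            "gc": np.nan, "partial": ends - starts < bin_size,
        }))
    bins = pd.concat(rows, ignore_index=True)
    return bins[BIN_COLUMNS]


def gc_annotate(bins: pd.DataFrame,
                sequence_source: Mapping[str, str] | str | Path) -> pd.DataFrame:
    """Annotate bins with GC fraction (G+C)/(A+C+G+T); N bases excluded.

    ``sequence_source`` is a FASTA path or a chrom→sequence mapping.  A bin
    with no unambiguous bases gets ``gc = NaN`` (flagged missing).
    """
    if not isinstance(sequence_source, Mapping):
        from pyfaidx import Fasta

        fa = Fasta(str(sequence_source))
        sequence_source = {name: str(fa[name][:]) for name in fa.keys()}

    out = bins.copy()
    gc = np.full(len(bins), np.nan)
    for i, (chrom, start, end) in enumerate(zip(bins["chrom"], bins["start"], bins["end"])):
        if chrom not in sequence_source:
            raise KeyError(f"no sequence for chromosome {chrom!r}")
        seq = sequence_source[chrom]
        if end > len(seq):
            raise ValueError(f"bin {chrom}:{start}-{end} outside sequence (len {len(seq)})")
        sub = np.frombuffer(seq[start:end].upper().encode("ascii"), dtype="S1")
        n_gc = int(np.sum((sub == b"G") | (sub == b"C")))
        n_at = int(np.sum((sub == b"A") | (sub == b"T")))
        denom = n_gc + n_at
        gc[i] = n_gc / denom if denom else np.nan
    out["gc"] = gc
    return out


def region_mean_methylation(sites: pd.DataFrame,
                            region: tuple[str, int, int],
                            weight_by_depth: bool = False) -> float:
    """Mean beta of CpG sites inside ``region`` (chrom, start, end).

    Unweighted by default; optional depth weighting.  Returns NaN (missing)
    when no site falls in the region — never 0.
    """
    chrom, start, end = region
    if start >= end or start < 0:
        raise ValueError(f"malformed interval {chrom}:{start}-{end}")
    sel = sites[(sites["chrom"] == chrom)
                & (sites["pos"] >= start) & (sites["pos"] < end)]
    if sel.empty:
        return float("nan")
    if weight_by_depth:
        depth = sel["depth"].to_numpy(dtype=float)
        if depth.sum() <= 0:
            return float("nan")
        return float(np.average(sel["beta"], weights=depth))
    return float(sel["beta"].mean())


def regions_mean_methylation(sites: pd.DataFrame, regions: pd.DataFrame,
                             weight_by_depth: bool = False) -> np.ndarray:
    """Vectorised :func:`region_mean_methylation` over a sorted region table.

    Regions must be non-overlapping within each chromosome.
    """
    out = np.full(len(regions), np.nan)
    for chrom, reg in regions.groupby("chrom", sort=False):
        sub = sites[sites["chrom"] == chrom]
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        beta = sub["beta"].to_numpy()[order]
        depth = sub["depth"].to_numpy(dtype=float)[order]
        lo = np.searchsorted(pos, reg["start"].to_numpy())
        hi = np.searchsorted(pos, reg["end"].to_numpy())
        for ridx, a, b in zip(reg.index, lo, hi):
            if b > a:
                if weight_by_depth and depth[a:b].sum() > 0:
                    out[regions.index.get_loc(ridx)] = np.average(
                        beta[a:b], weights=depth[a:b])
                else:
                    out[regions.index.get_loc(ridx)] = beta[a:b].mean()
    return out


# ---------------------------------------------------------------------------
# Standard-format I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ into a region frame (0-based half-open, native)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    names = ["chrom", "start", "end", "name", "score", "strand"][:min(ncol, 6)]
    names += [f"extra{i}" for i in range(ncol - len(names))]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bed(df: pd.DataFrame, path: str | Path,
              columns: Sequence[str] | None = None) -> None:
    cols = list(columns) if columns else [c for c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a methylation bedGraph (chrom start end value) into a CpG frame.

    One row per single-base interval; beta taken from the value column
    (rescaled from percent when values exceed 1).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"],
                     dtype={"chrom": str})
    beta = df["value"].to_numpy(dtype=float)
    if np.nanmax(beta, initial=0.0) > 1.0:
        beta = beta / 100.0
    return pd.DataFrame({"chrom": df["chrom"], "pos": df["start"].astype(np.int64),
                         "beta": beta, "depth": 0})


def read_bismark_cov(path: str | Path) -> pd.DataFrame:
    """Read Bismark coverage TSV (chrom, pos1, pos1, meth%, count_M, count_U).

    Positions are 1-based in the file and converted to 0-based.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "pos1", "pos2", "meth_pct", "count_m", "count_u"],
                     dtype={"chrom": str})
    depth = (df["count_m"] + df["count_u"]).astype(np.int64)
    return pd.DataFrame({
        "chrom": df["chrom"],
        "pos": df["pos1"].astype(np.int64) - 1,
        "beta": df["meth_pct"].to_numpy(dtype=float) / 100.0,
        "depth": depth,
    })


def write_bismark_cov(sites: pd.DataFrame, path: str | Path) -> None:
    depth = sites["depth"].to_numpy()
    count_m = np.round(sites["beta"].to_numpy() * depth).astype(np.int64)
    out = pd.DataFrame({
        "chrom": sites["chrom"],
        "pos1": sites["pos"].astype(np.int64) + 1,
        "pos2": sites["pos"].astype(np.int64) + 1,
        "meth_pct": np.round(sites["beta"].to_numpy() * 100.0, 6),
        "count_m": count_m,
        "count_u": depth - count_m,
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    """Read a BED-like fragment table: chrom, start, end, n_cpg, n_meth."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "n_cpg", "n_meth"],
                     dtype={"chrom": str})
    for col in ("start", "end", "n_cpg", "n_meth"):
        df[col] = df[col].astype(np.int64)
    return df


def write_fragments(frags: pd.DataFrame, path: str | Path) -> None:
    frags.to_csv(path, sep="\t", header=False, index=False,
                 columns=["chrom", "start", "end", "n_cpg", "n_meth"])
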