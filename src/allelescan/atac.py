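"""ATAC-seq signal: Tn5 cut sites, sliding-window intensities, TSS QC.

The local accessibility signal for a region of linkage disequilibrium is the
Tn5 cut-site density (cut sites per bp) in a 150-bp window sliding every
10 bp, normalised by the sample's cut-site density over the whole region.
This per-sample normalisation makes the intensity matrix invariant to
sequencing depth, which is what allows samples to be compared directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "WindowGrid",
    "IntensityMatrix",
    "shift_cut_sites",
    "make_window_grid",
    "local_intensity",
    "tss_enrichment",
]

DEFAULT_WINDOW_LENGTH = 150
DEFAULT_STEP = 10
TSS_PASS_THRESHOLD = 3.0


@dataclass(frozen=True)
class Region:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def parse(cls, text: str) -> "Region":
        """Parse ``chrom:start-end`` (0-based half-open, commas allowed)."""
        try:
            chrom, span = text.rsplit(":", 1)
            start_s, end_s = span.replace(",", "").split("-")
            return cls(chrom, int(start_s), int(end_s))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse region string {text!r}") from exc


@dataclass(frozen=True)
class WindowGrid:
    """Sliding windows fully contained in a region.

    Window ``k`` spans ``[start + k*step, start + k*step + window_length)``;
    placements that would overhang the region end are dropped.
    """

    region: Region
    window_length: int = DEFAULT_WINDOW_LENGTH
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.step < 1:
            raise ValueError("window_length and step must be positive")
        if self.region.length < self.window_length:
            raise ValueError(
                f"region length {self.region.length} shorter than window "
                f"{self.window_length}"
            )

    @property
    def n_windows(self) -> int:
        return (self.region.length - self.window_length) // self.step + 1

    @property
    def starts(self) -> np.ndarray:
        return self.region.start + self.step * np.arange(self.n_windows)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_length


@dataclass
class IntensityMatrix:
    """Normalised local intensity d_ij over windows i and samples j."""

    values: np.ndarray  # (n_windows, n_samples)
    grid: WindowGrid
    samples: list[str]
    region_counts: np.ndarray  # per-sample cut sites in the region
    zero_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.samples)
        df.insert(0, "window_start", self.grid.starts)
        df.insert(1, "window_end", self.grid.ends)
        return df


def shift_cut_sites(
    reads: pd.DataFrame, plus_offset: int = 4, minus_offset: int = 5
) -> pd.DataFrame:
    """Adjust aligned-read stubs to Tn5 insertion centers.

    Plus-strand reads yield ``start + plus_offset``; minus-strand reads
    ``end - minus_offset`` (defaults +4/-5, the conventional Tn5 dimer
    offsets).  Expects columns ``chrom, start, end, strand`` (and optionally
    ``sample_id``, carried through).
    """
    strand = reads["strand"].to_numpy()
    bad = ~np.isin(strand, ["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand value {strand[bad][0]!r}")
    start = reads["start"].to_numpy()
    end = reads["end"].to_numpy()
    if (start >= end).any():
        raise ValueError("read stubs must satisfy start < end")
    pos = np.where(strand == "+", start + plus_offset, end - minus_offset)
    out = pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos})
    if "sample_id" in reads.columns:
        out["sample_id"] = reads["sample_id"].to_numpy()
    return out


def make_window_grid(
    region: Region | str,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    step: int = DEFAULT_STEP,
) -> WindowGrid:
    if isinstance(region, str):
        region = Region.parse(region)
    return WindowGrid(region, window_length, step)


def local_intensity(
    cut_sites: pd.DataFrame,
    grid: WindowGrid,
    samples: list[str] | None = None,
) -> IntensityMatrix:
    """Compute the normalised intensity matrix d_ij.

    ``d_ij = (sites of sample j in window i / window_length) /
    (sites of sample j in region / region_length)``.  Sites outside the
    region are ignored.  A sample with zero sites in the region gets an
    all-zero column and is listed in ``zero_samples``.
    """
    if grid.n_windows < 1:
        raise ValueError("empty window grid")
    region = grid.region
    in_region = (
        (cut_sites["chrom"] == region.chrom)
        & (cut_sites["pos"] >= region.start)
        & (cut_sites["pos"] < region.end)
    )
    sites = cut_sites.loc[in_region]
    if samples is None:
        samples = sorted(cut_sites["sample_id"].unique())

    starts, ends = grid.starts, grid.ends
    values = np.zeros((grid.n_windows, len(samples)))
    region_counts = np.zeros(len(samples))
    zero_samples: list[str] = []
    grouped = dict(iter(sites.groupby("sample_id")))
    for j, sample in enumerate(samples):
        sub = grouped.get(sample)
        n_region = 0 if sub is None else len(sub)
        region_counts[j] = n_region
        if n_region == 0:
            zero_samples.append(sample)
            continue
        pos = np.sort(sub["pos"].to_numpy())
        win_counts = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
        window_density = win_counts / grid.window_length
        region_density = n_region / region.length
        values[:, j] = window_density / region_density
    return IntensityMatrix(values, grid, list(samples), region_counts, zero_samples)


def _depth_profile(pos: np.ndarray, start: int, length: int) -> np.ndarray:
    sel = pos[(pos >= start) & (pos < start + length)]
    return np.bincount(sel - start, minlength=length).astype(float)


def tss_enrichment(
    cut_sites: pd.DataFrame,
    tss: pd.DataFrame,
    half_window: int = 1000,
    flank: int = 100,
    central_window: int = 21,
    threshold: float = TSS_PASS_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample TSS enrichment QC.

    For each gene the cut-site depth profile over ``[TSS - 1000, TSS + 1000)``
    is normalised by the mean depth of the two outermost 100-bp flanks; the
    per-gene score is the normalised depth in a small central window (21 bp
    around the TSS, to damp shot noise), and the sample score is the mean over
    genes.  Samples with score below 3 fail QC.  ``tss`` needs columns
    ``chrom, pos`` and optionally ``strand`` (minus-strand profiles are
    flipped before scoring).

    Genes whose flank depth is zero are skipped with a warning.
    """
    if len(tss) == 0:
        raise ValueError("need at least one TSS")
    length = 2 * half_window
    center = half_window
    half_c = central_window // 2
    strands = tss["strand"].to_numpy() if "strand" in tss.columns else np.repeat("+", len(tss))

    records = []
    for sample, sub in cut_sites.groupby("sample_id"):
        scores = []
        for (_, gene), strand in zip(tss.iterrows(), strands):
            chrom_pos = sub.loc[sub["chrom"] == gene["chrom"], "pos"].to_numpy()
            profile = _depth_profile(chrom_pos, int(gene["pos"]) - half_window, length)
            if strand == "-":
                profile = profile[::-1]
            flank_mean = 0.5 * (profile[:flank].mean() + profile[-flank:].mean())
            if flank_mean == 0:
                warnings.warn(
                    f"sample {sample}: zero flank depth at TSS "
                    f"{gene['chrom']}:{gene['pos']}, gene skipped",
                    stacklevel=2,
                )
                continue
            central = profile[center - half_c : center + half_c + 1].mean()
            scores.append(central / flank_mean)
        score = float(np.mean(scores)) if scores else float("nan")
        records.append(
            {
                "sample_id": sample,
                "tss_enrichment": score,
                "n_genes": len(scores),
                "pass": bool(score >= threshold) if scores else False,
            }
        )
    return pd.DataFrame(records)
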