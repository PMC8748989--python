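"""Readers and writers for the package's plain-text interchange formats.

All tabular files are TSV with named header columns; BED-like files are
0-based half-open.  Writers prepend ``#``-comment header lines recording the
generating parameters so that any output file documents its own provenance.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .atac import IntensityMatrix, Region, WindowGrid
from .design import Variant

__all__ = [
    "ParseError",
    "read_variants",
    "read_genotypes",
    "read_vcf_dosages",
    "read_cutsites",
    "write_cutsites",
    "read_counts",
    "write_table",
    "read_table",
    "read_intensity",
    "write_intensity",
    "write_segmentation_bed",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _header_lines(path) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def write_table(df: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write a TSV with a ``#``-comment provenance header."""
    buf = _io.StringIO()
    if params:
        for key, value in params.items():
            buf.write(f"# {key}={value}\n")
    df.to_csv(buf, sep="\t", index=False)
    Path(path).write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_variants(path) -> list[Variant]:
    """Read a variant table (columns: id, chrom, pos, ref, alt)."""
    df = _read_tsv(path, ["id", "chrom", "pos", "ref", "alt"])
    variants = []
    offset = _header_lines(path) + 2  # comments + header line, 1-based data rows
    for idx, row in df.iterrows():
        try:
            variants.append(
                Variant(str(row["id"]), str(row["chrom"]), int(row["pos"]),
                        str(row["ref"]), str(row["alt"]))
            )
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {idx + offset}: {exc}") from exc
    return variants


def read_genotypes(path) -> pd.Series:
    """Read a dosage TSV (columns: sample_id, dosage) into a Series.

    Dosages must be integers in {0, 1, 2}; violations raise
    :class:`ParseError` naming the line.
    """
    df = _read_tsv(path, ["sample_id", "dosage"])
    offset = _header_lines(path) + 2
    for idx, value in df["dosage"].items():
        try:
            dosage = int(value)
            if dosage not in (0, 1, 2):
                raise ValueError
        except (ValueError, TypeError):
            raise ParseError(
                f"{path}: line {idx + offset}: dosage {value!r} is not in {{0, 1, 2}}"
            ) from None
    return pd.Series(
        df["dosage"].astype(int).to_numpy(), index=df["sample_id"].astype(str), name="dosage"
    )


def read_vcf_dosages(path, variant_id: str | None = None) -> pd.Series:
    """Extract dosages for one biallelic site from a plain-text VCF.

    ``variant_id`` selects by the ID column; by default the first biallelic
    SNV with GT genotypes is used.  Dosage counts ALT alleles.
    """
    samples: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ParseError(f"{path}: line {lineno}: VCF record has no sample columns")
            vid, ref, alt = fields[2], fields[3], fields[4]
            if variant_id is not None and vid != variant_id:
                continue
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                if variant_id is not None:
                    raise ParseError(f"{path}: line {lineno}: site {vid!r} is not a biallelic SNV")
                continue
            fmt = fields[8].split(":")
            if "GT" not in fmt:
                raise ParseError(f"{path}: line {lineno}: no GT field")
            gt_idx = fmt.index("GT")
            dosages = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = [a for a in gt.split("/") if a != "."]
                dosages.append(sum(int(a) for a in alleles))
            return pd.Series(dosages, index=samples, name="dosage", dtype=int)
    target = variant_id if variant_id is not None else "a biallelic SNV"
    raise ParseError(f"{path}: {target} not found")


def read_cutsites(path) -> pd.DataFrame:
    """Read cut sites from a 4-column BED-like TSV (chrom, start, end, sample_id)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "sample_id"],
    )
    if (df["end"] != df["start"] + 1).any():
        bad = df.index[df["end"] != df["start"] + 1][0]
        raise ParseError(
            f"{path}: line {bad + 1 + _header_lines(path)}: cut-site intervals must be 1 bp"
        )
    return pd.DataFrame(
        {"chrom": df["chrom"], "pos": df["start"].astype(int), "sample_id": df["sample_id"]}
    )


def write_cutsites(cut_sites: pd.DataFrame, path, params: dict | None = None) -> None:
    """Write cut sites as 4-column BED-like TSV (chrom, start, end=start+1, sample_id)."""
    buf = _io.StringIO()
    if params:
        for key, value in params.items():
            buf.write(f"# {key}={value}\n")
    bed = pd.DataFrame(
        {
            "chrom": cut_sites["chrom"],
            "start": cut_sites["pos"].astype(int),
            "end": cut_sites["pos"].astype(int) + 1,
            "sample_id": cut_sites["sample_id"],
        }
    )
    bed.to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(buf.getvalue())


def read_counts(path) -> pd.DataFrame:
    """Read an MPRA count table (barcode, oligo_id, replicate, dna_count, rna_count)."""
    df = _read_tsv(path, ["barcode", "replicate", "dna_count", "rna_count"])
    for col in ("dna_count", "rna_count"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0) | (values % 1 != 0)
        if bad.any():
            idx = df.index[bad][0]
            raise ParseError(
                f"{path}: line {idx + _header_lines(path) + 2}: "
                f"{col} {df.loc[idx, col]!r} is not a non-negative integer"
            )
    return df


def write_intensity(matrix: IntensityMatrix, path, params: dict | None = None) -> None:
    header = dict(params or {})
    header.setdefault(
        "region",
        f"{matrix.grid.region.chrom}:{matrix.grid.region.start}-{matrix.grid.region.end}",
    )
    header.setdefault("window_length", matrix.grid.window_length)
    header.setdefault("step", matrix.grid.step)
    write_table(matrix.to_frame(), path, header)


def read_intensity(path, chrom: str = "chr1") -> IntensityMatrix:
    """Read an intensity TSV back into an :class:`IntensityMatrix`.

    The region/window geometry is reconstructed from the header comments when
    present, else inferred from the window coordinates.
    """
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
    df = read_table(path)
    starts = df["window_start"].to_numpy()
    ends = df["window_end"].to_numpy()
    window_length = int(meta.get("window_length", ends[0] - starts[0]))
    step = int(meta.get("step", starts[1] - starts[0] if len(starts) > 1 else window_length))
    if "region" in meta:
        region = Region.parse(meta["region"])
    else:
        region = Region(chrom, int(starts[0]), int(ends[-1]))
    samples = [c for c in df.columns if c not in ("window_start", "window_end")]
    values = df[samples].to_numpy(dtype=float)
    return IntensityMatrix(
        values=values,
        grid=WindowGrid(region, window_length, step),
        samples=samples,
        region_counts=np.full(len(samples), np.nan),
    )


def write_segmentation_bed(segmentation, grid: WindowGrid, path, params: dict | None = None) -> None:
    """Write a segmentation as BED: chrom, start, end, label, cost per segment."""
    starts, ends = grid.starts, grid.ends
    rows = [
        {
            "chrom": grid.region.chrom,
            "start": int(starts[seg.i0]),
            "end": int(ends[seg.i1]),
            "label": seg.label,
            "cost": seg.cost,
        }
        for seg in segmentation.segments
    ]
    buf = _io.StringIO()
    header = dict(params or {})
    header.setdefault("lambda1", segmentation.lambda1)
    header.setdefault("lambda2", segmentation.lambda2)
    for key, value in header.items():
        buf.write(f"# {key}={value}\n")
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(buf.getvalue())
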