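"""Seeded synthetic data for the allele-dependent accessibility and MPRA stages.

The generators emulate the structure the downstream analyses assume, not any
particular sequencing run:

* genotypes at a lead variant are Hardy-Weinberg draws at a given minor-allele
  frequency, coded as minor-allele dosage 0/1/2;
* ATAC-seq Tn5 cut sites over an LD region follow a homogeneous Poisson
  background, with a planted interval whose rate is multiplied by
  ``1 + effect_per_allele * dosage`` — an allele-dependent accessibility peak;
* MPRA DNA barcode counts are negative-binomial (mean/dispersion
  parameterisation, variance ``mu + mu^2/dispersion``); RNA counts are Poisson
  with mean proportional to the barcode's DNA count times ``2**effect`` for
  alternative-allele constructs.

All randomness flows from a single ``numpy`` generator per call, so a fixed
seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import OFFSETS

__all__ = [
    "AtacSimConfig",
    "MpraSimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_atac",
    "simulate_mpra",
    "cutsites_to_read_stubs",
]


@dataclass(frozen=True)
class AtacSimConfig:
    """Study conditions for one simulated LD region.

    ``background_rate`` is the expected number of Tn5 cut sites per bp per
    sample outside any planted interval.  Inside ``[planted_start,
    planted_end)`` the rate is multiplied by ``1 + effect_per_allele *
    dosage_j`` for sample ``j``.
    """

    n_samples: int = 161
    region_length: int = 5000
    maf: float = 0.2
    background_rate: float = 0.05
    planted_start: int | None = None
    planted_end: int | None = None
    effect_per_allele: float = 0.0
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.region_length < 1:
            raise ValueError("region_length must be positive")
        if not 0 < self.maf <= 0.5:
            raise ValueError("maf must lie in (0, 0.5]")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.effect_per_allele < 0:
            raise ValueError("effect_per_allele must be non-negative")
        has_start, has_end = self.planted_start is not None, self.planted_end is not None
        if has_start != has_end:
            raise ValueError("planted_start and planted_end must be given together")
        if has_start:
            if not 0 <= self.planted_start < self.planted_end <= self.region_length:
                raise ValueError(
                    "planted interval must satisfy 0 <= start < end <= region_length"
                )


@dataclass(frozen=True)
class MpraSimConfig:
    """Study conditions for one simulated MPRA screen."""

    n_variants: int = 10
    barcodes_per_oligo: int = 100
    mean_dna_count: float = 50.0
    dispersion: float = 10.0
    allelic_log2_effects: tuple[float, ...] | None = None
    baseline_log2_activity: float = 0.0
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be positive")
        if self.barcodes_per_oligo < 1:
            raise ValueError("barcodes_per_oligo must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mean_dna_count <= 0 or self.dispersion <= 0:
            raise ValueError("mean_dna_count and dispersion must be positive")
        if self.allelic_log2_effects is not None:
            effects = tuple(float(e) for e in self.allelic_log2_effects)
            if len(effects) != self.n_variants:
                raise ValueError("allelic_log2_effects must have one entry per variant")
            object.__setattr__(self, "allelic_log2_effects", effects)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulation run (for recovery checks)."""

    genotypes: np.ndarray | None = None
    planted_start: int | None = None
    planted_end: int | None = None
    allelic_log2_effects: dict[str, float] = field(default_factory=dict)


def simulate_genotypes(n_samples: int, maf: float, seed=None) -> np.ndarray:
    """Draw Hardy-Weinberg minor-allele dosages ``Binomial(2, maf)``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be positive")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=n_samples).astype(np.int64)


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"S{i:0{width}d}" for i in range(n)]


def simulate_atac(
    config: AtacSimConfig, genotypes: np.ndarray | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-sample Tn5 cut sites over an LD region.

    Returns a BED-like frame with columns ``chrom, pos, sample_id`` (one row
    per cut site, positions 0-based within the region) and the ground truth.
    Cut-site counts in any interval are Poisson with rate ``background_rate *
    length``, multiplied inside the planted interval by ``1 +
    effect_per_allele * dosage``.
    """
    rng = np.random.default_rng(config.seed)
    if genotypes is None:
        genotypes = simulate_genotypes(config.n_samples, config.maf, rng)
    else:
        genotypes = np.asarray(genotypes, dtype=np.int64)
        if genotypes.shape != (config.n_samples,):
            raise ValueError("genotypes must have one dosage per sample")

    ids = _sample_ids(config.n_samples)
    length = config.region_length
    rows_pos: list[np.ndarray] = []
    rows_sample: list[np.ndarray] = []
    for j, sample in enumerate(ids):
        n_bg = rng.poisson(config.background_rate * length)
        pos = rng.uniform(0, length, size=n_bg)
        if config.planted_start is not None and config.effect_per_allele > 0:
            extra_rate = config.background_rate * config.effect_per_allele * genotypes[j]
            span = config.planted_end - config.planted_start
            n_extra = rng.poisson(extra_rate * span)
            extra = rng.uniform(config.planted_start, config.planted_end, size=n_extra)
            pos = np.concatenate([pos, extra])
        pos = np.sort(pos.astype(np.int64))
        rows_pos.append(pos)
        rows_sample.append(np.repeat(sample, pos.size))

    cut_sites = pd.DataFrame(
        {
            "chrom": config.chrom,
            "pos": np.concatenate(rows_pos) if rows_pos else np.array([], dtype=np.int64),
            "sample_id": np.concatenate(rows_sample) if rows_sample else np.array([], dtype=object),
        }
    )
    truth = SimTruth(
        genotypes=genotypes,
        planted_start=config.planted_start,
        planted_end=config.planted_end,
    )
    return cut_sites, truth


def _random_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> np.ndarray:
    """Unique random barcodes (re-drawing the rare collision)."""
    bases = np.array(list("ACGT"))
    while True:
        codes = rng.integers(0, 4, size=(n, length))
        barcodes = np.array(["".join(row) for row in bases[codes]])
        if len(np.unique(barcodes)) == n:
            return barcodes


def simulate_mpra(config: MpraSimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate an MPRA screen with planted allelic effects.

    Returns ``(barcode_map, counts, truth)``:

    * ``barcode_map`` — one row per barcode: ``barcode, oligo_id, variant_id,
      allele, strand, offset`` (every barcode maps to one oligo; each of the
      12 contexts per variant receives ``barcodes_per_oligo`` barcodes);
    * ``counts`` — one row per barcode and replicate: ``barcode, oligo_id,
      replicate, dna_count, rna_count``.
    """
    rng = np.random.default_rng(config.seed)
    effects = config.allelic_log2_effects
    if effects is None:
        effects = tuple(0.0 for _ in range(config.n_variants))

    width = max(3, len(str(config.n_variants - 1)))
    variant_ids = [f"var{i:0{width}d}" for i in range(config.n_variants)]

    var_col, allele_col, strand_col, offset_col, oligo_col = [], [], [], [], []
    effect_col = []
    for vid, eff in zip(variant_ids, effects):
        for allele in ("ref", "alt"):
            for strand in ("+", "-"):
                for offset in OFFSETS:
                    sign = "+" if offset >= 0 else "-"
                    oligo = f"{vid}:{allele}:{strand}:{sign}{abs(offset)}"
                    for _ in range(config.barcodes_per_oligo):
                        var_col.append(vid)
                        allele_col.append(allele)
                        strand_col.append(strand)
                        offset_col.append(offset)
                        oligo_col.append(oligo)
                        effect_col.append(eff if allele == "alt" else 0.0)

    n_barcodes = len(oligo_col)
    barcode_map = pd.DataFrame(
        {
            "barcode": _random_barcodes(rng, n_barcodes),
            "oligo_id": oligo_col,
            "variant_id": var_col,
            "allele": allele_col,
            "strand": strand_col,
            "offset": offset_col,
        }
    )

    log2_mu = config.baseline_log2_activity + np.asarray(effect_col)
    frames = []
    for rep in range(1, config.n_replicates + 1):
        # NB via gamma-Poisson mixture: rate ~ Gamma(k, mu/k), counts ~ Poisson(rate)
        lam = rng.gamma(config.dispersion, config.mean_dna_count / config.dispersion, n_barcodes)
        dna = rng.poisson(lam)
        rna = rng.poisson(dna * np.exp2(log2_mu))
        frames.append(
            pd.DataFrame(
                {
                    "barcode": barcode_map["barcode"],
                    "oligo_id": barcode_map["oligo_id"],
                    "replicate": rep,
                    "dna_count": dna,
                    "rna_count": rna,
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    truth = SimTruth(allelic_log2_effects=dict(zip(variant_ids, effects)))
    return barcode_map, counts, truth


def cutsites_to_read_stubs(
    cut_sites: pd.DataFrame, read_length: int = 50, seed=None
) -> pd.DataFrame:
    """Un-shift cut sites into aligned-read stubs (chrom, start, end, strand).

    Inverse of the Tn5 +4/-5 adjustment: a plus-strand read starting at
    ``site - 4`` or a minus-strand read ending at ``site + 5`` yields the
    original site after shifting.  Strands are assigned at random.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pos = cut_sites["pos"].to_numpy()
    minus = rng.random(len(pos)) < 0.5
    start = np.where(minus, pos + 5 - read_length, pos - 4)
    end = start + read_length
    out = pd.DataFrame(
        {
            "chrom": cut_sites["chrom"].to_numpy(),
            "start": start,
            "end": end,
            "strand": np.where(minus, "-", "+"),
        }
    )
    if "sample_id" in cut_sites.columns:
        out["sample_id"] = cut_sites["sample_id"].to_numpy()
    return out
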