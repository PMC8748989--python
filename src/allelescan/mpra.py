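"""MPRA quantification: barcode-map filtering, activities, allelic scores.

The pipeline mirrors how barcoded reporter screens are scored in practice:

1. barcode-to-oligo alignments are filtered (at most 4 mismatches within the
   designed oligo; no mismatch within 10 bp of the variant);
2. the barcode map keeps combinations supported by at least 2 reads; a
   barcode hitting several oligos is rescued only when at least 50 reads
   support it and one combination holds at least 95% of them;
3. DNA and RNA barcode counts are library-normalised to counts per 10
   million reads, and each barcode's activity is
   ``b_i = log2((1 + #RNA_i) / (1 + #DNA_i))``;
4. a variant's log2 score is the weighted mean activity of its alternative-
   allele barcodes minus that of its reference-allele barcodes, pooled over
   the six genomic contexts and all replicates; strand-restricted scores use
   only the constructs of one strand.  Significance comes from a two-sided
   permutation test on allele labels, with Benjamini-Hochberg q-values
   across the screen.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MAX_MISMATCHES",
    "MIN_VARIANT_DISTANCE",
    "MIN_COMBO_READS",
    "MIN_MULTI_READS",
    "MIN_MULTI_FRACTION",
    "EmptyLibraryError",
    "filter_alignments",
    "call_barcode_map",
    "normalize_counts",
    "barcode_activity",
    "score_variant",
    "test_variants",
    "MPRAScorer",
]

MAX_MISMATCHES = 4
MIN_VARIANT_DISTANCE = 10  # bp; mismatches at <= this distance disqualify
MIN_COMBO_READS = 2
MIN_MULTI_READS = 50
MIN_MULTI_FRACTION = 0.95
NORM_FACTOR = 1e7  # counts per 10 million reads


class EmptyLibraryError(ValueError):
    """A replicate library has zero total reads."""


def filter_alignments(records: pd.DataFrame) -> pd.DataFrame:
    """Drop alignments with >4 oligo mismatches or a mismatch within 10 bp
    of the variant.

    ``records`` needs columns ``n_mismatches`` and
    ``min_mismatch_distance`` (NaN or inf when there is no mismatch).
    """
    dist = records["min_mismatch_distance"].astype(float).fillna(np.inf)
    keep = (records["n_mismatches"] <= MAX_MISMATCHES) & (dist > MIN_VARIANT_DISTANCE)
    return records.loc[keep].reset_index(drop=True)


def call_barcode_map(records: pd.DataFrame) -> pd.DataFrame:
    """Resolve filtered alignments into a unique barcode -> oligo map.

    Combinations with fewer than 2 supporting reads are dropped.  A barcode
    left with a single oligo is kept.  A multi-mapped barcode is kept only if
    its total read support is at least 50 and a single combination holds at
    least 95% of those reads, in which case it is assigned to that
    combination; otherwise it is discarded.

    Returns columns ``barcode, oligo_id, reads``.
    """
    combos = (
        records.groupby(["barcode", "oligo_id"], as_index=False)["read_count"]
        .sum()
        .rename(columns={"read_count": "reads"})
    )
    combos = combos[combos["reads"] >= MIN_COMBO_READS]
    kept = []
    for barcode, grp in combos.groupby("barcode"):
        if len(grp) == 1:
            kept.append(grp)
            continue
        total = grp["reads"].sum()
        best = grp.loc[[grp["reads"].idxmax()]]
        if total >= MIN_MULTI_READS and best["reads"].iloc[0] / total >= MIN_MULTI_FRACTION:
            kept.append(best)
    if not kept:
        return pd.DataFrame(columns=["barcode", "oligo_id", "reads"])
    return pd.concat(kept, ignore_index=True)[["barcode", "oligo_id", "reads"]]


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Library-normalise DNA and RNA counts to counts per 10 million reads.

    Totals are computed per replicate, separately for DNA and RNA.  Adds
    ``dna_norm`` and ``rna_norm`` columns.
    """
    out = counts.copy()
    for col, norm in (("dna_count", "dna_norm"), ("rna_count", "rna_norm")):
        totals = out.groupby("replicate")[col].transform("sum")
        if (totals == 0).any():
            rep = out.loc[totals == 0, "replicate"].iloc[0]
            raise EmptyLibraryError(f"replicate {rep!r} has zero total {col}")
        out[norm] = out[col] * NORM_FACTOR / totals
    return out


def barcode_activity(rna_norm, dna_norm) -> np.ndarray:
    """Per-barcode activity ``b_i = log2((1 + RNA_norm) / (1 + DNA_norm))``."""
    rna = np.asarray(rna_norm, dtype=float)
    dna = np.asarray(dna_norm, dtype=float)
    if (rna < 0).any() or (dna < 0).any():
        raise ValueError("normalized counts must be non-negative")
    return np.log2((1.0 + rna) / (1.0 + dna))


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def _allele_score(b: np.ndarray, is_alt: np.ndarray, w: np.ndarray) -> float:
    return _weighted_mean(b[is_alt], w[is_alt]) - _weighted_mean(b[~is_alt], w[~is_alt])


def score_variant(activities: pd.DataFrame, weighting: str = "uniform") -> dict:
    """Score one variant from its per-barcode activities.

    ``activities`` needs columns ``allele`` ("ref"/"alt"), ``b`` and, for
    DNA-abundance weighting, ``dna_norm``; a ``strand`` column enables the
    strand-restricted scores.  The log2 score is the weighted mean activity
    of alt barcodes minus that of ref barcodes, pooled over contexts and
    replicates.  Returns a dict with ``log2_score``, strand scores (NaN when
    a strand lacks barcodes of either allele), barcode counts and a
    ``scoreable`` flag (False when an allele has no barcodes).
    """
    b = activities["b"].to_numpy(dtype=float)
    is_alt = activities["allele"].to_numpy() == "alt"
    if weighting == "uniform":
        w = np.ones(len(b))
    elif weighting == "dna":
        w = activities["dna_norm"].to_numpy(dtype=float) + 1.0
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    n_ref, n_alt = int((~is_alt).sum()), int(is_alt.sum())
    result = {
        "n_barcodes_ref": n_ref,
        "n_barcodes_alt": n_alt,
        "scoreable": n_ref > 0 and n_alt > 0,
        "log2_score": np.nan,
        "log2_pos_strand": np.nan,
        "log2_neg_strand": np.nan,
    }
    if not result["scoreable"]:
        return result
    result["log2_score"] = _allele_score(b, is_alt, w)
    if "strand" in activities.columns:
        strand = activities["strand"].to_numpy()
        for sym, key in (("+", "log2_pos_strand"), ("-", "log2_neg_strand")):
            sel = strand == sym
            if is_alt[sel].any() and (~is_alt[sel]).any():
                result[key] = _allele_score(b[sel], is_alt[sel], w[sel])
    return result


def _permutation_p(
    b: np.ndarray,
    is_alt: np.ndarray,
    w: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
    max_exhaustive: int = 20000,
    method: str = "auto",
) -> float:
    """Two-sided p for the allele-label permutation test.

    Exhaustive over all label assignments when feasible (p = fraction of
    assignments at least as extreme, the identity included); otherwise
    ``p = (1 + #{|perm| >= |obs|}) / (1 + n_permutations)`` from random
    draws.
    """
    n = len(b)
    n_alt = int(is_alt.sum())
    obs = abs(_allele_score(b, is_alt, w))
    if np.ptp(b) == 0:
        return 1.0
    n_total = comb(n, n_alt)
    if method == "exhaustive" or (method == "auto" and n_total <= max_exhaustive):
        hits = 0
        idx = np.arange(n)
        for alt_idx in combinations(idx, n_alt):
            mask = np.zeros(n, dtype=bool)
            mask[list(alt_idx)] = True
            if abs(_allele_score(b, mask, w)) >= obs - 1e-12:
                hits += 1
        return hits / n_total
    # vectorised random permutations: draw row-wise permutations of indices
    hits = 0
    chunk = max(1, min(n_permutations, int(2e7 / max(n, 1))))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        order = np.argsort(rng.random((k, n)), axis=1)
        alt_idx = order[:, :n_alt]
        ref_idx = order[:, n_alt:]
        wa = w[alt_idx]
        wr = w[ref_idx]
        perm = (b[alt_idx] * wa).sum(1) / wa.sum(1) - (b[ref_idx] * wr).sum(1) / wr.sum(1)
        hits += int((np.abs(perm) >= obs - 1e-12).sum())
        done += k
    return (1 + hits) / (1 + n_permutations)


def test_variants(
    activities: pd.DataFrame,
    n_permutations: int = 10000,
    seed=None,
    weighting: str = "uniform",
    method: str = "auto",
) -> pd.DataFrame:
    """Score and test every variant in a screen.

    ``activities`` needs columns ``variant_id, allele, b`` (plus ``strand``
    and ``dna_norm`` for strand scores and DNA weighting).  Returns one row
    per variant with the pooled and strand-restricted log2 scores, the
    permutation ``p_value`` and the Benjamini-Hochberg ``q_value`` computed
    across all scoreable variants of the screen.  Rows are sorted by variant
    id, so the result is independent of input row order.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for vid in sorted(activities["variant_id"].unique()):
        sub = activities[activities["variant_id"] == vid]
        sub = sub.sort_values(["allele", "b"], kind="mergesort")  # canonical order
        row = {"variant_id": vid, **score_variant(sub, weighting)}
        if row["scoreable"]:
            b = sub["b"].to_numpy(dtype=float)
            is_alt = sub["allele"].to_numpy() == "alt"
            w = (
                sub["dna_norm"].to_numpy(dtype=float) + 1.0
                if weighting == "dna"
                else np.ones(len(b))
            )
            row["p_value"] = _permutation_p(b, is_alt, w, n_permutations, rng, method=method)
        else:
            row["p_value"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out["q_value"] = np.nan
    valid = out["p_value"].notna()
    if valid.any():
        out.loc[valid, "q_value"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return out


class MPRAScorer(BaseEstimator):
    """Allelic activity scoring for an MPRA screen.

    Parameters mirror :func:`test_variants`.  ``fit(counts, barcode_map)``
    takes the raw count table (``barcode, replicate, dna_count, rna_count``)
    and the barcode map annotated with ``variant_id, allele`` (and optionally
    ``strand``); it normalises counts, computes per-barcode activities and
    produces ``variant_scores_`` (one row per variant) and ``activities_``
    (one row per barcode and replicate).
    """

    def __init__(
        self,
        n_permutations: int = 10000,
        weighting: str = "uniform",
        fdr: float = 0.05,
        random_state=None,
    ):
        self.n_permutations = n_permutations
        self.weighting = weighting
        self.fdr = fdr
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, barcode_map: pd.DataFrame):
        norm = normalize_counts(counts)
        ann_cols = ["barcode", "variant_id", "allele"] + (
            ["strand"] if "strand" in barcode_map.columns else []
        )
        merged = norm.merge(barcode_map[ann_cols], on="barcode", how="inner")
        merged["b"] = barcode_activity(merged["rna_norm"], merged["dna_norm"])
        self.activities_ = merged
        self.variant_scores_ = test_variants(
            merged,
            n_permutations=self.n_permutations,
            seed=self.random_state,
            weighting=self.weighting,
        )
        self.variant_scores_["significant"] = self.variant_scores_["q_value"] < self.fdr
        return self
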