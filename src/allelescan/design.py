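"""MPRA oligonucleotide design.

For every biallelic SNV the assay tests twelve 120-nt constructs: the two
alleles placed in six genomic contexts (positive and negative strand crossed
with three sliding windows that put the variant at -20, 0 or +20 bp from the
oligo center).  Each core sequence is flanked by fixed 15-nt amplification
adapters before synthesis.

Coordinate conventions used here:

* the 120-nt core is 0-based; its "center" is index 60, so offset ``o``
  places the variant base at in-core index ``60 + o`` on the plus strand;
* minus-strand designs are the reverse complement of the corresponding
  plus-strand core, which puts the variant at index ``119 - (60 + o)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "ADAPTER_5P",
    "ADAPTER_3P",
    "CORE_LENGTH",
    "CENTER_INDEX",
    "OFFSETS",
    "Variant",
    "OligoDesign",
    "ReferenceMismatchError",
    "design_oligos",
    "design_all",
    "write_design",
]

ADAPTER_5P = "ACTGGCCGCTTGACG"
ADAPTER_3P = "CACTGCGGCTCCTGC"
CORE_LENGTH = 120
CENTER_INDEX = 60
OFFSETS = (-20, 0, 20)

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ReferenceMismatchError(ValueError):
    """The supplied reference context disagrees with the variant's ref allele."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Variant:
    """A biallelic single-nucleotide variant.

    ``pos`` is the 1-based genomic coordinate of the variant base.
    """

    id: str
    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        ref, alt = self.ref.upper(), self.alt.upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
            raise ValueError(
                f"variant {self.id!r}: only single-nucleotide A/C/G/T alleles are "
                f"supported (got ref={self.ref!r}, alt={self.alt!r})"
            )
        if ref == alt:
            raise ValueError(f"variant {self.id!r}: ref and alt alleles are identical")
        object.__setattr__(self, "ref", ref)
        object.__setattr__(self, "alt", alt)


@dataclass(frozen=True)
class OligoDesign:
    """One of the twelve designed sequences for a variant."""

    variant_id: str
    allele: str  # "ref" | "alt"
    strand: str  # "+" | "-"
    offset: int  # variant position relative to core center, + strand
    core: str  # 120-nt core sequence

    @property
    def full(self) -> str:
        """Core flanked by the fixed synthesis adapters."""
        return ADAPTER_5P + self.core + ADAPTER_3P

    @property
    def oligo_id(self) -> str:
        sign = "+" if self.offset >= 0 else "-"
        return f"{self.variant_id}:{self.allele}:{self.strand}:{sign}{abs(self.offset)}"


def design_oligos(
    variant: Variant,
    reference_context: str,
    variant_index: int | None = None,
) -> list[OligoDesign]:
    """Design the 12 oligos (2 alleles x 2 strands x 3 offsets) for one SNV.

    Parameters
    ----------
    variant
        The SNV to design for.
    reference_context
        Reference sequence surrounding the variant.  Must extend at least
        80 nt on both sides of the variant base (161 nt if centered), so
        that all three window placements fit.
    variant_index
        0-based index of the variant base within ``reference_context``.
        Defaults to the middle of the context (``len(context) // 2``).

    Raises
    ------
    ReferenceMismatchError
        If the context base at the variant position is not the ref allele.
    ValueError
        For indel alleles or contexts too short to hold all windows.
    """
    context = reference_context.upper()
    idx = len(context) // 2 if variant_index is None else variant_index
    if not 0 <= idx < len(context):
        raise ValueError(f"variant_index {idx} outside context of length {len(context)}")
    if context[idx] != variant.ref:
        raise ReferenceMismatchError(
            f"variant {variant.id!r}: context base {context[idx]!r} at index {idx} "
            f"does not match ref allele {variant.ref!r}"
        )
    # window for offset o spans [idx - (CENTER + o), idx - (CENTER + o) + 120)
    starts = {o: idx - (CENTER_INDEX + o) for o in OFFSETS}
    if min(starts.values()) < 0 or max(starts.values()) + CORE_LENGTH > len(context):
        raise ValueError(
            f"variant {variant.id!r}: reference context too short to place all "
            f"windows (need 80 nt on both sides of the variant)"
        )

    designs: list[OligoDesign] = []
    for allele_label, base in (("ref", variant.ref), ("alt", variant.alt)):
        seq = context[:idx] + base + context[idx + 1 :]
        for offset in OFFSETS:
            start = starts[offset]
            core_plus = seq[start : start + CORE_LENGTH]
            designs.append(OligoDesign(variant.id, allele_label, "+", offset, core_plus))
            designs.append(
                OligoDesign(variant.id, allele_label, "-", offset, reverse_complement(core_plus))
            )
    return designs


def design_all(
    variants: Iterable[Variant],
    contexts: dict[str, str] | Sequence[str],
) -> list[OligoDesign]:
    """Design oligos for many variants.

    ``contexts`` maps variant id to reference context (or is a parallel
    sequence).  Output order follows input order; the result is independent
    of it as a set.
    """
    variants = list(variants)
    if not isinstance(contexts, dict):
        contexts = {v.id: c for v, c in zip(variants, contexts, strict=True)}
    designs: list[OligoDesign] = []
    for variant in variants:
        designs.extend(design_oligos(variant, contexts[variant.id]))
    return designs


def write_design(designs: Sequence[OligoDesign], fasta_path, manifest_path=None) -> None:
    """Write designs as FASTA (full sequences) plus an optional TSV manifest.

    FASTA ids encode (variant, allele, strand, offset).  Duplicate ids are an
    integrity error.
    """
    designs = list(designs)
    if not designs:
        raise ValueError("empty design list")
    ids = [d.oligo_id for d in designs]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate design id {dup!r}")

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(d.full), id=d.oligo_id, description="") for d in designs]
    seqio_write(records, str(fasta_path), "fasta")

    if manifest_path is not None:
        import pandas as pd

        pd.DataFrame(
            {
                "oligo_id": ids,
                "variant_id": [d.variant_id for d in designs],
                "allele": [d.allele for d in designs],
                "strand": [d.strand for d in designs],
                "offset": [d.offset for d in designs],
                "core": [d.core for d in designs],
                "full": [d.full for d in designs],
            }
        ).to_csv(manifest_path, sep="\t", index=False)
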