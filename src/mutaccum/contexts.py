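"""Mutation-context classification and spectrum assembly.

Each somatic variant is mapped to one category of its class catalog:

* SBS -> 96 trinucleotide categories, reported on the pyrimidine strand
  (a G>A at 5'-CGT-3' is counted as its reverse complement A[C>T]G);
* DBS -> 78 canonical doublet categories;
* indel -> 83 categories by size, homopolymer/tandem-repeat context and
  flanking microhomology (deletions only);
* SV -> 16 categories by type and length bin (translocations unbinned).

Per-clone category counts are assembled into spectrum matrices
(catalog x clones) that feed the signature-refitting and per-context
statistics layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import (
    CATALOGS,
    COMPLEMENT,
    DBS78_SET,
    PYRIMIDINES,
    revcomp,
    sv_length_bin,
)
from .io import MutationRecord, ReferenceGenome, fetch_flanks

logger = logging.getLogger(__name__)

# repeat/homology scanning window; catalog caps at 5+/6+ units, so longer
# scans cannot change any label
_SCAN_WINDOW = 100


@dataclass
class ContextSpectrum:
    """Counts over a fixed context catalog for one clone and variant class."""

    clone_id: str
    var_class: str
    catalog: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.catalog):
            raise ValueError("counts length must match catalog length")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(self.catalog), name=self.clone_id)


class ClassificationError(ValueError):
    """Raised when a record contradicts the reference or the catalog."""


# ---------------------------------------------------------------------------
# SBS
# ---------------------------------------------------------------------------


def classify_sbs(rec: MutationRecord, flanks: str) -> str | None:
    """Classify a single-base substitution given its 3-mer reference context.

    ``flanks`` is the reference trinucleotide centred on the variant.
    Purine-reference variants are reverse complemented so the reported
    reference base is C or T. Returns None (caller logs/skips) when the
    context contains N.
    """
    if rec.var_class != "SBS":
        raise ClassificationError(f"not an SBS record: {rec}")
    flanks = flanks.upper()
    if len(flanks) != 3:
        raise ClassificationError(f"SBS context must be a 3-mer, got {flanks!r}")
    if "N" in flanks:
        return None
    if flanks[1] != rec.ref.upper():
        raise ClassificationError(
            f"reference mismatch at {rec.chrom}:{rec.pos}: "
            f"VCF ref {rec.ref} vs genome {flanks[1]}"
        )
    ref, alt = rec.ref.upper(), rec.alt.upper()
    if ref not in PYRIMIDINES:
        flanks = revcomp(flanks)
        ref = COMPLEMENT[ref]
        alt = COMPLEMENT[alt]
    return f"{flanks[0]}[{ref}>{alt}]{flanks[2]}"


# ---------------------------------------------------------------------------
# DBS
# ---------------------------------------------------------------------------


def classify_dbs(rec: MutationRecord) -> str:
    """Map a doublet substitution onto the 78-category canonical catalog.

    The catalog fixes one strand for every ref/alt doublet pair; doublets
    not listed are reverse complemented (both ref and alt) onto their
    canonical representative.
    """
    if rec.var_class != "DBS":
        raise ClassificationError(f"not a DBS record: {rec}")
    ref, alt = rec.ref.upper(), rec.alt.upper()
    if ref == alt:
        raise ClassificationError(f"DBS with identical ref and alt at {rec.chrom}:{rec.pos}")
    label = f"{ref}>{alt}"
    if label in DBS78_SET:
        return label
    rc = f"{revcomp(ref)}>{revcomp(alt)}"
    if rc in DBS78_SET:
        return rc
    raise ClassificationError(
        f"doublet {label} (and reverse complement {rc}) not in the 78-category "
        "catalog; doublets must change both bases"
    )


# ---------------------------------------------------------------------------
# Indels (ID83)
# ---------------------------------------------------------------------------


def _count_copies_before(genome: ReferenceGenome, chrom: str, motif: str,
                         first: int) -> int:
    """Tandem copies of ``motif`` ending just before 1-based position ``first``."""
    size = len(motif)
    n = 0
    start = first - size
    while n * size < _SCAN_WINDOW and start >= 1:
        if genome.fetch(chrom, start, start + size - 1) != motif:
            break
        n += 1
        start -= size
    return n


def _count_copies_from(genome: ReferenceGenome, chrom: str, motif: str,
                       first: int) -> int:
    """Tandem copies of ``motif`` starting at 1-based position ``first``."""
    size = len(motif)
    length = genome.chrom_length(chrom)
    n = 0
    start = first
    while n * size < _SCAN_WINDOW and start + size - 1 <= length:
        if genome.fetch(chrom, start, start + size - 1) != motif:
            break
        n += 1
        start += size
    return n


def _microhomology(genome: ReferenceGenome, chrom: str, deleted: str,
                   first: int) -> int:
    """Longest homology between the deleted sequence and its flanks.

    Scans the prefix of the deleted sequence against the reference bases
    immediately following the deletion, and its suffix against the bases
    immediately preceding it; returns the longer match, capped at
    len(deleted) - 1 (a full-length match would be a tandem repeat).
    """
    size = len(deleted)
    length = genome.chrom_length(chrom)
    cap = size - 1
    fwd = 0
    for i in range(cap):
        p = first + size + i
        if p > length or genome.fetch(chrom, p, p) != deleted[i]:
            break
        fwd += 1
    rev = 0
    for i in range(cap):
        p = first - 1 - i
        if p < 1 or genome.fetch(chrom, p, p) != deleted[size - 1 - i]:
            break
        rev += 1
    return min(max(fwd, rev), cap)


def _size_label(size: int, cap: int = 5) -> str:
    return f"{cap}+" if size >= cap else str(size)


def _pyrimidine_base(base: str) -> str:
    return base if base in PYRIMIDINES else COMPLEMENT[base]


def classify_indel(rec: MutationRecord, genome: ReferenceGenome) -> str | None:
    """Classify a left-aligned indel into the 83-category scheme.

    Deletions count the tandem copies of the deleted motif present in the
    reference (including the deleted copy): a copy number of one with
    flanking microhomology becomes an M category, otherwise an R (repeat)
    category. Insertions count the pre-existing copies of the inserted
    motif. 1-bp events are reported by pyrimidine-normalized base instead
    of R. Complex substitutions (ref and alt both multi-base, not
    anchor-prefixed) return None and are excluded by the caller.
    """
    if rec.var_class != "INDEL":
        raise ClassificationError(f"not an indel record: {rec}")
    ref, alt = rec.ref.upper(), rec.alt.upper()
    if len(ref) > len(alt) and ref.startswith(alt):
        deleted = ref[len(alt):]
        first = rec.pos + len(alt)  # 1-based first deleted base
        return _classify_deletion(genome, rec.chrom, deleted, first)
    if len(alt) > len(ref) and alt.startswith(ref):
        inserted = alt[len(ref):]
        after = rec.pos + len(ref) - 1  # inserted right after this base
        return _classify_insertion(genome, rec.chrom, inserted, after)
    logger.warning("complex indel excluded at %s:%d %s>%s", rec.chrom, rec.pos, ref, alt)
    return None


def _classify_deletion(genome: ReferenceGenome, chrom: str, deleted: str,
                       first: int) -> str | None:
    if "N" in deleted:
        return None
    size = len(deleted)
    copies = (
        1
        + _count_copies_before(genome, chrom, deleted, first)
        + _count_copies_from(genome, chrom, deleted, first + size)
    )
    if size == 1:
        base = _pyrimidine_base(deleted)
        n = "6+" if copies >= 6 else str(copies)
        return f"1:Del:{base}:{n}"
    size_lab = _size_label(size)
    if copies >= 2:
        n = "6+" if copies >= 6 else str(copies)
        return f"{size_lab}:Del:R:{n}"
    hom = _microhomology(genome, chrom, deleted, first)
    if hom >= 1:
        n = "5+" if hom >= 5 else str(hom)
        return f"{size_lab}:Del:M:{n}"
    return f"{size_lab}:Del:R:1"


def _classify_insertion(genome: ReferenceGenome, chrom: str, inserted: str,
                        after: int) -> str | None:
    if "N" in inserted:
        return None
    size = len(inserted)
    copies = (
        _count_copies_before(genome, chrom, inserted, after + 1)
        + _count_copies_from(genome, chrom, inserted, after + 1)
    )
    n = "5+" if copies >= 5 else str(copies)
    if size == 1:
        base = _pyrimidine_base(inserted)
        return f"1:Ins:{base}:{n}"
    return f"{_size_label(size)}:Ins:R:{n}"


# ---------------------------------------------------------------------------
# SV
# ---------------------------------------------------------------------------


def classify_sv(rec: MutationRecord) -> str | None:
    """Classify a structural variant by type and length bin.

    Translocations form a single category (length is not applicable);
    DEL/DUP/INV are binned on length. Non-translocations with no usable
    length return None and are excluded by the caller. Sub-1 kb lengths
    fold into the 1-10 kb bin and are logged.
    """
    if rec.var_class != "SV":
        raise ClassificationError(f"not an SV record: {rec}")
    if rec.sv_type == "TRA":
        return "TRA"
    if rec.sv_len is None:
        logger.warning("SV without length excluded at %s:%d", rec.chrom, rec.pos)
        return None
    if rec.sv_len <= 1000:
        logger.info(
            "SV of %d bp at %s:%d folded into the 1kb-10kb bin",
            rec.sv_len, rec.chrom, rec.pos,
        )
    return f"{rec.sv_type}_{sv_length_bin(rec.sv_len)}"


# ---------------------------------------------------------------------------
# Spectrum assembly
# ---------------------------------------------------------------------------


def classify_record(rec: MutationRecord, genome: ReferenceGenome | None) -> str | None:
    """Dispatch a record to its class-specific classifier."""
    if rec.var_class == "SBS":
        if genome is None:
            raise ClassificationError("SBS classification needs a reference genome")
        flanks = fetch_flanks(genome, rec.chrom, rec.pos, 1)
        return classify_sbs(rec, flanks)
    if rec.var_class == "DBS":
        return classify_dbs(rec)
    if rec.var_class == "INDEL":
        if genome is None:
            raise ClassificationError("indel classification needs a reference genome")
        return classify_indel(rec, genome)
    return classify_sv(rec)


def build_spectrum_matrix(
    records_by_clone: Mapping[str, Iterable[MutationRecord]],
    genome: ReferenceGenome | None,
    var_class: str,
) -> tuple[list[ContextSpectrum], pd.DataFrame]:
    """Assemble per-clone context spectra for one variant class.

    Returns the list of ContextSpectrum objects and the catalog x clones
    count matrix (rows in canonical catalog order, one column per clone;
    clones with zero variants of the class keep an all-zero column).
    Unclassifiable records (N context, complex indels, length-less SVs)
    are excluded with a logged per-clone tally.
    """
    catalog = CATALOGS[var_class]
    index = {label: i for i, label in enumerate(catalog)}
    spectra: list[ContextSpectrum] = []
    for clone_id, records in records_by_clone.items():
        counts = np.zeros(len(catalog), dtype=int)
        excluded = 0
        for rec in records:
            if rec.var_class != var_class:
                continue
            label = classify_record(rec, genome)
            if label is None:
                excluded += 1
                continue
            counts[index[label]] += 1
        if excluded:
            logger.warning(
                "clone %s: %d %s record(s) excluded from the spectrum",
                clone_id, excluded, var_class,
            )
        spectra.append(ContextSpectrum(clone_id, var_class, catalog, counts))
    matrix = pd.DataFrame(
        {s.clone_id: s.counts for s in spectra}, index=list(catalog), dtype=int
    )
    return spectra, matrix


def write_spectrum_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="context")


def read_spectrum_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="context")
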