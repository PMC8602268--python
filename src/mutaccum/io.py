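"""File input/output and the package's domain types.

Reads the standard files the pipeline touches -- somatic VCFs (SNV/indel and
SV dialects), an indexed FASTA reference, signature definition and exposure
tables, clone metadata, and driver-gene interval lists -- into plain Python
/ pandas containers, with validation at the boundary.

Coordinates follow VCF convention: 1-based, inclusive. Indels are consumed
as left-aligned by the upstream caller and are not re-normalized here.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .catalogs import revcomp

logger = logging.getLogger(__name__)

VALID_VAR_CLASSES = ("SBS", "DBS", "INDEL", "SV")
VALID_SV_TYPES = ("DEL", "DUP", "INV", "TRA")

_BREAKEND_RE = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


class VcfFormatError(ValueError):
    """Raised when a VCF row cannot be interpreted."""


class FlankBoundaryError(ValueError):
    """Raised when a requested flank window falls off the contig."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationRecord:
    """One somatic variant.

    ``var_class`` is SBS for 1-bp substitutions, DBS for 2-bp doublet
    substitutions, INDEL for length-changing small variants, and SV for
    symbolic/breakend structural records. ``sv_len`` is absent (None) for
    translocations, which have no meaningful length.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    sv_type: str | None = None
    sv_len: int | None = None
    filter: str = "PASS"
    consequence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.var_class not in VALID_VAR_CLASSES:
            raise ValueError(f"unknown var_class {self.var_class!r}")
        if self.var_class == "SBS" and not (len(self.ref) == len(self.alt) == 1):
            raise ValueError("SBS requires 1-bp ref and alt")
        if self.var_class == "DBS" and not (len(self.ref) == len(self.alt) == 2):
            raise ValueError("DBS requires 2-bp ref and alt")
        if self.sv_type is not None and self.sv_type not in VALID_SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.sv_type == "TRA" and self.sv_len is not None:
            raise ValueError("translocations carry no sv_len")


@dataclass(frozen=True)
class CloneMeta:
    """Clone-level metadata: which patient a clone came from, the patient's
    age in years, and the disease group (healthy, ALC, NASH, PSC, ...)."""

    clone_id: str
    patient_id: str
    age: float
    group: str

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")


@dataclass
class SignatureModel:
    """A signature definition matrix plus optional per-sample exposures.

    ``definitions`` is contexts x signatures with nonnegative entries and
    columns summing to 1 (each signature is a probability distribution over
    contexts). ``exposures`` (samples x signatures) and ``sample_types``
    carry a per-cancer-type exposure table when present.
    """

    contexts: list[str]
    signatures: list[str]
    definitions: np.ndarray
    exposures: pd.DataFrame | None = None
    sample_types: pd.Series | None = None

    def __post_init__(self) -> None:
        self.definitions = np.asarray(self.definitions, dtype=float)
        if self.definitions.shape != (len(self.contexts), len(self.signatures)):
            raise ValueError(
                f"definitions shape {self.definitions.shape} does not match "
                f"{len(self.contexts)} contexts x {len(self.signatures)} signatures"
            )
        if (self.definitions < 0).any():
            raise ValueError("signature definitions must be nonnegative")
        colsums = self.definitions.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            bad = [s for s, c in zip(self.signatures, colsums) if abs(c - 1) > 1e-6]
            raise ValueError(f"signature columns must sum to 1: {bad}")

    def subset(self, names: Sequence[str]) -> "SignatureModel":
        """Restrict the definition matrix to the named signatures."""
        idx = [self.signatures.index(n) for n in names]
        return SignatureModel(
            contexts=list(self.contexts),
            signatures=[self.signatures[i] for i in idx],
            definitions=self.definitions[:, idx],
        )


@dataclass(frozen=True)
class DriverGene:
    """A driver gene as a set of 1-based inclusive genomic intervals, each
    tagged with a region label (coding, promoter, UTR, ...)."""

    gene: str
    chrom: str
    intervals: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError(f"gene {self.gene} has no intervals")
        for start, end, _label in self.intervals:
            if start > end or start < 1:
                raise ValueError(f"bad interval [{start}, {end}] for {self.gene}")


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------


def _classify_small(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SBS"
    if len(ref) == 2 and len(alt) == 2:
        return "DBS"
    return "INDEL"


def _sv_from_symbolic(chrom: str, pos: int, alt: str, info,
                      stop: int | None) -> tuple[str, int | None] | None:
    svtype = info.get("SVTYPE")
    if svtype is None:
        svtype = alt.strip("<>").split(":")[0]
    svtype = str(svtype).upper()
    if svtype in ("TRA", "BND", "CTX"):
        return "TRA", None
    if svtype not in ("DEL", "DUP", "INV"):
        return None
    # pysam surfaces the END INFO key as record.stop
    try:
        svlen = info.get("SVLEN")
    except ValueError:  # key not declared in the header
        svlen = None
    if stop is not None and stop > pos:
        length = stop - pos
    elif svlen is not None:
        if isinstance(svlen, tuple):
            svlen = svlen[0]
        length = abs(int(svlen))
    else:
        return None
    return svtype, length


def _sv_from_breakend(chrom: str, pos: int, alt: str) -> tuple[str, int | None] | None:
    m = _BREAKEND_RE.search(alt)
    if m is None:
        return None
    mate_chrom, mate_pos = m.group(1), int(m.group(2))
    if mate_chrom != chrom:
        return "TRA", None
    # Intra-chromosomal breakend: the context schema only needs type+length.
    # Bracket orientation gives the type: t[p[ joins rightward (DEL-like),
    # ]p]t joins leftward (DUP-like), t]p] and [p[t connect same-direction
    # strands (INV-like).
    length = abs(mate_pos - pos)
    seq_first = alt[0] not in "[]"
    if "[" in alt:
        svtype = "DEL" if seq_first else "INV"
    else:
        svtype = "INV" if seq_first else "DUP"
    return svtype, length


def read_vcf_variants(path: str | Path, pass_only: bool = True) -> list[MutationRecord]:
    """Read somatic variants from a VCF 4.x file into MutationRecords.

    Multi-allelic rows are split into one record per alternate allele, each
    classified independently. SVs may be encoded as symbolic ALTs with
    SVTYPE/END (or SVLEN) INFO keys, or as breakend ALTs; breakend mates on
    the same chromosome yield ``|mate_pos - pos|`` as the length, while
    inter-chromosomal mates become translocations. Records with an SVTYPE
    this schema does not know are skipped with a warning.

    With ``pass_only`` set (the default, matching typical somatic
    post-processing) only rows whose FILTER is PASS are returned.
    """
    path = Path(path)
    records: list[MutationRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for row in vcf:
            filters = list(row.filter.keys())
            filter_str = ";".join(filters) if filters else "PASS"
            if pass_only and filter_str != "PASS":
                continue
            consequence = row.info.get("CSQ") if "CSQ" in row.info else None
            if isinstance(consequence, tuple):
                consequence = consequence[0]
            for alt in row.alts or ():
                rec = _row_to_record(row, alt, filter_str, consequence)
                if rec is not None:
                    records.append(rec)
    return records


def _row_to_record(row, alt: str, filter_str: str, consequence) -> MutationRecord | None:
    chrom, pos, ref = row.chrom, row.pos, row.ref
    if alt.startswith("<"):
        sv = _sv_from_symbolic(chrom, pos, alt, row.info, row.stop)
        if sv is None:
            logger.warning(
                "skipping SV with unknown SVTYPE/length at %s:%d (%s)", chrom, pos, alt
            )
            return None
        sv_type, sv_len = sv
        return MutationRecord(
            chrom, pos, ref, alt, "SV", sv_type=sv_type, sv_len=sv_len,
            filter=filter_str,
        )
    if "[" in alt or "]" in alt:
        sv = _sv_from_breakend(chrom, pos, alt)
        if sv is None:
            logger.warning("skipping unparseable breakend at %s:%d (%s)", chrom, pos, alt)
            return None
        sv_type, sv_len = sv
        return MutationRecord(
            chrom, pos, ref, alt, "SV", sv_type=sv_type, sv_len=sv_len,
            filter=filter_str,
        )
    return MutationRecord(
        chrom, pos, ref, alt, _classify_small(ref, alt),
        filter=filter_str, consequence=consequence,
    )


def write_vcf(records: Iterable[MutationRecord], path: str | Path,
              contigs: dict[str, int] | None = None) -> None:
    """Write MutationRecords to an uncompressed VCF 4.2 file.

    ``contigs`` maps contig name to length for the header; names are taken
    from the records when omitted. Records are written sorted by
    (chrom, pos). SV records are emitted as symbolic ALTs with SVTYPE and,
    for non-translocations, END = pos + sv_len.
    """
    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    if contigs is None:
        contigs = {r.chrom: 2**29 for r in records}
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={name},length={length}>" for name, length in contigs.items()]
    lines.append('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    lines.append('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">')
    lines.append('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    lines.append('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">')
    lines.append('##FILTER=<ID=LowQual,Description="Low quality">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for rec in records:
        info_parts = []
        alt = rec.alt
        if rec.var_class == "SV" and not ("[" in alt or "]" in alt):
            alt = f"<{rec.sv_type}>"
            info_parts.append(f"SVTYPE={rec.sv_type}")
            if rec.sv_len is not None:
                info_parts.append(f"END={rec.pos + rec.sv_len}")
        if rec.consequence:
            info_parts.append(f"CSQ={rec.consequence}")
        info = ";".join(info_parts) if info_parts else "."
        lines.append(
            f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{alt}\t.\t{rec.filter}\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA flanks
# ---------------------------------------------------------------------------


class ReferenceGenome:
    """Thin wrapper over an indexed FASTA for flank lookups."""

    def __init__(self, path: str | Path):
        self._fasta = Fasta(str(path), sequence_always_upper=True)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._fasta

    def chrom_length(self, chrom: str) -> int:
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive fetch."""
        return str(self._fasta[chrom][start - 1 : end]).upper()

    def close(self) -> None:
        self._fasta.close()


def fetch_flanks(genome: ReferenceGenome, chrom: str, pos: int, k: int) -> str:
    """Return the uppercase 2k+1-mer centred on ``pos`` (1-based).

    Raises FlankBoundaryError when the window runs off either end of the
    contig, and ValueError on non-ACGTN bases.
    """
    if chrom not in genome:
        raise KeyError(f"contig {chrom!r} not in reference")
    length = genome.chrom_length(chrom)
    if pos - k < 1 or pos + k > length:
        raise FlankBoundaryError(
            f"window [{pos - k}, {pos + k}] outside contig {chrom} (len {length})"
        )
    seq = genome.fetch(chrom, pos - k, pos + k)
    if not set(seq) <= set("ACGTN"):
        raise ValueError(f"non-ACGTN base in reference at {chrom}:{pos}: {seq}")
    return seq


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------


def read_signature_definitions(path: str | Path) -> SignatureModel:
    """Read a COSMIC-layout signature definition TSV.

    First column holds context labels; remaining columns are signatures
    whose entries are per-context probabilities (columns sum to 1).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SignatureModel(
        contexts=list(df.index.astype(str)),
        signatures=list(df.columns.astype(str)),
        definitions=df.to_numpy(dtype=float),
    )


def read_exposure_table(path: str | Path, type_column: str = "Cancer Types"
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Read a per-sample signature exposure table.

    Layout: one row per sample with a sample-name column first, a
    cancer-type column, and one column per signature. Returns the
    (samples x signatures) exposure matrix and the sample -> cancer-type
    labels. Negative exposures are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    if type_column not in df.columns:
        # tolerate common alternative spellings before failing
        for cand in ("Cancer_Type", "cancer_type", "Cancer Types", "Cancer Type"):
            if cand in df.columns:
                type_column = cand
                break
        else:
            raise VcfFormatError(
                f"exposure table {path} lacks a cancer-type column "
                f"(have: {list(df.columns)})"
            )
    sample_col = df.columns[0]
    df = df.set_index(sample_col)
    types = df[type_column].astype(str)
    exposures = df.drop(columns=[type_column]).astype(float)
    if (exposures.to_numpy() < 0).any():
        raise ValueError(f"negative exposure values in {path}")
    return exposures, types


def read_clone_metadata(path: str | Path) -> list[CloneMeta]:
    """Read clone metadata TSV (clone_id, patient_id, age, group)."""
    df = pd.read_csv(path, sep="\t")
    required = {"clone_id", "patient_id", "age", "group"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"metadata {path} missing columns {sorted(missing)}")
    if df["clone_id"].duplicated().any():
        dupes = df.loc[df["clone_id"].duplicated(), "clone_id"].tolist()
        raise ValueError(f"duplicate clone_ids in metadata: {dupes}")
    patient_groups = df.groupby("patient_id")["group"].nunique()
    if (patient_groups > 1).any():
        bad = patient_groups[patient_groups > 1].index.tolist()
        raise ValueError(f"patients assigned to multiple groups: {bad}")
    return [
        CloneMeta(str(r.clone_id), str(r.patient_id), float(r.age), str(r.group))
        for r in df.itertuples()
    ]


def write_clone_metadata(meta: Sequence[CloneMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "clone_id": [m.clone_id for m in meta],
            "patient_id": [m.patient_id for m in meta],
            "age": [m.age for m in meta],
            "group": [m.group for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def read_driver_genes(path: str | Path) -> list[DriverGene]:
    """Read a driver-gene interval TSV (gene, chrom, start, end, region_label)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise VcfFormatError(f"driver table {path} missing columns {sorted(missing)}")
    if "region_label" not in df.columns:
        df["region_label"] = "coding"
    genes = []
    for (gene, chrom), sub in df.groupby(["gene", "chrom"], sort=True):
        intervals = tuple(
            (int(r.start), int(r.end), str(r.region_label)) for r in sub.itertuples()
        )
        genes.append(DriverGene(gene=str(gene), chrom=str(chrom), intervals=intervals))
    return genes
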