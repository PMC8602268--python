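"""Driver-gene mutation tallies.

Consequence categories are consumed from upstream annotation (or the
synthetic generator); this module decides which count as non-synonymous
and builds an oncoprint-style sample x gene table in which each cell holds
the most severe overlapping mutation category. Severity ranking (most to
least): frameshift/nonsense > missense > other non-synonymous (splice,
inframe) > promoter/UTR > none. Selection testing (dN/dS style) is an
external analysis and is not performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import DriverGene, MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_NONSYN = frozenset({
    "frameshift_variant",
    "disruptive_inframe_deletion",
    "disruptive_inframe_insertion",
    "stop_gained",
    "missense_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "splice_region_variant",
})

DEFAULT_CLINVAR = frozenset({"VUS", "likely_pathogenic", "pathogenic"})

# most severe first; "none" is the empty cell
SEVERITY_ORDER = (
    "frameshift_nonsense",
    "missense",
    "other_nonsyn",
    "promoter_utr",
    "none",
)
_SEVERITY_RANK = {cat: i for i, cat in enumerate(SEVERITY_ORDER)}

_FRAMESHIFT_NONSENSE = frozenset({
    "frameshift_variant", "stop_gained",
    "disruptive_inframe_deletion", "disruptive_inframe_insertion",
})


@dataclass(frozen=True)
class ConsequenceRule:
    """Which annotation strings count as non-synonymous."""

    nonsyn_categories: frozenset[str] = DEFAULT_NONSYN
    clinvar_categories: frozenset[str] = DEFAULT_CLINVAR
    include_hotspots: bool = True

    def __post_init__(self) -> None:
        if not self.nonsyn_categories:
            raise ValueError("nonsyn_categories must be non-empty")


def classify_consequence(rec: MutationRecord, rules: ConsequenceRule,
                         clinvar: str | None = None,
                         hotspot: bool = False) -> str:
    """Return "non_synonymous" or "other" for one annotated record.

    A record is non-synonymous when its consequence annotation is in the
    rule set, or its ClinVar class is accepted, or it is a flagged hotspot.
    Unannotated records classify as "other" (tallied by the caller's log).
    """
    if rec.consequence is None and clinvar is None and not hotspot:
        logger.debug("unannotated record at %s:%d", rec.chrom, rec.pos)
        return "other"
    if rec.consequence in rules.nonsyn_categories:
        return "non_synonymous"
    if clinvar is not None and clinvar in rules.clinvar_categories:
        return "non_synonymous"
    if hotspot and rules.include_hotspots:
        return "non_synonymous"
    return "other"


def _severity_of(rec: MutationRecord, region_label: str,
                 rules: ConsequenceRule) -> str:
    cons = rec.consequence
    if region_label.lower() in ("promoter", "utr", "5utr", "3utr", "upstream"):
        return "promoter_utr"
    if cons is None:
        return "none"
    if cons in _FRAMESHIFT_NONSENSE:
        return "frameshift_nonsense"
    if cons == "missense_variant":
        return "missense"
    if cons in rules.nonsyn_categories:
        return "other_nonsyn"
    return "none"


def tally_driver_mutations(
    records_by_sample: Mapping[str, Iterable[MutationRecord]],
    genes: Sequence[DriverGene],
    rules: ConsequenceRule | None = None,
) -> pd.DataFrame:
    """Most severe overlapping mutation category per sample x gene.

    Interval overlap is 1-based inclusive over the span a record occupies
    ([pos, pos + len(ref) - 1] for small variants, [pos, pos + sv_len] for
    length-carrying SVs). Cells with no overlapping mutation hold "none".
    """
    rules = rules or ConsequenceRule()
    samples = list(records_by_sample)
    table = pd.DataFrame("none", index=samples,
                         columns=[g.gene for g in genes])
    for sample, records in records_by_sample.items():
        for rec in records:
            span_end = rec.pos + (rec.sv_len if rec.sv_len else len(rec.ref)) - 1
            for gene in genes:
                if gene.chrom != rec.chrom:
                    continue
                for start, end, region in gene.intervals:
                    if rec.pos <= end and span_end >= start:
                        cat = _severity_of(rec, region, rules)
                        if _SEVERITY_RANK[cat] < _SEVERITY_RANK[table.at[sample, gene.gene]]:
                            table.at[sample, gene.gene] = cat
    return table
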