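"""Canonical mutation-context catalogs.

Four fixed category schemes are used throughout the package:

* SBS96  -- single base substitutions in trinucleotide context, reported on
  the pyrimidine strand: 6 substitution types x 16 flank combinations.
* DBS78  -- doublet base substitutions collapsed onto 10 canonical reference
  doublets (78 categories after strand collapsing).
* ID83   -- small insertions/deletions split by size, repeat context and
  flanking microhomology.
* SV16   -- structural variants split by type (DEL/DUP/INV/TRA) and, except
  for translocations, by length bin.

Catalog orders are fixed and deterministic; spectrum matrices produced by
:mod:`mutaccum.contexts` always use these orders.
"""

from __future__ import annotations

import bisect

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string (case preserved as upper)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


# ---------------------------------------------------------------------------
# SBS96
# ---------------------------------------------------------------------------

SBS_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def _build_sbs96() -> list[str]:
    labels = []
    for sub in SBS_SUBSTITUTIONS:
        ref = sub[0]
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


SBS96 = tuple(_build_sbs96())


# ---------------------------------------------------------------------------
# DBS78
# ---------------------------------------------------------------------------
# The 78 canonical doublet categories. For each of the ten canonical
# reference doublets the alternate doublets listed are those in which both
# bases change; palindromic reference doublets (AT, CG, GC, TA) keep only
# one member of each alt/revcomp(alt) pair, following the published catalog.

_DBS78_ALTS: dict[str, tuple[str, ...]] = {
    "AC": ("CA", "CG", "CT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "AT": ("CA", "CC", "CG", "GA", "GC", "TA"),
    "CC": ("AA", "AG", "AT", "GA", "GG", "GT", "TA", "TG", "TT"),
    "CG": ("AT", "GC", "GT", "TA", "TC", "TT"),
    "CT": ("AA", "AC", "AG", "GA", "GC", "GG", "TA", "TC", "TG"),
    "GC": ("AA", "AG", "AT", "CA", "CG", "TA"),
    "TA": ("AT", "CG", "CT", "GC", "GG", "GT"),
    "TC": ("AA", "AG", "AT", "CA", "CG", "CT", "GA", "GG", "GT"),
    "TG": ("AA", "AC", "AT", "CA", "CC", "CT", "GA", "GC", "GT"),
    "TT": ("AA", "AC", "AG", "CA", "CC", "CG", "GA", "GC", "GG"),
}

DBS78 = tuple(
    f"{ref}>{alt}" for ref in sorted(_DBS78_ALTS) for alt in _DBS78_ALTS[ref]
)

DBS78_SET = frozenset(DBS78)


# ---------------------------------------------------------------------------
# ID83
# ---------------------------------------------------------------------------
# Naming convention: "<size>:<Del|Ins>:<C|T|R|M>:<n>".
#   1-bp events carry the pyrimidine-normalized base (C or T).
#     deletions:  n = homopolymer run length in the reference including the
#                 deleted base, 1..5 then "6+".
#     insertions: n = pre-existing run length of the inserted base, 0..4
#                 then "5+".
#   >=2-bp events carry R (repeat) with size capped at "5+":
#     deletions:  n = tandem copies of the deleted motif including the
#                 deleted copy, 1..5 then "6+".
#     insertions: n = pre-existing tandem copies of the inserted motif,
#                 0..4 then "5+".
#   Deletions with exactly one motif copy and >=1 bp of flanking
#   microhomology are reclassified M with n = homology length (capped).


def _build_id83() -> list[str]:
    labels: list[str] = []
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{n}" for n in [1, 2, 3, 4, 5, "6+"]]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{n}" for n in [0, 1, 2, 3, 4, "5+"]]
    for size in (2, 3, 4, "5+"):
        labels += [f"{size}:Del:R:{n}" for n in [1, 2, 3, 4, 5, "6+"]]
    for size in (2, 3, 4, "5+"):
        labels += [f"{size}:Ins:R:{n}" for n in [0, 1, 2, 3, 4, "5+"]]
    labels += ["2:Del:M:1"]
    labels += [f"3:Del:M:{n}" for n in (1, 2)]
    labels += [f"4:Del:M:{n}" for n in (1, 2, 3)]
    labels += [f"5+:Del:M:{n}" for n in (1, 2, 3, 4, "5+")]
    return labels


ID83 = tuple(_build_id83())


# ---------------------------------------------------------------------------
# SV16
# ---------------------------------------------------------------------------
# Length bins are left-open/right-closed intervals in bp:
# (1 kb, 10 kb], (10 kb, 100 kb], (100 kb, 1 Mb], (1 Mb, 10 Mb], (10 Mb, inf).
# Lengths <= 1 kb fold into the first bin (callers are warned upstream).
# Translocations have no meaningful length and form a single category.

SV_TYPES_BINNED = ("DEL", "DUP", "INV")
SV_LENGTH_BIN_LABELS = ("1kb-10kb", "10kb-100kb", "100kb-1Mb", "1Mb-10Mb", ">10Mb")
_SV_BIN_EDGES = (10_000, 100_000, 1_000_000, 10_000_000)

SV16 = tuple(
    f"{svtype}_{binlab}" for svtype in SV_TYPES_BINNED for binlab in SV_LENGTH_BIN_LABELS
) + ("TRA",)


def sv_length_bin(length: int) -> str:
    """Map a positive SV length (bp) to its catalog bin label.

    Bins are right-closed; e.g. exactly 10,000 bp falls in "1kb-10kb".
    Lengths of 1 kb or less fold into the first bin.
    """
    if length <= 0:
        raise ValueError(f"SV length must be positive, got {length}")
    idx = bisect.bisect_left(_SV_BIN_EDGES, length)
    return SV_LENGTH_BIN_LABELS[idx]


CATALOGS: dict[str, tuple[str, ...]] = {
    "SBS": SBS96,
    "DBS": DBS78,
    "INDEL": ID83,
    "SV": SV16,
}
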