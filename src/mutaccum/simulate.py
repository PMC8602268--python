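"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator inverts the burden model: clones are nested in patients,
patient ages are uniform on a range, each patient carries a random slope
offset, and clone mutation counts are Poisson around ``slope_i * age``
(or exactly equal to the mean with noise switched off). Per-clone SBS
spectra are drawn from a known mixture of signature columns, and a toy
reference genome plus per-clone VCFs are written such that re-classifying
the VCFs against the toy genome reproduces the drawn spectra exactly.

Default study conditions: 7 patients per group with 2 clones each, ages
uniform on 20-70 years, healthy accumulation rates of 46 SBS/year and
9 indels/year with modest between-patient spread, and Poisson count noise.
DBS and SV burdens are small (under one event per year), matching cohorts
in which those classes are too sparse for signature analysis.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Faidx

from .catalogs import BASES, SBS96, CATALOGS
from .contexts import ContextSpectrum
from .io import CloneMeta, SignatureModel, write_clone_metadata, write_vcf, MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_SLOPES = {"SBS": 46.0, "INDEL": 9.0, "DBS": 0.8, "SV": 0.4}
DEFAULT_PATIENT_SD = {"SBS": 4.0, "INDEL": 0.8, "DBS": 0.1, "SV": 0.05}


class GenerationError(RuntimeError):
    """Raised when a synthetic dataset cannot be realized."""


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one cohort group.

    ``slopes`` are true accumulation rates (mutations/year) per variant
    class; ``patient_sd`` the SD of the per-patient slope random effect in
    the same units (patient slopes are truncated at zero). ``signature_mix``
    are the mixing weights over the signature model's columns used to draw
    SBS spectra.
    """

    group: str = "healthy"
    n_patients: int = 7
    clones_per_patient: int | tuple[int, int] = 2
    age_range: tuple[float, float] = (20.0, 70.0)
    slopes: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    patient_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PATIENT_SD))
    count_noise: str = "poisson"
    signature_mix: tuple[float, ...] = (0.55, 0.25, 0.15, 0.05)
    seed: int = 0
    genome_len: int = 100_000

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if any(v < 0 for v in self.slopes.values()):
            raise ValueError("slopes must be nonnegative")
        if any(v < 0 for v in self.patient_sd.values()):
            raise ValueError("patient_sd must be nonnegative")
        if self.count_noise not in ("poisson", "none"):
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        mix = np.asarray(self.signature_mix, dtype=float)
        if (mix < 0).any() or abs(mix.sum() - 1) > 1e-6:
            raise ValueError("signature_mix must be nonnegative and sum to 1")
        lo, hi = self.age_range
        if not 0 < lo <= hi:
            raise ValueError(f"bad age_range {self.age_range}")


@dataclass
class GroundTruth:
    """Everything the generator knows about a simulated cohort."""

    group: str
    meta: list[CloneMeta]
    counts: dict[str, dict[str, float]]          # clone_id -> class -> true count
    patient_slopes: dict[str, dict[str, float]]  # patient_id -> class -> slope
    group_slopes: dict[str, float]
    signature_mix: tuple[float, ...]
    sbs_spectra: dict[str, np.ndarray] = field(default_factory=dict)

    def class_counts(self, var_class: str) -> dict[str, float]:
        return {cid: c[var_class] for cid, c in self.counts.items()}

    def to_json(self) -> dict:
        return {
            "group": self.group,
            "group_slopes": self.group_slopes,
            "signature_mix": list(self.signature_mix),
            "patient_slopes": self.patient_slopes,
            "counts": self.counts,
            "sbs_spectra": {c: s.tolist() for c, s in self.sbs_spectra.items()},
        }


def merge_truths(truths: Sequence[GroundTruth]) -> GroundTruth:
    """Concatenate per-group cohorts into one multi-group truth object."""
    merged = GroundTruth(
        group="+".join(t.group for t in truths),
        meta=[m for t in truths for m in t.meta],
        counts={}, patient_slopes={}, group_slopes={},
        signature_mix=truths[0].signature_mix if truths else (),
    )
    for t in truths:
        merged.counts.update(t.counts)
        merged.patient_slopes.update(t.patient_slopes)
        merged.sbs_spectra.update(t.sbs_spectra)
    return merged


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimConfig) -> GroundTruth:
    """Simulate one group: ages, patient slopes, and per-clone true counts.

    Patient ages ~ Uniform(age_range); patient slope per class
    = group slope + Normal(0, patient_sd), truncated at zero; clone count
    ~ Poisson(slope_i * age), or exactly slope_i * age with
    ``count_noise="none"``. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = list(cfg.slopes)
    truth = GroundTruth(
        group=cfg.group, meta=[], counts={}, patient_slopes={},
        group_slopes=dict(cfg.slopes), signature_mix=tuple(cfg.signature_mix),
    )
    for p in range(cfg.n_patients):
        patient_id = f"{cfg.group}{p + 1}"
        age = float(rng.uniform(*cfg.age_range))
        slopes_i = {}
        for cls in classes:
            sd = cfg.patient_sd.get(cls, 0.0)
            slopes_i[cls] = max(0.0, cfg.slopes[cls] + float(rng.normal(0, sd)))
        truth.patient_slopes[patient_id] = slopes_i
        n_clones = _n_clones(cfg.clones_per_patient, rng)
        for c in range(n_clones):
            clone_id = f"{patient_id}{chr(ord('a') + c)}"
            truth.meta.append(CloneMeta(clone_id, patient_id, age, cfg.group))
            counts = {}
            for cls in classes:
                mean = slopes_i[cls] * age
                if cfg.count_noise == "poisson":
                    counts[cls] = float(rng.poisson(mean))
                else:
                    counts[cls] = mean
            truth.counts[clone_id] = counts
    return truth


def _n_clones(spec: int | tuple[int, int], rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# Spectrum draws
# ---------------------------------------------------------------------------


def simulate_catalog(n: int, mix: Sequence[float], model: SignatureModel,
                     seed: int | np.random.Generator = 0,
                     clone_id: str = "sim", var_class: str = "SBS"
                     ) -> ContextSpectrum:
    """Draw an n-mutation context spectrum from a signature mixture.

    Context categories are sampled from the categorical distribution
    ``definitions @ mix``; the returned spectrum sums to exactly ``n``.
    """
    mix = np.asarray(mix, dtype=float)
    if len(mix) != len(model.signatures):
        raise ValueError(
            f"mix has {len(mix)} weights for {len(model.signatures)} signatures")
    if (mix < 0).any() or abs(mix.sum() - 1) > 1e-6:
        raise ValueError("mix weights must be nonnegative and sum to 1")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = model.definitions @ mix
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs) if n > 0 else np.zeros(len(probs), dtype=int)
    return ContextSpectrum(clone_id, var_class, tuple(model.contexts), counts)


# ---------------------------------------------------------------------------
# Synthetic signature and exposure fixtures
# ---------------------------------------------------------------------------


def make_synthetic_signatures(n_signatures: int = 4, catalog: str = "SBS",
                              seed: int = 20210, concentration: float = 0.05
                              ) -> SignatureModel:
    """Build a synthetic signature definition matrix.

    Columns are sparse Dirichlet draws over the catalog, giving
    well-separated signatures suitable for recovery experiments. This is a
    synthetic stand-in constructed by the package, not a published catalog.
    """
    labels = CATALOGS[catalog]
    rng = np.random.default_rng(seed)
    defs = rng.dirichlet(np.full(len(labels), concentration), size=n_signatures).T
    names = [f"SYN{chr(ord('A') + i)}" for i in range(n_signatures)]
    return SignatureModel(contexts=list(labels), signatures=names, definitions=defs)


def make_synthetic_exposures(
    signatures: Sequence[str],
    prevalence_by_type: Mapping[str, Mapping[str, float]],
    n_samples: int = 20,
    seed: int = 20211,
) -> tuple[pd.DataFrame, pd.Series]:
    """Build a synthetic per-cancer-type exposure table.

    ``prevalence_by_type[type][sig]`` is the fraction of that type's samples
    in which the signature is present; present samples get a positive
    exposure, absent samples zero (the zero-filled convention of pan-cancer
    exposure tables).
    """
    rng = np.random.default_rng(seed)
    rows, types, names = [], [], []
    for ctype, prevalences in prevalence_by_type.items():
        for i in range(n_samples):
            row = []
            for sig in signatures:
                prev = prevalences.get(sig, 0.0)
                present = rng.random() < prev
                row.append(float(rng.integers(50, 2000)) if present else 0.0)
            rows.append(row)
            types.append(ctype)
            names.append(f"{ctype}_s{i + 1}")
    exposures = pd.DataFrame(rows, index=names, columns=list(signatures))
    return exposures, pd.Series(types, index=names, name="cancer_type")


# ---------------------------------------------------------------------------
# Toy genome and VCF emission
# ---------------------------------------------------------------------------

_ALL_TRINUCS = [a + b + c for a in BASES for b in BASES for c in BASES]


def make_toy_genome(length: int, rng: np.random.Generator) -> str:
    """Random toy chromosome guaranteed to contain all 64 trinucleotides.

    A prefix concatenating every 3-mer guarantees coverage; the remainder
    is i.i.d. uniform ACGT.
    """
    prefix = "".join(_ALL_TRINUCS)
    n_rand = max(length - len(prefix), 0)
    body = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n_rand)])
    return prefix + body


def _position_index(genome: str) -> dict[str, list[int]]:
    """1-based center positions of every interior trinucleotide."""
    index: dict[str, list[int]] = {t: [] for t in _ALL_TRINUCS}
    for i in range(1, len(genome) - 1):
        index[genome[i - 1 : i + 2]].append(i + 1)
    return index


def _sbs_context_of(label: str) -> tuple[str, str, str]:
    """Split an SBS96 label into (reference trinuc, ref base, alt base)."""
    five, rest = label[0], label[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt


def spectrum_to_records(spectrum: ContextSpectrum, position_index,
                        rng: np.random.Generator, chrom: str = "chr1"
                        ) -> list[MutationRecord]:
    """Place a drawn SBS spectrum onto the toy genome as MutationRecords.

    Positions are sampled without replacement within the clone so every
    record is a distinct site whose reference trinucleotide classifies back
    to the drawn category.
    """
    demand: dict[str, list[tuple[str, int]]] = {}
    for label, count in zip(spectrum.catalog, spectrum.counts):
        if count == 0:
            continue
        trinuc, _ref, alt = _sbs_context_of(label)
        demand.setdefault(trinuc, []).append((alt, int(count)))
    records: list[MutationRecord] = []
    for trinuc, wants in sorted(demand.items()):
        total = sum(c for _, c in wants)
        positions = position_index.get(trinuc, [])
        if total > len(positions):
            raise GenerationError(
                f"need {total} sites with trinucleotide {trinuc} but the toy "
                f"genome has {len(positions)}; increase genome_len"
            )
        chosen = rng.choice(len(positions), size=total, replace=False)
        it = iter(chosen)
        for alt, count in wants:
            for _ in range(count):
                pos = positions[int(next(it))]
                records.append(MutationRecord(
                    chrom=chrom, pos=pos, ref=trinuc[1], alt=alt,
                    var_class="SBS",
                ))
    return records


def write_synthetic_dataset(truth: GroundTruth, model: SignatureModel,
                            outdir: str | Path, cfg: SimConfig) -> dict:
    """Write a complete synthetic dataset to ``outdir``.

    Emits reference.fa (+ .fai), one VCF per clone whose SBS records
    classify back to the drawn spectrum exactly, metadata.tsv, per-class
    count tables, the drawn SBS spectrum matrix, and ground_truth.json.
    Returns a manifest dict of the files written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xD47A)))

    genome_len = cfg.genome_len
    for attempt in range(3):
        genome = make_toy_genome(genome_len, rng)
        index = _position_index(genome)
        try:
            per_clone = _draw_and_place(truth, model, index, rng)
            break
        except GenerationError as exc:
            logger.warning("placement failed (%s); regenerating a larger toy genome",
                           exc)
            genome_len *= 4
    else:
        raise GenerationError("could not place all spectra after genome retries")

    fasta_path = outdir / "reference.fa"
    with open(fasta_path, "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(genome), 80):
            fh.write(genome[i : i + 80] + "\n")
    Faidx(str(fasta_path)).close()

    vcf_dir = outdir / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    contigs = {"chr1": len(genome)}
    for clone_id, records in per_clone.items():
        write_vcf(records, vcf_dir / f"{clone_id}.vcf", contigs=contigs)

    write_clone_metadata(truth.meta, outdir / "metadata.tsv")

    counts_df = pd.DataFrame(truth.counts).T
    counts_df.index.name = "clone_id"
    counts_df.to_csv(outdir / "counts.tsv", sep="\t")

    spectra = pd.DataFrame(
        {cid: truth.sbs_spectra[cid] for cid in truth.counts},
        index=list(model.contexts), dtype=int,
    )
    spectra.to_csv(outdir / "spectra_SBS_truth.tsv", sep="\t",
                   index_label="context")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)

    return {
        "reference": str(fasta_path),
        "vcf_dir": str(vcf_dir),
        "metadata": str(outdir / "metadata.tsv"),
        "counts": str(outdir / "counts.tsv"),
        "spectra_truth": str(outdir / "spectra_SBS_truth.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
        "n_clones": len(truth.counts),
    }


def _draw_and_place(truth: GroundTruth, model: SignatureModel, index,
                    rng: np.random.Generator) -> dict[str, list[MutationRecord]]:
    per_clone: dict[str, list[MutationRecord]] = {}
    for clone in truth.meta:
        n_sbs = int(round(truth.counts[clone.clone_id]["SBS"]))
        spectrum = simulate_catalog(
            n_sbs, truth.signature_mix, model, seed=rng,
            clone_id=clone.clone_id,
        )
        truth.sbs_spectra[clone.clone_id] = spectrum.counts.copy()
        per_clone[clone.clone_id] = spectrum_to_records(spectrum, index, rng)
    return per_clone
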