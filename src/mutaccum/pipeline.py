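"""End-to-end orchestration: simulate/classify -> signatures -> statistics.

A single YAML config drives the run. Input is either a directory of
per-clone somatic VCFs plus a reference FASTA and metadata table, or a
``simulate`` block describing synthetic cohorts (exactly one of the two).
All randomness funnels through the config seed, and the run manifest
records the config hash, seed and every file written, so reruns at a fixed
seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .burden import (
    GroupComparison,
    compare_groups,
    context_load_tests,
    fit_burden_regression,
    normality_check,
    regression_table,
    summary,
)
from .contexts import build_spectrum_matrix, write_spectrum_matrix
from .drivers import ConsequenceRule, tally_driver_mutations
from .io import (
    ReferenceGenome,
    read_clone_metadata,
    read_driver_genes,
    read_exposure_table,
    read_signature_definitions,
    read_vcf_variants,
)
from .signatures import SignatureRefit, select_signatures
from .simulate import (
    SimConfig,
    make_synthetic_signatures,
    merge_truths,
    simulate_cohort,
    write_synthetic_dataset,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    reference_group: str = "healthy"
    selection_threshold: float = 0.10
    alpha: float = 0.05
    vcf_dir: Path | None = None
    reference: Path | None = None
    metadata: Path | None = None
    signatures: Path | None = None
    exposures: Path | None = None
    exposure_types: list[str] = field(default_factory=list)
    drivers: Path | None = None
    simulate: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if (self.vcf_dir is None) == (self.simulate is None):
            raise ValueError(
                "config must provide exactly one of vcf_dir or a simulate block")
        if not 0 < self.selection_threshold <= 1:
            raise ValueError("selection threshold must be in (0, 1]")
        if self.vcf_dir is not None and (self.reference is None or self.metadata is None):
            raise ValueError("vcf_dir mode needs reference and metadata paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        paths = {k: Path(v) for k, v in raw.items()
                 if k in ("outdir", "vcf_dir", "reference", "metadata",
                          "signatures", "exposures", "drivers") and v is not None}
        return cls(
            outdir=paths.pop("outdir", Path("mutaccum_out")),
            seed=int(raw.get("seed", 0)),
            reference_group=str(raw.get("reference_group", "healthy")),
            selection_threshold=float(raw.get("selection_threshold", 0.10)),
            alpha=float(raw.get("alpha", 0.05)),
            simulate=raw.get("simulate"),
            exposure_types=list(raw.get("exposure_types", [])),
            **paths,
        )


def _config_hash(cfg: PipelineConfig) -> str:
    payload = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _sim_configs(cfg: PipelineConfig) -> list[SimConfig]:
    block = cfg.simulate or {}
    groups = block.get("groups") or {"healthy": {}}
    configs = []
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in ss.generate_state(len(groups)) % (2**31)]
    common = {k: v for k, v in block.items() if k != "groups"}
    for (group, overrides), seed in zip(sorted(groups.items()), seeds):
        params = dict(common)
        params.update(overrides or {})
        params.pop("seed", None)
        if "slopes" in params:
            params["slopes"] = {str(k): float(v) for k, v in params["slopes"].items()}
        if "patient_sd" in params:
            params["patient_sd"] = {str(k): float(v)
                                    for k, v in params["patient_sd"].items()}
        if "age_range" in params:
            params["age_range"] = tuple(params["age_range"])
        if "signature_mix" in params:
            params["signature_mix"] = tuple(params["signature_mix"])
        if "clones_per_patient" in params and not isinstance(
                params["clones_per_patient"], int):
            params["clones_per_patient"] = tuple(params["clones_per_patient"])
        configs.append(SimConfig(group=group, seed=seed, **params))
    return configs


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run simulate/classify -> signature refit -> burden statistics.

    Returns the manifest dict (also written to ``outdir/manifest.json``).
    Any stage failure raises PipelineError naming the stage; outputs written
    before the failure are left in place for inspection.
    """
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "outputs": {},
        "totals": {},
    }

    # --- stage 1: obtain inputs ------------------------------------------
    try:
        if cfg.simulate is not None:
            sim_cfgs = _sim_configs(cfg)
            truth = merge_truths([simulate_cohort(c) for c in sim_cfgs])
            sig_model = make_synthetic_signatures()
            data_manifest = write_synthetic_dataset(
                truth, sig_model, outdir / "data", sim_cfgs[0])
            vcf_dir = Path(data_manifest["vcf_dir"])
            reference = Path(data_manifest["reference"])
            meta = truth.meta
            manifest["outputs"]["data"] = data_manifest
        else:
            vcf_dir, reference = cfg.vcf_dir, cfg.reference
            meta = read_clone_metadata(cfg.metadata)
            sig_model = (read_signature_definitions(cfg.signatures)
                         if cfg.signatures else None)
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("inputs", str(exc)) from exc

    # --- stage 2: classify ------------------------------------------------
    try:
        genome = ReferenceGenome(reference)
        records_by_clone = {}
        n_pass = 0
        for m in meta:
            path = Path(vcf_dir) / f"{m.clone_id}.vcf"
            recs = read_vcf_variants(path, pass_only=True) if path.exists() else []
            records_by_clone[m.clone_id] = recs
            n_pass += len(recs)
        spectra, sbs_matrix = build_spectrum_matrix(records_by_clone, genome, "SBS")
        write_spectrum_matrix(sbs_matrix, outdir / "spectra_SBS.tsv")
        manifest["outputs"]["spectra_SBS"] = str(outdir / "spectra_SBS.tsv")
        manifest["totals"]["pass_records"] = n_pass
        manifest["totals"]["classified_SBS"] = int(sbs_matrix.to_numpy().sum())
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # --- stage 3: signatures ----------------------------------------------
    try:
        if sig_model is not None:
            fit_model = sig_model
            if cfg.exposures is not None and cfg.exposure_types:
                exposures, types = read_exposure_table(cfg.exposures)
                selected = select_signatures(
                    exposures, types, cfg.exposure_types,
                    threshold=cfg.selection_threshold)
                if selected:
                    fit_model = sig_model.subset(
                        [s for s in selected if s in sig_model.signatures])
            refit = SignatureRefit(sbs_matrix, fit_model).fit()
            refit.absolute.to_csv(outdir / "signature_absolute.tsv", sep="\t",
                                  index_label="signature")
            refit.relative.to_csv(outdir / "signature_relative.tsv", sep="\t",
                                  index_label="signature")
            manifest["outputs"]["signature_absolute"] = str(
                outdir / "signature_absolute.tsv")
            manifest["outputs"]["signature_relative"] = str(
                outdir / "signature_relative.tsv")
    except Exception as exc:
        raise PipelineError("signatures", str(exc)) from exc

    # --- stage 4: burden statistics ---------------------------------------
    try:
        counts = {cid: int(col.sum()) for cid, col in sbs_matrix.items()}
        groups = sorted({m.group for m in meta})
        fits = {g: fit_burden_regression(counts, meta, group=g) for g in groups}
        comparisons: list[GroupComparison] = []
        ref_group = cfg.reference_group
        if ref_group in fits:
            for g in groups:
                if g != ref_group:
                    comparisons.append(compare_groups(fits[g], fits[ref_group]))
        regression_table(list(fits.values())).to_csv(
            outdir / "regression.tsv", sep="\t", index=False)
        if comparisons:
            pd.DataFrame([c.summary_row() for c in comparisons]).to_csv(
                outdir / "comparisons.tsv", sep="\t", index=False)
            manifest["outputs"]["comparisons"] = str(outdir / "comparisons.tsv")
        counts_by_group = {
            g: [counts[m.clone_id] for m in meta if m.group == g] for g in groups
        }
        normality_check(counts_by_group).to_csv(
            outdir / "normality.tsv", sep="\t", index=False)
        group_of = {m.clone_id: m.group for m in meta}
        ctx_frames = []
        for g in groups:
            if g == ref_group or ref_group not in groups:
                continue
            ctx = context_load_tests(sbs_matrix, group_of, g, ref_group)
            ctx.insert(0, "group", g)
            ctx_frames.append(ctx)
        if ctx_frames:
            pd.concat(ctx_frames).to_csv(outdir / "context_tests.tsv", sep="\t")
            manifest["outputs"]["context_tests"] = str(outdir / "context_tests.tsv")
        manifest["outputs"]["regression"] = str(outdir / "regression.tsv")
        manifest["outputs"]["normality"] = str(outdir / "normality.tsv")
        manifest["totals"]["stats_input"] = int(sum(counts.values()))
        print(summary(list(fits.values()), comparisons))
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc

    # --- stage 5: drivers ---------------------------------------------------
    try:
        if cfg.drivers is not None:
            genes = read_driver_genes(cfg.drivers)
            table = tally_driver_mutations(records_by_clone, genes,
                                           ConsequenceRule())
            table.to_csv(outdir / "driver_tally.tsv", sep="\t",
                         index_label="clone_id")
            manifest["outputs"]["driver_tally"] = str(outdir / "driver_tally.tsv")
    except Exception as exc:
        raise PipelineError("drivers", str(exc)) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    manifest_path = outdir / "manifest.json"
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
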