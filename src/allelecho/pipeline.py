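"""End-to-end orchestration: simulate -> allele fractions -> copy number
-> consequence annotation -> imbalance report.

Each stage is a pure function of its input files plus configuration; the
manifest written by :func:`run_all` records SHA-256 hashes of every stage
output, so identical seeds yield identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .allelefrac import (
    DEFAULT_ALPHA,
    DEFAULT_ERROR_RATE,
    DEFAULT_MIN_READS,
    allele_fraction,
    allele_fraction_table,
)
from .annot import classify, read_transcript_table, strata
from .cnfit import DEFAULT_CN_MAX, assign_all, fit_sample_model
from .core import AlleleCounts, ConfigurationError, SampleModel
from .imbalance import (
    DEFAULT_HIGH_COVERAGE,
    DEFAULT_LOW_COVERAGE,
    DEFAULT_OUTLIER_THRESHOLD,
    build_records,
    report,
)
from .sim import SimConfig, read_counts, read_vcf, simulate_counts, simulate_genome, write_fixture

log = logging.getLogger("allelecho")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run."""

    out_dir: str = "allelecho_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    min_reads: int = DEFAULT_MIN_READS
    alpha: float = DEFAULT_ALPHA
    error_rate: float = DEFAULT_ERROR_RATE
    cn_max: int = DEFAULT_CN_MAX
    coverage_weight: float = 1.0
    high_coverage_cutoff: int = DEFAULT_HIGH_COVERAGE
    low_coverage_cutoff: int = DEFAULT_LOW_COVERAGE
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD
    figures: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            sim = dict(self.sim)
            if "segment_cn_weights" in sim:
                sim["segment_cn_weights"] = {
                    int(k): float(v) for k, v in sim["segment_cn_weights"].items()
                }
            self.sim = SimConfig(**sim)
        for name in ("min_reads", "cn_max", "high_coverage_cutoff", "low_coverage_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)


# --- stages ---------------------------------------------------------------


def stage_simulate(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    truth = simulate_genome(cfg.sim)
    counts = simulate_counts(truth)
    paths = write_fixture(truth, counts, out / "sim")
    log.info("simulated %d SNVs on %d segments", len(truth.snvs), len(truth.segments))
    return paths


def stage_af(cfg: PipelineConfig, counts_path, out: Path) -> Path:
    if not Path(counts_path).exists():
        raise StageError("af", f"counts file not found: {counts_path}")
    counts = read_counts(counts_path)
    table = allele_fraction_table(
        counts, min_reads=cfg.min_reads, alpha=cfg.alpha, error_rate=cfg.error_rate
    )
    out.mkdir(parents=True, exist_ok=True)
    path = out / "af.tsv"
    table.to_csv(path, sep="\t", index=False)
    log.info("allele fractions for %d SNVs (%d pass filters)",
             len(table), int(table["pass_filters"].sum()))
    return path


def stage_cn(cfg: PipelineConfig, af_path, out: Path) -> tuple[Path, Path]:
    if not Path(af_path).exists():
        raise StageError("cn", f"allele-fraction table not found: {af_path}")
    af = pd.read_csv(af_path, sep="\t")
    usable = af[
        (af["dna_total_reads"] >= cfg.min_reads) & (af["germline_total_reads"] > 0)
    ].reset_index(drop=True)
    if usable.empty:
        raise StageError("cn", "no SNVs with sufficient DNA coverage")
    pooled = [
        allele_fraction(AlleleCounts(int(r.dna_mutant_reads), int(r.dna_total_reads)))
        for r in usable.itertuples()
    ]
    ratios = (usable["dna_total_reads"] / usable["germline_total_reads"]).to_numpy()
    model = fit_sample_model(
        ratios, pooled,
        germline_totals=usable["germline_total_reads"].to_numpy(dtype=float),
        cn_max=cfg.cn_max, coverage_weight=cfg.coverage_weight,
    )
    fits = assign_all(
        pooled, ratios, model, cn_max=cfg.cn_max,
        coverage_weight=cfg.coverage_weight,
        germline_totals=usable["germline_total_reads"].to_numpy(dtype=float),
    )
    out.mkdir(parents=True, exist_ok=True)
    cn_path = out / "cn.tsv"
    pd.DataFrame(
        {
            "snv_id": usable["snv_id"],
            "cn": [f.cn for f in fits],
            "m": [f.m for f in fits],
            "loglik": [f.loglik for f in fits],
            "margin": [f.runner_up_margin for f in fits],
        }
    ).to_csv(cn_path, sep="\t", index=False)
    model_path = out / "sample_model.json"
    with open(model_path, "w") as fh:
        json.dump(
            {"rho": model.purity, "psi": model.psi, "c": model.coverage_scale,
             "loglik": model.loglik, "flags": model.flags},
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")
    log.info("sample model: rho=%.2f psi=%.2f c=%.3f %s",
             model.purity, model.psi, model.coverage_scale, model.flags)
    return cn_path, model_path


def stage_annot(cfg: PipelineConfig, vcf_path, tx_path, fasta_path, out: Path) -> Path:
    for p, name in [(vcf_path, "VCF"), (tx_path, "transcript table"), (fasta_path, "FASTA")]:
        if not Path(p).exists():
            raise StageError("annot", f"{name} not found: {p}")
    import pyfaidx

    snvs = read_vcf(vcf_path)
    transcripts = read_transcript_table(tx_path)
    ref = pyfaidx.Fasta(str(fasta_path))
    rows = []
    for snv in snvs:
        tx = transcripts.get(snv.transcript_id)
        if tx is None:
            raise StageError("annot", f"no transcript model for {snv.transcript_id}")
        csq = classify(snv, tx, ref)
        rows.append(
            dict(
                snv_id=snv.snv_id,
                consequence=csq.klass.value,
                codon_ref=csq.codon_ref,
                codon_alt=csq.codon_alt,
                aa_ref=csq.aa_ref,
                aa_alt=csq.aa_alt,
                exon_index=csq.exon_index,
                n_exons=csq.n_exons,
                flags=";".join(csq.flags),
            )
        )
    df = pd.DataFrame(rows)
    lab = strata(df["consequence"])
    df["ptc_group"] = lab["ptc_group"].to_numpy()
    df["coding_group"] = lab["coding_group"].to_numpy()
    out.mkdir(parents=True, exist_ok=True)
    path = out / "consequences.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def stage_imbalance(cfg: PipelineConfig, af_path, cn_path, annot_path, out: Path) -> dict:
    for p, name in [(af_path, "af table"), (cn_path, "cn table"), (annot_path, "annotation")]:
        if not Path(p).exists():
            raise StageError("imbalance", f"{name} not found: {p}")
    af = pd.read_csv(af_path, sep="\t")
    cn = pd.read_csv(cn_path, sep="\t")
    annot = pd.read_csv(annot_path, sep="\t")
    records = build_records(af, cn, annot)
    return report(
        records, out,
        high_cutoff=cfg.high_coverage_cutoff,
        low_cutoff=cfg.low_coverage_cutoff,
        outlier_threshold=cfg.outlier_threshold,
        figures=cfg.figures,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig) -> dict:
    """Run every stage in order under ``cfg.out_dir``; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        sim_paths = stage_simulate(cfg, out)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e
    af_path = stage_af(cfg, sim_paths["counts"], out)
    cn_path, model_path = stage_cn(cfg, af_path, out)
    annot_path = stage_annot(
        cfg, sim_paths["vcf"], sim_paths["transcripts"], sim_paths["fasta"], out
    )
    try:
        summary = stage_imbalance(cfg, af_path, cn_path, annot_path, out)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("imbalance", str(e)) from e

    tracked = {
        **{f"sim/{k}": p for k, p in sim_paths.items()},
        "af": af_path,
        "cn": cn_path,
        "sample_model": model_path,
        "consequences": annot_path,
        "imbalance": out / "imbalance.tsv",
        "summary": out / "summary.json",
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": _jsonable(dataclasses.asdict(cfg)),
        "hashes": {k: _sha256(Path(p)) for k, p in sorted(tracked.items())},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", out / "summary.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
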