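"""End-to-end orchestration: simulate -> classify -> scan -> refine -> annotate.

Stages communicate through plain files under one output directory and a
JSON manifest records config, seed, per-stage outputs (sha256), and
timings, so a run is reproducible from its manifest alone.  Partial runs
are supported with ``from_stage``/``to_stage``; a stage whose declared
inputs are missing fails with a clear precondition error.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .coseg_classifier import ClassifierParams, classify_table
from .consequence_annot import (
    classify_coding_variant,
    enumerate_aberrant_isoforms,
    load_domain_table,
    report_truncation,
    translate_isoform,
)
from .cross_simulator import (
    CrossConfig,
    build_truth_table,
    sample_depths,
    emit_vcf,
    simulate_offspring,
    simulate_panel,
)
from .errors import PipelineError
from .genome_scan import CandidateInterval, call_interval, fine_scan, scan
from .io_formats import LibrarySpec, read_variant_table, write_scan_outputs
from .recombinant_refine import (
    detect_recombinants,
    read_genotype_table,
    refine_interval,
)

STAGES = ["simulate", "classify", "scan", "fine_scan", "refine", "annotate"]

__all__ = ["STAGES", "run_all", "default_config", "demo_config"]


def default_config() -> dict:
    """Run configuration mirroring the default synthetic cross."""
    return {
        "cross": {},
        "classifier": {},
        "scan": {"window": 1_000_000, "step": 100_000, "min_scaffold": 1_000_000},
        "fine_scan": {"window": 200_000, "step": 50_000},
        "interval": {"frac_of_peak": 0.9, "min_informative": 10},
        "refine": {"n_markers": 40, "trust_single": False},
        "annotate": {"max_scan": 2000},
    }


def demo_config() -> dict:
    """Scaled-down configuration for quick demonstrations and tests."""
    cfg = default_config()
    cfg["cross"] = {
        "scaffold_lengths": (6_000_000, 3_000_000, 2_000_000),
        "causal_pos": 3_500_000,
    }
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(stage: str, *paths: Path) -> None:
    for p in paths:
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r} requires {p.name} from an earlier stage; "
                f"run from an earlier stage or provide {p}"
            )


def _stage_simulate(ctx: dict) -> List[Path]:
    config: CrossConfig = ctx["cross_config"]
    rng = np.random.default_rng(config.seed)
    panel, founders = simulate_panel(config, rng)
    pedigree = simulate_offspring(founders, panel, config, rng)
    truth = build_truth_table(panel, founders, pedigree, config)
    truth = sample_depths(truth, config, rng=rng)
    vcf = ctx["outdir"] / "sim.vcf"
    emit_vcf(truth, config, vcf)
    truth_tsv = ctx["outdir"] / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    # per-individual genotypes at informative phase-linked markers on the
    # causal scaffold, for the refinement stage (error-free genotyping)
    n_markers = ctx["config"]["refine"].get("n_markers", 40)
    causal_name = config.scaffold_names[config.causal_scaffold]
    linked_rows = np.flatnonzero(
        truth["linked"].to_numpy() & (truth["scaffold"] == causal_name).to_numpy()
    )
    take = np.unique(np.linspace(0, len(linked_rows) - 1, n_markers).astype(int))
    rows = linked_rows[take]
    carrier_is_alt = truth["carrier_allele"].to_numpy()[rows] == "alt"
    records = []
    for i in range(len(pedigree.phenotype)):
        alt_dose = (
            pedigree.pat_alleles[i, rows].astype(int) + pedigree.mat_alleles[i, rows]
        )
        dose = np.where(carrier_is_alt, alt_dose, 2 - alt_dose)
        for r, d in zip(rows, dose):
            records.append(
                (
                    f"ind_{i + 1}",
                    pedigree.phenotype[i],
                    truth["scaffold"].iat[r],
                    int(truth["pos"].iat[r]) + 1,
                    int(d),
                )
            )
    geno = pd.DataFrame(
        records, columns=["individual_id", "phenotype", "scaffold", "pos", "dose"]
    )
    geno_tsv = ctx["outdir"] / "genotypes.tsv"
    geno.to_csv(geno_tsv, sep="\t", index=False)
    return [vcf, truth_tsv, geno_tsv]


def _stage_classify(ctx: dict) -> List[Path]:
    vcf = ctx["outdir"] / "sim.vcf"
    _require("classify", vcf)
    config: CrossConfig = ctx["cross_config"]
    specs = [LibrarySpec("father", "FATHER")]
    specs += [
        LibrarySpec("mother", f"MOTHER{m}") for m in range(1, config.n_mothers + 1)
    ]
    specs += [
        LibrarySpec("homo_pool", "POOL_HOMO", "pool", config.n_homo_offspring),
        LibrarySpec("het_pool", "POOL_HET", "pool", config.n_het_offspring),
    ]
    reader = read_variant_table(vcf, specs)
    statuses, _summary = classify_table(iter(reader), ctx["classifier_params"])
    frame = pd.DataFrame(
        [
            (s.scaffold, s.pos, s.vclass, s.status, s.carrier_allele, s.homo_freq, s.het_freq)
            for s in statuses
        ],
        columns=["scaffold", "pos", "vclass", "status", "carrier_allele", "homo_freq", "het_freq"],
    )
    out = ctx["outdir"] / "statuses.tsv"
    frame.to_csv(out, sep="\t", index=False, na_rep="NA")
    counts = dict(_summary.by_status)
    counts["read_report"] = reader.report
    summary = ctx["outdir"] / "classify_summary.json"
    summary.write_text(json.dumps(counts, indent=2, sort_keys=True))
    return [out, summary]


def _stage_scan(ctx: dict) -> List[Path]:
    statuses_tsv = ctx["outdir"] / "statuses.tsv"
    _require("scan", statuses_tsv)
    statuses = pd.read_csv(statuses_tsv, sep="\t")
    config: CrossConfig = ctx["cross_config"]
    lengths = dict(zip(config.scaffold_names, config.scaffold_lengths))
    windows = scan(statuses, lengths, **ctx["config"]["scan"])
    tsv, bed = write_scan_outputs(windows, ctx["outdir"] / "scan")
    interval = call_interval(windows, **ctx["config"]["interval"])
    interval_json = ctx["outdir"] / "interval.json"
    interval_json.write_text(json.dumps(asdict(interval), indent=2))
    return [tsv, bed, interval_json]


def _stage_fine_scan(ctx: dict) -> List[Path]:
    statuses_tsv = ctx["outdir"] / "statuses.tsv"
    interval_json = ctx["outdir"] / "interval.json"
    _require("fine_scan", statuses_tsv, interval_json)
    statuses = pd.read_csv(statuses_tsv, sep="\t")
    interval = json.loads(interval_json.read_text())
    config: CrossConfig = ctx["cross_config"]
    lengths = dict(zip(config.scaffold_names, config.scaffold_lengths))
    windows = fine_scan(
        statuses,
        interval["scaffold"],
        lengths[interval["scaffold"]],
        **ctx["config"]["fine_scan"],
    )
    tsv, bed = write_scan_outputs(windows, ctx["outdir"] / "fine")
    return [tsv, bed]


def _stage_refine(ctx: dict) -> List[Path]:
    interval_json = ctx["outdir"] / "interval.json"
    geno_tsv = ctx["outdir"] / "genotypes.tsv"
    _require("refine", interval_json, geno_tsv)
    d = json.loads(interval_json.read_text())
    interval = CandidateInterval(**d)
    genotypes = read_genotype_table(geno_tsv)
    profiles = detect_recombinants(genotypes, interval)
    refined = refine_interval(
        interval, profiles, trust_single=ctx["config"]["refine"].get("trust_single", False)
    )
    out = ctx["outdir"] / "refined.json"
    out.write_text(
        json.dumps(
            {
                "scaffold": refined.scaffold,
                "start": refined.start,
                "end": refined.end,
                "length_mb": refined.length_mb,
                "n_recombinants_used": refined.n_recombinants_used,
                "n_recombinants_detected": sum(p.is_recombinant for p in profiles),
            },
            indent=2,
        )
    )
    return [out]


def _stage_annotate(ctx: dict) -> List[Path]:
    """Consequence demo on the bundled synthetic splice-disruption gene.

    The mapping stages localise the causal region; this stage demonstrates
    the consequence engine on a synthetic gene carrying the same class of
    lesion (a donor-site MNP), since no real genome is bundled.
    """
    from .synthetic_genes import build_pmel_like_gene, write_gene_files

    gene = build_pmel_like_gene()
    fasta, gff = write_gene_files(gene, ctx["outdir"])
    call = classify_coding_variant(gene.model, gene.variant, gene.genome)
    isoforms = enumerate_aberrant_isoforms(
        gene.model,
        gene.disrupted_intron,
        gene.genome,
        max_scan=ctx["config"]["annotate"].get("max_scan", 2000),
    )
    domains = load_domain_table()
    reference_protein = gene.model.reference_protein(gene.genome)
    rows = []
    for iso in isoforms:
        tr = translate_isoform(iso, gene.model, gene.genome)
        trunc = report_truncation(tr.protein, reference_protein, domains)
        rows.append(
            {
                "kind": iso.kind,
                "retained_length": iso.retained_length,
                "protein_length": len(tr.protein),
                "truncated": tr.truncated,
                "domains_lost": ",".join(trunc.lost) or ".",
                "domains_partial": ",".join(trunc.partial) or ".",
            }
        )
    report = {
        "variant": f"{gene.variant.scaffold}:{gene.variant.pos + 1}"
        f"{gene.variant.ref}>{gene.variant.alt}",
        "category": call.category,
        "detail": list(call.detail),
        "reference_protein_length": len(reference_protein),
        "isoforms": rows,
    }
    out = ctx["outdir"] / "annotation.json"
    out.write_text(json.dumps(report, indent=2))
    return [fasta, gff, out]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "scan": _stage_scan,
    "fine_scan": _stage_fine_scan,
    "refine": _stage_refine,
    "annotate": _stage_annotate,
}


def run_all(
    config: Optional[dict] = None,
    outdir: str | Path = "cosegmap_run",
    seed: Optional[int] = None,
    from_stage: Optional[str] = None,
    to_stage: Optional[str] = None,
) -> dict:
    """Execute the pipeline and return (and write) the run manifest.

    ``seed`` overrides the cross seed; every stage's randomness derives
    from it, so identical (config, seed) pairs reproduce identical outputs.
    """
    config = {**default_config(), **(config or {})}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cross_kwargs = dict(config.get("cross", {}))
    if seed is not None:
        cross_kwargs["seed"] = int(seed)
    cross_config = CrossConfig(**cross_kwargs)
    params = ClassifierParams(**config.get("classifier", {}))

    for name in (from_stage, to_stage):
        if name is not None and name not in STAGES:
            raise PipelineError(f"unknown stage {name!r}; stages are {STAGES}")
    lo = STAGES.index(from_stage) if from_stage else 0
    hi = STAGES.index(to_stage) if to_stage else len(STAGES) - 1

    ctx = {
        "config": config,
        "cross_config": cross_config,
        "classifier_params": params,
        "outdir": outdir,
    }
    manifest: Dict = {
        "tool": "cosegmap",
        "version": __version__,
        "seed": cross_config.seed,
        "config": json.loads(json.dumps(config, default=list)),
        "stages": {},
    }
    for stage in STAGES[lo : hi + 1]:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FN[stage](ctx)
        except PipelineError:
            raise
        except Exception as exc:  # halt naming the failing stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs},
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
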