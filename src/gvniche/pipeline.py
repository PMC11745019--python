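"""End-to-end orchestration: habitats -> abundance -> qc -> niche ->
association -> functional profiles, with a machine-readable run manifest.

Every stage is a pure function of (inputs, config); rerunning with the same
config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .abundance import (
    build_abundance,
    load_contig_coverage,
    load_sample_sheet,
    presence_filter,
    size_fraction_ratio,
    upset_intersections,
)
from .association import SparsePLS, correlation_circle, pearson_matrix, relative_abundance
from .config import RunConfig
from .functions import (
    env_pathway_correlation,
    gene_abundance,
    load_annotations,
    marker_prevalence,
    pathway_matrix,
    taxon_percentages,
    ternary_proportions,
)
from .habitat import EnvProfile, cluster_depths
from .io import read_table, write_table
from .niche import classify_ecotype, zscore_matrix
from .qc import load_genome_table, marker_qc_filter, taxonomy_summary, write_qc_report
from .simulate import LakeSimulator

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("gvniche")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write all result tables plus ``manifest.json``.

    Returns the manifest dict (stage record counts, thresholds, checksums).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "gvniche_version": __version__}
    manifest: dict = {
        "gvniche_version": __version__,
        "seed": config.seed,
        "thresholds": {
            "breadth_threshold": config.breadth_threshold,
            "correlation_cutoff": config.correlation_cutoff,
            "k_habitats": config.k_habitats,
            "qc": {
                "uni56_max_exclusive": config.qc_uni56_max_exclusive,
                "gvog9_min": config.qc_gvog9_min,
                "gvog7df_max": config.qc_gvog7df_max,
            },
        },
        "abundance_basis": config.abundance_basis,
        "stages": {},
        "inputs": {},
    }

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    manifest["stages"].setdefault(name, {})["status"] = "failed"
                    raise PipelineError(name, exc) from exc
                return False

        return _Ctx()

    # ---------------------------------------------------------------- inputs
    with _stage("inputs"):
        if config.simulate is not None:
            sim = LakeSimulator(config.simulate).simulate_all()
            input_dir = outdir / "inputs"
            paths = sim.write(input_dir, seed=config.simulate.seed)
            env, sheet, coverage = sim.env, sim.sheet, sim.coverage
            genome_table, annotations, eukaryotes = (
                sim.genome_table,
                sim.annotations,
                sim.eukaryotes,
            )
            manifest["inputs"] = {k: str(v) for k, v in paths.items()}
        else:
            env = EnvProfile.from_tsv(config.env_tsv)
            sheet = load_sample_sheet(config.samples_tsv)
            coverage = load_contig_coverage(config.coverage_tsv)
            genome_table = load_genome_table(config.genomes_tsv)
            annotations = load_annotations(config.annotations_tsv) if config.annotations_tsv else None
            eukaryotes = (
                read_table(config.eukaryotes_tsv).set_index("taxon")
                if config.eukaryotes_tsv
                else None
            )
            for name in ("env_tsv", "samples_tsv", "coverage_tsv", "genomes_tsv",
                         "annotations_tsv", "eukaryotes_tsv"):
                value = getattr(config, name)
                if value:
                    manifest["inputs"][name] = {"path": value, "sha256": _sha256(Path(value))}

    # --------------------------------------------------------------- habitat
    with _stage("habitat"):
        partition = cluster_depths(env, k=config.k_habitats)
        partition.to_tsv(outdir / "habitats.tsv", **meta)
        manifest["stages"]["habitat"] = {
            "n_depths": len(env.depths),
            "k": partition.k,
            "members": {lab: partition.members(lab) for lab in partition.labels},
        }
        log.info("habitat: %d depths -> %d habitats", len(env.depths), partition.k)

    # ------------------------------------------------------------- abundance
    with _stage("abundance"):
        raw = build_abundance(coverage, sheet, basis=config.abundance_basis)
        filtered = presence_filter(raw, config.breadth_threshold)
        filtered.to_tsv(outdir / "abundance.tsv", **meta)
        write_table(
            filtered.breadth.rename_axis("genome_id").reset_index(),
            outdir / "breadth.tsv",
            metadata=meta,
        )
        ratios = size_fraction_ratio(filtered, sheet)
        write_table(ratios.rename_axis("genome_id").reset_index(), outdir / "ratios.tsv", metadata=meta)
        habitat_of_sample = {
            row.sample_id: partition.habitat_for_depth(row.depth_m) for row in sheet.itertuples()
        }
        upset = upset_intersections(filtered, habitat_of_sample)
        write_table(upset, outdir / "upset.tsv", metadata=meta)
        manifest["stages"]["abundance"] = {
            "n_genomes": len(filtered.genomes),
            "n_samples": len(filtered.samples),
            "n_present": int((filtered.values > 0).any(axis=1).sum()),
        }
        log.info(
            "abundance: %d genomes x %d samples (%s, breadth >= %.2f)",
            len(filtered.genomes), len(filtered.samples), filtered.basis, config.breadth_threshold,
        )

    # -------------------------------------------------------------------- qc
    with _stage("qc"):
        passed, failed = marker_qc_filter(
            genome_table,
            uni56_max_exclusive=config.qc_uni56_max_exclusive,
            gvog9_min=config.qc_gvog9_min,
            gvog7df_max=config.qc_gvog7df_max,
        )
        write_qc_report(passed, failed, outdir / "qc_report.tsv", **meta)
        tax = taxonomy_summary(genome_table, "order")
        write_table(tax, outdir / "taxonomy_summary.tsv", metadata=meta)
        manifest["stages"]["qc"] = {"n_pass": len(passed), "n_fail": len(failed)}
        log.info("qc: %d pass / %d fail", len(passed), len(failed))

    # ----------------------------------------------------------------- niche
    with _stage("niche"):
        z = zscore_matrix(filtered)
        calls = classify_ecotype(filtered, z, partition, sheet)
        write_table(calls, outdir / "niche_calls.tsv", metadata=meta)
        manifest["stages"]["niche"] = {
            "n_genomes": len(calls),
            "ecotype_counts": calls["ecotype"].value_counts().to_dict(),
        }
        log.info("niche: %d calls (%s)", len(calls), manifest["stages"]["niche"]["ecotype_counts"])

    # ----------------------------------------------------------- association
    with _stage("association"):
        if eukaryotes is not None:
            cellular = [
                row.sample_id for row in sheet.itertuples() if row.fraction == "cellular"
            ]
            shared = [s for s in cellular if s in eukaryotes.columns]
            gv_block = relative_abundance(filtered.values[shared])
            euk_block = relative_abundance(eukaryotes[shared])
            corr = pearson_matrix(gv_block, euk_block, cutoff=config.correlation_cutoff)
            write_table(corr, outdir / "correlations.tsv", metadata=meta)
            model = SparsePLS(
                n_components=config.spls_components,
                keep_x=config.spls_keep_x,
                keep_y=config.spls_keep_y,
            )
            results = model.fit(gv_block, euk_block)
            write_table(results.variates_frame(), outdir / "spls_variates.tsv", metadata=meta)
            circle = correlation_circle(results, gv_block, euk_block, cutoff=config.correlation_cutoff)
            write_table(circle, outdir / "corr_circle.tsv", metadata=meta)
            manifest["stages"]["association"] = {
                "n_correlated_pairs": len(corr),
                "n_retained_circle": int(circle["retained"].sum()),
                "spls_iterations": results.n_iter,
            }
            log.info("association: %d pairs over cutoff", len(corr))
        else:
            manifest["stages"]["association"] = {"skipped": "no eukaryote table"}

    # ------------------------------------------------------ function_profile
    with _stage("function_profile"):
        if annotations is not None:
            gene_ab = gene_abundance(annotations, filtered, coverage)
            pm = pathway_matrix(gene_ab, annotations)
            write_table(pm.reset_index(), outdir / "pathway_matrix.tsv", metadata=meta)
            corr = env_pathway_correlation(pm, env, sheet)
            write_table(corr.rename_axis("pathway").reset_index(), outdir / "pathway_env_corr.tsv", metadata=meta)
            tern = ternary_proportions(pm, gene_ab, annotations, calls)
            write_table(tern.reset_index(), outdir / "ternary.tsv", metadata=meta)
            grouping = calls.set_index("genome_id")["habitat"].dropna()
            prevalence = marker_prevalence(annotations, grouping, config.marker)
            write_table(prevalence, outdir / "marker_prevalence.tsv", metadata=meta)
            taxper = taxon_percentages(annotations, min_count=config.taxon_min_count)
            write_table(taxper, outdir / "taxon_percentages.tsv", metadata=meta)
            manifest["stages"]["function_profile"] = {
                "n_genes": len(gene_ab),
                "n_pathways": len(pm),
                "n_taxa": len(taxper),
            }
            log.info("functions: %d genes, %d pathways", len(gene_ab), len(pm))
        else:
            manifest["stages"]["function_profile"] = {"skipped": "no annotation table"}

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
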