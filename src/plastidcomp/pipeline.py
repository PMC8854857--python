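"""End-to-end comparative analysis: structure -> SSRs -> divergence -> dN/dS.

Reads a YAML run configuration, executes each stage, and writes the report
tables as UTF-8 TSV files ('.' decimal), plus a JSON run manifest recording
parameters so every emitted number can be reproduced by calling the owning
module directly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon import DEFAULT_FILTERS, build_codon_alignment, dnds_matrix, dnds_table
from .divergence import (
    classify_sites,
    divergence_matrix,
    hypervariable_regions,
    nucleotide_diversity,
    read_alignment,
    region_variability,
    sliding_windows,
)
from .io import CircularGenome, FeatureTable, gc_content, read_fasta, read_features
from .quadripartite import canonical_rotation, detect_quadripartite, junction_context
from .ssr import DEFAULT_THRESHOLDS, classify_ssrs, find_ssrs, ssr_summary

log = logging.getLogger("plastidcomp")


class ConfigurationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs and parameters of one comparative run."""

    fasta: list[str]
    gff: list[str]
    reference: str
    out_dir: str
    alignment: str | None = None
    min_ir_len: int = 1000
    ssr_thresholds: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    window: int = 600
    step: int = 200
    dnds_filters: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_FILTERS))
    top_k_hotspots: int = 10
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "ssr_thresholds" in raw:
            raw["ssr_thresholds"] = {int(k): int(v) for k, v in raw["ssr_thresholds"].items()}
        try:
            return cls(**raw)
        except TypeError as e:
            raise ConfigurationError(str(e)) from e


def run_all(config: RunConfig) -> dict[str, object]:
    """Execute every stage and write the report bundle; returns the results.

    Raises :class:`StageError` naming the failing stage; tables written by
    earlier stages are preserved.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    manifest = {
        "version": __version__,
        "parameters": {
            "min_ir_len": config.min_ir_len,
            "ssr_thresholds": config.ssr_thresholds,
            "window": config.window,
            "step": config.step,
            "dnds_filters": config.dnds_filters,
            "seed": config.seed,
        },
        "inputs": {"fasta": config.fasta, "gff": config.gff,
                   "alignment": config.alignment, "reference": config.reference},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn()
            except Exception as e:  # noqa: BLE001 - report the stage then re-raise
                raise StageError(name, e) from e
            manifest["stages"][name] = round(time.time() - t0, 3)
            log.info("stage %s: done in %.2fs", name, manifest["stages"][name])
        return deco

    genomes: dict[str, CircularGenome] = {}
    tables: dict[str, FeatureTable] = {}
    partitions = {}

    @stage("load")
    def _load():
        for path in config.fasta:
            for g in read_fasta(path):
                genomes[g.id] = g
        if config.reference not in genomes:
            raise ConfigurationError(
                f"reference {config.reference!r} not among genome ids {sorted(genomes)}"
            )
        for path in config.gff:
            for gid, g in genomes.items():
                try:
                    tables[gid] = read_features(path, g)
                except LookupError:
                    continue
        missing = sorted(set(genomes) - set(tables))
        if missing:
            raise ConfigurationError(f"no annotations found for genomes: {missing}")

    @stage("quadripartite")
    def _quad():
        rows = []
        ctx_rows = []
        for gid, g in genomes.items():
            part = detect_quadripartite(g, min_ir_len=config.min_ir_len)
            partitions[gid] = part
            rows.append(
                {
                    "genome": gid,
                    "size_bp": g.length,
                    "LSC_bp": part.lsc_len,
                    "SSC_bp": part.ssc_len,
                    "IR_bp": part.irb_len,
                    "GC_pct": round(100 * gc_content(g), 1),
                    "JLB": part.jlb,
                    "JSB": part.jsb,
                    "JSA": part.jsa,
                    "JLA": part.jla,
                }
            )
            for ctx in junction_context(part, tables[gid]):
                ctx_rows.append({"genome": gid, **ctx.__dict__})
        pd.DataFrame(rows).to_csv(out / "table1_structure.tsv", sep="\t", index=False)
        pd.DataFrame(ctx_rows).to_csv(out / "junction_context.tsv", sep="\t", index=False)
        results["partitions"] = partitions

    @stage("ssr")
    def _ssr():
        loci_by_genome = {}
        loci_rows = []
        for gid, g in genomes.items():
            loci = find_ssrs(g, config.ssr_thresholds)
            classify_ssrs(loci, partitions[gid], tables[gid])
            loci_by_genome[gid] = loci
            for x in loci:
                loci_rows.append(
                    {
                        "genome": gid,
                        "motif": x.motif,
                        "canonical": x.canonical,
                        "unit_len": x.unit_len,
                        "copies": x.copies,
                        "start": x.start,
                        "end": x.end,
                        "structural_region": x.structural_region,
                        "functional_region": x.functional_region,
                    }
                )
        summary = ssr_summary(loci_by_genome, partitions)
        pd.DataFrame(loci_rows).to_csv(out / "ssr_loci.tsv", sep="\t", index=False)
        summary.per_genome.to_csv(out / "table2_ssr_regions.tsv", sep="\t")
        summary.unit_counts.to_csv(out / "ssr_unit_classes.tsv", sep="\t")
        pd.Series(summary.density_per_kb, name="ssr_per_kb").to_csv(
            out / "ssr_density.tsv", sep="\t"
        )
        results["ssr_summary"] = summary
        results["ssr_loci"] = loci_by_genome

    @stage("divergence")
    def _div():
        if config.alignment is None:
            raise ConfigurationError(
                "no alignment provided: set 'alignment' in the config "
                "(produced externally, e.g. with MAFFT, or by the simulator)"
            )
        aln = read_alignment(config.alignment, reference_id=config.reference)
        ref_part = partitions[config.reference]
        sites = classify_sites(aln, partition=ref_part)
        div = nucleotide_diversity(aln)
        rows = [
            {
                "region": name,
                "sites": sc.total_columns,
                "gap_free": sc.gap_free_columns,
                "variable": sc.variable_sites,
                "informative": sc.parsimony_informative_sites,
                "informative_pct_of_variable": round(
                    100 * sc.parsimony_informative_sites / sc.variable_sites, 2
                )
                if sc.variable_sites
                else 0.0,
            }
            for name, sc in [("genome", sites)] + [
                (k, v) for k, v in sites.per_region.items()
            ]
        ]
        pd.DataFrame(rows).to_csv(out / "table3_sites.tsv", sep="\t", index=False)
        windows = sliding_windows(aln, config.window, config.step)
        pd.DataFrame(
            [
                {"start": w.start, "end": w.end, "midpoint": w.midpoint, "pi": w.pi}
                for w in windows
            ]
        ).to_csv(out / "window_pi.tsv", sep="\t", index=False)
        hot = hypervariable_regions(
            windows, aln, tables[config.reference], k=config.top_k_hotspots
        )
        pd.DataFrame(
            [
                {
                    "start": h.start,
                    "end": h.end,
                    "peak_pi": h.peak_pi,
                    "features": ";".join(h.features),
                }
                for h in hot
            ]
        ).to_csv(out / "hypervariable_regions.tsv", sep="\t", index=False)
        divergence_matrix(aln).to_csv(out / "table4_indels_substitutions.tsv", sep="\t")
        rv = region_variability(aln, tables[config.reference])
        rv.to_csv(out / "region_variability.tsv", sep="\t", index=False)
        results.update(
            sites=sites, diversity=div, windows=windows, hotspots=hot,
            region_variability=rv, alignment=aln,
        )
        manifest["diversity"] = {"pi": div.pi, "theta": div.theta, "S": div.S, "L": div.L}

    @stage("dnds")
    def _dnds():
        codon_aln = build_codon_alignment(genomes, tables)
        results["codon_alignment"] = codon_aln
        if len(codon_aln.genes_used) == 0:
            log.warning("no shared genes; skipping dN/dS")
            return
        rates = dnds_matrix(codon_aln, config.dnds_filters)
        dnds_table(rates).to_csv(out / "table5_dnds.tsv", sep="\t")
        pd.DataFrame([r.__dict__ for r in rates]).to_csv(
            out / "dnds_pairs.tsv", sep="\t", index=False
        )
        results["dnds"] = rates
        manifest["genes_used"] = codon_aln.genes_used
        manifest["genes_excluded"] = codon_aln.genes_excluded

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
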