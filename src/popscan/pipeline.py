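"""Stage orchestration behind the command-line interface.

``run_pipeline`` composes the library modules into the standard analysis:
load + filter the VCF, windowed diversity/differentiation, LD decay,
sex-chromosome vs autosome comparison, local-PCA inversion scan, and the
composite sweep scan.  Every output is a TSV with a header or JSON; a run
log records versions, the seed and all thresholds.  A stage failure leaves
partial outputs plus a ``FAILED`` marker naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import GenotypeMatrix, make_windows
from .io import filter_sites, read_chrom_lengths, read_intervals, read_popmap, read_vcf
from .localpca import scan_genome
from .stats import compare_chromosome_groups, ld_decay, window_stats_table
from .sweep import run_sweep_scan

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Structured configuration for one pipeline run."""

    vcf: str
    popmap: str
    chrom_lengths: str
    outdir: str
    genes: str | None = None
    annotations: str | None = None
    term_map: str | None = None  # JSON/YAML gene -> [terms]
    # windows
    window_size: int = 50_000
    window_step: int = 10_000
    # site filters
    max_missing: float = 0.10
    min_depth: float | None = 4
    max_depth: float | None = 500
    # sweep scan
    scan_quantile: float = 0.05
    maf_min: float = 0.05
    differential_mode: str = "both"
    # local PCA
    snps_per_window: int = 100
    pca_k: int = 2
    mds_axes: int = 2
    threshold_mads: float = 4.0
    min_outlier_windows: int = 3
    # LD
    ld_max_dist: int = 50_000
    ld_bin_width: int = 100
    # stage toggles
    run_localpca: bool = True
    # population roles
    focal_pop: str | None = None
    refuge_pops: tuple[str, str] | None = None
    z_chrom: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("refuge_pops"), list):
            raw["refuge_pops"] = tuple(raw["refuge_pops"])
        return cls(**raw)

    def validate(self, popmap: Mapping[str, str]) -> None:
        pops = set(popmap.values())
        for role, name in (
            ("focal_pop", self.focal_pop),
            ("refuge_pops[0]", self.refuge_pops[0] if self.refuge_pops else None),
            ("refuge_pops[1]", self.refuge_pops[1] if self.refuge_pops else None),
        ):
            if name is not None and name not in pops:
                raise ValueError(f"{role} {name!r} is not a population in the popmap")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage; returns the mapping of output names to paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "validate"
    try:
        popmap = read_popmap(config.popmap)
        config.validate(popmap)
        lengths = read_chrom_lengths(config.chrom_lengths)

        stage = "load"
        gm = read_vcf(config.vcf, popmap, annotations=config.annotations)
        gm, filter_report = filter_sites(
            gm,
            max_missing=config.max_missing,
            min_depth=config.min_depth,
            max_depth=config.max_depth,
        )
        genes = read_intervals(config.genes) if config.genes else None

        stage = "stats"
        windows = make_windows(lengths, config.window_size, config.window_step)
        stats = window_stats_table(gm, windows)
        outputs["window_stats"] = outdir / "window_stats.tsv"
        _write_tsv(stats, outputs["window_stats"])
        for pop in gm.population_names:
            curve = ld_decay(
                gm, pop, max_dist=config.ld_max_dist, bin_width=config.ld_bin_width
            )
            frame = pd.DataFrame(
                {
                    "dist_bp": curve.bin_mids,
                    "mean_r2": curve.mean_r2,
                    "n_pairs": curve.counts,
                    "smoothed_r2": curve.smoothed_r2,
                }
            )
            key = f"ld_decay_{pop}"
            outputs[key] = outdir / f"ld_decay_{pop}.tsv"
            _write_tsv(frame, outputs[key])
            half = curve.half_max_bp
            (outdir / f"ld_half_max_{pop}.json").write_text(
                json.dumps({"population": pop, "half_max_bp": half})
            )
        if config.z_chrom is not None:
            autosomes = [c for c in lengths if c != config.z_chrom]
            reports = []
            for pop in gm.population_names:
                rep = compare_chromosome_groups(
                    stats, [config.z_chrom], autosomes, f"pi_{pop}"
                )
                rep["comparison"] = f"pi_{pop}: Z vs autosomes"
                reports.append(rep)
            outputs["chromosome_comparison"] = outdir / "chromosome_comparison.json"
            outputs["chromosome_comparison"].write_text(
                json.dumps(reports, default=str, indent=1)
            )

        stage = "localpca"
        if config.run_localpca:
            result, mds_by_chrom, regions, calls = scan_genome(
                gm,
                snps_per_window=config.snps_per_window,
                k=config.pca_k,
                n_axes=config.mds_axes,
                threshold_mads=config.threshold_mads,
                min_windows=config.min_outlier_windows,
                seed=config.seed,
            )
        else:
            result, mds_by_chrom, calls = None, {}, []
        mds_rows = []
        for chrom, mds in mds_by_chrom.items():
            idx = result.chrom_indices(chrom)
            sub = result.windows.iloc[idx]
            for local_i, (_, row) in enumerate(sub.iterrows()):
                rec = {"chrom": chrom, "start": row["start"], "end": row["end"]}
                for ax in range(mds.shape[1]):
                    rec[f"mds{ax + 1}"] = mds[local_i, ax]
                mds_rows.append(rec)
        if config.run_localpca:
            outputs["local_pca_mds"] = outdir / "local_pca_mds.tsv"
            _write_tsv(pd.DataFrame(mds_rows), outputs["local_pca_mds"])
        inv_payload = []
        for reg, call, ver in calls:
            inv_payload.append(
                {
                    "region": f"{reg.chrom}:{reg.start}-{reg.end}",
                    "mds_axis": reg.axis + 1,
                    "success": call.success,
                    "reason": call.reason,
                    "genotypes": (
                        call.genotype_labels.to_dict() if call.success else None
                    ),
                    "cluster_het": (
                        [float(x) for x in call.cluster_het]
                        if call.cluster_het is not None
                        else None
                    ),
                    "ld_verification": (
                        {
                            "performed": ver.performed,
                            "passes": ver.passes,
                            "mean_r2_all": ver.mean_r2_all,
                            "mean_r2_noncarrier": ver.mean_r2_noncarrier,
                            "background_all": ver.background_all,
                            "background_noncarrier": ver.background_noncarrier,
                        }
                        if ver is not None
                        else None
                    ),
                }
            )
        if config.run_localpca:
            outputs["inversions"] = outdir / "inversions.json"
            outputs["inversions"].write_text(json.dumps(inv_payload, indent=1))

        stage = "sweepscan"
        if config.focal_pop and config.refuge_pops:
            term_map = None
            if config.term_map:
                text = Path(config.term_map).read_text()
                term_map = (
                    json.loads(text)
                    if config.term_map.endswith(".json")
                    else yaml.safe_load(text)
                )
            cand = run_sweep_scan(
                gm,
                stats,
                config.focal_pop,
                config.refuge_pops,
                genes=genes,
                term_map=term_map,
                q=config.scan_quantile,
                maf_min=config.maf_min,
                mode=config.differential_mode,
            )
            outputs["sweep_regions"] = outdir / "sweep_regions.tsv"
            _write_tsv(cand.regions, outputs["sweep_regions"])
            outputs["sweep_snps"] = outdir / "sweep_outlier_snps.tsv"
            _write_tsv(cand.outlier_snps, outputs["sweep_snps"])
            outputs["sweep_genes"] = outdir / "sweep_candidate_genes.tsv"
            _write_tsv(cand.candidate_genes, outputs["sweep_genes"])
            if cand.enrichment is not None:
                outputs["sweep_enrichment"] = outdir / "sweep_enrichment.tsv"
                _write_tsv(cand.enrichment, outputs["sweep_enrichment"])

        stage = "runlog"
        runlog = {
            "popscan_version": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "seed": config.seed,
            "filter_report": filter_report,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(config).items()
            },
        }
        outputs["run_log"] = outdir / "run_log.json"
        outputs["run_log"].write_text(json.dumps(runlog, indent=1))
    except Exception as exc:  # noqa: BLE001 - marker file then re-raise with stage
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return outputs
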