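"""End-to-end pipeline: panel -> QC -> association -> power -> PRS -> survival.

``run_pipeline`` is a pure function of (inputs, config, seed): rerunning
with the same configuration reproduces the output bundle byte for byte.
Every stage failure is re-raised with the stage name attached.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from . import __version__
from .association import association_scan, results_to_frame
from .cohort import (
    assemble_cohort,
    read_genotype_table,
    read_genotypes_vcf,
    read_phenotypes,
)
from .errors import VtePanelError
from .panel import bundled_panel, load_panel
from .power import detectable_or_grid
from .prs import WeightSet, compute_prs, median_split, or_by_prs_bin, standardize_prs
from .survival import fits_to_frame, recurrence_analysis


class StageError(VtePanelError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    genotypes_path: str
    phenotypes_path: str
    outdir: str
    panel_path: str | None = None  # None -> bundled Thai VTE panel
    call_rate_min: float = 0.95
    hwe_alpha: float = 0.05
    weight_source: Literal["literature", "cohort"] = "literature"
    missing_policy: Literal["zero", "mean_dosage_controls"] = "mean_dosage_controls"
    prs_bin_edges: Sequence[float] | None = None  # None -> control z quartiles
    survival_cap: float = 24.0
    power_eaf_grid: Sequence[float] = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
    adjust_p_threshold: float = 0.05
    seed: int = 0


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str, **kwargs) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vtepanel {__version__}\tconfig={config_hash}\n")
        df.to_csv(fh, sep="\t", **kwargs)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns artifact paths."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_dict.pop("outdir")  # destination is not analysis provenance
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    artifacts: dict[str, str] = {}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except VtePanelError:
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise StageError(name, exc) from exc

        return deco

    @stage("load")
    def loaded():
        panel = (
            load_panel(config.panel_path) if config.panel_path else bundled_panel()
        )
        gpath = str(config.genotypes_path)
        if gpath.endswith((".vcf", ".vcf.gz", ".bcf")):
            genotypes = read_genotypes_vcf(gpath, panel)
        else:
            genotypes = read_genotype_table(gpath, panel)
        subjects = read_phenotypes(config.phenotypes_path)
        return assemble_cohort(panel, genotypes, subjects)

    cohort = loaded

    @stage("qc")
    def qc_result():
        from .qc import apply_qc

        filtered, report = apply_qc(cohort, config.call_rate_min, config.hwe_alpha)
        report.to_tsv(outdir / "qc_report.tsv")
        return filtered

    cohort_qc = qc_result
    artifacts["qc_report"] = str(outdir / "qc_report.tsv")

    @stage("association")
    def scan_results():
        allelic = association_scan(
            cohort_qc, ("allelic",), adjust=True,
            adjust_p_threshold=config.adjust_p_threshold,
        )
        models = association_scan(
            cohort_qc, ("dominant", "recessive"), adjust=True,
            adjust_p_threshold=config.adjust_p_threshold,
        )
        _write_tsv(
            results_to_frame(allelic, cohort_qc.panel),
            outdir / "association_allelic.tsv", cfg_hash, index=False,
        )
        _write_tsv(
            results_to_frame(models, cohort_qc.panel),
            outdir / "genetic_models.tsv", cfg_hash, index=False,
        )
        return allelic

    allelic_results = scan_results
    artifacts["association_allelic"] = str(outdir / "association_allelic.tsv")
    artifacts["genetic_models"] = str(outdir / "genetic_models.tsv")

    @stage("power")
    def power_table():
        grid = detectable_or_grid(
            cohort_qc.n_cases, cohort_qc.n_controls, list(config.power_eaf_grid)
        )
        _write_tsv(grid, outdir / "power_grid.tsv", cfg_hash, index=False)
        return grid

    _ = power_table
    artifacts["power_grid"] = str(outdir / "power_grid.tsv")

    @stage("prs")
    def prs_result():
        cohort_ors = None
        if config.weight_source == "cohort":
            cohort_ors = {r.rsid: r.or_estimate for r in allelic_results}
        weights = WeightSet.from_panel(
            cohort_qc.panel, config.weight_source, cohort_ors
        )
        genotyped = set(cohort_qc.genotypes.rsids)
        weights.betas = {r: b for r, b in weights.betas.items() if r in genotyped}
        raw = compute_prs(
            cohort_qc.genotypes, weights, config.missing_policy,
            control_ids=cohort_qc.control_ids,
        )
        prs = standardize_prs(raw, cohort_qc.control_ids)
        median_split(prs)
        status = {s.subject_id: s.status for s in cohort_qc.subjects}
        bins = or_by_prs_bin(prs, status, config.prs_bin_edges)
        _write_tsv(prs.scores, outdir / "prs_subjects.tsv", cfg_hash)
        _write_tsv(bins, outdir / "prs_bins.tsv", cfg_hash, index=False)
        return prs

    prs = prs_result
    artifacts["prs_subjects"] = str(outdir / "prs_subjects.tsv")
    artifacts["prs_bins"] = str(outdir / "prs_bins.tsv")

    @stage("survival")
    def survival_summary():
        fits = recurrence_analysis(cohort_qc, prs, cap=config.survival_cap)
        _write_tsv(
            fits_to_frame(fits), outdir / "survival_summary.tsv", cfg_hash,
            index=False,
        )
        for name, fit in fits.items():
            for group, km in fit.km_tables.items():
                _write_tsv(
                    km, outdir / f"km_{name}_{group}.tsv", cfg_hash, index=False
                )
        return fits

    _ = survival_summary
    artifacts["survival_summary"] = str(outdir / "survival_summary.tsv")

    manifest = {
        "tool": "vtepanel",
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": cfg_hash,
        "artifacts": sorted(artifacts),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    artifacts["manifest"] = str(outdir / "manifest.json")
    return artifacts
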