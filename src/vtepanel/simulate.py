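"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so the whole
pipeline is testable without patient data: Hardy-Weinberg genotypes at the
observed control effect-allele frequencies, case genotypes drawn at the
observed case frequencies (marginal emulation; a logistic-selection mode
exists for covariate-confounded scenarios), demographics matching the
study cohort (age median 44.5 years, IQR 32-57; BMI 24.5 +/- 4.0 kg/m2;
55% male), a 70.5% provoked / 29.5% unprovoked case split, and exponential
recurrence times over a 24-month window with a PRS-group hazard ratio near
the reported 3.53 in the unprovoked stratum and 1.0 in the provoked one.

What it deliberately does not emulate: linkage disequilibrium between panel
variants, population structure, and any non-exponential hazard shape.

A single integer seed drives a splittable generator; every draw is
reproducible from (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    Cohort,
    GenotypeMatrix,
    RecurrenceRecord,
    Subject,
    assemble_cohort,
    write_phenotypes,
)
from .errors import UsageError, ValidationError
from .panel import Panel, bundled_eafs, bundled_panel, write_panel
from .prs import WeightSet, compute_prs


@dataclass
class SimulationConfig:
    """Study-shaped defaults; override any field for designed experiments."""

    n_case: int = 122
    n_control: int = 87
    panel: Panel | None = None  # default: bundled 38-variant panel
    control_eafs: Mapping[str, float] | None = None  # default: observed controls
    case_eafs: Mapping[str, float] | None = None  # default: observed cases
    case_ors: Mapping[str, float] | None = None  # alternative to case_eafs
    age_median: float = 44.5
    age_iqr: tuple[float, float] = (32.0, 57.0)
    bmi_mean: float = 24.5
    bmi_sd: float = 4.0
    male_fraction: float = 0.549
    diagnosis_fractions: tuple[float, float, float] = (0.795, 0.131, 0.074)
    provoked_fraction: float = 0.705
    baseline_monthly_hazard: float = 0.028  # ~49% 2-year recurrence at HR 1
    hr_provoked: float = 1.0
    hr_unprovoked: float = 3.53
    recurrence_cap: float = 24.0
    missing_call_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case_eafs is not None and self.case_ors is not None:
            raise UsageError("provide case EAFs or case ORs, not both")
        if self.panel is None:
            self.panel = bundled_panel()
            observed = bundled_eafs()
            if self.control_eafs is None:
                self.control_eafs = observed["eaf_control"].to_dict()
            if self.case_eafs is None and self.case_ors is None:
                self.case_eafs = observed["eaf_case"].to_dict()
        if self.control_eafs is None:
            raise UsageError("control EAFs required with a custom panel")
        if self.case_eafs is None and self.case_ors is None:
            raise UsageError("case EAFs or case ORs required with a custom panel")
        for name, m in (("control", self.control_eafs), ("case", self.case_eafs)):
            if m is None:
                continue
            bad = {r: p for r, p in m.items() if not 0 <= p <= 1}
            if bad:
                raise ValidationError(f"{name} EAFs outside [0,1]: {bad}")
        if self.baseline_monthly_hazard <= 0:
            raise ValidationError("baseline hazard must be positive")
        if not 0 <= self.missing_call_rate < 1:
            raise ValidationError("missing-call rate must lie in [0,1)")


def simulate_genotypes(
    n: int, eaf: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Dosages for n subjects at one Hardy-Weinberg site with the given EAF."""
    if not 0 <= eaf <= 1:
        raise ValidationError(f"EAF {eaf} outside [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = [(1 - eaf) ** 2, 2 * eaf * (1 - eaf), eaf**2]
    return rng.choice([0.0, 1.0, 2.0], size=n, p=probs)


def _case_eaf_from_or(control_eaf: float, or_alt: float) -> float:
    odds = or_alt * control_eaf / (1 - control_eaf)
    return odds / (1 + odds)


def generate_cohort(config: SimulationConfig) -> tuple[Cohort, dict]:
    """Draw a full synthetic cohort plus its ground-truth record."""
    panel = config.panel
    rng_geno, rng_cov, rng_recur, rng_miss = np.random.default_rng(
        config.seed
    ).spawn(4)

    case_ids = [f"case_{i+1:04d}" for i in range(config.n_case)]
    control_ids = [f"ctrl_{i+1:04d}" for i in range(config.n_control)]
    subject_ids = case_ids + control_ids

    true_case_eafs: dict[str, float] = {}
    dosage = np.empty((len(panel), len(subject_ids)))
    for j, v in enumerate(panel):
        p_ctrl = float(config.control_eafs[v.rsid])
        if config.case_eafs is not None:
            p_case = float(config.case_eafs[v.rsid])
        else:
            or_alt = float(config.case_ors.get(v.rsid, 1.0))
            if not 0 < p_ctrl < 1:
                p_case = p_ctrl  # monomorphic: OR cannot move it
            else:
                p_case = _case_eaf_from_or(p_ctrl, or_alt)
        true_case_eafs[v.rsid] = p_case
        dosage[j, : config.n_case] = simulate_genotypes(
            config.n_case, p_case, rng_geno
        )
        dosage[j, config.n_case:] = simulate_genotypes(
            config.n_control, p_ctrl, rng_geno
        )

    # PRS group must be fixed before masking calls, from the complete genotypes
    genotypes_complete = GenotypeMatrix(panel.rsids, subject_ids, dosage.copy())
    weights = WeightSet.from_panel(panel, "literature")
    raw = compute_prs(genotypes_complete, weights, missing_policy="zero")["raw"]
    high_prs = (raw > raw.median()).to_dict()

    if config.missing_call_rate > 0:
        mask = rng_miss.random(dosage.shape) < config.missing_call_rate
        dosage[mask] = np.nan
    genotypes = GenotypeMatrix(panel.rsids, subject_ids, dosage)

    age_sd = (config.age_iqr[1] - config.age_iqr[0]) / 1.349
    subjects: list[Subject] = []
    diag_labels = ("DVT", "PE", "DVT_PE")
    for sid in subject_ids:
        is_case = sid.startswith("case")
        age = float(np.clip(rng_cov.normal(config.age_median, age_sd), 18, 95))
        bmi = float(np.clip(rng_cov.normal(config.bmi_mean, config.bmi_sd), 15, 45))
        sex = "male" if rng_cov.random() < config.male_fraction else "female"
        if not is_case:
            subjects.append(Subject(sid, "control", age, sex, bmi))
            continue
        diagnosis = diag_labels[
            rng_cov.choice(3, p=np.asarray(config.diagnosis_fractions) /
                           sum(config.diagnosis_fractions))
        ]
        risk_class = (
            "provoked" if rng_cov.random() < config.provoked_fraction else "unprovoked"
        )
        hr = config.hr_provoked if risk_class == "provoked" else config.hr_unprovoked
        hazard = config.baseline_monthly_hazard * (hr if high_prs[sid] else 1.0)
        t = float(rng_recur.exponential(1.0 / hazard))
        if t > config.recurrence_cap:
            followup = RecurrenceRecord(time=config.recurrence_cap, event=False)
        else:
            followup = RecurrenceRecord(time=round(t, 2), event=True)
        subjects.append(
            Subject(sid, "case", age, sex, bmi, diagnosis, risk_class, followup)
        )

    cohort = assemble_cohort(panel, genotypes, subjects)
    truth = {
        "seed": config.seed,
        "n_case": config.n_case,
        "n_control": config.n_control,
        "true_control_eafs": {r: float(config.control_eafs[r]) for r in panel.rsids},
        "true_case_eafs": true_case_eafs,
        "hr_provoked": config.hr_provoked,
        "hr_unprovoked": config.hr_unprovoked,
        "baseline_monthly_hazard": config.baseline_monthly_hazard,
        "missing_call_rate": config.missing_call_rate,
        "high_prs_truth": {s: bool(h) for s, h in high_prs.items()},
    }
    return cohort, truth


def _vcf_alleles(effect: str, reference: str) -> tuple[str, str]:
    """Panel alleles -> (REF, ALT) with an anchor base for deletion tokens."""
    if reference == "-":
        return "N", "N" + effect
    if effect == "-":
        return "N" + reference, "N"
    return reference, effect


def write_vcf(cohort: Cohort, path: str | Path) -> None:
    """Write cohort genotypes as a plain VCF 4.2 (ALT = panel effect allele)."""
    gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=vtepanel {__version__} synthetic cohort\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.genotypes.subject_ids)
            + "\n"
        )
        for j, rsid in enumerate(cohort.genotypes.rsids):
            v = cohort.panel.get(rsid)
            ref, alt = _vcf_alleles(v.effect_allele, v.reference_allele)
            gts = [
                "./." if math.isnan(d) else gt_for[d]
                for d in cohort.genotypes.dosage[j]
            ]
            fh.write(
                f"1\t{(j + 1) * 100}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_fixture(cohort: Cohort, outdir: str | Path, truth: dict | None = None) -> dict:
    """Write cohort.vcf + phenotypes.tsv + panel.tsv (+ truth.json) to a dir.

    Files round-trip through the cohort readers to an equal cohort; with a
    fixed seed the files are byte-identical across runs.
    """
    if not cohort.subjects:
        raise ValidationError("empty cohort")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "cohort.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
        "panel": outdir / "panel.tsv",
    }
    write_vcf(cohort, paths["vcf"])
    write_phenotypes(cohort.subjects, paths["phenotypes"])
    write_panel(cohort.panel, paths["panel"])
    if truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return {k: str(p) for k, p in paths.items()}
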