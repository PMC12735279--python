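"""Cohort assembly: genotype and phenotype I/O oriented to the active panel.

Genotypes are stored as effect-allele dosage — the per-subject count
(0/1/2) of the panel's designated effect allele — with ``NaN`` marking
missing calls.  VCF input is re-oriented automatically when the file's
REF/ALT are flipped relative to the panel.  Missing dosages are never
imputed here; each downstream stage declares its own missing-data policy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .panel import Panel, VariantDef

logger = logging.getLogger(__name__)

RECURRENCE_CAP_MONTHS = 24.0


@dataclass(frozen=True)
class RecurrenceRecord:
    """Time from anticoagulant discontinuation to recurrence or censoring.

    ``time`` is in months and is truncated to the 2-year observation window
    by the survival stage; ``event`` is True for a confirmed recurrence.
    """

    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValidationError(f"negative follow-up time: {self.time}")


@dataclass(frozen=True)
class Subject:
    subject_id: str
    status: Literal["case", "control"]
    age: float
    sex: Literal["male", "female"]
    bmi: float
    diagnosis: Literal["DVT", "PE", "DVT_PE"] | None = None
    risk_class: Literal["provoked", "unprovoked"] | None = None
    followup: RecurrenceRecord | None = None

    def __post_init__(self) -> None:
        if self.status == "control" and (
            self.diagnosis is not None
            or self.risk_class is not None
            or self.followup is not None
        ):
            raise ValidationError(
                f"{self.subject_id}: diagnosis/risk_class/followup only valid for cases"
            )
        if self.age < 0:
            raise ValidationError(f"{self.subject_id}: negative age")
        if self.bmi <= 0:
            raise ValidationError(f"{self.subject_id}: non-positive BMI")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class GenotypeMatrix:
    """Effect-allele dosage matrix, variants x subjects; NaN = missing call."""

    rsids: list[str]
    subject_ids: list[str]
    dosage: np.ndarray  # float, shape (len(rsids), len(subject_ids))

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.rsids), len(self.subject_ids)):
            raise ValidationError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.rsids)} variants x {len(self.subject_ids)} subjects"
            )
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = np.argwhere(~valid)[0]
            raise ValidationError(
                f"dosage for {self.rsids[bad[0]]}/{self.subject_ids[bad[1]]} "
                f"is {self.dosage[tuple(bad)]}; must be 0, 1, 2 or missing"
            )

    def row(self, rsid: str) -> np.ndarray:
        return self.dosage[self.rsids.index(rsid)]

    def subset_subjects(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.subject_ids.index(s) for s in ids]
        return GenotypeMatrix(list(self.rsids), list(ids), self.dosage[:, idx])

    def drop_variants(self, rsids: Iterable[str]) -> "GenotypeMatrix":
        drop = set(rsids)
        keep = [i for i, r in enumerate(self.rsids) if r not in drop]
        return GenotypeMatrix(
            [self.rsids[i] for i in keep], list(self.subject_ids), self.dosage[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.rsids, columns=self.subject_ids)

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.rsids == other.rsids
            and self.subject_ids == other.subject_ids
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass
class Cohort:
    panel: Panel
    genotypes: GenotypeMatrix
    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = {s.subject_id for s in self.subjects}
        extra = [s for s in self.genotypes.subject_ids if s not in ids]
        if extra:
            raise ValidationError(
                f"genotyped subjects missing from phenotypes: {', '.join(extra[:5])}"
            )
        panel_rsids = set(self.panel.rsids)
        alien = [r for r in self.genotypes.rsids if r not in panel_rsids]
        if alien:
            raise ValidationError(
                f"genotyped variants absent from panel: {', '.join(alien[:5])}"
            )

    @property
    def n_cases(self) -> int:
        return sum(s.is_case for s in self.subjects)

    @property
    def n_controls(self) -> int:
        return sum(not s.is_case for s in self.subjects)

    @property
    def case_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if s.is_case]

    @property
    def control_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects if not s.is_case]

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def dosages(self, rsid: str, ids: Sequence[str] | None = None) -> np.ndarray:
        """Dosage vector for one variant, optionally restricted to ``ids``."""
        row = self.genotypes.row(rsid)
        if ids is None:
            return row
        idx = [self.genotypes.subject_ids.index(s) for s in ids]
        return row[idx]

    def covariate_frame(self) -> pd.DataFrame:
        """Regression covariates: age (years), sex (male=1), BMI (kg/m2)."""
        rows = {
            s.subject_id: {
                "age": s.age,
                "sex": 1.0 if s.sex == "male" else 0.0,
                "bmi": s.bmi,
                "status": 1.0 if s.is_case else 0.0,
            }
            for s in self.subjects
        }
        return pd.DataFrame.from_dict(rows, orient="index").loc[
            self.genotypes.subject_ids
        ]


def _strip_anchor(ref: str, alt: str) -> tuple[str, str]:
    """Reduce a REF/ALT pair to the panel's minimal-allele convention.

    Shared leading bases (the VCF indel anchor) are stripped; an allele that
    empties out becomes the deletion token ``"-"``.
    """
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], "-"
    elif len(alt) > 1 and len(ref) == 1 and alt[0] == ref[0]:
        ref, alt = "-", alt[1:]
    return ref, alt


def _orientation(variant: VariantDef, vcf_ref: str, vcf_alt: str) -> str:
    """'alt' if the VCF ALT is the panel effect allele, 'ref' if flipped."""
    for r, a in ((vcf_ref, vcf_alt), _strip_anchor(vcf_ref, vcf_alt)):
        if (a, r) == (variant.effect_allele, variant.reference_allele):
            return "alt"
        if (r, a) == (variant.effect_allele, variant.reference_allele):
            return "ref"
    warnings.warn(
        f"{variant.rsid}: VCF alleles {vcf_ref}/{vcf_alt} do not match panel "
        f"{variant.effect_allele}/{variant.reference_allele}; assuming ALT is "
        "the effect allele"
    )
    return "alt"


def read_genotypes_vcf(path: str | Path, panel: Panel) -> GenotypeMatrix:
    """Read effect-allele dosages from a VCF with GT fields.

    Variants are matched by the ID column (the panel is rsID-keyed); sites
    whose REF/ALT orientation is flipped relative to the panel are
    re-oriented (dosage = 2 - alt count) with a logged note.  Panel variants
    absent from the file come back all-missing with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    n = len(subject_ids)
    rows: dict[str, np.ndarray] = {}
    for rec in vcf:
        if rec.ID is None or rec.ID not in panel:
            continue
        variant = panel.get(rec.ID)
        alt = rec.ALT[0] if rec.ALT else ""
        orient = _orientation(variant, rec.REF, alt)
        if orient == "ref":
            logger.info("%s: flipped orientation relative to panel", rec.ID)
        dosage = np.full(n, np.nan)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            if not alleles or any(a < 0 for a in alleles):
                continue
            alt_count = float(sum(1 for a in alleles if a == 1))
            dosage[i] = alt_count if orient == "alt" else len(alleles) - alt_count
        rows[rec.ID] = dosage
    vcf.close()
    dosage = np.full((len(panel), n), np.nan)
    for j, v in enumerate(panel):
        if v.rsid in rows:
            dosage[j] = rows[v.rsid]
        else:
            warnings.warn(f"{v.rsid}: not present in {path}; recorded as all-missing")
    return GenotypeMatrix(panel.rsids, subject_ids, dosage)


def read_genotype_table(path: str | Path, panel: Panel) -> GenotypeMatrix:
    """Read a dosage TSV: rows = rsIDs, columns = subjects, cells 0/1/2/NA."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: cell ({df.index[i]}, {df.columns[j]}) = {values[i, j]!r}; "
            "dosage must be 0, 1, 2 or NA"
        )
    alien = [r for r in df.index if r not in panel]
    if alien:
        raise ValidationError(
            f"{path}: rsIDs not in panel: {', '.join(map(str, alien[:5]))}"
        )
    return GenotypeMatrix(list(df.index), [str(c) for c in df.columns], values)


def write_genotype_table(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = genotypes.to_frame()
    df.index.name = "rsid"
    df.to_csv(path, sep="\t", float_format="%.0f", na_rep="NA")


_PHENO_REQUIRED = ("subject_id", "status", "age", "sex", "bmi")


def read_phenotypes(path: str | Path) -> list[Subject]:
    """Read the phenotype TSV into :class:`Subject` records.

    Required columns: subject_id, status, age, sex, bmi.  Optional:
    diagnosis, risk_class, time_months, event (the latter two populate the
    recurrence follow-up for cases).
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"subject_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    subjects = []
    for _, row in df.iterrows():
        followup = None
        time = row.get("time_months")
        event = row.get("event")
        has_time = time is not None and not pd.isna(time)
        has_event = event is not None and not pd.isna(event)
        if has_event and not has_time:
            raise ValidationError(
                f"{row['subject_id']}: event flag without a follow-up time"
            )
        if has_time:
            followup = RecurrenceRecord(
                time=float(time), event=bool(int(event)) if has_event else False
            )

        def _opt(col: str):
            v = row.get(col)
            return None if v is None or pd.isna(v) else str(v)

        subjects.append(
            Subject(
                subject_id=str(row["subject_id"]),
                status=str(row["status"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                bmi=float(row["bmi"]),
                diagnosis=_opt("diagnosis"),
                risk_class=_opt("risk_class"),
                followup=followup,
            )
        )
    return subjects


def write_phenotypes(subjects: Sequence[Subject], path: str | Path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "status": s.status,
                "age": repr(s.age),  # shortest round-trip float form
                "sex": s.sex,
                "bmi": repr(s.bmi),
                "diagnosis": s.diagnosis or "",
                "risk_class": s.risk_class or "",
                "time_months": "" if s.followup is None else repr(s.followup.time),
                "event": "" if s.followup is None else int(s.followup.event),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def assemble_cohort(
    panel: Panel,
    genotypes: GenotypeMatrix,
    subjects: Sequence[Subject],
    require_both_classes: bool = True,
) -> Cohort:
    """Join genotypes and phenotypes into a :class:`Cohort`.

    Subjects without genotypes are dropped with a warning.  By default the
    cohort must contain at least one case and one control (association
    stages need the contrast); pass ``require_both_classes=False`` for
    PRS-only use.
    """
    genotyped = set(genotypes.subject_ids)
    kept = [s for s in subjects if s.subject_id in genotyped]
    if not kept:
        raise ValidationError("no overlap between genotyped and phenotyped subjects")
    dropped = len(subjects) - len(kept)
    if dropped:
        warnings.warn(f"{dropped} phenotyped subject(s) lack genotypes; dropped")
    cohort = Cohort(panel=panel, genotypes=genotypes, subjects=kept)
    if require_both_classes and (cohort.n_cases == 0 or cohort.n_controls == 0):
        raise ValidationError(
            f"association requires both classes; got {cohort.n_cases} cases / "
            f"{cohort.n_controls} controls"
        )
    return cohort
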