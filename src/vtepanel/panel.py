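"""SNP panel definition: the curated set of VTE-associated variants.

Every downstream stage (genotype orientation, association, PRS weighting)
is keyed on the :class:`Panel`.  A panel row carries the variant identity,
the designated effect allele (the allele whose dosage is counted; protective
variants still designate the published effect allele and enter the PRS with
a negative weight), the other allele, and the published odds ratio used as
the default PRS weight.

The bundled panel covers 38 variants in 26 genes from the Thai VTE
case-control study; the tab-separated format lets users extend or replace it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Literal

import pandas as pd

from .errors import FormatError, UsageError, ValidationError

PANEL_COLUMNS = ("gene", "rsid", "effect_allele", "reference_allele", "literature_or")

_BUNDLED_PANEL = "vte_thai_panel.tsv"
_BUNDLED_EAFS = "vte_thai_eafs.tsv"


@dataclass(frozen=True)
class VariantDef:
    """One panel SNP.

    ``effect_allele`` may be a single base, a multi-base string, or ``"-"``
    for a deletion allele (e.g. the ABO exon-6 single-base deletion).
    """

    gene: str
    rsid: str
    effect_allele: str
    reference_allele: str
    literature_or: float
    category: Literal["established", "novel"] = "established"

    def __post_init__(self) -> None:
        if self.effect_allele == self.reference_allele:
            raise ValidationError(
                f"{self.rsid}: effect and reference allele are both "
                f"{self.effect_allele!r}"
            )
        if not (self.literature_or > 0) or not math.isfinite(self.literature_or):
            raise ValidationError(
                f"{self.rsid}: literature OR must be a positive finite number, "
                f"got {self.literature_or!r}"
            )


@dataclass(frozen=True)
class Panel:
    """Ordered, rsID-unique collection of :class:`VariantDef`."""

    variants: tuple[VariantDef, ...]
    name: str = "panel"
    genome_build: str = "GRCh38"  # informational only; no liftover logic

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValidationError("panel is empty")
        seen: set[str] = set()
        for v in self.variants:
            if v.rsid in seen:
                raise ValidationError(f"duplicate rsID in panel: {v.rsid}")
            seen.add(v.rsid)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[VariantDef]:
        return iter(self.variants)

    def __contains__(self, rsid: str) -> bool:
        return any(v.rsid == rsid for v in self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    @property
    def genes(self) -> list[str]:
        return [v.gene for v in self.variants]

    def get(self, rsid: str) -> VariantDef:
        for v in self.variants:
            if v.rsid == rsid:
                return v
        raise KeyError(rsid)


def load_panel(path: str | Path, name: str | None = None) -> Panel:
    """Load a panel from a tab-separated file.

    Required columns: gene, rsid, effect_allele, reference_allele,
    literature_or; optional: category.  ``#`` lines are comments.  Row order
    is preserved.  Raises :class:`FormatError` on layout problems and
    :class:`ValidationError` on domain violations (duplicate rsID,
    non-positive OR).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty panel file") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    if df.empty:
        raise FormatError(f"{path}: panel file has a header but no variants")
    variants = []
    for _, row in df.iterrows():
        try:
            lit_or = float(row["literature_or"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{row['rsid']}: literature OR {row['literature_or']!r} is not a number"
            ) from None
        variants.append(
            VariantDef(
                gene=row["gene"],
                rsid=row["rsid"],
                effect_allele=row["effect_allele"],
                reference_allele=row["reference_allele"],
                literature_or=lit_or,
                category=row.get("category", "established") or "established",
            )
        )
    return Panel(tuple(variants), name=name or path.stem)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the tab-separated format read by :func:`load_panel`."""
    rows = [
        {
            "gene": v.gene,
            "rsid": v.rsid,
            "effect_allele": v.effect_allele,
            "reference_allele": v.reference_allele,
            "literature_or": v.literature_or,
            "category": v.category,
        }
        for v in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def bundled_panel() -> Panel:
    """The packaged 38-variant Thai VTE panel."""
    with resources.as_file(
        resources.files("vtepanel.data").joinpath(_BUNDLED_PANEL)
    ) as p:
        return load_panel(p, name="vte_thai_38snp")


def bundled_eafs() -> pd.DataFrame:
    """Observed case/control effect-allele frequencies of the bundled panel.

    Index: rsid; columns eaf_case, eaf_control.  These drive the synthetic
    cohort generator's defaults.
    """
    with resources.as_file(
        resources.files("vtepanel.data").joinpath(_BUNDLED_EAFS)
    ) as p:
        df = pd.read_csv(p, sep="\t", comment="#", dtype={"rsid": str})
    return df.set_index("rsid")


def weight_of(
    variant: VariantDef,
    source: Literal["literature", "cohort"] = "literature",
    cohort_or: float | None = None,
) -> float:
    """PRS weight for one variant: the natural-log odds ratio.

    ``source="literature"`` uses the panel's published OR; ``source="cohort"``
    uses a caller-supplied in-cohort OR.  Protective ORs (<1) yield negative
    weights.
    """
    if source == "literature":
        return math.log(variant.literature_or)
    if source == "cohort":
        if cohort_or is None:
            raise UsageError(f"{variant.rsid}: cohort weight requested without a cohort OR")
        if not (cohort_or > 0) or not math.isfinite(cohort_or):
            raise UsageError(f"{variant.rsid}: cohort OR must be positive and finite")
        return math.log(cohort_or)
    raise UsageError(f"unknown weight source {source!r}")
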