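"""Polygenic risk score: weighted dosage sum, control-referenced z-scores,
median split and OR-by-score-bin reporting.

The score is the plain weighted sum PRS_j = sum_i beta_i * dosage_ij with
beta_i = ln(OR_i), then standardized against the control distribution:
z = (PRS - mean_controls) / SD_controls.  No LD adjustment is performed —
the panel is a curated set of variants treated marginally.

Default weights are the panel's published (literature) odds ratios, which
keeps the case/control contrast out-of-sample; in-cohort weights are
available for sensitivity analysis, falling back per variant to the
literature value when the in-cohort OR is undefined (zero cell or
monomorphic), with the fallback flagged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .association import TwoByTwo, exact_ci, odds_ratio, woolf_ci
from .cohort import Cohort, GenotypeMatrix
from .errors import UsageError, ValidationError
from .panel import Panel, weight_of


@dataclass
class WeightSet:
    """Per-rsID natural-log OR weights."""

    betas: dict[str, float]
    source: Literal["literature", "cohort"] = "literature"
    fallbacks: tuple[str, ...] = ()  # rsIDs where cohort weights fell back

    def __post_init__(self) -> None:
        bad = [r for r, b in self.betas.items() if not math.isfinite(b)]
        if bad:
            raise ValidationError(f"non-finite weight(s) for {', '.join(bad[:5])}")

    @classmethod
    def from_panel(
        cls,
        panel: Panel,
        source: Literal["literature", "cohort"] = "literature",
        cohort_ors: Mapping[str, float] | None = None,
    ) -> "WeightSet":
        """Build weights from the panel; ``cohort`` mode needs per-rsID ORs
        and falls back to literature where an OR is missing or unusable."""
        betas: dict[str, float] = {}
        fallbacks: list[str] = []
        for v in panel:
            if source == "literature":
                betas[v.rsid] = weight_of(v, "literature")
                continue
            if cohort_ors is None:
                raise UsageError("cohort weights requested without cohort ORs")
            or_ = cohort_ors.get(v.rsid)
            if or_ is None or not (0 < or_ < math.inf) or math.isnan(or_):
                betas[v.rsid] = weight_of(v, "literature")
                fallbacks.append(v.rsid)
            else:
                betas[v.rsid] = weight_of(v, "cohort", cohort_or=or_)
        if fallbacks:
            warnings.warn(
                f"{len(fallbacks)} variant(s) fell back to literature weights: "
                + ", ".join(fallbacks[:5])
            )
        return cls(betas=betas, source=source, fallbacks=tuple(fallbacks))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rsid": list(self.betas),
                "beta": list(self.betas.values()),
                "source": [
                    "literature" if r in self.fallbacks else self.source
                    for r in self.betas
                ],
            }
        )


@dataclass
class PRSResult:
    """Per-subject scores plus the control reference used to standardize."""

    scores: pd.DataFrame  # index subject_id; columns raw, z, n_missing [, group]
    control_mean: float
    control_sd: float

    @property
    def z(self) -> pd.Series:
        return self.scores["z"]


def compute_prs(
    genotypes: GenotypeMatrix,
    weights: WeightSet,
    missing_policy: Literal["zero", "mean_dosage_controls"] = "mean_dosage_controls",
    control_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Raw PRS per subject (columns raw, n_missing).

    ``mean_dosage_controls`` substitutes a variant's mean control dosage for
    missing calls (keeps scores comparable across subjects with different
    completeness); ``zero`` treats missing as zero effect alleles.
    """
    missing_weights = [r for r in genotypes.rsids if r not in weights.betas]
    if missing_weights:
        raise ValidationError(
            f"no weight for genotyped variant(s): {', '.join(missing_weights[:5])}"
        )
    beta = np.array([weights.betas[r] for r in genotypes.rsids])
    dosage = genotypes.dosage.copy()
    miss = np.isnan(dosage)
    if missing_policy == "zero":
        fill = np.zeros(len(genotypes.rsids))
    elif missing_policy == "mean_dosage_controls":
        if control_ids is not None:
            idx = [genotypes.subject_ids.index(s) for s in control_ids]
            ref = dosage[:, idx]
        else:
            ref = dosage
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-NaN rows handled below
            fill = np.nanmean(ref, axis=1)
        fill = np.where(np.isnan(fill), 0.0, fill)
    else:
        raise UsageError(f"unknown missing policy {missing_policy!r}")
    dosage[miss] = np.broadcast_to(fill[:, None], dosage.shape)[miss]
    raw = beta @ dosage
    return pd.DataFrame(
        {"raw": raw, "n_missing": miss.sum(axis=0)},
        index=pd.Index(genotypes.subject_ids, name="subject_id"),
    )


def standardize_prs(raw: pd.DataFrame, control_ids: Sequence[str]) -> PRSResult:
    """Z-score all subjects against the control mean and (sample) SD."""
    control_ids = list(control_ids)
    if len(control_ids) < 2:
        raise ValidationError("need at least two controls to standardize")
    ref = raw.loc[control_ids, "raw"]
    mean, sd = float(ref.mean()), float(ref.std(ddof=1))
    if sd == 0:
        raise ValidationError("control PRS standard deviation is zero")
    scores = raw.copy()
    scores["z"] = (scores["raw"] - mean) / sd
    return PRSResult(scores=scores, control_mean=mean, control_sd=sd)


def median_split(
    prs: PRSResult, reference_ids: Sequence[str] | None = None
) -> pd.Series:
    """Label subjects low/high by the median standardized score.

    The median is computed over ``reference_ids`` (default: every scored
    subject); ties at the median go to "low" so the high group strictly
    exceeds it.  Labels are stored in ``prs.scores["group"]`` and returned.
    """
    z = prs.z
    ref = z.loc[list(reference_ids)] if reference_ids is not None else z
    if len(ref) < 2:
        raise ValidationError("need at least two subjects for a median split")
    med = float(ref.median())
    labels = pd.Series(np.where(z > med, "high", "low"), index=z.index, name="group")
    if (labels == "low").all():
        warnings.warn("all scores at or below the median; high-PRS group is empty")
    prs.scores["group"] = labels
    return labels


def or_by_prs_bin(
    prs: PRSResult,
    status: Mapping[str, str] | pd.Series,
    bin_edges: Sequence[float] | None = None,
    reference_bin: int = 0,
) -> pd.DataFrame:
    """Per-bin VTE odds ratio versus a reference score bin.

    Default bins: quartiles of the control z-scores, reference = lowest bin.
    ORs are cross-product with Woolf CIs (exact CI on zero cells).
    """
    status = pd.Series(status).loc[prs.scores.index]
    is_case = (status == "case").to_numpy()
    z = prs.z.to_numpy()
    if bin_edges is None:
        ctrl_z = z[~is_case]
        bin_edges = list(np.quantile(ctrl_z, [0.25, 0.5, 0.75]))
    edges = list(bin_edges)
    if edges != sorted(edges):
        raise ValidationError("bin edges must be sorted")
    bins = np.digitize(z, edges)
    n_bins = len(edges) + 1
    if n_bins < 2:
        raise ValidationError("need at least two bins for a contrast")
    ref_cases = int((is_case & (bins == reference_bin)).sum())
    ref_controls = int((~is_case & (bins == reference_bin)).sum())
    if ref_cases + ref_controls == 0:
        raise ValidationError(f"reference bin {reference_bin} is empty")
    labels = (
        [f"z<={edges[0]:.3g}"]
        + [f"{lo:.3g}<z<={hi:.3g}" for lo, hi in zip(edges, edges[1:])]
        + [f"z>{edges[-1]:.3g}"]
    )
    rows = []
    for b in range(n_bins):
        n_ca = int((is_case & (bins == b)).sum())
        n_co = int((~is_case & (bins == b)).sum())
        row = {"bin": labels[b], "n_case": n_ca, "n_control": n_co}
        if b == reference_bin:
            row.update(or_estimate=1.0, ci_low=math.nan, ci_high=math.nan,
                       reference=True)
        else:
            table = TwoByTwo(n_ca, ref_cases, n_co, ref_controls, unit="subject")
            if table.degenerate:
                row.update(or_estimate=math.nan, ci_low=math.nan,
                           ci_high=math.nan, reference=False)
            else:
                or_est = odds_ratio(table)
                ci = woolf_ci(table) if min(table.cells) > 0 else exact_ci(table)
                row.update(or_estimate=or_est, ci_low=ci[0], ci_high=ci[1],
                           reference=False)
        rows.append(row)
    return pd.DataFrame(rows)
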