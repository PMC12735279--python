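"""Genotyping quality control: call rate, Hardy-Weinberg, replicate concordance.

Filters mirror standard panel-genotyping practice: a variant passes if its
call rate exceeds the minimum (strictly, so the default reads "> 95%") and
its exact Hardy-Weinberg test in controls is not significant.  HWE deviation
in controls is a genotyping-error signal, which is why only controls enter
the test.

The HWE test is the exact conditional test: conditioned on the observed
allele counts, the p-value sums the probabilities of all heterozygote counts
whose probability does not exceed that of the observed count.  Exactness
matters at the panel's rare-allele sites, where the chi-square approximation
is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .cohort import Cohort, GenotypeMatrix
from .errors import ValidationError


def call_rate(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-variant fraction of non-missing calls (exact fraction)."""
    if genotypes.dosage.size == 0:
        raise ValidationError("empty genotype matrix")
    called = (~np.isnan(genotypes.dosage)).sum(axis=1)
    frac = called / genotypes.dosage.shape[1]
    return pd.Series(frac, index=genotypes.rsids, name="call_rate")


def _hwe_het_probabilities(n_het_obs: int, n: int, n_eff_alleles: int) -> np.ndarray:
    """P(het count) for every attainable heterozygote count, given n subjects
    and the effect-allele count; index h into the returned vector is the
    heterozygote count (entries of impossible parity are 0)."""
    m = min(n_eff_alleles, 2 * n - n_eff_alleles)  # rarer allele count
    hs = np.arange(m % 2, m + 1, 2)
    # log P(h) up to a constant: n! 2^h / (h! n_hom_rare! n_hom_common!)
    hom_rare = (m - hs) // 2
    hom_common = n - hs - hom_rare
    logp = hs * np.log(2.0) - (
        gammaln(hs + 1) + gammaln(hom_rare + 1) + gammaln(hom_common + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    out = np.zeros(m + 1)
    out[hs] = p
    return out


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_eff: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value for one genotype triple."""
    for c in (n_hom_ref, n_het, n_hom_eff):
        if c < 0 or c != int(c):
            raise ValidationError(f"genotype counts must be non-negative integers, got {c}")
    n = n_hom_ref + n_het + n_hom_eff
    if n == 0:
        raise ValidationError("all genotype counts are zero")
    m_eff = n_het + 2 * n_hom_eff
    probs = _hwe_het_probabilities(n_het, n, m_eff)
    p_obs = probs[n_het]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-effect) counts from a dosage vector; missing skipped."""
    d = dosages[~np.isnan(dosages)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def replicate_concordance(run_a: GenotypeMatrix, run_b: GenotypeMatrix) -> float:
    """Fraction of cells non-missing in both runs that agree."""
    if run_a.rsids != run_b.rsids or run_a.subject_ids != run_b.subject_ids:
        raise ValidationError("replicate runs cover different variants or subjects")
    both = ~np.isnan(run_a.dosage) & ~np.isnan(run_b.dosage)
    if not both.any():
        raise ValidationError("no cells called in both runs")
    return float((run_a.dosage[both] == run_b.dosage[both]).mean())


@dataclass
class QCReport:
    table: pd.DataFrame  # per-variant: call_rate, hwe_p, flags, pass
    call_rate_min: float
    hwe_alpha: float

    @property
    def dropped(self) -> list[str]:
        return list(self.table.index[~self.table["pass"]])

    @property
    def kept(self) -> list[str]:
        return list(self.table.index[self.table["pass"]])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# QC thresholds: call_rate > {self.call_rate_min}, "
                f"HWE (controls) p > {self.hwe_alpha}\n"
            )
            self.table.to_csv(fh, sep="\t")


def apply_qc(
    cohort: Cohort,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.05,
) -> tuple[Cohort, QCReport]:
    """Drop variants failing the call-rate or control-HWE filter.

    ``hwe_alpha=0`` disables the HWE filter (p <= 0 never holds).  Variants
    with no called controls cannot be HWE-tested; they carry ``hwe_p = NaN``
    and are judged on call rate alone.
    """
    rates = call_rate(cohort.genotypes)
    control_ids = cohort.control_ids
    rows = []
    for rsid in cohort.genotypes.rsids:
        ctrl = cohort.dosages(rsid, control_ids) if control_ids else np.array([])
        counts = genotype_counts(ctrl)
        if sum(counts) == 0:
            hwe_p = np.nan
        else:
            hwe_p = hwe_exact_test(*counts)
        cr = rates[rsid]
        flags = []
        if not cr > call_rate_min:
            flags.append("low_call_rate")
        if np.isfinite(hwe_p) and hwe_p <= hwe_alpha:
            flags.append("hwe_fail")
        rows.append(
            {
                "rsid": rsid,
                "call_rate": cr,
                "hwe_p": hwe_p,
                "flags": ";".join(flags),
                "pass": not flags,
            }
        )
    table = pd.DataFrame(rows).set_index("rsid")
    report = QCReport(table=table, call_rate_min=call_rate_min, hwe_alpha=hwe_alpha)
    if report.dropped:
        filtered = Cohort(
            panel=cohort.panel,
            genotypes=cohort.genotypes.drop_variants(report.dropped),
            subjects=cohort.subjects,
        )
    else:
        filtered = cohort
    return filtered, report
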