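import math

import numpy as np
import pandas as pd
import pytest

from vtepanel.cohort import GenotypeMatrix
from vtepanel.errors import UsageError, ValidationError
from vtepanel.prs import (
    PRSResult,
    WeightSet,
    compute_prs,
    median_split,
    or_by_prs_bin,
    standardize_prs,
)


def _gm(rsids, subject_ids, dosage):
    return GenotypeMatrix(list(rsids), list(subject_ids), np.asarray(dosage, float))


def test_prs_zero_genotypes_zero_score():
    gm = _gm(["r1", "r2"], ["s1", "s2"], [[0, 0], [0, 0]])
    w = WeightSet({"r1": 0.5, "r2": -0.2})
    assert (compute_prs(gm, w)["raw"] == 0).all()


def test_prs_closed_form():
    gm = _gm(["r1", "r2"], ["s1"], [[2], [1]])
    w = WeightSet({"r1": math.log(2), "r2": math.log(0.5)})
    assert compute_prs(gm, w)["raw"].iloc[0] == pytest.approx(math.log(2))


def test_prs_matches_brute_force(rng):
    rsids = [f"r{i}" for i in range(20)]
    subjects = [f"s{j}" for j in range(50)]
    dosage = rng.choice([0.0, 1.0, 2.0], size=(20, 50))
    betas = {r: float(b) for r, b in zip(rsids, rng.normal(0, 0.5, 20))}
    raw = compute_prs(_gm(rsids, subjects, dosage), WeightSet(betas))["raw"]
    for j, s in enumerate(subjects):
        expected = sum(betas[r] * dosage[i, j] for i, r in enumerate(rsids))
        assert raw.loc[s] == pytest.approx(expected, abs=1e-12)


def test_prs_missing_weight_is_an_error():
    gm = _gm(["r1", "r2"], ["s1"], [[0], [0]])
    with pytest.raises(ValidationError, match="r2"):
        compute_prs(gm, WeightSet({"r1": 0.1}))


def test_prs_missing_policies():
    gm = _gm(["r1"], ["s1", "s2", "s3"], [[np.nan, 2, 0]])
    w = WeightSet({"r1": 1.0})
    zero = compute_prs(gm, w, missing_policy="zero")
    assert zero.loc["s1", "raw"] == 0.0 and zero.loc["s1", "n_missing"] == 1
    mean = compute_prs(gm, w, missing_policy="mean_dosage_controls",
                       control_ids=["s2", "s3"])
    assert mean.loc["s1", "raw"] == pytest.approx(1.0)  # mean control dosage
    with pytest.raises(UsageError):
        compute_prs(gm, w, missing_policy="bogus")


def test_prs_linearity_in_weights(rng):
    rsids = [f"r{i}" for i in range(5)]
    dosage = rng.choice([0.0, 1.0, 2.0], size=(5, 10))
    gm = _gm(rsids, [f"s{j}" for j in range(10)], dosage)
    betas = {r: float(b) for r, b in zip(rsids, rng.normal(0, 1, 5))}
    raw = compute_prs(gm, WeightSet(betas))["raw"]
    scaled = compute_prs(gm, WeightSet({r: 3 * b for r, b in betas.items()}))["raw"]
    assert np.allclose(scaled, 3 * raw)


def test_standardize_against_controls():
    raw = pd.DataFrame({"raw": [1.0, 2.0, 3.0, 2.0, 3.0]},
                       index=["c1", "c2", "c3", "p1", "p2"])
    res = standardize_prs(raw, ["c1", "c2", "c3"])
    assert res.control_mean == 2.0 and res.control_sd == 1.0
    assert res.z.loc["p1"] == 0.0 and res.z.loc["p2"] == 1.0
    ctrl_z = res.z.loc[["c1", "c2", "c3"]]
    assert ctrl_z.mean() == pytest.approx(0.0, abs=1e-10)
    assert ctrl_z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_standardize_requires_control_spread():
    raw = pd.DataFrame({"raw": [1.0, 1.0, 2.0]}, index=["c1", "c2", "p1"])
    with pytest.raises(ValidationError):
        standardize_prs(raw, ["c1", "c2"])
    with pytest.raises(ValidationError):
        standardize_prs(raw, ["c1"])


def test_standardized_scores_invariant_to_affine_weight_shift(rng):
    """Scaling every weight rescales raw scores but leaves z-scores fixed."""
    rsids = [f"r{i}" for i in range(6)]
    dosage = rng.choice([0.0, 1.0, 2.0], size=(6, 30))
    gm = _gm(rsids, [f"s{j}" for j in range(30)], dosage)
    controls = [f"s{j}" for j in range(15)]
    betas = {r: float(b) for r, b in zip(rsids, rng.normal(0, 1, 6))}
    z1 = standardize_prs(compute_prs(gm, WeightSet(betas)), controls).z
    z2 = standardize_prs(
        compute_prs(gm, WeightSet({r: 2.5 * b for r, b in betas.items()})), controls
    ).z
    assert np.allclose(z1, z2, atol=1e-10)


def test_median_split_tie_rule():
    scores = pd.DataFrame({"raw": [0, 0, 0], "z": [-1.0, 0.0, 1.0]},
                          index=["a", "b", "c"])
    prs = PRSResult(scores=scores, control_mean=0, control_sd=1)
    labels = median_split(prs)
    assert list(labels) == ["low", "low", "high"]


def test_median_split_degenerate_all_equal():
    scores = pd.DataFrame({"raw": [0] * 4, "z": [0.0] * 4},
                          index=list("abcd"))
    prs = PRSResult(scores=scores, control_mean=0, control_sd=1)
    with pytest.warns(UserWarning):
        labels = median_split(prs)
    assert (labels == "low").all()


def test_median_split_balanced_without_ties(rng):
    z = rng.normal(size=101)
    scores = pd.DataFrame({"raw": z, "z": z},
                          index=[f"s{i}" for i in range(101)])
    prs = PRSResult(scores=scores, control_mean=0, control_sd=1)
    labels = median_split(prs)
    assert abs((labels == "high").sum() - (labels == "low").sum()) <= 1


def test_or_by_prs_bin_no_gradient_gives_unit_or():
    z = np.concatenate([np.linspace(-2, 2, 40)] * 2)
    ids = [f"s{i}" for i in range(80)]
    scores = pd.DataFrame({"raw": z, "z": z}, index=ids)
    prs = PRSResult(scores=scores, control_mean=0, control_sd=1)
    status = pd.Series(["case"] * 40 + ["control"] * 40, index=ids)
    out = or_by_prs_bin(prs, status, bin_edges=[0.0])
    assert len(out) == 2
    assert out.loc[1, "or_estimate"] == pytest.approx(1.0)


def test_or_by_prs_bin_single_bin_is_an_error():
    z = np.linspace(-1, 1, 10)
    ids = [f"s{i}" for i in range(10)]
    prs = PRSResult(
        scores=pd.DataFrame({"raw": z, "z": z}, index=ids),
        control_mean=0, control_sd=1,
    )
    status = pd.Series(["case"] * 5 + ["control"] * 5, index=ids)
    with pytest.raises(ValidationError):
        or_by_prs_bin(prs, status, bin_edges=[])


def test_or_by_prs_bin_increasing_risk_gives_increasing_or(rng):
    """Logistic case risk rising in z produces a non-decreasing OR gradient
    across quartile bins (one seeded replicate at generous n)."""
    n = 4000
    z = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.5 + 1.0 * z)))
    case = rng.random(n) < p
    ids = [f"s{i}" for i in range(n)]
    prs = PRSResult(
        scores=pd.DataFrame({"raw": z, "z": z}, index=ids),
        control_mean=0, control_sd=1,
    )
    status = pd.Series(np.where(case, "case", "control"), index=ids)
    out = or_by_prs_bin(prs, status)
    ors = out["or_estimate"].tolist()
    assert all(b >= a for a, b in zip(ors, ors[1:]))


def test_weightset_cohort_fallback(panel38):
    cohort_ors = {r: 1.5 for r in panel38.rsids}
    cohort_ors["rs2066865"] = math.inf  # undefined in-cohort OR
    with pytest.warns(UserWarning, match="fell back"):
        w = WeightSet.from_panel(panel38, "cohort", cohort_ors)
    assert w.fallbacks == ("rs2066865",)
    assert w.betas["rs2066865"] == pytest.approx(math.log(1.56))
    assert w.betas["rs4524"] == pytest.approx(math.log(1.5))
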