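"""Expression-side statistics.

Covers the four computations a two-group (normal vs model) expression study
needs here: quantile normalization of the intensity matrix, fold-change
differential-expression filtering (threshold >=2.0, boundary inclusive),
relative quantification of qRT-PCR Ct tables by the standard 2^(-ddCt) method,
and Pearson correlation / paired-samples t-tests for the ceRNA evidence.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("normal", "model")

#: DE fold-change threshold on the linear scale (either direction, inclusive).
DEFAULT_FC_THRESHOLD = 2.0


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one probe.

    ``fold_change`` is the linear model/normal group-mean ratio; ``passes``
    iff max(fc, 1/fc) >= threshold.
    """

    probe_id: str
    fold_change: float
    direction: str
    passes: bool
    p_value: float

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError(f"{self.probe_id}: fold change must be > 0")


class ExpressionMatrix:
    """Probes x samples non-negative intensities with a two-group design."""

    def __init__(self, values: pd.DataFrame, group_of: pd.Series):
        if values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if values.index.duplicated().any():
            raise ValueError("duplicate probe ids")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative intensities")
        group_of = group_of.reindex(values.columns)
        if group_of.isna().any():
            missing = list(values.columns[group_of.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(group_of) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
        for g in GROUPS:
            if (group_of == g).sum() < 2:
                raise ValueError(f"group {g!r} needs >=2 samples")
        self.values = values
        self.group_of = group_of

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.group_of.index[self.group_of == group])

    def normalized(self) -> "ExpressionMatrix":
        out = self.values.copy()
        out.loc[:, :] = quantile_normalize(self.values.to_numpy(float))
        return ExpressionMatrix(out, self.group_of)


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column onto the common average distribution.

    Each column's sorted values become the vector of row means of the
    column-sorted matrix, re-assigned in original rank order; tied values
    receive the mean of the quantile values their ranks span.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty matrix")
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        _, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        sums = np.bincount(inverse, weights=assigned)
        out[:, j] = (sums / counts)[inverse]
    return out


def _two_group_p(x: np.ndarray, y: np.ndarray) -> float:
    """Paired t when group sizes match (samples paired by within-group order),
    Welch's t otherwise."""
    if len(x) == len(y):
        return paired_t_test(x, y)[1]
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def fold_change_filter(
    m: ExpressionMatrix,
    threshold: float = DEFAULT_FC_THRESHOLD,
    *,
    log_means: bool = False,
) -> list[DEResult]:
    """Fold-change DE filter on linear-scale group means.

    ``log_means`` switches the group summary to the geometric mean (mean of
    logs), for data where the arithmetic ratio is dominated by outliers.
    A probe passes when max(fc, 1/fc) >= threshold (boundary inclusive).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    normal = m.values[m.samples_in("normal")].to_numpy(float)
    model = m.values[m.samples_in("model")].to_numpy(float)
    results = []
    for i, probe in enumerate(m.probe_ids):
        xn, xm = normal[i], model[i]
        if log_means:
            if (xn <= 0).any() or (xm <= 0).any():
                raise ValueError(f"{probe}: non-positive intensity under log_means")
            mn, mm = 2 ** np.mean(np.log2(xn)), 2 ** np.mean(np.log2(xm))
        else:
            mn, mm = float(np.mean(xn)), float(np.mean(xm))
        if mn == 0:
            raise ValueError(f"{probe}: zero normal-group mean, ratio undefined")
        fc = mm / mn
        results.append(
            DEResult(
                probe_id=probe,
                fold_change=fc,
                direction="up" if fc >= 1 else "down",
                passes=max(fc, 1 / fc) >= threshold,
                p_value=_two_group_p(xm, xn),
            )
        )
    return results


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (opt-in; the default workflow
    filters on raw fold change and raw p < 0.05)."""
    return list(stats.false_discovery_control(p_values, method="bh"))


def de_table(results: list[DEResult], adjust: bool = False) -> pd.DataFrame:
    rows = [
        {
            "Probe": r.probe_id,
            "Fold_change": r.fold_change,
            "Direction": r.direction,
            "Passes": r.passes,
            "P_value": r.p_value,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows, columns=["Probe", "Fold_change", "Direction", "Passes", "P_value"]
    )
    if adjust and len(df):
        df["P_adjusted"] = bh_adjust(list(df["P_value"]))
    return df


CT_COLUMNS = ("sample_id", "group", "target_name", "reference_name", "ct_target", "ct_reference")


def validate_ct_table(t: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format Ct table (one row per sample x target)."""
    missing = set(CT_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    for col in ("ct_target", "ct_reference"):
        vals = t[col].to_numpy(float)
        if np.isnan(vals).any() or (vals <= 0).any() or (vals > 45).any():
            raise ValueError(f"{col}: Ct values must lie in (0, 45]")
    bad = set(t["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    for target, sub in t.groupby("target_name"):
        if sub["reference_name"].nunique() != 1:
            raise ValueError(f"{target}: inconsistent reference gene")
    return t


def delta_delta_ct(t: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative quantification by the standard ddCt method.

    Per sample, dCt = ct_target - ct_reference; per target,
    ddCt = mean dCt(model) - mean dCt(normal) and the relative quantity is
    2^(-ddCt) (amplification efficiency assumed exactly 2). Returns the
    per-target summary and the per-sample 2^(-dCt) values kept for t-tests.
    """
    t = validate_ct_table(t)
    per_sample = t.copy()
    per_sample["delta_ct"] = per_sample["ct_target"] - per_sample["ct_reference"]
    per_sample["rel_quantity"] = 2.0 ** (-per_sample["delta_ct"])
    summaries = []
    for target, sub in per_sample.groupby("target_name", sort=True):
        for g in GROUPS:
            if not (sub["group"] == g).any():
                raise ValueError(f"{target}: group {g!r} missing from Ct table")
        mean_dct = sub.groupby("group")["delta_ct"].mean()
        ddct = float(mean_dct["model"] - mean_dct["normal"])
        summaries.append(
            {
                "Target": target,
                "Reference": sub["reference_name"].iloc[0],
                "n_normal": int((sub["group"] == "normal").sum()),
                "n_model": int((sub["group"] == "model").sum()),
                "Delta_delta_ct": ddct,
                "Relative_quantity": 2.0 ** (-ddct),
            }
        )
    summary = pd.DataFrame(
        summaries,
        columns=["Target", "Reference", "n_normal", "n_model", "Delta_delta_ct", "Relative_quantity"],
    )
    return summary, per_sample


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-transform p (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired-samples t-test on differences d = x - y (two-sided, n-1 df).

    Degenerate cases: identical vectors give (0, 1); constant non-zero
    differences give an infinite t with the smallest representable p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, d[0]), math.nextafter(0.0, 1.0)
    res = stats.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)
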