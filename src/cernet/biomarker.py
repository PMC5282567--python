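"""qRT-PCR relative quantification and diagnostic evaluation.

Relative expression uses the 2^-ddCt model (amplification efficiency fixed
at 2): dCt = Ct_target - Ct_reference per sample (replicates averaged
first), ddCt subtracts the calibrator group's mean dCt, and
rq = 2^-ddCt. Diagnostic value is summarized by the empirical ROC curve:
AUC by pair counting (ties count one half), a DeLong normal-approximation
confidence interval, and the Youden-optimal cutoff. Marker-covariate
association defaults to Spearman rank correlation with an exact
permutation p-value at small n.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CT_QC_SD_CYCLES = 0.5  # replicate-spread flag threshold


@dataclass
class RocResult:
    auc: float
    orientation: str  # "higher-in-case" | "lower-in-case"
    ci_lo: float
    ci_hi: float
    thresholds: pd.DataFrame  # cutoff, sensitivity, specificity
    optimal_cutoff: float
    sensitivity: float
    specificity: float
    n_case: int
    n_control: int
    # oriented scores kept for paired AUC comparison
    _scores: np.ndarray = field(repr=False, default=None)
    _labels: np.ndarray = field(repr=False, default=None)


@dataclass
class CorrelationResult:
    covariate: str
    method: str
    r: float
    p: float
    n: int


@dataclass
class MarkerComparison:
    auc_a: float
    auc_b: float
    delta_auc: float
    z: float
    p: float


def ddct(ct: pd.DataFrame, target_gene: str, reference_gene: str,
         calibrator_group: str = "control") -> pd.DataFrame:
    """Per-sample 2^-ddCt relative expression of one gene vs a reference.

    ``ct`` needs columns sample, group, gene, replicate, ct. Replicates are
    averaged per (sample, gene) first; samples with replicate SD above
    0.5 cycles are flagged in the ``qc_flag`` column rather than dropped.
    """
    required = {"sample", "group", "gene", "replicate", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns {sorted(missing)}")
    if ((ct["ct"] <= 0) | (ct["ct"] > 45)).any():
        raise ValueError("Ct values must lie in (0, 45]")
    sub = ct[ct["gene"].isin([target_gene, reference_gene])]
    agg = sub.groupby(["sample", "group", "gene"])["ct"].agg(["mean", "std", "count"])
    agg = agg.reset_index()
    wide_mean = agg.pivot(index=["sample", "group"], columns="gene", values="mean")
    for gene, role in ((target_gene, "target"), (reference_gene, "reference")):
        if gene not in wide_mean.columns or wide_mean[gene].isna().any():
            raise ValueError(f"{role} gene {gene!r} missing for some samples")
    wide_sd = agg.pivot(index=["sample", "group"], columns="gene", values="std")
    out = wide_mean.reset_index()[["sample", "group"]].copy()
    if target_gene == reference_gene:
        out["delta_ct"] = 0.0
        qc_sd = wide_sd.reset_index()[target_gene].fillna(0.0)
    else:
        out["delta_ct"] = (wide_mean[target_gene] - wide_mean[reference_gene]).values
        qc_sd = wide_sd.reset_index()[[target_gene, reference_gene]].fillna(0.0).max(axis=1)
    calib = out.loc[out["group"] == calibrator_group, "delta_ct"]
    if calib.empty:
        raise ValueError(f"no samples in calibrator group {calibrator_group!r}")
    out["ddct"] = out["delta_ct"] - calib.mean()
    out["rq"] = 2.0 ** (-out["ddct"])
    out["qc_flag"] = (qc_sd > CT_QC_SD_CYCLES).values
    out.insert(1, "gene", target_gene)
    out.insert(2, "reference", reference_gene)
    return out


def group_summary(rel: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of rq per group."""
    return (rel.groupby("group")["rq"].agg(["mean", "std", "count"])
            .reset_index().rename(columns={"count": "n"}))


def _auc_from_ranks(case: np.ndarray, control: np.ndarray) -> float:
    """(concordant + 0.5 * tied) / (n_case * n_control) via average ranks."""
    pooled = np.concatenate([case, control])
    ranks = stats.rankdata(pooled)
    n1 = len(case)
    r1 = ranks[:n1].sum()
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * len(control))


def _delong_components(case: np.ndarray, control: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong placement values V10 (cases), V01 (controls)."""
    m, n = len(case), len(control)
    # placement of each case among controls and vice versa
    v10 = np.array([(np.sum(c > control) + 0.5 * np.sum(c == control)) / n
                    for c in case])
    v01 = np.array([(np.sum(case > c) + 0.5 * np.sum(case == c)) / m
                    for c in control])
    return float(v10.mean()), v10, v01


def roc(values, labels, positive: str = "case") -> RocResult:
    """Empirical ROC analysis of one continuous marker.

    The curve is oriented so AUC >= 0.5 (orientation recorded); thresholds
    sit at midpoints between consecutive sorted unique values; the optimal
    cutoff maximizes Youden's J = sensitivity + specificity - 1 with ties
    broken toward higher sensitivity; the CI is DeLong-based, truncated to
    [0, 1].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must align")
    pos_mask = labels == positive
    case, control = values[pos_mask], values[~pos_mask]
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both classes must be non-empty")
    auc_raw = _auc_from_ranks(case, control)
    if auc_raw >= 0.5:
        orientation, sign = "higher-in-case", 1.0
    else:
        orientation, sign = "lower-in-case", -1.0
    oc, occ = sign * case, sign * control
    auc, v10, v01 = _delong_components(oc, occ)
    var = (np.var(v10, ddof=1) / len(oc) if len(oc) > 1 else 0.0) + \
          (np.var(v01, ddof=1) / len(occ) if len(occ) > 1 else 0.0)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci_lo, ci_hi = max(0.0, auc - half), min(1.0, auc + half)

    uniq = np.unique(np.concatenate([oc, occ]))
    cuts = [uniq[0] - 1.0]
    cuts.extend((uniq[:-1] + uniq[1:]) / 2.0)
    cuts.append(uniq[-1] + 1.0)
    rows = []
    for cut in cuts:
        sens = float(np.mean(oc >= cut))
        spec = float(np.mean(occ < cut))
        rows.append((sign * cut, sens, spec))
    thresholds = pd.DataFrame(rows, columns=["cutoff", "sensitivity", "specificity"])
    j = thresholds["sensitivity"] + thresholds["specificity"] - 1.0
    best = thresholds.iloc[
        thresholds.assign(j=j).sort_values(
            ["j", "sensitivity"], ascending=[False, False], kind="mergesort"
        ).index[0]]
    return RocResult(
        auc=float(auc), orientation=orientation,
        ci_lo=float(min(ci_lo, auc)), ci_hi=float(max(ci_hi, auc)),
        thresholds=thresholds,
        optimal_cutoff=float(best["cutoff"]),
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        n_case=len(case), n_control=len(control),
        _scores=sign * values, _labels=pos_mask,
    )


def compare_markers(roc_a: RocResult, roc_b: RocResult) -> MarkerComparison:
    """Paired DeLong test for a difference in AUC on the same samples."""
    if roc_a._labels is None or roc_b._labels is None:
        raise ValueError("RocResults lack per-sample scores")
    if roc_a._labels.shape != roc_b._labels.shape or \
            not np.array_equal(roc_a._labels, roc_b._labels):
        raise ValueError("markers were not computed on the same samples")
    la = roc_a._labels
    auc_a, v10_a, v01_a = _delong_components(roc_a._scores[la], roc_a._scores[~la])
    auc_b, v10_b, v01_b = _delong_components(roc_b._scores[la], roc_b._scores[~la])
    m, n = int(la.sum()), int((~la).sum())
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + \
              (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = 0.0
    delta = auc_a - auc_b
    if var <= 0:
        z = 0.0 if delta == 0 else math.inf * np.sign(delta)
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return MarkerComparison(float(auc_a), float(auc_b), float(delta), float(z), float(p))


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, method: str) -> float:
    """Two-sided exact permutation p for a correlation, enumerating n!.

    Practical for n <= 10 (10! ~ 3.6M permutations, enumerated in chunks).
    """
    n = len(x)
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    x = (x - x.mean()) / x.std()
    y = (y - y.mean()) / y.std()
    r_obs = float(np.mean(x * y))
    count = total = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = np.array(list(itertools.islice(perms, 100_000)), dtype=int)
        if chunk.size == 0:
            break
        r = (x[chunk] * y).mean(axis=1)
        count += int(np.sum(np.abs(r) >= abs(r_obs) - 1e-12))
        total += len(chunk)
    return count / total


def correlate(marker, covariate, method: str = "spearman",
              name: str = "covariate") -> CorrelationResult:
    """Correlation between a marker and one clinical covariate.

    Pairs with missing values are dropped. Spearman is Pearson on average
    ranks. The p-value is exact (full permutation enumeration) for
    n <= 10, otherwise the usual t approximation on n - 2 df.
    """
    x = np.asarray(marker, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("marker and covariate must align")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    if method == "spearman":
        r = _spearman_r(x, y)
    elif method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")
    if n <= 10:
        p = _exact_permutation_p(x, y, method)
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(name, method, float(r), float(p), n)
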