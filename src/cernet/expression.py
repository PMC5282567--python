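"""Expression containers, normalization and differential-expression calling.

The screening logic mirrors a two-group (case vs control) transcriptome
comparison: fold change on group means with a pseudocount, a per-feature
two-sample test on the log2 scale (Welch's t for adequately sized groups,
Mann-Whitney U otherwise), Benjamini-Hochberg adjustment, and two nested
selections — "differential" (|FC| > 2, q < 0.05) and the stricter
"candidate" screen (|log2FC| > 1.5, p < 0.01, abundance floor).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from . import io

FEATURE_CLASSES = ("mirna", "lncrna", "mrna")
LNC_CATEGORIES = ("antisense", "intergenic", "intronic", "processed_transcript")

#: Columns of a DETable, in canonical order.
DETABLE_COLUMNS = [
    "feature", "feature_class", "mean_case", "mean_control", "fc", "log2fc",
    "p", "q", "direction", "max_group_signal", "passes_de", "passes_candidate",
]


@dataclass
class ExpressionMatrix:
    """Feature-by-sample expression values with case/control labels.

    Parameters
    ----------
    values : DataFrame
        Non-negative expression values (microarray signal or FPKM);
        index = feature ids, columns = sample ids.
    groups : Series
        Maps each sample id to ``"case"`` or ``"control"``.
    feature_class : str
        One of ``"mirna"``, ``"lncrna"``, ``"mrna"``.
    lnc_category : Series, optional
        Per-feature lncRNA category (antisense / intergenic / intronic /
        processed_transcript); only meaningful for the lncRNA class.
    """

    values: pd.DataFrame
    groups: pd.Series
    feature_class: str
    lnc_category: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.values.columns[self.groups.isna()].tolist()
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for grp in ("case", "control"):
            if (self.groups == grp).sum() < 1:
                raise ValueError(f"need at least one {grp} sample")

    @property
    def case_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "case"])

    @property
    def control_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == "control"])

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    def to_tsv(self, expr_path: str | Path, groups_path: str | Path | None = None) -> None:
        df = self.values.copy()
        df.insert(0, "feature", df.index)
        io.write_tsv(df, expr_path)
        if groups_path is not None:
            io.write_tsv(
                pd.DataFrame({"sample": self.groups.index, "group": self.groups.values}),
                groups_path,
            )

    @classmethod
    def from_tsv(cls, expr_path: str | Path, groups_path: str | Path,
                 feature_class: str) -> "ExpressionMatrix":
        df = io.read_tsv(expr_path)
        df = df.set_index(df.columns[0])
        df.index.name = None
        grp = io.read_tsv(groups_path)
        groups = pd.Series(grp["group"].values, index=grp["sample"].astype(str))
        return cls(df.astype(float), groups, feature_class)


def pool_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse each group to a single pooled pseudo-sample (group mean).

    Emulates equal-amount RNA pooling used in discovery-stage profiling while
    keeping per-sample matrices available for validation-stage statistics.
    """
    pooled = pd.DataFrame({
        "case_pool": matrix.values[matrix.case_samples].mean(axis=1),
        "control_pool": matrix.values[matrix.control_samples].mean(axis=1),
    })
    groups = pd.Series({"case_pool": "case", "control_pool": "control"})
    return ExpressionMatrix(pooled, groups, matrix.feature_class, matrix.lnc_category)


def fpkm(counts: pd.DataFrame, effective_lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped reads.

    value = 1e9 * count / (effective_length * library_size).
    """
    lengths = effective_lengths.reindex(counts.index)
    libs = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("effective lengths must be positive for every feature")
    if libs.isna().any() or (libs <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return 1e9 * counts.div(lengths, axis=0).div(libs, axis=1)


def lowess_normalize(case_signal: np.ndarray, control_signal: np.ndarray,
                     span: float = 0.3) -> tuple[np.ndarray, np.ndarray]:
    """Remove intensity-dependent bias between two paired channels.

    Works in MA space (M = log2 ratio, A = mean log2 intensity): the locally
    weighted regression of M on A is subtracted from M, and intensities are
    reconstructed holding A fixed. With no bias (M == 0) this is the identity.
    """
    case_signal = np.asarray(case_signal, dtype=float)
    control_signal = np.asarray(control_signal, dtype=float)
    if case_signal.shape != control_signal.shape or case_signal.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(case_signal) < 10:
        raise ValueError("need at least 10 features for a stable LOWESS fit")
    if (case_signal <= 0).any() or (control_signal <= 0).any():
        raise ValueError("signals must be strictly positive")
    m = np.log2(case_signal) - np.log2(control_signal)
    a = 0.5 * (np.log2(case_signal) + np.log2(control_signal))
    fit = _sm_lowess(m, a, frac=span, return_sorted=False)
    m_resid = m - fit
    return 2.0 ** (a + m_resid / 2.0), 2.0 ** (a - m_resid / 2.0)


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration of group assignments.

    Tie-aware: U is computed from average ranks; the two-sided p is the
    fraction of the C(n1+n2, n1) assignments whose min(U, n1*n2-U) is at
    least as extreme (small) as observed.
    """
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    stat_obs = min(u_obs, n1 * (n - n1) - u_obs)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        stat = min(u, n1 * (n - n1) - u)
        if stat <= stat_obs + 1e-9:
            count += 1
        total += 1
    return count / total


def de_test(matrix: ExpressionMatrix, method: str = "auto") -> pd.Series:
    """Per-feature two-sided p-values for case vs control.

    ``welch_t_on_log2`` runs Welch's t-test on log2(value + pseudocount);
    ``mann_whitney`` uses exact enumeration when the smaller group has <= 8
    samples and the tie-corrected normal approximation otherwise. ``auto``
    picks Welch's t when both groups have >= 3 samples.
    """
    case = matrix.values[matrix.case_samples].to_numpy(dtype=float)
    control = matrix.values[matrix.control_samples].to_numpy(dtype=float)
    n1, n2 = case.shape[1], control.shape[1]
    if min(n1, n2) < 1 or (n1 + n2) < 3:
        raise ValueError("need samples in both groups")
    if method == "auto":
        method = "welch_t_on_log2" if min(n1, n2) >= 3 else "mann_whitney"
    if method == "welch_t_on_log2":
        if min(n1, n2) < 2:
            raise ValueError("welch_t_on_log2 needs >= 2 samples per group")
        pc = _pseudocount(matrix.values)
        res = stats.ttest_ind(np.log2(case + pc), np.log2(control + pc),
                              axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance identical groups yield NaN; identical data = no evidence
        degenerate = np.all(case[:, :1] == case, axis=1) & \
            np.all(control[:, :1] == control, axis=1) & \
            (case[:, 0] == control[:, 0])
        p = np.where(np.isnan(p) & degenerate, 1.0, p)
    elif method == "mann_whitney":
        p = np.empty(matrix.n_features)
        exact = min(n1, n2) <= 8
        for i in range(matrix.n_features):
            x, y = case[i], control[i]
            if exact:
                p[i] = _exact_mannwhitney_p(x, y)
            else:
                if np.all(np.concatenate([x, y]) == x[0]):
                    p[i] = 1.0
                else:
                    p[i] = stats.mannwhitneyu(
                        x, y, alternative="two-sided", method="asymptotic",
                        use_continuity=False).pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(np.clip(p, 0.0, 1.0), index=matrix.values.index, name="p")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_i = min_{j >= i} p_(j) * m / j on the ascending sort, capped at 1,
    returned in the original input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bonferroni_adjust(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    return np.minimum(p * len(p), 1.0)


def _pseudocount(values: pd.DataFrame) -> float:
    """Half the smallest positive value in the matrix (keeps FC finite)."""
    arr = values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        return 0.5
    return float(positive.min()) * 0.5


def differential_expression(matrix: ExpressionMatrix, method: str = "auto",
                            fc_threshold: float = 2.0, q_threshold: float = 0.05,
                            log2fc_floor: float = 1.5, p_floor: float = 0.01,
                            copy_floor: float = 30.0, signal_floor: float = 500.0,
                            adjust: str = "bh") -> pd.DataFrame:
    """Build a DETable: fold changes, tests, BH adjustment and both screens.

    A pseudocount (half the smallest positive value) is added to both group
    means before the ratio so zero-mean features keep a finite, symmetric FC.
    """
    case_mean = matrix.values[matrix.case_samples].mean(axis=1)
    control_mean = matrix.values[matrix.control_samples].mean(axis=1)
    pc = _pseudocount(matrix.values)
    fc = (case_mean + pc) / (control_mean + pc)
    log2fc = np.log2(fc)
    p = de_test(matrix, method=method)
    if adjust == "bh":
        q = bh_adjust(p.to_numpy())
    elif adjust == "bonferroni":
        q = bonferroni_adjust(p.to_numpy())
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    max_group_signal = np.maximum(case_mean, control_mean)
    table = pd.DataFrame({
        "feature": matrix.values.index,
        "feature_class": matrix.feature_class,
        "mean_case": case_mean.values,
        "mean_control": control_mean.values,
        "fc": fc.values,
        "log2fc": log2fc.values,
        "p": p.values,
        "q": q,
        "max_group_signal": max_group_signal.values,
    })
    up = (table["log2fc"] > math.log2(fc_threshold)) & (table["q"] < q_threshold)
    down = (table["log2fc"] < -math.log2(fc_threshold)) & (table["q"] < q_threshold)
    table["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    table["passes_de"] = up | down
    abundance_floor = signal_floor if matrix.feature_class == "mirna" else copy_floor
    table["passes_candidate"] = (
        (table["log2fc"].abs() > log2fc_floor)
        & (table["p"] < p_floor)
        & (table["p"] > 0)
        & (table["max_group_signal"] >= abundance_floor)
    )
    return table[DETABLE_COLUMNS].reset_index(drop=True)


def call_de(detable: pd.DataFrame, fc_threshold: float = 2.0,
            q_threshold: float = 0.05) -> tuple[set[str], set[str]]:
    """Up/down feature sets: |FC| > fc_threshold and q < q_threshold (strict)."""
    lfc = math.log2(fc_threshold)
    sig = detable["q"] < q_threshold
    up = set(detable.loc[sig & (detable["log2fc"] > lfc), "feature"])
    down = set(detable.loc[sig & (detable["log2fc"] < -lfc), "feature"])
    return up, down


def candidate_filter(detable: pd.DataFrame, log2fc_floor: float = 1.5,
                     p_floor: float = 0.01, copy_floor: float = 30.0,
                     signal_floor: float = 500.0) -> set[str]:
    """The stricter validation screen on an existing DETable.

    |log2FC| > log2fc_floor (strict), p < p_floor with p > 0 (degenerate
    all-tie features excluded), and the class-appropriate abundance floor
    (signal for microarray miRNA, copies/FPKM for sequencing classes) met
    in at least one group.
    """
    floors = detable["feature_class"].map(
        lambda c: signal_floor if c == "mirna" else copy_floor)
    keep = (
        (detable["log2fc"].abs() > log2fc_floor)
        & (detable["p"] < p_floor)
        & (detable["p"] > 0)
        & (detable["max_group_signal"] >= floors)
    )
    return set(detable.loc[keep, "feature"])
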