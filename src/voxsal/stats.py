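"""Group-level statistics over regional saliency.

Covers the analysis chain applied after regional scoring:

* misclassification exclusion (only correctly classified subjects feed the
  group analyses, preventing cross-class contamination of saliency),
* inter-fold regression of per-fold area-mean saliency vectors,
* pairwise Kendall tau-b correlation between areas with two-sided p-values,
* per-area node score: the signed sum of significant tau coefficients with
  all other areas (a centrality proxy over the saliency-correlation graph),
* intra-network versus brain-wide correlation contrast per functional
  network,
* association of per-area saliency with clinical metrics (Pearson and
  Kendall with per-test p-values; dose restricted to medicated subjects),
* pairwise correlation among the clinical metrics themselves, overall and
  split by medication status.

Significance filtering uses raw p < alpha by default (no multiplicity
correction), with an optional Benjamini-Hochberg flag.  95% intervals are
normal-approximation mean +/- 1.96 * SEM throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import CT, PD, SubjectRecord

CLINICAL_METRICS = ("updrs_p3", "moca", "ledd", "years_onset")


class PredictionMissingError(ValueError):
    """A subject has no recorded prediction."""


def exclude_misclassified(
    subjects: Sequence[SubjectRecord],
) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Keep subjects whose prediction matches their label; report exclusions."""
    missing = [s.id for s in subjects if s.predicted_class is None]
    if missing:
        raise PredictionMissingError(f"subjects without predictions: {missing}")
    retained = [s for s in subjects if s.predicted_class == s.true_class]
    report = {
        PD: sum(1 for s in subjects if s.true_class == PD and s.predicted_class != PD),
        CT: sum(1 for s in subjects if s.true_class == CT and s.predicted_class != CT),
    }
    return retained, report


@dataclass(frozen=True)
class RegressionFit:
    fold_x: int
    fold_y: int
    slope: float
    intercept: float


def interfold_regression(fold_means: dict[int, np.ndarray]) -> list[RegressionFit]:
    """OLS of fold-j area means on fold-i area means, every unordered pair."""
    folds = sorted(fold_means)
    if len(folds) < 2:
        raise ValueError("need at least two folds")
    lengths = {len(np.asarray(fold_means[f])) for f in folds}
    if len(lengths) != 1:
        raise ValueError("fold mean vectors differ in area count")
    fits = []
    for fi, fj in combinations(folds, 2):
        x = np.asarray(fold_means[fi], dtype=float)
        y = np.asarray(fold_means[fj], dtype=float)
        if np.var(x) == 0:
            raise ValueError(f"fold {fi} mean vector has zero variance")
        res = sps.linregress(x, y)
        fits.append(
            RegressionFit(fold_x=fi, fold_y=fj, slope=float(res.slope), intercept=float(res.intercept))
        )
    return fits


@dataclass
class CorrelationTable:
    """Symmetric area-by-area Kendall tau-b matrix with matched p-values."""

    tau: pd.DataFrame
    pvals: pd.DataFrame
    n_subjects: int

    def __post_init__(self) -> None:
        t = self.tau.to_numpy(dtype=float)
        if t.shape[0] != t.shape[1]:
            raise ValueError("tau matrix must be square")
        finite = np.isfinite(t)
        if np.nanmax(np.abs(t[finite])) > 1 + 1e-12:
            raise ValueError("|tau| must be <= 1")
        asym = np.nanmax(np.abs(t - t.T)) if finite.any() else 0.0
        if asym > 1e-12:
            raise ValueError("tau matrix is not symmetric")
        d = np.diag(t)
        if not np.allclose(d[np.isfinite(d)], 1.0):
            raise ValueError("tau diagonal must be 1")
        p = self.pvals.to_numpy(dtype=float)
        pf = p[np.isfinite(p)]
        if pf.size and (pf.min() < 0 or pf.max() > 1):
            raise ValueError("p-values must lie in [0, 1]")


def _kendall(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    method = "exact" if (n <= 10 and not ties) else "asymptotic"
    res = sps.kendalltau(x, y, variant="b", method=method)
    return float(res.statistic), float(res.pvalue)


def pairwise_kendall(matrix: pd.DataFrame) -> CorrelationTable:
    """Kendall tau-b between every pair of area columns.

    Exact two-sided p-values for n <= 10 without ties, normal approximation
    otherwise.  Constant columns yield NaN tau/p with a warning.
    """
    n = len(matrix)
    if n < 3:
        raise ValueError(f"need >= 3 retained subjects, got {n}")
    cols = list(matrix.columns)
    vals = matrix.to_numpy(dtype=float)
    constant = [c for i, c in enumerate(cols) if np.all(vals[:, i] == vals[0, i])]
    if constant:
        warnings.warn(
            f"constant saliency columns, tau undefined: {constant}", RuntimeWarning
        )
    a = len(cols)
    tau = np.eye(a)
    pv = np.zeros((a, a))
    for i, j in combinations(range(a), 2):
        if cols[i] in constant or cols[j] in constant:
            tau[i, j] = tau[j, i] = np.nan
            pv[i, j] = pv[j, i] = np.nan
            continue
        t, p = _kendall(vals[:, i], vals[:, j])
        tau[i, j] = tau[j, i] = t
        pv[i, j] = pv[j, i] = p
    for i in range(a):
        if cols[i] in constant:
            tau[i, i] = np.nan
            pv[i, i] = np.nan
    return CorrelationTable(
        tau=pd.DataFrame(tau, index=cols, columns=cols),
        pvals=pd.DataFrame(pv, index=cols, columns=cols),
        n_subjects=n,
    )


def node_scores(table: CorrelationTable, alpha: float = 0.05) -> pd.Series:
    """NS(a) = signed sum of tau(a, b) over significant pairs b != a."""
    tau = table.tau.to_numpy(dtype=float).copy()
    pv = table.pvals.to_numpy(dtype=float)
    np.fill_diagonal(tau, 0.0)
    sig = np.isfinite(pv) & (pv < alpha) & np.isfinite(tau)
    np.fill_diagonal(sig, False)
    ns = np.where(sig, tau, 0.0).sum(axis=1)
    return pd.Series(ns, index=table.tau.index, name="node_score")


def network_contrast(
    table: CorrelationTable,
    memberships: dict[str, Sequence[str]],
    use_abs: bool = False,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Intra-network versus all-areas mean pairwise tau, per network.

    For each member area: intra = mean tau with other members, all = mean
    tau with every other area.  The network summary is the mean over member
    areas with a 1.96 * SEM half-width for both quantities.  ``use_abs``
    averages |tau|; ``significant_only`` restricts to p < alpha pairs.
    """
    cols = list(table.tau.columns)
    idx = {c: i for i, c in enumerate(cols)}
    tau = table.tau.to_numpy(dtype=float).copy()
    if significant_only:
        pv = table.pvals.to_numpy(dtype=float)
        tau[~(np.isfinite(pv) & (pv < alpha))] = np.nan
    if use_abs:
        tau = np.abs(tau)
    np.fill_diagonal(tau, np.nan)

    records = []
    for net, members in sorted(memberships.items()):
        mi = [idx[m] for m in members if m in idx]
        if len(mi) < 2:
            raise ValueError(f"network {net!r} needs >= 2 member areas")
        intra_vals, all_vals = [], []
        for i in mi:
            others_in = [j for j in mi if j != i]
            intra_vals.append(np.nanmean(tau[i, others_in]))
            all_vals.append(np.nanmean(np.delete(tau[i], i)))
        intra_vals = np.asarray(intra_vals)
        all_vals = np.asarray(all_vals)
        k = len(mi)
        sem = lambda v: float(1.96 * np.nanstd(v, ddof=1) / np.sqrt(k)) if k > 1 else 0.0
        records.append(
            (
                net,
                float(np.nanmean(intra_vals)),
                sem(intra_vals),
                float(np.nanmean(all_vals)),
                sem(all_vals),
                k,
            )
        )
    return pd.DataFrame(
        records,
        columns=["network", "intra_mean", "intra_halfwidth", "all_mean", "all_halfwidth", "n_members"],
    ).set_index("network")


def _metric_values(subjects: Sequence[SubjectRecord], metric: str) -> pd.Series:
    if metric not in CLINICAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    vals = {}
    for s in subjects:
        if s.true_class != PD:
            continue
        if metric == "ledd" and not s.medicated:
            continue
        vals[s.id] = getattr(s, metric)
    return pd.Series(vals, dtype=float)


def metric_association(
    matrix: pd.DataFrame,
    subjects: Sequence[SubjectRecord],
    metric: str,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-area Pearson and Kendall correlation of saliency with a metric.

    Patient subjects only, pairwise-complete over non-missing metric values;
    dose (ledd) is additionally restricted to medicated subjects.  Pearson
    p-values come from the t-distribution with n - 2 df.  Flags
    significance at raw p < alpha; optional Benjamini-Hochberg adjustment.
    """
    mvals = _metric_values(subjects, metric).dropna()
    ids = [i for i in matrix.index if i in mvals.index]
    if len(ids) < 3:
        raise ValueError(f"need >= 3 subjects with non-missing {metric}, got {len(ids)}")
    y = mvals.loc[ids].to_numpy()
    if np.all(y == y[0]):
        warnings.warn(f"metric {metric} is constant; correlations undefined", RuntimeWarning)
    records = []
    for area in matrix.columns:
        x = matrix.loc[ids, area].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            records.append((area, np.nan, np.nan, np.nan, np.nan, len(ids)))
            continue
        rho, p_rho = sps.pearsonr(x, y)
        t, p_t = _kendall(x, y)
        records.append((area, float(rho), float(p_rho), t, p_t, len(ids)))
    out = pd.DataFrame(
        records, columns=["area", "pearson_rho", "pearson_p", "kendall_tau", "kendall_p", "n"]
    ).set_index("area")
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        for col in ("pearson_p", "kendall_p"):
            ok = out[col].notna()
            if ok.any():
                out.loc[ok, col] = multipletests(out.loc[ok, col], method="fdr_bh")[1]
    out["significant"] = out["pearson_p"] < alpha
    return out


def metric_pairwise(
    subjects: Sequence[SubjectRecord], alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise correlations among the clinical metrics over patients.

    Computed overall and within medication-status subgroups when the
    subgroup has at least 3 complete pairs; otherwise the comparison is
    skipped with a note row.
    """
    pd_subjects = [s for s in subjects if s.true_class == PD]
    frame = pd.DataFrame(
        {
            "updrs_p3": [s.updrs_p3 for s in pd_subjects],
            "moca": [s.moca for s in pd_subjects],
            "ledd": [s.ledd for s in pd_subjects],
            "years_onset": [s.years_onset for s in pd_subjects],
            "medicated": [s.medicated for s in pd_subjects],
        },
        index=[s.id for s in pd_subjects],
    )
    groups = {"all": frame, "medicated": frame[frame.medicated], "unmedicated": frame[~frame.medicated]}
    records = []
    for gname, g in groups.items():
        for m1, m2 in combinations(CLINICAL_METRICS, 2):
            sub = g[[m1, m2]].dropna()
            if len(sub) < 3:
                records.append((gname, m1, m2, np.nan, np.nan, np.nan, np.nan, len(sub), "skipped: <3 complete pairs"))
                continue
            x, y = sub[m1].to_numpy(), sub[m2].to_numpy()
            if np.all(x == x[0]) or np.all(y == y[0]):
                records.append((gname, m1, m2, np.nan, np.nan, np.nan, np.nan, len(sub), "skipped: constant metric"))
                continue
            rho, p_rho = sps.pearsonr(x, y)
            t, p_t = _kendall(x, y)
            records.append((gname, m1, m2, float(rho), float(p_rho), t, p_t, len(sub), ""))
    out = pd.DataFrame(
        records,
        columns=["group", "metric_a", "metric_b", "pearson_rho", "pearson_p", "kendall_tau", "kendall_p", "n", "note"],
    ).set_index(["group", "metric_a", "metric_b"])
    out["significant"] = (out["pearson_p"] < alpha) | (out["kendall_p"] < alpha)
    return out


def network_memberships(atlas) -> dict[str, list[str]]:
    """Network name -> member area names, read off the atlas label table."""
    out: dict[str, list[str]] = {}
    for lab in atlas.labels:
        for net in sorted(lab.networks):
            out.setdefault(net, []).append(lab.name)
    return out
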