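"""Differential splicing and differential gene expression.

Plate data: distribution-level two-sample tests on per-cell PSI values.
The default pipeline combines the two-sample Anderson-Darling test with the
DTS statistic (a gap- and variance-weighted ECDF distance with permutation
inference), BH-adjusts each across tested events, takes the union of calls
at FDR < 0.10, and finally removes events whose significance is driven by
fewer than 10 interior-PSI cells in both populations.

Droplet data: pseudo-bulk splice-junction usage compared between two cell
populations with a label-permutation null (B = 100 by default); a junction
is called significant when the pooled mean log2 expression of its gene
exceeds 1.0, |dPSI| > 5 (percent) and the permutation p < 0.05.

Gene expression: Wilcoxon rank-sum on log2(x+1) values with BH control.
"""

from __future__ import annotations

import logging
import warnings
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .psi import PsiMatrix

log = logging.getLogger(__name__)

FDR_THRESHOLD = 0.10
OUTLIER_MIN_CELLS = 10
PLATE_LOG2FC_THRESHOLD = 0.5
DROPLET_LOG2FC_THRESHOLD = 1.0
DROPLET_EXPR_MIN = 1.0
DROPLET_DELTA_PSI_MIN = 5.0
DROPLET_P_MAX = 0.05


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def log2p1(x):
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def dts_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """DTS two-sample statistic: integral of |F1 - F2| over the pooled sample,
    weighted by the gap between consecutive pooled order statistics and the
    binomial standard deviation of the pooled ECDF."""
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    labels = np.concatenate([np.ones(x.size, bool), np.zeros(y.size, bool)])
    pooled = np.concatenate([x, y])
    order = np.argsort(pooled, kind="mergesort")
    z = pooled[order]
    lab = labels[order]
    return _dts_from_sorted(z, lab[None, :], x.size, y.size)[0]


def _dts_from_sorted(z: np.ndarray, lab: np.ndarray, n1: int, n2: int) -> np.ndarray:
    """DTS for B label rows over one sorted pooled sample (vectorized)."""
    n = z.size
    i = np.arange(1, n)  # evaluate at the first n-1 order statistics
    gaps = z[1:] - z[:-1]
    fp = i / n
    w = gaps / np.sqrt(fp * (1.0 - fp))
    c1 = np.cumsum(lab, axis=1)[:, :-1]
    f1 = c1 / n1
    f2 = (i[None, :] - c1) / n2
    return np.sum(np.abs(f1 - f2) * w[None, :], axis=1)


def _permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Smoothed permutation p-value, bounded below by 1/(B+1)."""
    b = null.size
    exceed = int(np.sum(null >= observed))
    return (1 + exceed) / (b + 1)


def two_sample_test(x: Sequence[float], y: Sequence[float], method: str,
                    n_perm: int = 1000,
                    rng: Optional[np.random.Generator] = None
                    ) -> tuple[float, float]:
    """Two-sample test of PSI distributions; returns (statistic, p_value).

    Methods: ks, ad, dts, wilcoxon, ttest, perm_mean. Insufficient samples
    (< 2 per group) yield (nan, nan) rather than an exception.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        return (np.nan, np.nan)
    if method == "ks":
        r = stats.ks_2samp(x, y)
        return float(r.statistic), float(r.pvalue)
    if method == "ad":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                r = stats.anderson_ksamp([x, y])
            except ValueError:  # all observations identical
                return (0.0, 1.0)
        return float(r.statistic), float(r.pvalue)
    if method == "wilcoxon":
        try:
            r = stats.mannwhitneyu(x, y, alternative="two-sided")
        except ValueError:
            return (np.nan, 1.0)
        return float(r.statistic), float(r.pvalue)
    if method == "ttest":
        r = stats.ttest_ind(x, y)
        p = float(r.pvalue) if np.isfinite(r.pvalue) else 1.0
        return float(r.statistic), p
    if method in ("dts", "perm_mean"):
        if rng is None:
            rng = np.random.default_rng()
        pooled = np.concatenate([x, y])
        labels = np.concatenate([np.ones(x.size, bool), np.zeros(y.size, bool)])
        order = np.argsort(pooled, kind="mergesort")
        z, lab = pooled[order], labels[order]
        perm_lab = rng.permuted(np.tile(lab, (n_perm, 1)), axis=1)
        if method == "dts":
            observed = _dts_from_sorted(z, lab[None, :], x.size, y.size)[0]
            null = _dts_from_sorted(z, perm_lab, x.size, y.size)
        else:
            observed = abs(x.mean() - y.mean())
            s1 = perm_lab @ z
            total = z.sum()
            null = np.abs(s1 / x.size - (total - s1) / y.size)
        return float(observed), _permutation_pvalue(observed, null)
    raise ValueError(f"unknown method {method!r}")


def remove_outlier_events(result: pd.DataFrame, psi: PsiMatrix,
                          groups: pd.Series, group_pair: tuple[str, str],
                          min_cells: int = OUTLIER_MIN_CELLS) -> pd.DataFrame:
    """Drop significant events driven by extreme-only cells.

    A significant event is retained only when at least one of the two
    populations has >= ``min_cells`` cells with PSI strictly inside (0, 1);
    otherwise it is flagged outlier-driven and de-called. Removal never adds
    significance.
    """
    g1, g2 = group_pair
    cells1 = groups.index[groups == g1]
    cells2 = groups.index[groups == g2]
    result = result.copy()
    result["outlier_removed"] = False
    for idx, row in result.iterrows():
        if not row["significant"]:
            continue
        ev = row["event_id"]
        interior = []
        for cells in (cells1, cells2):
            vals = psi.psi.loc[ev, psi.psi.columns.intersection(cells)].dropna()
            interior.append(int(((vals > 0) & (vals < 1)).sum()))
        if max(interior) < min_cells:
            result.loc[idx, "significant"] = False
            result.loc[idx, "outlier_removed"] = True
    return result


def differential_splicing_plate(psi: PsiMatrix, groups: pd.Series,
                                group_pair: tuple[str, str],
                                method: str = "ad+dts",
                                fdr_threshold: float = FDR_THRESHOLD,
                                min_cells: int = 25,
                                outlier_min: int = OUTLIER_MIN_CELLS,
                                n_perm: int = 1000,
                                seed: Optional[int] = None) -> pd.DataFrame:
    """Differential splicing between two cell populations (plate data).

    Events must carry a non-missing PSI in at least ``min_cells`` cells
    overall and at least 2 per population. ``method`` is one of ks, ad, dts,
    wilcoxon, ttest, perm_mean, or the default combination "ad+dts" (union
    of per-test BH calls at ``fdr_threshold``, then outlier removal).
    delta_psi is reported on the percent scale as group2 - group1.
    """
    g1, g2 = group_pair
    rng = np.random.default_rng(seed)
    cells1 = [c for c in psi.psi.columns if groups.get(c) == g1]
    cells2 = [c for c in psi.psi.columns if groups.get(c) == g2]
    if not cells1 or not cells2:
        raise ValueError(f"no cells found for groups {group_pair}")

    single = method != "ad+dts"
    methods = [method] if single else ["ad", "dts"]
    rows = []
    for ev in psi.psi.index:
        x = psi.psi.loc[ev, cells1].dropna().to_numpy()
        y = psi.psi.loc[ev, cells2].dropna().to_numpy()
        if x.size + y.size < min_cells:
            continue
        row = {"event_id": ev, "n_g1": x.size, "n_g2": y.size}
        if x.size < 2 or y.size < 2:
            row["skip_reason"] = "insufficient_cells_per_group"
            for m in methods:
                row[f"stat_{m}"], row[f"p_{m}"] = np.nan, np.nan
            rows.append(row)
            continue
        row["skip_reason"] = ""
        row["mean_psi_g1"] = 100.0 * x.mean()
        row["mean_psi_g2"] = 100.0 * y.mean()
        row["delta_psi"] = row["mean_psi_g2"] - row["mean_psi_g1"]
        for m in methods:
            stat, p = two_sample_test(x, y, m, n_perm=n_perm, rng=rng)
            row[f"stat_{m}"], row[f"p_{m}"] = stat, p
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["event_id"])
    table = pd.DataFrame(rows)
    sig = np.zeros(len(table), dtype=bool)
    for m in methods:
        table[f"fdr_{m}"] = bh_fdr(table[f"p_{m}"].to_numpy())
        sig |= (table[f"fdr_{m}"] < fdr_threshold).fillna(False).to_numpy()
    table["significant"] = sig
    table = remove_outlier_events(table, psi, groups, group_pair,
                                  min_cells=outlier_min)
    return table


def differential_genes(expression: pd.DataFrame, groups: pd.Series,
                       group_pair: tuple[str, str],
                       log2fc_threshold: float = PLATE_LOG2FC_THRESHOLD,
                       fdr_threshold: float = FDR_THRESHOLD,
                       min_cells: int = 3,
                       gene_subset: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression on log2(x+1) values.

    Genes must be expressed (nonzero) in at least ``min_cells`` cells.
    direction is "up"/"down" when FDR < ``fdr_threshold`` and |log2FC|
    exceeds ``log2fc_threshold`` (g2 vs g1), else "ns".
    """
    g1, g2 = group_pair
    cells1 = [c for c in expression.columns if groups.get(c) == g1]
    cells2 = [c for c in expression.columns if groups.get(c) == g2]
    expressed = (expression > 0).sum(axis=1) >= min_cells
    genes = expression.index[expressed]
    if gene_subset is not None:
        genes = genes.intersection(gene_subset)
    rows = []
    for gene in genes:
        x = log2p1(expression.loc[gene, cells1].to_numpy())
        y = log2p1(expression.loc[gene, cells2].to_numpy())
        log2_fc = float(y.mean() - x.mean())
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            try:
                p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
            except ValueError:
                p = 1.0
        rows.append({"gene_id": gene, "log2_fc": log2_fc, "p_value": p})
    table = pd.DataFrame(rows, columns=["gene_id", "log2_fc", "p_value"])
    if len(table):
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
        up = (table["fdr"] < fdr_threshold) & (table["log2_fc"] > log2fc_threshold)
        down = (table["fdr"] < fdr_threshold) & (table["log2_fc"] < -log2fc_threshold)
        table["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    else:
        table["fdr"] = []
        table["direction"] = []
    return table


def droplet_feature_filters(gene_expression: pd.DataFrame,
                            sj_counts: pd.DataFrame,
                            groups: pd.Series,
                            group_pair: tuple[str, str],
                            gene_of_junction: Mapping[str, str],
                            min_rate: float = 0.10
                            ) -> tuple[list[str], list[str]]:
    """Droplet expression-rate filters before differential junction usage.

    A gene is kept when its nonzero-expression fraction reaches ``min_rate``
    in *both* populations; a junction is kept when its nonzero-count
    fraction reaches ``min_rate`` in *either* population and its gene is
    kept.
    """
    g1, g2 = group_pair
    cells1 = [c for c in gene_expression.columns if groups.get(c) == g1]
    cells2 = [c for c in gene_expression.columns if groups.get(c) == g2]
    rate_g1 = (gene_expression[cells1] > 0).mean(axis=1)
    rate_g2 = (gene_expression[cells2] > 0).mean(axis=1)
    kept_genes = gene_expression.index[(rate_g1 >= min_rate)
                                       & (rate_g2 >= min_rate)]
    jr1 = (sj_counts[[c for c in cells1 if c in sj_counts.columns]] > 0).mean(axis=1)
    jr2 = (sj_counts[[c for c in cells2 if c in sj_counts.columns]] > 0).mean(axis=1)
    kept_set = set(kept_genes)
    kept_junctions = [j for j in sj_counts.index
                      if ((jr1.get(j, 0) >= min_rate) or (jr2.get(j, 0) >= min_rate))
                      and gene_of_junction.get(j) in kept_set]
    return list(kept_genes), kept_junctions


def differential_splicing_droplet(sj_counts: pd.DataFrame,
                                  gene_counts: pd.DataFrame,
                                  expression: pd.DataFrame,
                                  groups: pd.Series,
                                  group_pair: tuple[str, str],
                                  gene_of_junction: Mapping[str, str],
                                  n_perm: int = 100,
                                  seed: Optional[int] = None,
                                  delta_psi_min: float = DROPLET_DELTA_PSI_MIN,
                                  expr_min: float = DROPLET_EXPR_MIN,
                                  p_max: float = DROPLET_P_MAX,
                                  fdr_adjust: bool = False) -> pd.DataFrame:
    """Permutation-based differential splice-junction usage (droplet data).

    Usage is recomputed from raw counts for every label shuffle; group sizes
    are fixed by construction. p = (1 + #{|dPSI_perm| >= |dPSI_obs|}) /
    (n_perm + 1). A junction is significant when pooled mean log2(x+1)
    expression of its gene > ``expr_min``, |dPSI_obs| > ``delta_psi_min``
    and p < ``p_max`` (raw p by default; BH-adjusted when ``fdr_adjust``).
    """
    g1, g2 = group_pair
    rng = np.random.default_rng(seed)
    cells1 = [c for c in sj_counts.columns if groups.get(c) == g1]
    cells2 = [c for c in sj_counts.columns if groups.get(c) == g2]
    cells = cells1 + cells2
    n1 = len(cells1)
    junctions = list(sj_counts.index)
    genes = [gene_of_junction[j] for j in junctions]

    sj = sj_counts[cells].to_numpy(float)
    gc = gene_counts.reindex(genes)[cells].to_numpy(float)

    mask1 = np.zeros(len(cells), bool)
    mask1[:n1] = True

    def usage_delta(mask: np.ndarray) -> np.ndarray:
        num1, num2 = sj[:, mask].sum(axis=1), sj[:, ~mask].sum(axis=1)
        den1, den2 = gc[:, mask].sum(axis=1), gc[:, ~mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u1 = np.where(den1 > 0, num1 / np.maximum(den1, 1), np.nan)
            u2 = np.where(den2 > 0, num2 / np.maximum(den2, 1), np.nan)
        return 100.0 * (u2 - u1), u1, u2

    delta_obs, u1, u2 = usage_delta(mask1)
    exceed = np.zeros(len(junctions), dtype=int)
    for _ in range(n_perm):
        perm = rng.permutation(len(cells))
        pm = np.zeros(len(cells), bool)
        pm[perm[:n1]] = True
        d_perm, _, _ = usage_delta(pm)
        with np.errstate(invalid="ignore"):
            exceed += np.where(np.isnan(d_perm), False,
                               np.abs(d_perm) >= np.abs(delta_obs))
    pvals = (1 + exceed) / (n_perm + 1)

    expr = log2p1(expression.reindex(genes)[cells].to_numpy())
    mean_expr = np.nanmean(expr, axis=1)

    table = pd.DataFrame({
        "junction": junctions, "gene_id": genes,
        "usage_g1": u1, "usage_g2": u2,
        "mean_psi_g1": 100.0 * u1, "mean_psi_g2": 100.0 * u2,
        "delta_psi": delta_obs, "mean_log2_expr": mean_expr,
        "p_value": pvals})
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    crit_p = table["fdr"] if fdr_adjust else table["p_value"]
    table["significant"] = ((table["mean_log2_expr"] > expr_min)
                            & (table["delta_psi"].abs() > delta_psi_min)
                            & (crit_p < p_max)
                            & table["delta_psi"].notna())
    return table
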