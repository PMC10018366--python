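"""Joint interpretation of differential splicing and differential expression,
plus PSI-based linear dimension reduction.

Gene-splicing relationship classes for a differentially spliced event:
coordinated (gene DE, same sign as dPSI), opposing (gene DE, opposite
sign), isoform_switching (gene not DE). Genes whose events mix classes
summarize to "complex".
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

log = logging.getLogger(__name__)


def classify_relation(diff_splice: pd.DataFrame, diff_gene: pd.DataFrame,
                      event_gene: pd.Series) -> pd.DataFrame:
    """Classify each differentially spliced event against its gene's DE call.

    ``diff_splice`` needs event_id / delta_psi / significant columns;
    ``diff_gene`` needs gene_id / log2_fc / direction; ``event_gene`` maps
    event_id -> gene_id. Both tables must be computed on the same group
    orientation (delta and fold change both group2 vs group1). Returns the
    event-level relation plus a per-gene summary column.
    """
    gene_tab = diff_gene.set_index("gene_id")
    rows = []
    for _, row in diff_splice[diff_splice["significant"]].iterrows():
        ev = row["event_id"]
        gene = event_gene.get(ev)
        if gene is None or gene not in gene_tab.index:
            continue
        direction = gene_tab.loc[gene, "direction"]
        log2_fc = float(gene_tab.loc[gene, "log2_fc"])
        delta = float(row["delta_psi"])
        if direction == "ns":
            relation = "isoform_switching"
        elif delta == 0:
            # distribution shift without a mean shift: no sign to compare
            log.info("event %s has delta_psi == 0; classed isoform_switching", ev)
            relation = "isoform_switching"
        elif np.sign(log2_fc) == np.sign(delta):
            relation = "coordinated"
        else:
            relation = "opposing"
        rows.append({"gene_id": gene, "event_id": ev, "delta_psi": delta,
                     "log2_fc": log2_fc, "relation": relation})
    table = pd.DataFrame(rows, columns=["gene_id", "event_id", "delta_psi",
                                        "log2_fc", "relation"])
    if len(table):
        summary = table.groupby("gene_id")["relation"].agg(
            lambda r: r.iloc[0] if r.nunique() == 1 else "complex")
        table["gene_relation_summary"] = table["gene_id"].map(summary)
    else:
        table["gene_relation_summary"] = []
    return table


def gene_relation_summary(relations: pd.DataFrame) -> pd.Series:
    """Per-gene relation class (complex when a gene's events mix classes)."""
    return relations.groupby("gene_id")["relation"].agg(
        lambda r: r.iloc[0] if r.nunique() == 1 else "complex")


def pca_with_na_recoding(matrix: pd.DataFrame,
                         n_components: int = 2,
                         min_cells: int = 25,
                         seed: Optional[int] = None
                         ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of cells with missing PSI entries randomly recoded.

    Missing entries are replaced by i.i.d. Uniform(0, 100)/100 draws under
    ``seed`` (the recoding the PSI dimension-reduction workflow applies
    before PCA). Features observed in fewer than ``min_cells`` cells are
    dropped first. Returns (cells x components coordinates, explained
    variance fractions). No unit-variance scaling is applied.
    """
    keep = matrix.notna().sum(axis=1) >= min_cells
    mat = matrix.loc[keep]
    if mat.shape[0] < 2:
        raise ValueError("fewer than 2 features left after filtering")
    values = mat.to_numpy(float).T  # cells x features
    missing = np.isnan(values)
    if missing.any():
        rng = np.random.default_rng(seed)
        values[missing] = rng.uniform(0.0, 100.0, size=int(missing.sum())) / 100.0
    pca = PCA(n_components=min(n_components, min(values.shape) - 1),
              svd_solver="full")
    coords = pca.fit_transform(values - values.mean(axis=0))
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=mat.columns, columns=cols),
            pca.explained_variance_ratio_)
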