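"""Percent-spliced-in quantification.

Plate data: per-cell PSI per event as the ratio of junction reads supporting
the alternative form over all reads supporting or skipping it,

    psi[event, cell] = included / (included + excluded),

annotated missing when fewer than ``MIN_CELL_READS`` informative reads exist
in that cell. Retained introns use length-normalized per-base coverage
against intron-skipping junction reads. Droplet data: pseudo-bulk splice
junction usage per cell type,

    U[sj, type] = sum_cells counts[sj] / sum_cells counts[gene[sj]].

PSI is stored on [0, 1]; report-scale values are 100x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import EventType, IndependentIntron, SpliceEvent

#: per-cell informative-read floor below which PSI is a missing value
MIN_CELL_READS = 10


@dataclass
class PsiMatrix:
    """Events x cells PSI values with explicit missing state (NaN) and the
    per-entry informative-read support."""

    psi: pd.DataFrame
    support: pd.DataFrame

    @property
    def event_ids(self) -> list[str]:
        return list(self.psi.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.psi.columns)

    def to_tsv(self, path) -> None:
        self.psi.to_csv(path, sep="\t", na_rep="NA")


def compute_psi_plate(events: Iterable[SpliceEvent],
                      junction_counts: pd.DataFrame,
                      min_reads: int = MIN_CELL_READS) -> PsiMatrix:
    """Compute per-cell PSI for validated non-RI events (vectorized over cells)."""
    rows_psi, rows_sup, ids = [], [], []
    zeros = np.zeros(junction_counts.shape[1])
    for ev in events:
        if ev.event_type == EventType.RI:
            continue
        inc_keys = [str(j) for j in ev.included_junctions]
        exc_keys = [str(j) for j in ev.excluded_junctions]
        if not inc_keys or not exc_keys:
            raise ValueError(f"event {ev.event_id} has an empty junction set")
        inc = junction_counts.reindex(inc_keys).fillna(0).to_numpy().sum(axis=0)
        exc = junction_counts.reindex(exc_keys).fillna(0).to_numpy().sum(axis=0)
        total = inc + exc
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(total >= min_reads, inc / np.maximum(total, 1), np.nan)
        rows_psi.append(psi)
        rows_sup.append(total)
        ids.append(ev.event_id)
    cells = junction_counts.columns
    psi = pd.DataFrame(rows_psi, index=ids, columns=cells, dtype=float)
    support = pd.DataFrame(rows_sup, index=ids, columns=cells)
    return PsiMatrix(psi=psi, support=support)


def compute_psi_ri(introns: Iterable[IndependentIntron],
                   intron_coverage: pd.DataFrame,
                   junction_counts: pd.DataFrame,
                   min_norm_coverage: float = MIN_CELL_READS,
                   min_skip_reads: float = MIN_CELL_READS) -> PsiMatrix:
    """Retained-intron PSI from length-normalized coverage and skip reads.

    c = total intron coverage / intron length (bp). Missing when c < 10 or
    skip reads < 10; else psi = c / (c + skip).
    """
    rows_psi, rows_sup, ids = [], [], []
    cells = junction_counts.columns
    for intron in introns:
        if intron.intron_id not in intron_coverage.index:
            continue
        cov = intron_coverage.loc[intron.intron_id].reindex(cells).fillna(0).to_numpy(float)
        if (cov < 0).any():
            raise ValueError(f"negative coverage for intron {intron.intron_id}")
        skip_key = str(intron.skip_junction)
        if skip_key in junction_counts.index:
            skip = junction_counts.loc[skip_key].to_numpy(float)
        else:
            skip = np.zeros(len(cells))
        c = cov / intron.length_bp
        ok = (c >= min_norm_coverage) & (skip >= min_skip_reads)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi = np.where(ok, c / np.maximum(c + skip, 1e-300), np.nan)
        rows_psi.append(psi)
        rows_sup.append(c + skip)
        ids.append(intron.intron_id)
    psi = pd.DataFrame(rows_psi, index=ids, columns=cells, dtype=float)
    support = pd.DataFrame(rows_sup, index=ids, columns=cells, dtype=float)
    return PsiMatrix(psi=psi, support=support)


def compute_sj_usage(junction_counts: pd.DataFrame,
                     gene_counts: pd.DataFrame,
                     cell_types: pd.Series,
                     gene_of_junction: Mapping[str, str]) -> pd.DataFrame:
    """Cell-type-level splice-junction usage (droplet pseudo-bulk).

    Returns a long-format table (junction, cell_type, numerator, denominator,
    usage); usage is NaN when the pseudo-bulk gene count is zero.
    """
    rows = []
    cell_types = cell_types.reindex(junction_counts.columns)
    for jid in junction_counts.index:
        gene = gene_of_junction.get(jid)
        if gene is None:
            raise ValueError(f"junction {jid} has no assigned gene")
        for ct in sorted(cell_types.dropna().unique()):
            cells = cell_types.index[cell_types == ct]
            num = float(junction_counts.loc[jid, cells].sum())
            den = (float(gene_counts.loc[gene, cells].sum())
                   if gene in gene_counts.index else 0.0)
            usage = num / den if den > 0 else np.nan
            rows.append({"junction": jid, "cell_type": ct, "numerator": num,
                         "denominator": den, "usage": usage})
    return pd.DataFrame(rows, columns=["junction", "cell_type", "numerator",
                                       "denominator", "usage"])


def psi_summary_filters(psi: PsiMatrix, min_cells: int = 25) -> list[str]:
    """Events with a non-missing PSI (>= 10 informative reads by construction)
    in at least ``min_cells`` cells — the eligibility set for modality
    assignment and differential splicing."""
    n_obs = psi.psi.notna().sum(axis=1)
    return list(psi.psi.index[n_obs >= min_cells])
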