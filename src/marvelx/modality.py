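"""Beta-distribution modality classification of PSI distributions.

Each eligible event's per-cell PSI values are fitted with a beta
distribution by maximum likelihood; the fitted (alpha, beta) shapes and the
empirical variance drive a sequential rule set:

1. bimodal     if alpha < 0.5 or beta < 0.5
2. included    if (alpha > 2 and beta < 1) or alpha/beta > 2
3. excluded    if (beta > 2 and alpha < 1) or beta/alpha > 2
4. middle      if alpha > 1 and beta > 1 and alpha ~= beta
5. multimodal  otherwise

Included/excluded calls are sub-classified as primary (variance < 0.001) or
dispersed. The bimodality adjustment distinguishes genuinely bimodal PSI
distributions from amplification artifacts by comparing the proportions of
cells at the two distribution ends, and reassigns false bimodals to
included/excluded by their mean PSI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .psi import PsiMatrix
from .types import Modality, SubModality

log = logging.getLogger(__name__)

#: exact 0/1 observations (count-ratio extremes) are moved to this bound
#: before fitting; the beta likelihood is undefined at the boundary itself.
#: Interior values are left untouched — they pose no likelihood problem and
#: clipping them would bias the fit.
CLIP_EPS = 1e-3
#: empirical-variance threshold separating primary from dispersed
VARIANCE_THRESHOLD = 0.001
#: relative tolerance for the "alpha = beta" middle rule
EQUALITY_RTOL = 0.05
#: bimodality-adjustment thresholds: true bimodal iff fold < 3 and diff < 0.5
BIMODAL_FOLD_MAX = 3.0
BIMODAL_DIFF_MAX = 0.5
#: distribution-end cutoffs on the [0, 1] scale (percent 75 / 25)
HI_CUT = 0.75
LO_CUT = 0.25


@dataclass
class ModalityCall:
    event_id: str
    alpha: float
    beta: float
    sample_variance: float
    n_cells: int
    modality: Modality
    sub_modality: SubModality
    bimodal_adjusted: bool = False
    pre_adjustment_modality: Optional[Modality] = None
    fit_warning: bool = False


def fit_beta_mle(values: np.ndarray) -> tuple[float, float, bool]:
    """Maximum-likelihood beta shape parameters for PSI values on [0, 1].

    Exact 0/1 observations are moved to [eps, 1-eps] before likelihood
    evaluation (the boundary has undefined likelihood); interior values are
    used as-is. Returns (alpha, beta, degenerate_flag); a degenerate
    (constant) sample yields a moment-matched fit with the flag set.
    """
    x = np.asarray(values, dtype=float).copy()
    if x.size < 2:
        raise ValueError("beta fit requires at least 2 values")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("PSI values must lie in [0, 1]")
    x[x == 0.0] = CLIP_EPS
    x[x == 1.0] = 1.0 - CLIP_EPS
    m, v = float(np.mean(x)), float(np.var(x))
    if v < 1e-12:
        # constant sample: moment-match a sharp beta at the observed mean
        log.warning("degenerate PSI sample (constant after clipping); "
                    "returning moment-matched fit")
        conc = 1.0 / CLIP_EPS
        return max(m * conc, CLIP_EPS), max((1 - m) * conc, CLIP_EPS), True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha, beta, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    return float(alpha), float(beta), False


def classify_modality(alpha: float, beta: float,
                      sample_variance: float) -> tuple[Modality, SubModality]:
    """Sequential modality rules on fitted beta shapes (strict inequalities)."""
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError(f"non-finite beta parameters ({alpha}, {beta})")
    if alpha <= 0 or beta <= 0:
        raise ValueError("beta parameters must be positive")
    if alpha < 0.5 or beta < 0.5:
        modality = Modality.BIMODAL
    elif (alpha > 2 and beta < 1) or alpha / beta > 2:
        modality = Modality.INCLUDED
    elif (beta > 2 and alpha < 1) or beta / alpha > 2:
        modality = Modality.EXCLUDED
    elif alpha > 1 and beta > 1 and abs(alpha - beta) <= EQUALITY_RTOL * max(alpha, beta):
        modality = Modality.MIDDLE
    else:
        modality = Modality.MULTIMODAL
    if modality in (Modality.INCLUDED, Modality.EXCLUDED):
        sub = (SubModality.PRIMARY if sample_variance < VARIANCE_THRESHOLD
               else SubModality.DISPERSED)
    else:
        sub = SubModality.NONE
    return modality, sub


def adjust_bimodality(psi_values: np.ndarray) -> tuple[bool, Optional[Modality]]:
    """Decide whether a bimodal call is genuine; if not, reassign by mean PSI.

    p_hi/p_lo are the fractions of cells beyond the 75/25 percent cutoffs.
    True bimodality requires fold difference < 3 AND absolute difference
    < 50% (strict). A one-sided distribution (min proportion 0 -> infinite
    fold) is always a false bimodal. Returns (is_true_bimodal, reassignment).
    """
    x = np.asarray(psi_values, dtype=float)
    x = x[~np.isnan(x)]
    n_hi = int(np.sum(x > HI_CUT))
    n_lo = int(np.sum(x < LO_CUT))
    # integer-count ratio keeps boundary cases (fold exactly 3) exact
    lo, hi = min(n_hi, n_lo), max(n_hi, n_lo)
    fold = np.inf if lo == 0 else hi / lo
    diff = abs(n_hi - n_lo) / x.size
    if fold < BIMODAL_FOLD_MAX and diff < BIMODAL_DIFF_MAX:
        return True, None
    mean = float(np.mean(x))
    return False, Modality.INCLUDED if mean > 0.5 else Modality.EXCLUDED


def assign_modalities(psi: PsiMatrix, eligible_events: list[str],
                      bimodal_adjust: bool = True) -> pd.DataFrame:
    """Fit, classify and (optionally) bimodal-adjust every eligible event.

    Returns a table with columns: event_id, alpha, beta, variance, n_cells,
    modality, sub_modality, pre_adjustment_modality, adjusted_flag.
    """
    rows = []
    for event_id in eligible_events:
        values = psi.psi.loc[event_id].dropna().to_numpy()
        if values.size < 2:
            continue
        alpha, beta, degenerate = fit_beta_mle(values)
        variance = float(np.var(values))
        modality, sub = classify_modality(alpha, beta, variance)
        pre = None
        adjusted = False
        if bimodal_adjust and modality == Modality.BIMODAL:
            is_true, reassigned = adjust_bimodality(values)
            if not is_true:
                pre, modality, adjusted = modality, reassigned, True
                sub = (SubModality.PRIMARY if variance < VARIANCE_THRESHOLD
                       else SubModality.DISPERSED)
        rows.append({
            "event_id": event_id, "alpha": alpha, "beta": beta,
            "variance": variance, "n_cells": int(values.size),
            "modality": modality.value, "sub_modality": sub.value,
            "pre_adjustment_modality": pre.value if pre else "",
            "adjusted_flag": adjusted, "fit_warning": degenerate})
    return pd.DataFrame(rows, columns=["event_id", "alpha", "beta", "variance",
                                       "n_cells", "modality", "sub_modality",
                                       "pre_adjustment_modality",
                                       "adjusted_flag", "fit_warning"])


def classify_modality_dynamics(modality_g1: Optional[str], sub_g1: Optional[str],
                               modality_g2: Optional[str], sub_g2: Optional[str]
                               ) -> str:
    """Modality change class for a differentially spliced event.

    explicit: the five-class modality differs between populations;
    implicit: only the primary/dispersed sub-modality differs;
    restricted: no modality change despite the significant distribution shift;
    undefined: a modality call is missing in either population.
    """
    if not modality_g1 or not modality_g2:
        return "undefined"
    if modality_g1 != modality_g2:
        return "explicit"
    if (sub_g1 or "none") != (sub_g2 or "none"):
        return "implicit"
    return "restricted"


def modality_dynamics_table(calls_g1: pd.DataFrame, calls_g2: pd.DataFrame,
                            differential_events: list[str]) -> pd.DataFrame:
    """Per differentially spliced event, classify the modality dynamics."""
    g1 = calls_g1.set_index("event_id")
    g2 = calls_g2.set_index("event_id")
    rows = []
    for ev in differential_events:
        m1 = g1["modality"].get(ev)
        m2 = g2["modality"].get(ev)
        s1 = g1["sub_modality"].get(ev)
        s2 = g2["sub_modality"].get(ev)
        rows.append({"event_id": ev, "modality_g1": m1 or "", "modality_g2": m2 or "",
                     "dynamics": classify_modality_dynamics(m1, s1, m2, s2)})
    return pd.DataFrame(rows, columns=["event_id", "modality_g1",
                                       "modality_g2", "dynamics"])
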