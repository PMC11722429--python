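"""Bulk RNA-seq normalization chain, CV~mean noise filter and DE testing.

The normalization chain, applied in order:

1. divide counts by gene length in kilobases;
2. scale each sample to counts-per-million of its length-normalized total;
3. add a pedestal of 2 (stabilizes zeros before the log);
4. log2 transform;
5. cyclic loess across samples: for every sample pair, the M (difference)
   vs A (average) trend is smoothed with loess and half the fitted trend
   subtracted from each member, cycling over all pairs a configurable
   number of times.

Noise filtering fits, per condition, a loess curve of the per-gene
coefficient of variation (on the linear scale) against mean log2
expression; the noise threshold is the smallest mean at which the fitted
CV drops below a cutoff (default 0.5), and the final threshold is the max
over conditions. Genes below threshold in both conditions are removed
before differential testing (Welch t on log2 values, BH across genes).

A qPCR relative-quantification helper (2^-ΔΔCt) rounds out the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .meta import bh_adjust

logger = logging.getLogger(__name__)

PEDESTAL_DEFAULT = 2.0
LOESS_CYCLES_DEFAULT = 3
LOESS_FRAC_DEFAULT = 0.4
# CV~mean curves need a narrower span than MA trends to resolve the
# detection threshold where the CV drops sharply
NOISE_LOESS_FRAC_DEFAULT = 0.2
CV_CUTOFF_DEFAULT = 0.5


@dataclass
class NormalizedMatrix:
    """Genes × samples log2 expression plus processing provenance."""

    data: pd.DataFrame
    provenance: List[str] = field(default_factory=list)


@dataclass
class NoiseModel:
    """Per-condition fitted CV-vs-mean curves and the derived threshold."""

    curves: Dict[str, pd.DataFrame]       # condition -> (mean, cv, fitted_cv)
    thresholds: Dict[str, float]          # per-condition mean-expression cutoffs
    noise_threshold: float                # max over conditions
    cv_cutoff: float


def length_normalize(counts: pd.DataFrame, gene_length: pd.Series) -> pd.DataFrame:
    """Counts per kilobase of gene length."""
    lengths = gene_length.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    return counts.div(lengths / 1000.0, axis=0)


def cpm(values: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (column) to a total of one million."""
    totals = values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total: {list(zero.index)}")
    return values.div(totals, axis=1) * 1e6


def cyclic_loess(
    logmat: pd.DataFrame,
    cycles: int = LOESS_CYCLES_DEFAULT,
    frac: float = LOESS_FRAC_DEFAULT,
) -> pd.DataFrame:
    """Pairwise MA-trend normalization across samples.

    For each ordered pair (i, j), M = x_i − x_j is loess-smoothed against
    A = (x_i + x_j)/2 and half the fitted trend moved from x_i to x_j,
    cycling ``cycles`` times over all pairs. Identical samples have M = 0
    everywhere and are left untouched.
    """
    x = logmat.to_numpy(dtype=float).copy()
    n_samples = x.shape[1]
    for _ in range(cycles):
        for i in range(n_samples - 1):
            for j in range(i + 1, n_samples):
                m = x[:, i] - x[:, j]
                if np.allclose(m, 0):
                    continue
                a = 0.5 * (x[:, i] + x[:, j])
                fit = lowess(m, a, frac=frac, it=2, return_sorted=False)
                x[:, i] -= fit / 2.0
                x[:, j] += fit / 2.0
    return pd.DataFrame(x, index=logmat.index, columns=logmat.columns)


def normalize_chain(
    counts: pd.DataFrame,
    gene_length: pd.Series,
    pedestal: float = PEDESTAL_DEFAULT,
    loess_cycles: int = LOESS_CYCLES_DEFAULT,
    loess_frac: float = LOESS_FRAC_DEFAULT,
) -> NormalizedMatrix:
    """Length-norm → CPM → pedestal → log2 → cyclic loess, with provenance."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    steps = []
    x = length_normalize(counts, gene_length)
    steps.append("length_normalized (per kb)")
    x = cpm(x)
    steps.append("cpm (column totals 1e6)")
    x = np.log2(x + pedestal)
    steps.append(f"pedestal +{pedestal} and log2")
    x = cyclic_loess(x, cycles=loess_cycles, frac=loess_frac)
    steps.append(f"cyclic loess ({loess_cycles} cycles, frac={loess_frac})")
    return NormalizedMatrix(data=x, provenance=steps)


def fit_noise_model(
    normalized: NormalizedMatrix,
    condition: pd.Series,
    cv_cutoff: float = CV_CUTOFF_DEFAULT,
    loess_frac: float = NOISE_LOESS_FRAC_DEFAULT,
) -> NoiseModel:
    """Fit per-condition CV~mean curves and derive the noise threshold.

    Per condition and gene: the mean of log2 expression (x axis) and the
    coefficient of variation sd/mean of the linearized (2**x) values
    across replicates (y axis); the CV is loess-smoothed against the mean
    and the threshold is the smallest mean at which the fitted curve falls
    below ``cv_cutoff`` (the low boundary when it is below everywhere, the
    high boundary when it never falls below).
    """
    data = normalized.data
    if len(data) < 50:
        raise ValueError("need at least 50 genes to fit a noise model")
    curves: Dict[str, pd.DataFrame] = {}
    thresholds: Dict[str, float] = {}
    for cond in condition.unique():
        cols = condition.index[condition == cond]
        if len(cols) < 2:
            raise ValueError(f"condition {cond} has fewer than 2 replicates")
        block = data[cols]
        mean_log = block.mean(axis=1).to_numpy()
        linear = np.power(2.0, block.to_numpy())
        cv = linear.std(axis=1, ddof=1) / linear.mean(axis=1)
        order = np.argsort(mean_log)
        fitted = np.empty_like(cv)
        fitted[order] = lowess(
            cv[order], mean_log[order], frac=loess_frac, it=2, return_sorted=False
        )
        curves[cond] = pd.DataFrame(
            {"mean_log2": mean_log, "cv": cv, "fitted_cv": fitted}, index=data.index
        )
        below = fitted[order] < cv_cutoff
        if below.all():
            thr = float(mean_log[order][0])      # low boundary: nothing filtered
        elif not below.any():
            thr = float(mean_log[order][-1])     # high boundary: all noise-biased
        else:
            thr = float(mean_log[order][np.argmax(below)])
        thresholds[cond] = thr
    return NoiseModel(
        curves=curves,
        thresholds=thresholds,
        noise_threshold=max(thresholds.values()),
        cv_cutoff=cv_cutoff,
    )


def filter_noise(
    normalized: NormalizedMatrix,
    model: NoiseModel,
    condition: pd.Series,
) -> Tuple[pd.DataFrame, pd.Index]:
    """Remove noise-biased genes below the model's threshold.

    A gene is kept when its mean log2 expression reaches the threshold in
    at least one condition (condition-wise max). Returns the kept matrix
    and the removed gene index; kept + removed = input.
    """
    data = normalized.data
    per_cond = pd.DataFrame(
        {
            cond: data[condition.index[condition == cond]].mean(axis=1)
            for cond in condition.unique()
        }
    )
    keep = per_cond.max(axis=1) >= model.noise_threshold
    removed = data.index[~keep]
    kept = data.loc[keep]
    assert len(kept) + len(removed) == len(data)
    return kept, removed


def differential_expression(
    filtered: pd.DataFrame,
    condition: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per gene on normalized log2 values, KD vs NT.

    Returns log2fc (mean KD − mean NT on the log2 scale), p, BH-adjusted
    p, and a direction ("up"/"down" for significant genes, else "none").
    """
    kd_cols = condition.index[condition == "KD"]
    nt_cols = condition.index[condition == "NT"]
    if len(kd_cols) < 2 or len(nt_cols) < 2:
        raise ValueError("need >= 2 replicates per condition")
    kd = filtered[kd_cols].to_numpy()
    nt = filtered[nt_cols].to_numpy()
    lfc = kd.mean(axis=1) - nt.mean(axis=1)
    res = stats.ttest_ind(kd, nt, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    adj = bh_adjust(p)
    direction = np.where(
        adj < alpha, np.where(lfc > 0, "up", "down"), "none"
    )
    return pd.DataFrame(
        {
            "gene_id": filtered.index,
            "log2fc": lfc,
            "p": p,
            "adj_p": adj,
            "direction": direction,
        }
    ).set_index("gene_id", drop=False)


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """qPCR relative quantification: fold change = 2^−ΔΔCt."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct_val = (ct_target_treated - ct_ref_treated) - (
        ct_target_control - ct_ref_control
    )
    return float(2.0 ** (-ddct_val))
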