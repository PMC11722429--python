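"""Single-timepoint dSILAC protein half-life analysis.

After a switch to heavy lysine/arginine media, newly synthesized protein
appears in the heavy channel. Under steady-state turnover the heavy/light
intensity ratio R of a peptide after labeling time ts (days) determines the
half-life:

    t_half = ts * ln(2) / ln(1 + R)

(equivalently R = 2**(ts/t_half) - 1). Protein half-lives are the harmonic
mean over the protein's unique peptides; differential turnover, abundance
and phosphosite calls between knockdown and control use Welch t-tests on
log2 values with Benjamini–Hochberg correction and fold-change thresholds.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .meta import bh_adjust

logger = logging.getLogger(__name__)

MIN_INTENSITY_DEFAULT = 1000.0
RATIO_LOW_DEFAULT = 0.01
RATIO_HIGH_DEFAULT = 100.0


def filter_peptides(
    table: pd.DataFrame,
    min_intensity: float = MIN_INTENSITY_DEFAULT,
    ratio_low: float = RATIO_LOW_DEFAULT,
    ratio_high: float = RATIO_HIGH_DEFAULT,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply peptide-level quality filters.

    Removes contaminant-flagged peptides, intensities *below*
    ``min_intensity``, and H/L ratios *lower than* ``ratio_low`` or
    *higher than* ``ratio_high`` (all strict inequalities, so boundary
    values are retained). Returns the kept table plus a removal log whose
    counts attribute each removed row to the first criterion it failed;
    kept + removed = input.
    """
    n_in = len(table)
    removal = {"contaminant": 0, "low_intensity": 0, "ratio_out_of_range": 0}

    contam = table["is_contaminant"].astype(bool)
    low_int = ~contam & (table["intensity"] < min_intensity)
    bad_ratio = (
        ~contam
        & ~low_int
        & ((table["hl_ratio"] < ratio_low) | (table["hl_ratio"] > ratio_high))
    )
    removal["contaminant"] = int(contam.sum())
    removal["low_intensity"] = int(low_int.sum())
    removal["ratio_out_of_range"] = int(bad_ratio.sum())
    kept = table.loc[~(contam | low_int | bad_ratio)].reset_index(drop=True)
    removal["kept"] = len(kept)
    removal["input"] = n_in
    assert removal["kept"] + removal["contaminant"] + removal["low_intensity"] + removal[
        "ratio_out_of_range"
    ] == n_in
    return kept, removal


def peptide_half_life(hl_ratio, ts):
    """Half-life in days from a heavy/light ratio at labeling time ts.

    ``t_half = ts * ln(2) / ln(1 + R)``; strictly decreasing in R.
    """
    r = np.asarray(hl_ratio, dtype=float)
    t = np.asarray(ts, dtype=float)
    if np.any(r <= 0):
        raise ValueError("heavy/light ratio must be > 0")
    if np.any(t <= 0):
        raise ValueError("labeling time must be > 0")
    out = t * np.log(2.0) / np.log1p(r)
    return out.item() if np.ndim(hl_ratio) == 0 and np.ndim(ts) == 0 else out


def _harmonic_mean(values: np.ndarray) -> float:
    return len(values) / np.sum(1.0 / values)


def protein_half_life(
    peptides: pd.DataFrame,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Roll peptide half-lives up to proteins by harmonic mean.

    Peptides sharing a sequence within a group are first collapsed to the
    median of their half-lives (charge states and repeated measurements of
    one peptide count once); the protein half-life is then the harmonic
    mean over the distinct peptide sequences. Grouping is per
    (protein, condition) with peptides pooled across replicates by
    default, or per (protein, condition, replicate) when
    ``per_replicate=True``.

    Input must carry a ``half_life`` column (see :func:`peptide_half_life`).
    """
    if "half_life" not in peptides.columns:
        peptides = peptides.assign(
            half_life=peptide_half_life(
                peptides["hl_ratio"].to_numpy(), peptides["ts"].to_numpy()
            )
        )
    keys = ["protein_id", "condition"] + (["replicate"] if per_replicate else [])
    collapsed = (
        peptides.groupby(keys + ["peptide_seq"], sort=False)["half_life"]
        .median()
        .reset_index()
    )
    rolled = collapsed.groupby(keys)["half_life"].agg(
        half_life=_harmonic_mean, n_peptides="size"
    )
    return rolled.reset_index()


def differential(
    kd: pd.DataFrame,
    nt: pd.DataFrame,
    log2fc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature KD-vs-control differential test on positive values.

    ``kd`` and ``nt`` are feature × replicate matrices of positive values
    (half-lives or intensities) indexed by feature id. For each feature
    with >= 2 finite replicates per condition: log2 fold change
    ``log2(mean_KD / mean_NT)``, two-sided Welch t-test on the log2 values,
    BH adjustment across tested features, and
    ``is_significant = |log2fc| >= log2fc_threshold AND adj_p < alpha``.
    Default thresholds are the half-life volcano settings (0.5 / 0.05);
    abundance and phosphosite calls use ``log2fc_threshold=1``.
    """
    shared = kd.index.intersection(nt.index)
    dropped = len(kd.index.union(nt.index)) - len(shared)
    if dropped:
        logger.info("%d features present in only one condition; excluded", dropped)

    rows = []
    for fid in shared:
        a = np.log2(kd.loc[fid].dropna().astype(float).to_numpy())
        b = np.log2(nt.loc[fid].dropna().astype(float).to_numpy())
        if len(a) < 2 or len(b) < 2:
            logger.info("feature %s has < 2 replicates in a condition; omitted", fid)
            continue
        lfc = np.mean(a) - np.mean(b)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(lfc, 0):
            p = 1.0  # degenerate: identical constant groups
        else:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
            if not np.isfinite(p):
                p = 1.0
        rows.append({"feature_id": fid, "log2fc": lfc, "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(adj_p=[], is_significant=[])
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["is_significant"] = (np.abs(out["log2fc"]) >= log2fc_threshold) & (
        out["adj_p"] < alpha
    )
    return out.set_index("feature_id", drop=False)


def density_shift_summary(
    halflife_kd: pd.Series, halflife_nt: pd.Series
) -> Dict[str, float]:
    """Global turnover shift between conditions over shared proteins.

    Reports the median paired ``log2(t_half_KD / t_half_NT)`` and the
    two-sided Wilcoxon signed-rank p-value. A positive median means
    globally slower turnover (longer half-lives) under knockdown.
    """
    shared = halflife_kd.index.intersection(halflife_nt.index)
    if len(shared) < 10:
        logger.warning("only %d shared proteins; shift estimate is unstable", len(shared))
    ratios = np.log2(
        halflife_kd.loc[shared].to_numpy() / halflife_nt.loc[shared].to_numpy()
    )
    if np.allclose(ratios, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(ratios).pvalue)
    return {
        "n_shared": int(len(shared)),
        "median_log2_ratio": float(np.median(ratios)),
        "wilcoxon_p": p,
    }
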