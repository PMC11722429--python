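"""Cross-screen fixed-effect meta-analysis of CRISPRi screen statistics.

Heterogeneous per-screen gene results (raw log fold changes or phenotype
scores, each on its own scale, with a two-sided p-value) are harmonized to
a common standardized scale and pooled by inverse-variance weighting.

Harmonization, per screen:

* ``beta`` — the screen's effect column standardized to zero mean, unit
  variance across its genes (a rank-free z-scoring of the native scale);
* ``p_trunc`` — the reported p-value truncated away from 0 and 1 so the
  normal quantile stays finite (extreme p-values would otherwise distort
  the pooled statistics; truncation makes results conservative);
* ``z`` — ``sign(beta) * Phi^-1(1 - p_trunc / 2)``, the test statistic
  implied by the reported p-value, signed by the effect;
* ``se`` — ``|beta| / |z|``, the standard error under which the
  standardized effect reproduces the reported evidence.

Pooling, per gene over the screens of a combination, is the classical
fixed-effect model: weights ``w_i = 1/se_i^2``, pooled effect
``sum(w b)/sum(w)``, pooled SE ``sum(w)^-1/2``, with Cochran's Q and I²
reporting heterogeneity (reported, never used to drop genes). A gene is a
*novel* association of a combination when no constituent screen calls it
significant after per-screen FDR adjustment but the pooled meta-analysis
does; hits additionally require directionality relative to the population
reference (|delta| >= an LFC-style threshold, default 1).
"""

from __future__ import annotations

import logging
from itertools import combinations as iter_combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

P_FLOOR_DEFAULT = 1e-300
P_CEILING_MARGIN_DEFAULT = 1e-16
EPSILON_BETA = 1e-8


def truncate_p(
    p,
    p_floor: float = P_FLOOR_DEFAULT,
    p_ceiling_margin: float = P_CEILING_MARGIN_DEFAULT,
):
    """Clamp p-values into ``[p_floor, 1 - p_ceiling_margin]``.

    Stabilizes extreme p-values (0 underflows, 1 gives a zero z) before
    conversion to normal quantiles. Monotone non-decreasing in ``p``.
    Scalar in, scalar out; array in, array out.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(np.maximum(arr, p_floor), 1.0 - p_ceiling_margin)
    return out.item() if np.isscalar(p) or np.ndim(p) == 0 else out


def harmonize_screen(
    table: pd.DataFrame,
    p_floor: float = P_FLOOR_DEFAULT,
    p_ceiling_margin: float = P_CEILING_MARGIN_DEFAULT,
    beta_mode: str = "zscored_effect",
    epsilon_beta: float = EPSILON_BETA,
) -> pd.DataFrame:
    """Standardize one screen's results to (beta, z, se) on a common scale.

    Parameters
    ----------
    table : DataFrame with columns ``gene_id, effect, p_raw``.
    beta_mode : "zscored_effect" (default) standardizes the effect column
        to mean 0, sd 1 across the screen's genes; "raw_effect" keeps the
        native scale (for inputs that are already standardized).

    Returns a DataFrame with columns
    ``gene_id, beta, p_trunc, z, se, beta_zero_flag``, indexed by gene.
    """
    effect = table["effect"].to_numpy(dtype=float)
    finite = np.isfinite(effect)
    if finite.sum() < 3:
        raise ValueError("need at least 3 genes with finite effects")
    sd = effect[finite].std()
    if beta_mode == "zscored_effect":
        if sd == 0:
            raise ValueError("effect column has zero spread; cannot standardize")
        beta = (effect - effect[finite].mean()) / sd
    elif beta_mode == "raw_effect":
        beta = effect.copy()
    else:
        raise ValueError(f"unknown beta_mode: {beta_mode!r}")

    p_trunc = truncate_p(table["p_raw"].to_numpy(dtype=float), p_floor, p_ceiling_margin)
    sign = np.where(beta >= 0, 1.0, -1.0)
    z = sign * stats.norm.isf(p_trunc / 2.0)

    # beta exactly 0: SE = |beta|/|z| degenerates; substitute an epsilon
    # effect and flag the gene.
    zero = beta == 0
    abs_beta = np.where(zero, epsilon_beta, np.abs(beta))
    se = abs_beta / np.abs(z)

    out = pd.DataFrame(
        {
            "gene_id": table["gene_id"].to_numpy(),
            "beta": beta,
            "p_trunc": p_trunc,
            "z": z,
            "se": se,
            "beta_zero_flag": zero,
        }
    ).set_index("gene_id", drop=False)
    n_trunc = int(
        np.sum(
            (table["p_raw"].to_numpy() < p_floor)
            | (table["p_raw"].to_numpy() > 1 - p_ceiling_margin)
        )
    )
    if n_trunc:
        logger.info("truncated %d extreme p-values", n_trunc)
    return out


def fixed_effect_pool(
    beta: np.ndarray, se: np.ndarray
) -> Dict[str, np.ndarray]:
    """Inverse-variance fixed-effect pooling with Cochran's Q and I².

    ``beta`` and ``se`` are arrays of shape (k,) for one gene or (n, k)
    for n genes over k screens. All SEs must be finite and positive;
    k must be >= 2.
    """
    b = np.atleast_2d(np.asarray(beta, dtype=float))
    s = np.atleast_2d(np.asarray(se, dtype=float))
    if b.shape != s.shape:
        raise ValueError("beta and se shapes differ")
    k = b.shape[1]
    if k < 2:
        raise ValueError("need at least 2 screens to pool")
    if np.any(~np.isfinite(s)) or np.any(s <= 0):
        raise ValueError("all standard errors must be finite and > 0")

    w = 1.0 / s**2
    sw = w.sum(axis=1)
    beta_pooled = (w * b).sum(axis=1) / sw
    se_pooled = sw**-0.5
    z_meta = beta_pooled / se_pooled
    p_meta = 2.0 * stats.norm.sf(np.abs(z_meta))
    q_stat = (w * (b - beta_pooled[:, None]) ** 2).sum(axis=1)
    q_df = k - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        i2 = np.where(q_stat > 0, np.maximum(0.0, (q_stat - q_df) / q_stat), 0.0)

    squeeze = np.ndim(beta) == 1
    out = {
        "beta_pooled": beta_pooled,
        "se_pooled": se_pooled,
        "z_meta": z_meta,
        "p_meta": p_meta,
        "q_stat": q_stat,
        "q_df": np.full(b.shape[0], q_df),
        "i2": i2,
    }
    if squeeze:
        out = {key: val[0] for key, val in out.items()}
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def screen_fdr(harmonized: pd.DataFrame) -> pd.Series:
    """Per-screen BH-adjusted p over the screen's full gene universe."""
    return pd.Series(
        bh_adjust(harmonized["p_trunc"].to_numpy()),
        index=harmonized.index,
        name="fdr_screen",
    )


def assess_novelty(
    meta: pd.DataFrame,
    constituent_fdrs: Mapping[str, pd.Series],
    alpha: float = 0.05,
) -> pd.Series:
    """Novelty rule: significant after meta FDR, in no constituent screen.

    ``is_novel = (fdr_screen >= alpha in every constituent) AND
    (fdr_meta < alpha)``.
    """
    not_sig_everywhere = np.ones(len(meta), dtype=bool)
    for sid, fdr in constituent_fdrs.items():
        aligned = fdr.reindex(meta.index)
        if aligned.isna().any():
            raise ValueError(f"screen {sid} missing FDRs for some meta genes")
        not_sig_everywhere &= (aligned >= alpha).to_numpy()
    return pd.Series(
        not_sig_everywhere & (meta["fdr_meta"] < alpha).to_numpy(),
        index=meta.index,
        name="is_novel",
    )


def classify_hits(
    meta: pd.DataFrame,
    population_reference: Optional[float] = None,
    lfc_threshold: float = 1.0,
    population_ref_mode: str = "all",
) -> pd.Series:
    """Directionality call relative to the population reference.

    ``up`` when novel and ``beta_pooled - reference >= lfc_threshold``;
    ``down`` when novel and ``<= -lfc_threshold`` (boundaries inclusive);
    ``none`` otherwise. The reference defaults to the mean pooled effect
    over all genes of the combination (``population_ref_mode="all"``), or
    over its novel genes (``"hits"``).
    """
    if population_reference is None:
        if population_ref_mode == "all":
            population_reference = float(meta["beta_pooled"].mean())
        elif population_ref_mode == "hits":
            novel = meta.loc[meta["is_novel"], "beta_pooled"]
            population_reference = float(novel.mean()) if len(novel) else float(
                meta["beta_pooled"].mean()
            )
        else:
            raise ValueError(f"unknown population_ref_mode: {population_ref_mode!r}")
    if not np.isfinite(population_reference):
        raise ValueError("population reference must be finite")
    delta = meta["beta_pooled"].to_numpy() - population_reference
    novel = meta["is_novel"].to_numpy()
    direction = np.where(
        novel & (delta >= lfc_threshold),
        "up",
        np.where(novel & (delta <= -lfc_threshold), "down", "none"),
    )
    return pd.Series(direction, index=meta.index, name="hit_direction")


def _combo_key(screen_ids: Sequence[str]) -> str:
    return "+".join(sorted(screen_ids))


def run_meta(
    screens: Mapping[str, pd.DataFrame],
    combinations: Union[str, Iterable[Sequence[str]]] = "all",
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    population_ref_mode: str = "all",
) -> Dict[str, pd.DataFrame]:
    """Fixed-effect meta-analysis over screen combinations.

    Parameters
    ----------
    screens : mapping of screen_id -> harmonized table
        (output of :func:`harmonize_screen`).
    combinations : "all" for every subset of >= 2 screens, or an explicit
        iterable of screen-id sequences.

    Returns a dict keyed by sorted screen ids joined with "+"; each value
    is a MetaResult DataFrame over the combination's gene intersection
    with pooled statistics, heterogeneity, FDR, novelty and hit direction.
    """
    ids = sorted(screens)
    if len(ids) < 2:
        raise ValueError("need at least 2 screens")
    if combinations == "all":
        requested: List[Sequence[str]] = [
            c for r in range(2, len(ids) + 1) for c in iter_combinations(ids, r)
        ]
    else:
        requested = [tuple(c) for c in combinations]
        for c in requested:
            if len(c) < 2:
                raise ValueError(f"combination {c} has fewer than 2 screens")

    fdrs = {sid: screen_fdr(screens[sid]) for sid in ids}

    results: Dict[str, pd.DataFrame] = {}
    for combo in requested:
        key = _combo_key(combo)
        gene_sets = [set(screens[sid].index) for sid in combo]
        shared = sorted(set.intersection(*gene_sets))
        if not shared:
            raise ValueError(f"combination {key} has an empty gene intersection")
        beta = np.column_stack(
            [screens[sid].loc[shared, "beta"].to_numpy() for sid in combo]
        )
        se = np.column_stack(
            [screens[sid].loc[shared, "se"].to_numpy() for sid in combo]
        )
        pooled = fixed_effect_pool(beta, se)
        meta = pd.DataFrame(pooled, index=pd.Index(shared, name="gene_id"))
        meta["k_screens"] = len(combo)
        meta["fdr_meta"] = bh_adjust(meta["p_meta"].to_numpy())
        meta["is_novel"] = assess_novelty(
            meta, {sid: fdrs[sid] for sid in combo}, alpha=alpha
        )
        meta["hit_direction"] = classify_hits(
            meta,
            lfc_threshold=lfc_threshold,
            population_ref_mode=population_ref_mode,
        )
        logger.info("combination %s: %d genes pooled", key, len(meta))
        results[key] = meta
    return results
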