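"""Cryptic splice-junction calling and mis-splicing categorization.

Loss of a splicing repressor (here TDP-43) de-represses normally silent
splice sites, producing cryptic exons: junctions essentially absent from
control samples that appear upon knockdown. Working from per-sample
percent-spliced-in (PSI) values, a junction is *significant* when
|ΔΨ| > 10% (ΔΨ = mean KD PSI − mean control PSI) and *cryptic* when

    ΔΨ > 0.10 and present in < 5% of control samples, or
    ΔΨ < −0.10 and present in > 10% of control samples

with "present" meaning PSI at or above a small detection floor (default
0.01). All inequalities are strict. Mis-spliced junctions are further
categorized against an exon annotation as cryptic exon, exon skipping,
intron retention or canonical junction. Coordinates are 0-based half-open;
categories are strand-symmetric.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_right
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DPSI_THRESHOLD_DEFAULT = 0.10
LOW_PRESENCE_DEFAULT = 0.05
HIGH_PRESENCE_DEFAULT = 0.10
DETECT_PSI_MIN_DEFAULT = 0.01

CATEGORY_CRYPTIC = "cryptic_exon"
CATEGORY_SKIPPING = "exon_skipping"
CATEGORY_RETENTION = "intron_retention"
CATEGORY_CANONICAL = "canonical_junction"
CATEGORY_OTHER = "other"

_PSI_COL = re.compile(r"^psi_(control|KD)_(\d+)$")


def psi_columns(table: pd.DataFrame) -> Tuple[list, list]:
    """Split ``psi_control_*`` / ``psi_KD_*`` sample columns by group."""
    ctrl = [c for c in table.columns if _PSI_COL.match(c) and "control" in c]
    kd = [c for c in table.columns if _PSI_COL.match(c) and "KD" in c]
    if not ctrl or not kd:
        raise ValueError("need psi_control_* and psi_KD_* columns")
    return ctrl, kd


def delta_psi(table: pd.DataFrame) -> pd.Series:
    """ΔΨ = mean(KD PSI) − mean(control PSI), missing values excluded.

    Records with a group entirely missing get NaN (and are logged);
    downstream rules skip them.
    """
    ctrl_cols, kd_cols = psi_columns(table)
    ctrl = table[ctrl_cols].mean(axis=1, skipna=True)
    kd = table[kd_cols].mean(axis=1, skipna=True)
    out = kd - ctrl
    n_bad = int(out.isna().sum())
    if n_bad:
        logger.info("%d records lack PSI in an entire group; skipped", n_bad)
    return out.rename("delta_psi")


def control_presence(
    table: pd.DataFrame, detect_psi_min: float = DETECT_PSI_MIN_DEFAULT
) -> pd.Series:
    """Fraction of control samples in which the junction is detected.

    Detection means PSI >= ``detect_psi_min``; missing PSIs count as not
    detected but stay in the denominator of observed samples.
    """
    ctrl_cols, _ = psi_columns(table)
    vals = table[ctrl_cols]
    detected = (vals >= detect_psi_min).sum(axis=1)
    observed = vals.notna().sum(axis=1)
    return (detected / observed).rename("control_presence")


def call_cryptic(
    dpsi: pd.Series,
    presence: pd.Series,
    dpsi_threshold: float = DPSI_THRESHOLD_DEFAULT,
    low_presence: float = LOW_PRESENCE_DEFAULT,
    high_presence: float = HIGH_PRESENCE_DEFAULT,
) -> pd.DataFrame:
    """Apply the significance and cryptic rules (strict inequalities).

    significant: |ΔΨ| > dpsi_threshold.
    cryptic: (ΔΨ > dpsi_threshold and presence < low_presence) or
    (ΔΨ < −dpsi_threshold and presence > high_presence).
    Cryptic implies significant by construction.
    """
    d = dpsi.to_numpy(dtype=float)
    pres = presence.to_numpy(dtype=float)
    significant = np.abs(d) > dpsi_threshold
    cryptic = ((d > dpsi_threshold) & (pres < low_presence)) | (
        (d < -dpsi_threshold) & (pres > high_presence)
    )
    significant = np.where(np.isnan(d), False, significant)
    cryptic = np.where(np.isnan(d) | np.isnan(pres), False, cryptic)
    assert not np.any(cryptic & ~significant)
    return pd.DataFrame(
        {"significant": significant, "cryptic": cryptic}, index=dpsi.index
    )


class AnnotationModel:
    """Exon annotation indexed for junction categorization.

    Built from an exon table (``gene, chrom, start, end, strand``,
    0-based half-open). Derives per-chromosome donor/acceptor site sets,
    adjacency (which sites flank the same intron) and intron intervals.
    """

    def __init__(self, exons: pd.DataFrame) -> None:
        self.donors: Dict[str, set] = {}
        self.acceptors: Dict[str, set] = {}
        self.introns: Dict[str, list] = {}      # (start, end) intron intervals
        self.exon_spans: Dict[str, list] = {}   # sorted (start, end) exon intervals
        for (gene, chrom), block in exons.groupby(["gene", "chrom"]):
            block = block.sort_values("start")
            starts = block["start"].to_numpy()
            ends = block["end"].to_numpy()
            self.donors.setdefault(chrom, set()).update(ends)
            self.acceptors.setdefault(chrom, set()).update(starts)
            self.exon_spans.setdefault(chrom, []).extend(zip(starts, ends))
            for i in range(len(block) - 1):
                self.introns.setdefault(chrom, []).append((ends[i], starts[i + 1]))
        for chrom in self.exon_spans:
            self.exon_spans[chrom].sort()
        for chrom in self.introns:
            self.introns[chrom].sort()

    def _in_intron(self, chrom: str, pos: int) -> bool:
        for s, e in self.introns.get(chrom, []):
            if s < pos < e:
                return True
        return False

    def _spans_exon(self, chrom: str, start: int, end: int) -> bool:
        for s, e in self.exon_spans.get(chrom, []):
            if start <= s and e <= end and not (s == start and e == end):
                return True
        return False

    def categorize(self, chrom: str, start: int, end: int,
                   annotation: Optional[str] = None) -> str:
        """Assign a mis-splicing category to one junction.

        canonical — both ends at annotated splice sites with no annotated
        exon inside; exon skipping — both ends annotated, >= 1 annotated
        exon fully inside the junction; cryptic exon — >= 1 end at an
        unannotated position inside an annotated intron; intron
        retention — the record represents intronic inclusion
        (``within_intron`` annotation status; a true junction between two
        adjacent splice sites shares its coordinates with the intron, so
        retention cannot be inferred from coordinates alone). Anything
        unresolvable is ``other``.
        """
        if start >= end:
            raise ValueError(f"junction {chrom}:{start}-{end} violates start < end")
        if annotation == "within_intron":
            return CATEGORY_RETENTION
        donor_known = start in self.donors.get(chrom, set())
        acceptor_known = end in self.acceptors.get(chrom, set())
        if donor_known and acceptor_known:
            if self._spans_exon(chrom, start, end):
                return CATEGORY_SKIPPING
            return CATEGORY_CANONICAL
        if (not donor_known and self._in_intron(chrom, start)) or (
            not acceptor_known and self._in_intron(chrom, end)
        ):
            return CATEGORY_CRYPTIC
        logger.info("junction %s:%d-%d unresolvable; categorized 'other'", chrom, start, end)
        return CATEGORY_OTHER


def categorize(table: pd.DataFrame, exons: pd.DataFrame) -> pd.Series:
    """Categorize every junction record against an exon annotation."""
    model = AnnotationModel(exons)
    cats = [
        model.categorize(
            row.chrom, int(row.start), int(row.end),
            getattr(row, "annotation", None),
        )
        for row in table.itertuples()
    ]
    return pd.Series(cats, index=table.index, name="category")


def classify_junctions(
    table: pd.DataFrame,
    exons: Optional[pd.DataFrame] = None,
    dpsi_threshold: float = DPSI_THRESHOLD_DEFAULT,
    low_presence: float = LOW_PRESENCE_DEFAULT,
    high_presence: float = HIGH_PRESENCE_DEFAULT,
    detect_psi_min: float = DETECT_PSI_MIN_DEFAULT,
) -> pd.DataFrame:
    """Full junction-calling pipeline: ΔΨ, presence, cryptic flag, category."""
    out = table[["junction_id", "chrom", "start", "end", "strand"]].copy()
    out["delta_psi"] = delta_psi(table)
    out["control_presence"] = control_presence(table, detect_psi_min)
    flags = call_cryptic(
        out["delta_psi"], out["control_presence"],
        dpsi_threshold, low_presence, high_presence,
    )
    out["significant"] = flags["significant"]
    out["cryptic"] = flags["cryptic"]
    if exons is not None:
        out["category"] = categorize(table, exons)
    return out
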