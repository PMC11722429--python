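"""Dual-sgRNA read-pair parsing, recombination filtering and counting.

Lentiviral delivery of dual-guide cassettes suffers template switching
during reverse transcription, producing proviruses whose two guides come
from different constructs. Such recombined pairs would be mis-assigned in
a pooled FACS screen, so read pairs are kept only when the guide found in
read 1 (position A) and the guide found in read 2 (position B) belong to
the same construct; pairs whose guides map to different constructs are
discarded as recombined, everything else is unmapped.

A small permutation-based gene scorer is included so a synthetic screen can
be taken from FASTQ to per-gene statistics without external screen
software; it is deliberately simple plumbing, not a re-implementation of
published guide-ranking algorithms.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

MATCHED = "matched"
RECOMBINED = "recombined"
UNMAPPED = "unmapped"


@dataclass
class ParseStats:
    """Read-pair accounting; total = matched + recombined + unmapped."""

    n_pairs_total: int = 0
    n_matched: int = 0
    n_recombined: int = 0
    n_unmapped: int = 0

    def check(self) -> None:
        assert self.n_pairs_total == (
            self.n_matched + self.n_recombined + self.n_unmapped
        )


def validate_library(library: pd.DataFrame) -> None:
    """Enforce guide-library invariants (unique per-position sequences,
    NT flag consistent with the target-gene column)."""
    required = {"construct_id", "guide_a_seq", "guide_b_seq", "target_gene", "is_nt"}
    missing = required - set(library.columns)
    if missing:
        raise ValueError(f"library missing columns: {sorted(missing)}")
    if library["guide_a_seq"].duplicated().any():
        raise ValueError("guide_a_seq not unique across constructs")
    if library["guide_b_seq"].duplicated().any():
        raise ValueError("guide_b_seq not unique across constructs")
    nt_mismatch = library["is_nt"] != (library["target_gene"] == "non-targeting")
    if nt_mismatch.any():
        raise ValueError("is_nt flag inconsistent with target_gene == 'non-targeting'")


class GuideIndex:
    """Exact-substring lookup of guides within a read window.

    Guides are indexed by sequence per position (A for read 1, B for
    read 2). ``search_window`` restricts the scanned start offsets
    (0-based, half-open); the default scans the whole read.
    """

    def __init__(
        self,
        library: pd.DataFrame,
        search_window: Optional[Tuple[int, int]] = None,
        same_gene_ok: bool = False,
    ) -> None:
        validate_library(library)
        self.a_index: Dict[str, int] = {
            s: i for i, s in enumerate(library["guide_a_seq"])
        }
        self.b_index: Dict[str, int] = {
            s: i for i, s in enumerate(library["guide_b_seq"])
        }
        self.construct_ids = library["construct_id"].to_numpy()
        self.genes = library["target_gene"].to_numpy()
        self.lengths_a = sorted({len(s) for s in self.a_index})
        self.lengths_b = sorted({len(s) for s in self.b_index})
        self.window = search_window
        self.same_gene_ok = same_gene_ok

    def _find(self, read: str, index: Dict[str, int], lengths) -> Optional[int]:
        if not read:
            return None
        lo, hi = 0, len(read)
        if self.window is not None:
            lo = max(self.window[0], 0)
            hi = min(self.window[1], len(read))
        for k in lengths:
            for start in range(lo, hi - k + 1):
                hit = index.get(read[start : start + k])
                if hit is not None:
                    return hit
        return None

    def match_read_pair(self, read1_seq: str, read2_seq: str) -> Tuple[str, Optional[str]]:
        """Classify one read pair.

        Returns ``(outcome, construct_id)`` where outcome is ``matched``
        (both guides found, same construct — or same target gene when the
        relaxed flag is set), ``recombined`` (both found, different
        constructs/genes) or ``unmapped`` (either guide missing).
        """
        ia = self._find(read1_seq or "", self.a_index, self.lengths_a)
        ib = self._find(read2_seq or "", self.b_index, self.lengths_b)
        if ia is None or ib is None:
            return UNMAPPED, None
        if ia == ib:
            return MATCHED, self.construct_ids[ia]
        if self.same_gene_ok and self.genes[ia] == self.genes[ib] and not (
            self.genes[ia] == "non-targeting"
        ):
            # relaxed reading: paired guides for the same target gene
            return MATCHED, self.construct_ids[ia]
        return RECOMBINED, None


def match_read_pair(
    read1_seq: str,
    read2_seq: str,
    library: pd.DataFrame,
    search_window: Optional[Tuple[int, int]] = None,
    same_gene_ok: bool = False,
) -> Tuple[str, Optional[str]]:
    """One-shot convenience wrapper around :class:`GuideIndex`."""
    return GuideIndex(library, search_window, same_gene_ok).match_read_pair(
        read1_seq, read2_seq
    )


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_pairs(fastq1, fastq2) -> Iterator[Tuple[str, str]]:
    """Iterate paired sequences from two FASTQ(.gz) files."""
    with _open_maybe_gz(fastq1) as f1, _open_maybe_gz(fastq2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        i = 0
        while True:
            try:
                rec1 = next(it1, None)
                rec2 = next(it2, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at pair {i}: {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError("FASTQ files have unequal numbers of records")
            yield rec1[1], rec2[1]
            i += 1


def count_pairs(
    pairs: Iterable[Tuple[str, str]], index: GuideIndex
) -> Tuple[pd.Series, ParseStats]:
    """Count matched construct assignments over a read-pair stream."""
    counts = pd.Series(0, index=index.construct_ids, dtype=np.int64)
    stats = ParseStats()
    for r1, r2 in pairs:
        stats.n_pairs_total += 1
        outcome, cid = index.match_read_pair(r1, r2)
        if outcome == MATCHED:
            stats.n_matched += 1
            counts[cid] += 1
        elif outcome == RECOMBINED:
            stats.n_recombined += 1
        else:
            stats.n_unmapped += 1
    stats.check()
    return counts, stats


def count_constructs(
    fastq_low: Tuple[str, str],
    fastq_high: Tuple[str, str],
    library: pd.DataFrame,
    search_window: Optional[Tuple[int, int]] = None,
    same_gene_ok: bool = False,
) -> Tuple[pd.DataFrame, Dict[str, ParseStats]]:
    """Per-construct counts for the low and high FACS fluorescence bins.

    ``fastq_low`` / ``fastq_high`` are (read1, read2) path pairs. Returns a
    CountTable (``construct_id, count_low, count_high``) and per-bin
    :class:`ParseStats`.
    """
    index = GuideIndex(library, search_window, same_gene_ok)
    low_counts, low_stats = count_pairs(read_pairs(*fastq_low), index)
    high_counts, high_stats = count_pairs(read_pairs(*fastq_high), index)
    table = pd.DataFrame(
        {
            "construct_id": library["construct_id"].to_numpy(),
            "count_low": low_counts.to_numpy(),
            "count_high": high_counts.to_numpy(),
        }
    )
    return table, {"low": low_stats, "high": high_stats}


def filter_low_count(table: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop constructs with fewer than ``min_total`` reads across bins."""
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = (table["count_low"] + table["count_high"]) >= min_total
    if not keep.any():
        logger.warning("all %d constructs fall below min_total=%d", len(table), min_total)
    return table.loc[keep].reset_index(drop=True)


def score_genes_permutation(
    table: pd.DataFrame,
    library: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Plumbing gene scorer: per-gene median log-ratio with permutation p.

    Counts are first normalized per bin to equal totals (library-size
    normalization); each construct's effect is
    ``log2((high + c) / (low + c))`` with pseudocount ``c``; a gene's effect
    is the median over its constructs. The two-sided p-value is the
    fraction of ``n_perm`` random same-size construct sets whose absolute
    median effect is at least the observed one, with the standard
    +1/(n_perm + 1) correction. Non-targeting constructs contribute to the
    permutation pool but are not scored as a gene.
    """
    rng = np.random.default_rng(seed)
    merged = table.merge(
        library[["construct_id", "target_gene", "is_nt"]], on="construct_id"
    )
    tot_low = merged["count_low"].sum()
    tot_high = merged["count_high"].sum()
    if tot_low == 0 or tot_high == 0:
        raise ValueError("a bin has zero total counts")
    scale = (tot_low + tot_high) / 2.0
    norm_low = merged["count_low"] * (scale / tot_low)
    norm_high = merged["count_high"] * (scale / tot_high)
    merged["effect"] = np.log2(norm_high + pseudocount) - np.log2(
        norm_low + pseudocount
    )

    pool = merged["effect"].to_numpy()
    scored = merged.loc[~merged["is_nt"]]
    gene_effect = scored.groupby("target_gene")["effect"].agg(["median", "size"])

    results = []
    for size, block in gene_effect.groupby("size"):
        perm = rng.choice(pool, size=(n_perm, int(size)), replace=True)
        null_abs = np.abs(np.median(perm, axis=1))
        obs = np.abs(block["median"].to_numpy())
        exceed = (null_abs[None, :] >= obs[:, None]).sum(axis=1)
        pvals = (exceed + 1.0) / (n_perm + 1.0)
        results.append(
            pd.DataFrame(
                {
                    "gene_id": block.index,
                    "effect": block["median"].to_numpy(),
                    "p_raw": pvals,
                    "n_constructs": int(size),
                }
            )
        )
    out = pd.concat(results, ignore_index=True).sort_values("gene_id")
    return out.reset_index(drop=True)
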