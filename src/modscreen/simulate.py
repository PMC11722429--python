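"""Synthetic-data generators with planted ground truth.

Every pipeline input — per-screen gene tables, paired dual-guide FASTQ,
dSILAC peptide tables, splice-junction PSI tables and negative-binomial
count matrices — can be generated here with a known truth table, so the
downstream statistics are testable without any external download.

All generators are deterministic under a fixed :class:`~modscreen.config.SimConfig`
seed; each draws from its own named substream (see ``SimConfig.rng``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimConfig, InvalidConfigError

BASES = np.array(list("ACGT"))

# gene classes planted in screen tables
CLASS_NULL = "null"
CLASS_SHARED = "shared"
CLASS_SPECIFIC = "specific"
CLASS_WEAK = "distributed_weak"


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def gen_screen_tables(cfg: SimConfig) -> Tuple[List[pd.DataFrame], pd.DataFrame]:
    """Simulate per-screen gene-level result tables.

    Null genes draw effects from a standard normal; the two-sided p-value is
    computed from the same draw treated as a z statistic, so null p-values
    are uniform. Shared hits carry the planted effect (mean
    ``cfg.effect_mean``, sd ``cfg.effect_sd``, random sign per gene) in every
    screen; screen-specific hits in exactly one screen; distributed-weak
    genes carry ``cfg.weak_effect_mean`` in every screen — individually
    sub-threshold, jointly detectable.

    Returns
    -------
    tables : list of DataFrame
        One per screen, columns ``screen_id, gene_id, effect, p_raw``.
    truth : DataFrame
        Columns ``gene_id, truth_class, truth_sign``.
    """
    rng = cfg.rng("screens")
    n = cfg.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(n)])

    n_shared = int(round(cfg.frac_shared_hits * n))
    n_specific = int(round(cfg.frac_specific_hits * n))
    n_weak = int(round(cfg.frac_weak_hits * n))
    if n_shared + n_specific + n_weak > n:
        raise InvalidConfigError("more planted hits than genes")

    order = rng.permutation(n)
    shared_idx = order[:n_shared]
    specific_idx = order[n_shared:n_shared + n_specific]
    weak_idx = order[n_shared + n_specific:n_shared + n_specific + n_weak]

    truth_class = np.full(n, CLASS_NULL, dtype=object)
    truth_class[shared_idx] = CLASS_SHARED
    truth_class[specific_idx] = CLASS_SPECIFIC
    truth_class[weak_idx] = CLASS_WEAK

    sign = np.zeros(n)
    planted = np.concatenate([shared_idx, specific_idx, weak_idx]).astype(int)
    sign[planted] = rng.choice([-1.0, 1.0], size=planted.size)

    # which screen hosts each specific hit
    host = rng.integers(0, cfg.n_screens, size=n_specific)

    tables = []
    for s in range(cfg.n_screens):
        effect = rng.standard_normal(n)
        mean = np.zeros(n)
        mean[shared_idx] = sign[shared_idx] * cfg.effect_mean
        mean[weak_idx] = sign[weak_idx] * cfg.weak_effect_mean
        mine = specific_idx[host == s]
        mean[mine] = sign[mine] * cfg.effect_mean
        hit = mean != 0
        # planted genes: effect around the planted mean with sd effect_sd
        effect[hit] = mean[hit] + rng.standard_normal(hit.sum()) * cfg.effect_sd
        p_raw = 2.0 * stats.norm.sf(np.abs(effect))
        tables.append(
            pd.DataFrame(
                {
                    "screen_id": f"screen_{s}",
                    "gene_id": gene_ids,
                    "effect": effect,
                    "p_raw": p_raw,
                }
            )
        )

    truth = pd.DataFrame(
        {"gene_id": gene_ids, "truth_class": truth_class, "truth_sign": sign}
    )
    return tables, truth


# ---------------------------------------------------------------------------
# dual-guide library and reads
# ---------------------------------------------------------------------------

def _random_kmers(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n distinct random k-mers."""
    seen: set = set()
    out: List[str] = []
    while len(out) < n:
        batch = ["".join(seq) for seq in rng.choice(BASES, size=(n, k))]
        for s in batch:
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return np.array(out)


def make_guide_library(cfg: SimConfig, n_nt: int = 10) -> pd.DataFrame:
    """Dual-guide library: one construct per target gene plus NT controls.

    Guide sequences are unique within each position (A and B) and across
    positions. Non-targeting constructs have ``target_gene`` set to
    ``"non-targeting"``.
    """
    rng = cfg.rng("library")
    n = cfg.n_constructs
    kmers = _random_kmers(rng, 2 * n, cfg.guide_length)
    guide_a, guide_b = kmers[:n], kmers[n:]
    genes = [f"G{i:06d}" for i in range(n - n_nt)] + ["non-targeting"] * n_nt
    return pd.DataFrame(
        {
            "construct_id": [f"C{i:05d}" for i in range(n)],
            "guide_a_seq": guide_a,
            "guide_b_seq": guide_b,
            "target_gene": genes,
            "is_nt": [g == "non-targeting" for g in genes],
        }
    )


@dataclass
class TruthCounts:
    """Per-construct intended counts and the realized recombined tally."""

    counts: pd.Series          # construct_id -> matched pairs written
    n_recombined: int
    n_total: int


def gen_dual_guide_reads(
    cfg: SimConfig,
    library: pd.DataFrame,
    fastq1_path,
    fastq2_path,
    weights: Optional[np.ndarray] = None,
    stage: str = "reads",
) -> TruthCounts:
    """Write paired FASTQ files for a pooled dual-guide sample.

    A fraction ``cfg.recombination_rate`` of pairs are recombined: guide A
    from one construct, guide B from another construct targeting a
    *different* gene (so the pair is recombined under both the
    same-construct and the same-gene reading of the filter). The guides are
    embedded at a random offset in random-sequence reads.

    ``weights`` (optional, per construct) sets relative construct
    abundances, e.g. to plant a depleted gene in one FACS bin.
    """
    if library.empty:
        raise ValueError("guide library is empty")
    rng = cfg.rng(stage)
    n = cfg.n_reads
    m = len(library)
    glen = len(library["guide_a_seq"].iloc[0])
    pad = max(cfg.read_length - glen, 2)

    p = None
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        p = weights / weights.sum()
    construct = rng.choice(m, size=n, p=p)
    recombined = rng.random(n) < cfg.recombination_rate

    genes = library["target_gene"].to_numpy()
    if recombined.any() and len(set(genes)) < 2:
        raise ValueError("library has a single target gene; cannot recombine")
    # partner for recombined pairs: a construct with a different target gene
    partner = construct.copy()
    for i in np.flatnonzero(recombined):
        while True:
            j = rng.integers(m)
            if genes[j] != genes[construct[i]]:
                partner[i] = j
                break

    ga = library["guide_a_seq"].to_numpy()
    gb = library["guide_b_seq"].to_numpy()
    offsets = rng.integers(0, pad, size=(n, 2))
    flank = rng.choice(BASES, size=(n, 2, pad))

    qual = "I" * cfg.read_length
    with open(fastq1_path, "w") as f1, open(fastq2_path, "w") as f2:
        for i in range(n):
            a = ga[construct[i]]
            b = gb[partner[i]]
            left1 = "".join(flank[i, 0, : offsets[i, 0]])
            right1 = "".join(flank[i, 0, offsets[i, 0]:])
            left2 = "".join(flank[i, 1, : offsets[i, 1]])
            right2 = "".join(flank[i, 1, offsets[i, 1]:])
            r1 = (left1 + a + right1)[: cfg.read_length]
            r2 = (left2 + b + right2)[: cfg.read_length]
            f1.write(f"@read{i}/1\n{r1}\n+\n{qual[: len(r1)]}\n")
            f2.write(f"@read{i}/2\n{r2}\n+\n{qual[: len(r2)]}\n")

    matched = construct[~recombined]
    counts = (
        pd.Series(matched)
        .value_counts()
        .reindex(range(m), fill_value=0)
        .sort_index()
    )
    counts.index = library["construct_id"].to_numpy()
    return TruthCounts(counts=counts, n_recombined=int(recombined.sum()), n_total=n)


# ---------------------------------------------------------------------------
# dSILAC peptides
# ---------------------------------------------------------------------------

def noiseless_ratio(half_life: np.ndarray, ts: float) -> np.ndarray:
    """Heavy/light ratio implied by a half-life at steady-state turnover:
    R = 2**(ts / t_half) - 1."""
    return 2.0 ** (ts / np.asarray(half_life, dtype=float)) - 1.0


def gen_peptide_table(cfg: SimConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a peptide-level dSILAC quantification table.

    Each protein gets a true half-life drawn uniformly from
    ``cfg.true_halflife_range`` (days). A fraction
    ``cfg.frac_halflife_change`` of proteins have their KD half-life scaled
    by ``2**cfg.halflife_lfc``. Peptide H/L ratios are the noiseless value
    ``2**(ts/t_half) - 1`` times multiplicative log-normal noise with
    CV ``cfg.ratio_cv``; intensities are log-normal around 1e5.

    Contaminant-flagged proteins and out-of-range ratio rows are injected
    at ``cfg.contaminant_rate`` / ``cfg.outlier_ratio_rate``.

    Returns the peptide table and a truth table with columns
    ``protein_id, condition, truth_half_life, truth_changed``.
    """
    rng = cfg.rng("peptides")
    ts = cfg.labeling_time
    lo, hi = cfg.true_halflife_range
    base_t = rng.uniform(lo, hi, size=cfg.n_proteins)
    changed = rng.random(cfg.n_proteins) < cfg.frac_halflife_change
    sigma = np.sqrt(np.log1p(cfg.ratio_cv**2)) if cfg.ratio_cv > 0 else 0.0

    plo, phi = cfg.peptides_per_protein
    n_pep = rng.integers(plo, phi + 1, size=cfg.n_proteins)

    rows = []
    truth_rows = []
    pep_counter = 0
    for k in range(cfg.n_proteins):
        pid = f"P{k:05d}"
        pep_seqs = [f"PEP{pep_counter + j:07d}" for j in range(n_pep[k])]
        pep_counter += n_pep[k]
        for cond in ("NT", "KD"):
            t_half = base_t[k]
            if cond == "KD" and changed[k]:
                t_half = base_t[k] * 2.0 ** cfg.halflife_lfc
            truth_rows.append(
                {
                    "protein_id": pid,
                    "condition": cond,
                    "truth_half_life": t_half,
                    "truth_changed": bool(changed[k]),
                }
            )
            r0 = noiseless_ratio(t_half, ts)
            for rep in range(1, cfg.n_replicates + 1):
                noise = (
                    np.exp(rng.standard_normal(n_pep[k]) * sigma - sigma**2 / 2)
                    if sigma > 0
                    else np.ones(n_pep[k])
                )
                intensities = np.exp(rng.standard_normal(n_pep[k]) * 0.8 + np.log(1e5))
                for j, seq in enumerate(pep_seqs):
                    rows.append(
                        {
                            "peptide_seq": seq,
                            "protein_id": pid,
                            "condition": cond,
                            "replicate": rep,
                            "intensity": intensities[j],
                            "hl_ratio": r0 * noise[j],
                            "ts": ts,
                            "is_contaminant": False,
                        }
                    )

    table = pd.DataFrame(rows)

    # injected nuisance rows: contaminants and out-of-range ratios
    n_contam = int(round(cfg.contaminant_rate * len(table)))
    n_outlier = int(round(cfg.outlier_ratio_rate * len(table)))
    extra = []
    for i in range(n_contam):
        extra.append(
            {
                "peptide_seq": f"CONTAMPEP{i:05d}",
                "protein_id": f"CONTAM{i % 7:03d}",
                "condition": "NT",
                "replicate": 1,
                "intensity": 1e5,
                "hl_ratio": 1.0,
                "ts": ts,
                "is_contaminant": True,
            }
        )
    for i in range(n_outlier):
        extra.append(
            {
                "peptide_seq": f"OUTLIERPEP{i:05d}",
                "protein_id": f"P{int(rng.integers(cfg.n_proteins)):05d}",
                "condition": "NT",
                "replicate": 1,
                "intensity": 1e5,
                "hl_ratio": float(rng.choice([0.001, 500.0])),
                "ts": ts,
                "is_contaminant": False,
            }
        )
    if extra:
        table = pd.concat([table, pd.DataFrame(extra)], ignore_index=True)

    truth = pd.DataFrame(truth_rows)
    return table, truth


# ---------------------------------------------------------------------------
# splice junctions on a toy genome
# ---------------------------------------------------------------------------

CATEGORY_CRYPTIC = "cryptic_exon"
CATEGORY_SKIPPING = "exon_skipping"
CATEGORY_RETENTION = "intron_retention"
CATEGORY_CANONICAL = "canonical_junction"


def _toy_annotation(n_genes: int, exon_len: int = 200, intron_len: int = 1000) -> pd.DataFrame:
    """Three-exon genes laid head-to-tail on one forward-strand chromosome."""
    rows = []
    pos = 1000
    for g in range(n_genes):
        for e in range(3):
            rows.append(
                {
                    "gene": f"TG{g:05d}",
                    "chrom": "chrT",
                    "start": pos,
                    "end": pos + exon_len,
                    "strand": "+",
                    "exon_number": e + 1,
                }
            )
            pos += exon_len + intron_len
        pos += 5000  # intergenic gap
    return pd.DataFrame(rows)


def gen_junction_table(
    cfg: SimConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a junction PSI table plus its toy exon annotation.

    Categories are planted with unambiguous geometry on three-exon genes:

    * canonical — joins the annotated ends of two adjacent exons; PSI high
      in both groups.
    * cryptic exon — donor at an annotated exon end, acceptor mid-intron;
      control PSI 0 (absent from controls), KD PSI = ``cfg.cryptic_dpsi``.
    * exon skipping — joins exon 1 to exon 3, spanning annotated exon 2;
      present in controls, KD PSI raised above the ΔΨ threshold.
    * intron retention — the record covers an intron (annotation
      ``within_intron``) with elevated inclusion in KD.

    PSI values get additive Gaussian noise of sd ``cfg.psi_noise``, clipped
    to [0, 1]. Returns ``(junctions, annotation, truth)``; truth carries
    ``truth_category`` and ``truth_cryptic``.
    """
    if cfg.n_samples_per_group < 2:
        raise InvalidConfigError("n_samples_per_group must be >= 2")
    rng = cfg.rng("junctions")
    n = cfg.n_junctions
    n_genes = n  # one junction per toy gene keeps geometry independent
    anno = _toy_annotation(n_genes)

    n_cr = int(round(cfg.frac_cryptic * n))
    n_sk = int(round(cfg.frac_skipping * n))
    n_ir = int(round(cfg.frac_retention * n))
    cats = np.array(
        [CATEGORY_CRYPTIC] * n_cr
        + [CATEGORY_SKIPPING] * n_sk
        + [CATEGORY_RETENTION] * n_ir
        + [CATEGORY_CANONICAL] * (n - n_cr - n_sk - n_ir),
        dtype=object,
    )
    rng.shuffle(cats)

    nc = cfg.n_samples_per_group
    ctrl_cols = [f"psi_control_{i + 1}" for i in range(nc)]
    kd_cols = [f"psi_KD_{i + 1}" for i in range(nc)]

    def noisy(values: np.ndarray) -> np.ndarray:
        if cfg.psi_noise > 0:
            values = values + rng.standard_normal(values.shape) * cfg.psi_noise
        return np.clip(values, 0.0, 1.0)

    by_gene = {g: df.sort_values("exon_number") for g, df in anno.groupby("gene")}

    rows = []
    truth_rows = []
    for j in range(n):
        ex = list(by_gene[f"TG{j:05d}"].itertuples())
        cat = cats[j]
        if cat == CATEGORY_CANONICAL:
            start, end = ex[0].end, ex[1].start
            annotation = "both_ends_annotated"
            ctrl = noisy(np.full(nc, 0.9))
            kd = noisy(np.full(nc, 0.9))
        elif cat == CATEGORY_SKIPPING:
            start, end = ex[0].end, ex[2].start
            annotation = "both_ends_annotated"
            ctrl = noisy(np.full(nc, 0.30))
            kd = noisy(np.full(nc, 0.60))
        elif cat == CATEGORY_CRYPTIC:
            start = ex[0].end
            end = ex[0].end + 400  # acceptor mid-intron, unannotated
            annotation = "one_end_novel"
            ctrl = np.zeros(nc)  # absent from every control sample
            kd = noisy(np.full(nc, cfg.cryptic_dpsi))
        else:  # intron retention: record covers intron 2
            start, end = ex[1].end, ex[2].start
            annotation = "within_intron"
            ctrl = noisy(np.full(nc, 0.05))
            kd = noisy(np.full(nc, 0.40))
        row = {
            "junction_id": f"J{j:06d}",
            "chrom": "chrT",
            "start": int(start),
            "end": int(end),
            "strand": "+",
            "annotation": annotation,
        }
        row.update(dict(zip(ctrl_cols, ctrl)))
        row.update(dict(zip(kd_cols, kd)))
        rows.append(row)
        truth_rows.append(
            {
                "junction_id": f"J{j:06d}",
                "truth_category": cat,
                "truth_cryptic": cat == CATEGORY_CRYPTIC,
            }
        )

    return pd.DataFrame(rows), anno, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def gen_count_matrix(
    cfg: SimConfig,
) -> Tuple[pd.DataFrame, pd.Series, pd.Series, pd.DataFrame]:
    """Simulate a two-condition negative-binomial count matrix.

    Per-gene baseline means are log-normal; counts are NB with dispersion
    ``cfg.nb_dispersion`` (var = mu + dispersion * mu^2). A fraction
    ``cfg.frac_de`` of genes are shifted by ±``cfg.de_lfc`` (log2) in KD.

    Returns ``(counts, gene_lengths, condition_labels, truth)`` with counts
    genes × samples, sample names ``NT_1.. KD_1..``.
    """
    rng = cfg.rng("counts")
    n = cfg.n_genes
    k = cfg.n_samples_per_group
    genes = [f"G{i:06d}" for i in range(n)]
    samples = [f"NT_{i + 1}" for i in range(k)] + [f"KD_{i + 1}" for i in range(k)]
    cond = pd.Series(["NT"] * k + ["KD"] * k, index=samples, name="condition")

    base_mu = np.exp(rng.standard_normal(n) * 1.2 + np.log(200.0))
    lengths = pd.Series(
        rng.integers(300, 10_000, size=n).astype(float), index=genes, name="gene_length"
    )

    n_de = int(round(cfg.frac_de * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_sign = rng.choice([-1.0, 1.0], size=n_de)
    lfc = np.zeros(n)
    lfc[de_idx] = de_sign * cfg.de_lfc

    disp = cfg.nb_dispersion
    nb_n = 1.0 / disp  # NB "size"; p = n / (n + mu)

    mat = np.empty((n, 2 * k), dtype=np.int64)
    for j, s in enumerate(samples):
        mu = base_mu * (2.0 ** lfc if cond[s] == "KD" else 1.0)
        mat[:, j] = rng.negative_binomial(nb_n, nb_n / (nb_n + mu))

    counts = pd.DataFrame(mat, index=genes, columns=samples)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "truth_de": np.isin(np.arange(n), de_idx),
            "truth_lfc": lfc,
        }
    )
    return counts, lengths, cond, truth
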