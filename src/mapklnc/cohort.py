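"""Tumor-vs-normal cohort statistics and the random-gene-set correlation null.

The central question this module answers: is the observed rank correlation
between a focal gene pair (e.g. a candidate lncRNA and an RNA-binding
protein) larger than what the cohort's correlation structure produces by
chance? The null is empirical — the focal correlation is compared, per
random gene set, against the Spearman correlations of each focal gene with
200 randomly drawn genes, summarized as a Z-score and a rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = [
    "CohortTable",
    "PerSetNull",
    "CorrelationNullResult",
    "fpkm_to_tpm",
    "strip_gene_versions",
    "preprocess_cohort",
    "group_compare",
    "correlation_null",
]


@dataclass
class CohortTable:
    """One cohort after preprocessing: unique genes, one sample per patient."""

    expr: ExpressionMatrix
    patient_of: Dict[str, str]  # sample -> patient


def fpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: scale each sample column to sum to 10^6.

    TPM_gs = FPKM_gs / (Σ_g FPKM_gs) × 10^6; idempotent on TPM input.
    """
    if expr.unit not in ("FPKM", "TPM"):
        raise ValueError(f"cannot convert unit {expr.unit!r}")
    totals = expr.values.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with all-zero expression: {bad}")
    values = expr.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=values, unit="TPM", sample_meta=expr.sample_meta)


def strip_gene_versions(gene_ids) -> List[str]:
    """Drop the Ensembl version suffix: 'ENSG00000225792.3' -> 'ENSG00000225792'."""
    return [str(g).split(".", 1)[0] for g in gene_ids]


def preprocess_cohort(
    expr: ExpressionMatrix,
    patient_map: Optional[pd.DataFrame] = None,
    duplicate_policy: str = "first",
) -> CohortTable:
    """Version-strip gene ids, drop duplicate genes, keep one specimen/patient.

    ``patient_map``: DataFrame indexed by sample id with ``patient_id`` and
    ``specimen_order`` columns; defaults to ``expr.sample_meta``. For a
    patient with several specimens only the lowest ``specimen_order`` is
    kept. Duplicate gene ids keep the first occurrence (``duplicate_policy
    ="first"``) or are dropped entirely (``"drop"``).
    """
    if patient_map is None:
        patient_map = expr.sample_meta
    if patient_map is None:
        raise ValueError("need a patient map (sample -> patient, specimen order)")
    missing = set(expr.samples) - set(patient_map.index)
    if missing:
        raise ValueError(f"patient map missing samples: {sorted(missing)}")

    values = expr.values.copy()
    values.index = strip_gene_versions(values.index)
    dup = values.index.duplicated(keep="first")
    if duplicate_policy == "first":
        values = values[~dup]
    elif duplicate_policy == "drop":
        dup_any = values.index.duplicated(keep=False)
        values = values[~dup_any]
    else:
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")

    keep = []
    seen_patients = set()
    order = patient_map.loc[expr.samples].sort_values("specimen_order", kind="mergesort")
    for sample, row in order.iterrows():
        if row["patient_id"] not in seen_patients:
            seen_patients.add(row["patient_id"])
            keep.append(sample)
    keep = [s for s in expr.samples if s in set(keep)]
    values = values[keep]
    meta = expr.sample_meta.loc[keep] if expr.sample_meta is not None else None
    out = ExpressionMatrix(values=values, unit=expr.unit, sample_meta=meta)
    return CohortTable(
        expr=out, patient_of={s: patient_map.loc[s, "patient_id"] for s in keep}
    )


def group_compare(
    tumor: CohortTable,
    normal: CohortTable,
    gene: str,
    equal_var: bool = True,
) -> Dict[str, object]:
    """Boxplot-style summary of one gene in two cohorts plus a t-test.

    Per cohort: mean, median, quartiles, and whiskers at the furthest data
    point within 1.5×IQR of the box. The p-value is a two-sided two-sample
    Student's t-test (classical equal-variance form by default).
    """
    def summary(table: CohortTable) -> Dict[str, float]:
        if gene not in table.expr.values.index:
            raise KeyError(f"gene {gene!r} absent from cohort")
        x = table.expr.values.loc[gene].to_numpy(dtype=float)
        if x.size < 2:
            raise ValueError("group size < 2")
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        return {
            "n": int(x.size),
            "mean": float(x.mean()),
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(lo),
            "whisker_high": float(hi),
        }

    x = tumor.expr.values.loc[gene].to_numpy(dtype=float)
    y = normal.expr.values.loc[gene].to_numpy(dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return {
        "gene": gene,
        "tumor": summary(tumor),
        "normal": summary(normal),
        "t": float(t),
        "pvalue": float(p),
    }


@dataclass(frozen=True)
class PerSetNull:
    mean_rho_a: float
    sd_rho_a: float
    z_a: float
    rank_a: int
    mean_rho_b: float
    sd_rho_b: float
    z_b: float
    rank_b: int


@dataclass
class CorrelationNullResult:
    gene_a: str
    gene_b: str
    rho_pair: float
    per_set: List[PerSetNull]
    mean_rank_a: float
    mean_rank_b: float
    mean_z_a: float
    mean_z_b: float


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1, then centered and L2-normalized so that
    the dot product of two rows is their Spearman correlation."""
    ranks = stats.rankdata(x, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    # constant rows have zero norm; caller filters them, guard anyway
    norms[norms == 0] = np.nan
    return ranks / norms


def correlation_null(
    cohort: CohortTable,
    gene_a: str,
    gene_b: str,
    n_random: int = 2000,
    n_sets: int = 10,
    seed: int = 0,
    rank_ties: str = "min",
) -> CorrelationNullResult:
    """Spearman correlation of a focal gene pair against a random-gene null.

    ``n_random`` genes are sampled without replacement (excluding the focal
    pair and any constant gene, which is resampled implicitly and logged)
    and split into ``n_sets`` disjoint sets. Per set and per focal gene:
    the mean and sd of the Spearman correlations with the set's genes, the
    Z-score of the focal-pair correlation against that distribution, and
    the rank of the focal-pair correlation among the set's correlations
    (rank 1 = highest). Mean ranks and mean Z across sets are reported.

    ``rank_ties="min"`` gives tied correlations the best (smallest) rank;
    ``"average"`` averages over ties.
    """
    values = cohort.expr.values
    for g in (gene_a, gene_b):
        if g not in values.index:
            raise KeyError(f"gene {g!r} absent from cohort")
    x = values.to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(values.index)}
    ia, ib = gene_pos[gene_a], gene_pos[gene_b]

    spread = x.max(axis=1) - x.min(axis=1)
    if spread[ia] == 0 or spread[ib] == 0:
        raise ValueError("focal gene is constant; Spearman undefined")
    constant = np.flatnonzero(spread == 0)
    if constant.size:
        warnings.warn(
            f"excluding {constant.size} constant gene(s) from the random pool"
        )
    pool = np.array(
        [i for i in range(x.shape[0]) if i not in (ia, ib) and spread[i] > 0]
    )
    if pool.size < n_random:
        warnings.warn(
            f"only {pool.size} genes available for the null; "
            f"reducing from {n_random}"
        )
        n_random = pool.size - pool.size % n_sets
    set_size = n_random // n_sets

    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_random, replace=False)

    normed = _rank_rows(x[np.concatenate(([ia, ib], chosen))])
    ra, rb = normed[0], normed[1]
    rho_pair = float(ra @ rb)

    per_set: List[PerSetNull] = []
    for s in range(n_sets):
        block = normed[2 + s * set_size : 2 + (s + 1) * set_size]
        rho_a = block @ ra
        rho_b = block @ rb
        stats_pairs = []
        for rho_vec in (rho_a, rho_b):
            mean, sd = float(rho_vec.mean()), float(rho_vec.std(ddof=1))
            z = (rho_pair - mean) / sd
            if rank_ties == "min":
                rank = 1 + int(np.sum(rho_vec > rho_pair))
            elif rank_ties == "average":
                rank = 1 + float(
                    np.sum(rho_vec > rho_pair) + 0.5 * np.sum(rho_vec == rho_pair)
                )
            else:
                raise ValueError(f"unknown rank_ties {rank_ties!r}")
            stats_pairs.append((mean, sd, z, rank))
        (ma, sa, za, ka), (mb, sb, zb, kb) = stats_pairs
        per_set.append(
            PerSetNull(
                mean_rho_a=ma, sd_rho_a=sa, z_a=za, rank_a=ka,
                mean_rho_b=mb, sd_rho_b=sb, z_b=zb, rank_b=kb,
            )
        )
    return CorrelationNullResult(
        gene_a=gene_a,
        gene_b=gene_b,
        rho_pair=rho_pair,
        per_set=per_set,
        mean_rank_a=float(np.mean([p.rank_a for p in per_set])),
        mean_rank_b=float(np.mean([p.rank_b for p in per_set])),
        mean_z_a=float(np.mean([p.z_a for p in per_set])),
        mean_z_b=float(np.mean([p.z_b for p in per_set])),
    )
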