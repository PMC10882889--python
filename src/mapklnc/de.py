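"""Differential-expression filtering and the conserved-DE intersection.

Implements the fold-change pipeline applied to FPKM matrices: per-gene
condition means with an expression floor, strict log2 fold-change cuts, the
sign-consistent intersection across several condition pairs, cohort
prevalence ranking, and the threshold filter (|log2FC| and FDR) applied to a
precomputed per-gene statistics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

__all__ = [
    "ComparisonResult",
    "DEGeneSet",
    "compare_conditions",
    "select_de",
    "intersect_conserved",
    "prevalence_rank",
    "threshold_de_table",
]


@dataclass(frozen=True)
class ComparisonResult:
    """Per-gene summary of one condition-pair comparison (B relative to A)."""

    gene_id: str
    mean_a: float
    mean_b: float
    log2fc: float
    expressed_flag: bool


@dataclass
class DEGeneSet:
    """Directional DE calls; ``up`` and ``down`` are disjoint id sets."""

    up: Set[str]
    down: Set[str]
    thresholds: Tuple[float, float] = (0.2, 1.0)  # (min_expr, log2fc_cut)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down")


def _log2fc(mean_a: float, mean_b: float, eps: float) -> float:
    a, b = mean_a + eps, mean_b + eps
    if a == 0.0 and b == 0.0:
        return float("nan")
    if a == 0.0:
        return float("inf")
    if b == 0.0:
        return float("-inf")
    return float(np.log2(b / a))


def compare_conditions(
    expr: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    floor: float = 0.2,
    eps: float = 0.0,
) -> List[ComparisonResult]:
    """Per-gene mean comparison of two conditions of an FPKM/TPM matrix.

    A gene is flagged not-expressed when its mean is below ``floor`` in
    *both* conditions — such genes are discarded downstream. ``eps`` is an
    optional pseudo-count added to both means before the log-ratio; with the
    default 0 a zero mean yields an infinite fold change, which passes any
    finite cut in :func:`select_de`.
    """
    samples_a = expr.condition_samples(cond_a)
    samples_b = expr.condition_samples(cond_b)
    means_a = expr.values[samples_a].mean(axis=1)
    means_b = expr.values[samples_b].mean(axis=1)
    results = []
    for gene in expr.genes:
        ma, mb = float(means_a[gene]), float(means_b[gene])
        expressed = not (ma < floor and mb < floor)
        results.append(
            ComparisonResult(
                gene_id=gene,
                mean_a=ma,
                mean_b=mb,
                log2fc=_log2fc(ma, mb, eps),
                expressed_flag=expressed,
            )
        )
    return results


def select_de(results: Sequence[ComparisonResult], cut: float = 1.0) -> DEGeneSet:
    """Directional selection at a strict |log2FC| cut among expressed genes."""
    if cut <= 0:
        raise ValueError("cut must be positive")
    up = {r.gene_id for r in results if r.expressed_flag and r.log2fc > cut}
    down = {r.gene_id for r in results if r.expressed_flag and r.log2fc < -cut}
    return DEGeneSet(up=up, down=down, thresholds=(float("nan"), cut))


def intersect_conserved(sets: Sequence[DEGeneSet]) -> DEGeneSet:
    """Genes DE with the same sign in every comparison.

    ``up`` is the intersection of all up sets, ``down`` of all down sets; a
    gene that switches direction between comparisons appears in neither.
    """
    if not sets:
        raise ValueError("need at least one DEGeneSet")
    if len(sets) < 2:
        raise ValueError("conserved intersection needs >= 2 comparisons")
    up = set.intersection(*(s.up for s in sets))
    down = set.intersection(*(s.down for s in sets))
    return DEGeneSet(up=up, down=down, thresholds=sets[0].thresholds)


def prevalence_rank(
    cohort: ExpressionMatrix,
    gene_ids: Set[str],
    min_expr: float = 0.2,
    min_frac: float = 0.9,
) -> pd.DataFrame:
    """Fraction of cohort samples expressing each gene, with average expression.

    A sample "expresses" a gene when its value is strictly above
    ``min_expr``. Genes expressed in strictly more than ``min_frac`` of
    samples are returned, ranked by average expression ascending (rank 1 =
    lowest average), mirroring a prevalence bar plot read bottom-up.
    """
    if not gene_ids:
        raise ValueError("empty gene set")
    if cohort.unit not in ("FPKM", "TPM"):
        raise ValueError("prevalence ranking expects FPKM or TPM")
    genes = [g for g in cohort.genes if g in gene_ids]
    sub = cohort.values.loc[genes]
    frac = (sub > min_expr).sum(axis=1) / sub.shape[1]
    avg = sub.mean(axis=1)
    table = pd.DataFrame({"fraction_expressed": frac, "average_expression": avg})
    table = table[table["fraction_expressed"] > min_frac]
    table = table.sort_values("average_expression", kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table.index.name = "gene_id"
    return table


def threshold_de_table(
    stats: pd.DataFrame,
    log2_cut: float = 0.58,
    fdr_cut: float = 0.05,
) -> DEGeneSet:
    """Directional filter on a per-gene DE statistics table.

    ``stats`` is indexed by gene id with columns ``log2fc`` and ``pvalue``,
    plus optionally ``fdr``; when ``fdr`` is absent it is computed from the
    p-values by Benjamini–Hochberg. A gene is called at |log2fc| strictly
    above ``log2_cut`` and fdr strictly below ``fdr_cut``.
    """
    if "pvalue" not in stats.columns or "log2fc" not in stats.columns:
        raise ValueError("stats table needs 'log2fc' and 'pvalue' columns")
    pvals = stats["pvalue"].to_numpy(dtype=float)
    if np.any((pvals < 0) | (pvals > 1)) or np.any(np.isnan(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    if "fdr" in stats.columns:
        fdr = stats["fdr"].to_numpy(dtype=float)
    else:
        fdr = multipletests(pvals, method="fdr_bh")[1]
    lfc = stats["log2fc"].to_numpy(dtype=float)
    called = (np.abs(lfc) > log2_cut) & (fdr < fdr_cut)
    genes = stats.index.to_numpy()
    up = set(genes[called & (lfc > 0)])
    down = set(genes[called & (lfc < 0)])
    return DEGeneSet(up=up, down=down, thresholds=(float("nan"), log2_cut))
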