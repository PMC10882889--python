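"""Conserved differential expression across the three wild-type-vs-mutant
comparisons, plus cohort prevalence ranking of the conserved up genes.

Recomputes per-comparison fold changes from the simulated FPKM matrices,
intersects the directional calls, and checks recovery of the planted DE
genes. The conserved up set is then prevalence-ranked in a reassembled
"tumor cohort" (all mutant-condition samples pooled).
"""

import json
from pathlib import Path

import pandas as pd

from mapklnc import de
from mapklnc.expression import ExpressionMatrix, concat_samples
from mapklnc.simulate import SimConfig

BASE = Path(__file__).resolve().parent.parent / "results"
COMPARISONS = SimConfig().comparisons


def main() -> None:
    sim = BASE / "simulated"
    truth = json.loads((sim / "expression_truth.json").read_text())
    matrices = {
        cond: ExpressionMatrix.from_tsv(
            sim / f"expression_{cond}.tsv", unit="FPKM",
            meta_path=sim / f"meta_{cond}.tsv",
        )
        for cond in {c for pair in COMPARISONS for c in pair}
    }

    sets = []
    for cond_a, cond_b in COMPARISONS:
        combined = concat_samples([matrices[cond_a], matrices[cond_b]])
        results = de.compare_conditions(combined, cond_a, cond_b, floor=0.2)
        de_set = de.select_de(results, cut=1.0)
        sets.append(de_set)
        print(f"{cond_a} vs {cond_b}: {len(de_set.up)} up, {len(de_set.down)} down")

    conserved = de.intersect_conserved(sets)
    planted_up = set(truth["planted_de_ids_by_direction"]["up"])
    planted_down = set(truth["planted_de_ids_by_direction"]["down"])
    recovered = len(conserved.up & planted_up) + len(conserved.down & planted_down)
    false_pos = len(conserved.up - planted_up) + len(conserved.down - planted_down)
    print(f"conserved in all three: {len(conserved.up)} up, {len(conserved.down)} down"
          f" (planted recovered {recovered}/{len(planted_up) + len(planted_down)},"
          f" false positives {false_pos})")

    out = BASE / "de"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(g, "up") for g in sorted(conserved.up)]
        + [(g, "down") for g in sorted(conserved.down)],
        columns=["gene_id", "direction"],
    ).to_csv(out / "conserved_de.tsv", sep="\t", index=False)

    # prevalence of the conserved up genes in the pooled mutant cohort
    mutants = sorted({b for _, b in COMPARISONS})
    cohort = concat_samples([matrices[c] for c in mutants])
    ranked = de.prevalence_rank(cohort, conserved.up, min_expr=0.2, min_frac=0.9)
    ranked.to_csv(out / "prevalence.tsv", sep="\t")
    print(f"prevalence: {len(ranked)}/{len(conserved.up)} conserved up genes expressed "
          f"in > 90% of the pooled mutant samples")


if __name__ == "__main__":
    main()
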