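"""Generate the synthetic input bundle every later analysis step consumes.

Writes, under results/simulated/: reference and assembled GTFs with
transcript FASTA, per-condition FPKM matrices with metadata, a kinase
plate CSV with its peptide map, a drug-combination viability grid, qPCR
Ct tables, and the ground-truth JSON files the recovery analyses check
against.
"""

from pathlib import Path

import pandas as pd

from mapklnc import annotation, kinome, simulate
from mapklnc.simulate import SimConfig

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)

    bundle = simulate.gen_annotation(cfg)
    annotation.write_gtf(bundle.reference, OUT / "reference.gtf")
    annotation.write_gtf(bundle.assembled, OUT / "assembled.gtf")
    annotation.write_fasta(bundle.sequences, OUT / "assembled.fa")
    bundle.truth.to_json(OUT / "annotation_truth.json")
    print(
        f"annotation: {len(bundle.reference)} reference transcripts, "
        f"{len(bundle.assembled)} assembled "
        f"({len(bundle.truth.planted_novel_lncrna_ids)} planted novel lncRNAs)"
    )

    matrices, truth = simulate.gen_expression_cohorts(cfg)
    for cond, expr in matrices.items():
        expr.to_tsv(OUT / f"expression_{cond}.tsv")
        expr.meta_to_tsv(OUT / f"meta_{cond}.tsv")
    truth.to_json(OUT / "expression_truth.json")
    n_up = len(truth.planted_de_ids_by_direction["up"])
    n_down = len(truth.planted_de_ids_by_direction["down"])
    print(f"expression: {len(matrices)} cohorts, planted {n_up} up / {n_down} down")

    kinase_map = simulate.default_kinase_map()
    samples = ["control_1", "control_2", "treated_1", "treated_2"]
    layout = simulate.build_plate_layout(kinase_map, samples)
    assay, plate_truth = simulate.gen_kinase_plate(
        cfg, layout, kinase_map, treated_samples=["treated_1", "treated_2"]
    )
    kinome.write_plate_csv(assay, OUT / "plate.csv")
    pd.DataFrame(
        [(k, p) for k, peps in kinase_map.items() for p in peps],
        columns=["kinase", "peptide"],
    ).to_csv(OUT / "kinase_map.tsv", sep="\t", index=False)
    plate_truth.to_json(OUT / "plate_truth.json")
    print(f"plate: {len(assay.wells)} wells, planted effects {plate_truth.kinase_effects}")

    grid = simulate.gen_viability_grid(cfg)
    grid.effect.to_csv(OUT / "viability.csv")
    print(f"viability: {grid.effect.shape[0]}×{grid.effect.shape[1]} dose grid, "
          f"planted Bliss deviation {cfg.bliss_deviation}")

    design = {
        "targets": {"TARGET1": 4.0, "TARGET2": 0.25},
        "housekeeping": "GAPDH",
        "nc_ratios": {"CAND_LNC": 6.7, "MALAT1": 1.0, "GAPDH_RNA": 0.08},
    }
    ct, fractions = simulate.gen_ct_table(cfg, design)
    ct.rows.to_csv(OUT / "ct.csv", index=False)
    fractions.to_csv(OUT / "fractions.csv")
    print("qPCR: Ct table with planted folds {4.0, 0.25}, planted N/C ratios written")


if __name__ == "__main__":
    main()
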