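"""Kinase activity analysis of the simulated plate: calibration, peptide
profiles, kinase signatures, clustering, and treatment-vs-treatment
signature comparison.

Reads the plate written by 01_simulate_inputs.py, derives per-kinase
activities from ATP consumption, clusters samples by uncentered
correlation / average linkage, and reports the treated/control activity
ratio of the planted kinase.
"""

import json
from pathlib import Path

import pandas as pd

from mapklnc import kinome

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = BASE / "simulated"
    assay = kinome.read_plate_csv(sim / "plate.csv")
    kinase_map = kinome.read_kinase_map(sim / "kinase_map.tsv")
    truth = json.loads((sim / "plate_truth.json").read_text())

    calibration = kinome.calibrate_atp(assay)
    print(f"ATP calibration: slope {calibration.slope:.3f} RLU/nM, "
          f"intercept {calibration.intercept:.1f} RLU, R² {calibration.r_squared:.4f}")

    profiles = kinome.peptide_activity(assay, calibration)
    signatures = kinome.kinase_signature(profiles, kinase_map, min_peptides=3)
    table = pd.DataFrame(
        {s.sample_id: pd.Series(s.kinase_activities) for s in signatures}
    ).sort_index()
    table.index.name = "kinase"

    out = BASE / "kinome"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "signatures.tsv", sep="\t")

    linkage, order = kinome.cluster_profiles(table, axis="columns")
    (out / "samples.nwk").write_text(
        kinome.linkage_to_newick(linkage, list(table.columns)) + "\n"
    )
    print(f"sample dendrogram leaf order: {' '.join(order)}")

    controls = [c for c in table.columns if c.startswith("control")]
    treated = [c for c in table.columns if c.startswith("treated")]
    for kinase, effect in truth["kinase_effects"].items():
        ratio = table.loc[kinase, treated].mean() / table.loc[kinase, controls].mean()
        print(f"{kinase}: treated/control activity ratio {ratio:.3f} "
              f"(planted {effect})")


if __name__ == "__main__":
    main()
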