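"""End-to-end recovery and calibration benchmarks over the synthetic study.

Each function simulates the relevant inputs with :mod:`mapklnc.simulate`,
runs the corresponding pipeline stage, and returns the measured quantities
as a flat dict. These are the package's headline numbers: planted-truth
recovery rates, normalization identities, null calibrations and
round-trip errors. The analysis drivers, the test suite and the
reproduction script all call these functions rather than re-deriving them.
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as cohort_mod
from . import de as de_mod
from . import discovery, kinome, pharm, simulate
from .expression import ExpressionMatrix, concat_samples
from .simulate import SimConfig


def _child_seeds(seed: int, n: int) -> List[int]:
    """Deterministic sub-seeds below 2^31 derived from one master seed."""
    return [
        int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)
    ]


# ---------------------------------------------------------------------------


def discovery_recovery(seed: int) -> Dict[str, float]:
    """Full discovery cascade on the standard bundle (5 planted novel
    lncRNAs, 30 structural-noise transcripts, 50 reference-overlapping)."""
    bundle = simulate.gen_annotation(SimConfig(seed=seed))
    _, lnc_ids = discovery.discover(
        bundle.assembled, bundle.reference, bundle.sequences
    )
    planted = set(bundle.truth.planted_novel_lncrna_ids)
    return {
        "n_assembled": len(bundle.assembled),
        "n_planted": len(planted),
        "recovered": len(planted & set(lnc_ids)),
        "false_positives": len(set(lnc_ids) - planted),
    }


def conserved_de_recovery(seed: int, n_seeds: int = 20) -> Dict[str, float]:
    """Three-comparison conserved-DE intersection at the study conditions
    (2,000 genes, 20 up + 20 down planted at log2FC 2, noise sd 0.3 log2
    units, n = 6 per condition), repeated over independent simulations."""
    recovered, false_pos = [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(seed=s)
        matrices, truth = simulate.gen_expression_cohorts(cfg)
        sets = []
        for a, b in cfg.comparisons:
            combined = concat_samples([matrices[a], matrices[b]])
            sets.append(de_mod.select_de(de_mod.compare_conditions(combined, a, b)))
        inter = de_mod.intersect_conserved(sets)
        up = set(truth.planted_de_ids_by_direction["up"])
        down = set(truth.planted_de_ids_by_direction["down"])
        recovered.append(len(inter.up & up) + len(inter.down & down))
        false_pos.append(len(inter.up - up) + len(inter.down - down))
    return {
        "n_seeds": n_seeds,
        "n_planted": 40,
        "mean_recovered": float(np.mean(recovered)),
        "min_recovered": int(np.min(recovered)),
        "mean_false_positives": float(np.mean(false_pos)),
        "max_false_positives": int(np.max(false_pos)),
    }


def tpm_normalization(seed: int, n_matrices: int = 100) -> Dict[str, float]:
    """Column sums of FPKM→TPM output across random matrices, plus the
    idempotence error of re-normalizing TPM."""
    worst = 0.0
    worst_idem = 0.0
    for s in _child_seeds(seed, n_matrices):
        rng = np.random.default_rng(s)
        expr = ExpressionMatrix(
            values=pd.DataFrame(rng.exponential(5.0, size=(100, 20))), unit="FPKM"
        )
        tpm = cohort_mod.fpkm_to_tpm(expr)
        sums = tpm.values.sum(axis=0).to_numpy()
        worst = max(worst, float(np.abs(sums / 1e6 - 1.0).max()))
        again = cohort_mod.fpkm_to_tpm(tpm)
        denom = np.abs(tpm.values.to_numpy()).max()
        worst_idem = max(
            worst_idem,
            float(np.abs(again.values.to_numpy() - tpm.values.to_numpy()).max())
            / denom,
        )
    return {
        "n_matrices": n_matrices,
        "max_colsum_rel_error": worst,
        "max_idempotence_rel_error": worst_idem,
    }


def _null_cohort(seed: int, rho: float, n_genes: int, n: int):
    cfg = SimConfig(
        seed=seed, planted_rho=rho, cohort_sizes={"C": n}, comparisons=(),
        n_genes=n_genes, n_planted_up=0, n_planted_down=0,
    )
    matrices, truth = simulate.gen_expression_cohorts(cfg)
    return cohort_mod.preprocess_cohort(matrices["C"]), truth


def correlation_null_calibration(
    seed: int, n_reps: int = 200, n_genes: int = 2500, n_samples: int = 366
) -> Dict[str, float]:
    """Z-score calibration of the random-gene-set null under full
    independence, and rank recovery of a planted Spearman-0.4 pair."""
    seeds = _child_seeds(seed, n_reps + 1)
    zs = []
    for s in seeds[:-1]:
        table, truth = _null_cohort(s, rho=0.0, n_genes=n_genes, n=n_samples)
        res = cohort_mod.correlation_null(table, *truth.correlated_pair, seed=s)
        zs.append(res.mean_z_a)
    zs = np.asarray(zs)

    table, truth = _null_cohort(seeds[-1], rho=0.4, n_genes=n_genes, n=n_samples)
    planted = cohort_mod.correlation_null(table, *truth.correlated_pair, seed=seeds[-1])
    ranks = [p.rank_a for p in planted.per_set]
    return {
        "n_reps": n_reps,
        "n_samples": n_samples,
        "null_z_mean": float(zs.mean()),
        "null_z_sd": float(zs.std(ddof=1)),
        "planted_rho_pair": planted.rho_pair,
        "planted_mean_rank": planted.mean_rank_a,
        "planted_sets_rank_le2": int(sum(r <= 2 for r in ranks)),
        "n_sets": len(ranks),
    }


def _signature_table(assay, kinase_map) -> pd.DataFrame:
    calibration = kinome.calibrate_atp(assay)
    profiles = kinome.peptide_activity(assay, calibration)
    signatures = kinome.kinase_signature(profiles, kinase_map)
    table = pd.DataFrame(
        {s.sample_id: pd.Series(s.kinase_activities) for s in signatures}
    ).sort_index()
    return table


def kinome_round_trip(seed: int, n_cluster_trials: int = 100,
                      n_split_sims: int = 100) -> Dict[str, float]:
    """Zero-noise recovery of a planted kinase effect, UPGMA agreement with
    a brute-force oracle, and treated/control separation at the top of the
    sample dendrogram under 2% plate noise."""
    kmap_lists = simulate.default_kinase_map()
    kinase_map = {k: set(v) for k, v in kmap_lists.items()}

    # exact round trip at zero noise
    cfg0 = SimConfig(seed=seed, plate_noise_cv=0.0, plate_effect={"K1": 0.5})
    layout = simulate.build_plate_layout(kmap_lists, ["ctrl", "trt"])
    assay, _ = simulate.gen_kinase_plate(cfg0, layout, kmap_lists, ["trt"])
    table = _signature_table(assay, kinase_map)
    ratio = float(table.loc["K1", "trt"] / table.loc["K1", "ctrl"])

    # UPGMA vs exhaustive oracle on random matrices
    agree = 0
    for s in _child_seeds(seed, n_cluster_trials):
        rng = np.random.default_rng(s)
        x = rng.normal(size=(8, 8)) + 4.0
        d = kinome.uncentered_correlation_distance(x)
        impl = kinome.upgma(d)
        oracle = _brute_force_upgma(d)
        if np.allclose(impl, oracle, atol=1e-12):
            agree += 1

    # top-split separation under noise
    controls = [f"ctrl_{i}" for i in range(3)]
    treated = [f"trt_{i}" for i in range(3)]
    layout6 = simulate.build_plate_layout(kmap_lists, controls + treated)
    split_ok = 0
    for s in _child_seeds(seed + 1, n_split_sims):
        cfg = SimConfig(seed=s, plate_noise_cv=0.02, plate_effect={"K1": 0.5})
        noisy_assay, _ = simulate.gen_kinase_plate(cfg, layout6, kmap_lists, treated)
        sig = _signature_table(noisy_assay, kinase_map)
        linkage, _ = kinome.cluster_profiles(sig, axis="columns")
        left, right = _root_split(linkage, list(sig.columns))
        if {frozenset(left), frozenset(right)} == {
            frozenset(controls), frozenset(treated)
        }:
            split_ok += 1
    return {
        "zero_noise_effect_ratio": ratio,
        "zero_noise_ratio_error": abs(ratio - 0.5),
        "upgma_oracle_agreement": agree / n_cluster_trials,
        "n_cluster_trials": n_cluster_trials,
        "top_split_rate": split_ok / n_split_sims,
        "n_split_sims": n_split_sims,
    }


def _brute_force_upgma(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    ids = list(range(n))
    merges = []
    next_id = n
    while len(ids) > 1:
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(
                    np.mean([dist[x, y] for x in clusters[a] for y in clusters[b]])
                )
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        merges.append([a, b, d, len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        ids = [i for i in ids if i not in (a, b)] + [next_id]
        next_id += 1
    return np.array(merges)


def _root_split(linkage: np.ndarray, labels: Sequence[str]):
    """Leaf label sets of the two subtrees under the dendrogram root."""
    n = len(labels)
    children = {n + k: (int(r[0]), int(r[1])) for k, r in enumerate(linkage)}

    def leaves(node):
        if node < n:
            return [labels[node]]
        a, b = children[node]
        return leaves(a) + leaves(b)

    root_a, root_b = children[n + len(linkage) - 1]
    return leaves(root_a), leaves(root_b)


def combination_index_recovery(seed: int, n_reps: int = 100) -> Dict[str, float]:
    """Exact CI = 0 under Bliss independence and mean CI under a planted
    −0.5 log2 deviation with 2% viability noise."""
    grid0 = simulate.gen_viability_grid(
        SimConfig(seed=seed, bliss_deviation=0.0, viability_noise_cv=0.0)
    )
    exact = float(np.nanmax(np.abs(pharm.combination_index(grid0).ci_matrix)))
    means = []
    for s in _child_seeds(seed, n_reps):
        grid = simulate.gen_viability_grid(
            SimConfig(seed=s, bliss_deviation=-0.5, viability_noise_cv=0.02)
        )
        means.append(pharm.combination_index(grid).mean_ci)
    return {
        "bliss_independent_max_abs_ci": exact,
        "mean_ci": float(np.mean(means)),
        "n_reps": n_reps,
    }


def qpcr_round_trips(seed: int) -> Dict[str, float]:
    """Zero-noise ΔΔCt and nuclear/cytoplasmic round trips."""
    ct, fractions = simulate.gen_ct_table(
        SimConfig(seed=seed),
        {
            "targets": {"X": 4.0},
            "nc_ratios": {"T": 6.7, "M": 1.0},
            "ct_noise_sd": 0.0,
        },
    )
    fold = pharm.relative_expression(ct, "X", "treated", "control")
    ratio = pharm.nc_ratio(fractions, "T", "M")
    return {
        "ddct_fold": float(fold),
        "ddct_fold_error": abs(fold - 4.0),
        "nc_ratio": float(ratio),
        "nc_ratio_error": abs(ratio - 6.7),
    }


def statistical_calibration(
    seed: int, n_fdr_reps: int = 500, n_ttest_reps: int = 10_000
) -> Dict[str, float]:
    """Empirical FDR of the threshold filter on global-null expression
    simulations, and type-I error of the two-sample t-test at alpha 0.05."""
    fdr_seeds = _child_seeds(seed, 2)
    rng = np.random.default_rng(fdr_seeds[0])
    fdps = []
    n_genes, n_per_group = 200, 6
    for _ in range(n_fdr_reps):
        log2x_a = rng.normal(5.0, 1.0, size=(n_genes, n_per_group))
        log2x_b = rng.normal(5.0, 1.0, size=(n_genes, n_per_group))
        pvals = sps.ttest_ind(log2x_a, log2x_b, axis=1).pvalue
        lfc = np.log2((2.0**log2x_b).mean(axis=1) / (2.0**log2x_a).mean(axis=1))
        table = pd.DataFrame(
            {"log2fc": lfc, "pvalue": pvals},
            index=[f"g{i}" for i in range(n_genes)],
        )
        s = de_mod.threshold_de_table(table)
        n_disc = len(s.up) + len(s.down)
        fdps.append(n_disc / max(n_disc, 1) if n_disc else 0.0)
    empirical_fdr = float(np.mean(fdps))

    rng = np.random.default_rng(fdr_seeds[1])
    rejections = 0
    for _ in range(n_ttest_reps):
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        _, p = pharm.two_sample_test(x, y)
        rejections += p < 0.05
    return {
        "empirical_fdr": empirical_fdr,
        "n_fdr_reps": n_fdr_reps,
        "ttest_type1_error": rejections / n_ttest_reps,
        "n_ttest_reps": n_ttest_reps,
    }
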