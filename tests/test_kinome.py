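import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import squareform

from mapklnc import simulate
from mapklnc.kinome import (
    ActivityProfile,
    KinaseSignature,
    PlateAssay,
    calibrate_atp,
    cluster_profiles,
    compare_signatures,
    kinase_signature,
    linkage_to_newick,
    peptide_activity,
    uncentered_correlation_distance,
    upgma,
)
from mapklnc.simulate import SimConfig


def make_assay(rows, atp_start=250.0):
    defaults = {
        "well": "", "row": "A", "col": 1, "class": "experimental",
        "peptide": "", "sample": "", "replicate": 1, "standard_conc": np.nan,
        "luminescence": 0.0,
    }
    table = pd.DataFrame([{**defaults, "well": f"W{i}", **r} for i, r in enumerate(rows)])
    return PlateAssay(wells=table, atp_start=atp_start)


def standard(conc, rlu):
    return {"class": "ATP_standard", "standard_conc": conc, "luminescence": rlu}


class TestCalibration:
    def test_exact_linear_fit(self):
        assay = make_assay(
            [standard(0, 100), standard(125, 600), standard(250, 1100)]
        )
        cal = calibrate_atp(assay)
        assert cal.slope == pytest.approx(4.0)
        assert cal.intercept == pytest.approx(100.0)
        assert cal.atp_from_rlu(600) == pytest.approx(125.0)

    def test_noisy_fit_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        conc = np.array([0.0, 50.0, 100.0, 150.0, 250.0])
        rlu = 80.0 + 3.7 * conc + rng.normal(0, 10, size=conc.size)
        assay = make_assay([standard(c, r) for c, r in zip(conc, rlu)])
        cal = calibrate_atp(assay)
        X = np.column_stack([conc, np.ones_like(conc)])
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ rlu)
        assert cal.slope == pytest.approx(slope)
        assert cal.intercept == pytest.approx(intercept)

    def test_single_concentration_rejected(self):
        assay = make_assay([standard(250, 1000), standard(250, 1010)])
        with pytest.raises(ValueError):
            calibrate_atp(assay)

    def test_negative_slope_rejected(self):
        assay = make_assay([standard(0, 1000), standard(250, 100)])
        with pytest.raises(ValueError):
            calibrate_atp(assay)


class TestPeptideActivity:
    def assay(self):
        return make_assay(
            [
                standard(0, 100),
                standard(250, 1100),
                {"class": "no_peptide", "sample": "s1", "luminescence": 1060.0},
                {"class": "no_sample", "luminescence": 1100.0},
                # peptide p1 reads like the no-peptide well -> zero activity
                {"peptide": "p1", "sample": "s1", "luminescence": 1060.0},
                # peptide p2 consumed 50 nM beyond background
                {"peptide": "p2", "sample": "s1", "luminescence": 860.0},
            ]
        )

    def test_background_identity_gives_zero(self):
        profiles = peptide_activity(self.assay(), calibrate_atp(self.assay()))
        (p1,) = [p for p in profiles if p.sample_id == "s1"]
        assert p1.peptide_activities["p1"] == pytest.approx(0.0)
        assert p1.peptide_activities["p2"] == pytest.approx(50.0)

    def test_no_sample_wells_read_full_atp(self):
        assay = self.assay()
        cal = calibrate_atp(assay)
        no_sample = assay.of_class("no_sample")["luminescence"].iloc[0]
        assert cal.atp_from_rlu(no_sample) == pytest.approx(250.0)

    def test_conservation_consumed_plus_remaining(self):
        assay = self.assay()
        cal = calibrate_atp(assay)
        for rlu in assay.of_class("experimental")["luminescence"]:
            remaining = cal.atp_from_rlu(rlu)
            consumed = assay.atp_start - remaining
            assert consumed + remaining == pytest.approx(assay.atp_start)

    def test_missing_no_peptide_control_rejected(self):
        assay = make_assay(
            [
                standard(0, 100),
                standard(250, 1100),
                {"peptide": "p1", "sample": "orphan", "luminescence": 900.0},
            ]
        )
        with pytest.raises(ValueError):
            peptide_activity(assay, calibrate_atp(assay))

    def test_zero_noise_planted_consumption_recovered(self, noiseless_plate):
        assay, kinase_map, _ = noiseless_plate
        profiles = peptide_activity(assay, calibrate_atp(assay))
        by_sample = {p.sample_id: p for p in profiles}
        for peptide, ctrl_act in by_sample["ctrl"].peptide_activities.items():
            trt_act = by_sample["trt"].peptide_activities[peptide]
            expected = 0.5 if peptide.startswith("K1_") else 1.0
            assert trt_act / ctrl_act == pytest.approx(expected, abs=1e-9)


class TestKinaseSignature:
    profiles = [
        ActivityProfile(
            "s",
            {
                "a1": 1.0, "a2": 2.0, "a3": 3.0,   # kinase A: 3 peptides
                "b1": 5.0, "b2": 7.0,               # kinase B: only 2
            },
        )
    ]
    kinase_map = {"A": {"a1", "a2", "a3"}, "B": {"b1", "b2", "b3"}}

    def test_mean_of_three_peptides(self):
        (sig,) = kinase_signature(self.profiles, self.kinase_map)
        assert sig.kinase_activities["A"] == pytest.approx(2.0)
        assert sig.n_peptides_used["A"] == 3

    def test_kinase_below_min_peptides_omitted(self):
        (sig,) = kinase_signature(self.profiles, self.kinase_map)
        assert "B" not in sig.kinase_activities

    def test_median_aggregator(self):
        (sig,) = kinase_signature(
            self.profiles, self.kinase_map, aggregator="median"
        )
        assert sig.kinase_activities["A"] == pytest.approx(2.0)

    def test_empty_mapping_rejected(self):
        with pytest.raises(ValueError):
            kinase_signature(self.profiles, {})

    def test_planted_effect_round_trip(self, noiseless_plate):
        assay, kinase_map, truth = noiseless_plate
        profiles = peptide_activity(assay, calibrate_atp(assay))
        sigs = {s.sample_id: s for s in kinase_signature(profiles, kinase_map)}
        for kinase, effect in truth.kinase_effects.items():
            ratio = (
                sigs["trt"].kinase_activities[kinase]
                / sigs["ctrl"].kinase_activities[kinase]
            )
            assert ratio == pytest.approx(effect, abs=1e-9)
        # unaffected kinases unchanged
        assert sigs["trt"].kinase_activities["K2"] == pytest.approx(
            sigs["ctrl"].kinase_activities["K2"], abs=1e-9
        )


def brute_force_upgma(dist):
    """O(n^3) UPGMA oracle over explicit member lists."""
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
                d = np.mean(
                    [dist[x, y] for x in clusters[a] for y in clusters[b]]
                )
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append([a, b, d, len(clusters[a]) + len(clusters[b])])
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        ids = [i for i in ids if i not in (a, b)] + [next_id]
        next_id += 1
    return np.array(merges)


class TestClustering:
    def test_positive_scalar_multiple_distance_zero(self):
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 0.5]])
        d = uncentered_correlation_distance(x)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] > 0

    def test_uncentered_not_shift_invariant(self):
        x = np.array([[1.0, 2.0, 3.0], [11.0, 12.0, 13.0]])
        d = uncentered_correlation_distance(x)
        assert d[0, 1] > 1e-4  # Pearson would be 0 here

    def test_zero_vector_gets_maximal_distance(self):
        x = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, 1.0]])
        with pytest.warns(UserWarning):
            d = uncentered_correlation_distance(x)
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0

    def test_matches_brute_force_oracle_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            x = rng.normal(size=(8, 5)) + 4.0
            d = uncentered_correlation_distance(x)
            impl = upgma(d)
            oracle = brute_force_upgma(d)
            np.testing.assert_allclose(impl, oracle, atol=1e-12)

    def test_matches_scipy_average_linkage_heights(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(10, 6)) + 4.0
        d = uncentered_correlation_distance(x)
        impl = upgma(d)
        ref = scipy_linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(
            np.sort(impl[:, 2]), np.sort(ref[:, 2]), atol=1e-10
        )

    def test_cluster_profiles_returns_leaf_order(self):
        df = pd.DataFrame(
            np.random.default_rng(0).normal(size=(4, 6)) + 3,
            index=["f1", "f2", "f3", "f4"],
        )
        linkage_matrix, order = cluster_profiles(df, axis="rows")
        assert sorted(order) == ["f1", "f2", "f3", "f4"]
        assert linkage_matrix.shape == (3, 4)

    def test_newick_well_formed(self):
        import dendropy

        df = pd.DataFrame(
            np.random.default_rng(1).normal(size=(5, 4)) + 3,
            index=list("abcde"),
        )
        linkage_matrix, _ = cluster_profiles(df, axis="rows")
        newick = linkage_to_newick(linkage_matrix, list(df.index))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == set("abcde")


class TestCompareSignatures:
    def sig(self, name, values):
        return KinaseSignature(
            name, dict(values), {k: 3 for k in values}
        )

    def test_self_comparison_r_one(self):
        a = self.sig("a", {"K1": 2.0, "K2": 4.0, "K3": 1.0, "K4": 8.0})
        c = self.sig("c", {"K1": 1.0, "K2": 1.0, "K3": 2.0, "K4": 2.0})
        assert compare_signatures(a, a, c) == pytest.approx(1.0)

    def test_signature_equal_to_control_degenerate(self):
        c = self.sig("c", {"K1": 1.0, "K2": 2.0, "K3": 3.0})
        with pytest.raises(ValueError):
            compare_signatures(c, self.sig("b", {"K1": 2.0, "K2": 3.0, "K3": 4.0}), c)

    def test_no_shared_kinases_rejected(self):
        a = self.sig("a", {"K1": 1.0})
        b = self.sig("b", {"K2": 1.0})
        with pytest.raises(ValueError):
            compare_signatures(a, b, self.sig("c", {"K3": 1.0}))

    def test_disjoint_planted_effects_near_zero_mean_r(self):
        """Two treatments hitting disjoint kinase sets should have
        uncorrelated control-normalized signatures on average."""
        rng = np.random.default_rng(13)
        rs = []
        kinases = [f"K{i}" for i in range(12)]
        for _ in range(100):
            base = {k: rng.uniform(20, 80) for k in kinases}
            # effects random in direction (2^N(0,1)) on disjoint kinase sets
            a = {
                k: v * (2.0 ** rng.normal(0, 1) if i < 6 else 1.0)
                * np.exp(rng.normal(0, 0.05))
                for i, (k, v) in enumerate(base.items())
            }
            b = {
                k: v * (2.0 ** rng.normal(0, 1) if i >= 6 else 1.0)
                * np.exp(rng.normal(0, 0.05))
                for i, (k, v) in enumerate(base.items())
            }
            rs.append(
                compare_signatures(
                    self.sig("a", a), self.sig("b", b), self.sig("c", base)
                )
            )
        assert abs(np.mean(rs)) < 0.1
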