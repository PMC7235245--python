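import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ithkit import ith
from ithkit.constants import STATUS_AMP, STATUS_NEUTRAL
from ithkit.scna import CopyNumberProfile


def _profile(status, sid="s"):
    status = np.asarray(status)
    return CopyNumberProfile(sid, status, np.full(status.size, 2))


def _random_distance_matrix(rng, k):
    iu = np.triu_indices(k, 1)
    d = np.zeros((k, k))
    d[iu] = rng.random(len(iu[0]))
    return d + d.T


class TestDistances:
    def test_identical_profiles_distance_zero(self):
        p = _profile([2, 2, 3, 0])
        assert ith.scna_distance(p, p) == 0.0

    def test_all_probes_differ_distance_one(self):
        a = _profile([2, 2, 2, 2])
        b = _profile([3, 3, 3, 3])
        assert ith.scna_distance(a, b) == 1.0

    def test_ten_probe_toy_matches_elementwise_count(self, rng):
        a = rng.integers(0, 4, 10)
        b = a.copy()
        b[[1, 4, 7]] = (b[[1, 4, 7]] + 1) % 4
        assert ith.scna_distance(_profile(a), _profile(b)) == pytest.approx(0.3)

    def test_subset_equals_full_computation_on_sliced_profiles(self, rng):
        a, b = rng.integers(0, 4, 100), rng.integers(0, 4, 100)
        subset = np.flatnonzero(rng.random(100) < 0.4)
        d_sub = ith.scna_distance(_profile(a), _profile(b), subset)
        d_sliced = ith.scna_distance(_profile(a[subset]), _profile(b[subset]))
        assert d_sub == d_sliced

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ith.scna_distance(_profile([2, 2]), _profile([2, 2, 2]))

    def test_methylation_forced_arithmetic(self):
        d = ith.methylation_distance(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert d == pytest.approx(np.sqrt(2))
        d_scaled = ith.methylation_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0]), scaled=True
        )
        assert d_scaled == pytest.approx(1.0)

    def test_methylation_matches_direct_formula(self, rng):
        b1, b2 = rng.random(5000), rng.random(5000)
        expect = float(np.sqrt(((b1 - b2) ** 2).sum()))
        assert abs(ith.methylation_distance(b1, b2) - expect) < 1e-12

    def test_empty_subset_rejected(self, rng):
        with pytest.raises(ValueError):
            ith.methylation_distance(rng.random(5), rng.random(5), np.array([], int))


class TestApith:
    def test_two_samples_equals_single_distance(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert ith.apith(d) == 0.4

    def test_three_samples_mean(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = 0.1
        d[0, 2] = d[2, 0] = 0.2
        d[1, 2] = d[2, 1] = 0.3
        assert ith.apith(d) == pytest.approx(0.2)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            ith.apith(np.zeros((1, 1)))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 10), st.integers(0, 2**31 - 1))
    def test_equals_brute_force_pair_enumeration(self, k, seed):
        rng = np.random.default_rng(seed)
        d = _random_distance_matrix(rng, k)
        pairs = [d[i, j] for i, j in itertools.combinations(range(k), 2)]
        assert abs(ith.apith(d) - sum(pairs) / len(pairs)) < 1e-12


class TestNaiveIth:
    def test_identical_samples_zero(self):
        p = _profile([2, 3, 3, 2])
        assert ith.naive_ith([p, p, p]) == 0.0

    def test_toy_brute_force(self):
        base = np.full(10, STATUS_NEUTRAL)
        shared = base.copy()
        shared[[0, 1]] = STATUS_AMP  # AMP in all samples
        private = shared.copy()
        private[[5, 6, 7]] = STATUS_AMP  # AMP in one sample only
        profiles = [_profile(shared), _profile(shared), _profile(private)]
        assert ith.naive_ith(profiles) == pytest.approx(0.3)

    def test_monotone_under_added_samples(self, rng):
        profiles = [
            _profile(rng.choice([STATUS_NEUTRAL, STATUS_AMP], 200, p=[0.7, 0.3]))
            for _ in range(5)
        ]
        vals = [ith.naive_ith(profiles[: k + 1]) for k in range(1, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestVarianceModel:
    def test_all_k2_falls_back_to_equal_weights(self):
        rng = np.random.default_rng(0)
        dmats = [_random_distance_matrix(rng, 2) for _ in range(10)]
        with pytest.warns(UserWarning, match="k >= 4"):
            model = ith.estimate_variance_model(dmats)
        assert model.c == 0.0
        results = [ith.ApithResult(f"p{i}", 2, float(d[0, 1]), "scna")
                   for i, d in enumerate(dmats)]
        weighted = ith.apith_weights(results, model)
        assert all(r.weight == pytest.approx(1.0) for r in weighted)
        assert all(r.variance == pytest.approx(model.sigma2_d) for r in weighted)

    def test_variance_strictly_decreasing_in_k(self):
        model = ith.VarianceModel(sigma2_d=0.01, c=0.002)
        vals = [ith.apith_variance(k, model) for k in range(2, 12)]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_weights_invariant_to_distance_rescaling(self):
        rng = np.random.default_rng(5)
        ks = rng.integers(2, 8, 40)
        dmats = [_random_distance_matrix(rng, int(k)) for k in ks]
        def weights(scale):
            model = ith.estimate_variance_model([d * scale for d in dmats])
            res = [
                ith.ApithResult(f"p{i}", d.shape[0], ith.apith(d * scale), "scna")
                for i, d in enumerate(dmats)
            ]
            return np.array([r.weight for r in ith.apith_weights(res, model)])
        assert np.allclose(weights(1.0), weights(7.5), rtol=1e-9)

    def test_moment_estimator_recovers_known_components(self):
        rng = np.random.default_rng(11)
        sa, se = 0.04, 0.06
        dmats = []
        for _ in range(800):
            k = int(rng.integers(3, 9))
            a = rng.normal(0, sa, k)
            iu = np.triu_indices(k, 1)
            d = np.zeros((k, k))
            d[iu] = 0.5 + a[iu[0]] + a[iu[1]] + rng.normal(0, se, len(iu[0]))
            dmats.append(d + d.T)
        model = ith.estimate_variance_model(dmats)
        assert model.c == pytest.approx(sa**2, rel=0.2)
        assert model.sigma2_d == pytest.approx(2 * sa**2 + se**2, rel=0.1)


class TestRegionApith:
    def test_planted_body_only_heterogeneity(self, rng):
        ann = pd.DataFrame(
            {
                "gene_context": ["TSS200"] * 40 + ["body"] * 40,
                "cpg_context": ["island"] * 80,
                "driver_class": ["other"] * 80,
            }
        )
        beta_by_patient = {}
        for p in range(4):
            cols = {}
            for s in range(3):
                b = np.full(80, 0.3) + rng.normal(0, 0.01, 80)
                b[40:] += rng.normal(0, 0.2, 40)  # divergence only in bodies
                cols[f"P{p}S{s}"] = np.clip(b, 0, 1)
            beta_by_patient[f"P{p}"] = pd.DataFrame(cols)
        table = ith.region_apith(beta_by_patient, ann, "gene_context")
        wide = table.pivot(index="patient_id", columns="region", values="apith")
        assert (wide["body"] > wide["TSS200"]).all()
        t, p = ith.region_apith_ttest(table, "body", "TSS200")
        assert t > 0 and p < 0.05

    def test_constant_betas_zero_everywhere(self):
        ann = pd.DataFrame(
            {
                "gene_context": ["body"] * 30,
                "cpg_context": ["island"] * 30,
                "driver_class": ["other"] * 30,
            }
        )
        beta = pd.DataFrame({"s1": np.full(30, 0.4), "s2": np.full(30, 0.4)})
        table = ith.region_apith({"P1": beta}, ann, "gene_context")
        assert (table["apith"] == 0).all()

    def test_tiny_region_skipped_with_warning(self, rng):
        ann = pd.DataFrame(
            {
                "gene_context": ["body"] * 30 + ["3'UTR"] * 3,
                "cpg_context": ["island"] * 33,
                "driver_class": ["other"] * 33,
            }
        )
        beta = pd.DataFrame(rng.random((33, 3)), columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="skipped"):
            table = ith.region_apith({"P1": beta}, ann, "gene_context")
        assert set(table["region"]) == {"body"}


class TestPublicPrivateAndFilter:
    def test_public_private_labels(self):
        events = pd.DataFrame(
            {
                "patient_id": ["p1"] * 6,
                "sample_id": ["s1", "s2", "s3"] * 2,
                "event_id": ["mutA"] * 3 + ["mutB"] * 3,
                "present": [1, 1, 1, 1, 1, 0],
            }
        )
        out = ith.classify_public_private(events).set_index("event_id")
        assert out.loc["mutA", "label"] == "public"
        assert out.loc["mutB", "label"] == "private"

    def test_single_sample_patient_rejected(self):
        events = pd.DataFrame(
            {
                "patient_id": ["p1"],
                "sample_id": ["s1"],
                "event_id": ["mutA"],
                "present": [1],
            }
        )
        with pytest.raises(ValueError, match="one sample"):
            ith.classify_public_private(events)

    def test_variant_filter_boundaries(self):
        table = pd.DataFrame(
            {
                "variant": ["keep", "alt_eq_3", "tumor_depth_2", "normal_depth_2",
                            "vaf_low", "vaf_boundary"],
                "alt_count": [4, 3, 4, 4, 4, 4],
                "depth_tumor": [30, 30, 2, 30, 30, 30],
                "depth_normal": [30, 30, 30, 2, 30, 30],
                "vaf": [0.5, 0.5, 0.5, 0.5, 0.09999, 0.1],
            }
        )
        kept = set(ith.filter_somatic_variants(table)["variant"])
        assert kept == {"keep", "vaf_boundary"}

    def test_empty_table_passes_through(self):
        table = pd.DataFrame(
            columns=["alt_count", "depth_tumor", "depth_normal", "vaf"]
        )
        assert len(ith.filter_somatic_variants(table)) == 0
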