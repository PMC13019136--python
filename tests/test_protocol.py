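"""Site/server protocol: artifacts, alignment, reference library, verdicts."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fedprint as fp
from fedprint.explain import SurrogateSettings
from fedprint.preprocess import PreprocConfig
from fedprint.protocol import (
    AlignmentResult,
    TrialOutcome,
    VerifierModel,
    build_reference,
    run_federated_experiment,
    run_site,
    simulate_references,
    train_verifier,
    validate_alignment,
    verify,
)

FAST = SurrogateSettings(n_samples=150)


@pytest.fixture(scope="module")
def three_artifacts(injected_cohort):
    G, Y = injected_cohort
    parts = fp.partition_sites(G, Y, 3, seed=1)
    return [
        run_site(
            Gk, Yk, PreprocConfig.from_label(5), epsilon=3.0, seed=k,
            n_trees=25, n_instances=10, settings=FAST, site_id=f"site{k}",
        )
        for k, (Gk, Yk) in enumerate(parts)
    ]


@pytest.fixture(scope="module")
def small_library(injected_cohort):
    G, Y = injected_cohort
    Gp = fp.perturb_genotypes(G, 3.0, seed=2)
    return simulate_references(
        Gp, Y, R=3, subsample=200, seed=3, n_trees=25, n_instances=10, settings=FAST
    )


class TestRunSite:
    def test_artifact_structurally_valid(self, three_artifacts):
        for art in three_artifacts:
            assert art.perturbed.is_dosage()
            assert len(art.explanation.coefficients) == art.perturbed.n_loci
            assert art.explanation.locus_ids == art.perturbed.locus_ids
            assert len(art.phenotypes) == art.perturbed.n_samples

    def test_identity_limit_without_noise(self, small_cohort):
        G, Y = small_cohort
        art = run_site(
            G, Y, PreprocConfig(dedupe=True), epsilon=math.inf, seed=1,
            n_trees=20, n_instances=5, settings=FAST,
        )
        np.testing.assert_array_equal(art.perturbed.values, G.values)

    def test_serialized_artifact_under_one_megabyte(self, tmp_path):
        spec = fp.CohortSpec(n_samples=2504, n_loci=100, seed=41)
        G, Y = fp.generate_cohort(spec, inject=False)
        art = run_site(
            G, Y, PreprocConfig(scale=True), epsilon=3.0, seed=1,
            n_trees=25, n_instances=10, settings=FAST,
        )
        from fedprint.io import write_artifact

        write_artifact(art, tmp_path)
        total = sum(f.stat().st_size for f in tmp_path.iterdir())
        assert total < 1_000_000


class TestAlignment:
    def test_aligned_artifacts_pass(self, three_artifacts):
        assert validate_alignment(three_artifacts).ok

    def test_swapped_loci_reported_with_position(self, three_artifacts):
        bad = three_artifacts[0], _swap_loci(three_artifacts[1], 2, 5)
        res = validate_alignment(list(bad))
        assert not res.ok
        assert "position 2" in res.message

    def test_invalid_cell_reported_with_coordinates(self, three_artifacts):
        import copy

        bad = copy.deepcopy(three_artifacts[1])
        bad.perturbed.values[4, 6] = 3.0
        res = validate_alignment([three_artifacts[0], bad])
        assert not res.ok
        assert "(4, 6)" in res.message


def _swap_loci(art, i, j):
    import copy

    out = copy.deepcopy(art)
    order = list(range(out.perturbed.n_loci))
    order[i], order[j] = order[j], order[i]
    out.perturbed = out.perturbed.take_loci(order)
    out.explanation.locus_ids = list(out.perturbed.locus_ids)
    return out


class TestBuildReference:
    def test_row_counts_sum(self, three_artifacts):
        X_ref, Y_ref = build_reference(three_artifacts)
        assert X_ref.n_samples == sum(a.perturbed.n_samples for a in three_artifacts)
        assert len(Y_ref) == X_ref.n_samples

    def test_sample_ids_site_prefixed_and_unique(self, three_artifacts):
        X_ref, _ = build_reference(three_artifacts)
        assert len(set(X_ref.sample_ids)) == X_ref.n_samples
        assert X_ref.sample_ids[0].startswith("site0:")

    def test_single_site_is_identity_on_values(self, three_artifacts):
        X_ref, _ = build_reference(three_artifacts[:1])
        np.testing.assert_array_equal(X_ref.values, three_artifacts[0].perturbed.values)


class TestReferenceLibrary:
    def test_library_counts_and_labels(self, small_library):
        assert small_library.vectors.shape[0] == 45  # 15 configs x R=3
        assert sorted(set(small_library.labels)) == list(range(1, 16))

    def test_scaling_flag_separates_replicate_clouds(self, small_library):
        """Configs differing in scaling produce separated vector clouds."""
        V, L = small_library.vectors, small_library.labels
        scale_on = V[np.isin(L, [lab for lab in range(1, 16) if lab & 2])]
        scale_off = V[np.isin(L, [lab for lab in range(1, 16) if not lab & 2])]
        between = np.linalg.norm(scale_on.mean(axis=0) - scale_off.mean(axis=0))
        within = np.linalg.norm(scale_on - scale_on.mean(axis=0), axis=1).mean()
        assert between > 0.25 * within


class TestTrainVerifier:
    def test_c15_identity_mapping(self, small_library):
        v = train_verifier(small_library, C=15, seed=1, n_trees=40)
        assert len(set(v.label_to_cluster.values())) == 15

    def test_c2_two_nonempty_clusters(self, small_library):
        v = train_verifier(small_library, C=2, seed=1, n_trees=40)
        values = list(v.label_to_cluster.values())
        assert set(values) == {0, 1}

    def test_invalid_cluster_count_rejected(self, small_library):
        with pytest.raises(ValueError):
            train_verifier(small_library, C=7)

    def test_resubstitution_bounds_holdout(self, small_library):
        from fedprint.protocol import evaluate_verifier

        v = train_verifier(small_library, C=15, seed=1, n_trees=40)
        resub = (v.predict_labels(small_library.vectors) == small_library.labels).mean()
        holdout = evaluate_verifier(small_library, C=15, seed=1, n_trees=40, test_size=0.33)
        assert resub >= holdout - 1e-9


class TestVerify:
    def test_identical_configs_noiseless_mostly_compatible(self, small_cohort):
        """At eps=inf on shared data, identical pipelines are detected."""
        G, Y = small_cohort
        outcomes = []
        for t in range(3):
            out = run_federated_experiment(
                G, Y, K=2, epsilon=math.inf, scenario="all-same", seed=100 + t,
                C=2, R=3, subsample=150, n_trees=25, n_instances=10, settings=FAST,
            )
            outcomes.append(out.report.verdict == "COMPATIBLE")
        assert sum(outcomes) >= 2

    def test_differing_labels_yield_flag_difference(self):
        verifier = VerifierModel(
            classifier=_FixedPredictions([3, 3, 7]),
            cluster_count=15,
            label_to_cluster={lab: lab - 1 for lab in range(1, 16)},
            locus_ids=["a", "b", "c"],
        )
        report = verify([_dummy_artifact(f"s{i}") for i in range(3)], verifier)
        assert report.verdict == "INCOMPATIBLE"
        # configs 3 (scale+resample) vs 7 (outlier+scale+resample): outlier differs
        assert report.differing_flags == ["outlier"]

    def test_single_artifact_trivially_compatible(self, three_artifacts, small_library):
        verifier = train_verifier(small_library, C=15, seed=1, n_trees=40)
        report = verify(three_artifacts[:1], verifier)
        assert report.verdict == "COMPATIBLE"

    @given(
        st.lists(st.integers(1, 15), min_size=2, max_size=6),
        st.sampled_from([15, 5, 4, 3, 2]),
        st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=50)
    def test_verdict_rule_equals_cluster_equality(self, labels, C, map_seed):
        """verify() returns COMPATIBLE exactly when clusters coincide."""
        rng = np.random.default_rng(map_seed)
        if C == 15:
            mapping = {lab: lab - 1 for lab in range(1, 16)}
        else:
            mapping = {lab: int(rng.integers(0, C)) for lab in range(1, 16)}
        verifier = VerifierModel(
            classifier=_FixedPredictions(labels),
            cluster_count=C,
            label_to_cluster=mapping,
            locus_ids=["a", "b", "c"],
        )
        arts = [_dummy_artifact(f"s{i}") for i in range(len(labels))]
        report = verify(arts, verifier)
        expect_compatible = len({mapping[lab] for lab in labels}) == 1
        assert (report.verdict == "COMPATIBLE") == expect_compatible
        flag_vectors = {PreprocConfig.from_label(lab).flags for lab in labels}
        if report.verdict == "COMPATIBLE":
            assert report.differing_flags == []
        else:
            from fedprint.preprocess import FLAG_NAMES

            expected_diff = [
                n for j, n in enumerate(FLAG_NAMES)
                if len({fv[j] for fv in flag_vectors}) > 1
            ]
            assert report.differing_flags == expected_diff


class _FixedPredictions:
    """Classifier stub returning a preset label per successive call."""

    def __init__(self, labels):
        self._labels = list(labels)
        self._i = 0

    def predict(self, X):
        out = np.array([self._labels[self._i]])
        self._i += 1
        return out


def _dummy_artifact(site_id):
    from fedprint.explain import ExplanationVector

    G = fp.GenotypeMatrix(np.zeros((2, 3)), [f"{site_id}_a", f"{site_id}_b"], ["a", "b", "c"])
    return fp.SiteArtifact(
        site_id=site_id,
        perturbed=G,
        phenotypes=fp.PhenotypeVector([0, 1]),
        explanation=ExplanationVector(np.zeros(3), ["a", "b", "c"], 1),
        epsilon=3.0,
    )


class TestExperimentScenarios:
    def test_ground_truth_by_scenario(self, small_cohort):
        G, Y = small_cohort
        same = run_federated_experiment(
            G, Y, K=2, epsilon=3.0, scenario="all-same", seed=1,
            R=2, subsample=120, n_trees=15, n_instances=5, settings=FAST,
        )
        diff = run_federated_experiment(
            G, Y, K=2, epsilon=3.0, scenario="one-differs", seed=1,
            R=2, subsample=120, n_trees=15, n_instances=5, settings=FAST,
        )
        assert same.expected_verdict == "COMPATIBLE"
        assert diff.expected_verdict == "INCOMPATIBLE"
        assert len(set(diff.site_configs)) == 2

    def test_unknown_scenario_rejected(self, small_cohort):
        G, Y = small_cohort
        with pytest.raises(ValueError):
            run_federated_experiment(G, Y, scenario="nope")


def test_information_barrier_server_signatures():
    """Server-side operations accept only artifact-derived inputs."""
    import inspect

    for fn in (validate_alignment, build_reference, verify):
        params = inspect.signature(fn).parameters
        assert "config" not in params and "model" not in params
    # simulate_references sees only the perturbed concatenation
    params = inspect.signature(simulate_references).parameters
    assert list(params)[:2] == ["X_ref", "Y_ref"]
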