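import dataclasses
import math

import numpy as np
import pytest

from mlpa_ddr import (
    CallValue,
    FoldInductionProfile,
    GeneratorConfig,
    GenotypeLabel,
    SampleMetadata,
    TrainingConfig,
    cross_validate,
    cross_validate_nested,
    fit,
    mds_embed,
)
from mlpa_ddr.classifier import NestedClassifier
from mlpa_ddr.synthetic_cohort import default_mu_log2fi

EXPECTED_CALL = {
    GenotypeLabel.WT: CallValue.FUNCTIONAL,
    GenotypeLabel.TP53_BIALLELIC: CallValue.P53_DYSFUNCTIONAL,
    GenotypeLabel.ATM_BIALLELIC: CallValue.ATM_DYSFUNCTIONAL,
}


def prototype_profile(panel, genotype, sample_id="proto"):
    """Generator mean profile with zero noise: FI = 2**mu per gene."""
    mu = default_mu_log2fi(panel)[genotype]
    return FoldInductionProfile(
        sample_id=sample_id, fi={g: 2.0**m for g, m in mu.items()}
    )


class TestFit:
    def test_training_accuracy_perfect_on_default_cohort(
        self, cohort, trained_model
    ):
        meta = {m.sample_id: m for m in cohort["metadata"]}
        for p in cohort["profiles"]:
            call = trained_model.predict(p)
            assert call.value is EXPECTED_CALL[meta[p.sample_id].genotype]

    def test_missing_class_rejected(self, cohort, panel):
        meta = [
            m
            for m in cohort["metadata"]
            if m.genotype is not GenotypeLabel.ATM_BIALLELIC
        ]
        profiles = [
            p for p in cohort["profiles"] if any(m.sample_id == p.sample_id for m in meta)
        ]
        with pytest.raises(ValueError, match="ATM_BIALLELIC"):
            fit(profiles, meta, panel)

    def test_refit_is_deterministic(self, cohort, panel, trained_model):
        again = fit(cohort["profiles"], cohort["metadata"], panel)
        for p in cohort["profiles"][:10]:
            a, b = trained_model.predict(p), again.predict(p)
            assert a.value is b.value
            assert a.stage1_margin == pytest.approx(b.stage1_margin, abs=1e-10)

    def test_training_order_permutation_changes_no_prediction(
        self, cohort, panel, trained_model
    ):
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(cohort["profiles"]))
        shuffled = [cohort["profiles"][i] for i in perm]
        model = fit(shuffled, cohort["metadata"], panel)
        for p in cohort["profiles"]:
            assert model.predict(p).value is trained_model.predict(p).value
            # margins agree up to solver tolerance; the calls are identical
            assert model.predict(p).stage1_margin == pytest.approx(
                trained_model.predict(p).stage1_margin, abs=1e-3
            )

    def test_stage_feature_sets(self, trained_model, panel):
        cluster1 = {g.gene_id for g in panel.classification_genes if g.cluster == "I"}
        assert set(trained_model.stage1.feature_order) == cluster1
        assert set(trained_model.stage2.feature_order) == {
            g.gene_id for g in panel.classification_genes
        }


class TestPredict:
    @pytest.mark.parametrize("genotype", list(EXPECTED_CALL))
    def test_prototype_profiles_called_correctly(
        self, trained_model, panel, genotype
    ):
        call = trained_model.predict(prototype_profile(panel, genotype))
        assert call.value is EXPECTED_CALL[genotype]
        if genotype is GenotypeLabel.WT:
            assert call.stage1_margin <= 0
        else:
            assert call.stage1_margin > 0

    def test_functional_calls_carry_no_stage2_margin(
        self, cohort, trained_model
    ):
        calls = trained_model.predict_many(cohort["profiles"])
        for c in calls:
            if c.value is CallValue.FUNCTIONAL:
                assert c.stage2_margin is None
            else:
                assert c.stage2_margin is not None

    def test_stage2_margin_sign_encodes_subtype(self, trained_model, panel):
        p53 = trained_model.predict(
            prototype_profile(panel, GenotypeLabel.TP53_BIALLELIC)
        )
        atm = trained_model.predict(
            prototype_profile(panel, GenotypeLabel.ATM_BIALLELIC)
        )
        assert p53.stage2_margin > 0 > atm.stage2_margin

    def test_missing_feature_rejected(self, trained_model, panel):
        profile = prototype_profile(panel, GenotypeLabel.WT)
        partial = FoldInductionProfile(
            sample_id="x",
            fi={g: v for g, v in profile.fi.items() if g != "NME1"},
        )
        with pytest.raises(ValueError, match="NME1"):
            trained_model.predict(partial)


class TestSerialization:
    def test_json_round_trip_preserves_decision_function(
        self, trained_model, cohort, tmp_path
    ):
        path = tmp_path / "model.json"
        trained_model.to_json(path)
        loaded = NestedClassifier.from_json(path)
        for p in cohort["profiles"]:
            a, b = trained_model.predict(p), loaded.predict(p)
            assert a.value is b.value
            assert a.stage1_margin == pytest.approx(b.stage1_margin, abs=1e-9)


class TestCrossValidation:
    def test_loo_perfect_on_strongly_separated_cohort(self, panel):
        """With noise far below the group separation every held-out sample
        is classified correctly."""
        from mlpa_ddr import compute_fi_table, resolve_profile, select_probes, simulate_cohort

        config = GeneratorConfig(
            n_per_group=10, seed=2, sigma_log2fi=0.05, sigma_tech=0.02,
            sigma_baseline=0.05,
        )
        measurements, metadata = simulate_cohort(config)
        fi = compute_fi_table(measurements, panel)
        profiles, _ = resolve_profile(fi, select_probes(fi, metadata, panel))
        report = cross_validate(profiles, metadata, panel)
        assert report.n_samples == len(profiles)
        assert report.percent("specificity") == 100
        assert report.percent("sensitivity_tp53") == 100
        assert report.percent("sensitivity_atm") == 100

    def test_three_sample_toy_runs_with_degenerate_folds(self, panel, caplog):
        profiles = [
            prototype_profile(panel, g, sample_id=g.value)
            for g in EXPECTED_CALL
        ]
        meta = [SampleMetadata(g.value, g) for g in EXPECTED_CALL]
        with caplog.at_level("WARNING", logger="mlpa_ddr"):
            report = cross_validate(profiles, meta, panel)
        assert report.n_samples == 3
        assert "degenerate" in caplog.text

    def test_fold_models_never_see_held_out_values(self, cohort, panel):
        """Mutating the held-out sample must not change the fold model:
        its prediction equals that of a model fitted on the remainder."""
        victim = cohort["profiles"][0]
        rest = cohort["profiles"][1:]
        mutated = FoldInductionProfile(
            sample_id=victim.sample_id,
            fi={g: v * 1000.0 for g, v in victim.fi.items()},
        )
        reference = fit(rest, cohort["metadata"], panel)
        expected = reference.predict(mutated)

        report = cross_validate(
            [mutated] + rest, cohort["metadata"], panel
        )
        key = (
            GenotypeLabel.WT
            if victim.sample_id.startswith("WT")
            else None
        )
        # reconstruct the victim's held-out call from the report is not
        # possible; instead verify directly against the reference model
        loo_model = fit(rest, cohort["metadata"], panel)
        got = loo_model.predict(mutated)
        assert got.value is expected.value
        assert got.stage1_margin == pytest.approx(
            expected.stage1_margin, abs=1e-9
        )
        assert report.n_samples == len(cohort["profiles"])

    def test_accuracy_degrades_to_chance_without_separation(self, panel):
        """Monotone spot-check: shrinking the generator's group separation
        drives LOO accuracy from ~1 toward chance."""
        from mlpa_ddr import compute_fi_table, resolve_profile, select_probes, simulate_cohort

        accuracies = []
        for scale in (1.0, 0.3, 0.0):
            mu = {
                g: {gene: m * scale for gene, m in genes.items()}
                for g, genes in default_mu_log2fi(panel).items()
            }
            config = GeneratorConfig(n_per_group=12, seed=5, mu_log2fi=mu)
            measurements, metadata = simulate_cohort(config)
            fi = compute_fi_table(measurements, panel)
            profiles, _ = resolve_profile(
                fi,
                select_probes(fi, metadata, panel)
                if scale > 0
                else _first_probe_selection(panel),
            )
            report = cross_validate(profiles, metadata, panel)
            meta = {m.sample_id: m for m in metadata}
            correct = sum(
                n
                for (g, c), n in report.counts.items()
                if EXPECTED_CALL[g] is c
            )
            accuracies.append(correct / report.n_samples)
        assert accuracies[0] >= 0.95
        assert accuracies[0] >= accuracies[1] >= accuracies[2] - 0.15
        assert accuracies[2] < 0.6  # chance level is 1/3

    def test_nested_selection_variant_runs(self, cohort, panel):
        small = cohort["fi"].iloc[:, list(range(8)) + list(range(30, 38)) + list(range(60, 68))]
        meta = [
            m for m in cohort["metadata"] if m.sample_id in small.columns
        ]
        report = cross_validate_nested(small, meta, panel)
        assert report.n_samples == small.shape[1]


def _first_probe_selection(panel):
    from mlpa_ddr.probe_selection import ProbeSelectionResult, SelectedProbe

    return ProbeSelectionResult(
        selection={
            g.gene_id: SelectedProbe(g.probe_ids[0], 1.0, 0.0)
            for g in panel.classification_genes
        }
    )


class TestMds:
    def _profiles_from_log2(self, vectors):
        genes = [f"g{i}" for i in range(len(vectors[0]))]
        return [
            FoldInductionProfile(
                sample_id=f"s{i}",
                fi={g: 2.0**x for g, x in zip(genes, vec)},
            )
            for i, vec in enumerate(vectors)
        ]

    def test_planar_input_distances_reproduced(self):
        rng = np.random.default_rng(0)
        plane = rng.normal(size=(8, 2))
        basis = np.linalg.qr(rng.normal(size=(5, 2)))[0].T  # 2 x 5 orthonormal
        vectors = plane @ basis  # 8 points in a 2-D subspace of R^5
        profiles = self._profiles_from_log2(vectors)
        emb = mds_embed(profiles)
        coords = np.array([emb.coordinates[p.sample_id] for p in profiles])
        for i in range(len(profiles)):
            for j in range(i + 1, len(profiles)):
                d_in = np.linalg.norm(vectors[i] - vectors[j])
                d_out = np.linalg.norm(coords[i] - coords[j])
                assert d_out == pytest.approx(d_in, abs=1e-9)

    def test_equidistant_triple_forms_equilateral_triangle(self):
        # pairwise log2-distance sqrt(2) between the three unit vectors
        vectors = np.eye(3)
        profiles = self._profiles_from_log2(vectors)
        emb = mds_embed(profiles)
        coords = np.array([emb.coordinates[p.sample_id] for p in profiles])
        sides = [
            np.linalg.norm(coords[i] - coords[j])
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        assert all(s == pytest.approx(math.sqrt(2), abs=1e-9) for s in sides)

    def test_duplicated_profile_gives_coincident_points(self):
        vectors = [[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [2.0, 0.0]]
        profiles = self._profiles_from_log2(vectors)
        emb = mds_embed(profiles)
        a = np.array(emb.coordinates["s1"])
        b = np.array(emb.coordinates["s2"])
        assert np.linalg.norm(a - b) == pytest.approx(0.0, abs=1e-9)

    def test_fewer_than_three_profiles_rejected(self):
        profiles = self._profiles_from_log2([[0.0], [1.0]])
        with pytest.raises(ValueError):
            mds_embed(profiles)

    def test_canonicalization_makes_embedding_deterministic(self, cohort):
        a = mds_embed(cohort["profiles"])
        b = mds_embed(list(cohort["profiles"]))
        for sid in a.coordinates:
            assert a.coordinates[sid] == pytest.approx(b.coordinates[sid])

    def test_agrees_with_skbio_pcoa_up_to_sign(self, cohort):
        skbio = pytest.importorskip("skbio")
        from scipy.spatial.distance import pdist, squareform

        profiles = cohort["profiles"][:15]
        genes = sorted(profiles[0].fi)
        X = np.log2([[p.fi[g] for g in genes] for p in profiles])
        dm = skbio.DistanceMatrix(
            squareform(pdist(X)), ids=[p.sample_id for p in profiles]
        )
        ref = skbio.stats.ordination.pcoa(dm, number_of_dimensions=2)
        emb = mds_embed(profiles)
        ours = np.array([emb.coordinates[p.sample_id] for p in profiles])
        theirs = ref.samples.to_numpy()
        for j in range(2):
            sign = np.sign(np.dot(ours[:, j], theirs[:, j])) or 1.0
            assert np.allclose(ours[:, j], sign * theirs[:, j], atol=1e-6)

    def test_genotype_groups_separate_in_embedding(self, cohort):
        """The ordination mirrors mutational status: group centroids are
        farther apart than typical within-group spread."""
        emb = mds_embed(cohort["profiles"])
        groups = {}
        for p in cohort["profiles"]:
            groups.setdefault(p.sample_id.split("_")[0], []).append(
                emb.coordinates[p.sample_id]
            )
        centroids = {g: np.mean(v, axis=0) for g, v in groups.items()}
        spread = np.mean(
            [
                np.linalg.norm(np.array(x) - centroids[g])
                for g, v in groups.items()
                for x in v
            ]
        )
        names = list(centroids)
        min_sep = min(
            np.linalg.norm(centroids[a] - centroids[b])
            for i, a in enumerate(names)
            for b in names[i + 1 :]
        )
        assert min_sep > spread
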