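import numpy as np
import pytest
from scipy.stats import spearmanr

from rtpred import synthetic_data as S
from rtpred.annotate import candidate_search
from rtpred.dlm import split_train_val
from rtpred.knn_baseline import stratify_by_similarity
from rtpred.molecules import tanimoto


class TestGenLibrary:
    def test_fully_deterministic_under_seed(self):
        cfg = S.GeneratorConfig(n_molecules=200, n_clusters=20, seed=3)
        r1, t1 = S.gen_library(cfg)
        r2, t2 = S.gen_library(S.GeneratorConfig(n_molecules=200, n_clusters=20, seed=3))
        assert all(
            a.mol_id == b.mol_id
            and a.rt == b.rt
            and a.mono_mass == b.mono_mass
            and np.array_equal(a.fingerprint, b.fingerprint)
            for a, b in zip(r1, r2)
        )
        assert np.array_equal(t1.weights, t2.weights)

    def test_zero_noise_gives_identical_rt_for_identical_fingerprints(self):
        cfg = S.GeneratorConfig(
            n_molecules=60,
            n_clusters=5,
            flip_mean=0.0,
            rt_noise_sd=0.0,
            background_fraction=0.0,
            nonretained_fraction=0.0,
            seed=4,
        )
        records, _ = S.gen_library(cfg)
        by_key = {}
        for r in records:
            by_key.setdefault(r.fingerprint.tobytes(), set()).add(r.rt)
        assert any(len(v) for v in by_key.values())
        assert all(len(rts) == 1 for rts in by_key.values())

    def test_cluster_mates_without_flips_are_identical(self):
        cfg = S.GeneratorConfig(
            n_molecules=30, n_clusters=2, flip_mean=0.0, background_fraction=0.0, seed=5
        )
        records, truth = S.gen_library(cfg)
        i, j = np.where(truth.cluster_labels == truth.cluster_labels[0])[0][:2]
        assert tanimoto(records[i].fingerprint, records[j].fingerprint) == 100.0

    def test_nonretained_fraction_and_rt_gap(self):
        cfg = S.GeneratorConfig(n_molecules=1000, n_clusters=100, seed=6)
        records, truth = S.gen_library(cfg)
        rts = np.array([r.rt for r in records])
        n_nr = int(truth.nonretained.sum())
        assert n_nr == round(cfg.nonretained_fraction * 1000)  # structural tail is exact
        assert (rts[truth.nonretained] <= cfg.nonretained_range[1]).all()
        # the void gap: nothing elutes between the band and the retained start
        assert not ((rts > cfg.nonretained_range[1]) & (rts < 250.0)).any()

    def test_similarity_strata_populated_at_all_thresholds(self):
        records, _ = S.gen_library(S.GeneratorConfig(seed=202))
        train, val = split_train_val(records, 0.75, seed=43)
        strata = stratify_by_similarity(val, train)
        for t, stratum in strata.items():
            assert stratum.n > 0, f"empty stratum at {t}%"

    def test_mass_collisions_present(self):
        records, _ = S.gen_library(S.GeneratorConfig(n_molecules=500, n_clusters=50, seed=8))
        masses = np.sort([r.mono_mass for r in records])
        rel_gaps = np.diff(masses) / masses[:-1] * 1e6
        assert (rel_gaps < 10).sum() > 20  # many <10 ppm neighbours

    def test_degenerate_configs_rejected(self):
        with pytest.raises(ValueError):
            S.GeneratorConfig(n_molecules=0)
        with pytest.raises(ValueError):
            S.GeneratorConfig(nonretained_fraction=1.5)
        with pytest.raises(ValueError, match="gap"):
            S.GeneratorConfig(nonretained_range=(25.0, 400.0))


class TestGenEcm:
    @pytest.fixture(scope="class")
    def library(self):
        return S.gen_library(S.GeneratorConfig(n_molecules=300, n_clusters=30, seed=9))

    def test_identity_warp_zero_noise_equals_reference(self, library):
        records, truth = library
        ecm = S.gen_ecm(records, truth, S.EcmConfig(warp="identity", noise_sd=0.0, seed=1))
        rt_map = dict(zip([r.mol_id for r in records], truth.rt_latent))
        ref = np.array([rt_map[m] for m in ecm.table["mol_id"]])
        assert np.allclose(ecm.table["rt_ecm_s"], ref)

    def test_monotone_warp_preserves_elution_order(self, library):
        records, truth = library
        ecm = S.gen_ecm(records, truth, S.EcmConfig(noise_sd=0.0, seed=2))
        rt_map = dict(zip([r.mol_id for r in records], truth.rt_latent))
        ref = np.array([rt_map[m] for m in ecm.table["mol_id"]])
        rho = spearmanr(ref, ecm.table["rt_ecm_s"]).statistic
        assert rho == pytest.approx(1.0)

    def test_nonretained_molecules_not_on_external_method(self, library):
        records, truth = library
        ecm = S.gen_ecm(records, truth, S.EcmConfig(seed=3))
        nr_ids = {r.mol_id for i, r in enumerate(records) if truth.nonretained[i]}
        assert not nr_ids & set(ecm.table["mol_id"])

    def test_anchor_selection_seeded(self, library):
        records, truth = library
        e1 = S.gen_ecm(records, truth, S.EcmConfig(seed=4))
        e2 = S.gen_ecm(records, truth, S.EcmConfig(seed=4))
        assert e1.anchor_ids == e2.anchor_ids
        with pytest.raises(ValueError):
            S.gen_ecm(records, truth, S.EcmConfig(n_anchors=10**6))

    def test_invalid_warp_rejected(self):
        with pytest.raises(ValueError):
            S.EcmConfig(warp_a=-1.0)
        with pytest.raises(ValueError):
            S.EcmConfig(warp="affine")


class TestGenQueryIons:
    @pytest.fixture(scope="class")
    def setup(self):
        records, truth = S.gen_library(
            S.GeneratorConfig(n_molecules=300, n_clusters=30, seed=9)
        )
        ecm = S.gen_ecm(records, truth, S.EcmConfig(seed=5))
        return records, truth, ecm

    def test_zero_mass_noise_truth_always_recovered(self, setup):
        records, truth, ecm = setup
        queries = S.gen_query_ions(ecm, records, mass_noise_ppm=0.0, seed=6)
        library = [r for i, r in enumerate(records) if not truth.nonretained[i]]
        sets = candidate_search(queries, library)
        assert all(cs.truth_present for cs in sets)

    def test_near_collisions_create_multicandidate_sets(self, setup):
        records, truth, ecm = setup
        queries = S.gen_query_ions(ecm, records, seed=7)
        library = [r for i, r in enumerate(records) if not truth.nonretained[i]]
        sets = candidate_search(queries, library)
        assert sum(cs.n_candidates > 1 for cs in sets) > 10

    def test_empty_selection_gives_empty_queries(self, setup):
        records, _, ecm = setup
        assert S.gen_query_ions(ecm, records, n_queries=0, seed=8) == []

    def test_deterministic_under_seed(self, setup):
        records, _, ecm = setup
        q1 = S.gen_query_ions(ecm, records, seed=11)
        q2 = S.gen_query_ions(ecm, records, seed=11)
        assert [(a.query_id, a.mz, a.adduct) for a in q1] == [
            (b.query_id, b.mz, b.adduct) for b in q2
        ]
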