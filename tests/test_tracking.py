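import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrtrace.core import RepertoireError
from tcrtrace.simulate import CohortSpec, generate_cohort, generate_patient_pair
from tcrtrace.tracking import (
    classify_publicity,
    clonal_persistence,
    highly_shared_clones,
    persistence_table,
    public_clone_stats,
)

from conftest import make_repertoire


def rep_from_cdr3s(cdr3s, **kwargs):
    return make_repertoire([("TRBV2", "TRBJ1-1", c, 1) for c in cdr3s], **kwargs)


CDR3S = [f"CASS{a}{b}F" for a in "ACDEFGHIKLMNPQRSTVW" for b in "ACDEFGHIKLMNPQRSTVW"]


class TestClonalPersistence:
    def test_identical_repertoires_100pct(self):
        a = rep_from_cdr3s(CDR3S[:10], sample_id="a")
        b = rep_from_cdr3s(CDR3S[:10], sample_id="b")
        assert clonal_persistence(a, b).persistence_pct == 100.0

    def test_disjoint_repertoires_0pct(self):
        a = rep_from_cdr3s(CDR3S[:10], sample_id="a")
        b = rep_from_cdr3s(CDR3S[10:20], sample_id="b")
        assert clonal_persistence(a, b).persistence_pct == 0.0

    def test_formula_on_unequal_sizes(self):
        # |A| = 10, |B| = 20, 3 shared -> 100·3/15 = 20%
        a = rep_from_cdr3s(CDR3S[:10], sample_id="a")
        b = rep_from_cdr3s(CDR3S[7:27], sample_id="b")
        res = clonal_persistence(a, b)
        assert res.n_shared == 3
        assert res.persistence_pct == pytest.approx(20.0, abs=1e-12)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_bounds(self, data):
        pool = CDR3S[:40]
        set_a = data.draw(st.sets(st.sampled_from(pool), min_size=1))
        set_b = data.draw(st.sets(st.sampled_from(pool), min_size=1))
        a = rep_from_cdr3s(sorted(set_a), sample_id="a")
        b = rep_from_cdr3s(sorted(set_b), sample_id="b")
        ab = clonal_persistence(a, b).persistence_pct
        ba = clonal_persistence(b, a).persistence_pct
        assert ab == ba
        assert 0.0 <= ab <= 100.0
        if set_a == set_b:
            assert ab == 100.0

    def test_same_keys_different_vj_do_not_match(self):
        a = make_repertoire([("TRBV2", "TRBJ1-1", "CASSLF", 1)], sample_id="a")
        b = make_repertoire([("TRBV9", "TRBJ1-1", "CASSLF", 1)], sample_id="b")
        assert clonal_persistence(a, b).persistence_pct == 0.0


class TestPersistenceTable:
    def test_synthetic_pair_recovers_injected_fraction(self):
        spec = CohortSpec(n_clones=500, persistence_fraction=0.2,
                          public_pool_size=0, seed=3)
        rng = np.random.default_rng(0)
        t0, t24 = generate_patient_pair(
            spec, rng, patient_id="P1", treatment="NTZ",
            subpopulation="CD8_naive", sample_stem="P1_CD8_naive",
        )
        table = persistence_table([t0, t24])
        assert len(table) == 1
        assert table.iloc[0]["persistence_pct"] == pytest.approx(20.0, abs=1e-12)

    def test_single_timepoint_patient_skipped(self):
        only_t0 = rep_from_cdr3s(CDR3S[:5], sample_id="x", timepoint="t0")
        assert len(persistence_table([only_t0])) == 0

    def test_invariant_to_sample_ordering(self):
        spec = CohortSpec(n_patients_ahsct=1, n_patients_ntz=1, n_clones=60,
                          public_pool_size=30, seed=9)
        cohort = generate_cohort(spec).repertoires
        t1 = persistence_table(cohort)
        t2 = persistence_table(cohort[::-1])
        assert t1.equals(t2)

    def test_matched_pairing_restricts_to_same_subpopulation(self):
        spec = CohortSpec(n_patients_ahsct=1, n_patients_ntz=0, n_clones=50,
                          public_pool_size=0, seed=4)
        cohort = generate_cohort(spec).repertoires
        cross = persistence_table(cohort, pairing="cross_subpopulation")
        matched = persistence_table(cohort, pairing="matched")
        assert len(cross) == 16  # 4 subpopulations × 4
        assert len(matched) == 4
        assert (matched["subpop_a"] == matched["subpop_b"]).all()


class TestPublicity:
    def _three_sample_cohort(self):
        shared = "CASSSHF"
        s1 = rep_from_cdr3s([shared, CDR3S[0]], sample_id="s1", patient_id="p1")
        s2 = rep_from_cdr3s([shared, CDR3S[1]], sample_id="s2", patient_id="p2")
        s3 = rep_from_cdr3s([CDR3S[2], CDR3S[3]], sample_id="s3", patient_id="p3")
        return [s1, s2, s3]

    def test_private_iff_in_one_sample(self):
        cohort = self._three_sample_cohort()
        records = classify_publicity(cohort)
        shared_key = ("TRBV2", "TRBJ1-1", "CASSSHF")
        assert records[shared_key].publicity == "public"
        assert records[shared_key].n_samples_sharing == 2
        private = [rec for rec in records.values() if rec.publicity == "private"]
        assert all(rec.n_samples_sharing == 1 for rec in private)
        assert len(private) == 4

    def test_patient_level_sharing_unit(self):
        shared = "CASSSHF"
        a = rep_from_cdr3s([shared], sample_id="a", patient_id="p1")
        b = rep_from_cdr3s([shared], sample_id="b", patient_id="p1")
        by_sample = classify_publicity([a, b], sharing_unit="sample")
        by_patient = classify_publicity([a, b], sharing_unit="patient")
        key = ("TRBV2", "TRBJ1-1", shared)
        assert by_sample[key].publicity == "public"
        assert by_patient[key].publicity == "private"

    def test_public_counts_sum_to_richness(self):
        cohort = self._three_sample_cohort()
        records = classify_publicity(cohort)
        for r in cohort:
            n_pub = sum(1 for k in r.clone_keys() if records[k].publicity == "public")
            n_priv = sum(1 for k in r.clone_keys() if records[k].publicity == "private")
            assert n_pub + n_priv == r.species_richness

    def test_public_clone_stats_extremes(self):
        same = [rep_from_cdr3s(CDR3S[:6], sample_id=f"s{i}", patient_id=f"p{i}")
                for i in range(3)]
        stats = public_clone_stats(same)
        assert (stats["pct_public"] == 100.0).all()
        disjoint = [rep_from_cdr3s(CDR3S[6 * i: 6 * i + 6], sample_id=f"d{i}",
                                   patient_id=f"p{i}") for i in range(3)]
        stats = public_clone_stats(disjoint)
        assert (stats["pct_public"] == 0.0).all()

    def test_sample_without_shared_clone_has_zero_public(self):
        stats = public_clone_stats(self._three_sample_cohort())
        assert stats.set_index("sample_id").loc["s3", "n_public"] == 0

    def test_injected_public_pool_recovered_on_synthetic_cohort(self):
        spec = CohortSpec(n_patients_ahsct=2, n_patients_ntz=2, n_clones=100,
                          public_pool_size=40, public_injection_rate=0.1, seed=21)
        cohort = generate_cohort(spec)
        records = classify_publicity(cohort.repertoires)
        pool = set(cohort.public_pool)
        for key, rec in records.items():
            if key in pool and len(rec.sample_ids) >= 2:
                assert rec.publicity == "public"
        # non-pool clones of distinct patients never collide at depth 0
        n_public_outside_pool = sum(
            1 for key, rec in records.items()
            if rec.publicity == "public" and key not in pool
            and len({s.rsplit("_", 1)[0] for s in rec.sample_ids}) > 1
        )
        assert n_public_outside_pool == 0


class TestHighlyShared:
    def test_threshold_larger_than_cohort_gives_empty(self):
        cohort = [rep_from_cdr3s(CDR3S[:4], sample_id=f"s{i}", patient_id=f"p{i}")
                  for i in range(3)]
        hits, matrix = highly_shared_clones(cohort, min_samples=11)
        assert hits == []
        assert matrix.shape == (0, 3)

    def test_injected_clone_above_threshold_included(self):
        shared = "CASSSHF"
        cohort = [rep_from_cdr3s([shared, CDR3S[i]], sample_id=f"s{i:02d}",
                                 patient_id=f"p{i}") for i in range(12)]
        hits, matrix = highly_shared_clones(cohort, min_samples=11)
        assert len(hits) == 1
        assert hits[0].clone_key == ("TRBV2", "TRBJ1-1", shared)
        assert matrix.loc["TRBV2|TRBJ1-1|" + shared].sum() == 12

    def test_lowering_threshold_is_monotone(self):
        rng = np.random.default_rng(17)
        cohort = []
        for i in range(8):
            picks = rng.choice(CDR3S[:30], size=10, replace=False)
            cohort.append(rep_from_cdr3s(sorted(picks), sample_id=f"s{i}",
                                         patient_id=f"p{i}"))
        prev: set = set()
        for threshold in (8, 6, 4, 2):
            hits, _ = highly_shared_clones(cohort, min_samples=threshold)
            keys = {h.clone_key for h in hits}
            assert prev <= keys
            prev = keys

    def test_min_samples_below_two_rejected(self):
        with pytest.raises(ValueError):
            highly_shared_clones([], min_samples=1)
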