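import math

import numpy as np
import pytest

from tcrtrace.architecture import (
    build_ld1_network,
    connected_fraction,
    degree_distribution,
    kmer_correlation_matrix,
    kmer_profile,
    ld1_edges,
)
from tcrtrace.core import RepertoireError
from tcrtrace.tracking import classify_publicity

from conftest import make_repertoire


def rep_from_cdr3s(cdr3s, counts=None, **kwargs):
    counts = counts or [1] * len(cdr3s)
    return make_repertoire(
        [("TRBV2", "TRBJ1-1", c, n) for c, n in zip(cdr3s, counts)], **kwargs
    )


def levenshtein(s, t):
    """Plain dynamic-programming edit distance (test oracle)."""
    prev = list(range(len(t) + 1))
    for i, cs in enumerate(s, 1):
        cur = [i]
        for j, ct in enumerate(t, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cs != ct)))
        prev = cur
    return prev[-1]


def brute_force_edges(strings):
    return {
        (min(a, b), max(a, b))
        for i, a in enumerate(strings)
        for b in strings[i + 1:]
        if levenshtein(a, b) == 1
    }


def random_similar_strings(rng, n, alphabet="ACDF", lengths=(4, 8)):
    """Low-diversity strings so LD-1 neighbors actually occur."""
    letters = np.array(list(alphabet))
    out = set()
    while len(out) < n:
        length = int(rng.integers(lengths[0], lengths[1] + 1))
        out.add("".join(letters[rng.integers(0, len(letters), length)]))
    return sorted(out)


class TestLd1Edges:
    def test_single_substitution_connects(self):
        net = build_ld1_network(rep_from_cdr3s(["CASSLF", "CASSLY"]))
        assert net.n_edges == 1
        assert net.degrees() == {"CASSLF": 1, "CASSLY": 1}

    def test_length_difference_two_never_connects(self):
        net = build_ld1_network(rep_from_cdr3s(["CASS", "CASSLY"]))
        assert net.n_edges == 0

    def test_single_indel_connects(self):
        assert ld1_edges(["CASSF", "CASSLF"]) == {("CASSF", "CASSLF")}

    def test_matches_bruteforce_on_random_fixture(self):
        rng = np.random.default_rng(123)
        strings = random_similar_strings(rng, 50)
        assert ld1_edges(strings) == brute_force_edges(strings)

    def test_no_self_edges_and_symmetric_degree(self):
        rng = np.random.default_rng(5)
        strings = random_similar_strings(rng, 80)
        net = build_ld1_network(rep_from_cdr3s(strings))
        assert all(a != b for a, b in net.graph.edges())
        assert sum(dict(net.graph.degree()).values()) == 2 * net.n_edges


class TestTopN:
    def test_top_n_caps_nodes_by_frequency(self):
        r = rep_from_cdr3s(["CAAAF", "CAACF", "CAADF", "CAAEF"], counts=[10, 5, 2, 1])
        net = build_ld1_network(r, top_n=2)
        assert set(net.graph.nodes()) == {"CAAAF", "CAACF"}

    def test_shared_cdr3_aggregates_frequency(self):
        r = make_repertoire(
            [("TRBV2", "TRBJ1-1", "CASSLF", 2), ("TRBV9", "TRBJ1-2", "CASSLF", 3),
             ("TRBV2", "TRBJ1-1", "CASSQF", 5)]
        )
        net = build_ld1_network(r)
        assert net.n_nodes == 2
        assert net.graph.nodes["CASSLF"]["frequency"] == pytest.approx(0.5)


class TestDegreeDistribution:
    def test_edgeless_network(self):
        net = build_ld1_network(rep_from_cdr3s(["CADLF", "CWWWWWF", "CKKKKKKKF"]))
        dd = degree_distribution(net)
        assert dd.to_dict("records") == [{"degree": 0, "n_nodes": 3, "fraction": 1.0}]

    def test_path_graph_degrees(self):
        # CASSAF - CASSGF - CASSGY is a path (ends at distance 2)
        net = build_ld1_network(rep_from_cdr3s(["CASSAF", "CASSGF", "CASSGY"]))
        dd = dict(zip(degree_distribution(net)["degree"],
                      degree_distribution(net)["n_nodes"]))
        assert dd == {1: 2, 2: 1}

    def test_matches_bruteforce_histogram(self):
        rng = np.random.default_rng(77)
        strings = random_similar_strings(rng, 120)
        net = build_ld1_network(rep_from_cdr3s(strings))
        oracle_deg = {s: 0 for s in strings}
        for a, b in brute_force_edges(strings):
            oracle_deg[a] += 1
            oracle_deg[b] += 1
        from collections import Counter

        oracle_hist = Counter(oracle_deg.values())
        dd = degree_distribution(net)
        assert dict(zip(dd["degree"], dd["n_nodes"])) == dict(oracle_hist)
        assert dd["n_nodes"].sum() == net.n_nodes
        assert dd["fraction"].sum() == pytest.approx(1.0, abs=1e-12)


class TestConnectedFraction:
    def test_all_isolated_gives_zero(self):
        net = build_ld1_network(rep_from_cdr3s(["CADLF", "CWWWWWF", "CKKKKKKKF"]))
        assert connected_fraction(net, "all") == 0.0

    def test_two_thirds_connected(self):
        net = build_ld1_network(rep_from_cdr3s(["CASSLF", "CASSLY", "CLMNPQW"]))
        assert connected_fraction(net, "all") == pytest.approx(200 / 3, abs=1e-9)

    def test_complete_triangle_fully_connected(self):
        net = build_ld1_network(rep_from_cdr3s(["CASSF", "CASSY", "CASSW"]))
        assert net.n_edges == 3
        assert connected_fraction(net, "all") == 100.0

    def test_per_class_fractions_and_weighted_average(self):
        shared, other = "CASSLF", "CASSLY"
        a = rep_from_cdr3s([shared, other, "CWWWWWF"], sample_id="a", patient_id="p1")
        b = rep_from_cdr3s([shared], sample_id="b", patient_id="p2")
        records = classify_publicity([a, b])
        net = build_ld1_network(a, publicity=records)
        pub = connected_fraction(net, "public")      # CASSLF: connected
        priv = connected_fraction(net, "private")    # CASSLY yes, CWWWWWF no
        all_ = connected_fraction(net, "all")
        assert pub == 100.0
        assert priv == 50.0
        assert all_ == pytest.approx((1 * pub + 2 * priv) / 3, abs=1e-9)

    def test_empty_class_flagged_nan(self):
        a = rep_from_cdr3s(["CASSLF"], sample_id="a", patient_id="p1")
        b = rep_from_cdr3s(["CASSLF"], sample_id="b", patient_id="p2")
        records = classify_publicity([a, b])
        net = build_ld1_network(a, publicity=records)
        assert math.isnan(connected_fraction(net, "private"))

    def test_missing_labels_rejected(self):
        net = build_ld1_network(rep_from_cdr3s(["CASSLF"]))
        with pytest.raises(RepertoireError):
            connected_fraction(net, "public")


class TestKmerProfile:
    def test_overlapping_3mers_of_single_cdr3(self):
        prof = kmer_profile(rep_from_cdr3s(["CASSL"]))
        assert prof.frequencies == pytest.approx(
            {"CAS": 1 / 3, "ASS": 1 / 3, "SSL": 1 / 3}
        )

    def test_cdr3_of_length_k(self):
        prof = kmer_profile(rep_from_cdr3s(["CAS"]))
        assert prof.frequencies == {"CAS": 1.0}

    def test_unique_cdr3_weighting_ignores_clone_multiplicity(self):
        one = make_repertoire([("TRBV2", "TRBJ1-1", "CASSL", 4)])
        two = make_repertoire(
            [("TRBV2", "TRBJ1-1", "CASSL", 2), ("TRBV9", "TRBJ1-2", "CASSL", 2)]
        )
        assert kmer_profile(one).frequencies == kmer_profile(two).frequencies

    def test_frequency_weighting_differs(self):
        r = rep_from_cdr3s(["CASSL", "CWWWL"], counts=[9, 1])
        uw = kmer_profile(r, weighting="unique_cdr3")
        fw = kmer_profile(r, weighting="clone_frequency")
        assert uw.frequencies["CAS"] == pytest.approx(1 / 6)
        assert fw.frequencies["CAS"] == pytest.approx(0.9 / 3)

    def test_short_cdr3s_skipped_and_empty_profile_rejected(self):
        r = rep_from_cdr3s(["CAF", "CASSLF"])
        prof = kmer_profile(r, k=4)
        assert all(len(kmer) == 4 for kmer in prof.frequencies)
        with pytest.raises(RepertoireError):
            kmer_profile(rep_from_cdr3s(["CAF"]), k=5)

    def test_sum_to_one_and_order_invariance(self):
        rng = np.random.default_rng(13)
        strings = random_similar_strings(rng, 30, alphabet="ACDEFGHIK", lengths=(5, 12))
        counts = list(rng.integers(1, 50, len(strings)))
        a = kmer_profile(rep_from_cdr3s(strings, counts))
        b = kmer_profile(rep_from_cdr3s(strings[::-1], counts[::-1]))
        assert sum(a.frequencies.values()) == pytest.approx(1.0, abs=1e-12)
        assert a.frequencies == b.frequencies


class TestKmerCorrelation:
    def test_self_correlation_one(self):
        p = kmer_profile(rep_from_cdr3s(["CASSL", "CASSQ"], [1, 1]), k=3)
        mat = kmer_correlation_matrix([p, p])
        assert mat.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_two_kmer_profiles_anticorrelate(self):
        # A = {CAS: .5, ASS: .5}, B = {SSL: .5, SLY: .5} over the 4-k-mer union
        a = rep_from_cdr3s(["CASS"], sample_id="a")
        b = rep_from_cdr3s(["SSLY"], sample_id="b", patient_id="p2")
        mat = kmer_correlation_matrix([kmer_profile(a), kmer_profile(b)])
        assert mat.loc["a", "b"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pairwise_pearson_oracle(self):
        rng = np.random.default_rng(19)
        profs = []
        for i in range(3):
            strings = random_similar_strings(rng, 20, alphabet="ACDEFG", lengths=(5, 9))
            profs.append(kmer_profile(rep_from_cdr3s(strings, sample_id=f"s{i}")))
        union = sorted(set().union(*(p.frequencies for p in profs)))
        vecs = [np.array([p.frequencies.get(k, 0.0) for k in union]) for p in profs]
        mat = kmer_correlation_matrix(profs)
        for i in range(3):
            for j in range(3):
                a, b = vecs[i], vecs[j]
                ad, bd = a - a.mean(), b - b.mean()
                oracle = float(np.sum(ad * bd) / math.sqrt(np.sum(ad**2) * np.sum(bd**2)))
                assert mat.iloc[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_mixed_k_rejected(self):
        p3 = kmer_profile(rep_from_cdr3s(["CASSL"]), k=3)
        p4 = kmer_profile(rep_from_cdr3s(["CASSL"]), k=4)
        with pytest.raises(RepertoireError):
            kmer_correlation_matrix([p3, p4])
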