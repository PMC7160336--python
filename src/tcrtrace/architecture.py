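"""Repertoire architecture: LD-1 similarity networks and k-mer spectra.

A repertoire's architecture is the all-to-all sequence similarity of its
CDR3s.  Two complementary views are implemented:

* an undirected *LD-1 network* over the top-N CDR3 amino-acid strings,
  with an edge wherever the Levenshtein distance between two distinct
  CDR3s is 1 (a single substitution, insertion or deletion) — degree
  distributions and connected-clone fractions summarize it;
* a *k-mer decomposition profile*: the normalized frequency distribution
  of overlapping length-k subsequences (default k = 3) over the
  repertoire's CDR3s, compared across samples by Pearson correlation.

Neighbor search uses a wildcard-pattern hash join rather than all-pairs
comparison: two equal-length strings are at Hamming distance 1 iff they
share a single-position wildcard pattern, and a string is at distance 1
from one a single letter longer iff it equals one of the longer string's
single-character deletions.  Strings whose lengths differ by ≥ 2 can never
be at distance 1.  The strategy is required (and tested) to be
edge-identical to brute-force Levenshtein over all pairs.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Repertoire, RepertoireError
from .tracking import CloneKey, SharingRecord

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class Ld1Network:
    """Undirected LD-1 graph over a repertoire's top-N CDR3 strings."""

    sample_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())


def ld1_edges(strings: list[str]) -> set[tuple[str, str]]:
    """All unordered pairs of distinct strings at Levenshtein distance 1.

    Hash-join on single-position wildcard patterns (substitutions) and
    single-character deletions (indels); exact by construction for
    distance exactly 1 between distinct strings.
    """
    edges: set[tuple[str, str]] = set()
    sub_patterns: dict[tuple[int, str], list[str]] = defaultdict(list)
    by_deletion: dict[str, list[str]] = defaultdict(list)
    string_set = set(strings)
    for s in strings:
        for i in range(len(s)):
            sub_patterns[(i, s[:i] + "\x00" + s[i + 1 :])].append(s)
            by_deletion[s[:i] + s[i + 1 :]].append(s)
    for bucket in sub_patterns.values():
        if len(bucket) > 1:
            for i, a in enumerate(bucket):
                for b in bucket[i + 1 :]:
                    if a != b:
                        edges.add((min(a, b), max(a, b)))
    for deleted, longer_list in by_deletion.items():
        if deleted in string_set:
            for longer in longer_list:
                if longer != deleted:
                    edges.add((min(deleted, longer), max(deleted, longer)))
    return edges


def build_ld1_network(
    r: Repertoire,
    top_n: int = 10_000,
    publicity: dict[CloneKey, SharingRecord] | None = None,
) -> Ld1Network:
    """LD-1 network over the repertoire's top-N CDR3s by aggregated frequency.

    Multiple clones sharing a CDR3 (different V/J) collapse into one node
    whose frequency is their summed frequency.  Ties in the top-N ranking
    break by higher frequency, then lexicographic CDR3.  When a cohort
    publicity classification is supplied, a node is labeled public if any
    of its constituent clone keys is public in the cohort.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    agg = r.cdr3_frequencies()
    ranked = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    nodes = [cdr3 for cdr3, _ in ranked]

    node_publicity: dict[str, str] = {}
    if publicity is not None:
        keep = set(nodes)
        node_publicity = {cdr3: "private" for cdr3 in nodes}
        for c in r.clones:
            if c.cdr3_aa in keep and publicity[c.key].publicity == "public":
                node_publicity[c.cdr3_aa] = "public"

    g = nx.Graph()
    for cdr3, freq in ranked:
        attrs = {"frequency": freq, "log_frequency": float(np.log10(freq))}
        if node_publicity:
            attrs["publicity"] = node_publicity[cdr3]
        g.add_node(cdr3, **attrs)
    # sorted so graph exports are byte-stable across processes (set order
    # depends on string hashing)
    g.add_edges_from(sorted(ld1_edges(nodes)))
    for node, deg in g.degree():
        g.nodes[node]["degree"] = deg
    return Ld1Network(sample_id=r.sample_id, graph=g)


def degree_distribution(net: Ld1Network) -> pd.DataFrame:
    """Node counts (and fractions) per degree, degree ascending."""
    counts: dict[int, int] = defaultdict(int)
    for _, deg in net.graph.degree():
        counts[deg] += 1
    total = net.n_nodes
    rows = [
        {"degree": d, "n_nodes": c, "fraction": c / total}
        for d, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["degree", "n_nodes", "fraction"])


def connected_fraction(net: Ld1Network, clone_class: str = "all") -> float:
    """Percentage of nodes of a publicity class with at least one LD-1 neighbor.

    NaN (the undefined flag) when no node belongs to the class.
    clone_class != 'all' requires publicity labels on the nodes.
    """
    if clone_class not in ("private", "public", "all"):
        raise ValueError(f"unknown clone class: {clone_class!r}")
    nodes = []
    for n, data in net.graph.nodes(data=True):
        if clone_class == "all":
            nodes.append(n)
        else:
            if "publicity" not in data:
                raise RepertoireError(
                    "publicity labels missing; build the network with a "
                    "cohort publicity classification"
                )
            if data["publicity"] == clone_class:
                nodes.append(n)
    if not nodes:
        return float("nan")
    connected = sum(1 for n in nodes if net.graph.degree(n) >= 1)
    return 100.0 * connected / len(nodes)


@dataclass(slots=True)
class KmerProfile:
    """Normalized frequency mapping of overlapping k-mers of one repertoire."""

    sample_id: str
    k: int
    frequencies: dict[str, float]

    def __post_init__(self) -> None:
        if any(len(kmer) != self.k for kmer in self.frequencies):
            raise RepertoireError("all k-mer keys must have length k")
        total = sum(self.frequencies.values())
        if self.frequencies and abs(total - 1.0) > 1e-9:
            raise RepertoireError(f"k-mer frequencies must sum to 1, got {total}")


def kmer_profile(r: Repertoire, k: int = 3, weighting: str = "unique_cdr3") -> KmerProfile:
    """Overlapping k-mer frequency distribution of a repertoire's CDR3s.

    weighting='unique_cdr3' (default): every distinct CDR3 contributes each
    of its len−k+1 k-mers once.  weighting='clone_frequency': contributions
    are weighted by aggregated clone frequency.  CDR3s shorter than k are
    skipped with a logged count.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weighting not in ("unique_cdr3", "clone_frequency"):
        raise ValueError(f"unknown weighting: {weighting!r}")
    agg = r.cdr3_frequencies()
    counts: dict[str, float] = defaultdict(float)
    n_skipped = 0
    for cdr3, freq in agg.items():
        if len(cdr3) < k:
            n_skipped += 1
            continue
        w = freq if weighting == "clone_frequency" else 1.0
        for i in range(len(cdr3) - k + 1):
            counts[cdr3[i : i + k]] += w
    if n_skipped:
        logger.info("%s: %d CDR3s shorter than k=%d skipped",
                    r.sample_id, n_skipped, k)
    if not counts:
        raise RepertoireError(
            f"{r.sample_id}: no CDR3 of length >= {k}; empty k-mer profile"
        )
    total = sum(counts.values())
    return KmerProfile(
        sample_id=r.sample_id,
        k=k,
        frequencies={kmer: v / total for kmer, v in sorted(counts.items())},
    )


def kmer_correlation_matrix(profiles) -> pd.DataFrame:
    """Pearson r between k-mer profiles, aligned on the k-mer union (zero-fill).

    Zero-variance profiles give NaN against every other profile; the
    diagonal is 1 by convention.
    """
    from .diversity import _pearson_matrix

    profiles = list(profiles)
    if len(profiles) < 2:
        raise RepertoireError("need at least 2 k-mer profiles")
    ks = {p.k for p in profiles}
    if len(ks) != 1:
        raise RepertoireError(f"profiles mix k values: {sorted(ks)}")
    union = sorted(set().union(*(p.frequencies.keys() for p in profiles)))
    idx = {kmer: j for j, kmer in enumerate(union)}
    mat = np.zeros((len(profiles), len(union)))
    for i, p in enumerate(profiles):
        for kmer, v in p.frequencies.items():
            mat[i, idx[kmer]] = v
    return _pearson_matrix(mat, [p.sample_id for p in profiles])


def kmer_profiles_to_frame(profiles) -> pd.DataFrame:
    """Long-format table (sample_id, kmer, frequency) for TSV export."""
    rows = [
        {"sample_id": p.sample_id, "kmer": kmer, "frequency": v}
        for p in profiles
        for kmer, v in p.frequencies.items()
    ]
    return pd.DataFrame(rows, columns=["sample_id", "kmer", "frequency"])
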