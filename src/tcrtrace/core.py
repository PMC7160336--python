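"""Domain types for TCRβ clone repertoires and per-sample summary statistics.

A *clone* (clonotype) is a unique V gene / J gene / CDR3 amino-acid
combination with a read count; a *repertoire* is the clone set of one
sorted T-cell sample together with its study metadata (patient, treatment
arm, T-cell subpopulation, timepoint, HLA-DRB1*15:01 status).

Clone frequencies are always recomputed from counts at construction time
(`Repertoire.from_clones`), which is the single normalization authority in
the package: files are never trusted for frequencies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

TREATMENTS = ("AHSCT", "NTZ")
SUBPOPULATIONS = (
    "CD4_naive", "CD4_memory", "CD4_CM", "CD4_EM",
    "CD8_naive", "CD8_memory", "CD8_CM", "CD8_EM", "CD8_TEMRA",
)
TIMEPOINTS = ("t0", "t24")
HLA_STATUSES = ("pos", "neg", "unknown")


class RepertoireError(ValueError):
    """Base class for domain validation errors."""


class CloneTableFormatError(RepertoireError):
    """A clone table or metadata table does not have the expected layout."""


class EmptyRepertoireError(RepertoireError):
    """No valid clones remain after filtering."""


def strip_allele(gene: str) -> str:
    """Reduce a gene call to gene level by stripping the allele suffix.

    ``TRBV5-1*01`` -> ``TRBV5-1``.  Databases and pipelines mix allele-level
    and gene-level calls; the clone key is gene-level throughout.
    """
    return gene.split("*", 1)[0].strip()


def is_valid_cdr3(cdr3: str) -> bool:
    """True if *cdr3* is a non-empty uppercase string over the 20-letter alphabet."""
    return bool(cdr3) and all(ch in AA_ALPHABET for ch in cdr3)


@dataclass(frozen=True, slots=True)
class Clone:
    """One V-J-CDR3(a.a.) clonotype with its abundance.

    ``v_gene``/``j_gene`` are allele-stripped (the clone-key form);
    ``v_call``/``j_call`` retain the calls as read from the source.
    """

    v_gene: str
    j_gene: str
    cdr3_aa: str
    count: int
    frequency: float = 0.0
    v_call: str = ""
    j_call: str = ""

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.v_gene, self.j_gene, self.cdr3_aa)

    def validate(self) -> None:
        if not is_valid_cdr3(self.cdr3_aa):
            raise RepertoireError(f"invalid CDR3 sequence: {self.cdr3_aa!r}")
        if self.count < 1:
            raise RepertoireError(f"clone count must be >= 1, got {self.count}")
        if not self.frequency > 0:
            raise RepertoireError(f"clone frequency must be > 0, got {self.frequency}")


@dataclass(slots=True)
class Repertoire:
    """One sample: a normalized clone set plus study metadata."""

    sample_id: str
    patient_id: str
    treatment: str
    subpopulation: str
    timepoint: str
    hla_drb1_1501: str = "unknown"
    clones: list[Clone] = field(default_factory=list)
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise RepertoireError(
                f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
            )
        if self.subpopulation not in SUBPOPULATIONS:
            raise RepertoireError(
                f"subpopulation must be one of {SUBPOPULATIONS}, "
                f"got {self.subpopulation!r}"
            )
        if self.timepoint not in TIMEPOINTS:
            raise RepertoireError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if self.hla_drb1_1501 not in HLA_STATUSES:
            raise RepertoireError(
                f"hla_drb1_1501 must be one of {HLA_STATUSES}, "
                f"got {self.hla_drb1_1501!r}"
            )

    # -- construction -------------------------------------------------

    @classmethod
    def from_clones(cls, clones: Iterable[Clone], **metadata) -> "Repertoire":
        """Build a normalized repertoire: merge duplicate keys, recompute frequencies.

        Duplicate (V, J, CDR3) keys are merged by summing counts; frequencies
        are set to count / Σcount.  Clones are stored in a deterministic
        order (count descending, then key) so that downstream outputs are
        reproducible regardless of input order.
        """
        merged: dict[tuple[str, str, str], Clone] = {}
        for c in clones:
            prev = merged.get(c.key)
            if prev is None:
                merged[c.key] = c
            else:
                merged[c.key] = replace(prev, count=prev.count + c.count)
        if not merged:
            raise EmptyRepertoireError(
                f"no valid clones for sample {metadata.get('sample_id', '?')!r}"
            )
        total = sum(c.count for c in merged.values())
        normalized = [replace(c, frequency=c.count / total) for c in merged.values()]
        normalized.sort(key=lambda c: (-c.count, c.key))
        for c in normalized:
            c.validate()
        return cls(clones=normalized, **metadata)

    # -- views ---------------------------------------------------------

    @property
    def species_richness(self) -> int:
        """SR: number of unique clones."""
        return len(self.clones)

    @property
    def n_reads(self) -> int:
        return sum(c.count for c in self.clones)

    def frequencies(self) -> np.ndarray:
        return np.array([c.frequency for c in self.clones], dtype=float)

    def clone_keys(self) -> set[tuple[str, str, str]]:
        return {c.key for c in self.clones}

    def cdr3_frequencies(self) -> dict[str, float]:
        """Aggregate clone frequency per distinct CDR3 string (summing over V/J)."""
        agg: dict[str, float] = {}
        for c in self.clones:
            agg[c.cdr3_aa] = agg.get(c.cdr3_aa, 0.0) + c.frequency
        return agg


@dataclass(slots=True)
class RepertoireStats:
    """Per-sample summary: reads, species richness, Shannon evenness."""

    sample_id: str
    n_reads: int
    n_clones: int
    shannon_evenness: float
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.n_reads < self.n_clones:
            raise RepertoireError(
                f"n_reads ({self.n_reads}) < n_clones ({self.n_clones})"
            )
        if not (0.0 < self.shannon_evenness <= 1.0 + 1e-12):
            raise RepertoireError(
                f"shannon_evenness out of (0, 1]: {self.shannon_evenness}"
            )


def summarize_repertoire(r: Repertoire) -> RepertoireStats:
    """Reads, clone count (SR) and Shannon evenness of one repertoire."""
    from .diversity import shannon_evenness

    return RepertoireStats(
        sample_id=r.sample_id,
        n_reads=r.n_reads,
        n_clones=r.species_richness,
        shannon_evenness=shannon_evenness(r.frequencies()),
        n_cells=r.n_cells,
    )


def correlate_stats(
    stats: Sequence[RepertoireStats] | Sequence[Mapping[str, float]],
    x: str,
    y: str,
) -> float:
    """Pearson correlation of two summary fields across samples.

    Samples with a missing value (None/NaN) in either field are excluded.
    Returns NaN — the undefined-correlation signal — when fewer than 3
    complete pairs remain or when either field has zero variance.
    """
    def get(s, name):
        v = s.get(name) if isinstance(s, Mapping) else getattr(s, name)
        return float(v) if v is not None else math.nan

    xs = np.array([get(s, x) for s in stats], dtype=float)
    ys = np.array([get(s, y) for s in stats], dtype=float)
    ok = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[ok], ys[ok]
    if xs.size < 3:
        return math.nan
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return math.nan
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    return float(np.dot(xd, yd) / math.sqrt(np.dot(xd, xd) * np.dot(yd, yd)))


def gene_usage(r: Repertoire, segment: str = "V", weighted: bool = False) -> dict[str, float]:
    """Gene-usage frequencies over V or J segments.

    weighted=False counts each clone once; weighted=True uses clone
    frequency mass.  Frequencies sum to 1 either way.
    """
    if segment not in ("V", "J"):
        raise ValueError(f"segment must be 'V' or 'J', got {segment!r}")
    attr = "v_gene" if segment == "V" else "j_gene"
    usage: dict[str, float] = {}
    for c in r.clones:
        g = getattr(c, attr)
        usage[g] = usage.get(g, 0.0) + (c.frequency if weighted else 1.0)
    total = sum(usage.values())
    return {g: v / total for g, v in sorted(usage.items())}
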