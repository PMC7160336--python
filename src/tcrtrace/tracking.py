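"""Clonal persistence across timepoints and public/private clone structure.

Persistence between two repertoires A and B is the size of the clone-key
intersection relative to the mean repertoire size, as a percentage:

    persistence(A, B) = 100 · |A ∩ B| / mean(|A|, |B|)

where clones are compared by their (V gene, J gene, CDR3 a.a.) key.  A
clone is *private* when present in exactly one repertoire of the cohort
and *public* when shared by at least two; the sharing unit can be the
sample or the patient (all of a patient's samples pooled).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .core import Repertoire, RepertoireError

logger = logging.getLogger(__name__)

CloneKey = tuple[str, str, str]


@dataclass(slots=True)
class PersistenceResult:
    sample_a: str
    sample_b: str
    n_shared: int
    size_a: int
    size_b: int
    persistence_pct: float

    def __post_init__(self) -> None:
        if self.n_shared > min(self.size_a, self.size_b):
            raise RepertoireError("n_shared exceeds the smaller repertoire")


@dataclass(slots=True)
class SharingRecord:
    clone_key: CloneKey
    n_samples_sharing: int
    sample_ids: list[str]
    publicity: str  # 'private' | 'public'


def clonal_persistence(a: Repertoire, b: Repertoire) -> PersistenceResult:
    """Key-set overlap between two repertoires as a percentage of mean size."""
    keys_a, keys_b = a.clone_keys(), b.clone_keys()
    if not keys_a or not keys_b:
        raise RepertoireError("clonal persistence is undefined for empty repertoires")
    shared = len(keys_a & keys_b)
    pct = 100.0 * shared / ((len(keys_a) + len(keys_b)) / 2.0)
    return PersistenceResult(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        n_shared=shared,
        size_a=len(keys_a),
        size_b=len(keys_b),
        persistence_pct=pct,
    )


def persistence_table(cohort, pairing: str = "cross_subpopulation") -> pd.DataFrame:
    """t0 → t24 persistence for every patient, across subpopulation pairs.

    pairing='cross_subpopulation' compares t0 of each subpopulation with
    t24 of every subpopulation of the same patient (the per-patient table
    layout); pairing='matched' keeps only same-subpopulation pairs.
    Patients missing a timepoint are skipped with a log entry.
    """
    if pairing not in ("cross_subpopulation", "matched"):
        raise ValueError(f"unknown pairing rule: {pairing!r}")
    by_patient: dict[str, dict[str, list[Repertoire]]] = defaultdict(
        lambda: {"t0": [], "t24": []}
    )
    for r in sorted(cohort, key=lambda r: r.sample_id):
        by_patient[r.patient_id][r.timepoint].append(r)

    rows = []
    for patient in sorted(by_patient):
        t0s, t24s = by_patient[patient]["t0"], by_patient[patient]["t24"]
        if not t0s or not t24s:
            logger.info("patient %s: only one timepoint present, skipped", patient)
            continue
        for a in t0s:
            for b in t24s:
                if pairing == "matched" and a.subpopulation != b.subpopulation:
                    continue
                res = clonal_persistence(a, b)
                rows.append(
                    {
                        "patient_id": patient,
                        "sample_a": res.sample_a,
                        "sample_b": res.sample_b,
                        "subpop_a": a.subpopulation,
                        "subpop_b": b.subpopulation,
                        "n_shared": res.n_shared,
                        "size_a": res.size_a,
                        "size_b": res.size_b,
                        "persistence_pct": res.persistence_pct,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "sample_a", "sample_b", "subpop_a", "subpop_b",
            "n_shared", "size_a", "size_b", "persistence_pct",
        ],
    )


def classify_publicity(cohort, sharing_unit: str = "sample") -> dict[CloneKey, SharingRecord]:
    """Map every distinct clone key to its sharing record.

    A key is public when it occurs in ≥ 2 sharing units (samples, or
    patients when sharing_unit='patient'), private otherwise.
    """
    if sharing_unit not in ("sample", "patient"):
        raise ValueError(f"unknown sharing unit: {sharing_unit!r}")
    samples_of: dict[CloneKey, set[str]] = defaultdict(set)
    units_of: dict[CloneKey, set[str]] = defaultdict(set)
    for r in cohort:
        unit = r.sample_id if sharing_unit == "sample" else r.patient_id
        for key in r.clone_keys():
            samples_of[key].add(r.sample_id)
            units_of[key].add(unit)
    records = {}
    for key in samples_of:
        n_units = len(units_of[key])
        records[key] = SharingRecord(
            clone_key=key,
            n_samples_sharing=n_units,
            sample_ids=sorted(samples_of[key]),
            publicity="public" if n_units >= 2 else "private",
        )
    return records


def public_clone_stats(
    cohort, records: dict[CloneKey, SharingRecord] | None = None,
    sharing_unit: str = "sample",
) -> pd.DataFrame:
    """Per-sample count and percentage (of SR) of cohort-public clones."""
    cohort = list(cohort)
    if records is None:
        records = classify_publicity(cohort, sharing_unit=sharing_unit)
    rows = []
    for r in cohort:
        n_public = sum(1 for k in r.clone_keys() if records[k].publicity == "public")
        rows.append(
            {
                "sample_id": r.sample_id,
                "patient_id": r.patient_id,
                "treatment": r.treatment,
                "subpopulation": r.subpopulation,
                "timepoint": r.timepoint,
                "n_clones": r.species_richness,
                "n_public": n_public,
                "pct_public": 100.0 * n_public / r.species_richness,
            }
        )
    return pd.DataFrame(rows)


def highly_shared_clones(
    cohort, min_samples: int = 11,
    records: dict[CloneKey, SharingRecord] | None = None,
) -> tuple[list[SharingRecord], pd.DataFrame]:
    """Clones shared by at least *min_samples* samples, plus a presence matrix.

    The default of 11 encodes "shared among more than 10 samples".  The
    presence matrix is clones × samples with 0/1 entries, ready for
    heatmap export.
    """
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    cohort = list(cohort)
    if records is None:
        records = classify_publicity(cohort, sharing_unit="sample")
    # n_samples_sharing counts the chosen unit; the >min_samples filter is
    # sample-based, so recount samples directly.
    hits = sorted(
        (rec for rec in records.values() if len(rec.sample_ids) >= min_samples),
        key=lambda rec: (-len(rec.sample_ids), rec.clone_key),
    )
    sample_ids = sorted(r.sample_id for r in cohort)
    matrix = pd.DataFrame(
        0,
        index=["|".join(rec.clone_key) for rec in hits],
        columns=sample_ids,
        dtype=int,
    )
    for rec in hits:
        matrix.loc["|".join(rec.clone_key), rec.sample_ids] = 1
    return hits, matrix
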