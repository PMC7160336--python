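"""Seeded generator of longitudinal, multi-subpopulation TCRβ cohorts.

The generator emulates the statistical structure the analyses assume — it
is not a biological V(D)J recombination model:

* two treatment arms with the study's sorting design: 7 AHSCT patients
  with 4 subpopulations (naive/memory CD4 and CD8) and 8 NTZ patients
  with 7 subpopulations (naive/CM/EM CD4 and CD8 plus CD8 TEMRA), each
  sampled at t0 and t24 (168 repertoires at the defaults);
* heavy-tailed clone frequencies under a geometric rank law
  f_i ∝ exp(−polarization · i), giving closed-form control of evenness
  (polarization 0 is the uniform repertoire);
* an injected cross-timepoint persistence fraction ρ: the t24 repertoire
  of a patient/subpopulation carries exactly round(ρ·n_clones) clone keys
  of its t0 partner, with freshly drawn frequencies;
* an injected pool of public clones shared across samples.

Read counts are either deterministic ("depth 0": expected frequencies
quantized at 10^6 total reads, floor one read per clone — the
sampling-noise-free test surface) or multinomial at depth reads per clone.

All randomness flows from one seed through `numpy.random.SeedSequence`
children keyed by (arm, patient, subpopulation), so adding a sample never
perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Clone, Repertoire, SUBPOPULATIONS
from .io import write_clone_table
from .tracking import CloneKey

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.array(list(_AA))

V_GENES = tuple(
    f"TRBV{n}" for n in (
        "2", "3-1", "4-1", "5-1", "5-4", "6-1", "6-5", "7-2", "7-9", "9",
        "10-3", "11-2", "12-5", "13", "14", "15", "18", "19", "20-1",
        "24-1", "25-1", "27", "28", "29-1", "30",
    )
)
J_GENES = tuple(
    f"TRBJ{n}" for n in (
        "1-1", "1-2", "1-3", "1-4", "1-5", "1-6",
        "2-1", "2-2", "2-3", "2-4", "2-5", "2-6", "2-7",
    )
)

AHSCT_SUBPOPULATIONS = ("CD4_naive", "CD4_memory", "CD8_naive", "CD8_memory")
NTZ_SUBPOPULATIONS = (
    "CD4_naive", "CD4_CM", "CD4_EM", "CD8_naive", "CD8_CM", "CD8_EM", "CD8_TEMRA"
)

_DEPTH0_TOTAL_READS = 1_000_000  # quantization resolution of the no-noise mode

#: Relative clonal-expansion strength of the sorted compartments: naive
#: repertoires are more even than memory, and terminally differentiated
#: effectors are the most polarized.  Multiplies CohortSpec.polarization.
SUBPOP_POLARIZATION_FACTOR = {
    "CD4_naive": 0.6, "CD8_naive": 0.6,
    "CD4_memory": 1.4, "CD8_memory": 1.4,
    "CD4_CM": 1.2, "CD8_CM": 1.2,
    "CD4_EM": 1.5, "CD8_EM": 1.5,
    "CD8_TEMRA": 1.8,
}


class PublicPoolExhaustedError(RuntimeError):
    """More public-clone injections requested than the pool can supply."""


@dataclass(slots=True)
class CohortSpec:
    """Parameters of one synthetic cohort; all outputs are pure in (spec, seed)."""

    n_patients_ahsct: int = 7
    n_patients_ntz: int = 8
    subpopulations_ahsct: tuple[str, ...] = AHSCT_SUBPOPULATIONS
    subpopulations_ntz: tuple[str, ...] = NTZ_SUBPOPULATIONS
    n_clones: int = 1000
    polarization: float = 0.01
    persistence_fraction: float = 0.2
    public_pool_size: int = 200
    public_injection_rate: float = 0.05
    cdr3_length_range: tuple[int, int] = (8, 20)
    polarization_sigma: float = 0.3  # lognormal per-sample spread of polarization
    depth: int = 0  # reads per clone; 0 = deterministic expected counts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.polarization < 0 or self.polarization_sigma < 0:
            raise ValueError("polarization and polarization_sigma must be >= 0")
        for name in ("persistence_fraction", "public_injection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.cdr3_length_range
        if not (3 <= lo <= hi):
            raise ValueError(f"invalid cdr3_length_range: {self.cdr3_length_range}")
        for sp in self.subpopulations_ahsct + self.subpopulations_ntz:
            if sp not in SUBPOPULATIONS:
                raise ValueError(f"unknown subpopulation: {sp!r}")


def generate_frequencies(n_clones: int, polarization: float) -> np.ndarray:
    """Geometric-rank clone frequencies f_i ∝ exp(−polarization·i), summing to 1."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if polarization < 0:
        raise ValueError("polarization must be >= 0")
    w = np.exp(-polarization * np.arange(n_clones, dtype=float))
    return w / w.sum()


def generate_cdr3(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    """Random CDR3: uniform length in range, anchored C…F, uniform interior."""
    lo, hi = length_range
    length = int(rng.integers(lo, hi + 1))
    interior = _AA_ARR[rng.integers(0, len(_AA_ARR), size=length - 2)]
    return "C" + "".join(interior) + "F"


def _new_key(
    rng: np.random.Generator,
    spec: CohortSpec,
    taken: set[CloneKey],
) -> CloneKey:
    """Draw a fresh (V, J, CDR3) key not present in *taken* (rejection loop)."""
    while True:
        key = (
            V_GENES[int(rng.integers(0, len(V_GENES)))],
            J_GENES[int(rng.integers(0, len(J_GENES)))],
            generate_cdr3(rng, spec.cdr3_length_range),
        )
        if key not in taken:
            return key


def generate_public_pool(spec: CohortSpec) -> list[CloneKey]:
    """The cohort-wide pool of clones injected as public, derived from the seed."""
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0)))
    pool: list[CloneKey] = []
    taken: set[CloneKey] = set()
    while len(pool) < spec.public_pool_size:
        key = _new_key(rng, spec, taken)
        taken.add(key)
        pool.append(key)
    return pool


def _effective_polarization(
    spec: CohortSpec, rng: np.random.Generator, subpopulation: str | None
) -> float:
    """Sample-level polarization: spec value × compartment factor × lognormal.

    The jitter draw happens unconditionally so the random stream stays
    aligned across polarization settings (same-seed cohorts differing only
    in polarization share all other draws).
    """
    z = float(rng.standard_normal())
    factor = SUBPOP_POLARIZATION_FACTOR.get(subpopulation or "", 1.0)
    return spec.polarization * factor * math.exp(spec.polarization_sigma * z)


def _assemble(
    spec: CohortSpec,
    keys: list[CloneKey],
    rng: np.random.Generator,
    effective_polarization: float | None = None,
    **metadata,
) -> Repertoire:
    """Assign geometric frequencies to shuffled keys and draw counts."""
    n = len(keys)
    if effective_polarization is None:
        effective_polarization = spec.polarization
    f = generate_frequencies(n, effective_polarization)
    order = rng.permutation(n)
    if spec.depth == 0:
        counts = np.maximum(1, np.rint(f * _DEPTH0_TOTAL_READS)).astype(np.int64)
    else:
        counts = rng.multinomial(spec.depth * n, f)
    clones = []
    for rank, key_idx in enumerate(order):
        if counts[rank] == 0:
            continue  # clone not observed at this sequencing depth
        v, j, cdr3 = keys[int(key_idx)]
        clones.append(Clone(v_gene=v, j_gene=j, cdr3_aa=cdr3, count=int(counts[rank]),
                            frequency=1.0, v_call=v, j_call=j))
    metadata.setdefault("n_cells", int(rng.integers(20_000, 300_000)))
    return Repertoire.from_clones(clones, **metadata)


def _draw_keys(
    spec: CohortSpec,
    rng: np.random.Generator,
    public_pool: list[CloneKey] | None,
    n_keys: int,
    forced: list[CloneKey],
    excluded: set[CloneKey],
) -> list[CloneKey]:
    """*forced* keys + public injections + fresh private keys, n_keys total."""
    keys = list(forced)
    taken = set(forced) | excluded
    n_free = n_keys - len(forced)
    if public_pool is not None and spec.public_injection_rate > 0:
        n_pub = round(spec.public_injection_rate * n_free)
        candidates = [k for k in public_pool if k not in taken]
        if n_pub > len(candidates):
            raise PublicPoolExhaustedError(
                f"need {n_pub} public clones, pool offers {len(candidates)}"
            )
        picked = rng.choice(len(candidates), size=n_pub, replace=False)
        for i in sorted(int(i) for i in picked):
            keys.append(candidates[i])
            taken.add(candidates[i])
        n_free -= n_pub
        # keep fresh private clones out of the pool so publicity is injected,
        # never accidental
        taken |= set(public_pool)
    for _ in range(n_free):
        key = _new_key(rng, spec, taken)
        taken.add(key)
        keys.append(key)
    return keys


def generate_repertoire(
    spec: CohortSpec,
    rng: np.random.Generator,
    public_pool: list[CloneKey] | None = None,
    **metadata,
) -> Repertoire:
    """One synthetic repertoire (n_clones unique keys, geometric frequencies)."""
    pol = _effective_polarization(spec, rng, metadata.get("subpopulation"))
    keys = _draw_keys(spec, rng, public_pool, spec.n_clones, [], set())
    return _assemble(spec, keys, rng, effective_polarization=pol, **metadata)


def generate_patient_pair(
    spec: CohortSpec,
    rng: np.random.Generator,
    public_pool: list[CloneKey] | None = None,
    **metadata,
) -> tuple[Repertoire, Repertoire]:
    """(t0, t24) pair with exactly round(ρ·n_clones) clone keys in common.

    The t24 repertoire re-draws frequencies for the persisting keys; its
    fresh keys (public injections included) are kept disjoint from the t0
    key set so the injected overlap is exact.
    """
    sample_stem = metadata.pop("sample_stem", metadata.get("patient_id", "S"))
    subpop = metadata.get("subpopulation")
    pol_t0 = _effective_polarization(spec, rng, subpop)
    keys_t0 = _draw_keys(spec, rng, public_pool, spec.n_clones, [], set())
    t0 = _assemble(spec, keys_t0, rng, effective_polarization=pol_t0,
                   timepoint="t0", sample_id=f"{sample_stem}_t0", **metadata)

    n_persist = round(spec.persistence_fraction * spec.n_clones)
    picked = rng.choice(spec.n_clones, size=n_persist, replace=False)
    persistent = [keys_t0[int(i)] for i in sorted(int(i) for i in picked)]
    pol_t24 = _effective_polarization(spec, rng, subpop)
    keys_t24 = _draw_keys(
        spec, rng, public_pool, spec.n_clones, persistent, set(keys_t0)
    )
    t24 = _assemble(spec, keys_t24, rng, effective_polarization=pol_t24,
                    timepoint="t24", sample_id=f"{sample_stem}_t24", **metadata)
    return t0, t24


#: Disease/antigen labels used by the synthetic annotation database, echoing
#: the category structure of curated TCR databases (mostly viral).
DB_CATEGORIES = ("EBV", "CMV", "Influenza", "HIV-1", "Multiple sclerosis")


def generate_annotation_db(
    spec: CohortSpec,
    n_decoys: int = 500,
    categories: tuple[str, ...] = DB_CATEGORIES,
):
    """Synthetic CDR3 annotation database for exercising the overlap stage.

    Contains every public-pool CDR3 (guaranteed hits in the generated
    cohort) plus *n_decoys* fresh CDR3s absent from it, each labeled with
    a category assigned round-robin.  Purely seed-derived.
    """
    from .annotate import DbRecord

    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 7)))
    pool = generate_public_pool(spec) if spec.public_pool_size > 0 else []
    cdr3s = [key[2] for key in pool]
    taken = {k[2] for k in pool}
    while len(cdr3s) < len(pool) + n_decoys:
        c = generate_cdr3(rng, spec.cdr3_length_range)
        if c not in taken:
            taken.add(c)
            cdr3s.append(c)
    return [
        DbRecord(
            cdr3_aa=cdr3,
            categories=(categories[i % len(categories)],),
            source="synthetic_db",
        )
        for i, cdr3 in enumerate(cdr3s)
    ]


@dataclass(slots=True)
class SyntheticCohort:
    """A generated cohort plus its ground truth (public pool) and metadata."""

    spec: CohortSpec
    repertoires: list[Repertoire]
    metadata: pd.DataFrame
    public_pool: list[CloneKey] = field(default_factory=list)


def generate_cohort(spec: CohortSpec, outdir: str | Path | None = None) -> SyntheticCohort:
    """The full two-arm, two-timepoint cohort; optionally written to disk.

    On disk: one AIRR TSV per sample, ``metadata.tsv``, the injected
    ``public_pool.tsv`` and a ``manifest.yaml`` recording every spec
    parameter including the seed.  Byte-reproducible given the spec.
    """
    pool = generate_public_pool(spec) if spec.public_pool_size > 0 else None
    arms = (
        ("AHSCT", "MS", spec.n_patients_ahsct, spec.subpopulations_ahsct),
        ("NTZ", "Ty", spec.n_patients_ntz, spec.subpopulations_ntz),
    )
    repertoires: list[Repertoire] = []
    meta_rows = []
    for arm_idx, (treatment, prefix, n_patients, subpops) in enumerate(arms):
        for p_idx in range(n_patients):
            patient_id = f"{prefix}{p_idx + 1:02d}"
            hla = "pos" if p_idx % 2 == 0 else "neg"
            for s_idx, subpop in enumerate(subpops):
                rng = np.random.default_rng(
                    np.random.SeedSequence((spec.seed, arm_idx + 1, p_idx, s_idx))
                )
                pair = generate_patient_pair(
                    spec, rng, public_pool=pool,
                    sample_stem=f"{patient_id}_{subpop}",
                    patient_id=patient_id, treatment=treatment,
                    subpopulation=subpop, hla_drb1_1501=hla,
                )
                for r in pair:
                    repertoires.append(r)
                    meta_rows.append(
                        {
                            "sample_id": r.sample_id,
                            "patient_id": r.patient_id,
                            "treatment": r.treatment,
                            "subpopulation": r.subpopulation,
                            "timepoint": r.timepoint,
                            "hla_drb1_1501": r.hla_drb1_1501,
                            "filename": f"{r.sample_id}.tsv",
                            "n_cells": r.n_cells,
                        }
                    )
    metadata = pd.DataFrame(meta_rows)
    cohort = SyntheticCohort(
        spec=spec, repertoires=repertoires, metadata=metadata,
        public_pool=pool or [],
    )
    if outdir is not None:
        write_cohort(cohort, outdir)
    return cohort


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in cohort.repertoires:
        write_clone_table(r.clones, outdir / f"{r.sample_id}.tsv")
    cohort.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(cohort.public_pool, columns=["v_gene", "j_gene", "cdr3_aa"]).to_csv(
        outdir / "public_pool.tsv", sep="\t", index=False
    )
    manifest = dataclasses.asdict(cohort.spec)
    manifest["cdr3_length_range"] = list(manifest["cdr3_length_range"])
    manifest["subpopulations_ahsct"] = list(manifest["subpopulations_ahsct"])
    manifest["subpopulations_ntz"] = list(manifest["subpopulations_ntz"])
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"cohort_spec": manifest}, fh, sort_keys=True)
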