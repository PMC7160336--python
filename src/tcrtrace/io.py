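"""Clone-table and cohort I/O.

The canonical clone-table dialect is the AIRR Rearrangement TSV restricted
to the four columns this pipeline needs: ``v_call``, ``j_call``,
``junction_aa``, ``duplicate_count``.  A permissive fallback dialect
(``irepertoire_like``) accepts any TSV through a configurable column map.

Filtering on load is conservative and logged: rows with an empty or
non-standard CDR3, or a non-positive count, are dropped and the number of
dropped rows reported to the module logger (stderr by default).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core import (
    Clone,
    CloneTableFormatError,
    EmptyRepertoireError,
    Repertoire,
    RepertoireError,
    is_valid_cdr3,
    strip_allele,
)

logger = logging.getLogger(__name__)

AIRR_COLUMNS: Mapping[str, str] = {
    "v_call": "v_call",
    "j_call": "j_call",
    "cdr3_aa": "junction_aa",
    "count": "duplicate_count",
}

#: Column layout of iRepertoire-style exports (fallback dialect); override
#: any entry through the ``column_map`` argument of :func:`read_clone_table`.
IREPERTOIRE_COLUMNS: Mapping[str, str] = {
    "v_call": "V",
    "j_call": "J",
    "cdr3_aa": "CDR3_aa",
    "count": "copy",
}

METADATA_COLUMNS = (
    "sample_id", "patient_id", "treatment", "subpopulation",
    "timepoint", "hla_drb1_1501", "filename",
)


def read_clone_table(
    path: str | Path,
    dialect: str = "airr",
    column_map: Mapping[str, str] | None = None,
) -> list[Clone]:
    """Parse one clone table into a list of validated clones.

    Rows failing the CDR3/count filters are dropped (and counted in the
    log); duplicate (V, J, CDR3) keys are merged by summing counts and
    frequencies recomputed as count/Σcount.
    """
    path = Path(path)
    if dialect == "airr":
        cols = dict(AIRR_COLUMNS)
    elif dialect == "irepertoire_like":
        cols = dict(IREPERTOIRE_COLUMNS)
    else:
        raise ValueError(f"unknown clone-table dialect: {dialect!r}")
    if column_map:
        cols.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    for role, name in cols.items():
        if name not in df.columns:
            raise CloneTableFormatError(
                f"{path.name}: missing required column {name!r} (for {role})"
            )

    n_raw = len(df)
    clones: list[Clone] = []
    for v_call, j_call, cdr3, count in zip(
        df[cols["v_call"]], df[cols["j_call"]], df[cols["cdr3_aa"]], df[cols["count"]]
    ):
        if pd.isna(cdr3) or pd.isna(count) or pd.isna(v_call) or pd.isna(j_call):
            continue
        cdr3 = str(cdr3).strip()
        if not is_valid_cdr3(cdr3):
            continue
        try:
            n = int(float(count))
        except ValueError:
            continue
        if n < 1:
            continue
        clones.append(
            Clone(
                v_gene=strip_allele(str(v_call)),
                j_gene=strip_allele(str(j_call)),
                cdr3_aa=cdr3,
                count=n,
                frequency=1.0,  # placeholder; normalized below
                v_call=str(v_call).strip(),
                j_call=str(j_call).strip(),
            )
        )
    n_dropped = n_raw - len(clones)
    if n_dropped:
        logger.info("%s: dropped %d of %d rows failing CDR3/count filters",
                    path.name, n_dropped, n_raw)
    if not clones:
        raise EmptyRepertoireError(f"{path.name}: no valid clones after filtering")
    # Normalize through a throwaway repertoire so there is one authority.
    tmp = Repertoire.from_clones(
        clones, sample_id="_", patient_id="_", treatment="AHSCT",
        subpopulation="CD4_naive", timepoint="t0",
    )
    return list(tmp.clones)


def write_clone_table(clones: Iterable[Clone], path: str | Path) -> None:
    """Write clones as an AIRR rearrangement TSV (the dialect we read back)."""
    rows = [
        {
            "v_call": c.v_call or c.v_gene,
            "j_call": c.j_call or c.j_gene,
            "junction_aa": c.cdr3_aa,
            "duplicate_count": c.count,
        }
        for c in clones
    ]
    pd.DataFrame(rows, columns=list(AIRR_COLUMNS.values())).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate the sample-metadata TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            raise CloneTableFormatError(
                f"{path.name}: missing required metadata column {col!r}"
            )
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise RepertoireError(f"duplicate sample_id in metadata: {sorted(set(dup))}")
    return df


def load_cohort(
    metadata_path: str | Path,
    clone_dir: str | Path,
    dialect: str = "airr",
    column_map: Mapping[str, str] | None = None,
) -> list[Repertoire]:
    """Load every sample listed in the metadata table.

    Each metadata row must resolve to a readable clone table in
    *clone_dir*; an unresolvable file raises an error naming the sample.
    """
    clone_dir = Path(clone_dir)
    meta = read_metadata(metadata_path)
    cohort: list[Repertoire] = []
    for row in meta.itertuples(index=False):
        fp = clone_dir / row.filename
        if not fp.exists():
            raise RepertoireError(
                f"sample {row.sample_id!r}: clone table not found: {fp}"
            )
        clones = read_clone_table(fp, dialect=dialect, column_map=column_map)
        n_cells = None
        if hasattr(row, "n_cells") and not pd.isna(row.n_cells):
            n_cells = int(float(row.n_cells))
        cohort.append(
            Repertoire.from_clones(
                clones,
                sample_id=row.sample_id,
                patient_id=row.patient_id,
                treatment=row.treatment,
                subpopulation=row.subpopulation,
                timepoint=row.timepoint,
                hla_drb1_1501=row.hla_drb1_1501,
                n_cells=n_cells,
            )
        )
    logger.info("loaded %d repertoires from %s", len(cohort), clone_dir)
    return cohort
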