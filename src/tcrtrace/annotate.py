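"""Annotation of repertoires against curated CDR3 databases.

Supports the export layouts of two public TCR databases — McPAS-TCR
(CSV; CDR3 beta column plus a pathology label) and VDJdb (TSV; cdr3 /
antigen.species / gene columns, TRB rows) — and bare one-CDR3-per-line
lists for literature datasets.  Matching is exact string comparison of
case-normalized CDR3 amino-acid sequences (optionally the full V-CDR3-J
key); no fuzzy matching and no editing of the C…F boundary residues, so
results are a documented function of the supplied database snapshot.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import Repertoire, RepertoireError, is_valid_cdr3, strip_allele

logger = logging.getLogger(__name__)

MCPAS_COLUMNS: Mapping[str, str] = {
    "cdr3_aa": "CDR3.beta.aa",
    "category": "Pathology",
    "v_gene": "TRBV",
    "j_gene": "TRBJ",
}
VDJDB_COLUMNS: Mapping[str, str] = {
    "cdr3_aa": "cdr3",
    "category": "antigen.species",
    "v_gene": "v.segm",
    "j_gene": "j.segm",
    "chain": "gene",
}


@dataclass(frozen=True, slots=True)
class DbRecord:
    """One database CDR3 with the categories (pathologies/antigens) it carries."""

    cdr3_aa: str
    categories: tuple[str, ...]
    source: str
    v_gene: str = ""
    j_gene: str = ""


@dataclass(slots=True)
class OverlapSummary:
    sample_id: str
    source: str
    n_overlap: int
    pct_overlap: float  # 100 · n_overlap / SR
    per_category: dict[str, int]


def load_db(
    path: str | Path,
    source_dialect: str,
    column_map: Mapping[str, str] | None = None,
    default_category: str | None = None,
) -> list[DbRecord]:
    """Parse a database export into normalized, de-duplicated records.

    CDR3s are uppercased and whitespace-stripped; rows with non-standard
    letters are dropped with a logged count.  Duplicate CDR3s collapse
    into one record carrying the union of their categories.
    """
    path = Path(path)
    if source_dialect == "mcpas":
        cols = dict(MCPAS_COLUMNS)
        df = pd.read_csv(path, dtype=str)
    elif source_dialect == "vdjdb":
        cols = dict(VDJDB_COLUMNS)
        df = pd.read_csv(path, sep="\t", dtype=str)
    elif source_dialect == "cdr3_list":
        cols = {}
        df = pd.DataFrame(
            {"cdr3_aa": [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]}
        )
        cols["cdr3_aa"] = "cdr3_aa"
    else:
        raise ValueError(f"unknown database dialect: {source_dialect!r}")
    if column_map:
        cols.update(column_map)
    if cols["cdr3_aa"] not in df.columns:
        raise RepertoireError(
            f"{path.name}: missing CDR3 column {cols['cdr3_aa']!r}"
        )
    if "chain" in cols and cols["chain"] in df.columns:
        df = df[df[cols["chain"]].fillna("TRB") == "TRB"]

    cat_col = cols.get("category")
    v_col, j_col = cols.get("v_gene"), cols.get("j_gene")
    merged: dict[str, dict] = {}
    n_dropped = 0
    for _, row in df.iterrows():
        raw = row[cols["cdr3_aa"]]
        if pd.isna(raw):
            n_dropped += 1
            continue
        cdr3 = str(raw).strip().upper()
        if not is_valid_cdr3(cdr3):
            n_dropped += 1
            continue
        cat = None
        if cat_col and cat_col in row.index and not pd.isna(row[cat_col]):
            cat = str(row[cat_col]).strip()
        if cat is None:
            cat = default_category or source_dialect
        entry = merged.setdefault(
            cdr3, {"categories": set(), "v_gene": "", "j_gene": ""}
        )
        entry["categories"].add(cat)
        for gene_key, col in (("v_gene", v_col), ("j_gene", j_col)):
            if col and col in row.index and not pd.isna(row[col]) and not entry[gene_key]:
                entry[gene_key] = strip_allele(str(row[col]))
    if n_dropped:
        logger.info("%s: dropped %d rows with missing/invalid CDR3",
                    path.name, n_dropped)
    if not merged:
        raise RepertoireError(f"{path.name}: no valid database records")
    return [
        DbRecord(
            cdr3_aa=cdr3,
            categories=tuple(sorted(entry["categories"])),
            source=source_dialect,
            v_gene=entry["v_gene"],
            j_gene=entry["j_gene"],
        )
        for cdr3, entry in sorted(merged.items())
    ]


def match_repertoire(
    r: Repertoire,
    db: list[DbRecord],
    match_on: str = "cdr3",
) -> OverlapSummary:
    """Overlap of one repertoire with a database, by exact CDR3 (or V-CDR3-J).

    n_overlap counts distinct repertoire clones whose CDR3 (or full key)
    occurs in the database; per-category tallies count matched clones per
    category, so a multi-category CDR3 contributes to several categories.
    """
    if match_on not in ("cdr3", "v_cdr3_j"):
        raise ValueError(f"unknown match mode: {match_on!r}")
    if not r.clones:
        raise RepertoireError("cannot match an empty repertoire")
    source = db[0].source if db else "db"
    by_cdr3: dict[str, DbRecord] = {rec.cdr3_aa: rec for rec in db}
    n_overlap = 0
    per_category: dict[str, int] = defaultdict(int)
    for clone in r.clones:
        rec = by_cdr3.get(clone.cdr3_aa)
        if rec is None:
            continue
        if match_on == "v_cdr3_j" and (
            rec.v_gene != clone.v_gene or rec.j_gene != clone.j_gene
        ):
            continue
        n_overlap += 1
        for cat in rec.categories:
            per_category[cat] += 1
    return OverlapSummary(
        sample_id=r.sample_id,
        source=source,
        n_overlap=n_overlap,
        pct_overlap=100.0 * n_overlap / r.species_richness,
        per_category=dict(sorted(per_category.items())),
    )


def overlap_by_category(
    cohort,
    db: list[DbRecord],
    match_on: str = "cdr3",
) -> pd.DataFrame:
    """Long table of per-sample, per-category overlap counts for group tests."""
    rows = []
    for r in cohort:
        summary = match_repertoire(r, db, match_on=match_on)
        base = {
            "sample_id": r.sample_id,
            "patient_id": r.patient_id,
            "treatment": r.treatment,
            "subpopulation": r.subpopulation,
            "timepoint": r.timepoint,
            "source": summary.source,
            "n_overlap": summary.n_overlap,
            "pct_overlap": summary.pct_overlap,
        }
        if summary.per_category:
            for cat, n in summary.per_category.items():
                rows.append({**base, "category": cat, "n_category": n})
        else:
            rows.append({**base, "category": "", "n_category": 0})
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "patient_id", "treatment", "subpopulation",
            "timepoint", "source", "n_overlap", "pct_overlap",
            "category", "n_category",
        ],
    )
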