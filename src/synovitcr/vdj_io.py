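"""Reading/writing VDJ contig tables and per-cell chain partitioning.

Supports two dialects:

* ``tenx`` — CellRanger ``filtered_contig_annotations.csv`` column convention
  (``barcode, chain, v_gene, d_gene, j_gene, cdr3, cdr3_nt, productive, umis``),
  extra columns ignored; optional ``patient_id``/``sample_id`` columns are
  honoured when present.
* ``airr`` — AIRR Rearrangement TSV with the minimal fields
  (``cell_id, locus, v_call, j_call, junction, junction_aa, productive``) plus
  the extras this package writes so that a write/read round trip is lossless.

Only productive TRA/TRB chains become :class:`ContigRecord` objects; everything
else is dropped with a counter.  Cells are classified as multiplets when a
barcode carries more than one beta chain or more than two alpha chains.
"""
from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping  # noqa: F401 (Mapping in signatures)

import pandas as pd

from .errors import FormatError

log = logging.getLogger(__name__)

LOCI: tuple[str, str] = ("TRA", "TRB")

TENX_REQUIRED = (
    "barcode", "chain", "v_gene", "d_gene", "j_gene",
    "cdr3", "cdr3_nt", "productive", "umis",
)
AIRR_REQUIRED = (
    "cell_id", "locus", "v_call", "j_call", "junction", "junction_aa", "productive",
)

_GENE_PREFIX = {"TRA": ("TRAV", "TRAJ"), "TRB": ("TRBV", "TRBJ")}

_TRUE_STRINGS = {"true", "t", "1", "yes"}
_FALSE_STRINGS = {"false", "f", "0", "no", "none", "nan", ""}


@dataclass(frozen=True, order=True)
class ContigRecord:
    """One assembled, productive TCR chain for one cell barcode."""

    barcode: str
    sample_id: str
    patient_id: str
    locus: str
    v_gene: str
    d_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    productive: bool
    umis: int


class PartitionStatus(str, Enum):
    OK = "OK"
    MULTIPLET = "MULTIPLET"
    ALPHA_ONLY = "ALPHA_ONLY"
    EMPTY = "EMPTY"


@dataclass(frozen=True)
class CellPartition:
    """Per-barcode grouping of productive chains with a multiplet classification."""

    barcode: str
    patient_id: str
    sample_id: str
    alpha_chains: tuple[ContigRecord, ...]
    beta_chains: tuple[ContigRecord, ...]
    status: PartitionStatus

    @property
    def chains(self) -> tuple[ContigRecord, ...]:
        return self.alpha_chains + self.beta_chains

    @property
    def cell_key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.sample_id, self.barcode)


def classify_chain_counts(n_alpha: int, n_beta: int) -> PartitionStatus:
    """Multiplet classification as a pure function of chain counts.

    A barcode with >1 beta chain or >2 alpha chains is a multiplet; with no
    beta but at least one alpha it is alpha-only; with no chains it is empty.
    """
    if n_beta > 1 or n_alpha > 2:
        return PartitionStatus.MULTIPLET
    if n_beta == 0 and n_alpha >= 1:
        return PartitionStatus.ALPHA_ONLY
    if n_beta == 0 and n_alpha == 0:
        return PartitionStatus.EMPTY
    return PartitionStatus.OK


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    raise FormatError(f"cannot interpret productive flag {value!r}")


def _check_columns(df: pd.DataFrame, required: Iterable[str], dialect: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{dialect} contig table is missing required column {col!r}")


def records_from_frame(
    df: pd.DataFrame,
    dialect: str = "tenx",
    *,
    patient_id: str = "",
    sample_id: str = "",
    report: dict | None = None,
) -> list[ContigRecord]:
    """Parse an in-memory contig table into :class:`ContigRecord` objects.

    Row-level filters: non-productive chains and loci other than TRA/TRB are
    dropped (counted in ``report``).  Gene names that do not match the locus
    prefix are retained verbatim but counted under ``gene_name_mismatch``.
    """
    counters = {"rows": 0, "non_productive": 0, "unrecognized_locus": 0,
                "gene_name_mismatch": 0}
    if dialect == "tenx":
        _check_columns(df, TENX_REQUIRED, dialect)
        cols = dict(barcode="barcode", locus="chain", v="v_gene", d="d_gene",
                    j="j_gene", nt="cdr3_nt", aa="cdr3", productive="productive",
                    umis="umis")
    elif dialect == "airr":
        _check_columns(df, AIRR_REQUIRED, dialect)
        cols = dict(barcode="cell_id", locus="locus", v="v_call", d="d_call",
                    j="j_call", nt="junction", aa="junction_aa",
                    productive="productive", umis="duplicate_count")
    else:
        raise FormatError(f"unknown contig table dialect {dialect!r}")

    def _str(row, col, default=""):
        if col not in row or pd.isna(row[col]):
            return default
        return str(row[col])

    records: list[ContigRecord] = []
    for row in df.to_dict("records"):
        counters["rows"] += 1
        if not _parse_bool(row.get(cols["productive"])):
            counters["non_productive"] += 1
            continue
        locus = _str(row, cols["locus"]).upper()
        if locus not in LOCI:
            counters["unrecognized_locus"] += 1
            continue
        v_gene, j_gene = _str(row, cols["v"]), _str(row, cols["j"])
        v_pref, j_pref = _GENE_PREFIX[locus]
        if (v_gene and not v_gene.startswith(v_pref)) or (
            j_gene and not j_gene.startswith(j_pref)
        ):
            counters["gene_name_mismatch"] += 1
        umis_raw = row.get(cols["umis"])
        umis = 0 if umis_raw is None or pd.isna(umis_raw) else int(umis_raw)
        records.append(
            ContigRecord(
                barcode=_str(row, "barcode" if dialect == "tenx" else "cell_id"),
                sample_id=_str(row, "sample_id", sample_id),
                patient_id=_str(row, "patient_id", patient_id),
                locus=locus,
                v_gene=v_gene,
                d_gene=_str(row, cols["d"]),
                j_gene=j_gene,
                cdr3_nt=_str(row, cols["nt"]),
                cdr3_aa=_str(row, cols["aa"]),
                productive=True,
                umis=umis,
            )
        )
    if counters["non_productive"] or counters["unrecognized_locus"]:
        log.info(
            "contig parsing dropped %d non-productive and %d off-locus rows "
            "(of %d)", counters["non_productive"], counters["unrecognized_locus"],
            counters["rows"],
        )
    if counters["gene_name_mismatch"]:
        log.warning("%d contigs carry gene names inconsistent with their locus",
                    counters["gene_name_mismatch"])
    if report is not None:
        report.update(counters)
    return records


def read_contig_table(
    path: str | Path,
    dialect: str = "tenx",
    *,
    patient_id: str = "",
    sample_id: str = "",
    report: dict | None = None,
) -> list[ContigRecord]:
    """Read a contig annotation table from disk (see module docstring for dialects)."""
    sep = "," if dialect == "tenx" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("contig table %s is empty", path)
        if report is not None:
            report.update({"rows": 0, "non_productive": 0,
                           "unrecognized_locus": 0, "gene_name_mismatch": 0})
        return []
    return records_from_frame(df, dialect, patient_id=patient_id,
                              sample_id=sample_id, report=report)


def build_cell_partitions(contigs: Iterable[ContigRecord]) -> list[CellPartition]:
    """Group contigs by (patient, sample, barcode) and classify each cell.

    Within-barcode duplicate chains (same locus, CDR3 nucleotide sequence, V
    and J call) are collapsed to the single record with the highest UMI count,
    so CellRanger duplicate consensus rows never trigger spurious multiplet
    calls.  Every distinct barcode in the input yields exactly one partition.
    """
    by_cell: "OrderedDict[tuple[str, str, str], dict]" = OrderedDict()
    for rec in contigs:
        key = (rec.patient_id, rec.sample_id, rec.barcode)
        chains = by_cell.setdefault(key, {})
        dup_key = (rec.locus, rec.cdr3_nt, rec.v_gene, rec.j_gene)
        prev = chains.get(dup_key)
        if prev is None or rec.umis > prev.umis:
            chains[dup_key] = rec

    partitions: list[CellPartition] = []
    for (patient, sample, barcode), chains in by_cell.items():
        alphas = tuple(sorted((r for r in chains.values() if r.locus == "TRA")))
        betas = tuple(sorted((r for r in chains.values() if r.locus == "TRB")))
        partitions.append(
            CellPartition(
                barcode=barcode,
                patient_id=patient,
                sample_id=sample,
                alpha_chains=alphas,
                beta_chains=betas,
                status=classify_chain_counts(len(alphas), len(betas)),
            )
        )
    return partitions


AIRR_COLUMNS = (
    "cell_id", "patient_id", "sample_id", "locus", "v_call", "d_call", "j_call",
    "junction", "junction_aa", "productive", "duplicate_count",
)


def write_airr(partitions: Iterable[CellPartition], path: str | Path) -> None:
    """Write one AIRR Rearrangement row per chain (all chains, even multiplets)."""
    rows = []
    for part in partitions:
        for rec in part.chains:
            rows.append((rec.barcode, rec.patient_id, rec.sample_id, rec.locus,
                         rec.v_gene, rec.d_gene, rec.j_gene, rec.cdr3_nt,
                         rec.cdr3_aa, "T" if rec.productive else "F", rec.umis))
    df = pd.DataFrame(rows, columns=AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cell metadata CSV (barcode, patient_id, sample_id, sample_type, cluster_label)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("barcode", "patient_id", "sample_id", "sample_type", "cluster_label"):
        if col not in df.columns:
            raise FormatError(f"cell metadata is missing required column {col!r}")
    return df


def partitions_by_patient(
    partitions: Iterable[CellPartition],
) -> Mapping[str, list[CellPartition]]:
    """Split a partition list per patient, preserving order."""
    out: "OrderedDict[str, list[CellPartition]]" = OrderedDict()
    for part in partitions:
        out.setdefault(part.patient_id, []).append(part)
    return out
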