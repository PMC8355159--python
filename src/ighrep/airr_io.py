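"""Reading and writing annotated IgH rearrangements.

The native on-disk dialect is the AIRR Rearrangement TSV (v1.x column
names).  Sample metadata that the community schema does not standardise
(``mouse_id``, ``strain``, ``subset``, ``replicate``) travel as extension
columns, which the AIRR standard explicitly allows.  The internal
canonical junctional region is the CDR3 (the junction minus the two
conserved anchor codons, Cys104 and Trp/Phe118); conversion happens once
at ingest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SUBSETS",
    "SequenceRecord",
    "GermlineSet",
    "gene_label",
    "translate_cdr3",
    "is_functional",
    "filter_functional",
    "read_airr_tsv",
    "write_airr_tsv",
    "read_germline_fasta",
    "write_germline_fasta",
]

logger = logging.getLogger(__name__)

#: Sorted B-cell subsets of the study design, in fixed display order.
SUBSETS = (
    "FoB",
    "ABC",
    "GCB_CD11cpos",
    "GCB_CD11cneg",
    "PB_CD11cpos",
    "PB_CD11cneg",
)

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


@dataclass(slots=True)
class SequenceRecord:
    """One annotated IgH rearrangement.

    ``v_call``/``j_call`` are gene-level labels (allele suffixes and
    secondary comma-separated calls are stripped at ingest, since clone
    grouping operates on the gene).  Exactly one of ``v_observed_nt``
    (the germline-aligned V segment, same coordinates as the germline
    reference slice) or ``v_mutation_count`` must be resolvable before
    somatic-hypermutation statistics can be computed.
    """

    record_id: str
    mouse_id: str
    strain: str
    subset: str
    replicate: int
    v_call: str
    j_call: str
    cdr3_nt: str
    cdr3_aa: str | None = None
    copies: int = 1
    v_observed_nt: str | None = None
    v_mutation_count: int | None = None
    functional: bool | None = None

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"record {self.record_id}: copies must be >= 1")
        if self.replicate < 1:
            raise ValueError(f"record {self.record_id}: replicate must be >= 1")
        if self.cdr3_aa is not None and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            raise ValueError(
                f"record {self.record_id}: cdr3_nt length {len(self.cdr3_nt)} "
                f"is not 3x cdr3_aa length {len(self.cdr3_aa)}"
            )


@dataclass(slots=True)
class GermlineSet:
    """Germline V/J reference segments keyed by gene label."""

    v_segments: dict[str, str] = field(default_factory=dict)
    j_segments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in {**self.v_segments, **self.j_segments}.items():
            if not seq:
                raise ValueError(f"germline segment {name} is empty")
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"germline segment {name}: bad alphabet {bad}")


def gene_label(call: str) -> str:
    """Collapse a (possibly ambiguous, allele-level) gene call to gene level.

    ``"IGHV1-72*01,IGHV1-72*02"`` becomes ``"IGHV1-72"``: the first
    comma-separated call is kept and the allele suffix after ``*`` dropped.
    """
    return call.split(",")[0].split("*")[0].strip()


def translate_cdr3(cdr3_nt: str) -> str:
    """Translate a CDR3 nucleotide string with the standard genetic code.

    Any codon containing ``N`` yields ``'X'``; stop codons yield ``'*'``.
    The length must be divisible by 3.
    """
    seq = cdr3_nt.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"CDR3 length {len(seq)} not divisible by 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"CDR3 alphabet not ACGTN: {bad}")
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in _STOP_CODONS:
            out.append("*")
        else:
            out.append(_CODON_TABLE[codon])
    return "".join(out)


def is_functional(record: SequenceRecord) -> bool:
    """Productivity of a rearrangement, computed from the CDR3 if unflagged.

    A record without an explicit flag is functional when its CDR3 length
    is a multiple of 3 (in-frame junction) and its translation contains
    no stop codon.
    """
    if record.functional is not None:
        return record.functional
    if len(record.cdr3_nt) % 3 != 0:
        return False
    return "*" not in translate_cdr3(record.cdr3_nt)


def filter_functional(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Keep only productive rearrangements (idempotent)."""
    return [r for r in records if is_functional(r)]


# Columns that must be present (after column_map renaming).  Exactly one
# of junction/cdr3 is needed, checked separately.
_MANDATORY = ("v_call", "j_call", "duplicate_count", "mouse_id", "strain", "subset", "replicate")

_BOOL_MAP = {"t": True, "true": True, "f": False, "false": False}


def read_airr_tsv(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    skipped: list | None = None,
) -> list[SequenceRecord]:
    """Read an AIRR Rearrangement TSV into SequenceRecords.

    Parameters
    ----------
    path
        TSV file with AIRR v1.x column names (``column_map`` renames
        legacy columns to them first).
    column_map
        Optional mapping from file column name to AIRR column name.
    skipped
        Optional list; rows with missing/unparseable mandatory fields are
        appended to it as ``{"row": <0-based data row>, "reason": str}``
        and excluded from the result.  A missing mandatory *column* is a
        hard error naming the column.

    Ingest is order-preserving: the n-th returned record comes from the
    n-th retained row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=column_map)
    for col in _MANDATORY:
        if col not in df.columns:
            raise ValueError(f"mandatory column missing: {col!r}")
    if "junction" not in df.columns and "cdr3" not in df.columns:
        raise ValueError("mandatory column missing: 'junction' or 'cdr3'")

    records: list[SequenceRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        try:
            records.append(_parse_row(row_d, i))
        except ValueError as exc:
            n_skipped += 1
            if skipped is not None:
                skipped.append({"row": i, "reason": str(exc)})
    if n_skipped:
        logger.warning("read_airr_tsv: skipped %d of %d rows", n_skipped, len(df))
    return records


def _parse_row(row: dict[str, str], index: int) -> SequenceRecord:
    rid = row.get("sequence_id") or f"row{index}"
    for col in _MANDATORY:
        if not row[col].strip():
            raise ValueError(f"blank mandatory field {col!r}")
    try:
        copies = int(row["duplicate_count"])
    except ValueError:
        raise ValueError(f"unparseable duplicate_count {row['duplicate_count']!r}") from None
    try:
        rep = int(row["replicate"])
    except ValueError:
        raise ValueError(f"unparseable replicate {row['replicate']!r}") from None

    cdr3 = row.get("cdr3", "").strip().upper()
    if not cdr3:
        junction = row.get("junction", "").strip().upper()
        if len(junction) < 7:
            raise ValueError("junction too short to trim anchor codons")
        cdr3 = junction[3:-3]

    cdr3_aa = row.get("cdr3_aa", "").strip() or None
    if cdr3_aa is None:
        junction_aa = row.get("junction_aa", "").strip()
        if junction_aa:
            cdr3_aa = junction_aa[1:-1]
        elif len(cdr3) % 3 == 0:
            cdr3_aa = translate_cdr3(cdr3)

    functional = _BOOL_MAP.get(row.get("productive", "").strip().lower())
    v_obs = row.get("v_sequence_alignment", "").strip().upper() or None
    vmut_raw = row.get("v_mutation_count", "").strip()
    v_mut = int(vmut_raw) if vmut_raw else None

    return SequenceRecord(
        record_id=rid,
        mouse_id=row["mouse_id"],
        strain=row["strain"],
        subset=row["subset"],
        replicate=rep,
        v_call=gene_label(row["v_call"]),
        j_call=gene_label(row["j_call"]),
        cdr3_nt=cdr3,
        cdr3_aa=cdr3_aa,
        copies=copies,
        v_observed_nt=v_obs,
        v_mutation_count=v_mut,
        functional=functional,
    )


_WRITE_COLUMNS = (
    "sequence_id",
    "mouse_id",
    "strain",
    "subset",
    "replicate",
    "v_call",
    "j_call",
    "cdr3",
    "cdr3_aa",
    "duplicate_count",
    "productive",
    "v_sequence_alignment",
    "v_mutation_count",
)


def write_airr_tsv(records: list[SequenceRecord], path: str | Path) -> None:
    """Write records as AIRR Rearrangement TSV (round-trips losslessly)."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.record_id,
                "mouse_id": r.mouse_id,
                "strain": r.strain,
                "subset": r.subset,
                "replicate": r.replicate,
                "v_call": r.v_call,
                "j_call": r.j_call,
                "cdr3": r.cdr3_nt,
                "cdr3_aa": r.cdr3_aa or "",
                "duplicate_count": r.copies,
                "productive": {True: "T", False: "F", None: ""}[r.functional],
                "v_sequence_alignment": r.v_observed_nt or "",
                "v_mutation_count": "" if r.v_mutation_count is None else r.v_mutation_count,
            }
        )
    pd.DataFrame(rows, columns=_WRITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_germline_fasta(v_path: str | Path, j_path: str | Path) -> GermlineSet:
    """Load germline V and J segments from two FASTA files."""
    v = {gene_label(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(v_path), "fasta")}
    j = {gene_label(rec.id): str(rec.seq).upper() for rec in SeqIO.parse(str(j_path), "fasta")}
    return GermlineSet(v_segments=v, j_segments=j)


def write_germline_fasta(germlines: GermlineSet, v_path: str | Path, j_path: str | Path) -> None:
    for path, segments in ((v_path, germlines.v_segments), (j_path, germlines.j_segments)):
        recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sorted(segments.items())]
        SeqIO.write(recs, str(path), "fasta")


def write_skip_report(skipped: list[dict], path: str | Path) -> None:
    """Persist the ingest skip report as TSV."""
    pd.DataFrame(skipped, columns=["row", "reason"]).to_csv(path, sep="\t", index=False)
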