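"""Screening rules applied to pre-computed annotation and search-hit tables.

These are the decision rules of the candidate-identification stage:
E-value cutoffs on homology hits, a minimum transmembrane-domain count,
exact-duplicate sequence removal, signal-peptide cleavage to mature
peptides, and transcript-to-locus isoform grouping. The external
predictions themselves (BLAST/HMM hits, TM counts, signal peptides) are
inputs, produced upstream by the usual search tools; only the filters
live here.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .evidence import ValidationError

__all__ = [
    "SourceDb",
    "HitRecord",
    "TopologyRecord",
    "filter_by_evalue",
    "filter_tm_topology",
    "remove_redundant",
    "derive_mature_peptide",
    "group_isoforms",
    "read_hit_table",
    "read_fasta",
    "write_fasta",
]


class SourceDb(enum.Enum):
    """Reference database a homology hit was found in."""

    LGIC = "lgic"
    IMMUNOME = "immunome"
    NEUROPEDIA = "neuropedia"
    MEROPS = "merops"
    GPCRDB = "gpcrdb"
    PFAM = "pfam"
    KEGG = "kegg"


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit (query vs reference database subject)."""

    query_id: str
    subject_id: str
    e_value: float
    source_db: SourceDb = SourceDb.PFAM

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValidationError(f"e_value must be >= 0, got {self.e_value}")


@dataclass(frozen=True)
class TopologyRecord:
    """Membrane-topology prediction for one query protein."""

    query_id: str
    n_tm_domains: int = 0
    has_signal_peptide: bool = False
    cleavage_pos: int | None = None

    def __post_init__(self) -> None:
        if self.n_tm_domains < 0:
            raise ValidationError("n_tm_domains must be >= 0")
        if self.has_signal_peptide != (self.cleavage_pos is not None):
            raise ValidationError("cleavage_pos must be present iff has_signal_peptide")
        if self.cleavage_pos is not None and self.cleavage_pos < 1:
            raise ValidationError("cleavage_pos is a 1-based residue index")


def filter_by_evalue(hits: Iterable[HitRecord], cutoff: float = 1e-10) -> list[HitRecord]:
    """Keep hits at or below the E-value cutoff, best hits first per query.

    The cutoff is inclusive (``e_value <= cutoff``). Surviving hits are
    grouped by query in order of first appearance and sorted ascending by
    E-value within each query; the sort is stable for equal E-values.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be > 0, got {cutoff}")
    kept = [h for h in hits if h.e_value <= cutoff]
    by_query: dict[str, list[HitRecord]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[HitRecord] = []
    for query_hits in by_query.values():
        out.extend(sorted(query_hits, key=lambda h: h.e_value))
    return out


def filter_tm_topology(
    records: Iterable[TopologyRecord], min_tm: int = 3
) -> list[TopologyRecord]:
    """Keep records with at least ``min_tm`` predicted transmembrane domains."""
    if min_tm < 0:
        raise ValidationError(f"min_tm must be >= 0, got {min_tm}")
    return [r for r in records if r.n_tm_domains >= min_tm]


def remove_redundant(
    ids_to_seqs: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, str]]:
    """Collapse exact-duplicate sequences.

    Each group of identical sequences is represented by its
    lexicographically smallest id. Returns ``(kept, collapsed)`` where
    ``collapsed`` maps every removed id to the id kept in its place.
    Uniqueness is exact string identity; sub-100%-identity clustering is
    deliberately not done here.
    """
    by_seq: dict[str, list[str]] = {}
    for seq_id, seq in ids_to_seqs.items():
        by_seq.setdefault(seq, []).append(seq_id)
    kept: dict[str, str] = {}
    collapsed: dict[str, str] = {}
    for seq, ids in by_seq.items():
        keep = min(ids)
        kept[keep] = seq
        for other in ids:
            if other != keep:
                collapsed[other] = keep
    return kept, collapsed


def derive_mature_peptide(seq: str, topo: TopologyRecord) -> str:
    """Strip an annotated signal peptide, yielding the mature peptide.

    ``topo.cleavage_pos`` is the 1-based index of the last signal-peptide
    residue; residues 1..cleavage_pos are removed. Without a signal
    peptide the sequence is returned unchanged.
    """
    if not topo.has_signal_peptide:
        return seq
    assert topo.cleavage_pos is not None
    if topo.cleavage_pos >= len(seq):
        raise ValidationError(
            f"cleavage_pos {topo.cleavage_pos} leaves no mature peptide "
            f"(sequence length {len(seq)})"
        )
    return seq[topo.cleavage_pos :]


def group_isoforms(candidates: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Count transcripts (isoforms) per locus from (transcript_id, locus_id) pairs."""
    return dict(Counter(locus for _tx, locus in candidates))


def read_hit_table(
    path: str | Path, source_db: SourceDb = SourceDb.PFAM
) -> list[HitRecord]:
    """Read BLAST tabular (outfmt 6 style) hits: qseqid sseqid ... evalue bitscore.

    Only the query id, subject id and E-value (column 11) are used.
    """
    hits: list[HitRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise ValidationError(
                f"line {lineno}: expected >= 11 tab-separated fields, got {len(fields)}"
            )
        hits.append(
            HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                e_value=float(fields[10]),
                source_db=source_db,
            )
        )
    return hits


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map (insertion-ordered)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(ids_to_seqs: Mapping[str, str], path: str | Path) -> None:
    """Write an id -> sequence map as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=seq_id, description="") for seq_id, seq in ids_to_seqs.items()]
    SeqIO.write(records, str(path), "fasta")
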