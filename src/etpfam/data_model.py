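"""Sequence, annotation and split types plus dataset-hygiene filters.

A dataset here is (i) a set of protein sequences, (ii) a split table assigning
each sequence id to exactly one partition (train / dev / test) together with
its domain annotations, and (iii) a family index mapping family accessions to
contiguous class indices.  Two hygiene rules are applied before any training:
a strict maximum-length filter (protein language models impose a positional
limit) and cross-partition deduplication, so that the same protein can never
appear in more than one partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError

PARTITIONS = ("train", "dev", "test")

SPLIT_COLUMNS = ["id", "partition", "family", "start", "end"]


@dataclass(frozen=True)
class ProteinSequence:
    """A raw amino-acid sequence with a unique identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FastaParseError(f"sequence '{self.id}' is empty")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class DomainAnnotation:
    """A family-labelled domain span, 1-based inclusive (Pfam convention)."""

    family: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}] for family {self.family}"
            )

    def as_zero_based(self) -> tuple[int, int]:
        """Return the span as a 0-based half-open interval (for windowing)."""
        return self.start - 1, self.end


@dataclass
class DatasetSplit:
    """Partition assignment and domain labels for every sequence id.

    ``records`` holds one row per domain: (id, partition, family, start, end).
    ``family_index`` is a bijection family accession <-> class index covering
    every family seen in any partition — including families present only in
    dev/test, which a classifier trained on this split can never predict but
    which still contribute false negatives at evaluation.
    """

    records: pd.DataFrame
    family_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPLIT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"split table missing columns: {missing}")
        parts_per_id = self.records.groupby("id")["partition"].nunique()
        bad = parts_per_id[parts_per_id > 1]
        if len(bad):
            raise ValueError(
                f"ids assigned to multiple partitions: {list(bad.index[:5])}"
            )
        bad_part = set(self.records["partition"]) - set(PARTITIONS)
        if bad_part:
            raise ValueError(f"unknown partitions: {sorted(bad_part)}")
        if not self.family_index:
            fams = sorted(self.records["family"].unique())
            self.family_index = {f: k for k, f in enumerate(fams)}

    @property
    def n_families(self) -> int:
        return len(self.family_index)

    def ids_in(self, partition: str) -> list[str]:
        mask = self.records["partition"] == partition
        return list(dict.fromkeys(self.records.loc[mask, "id"]))

    def partition_of(self, seq_id: str) -> str:
        rows = self.records.loc[self.records["id"] == seq_id, "partition"]
        if rows.empty:
            raise KeyError(seq_id)
        return rows.iloc[0]

    def annotations_for(self, seq_id: str) -> list[DomainAnnotation]:
        rows = self.records[self.records["id"] == seq_id]
        return [
            DomainAnnotation(r.family, int(r.start), int(r.end))
            for r in rows.itertuples()
        ]

    def labels_for(self, seq_id: str) -> list[int]:
        """Class indices of all families annotated on one sequence.

        The first entry corresponds to the leftmost domain (the primary label).
        """
        rows = self.records[self.records["id"] == seq_id].sort_values("start")
        return [self.family_index[f] for f in rows["family"]]


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into ProteinSequence records, order preserved.

    The id is the header token before the first whitespace.  A header with no
    sequence and duplicate ids are both rejected.
    """
    path = Path(path)
    seen: set[str] = set()
    out: list[ProteinSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            line_no = _find_header_line(path, rec.id)
            raise FastaParseError(
                f"{path}:{line_no}: record '{rec.id}' has a header but no sequence"
            )
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id '{rec.id}'")
        seen.add(rec.id)
        out.append(ProteinSequence(rec.id, str(rec.seq).upper()))
    return out


def _find_header_line(path: Path, rec_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[:1] == [rec_id]:
                return i
    return 0


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta-2line")


def filter_by_length(
    sequences: Sequence[ProteinSequence], max_len: int
) -> list[ProteinSequence]:
    """Keep sequences strictly shorter than ``max_len`` residues.

    The bound is strict: a sequence of exactly ``max_len`` residues is dropped.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    return [s for s in sequences if s.length < max_len]


def deduplicate_across_partitions(
    split: DatasetSplit, sequences: Sequence[ProteinSequence]
) -> tuple[DatasetSplit, pd.DataFrame]:
    """Remove duplicate residue-strings so no protein spans two partitions.

    Rules: a residue-string occurring in two or more partitions is removed from
    ALL of them; within a single partition the first occurrence (input order)
    is kept and the rest dropped.  Returns the cleaned split and a report of
    removed ids with the reason.
    """
    part_by_id = {
        r.id: r.partition for r in split.records.itertuples()
    }
    groups: dict[str, list[str]] = {}
    for seq in sequences:
        if seq.id in part_by_id:
            groups.setdefault(seq.residues, []).append(seq.id)

    removed: list[tuple[str, str]] = []
    for ids in groups.values():
        parts = {part_by_id[i] for i in ids}
        if len(parts) > 1:
            removed.extend((i, "cross-partition duplicate") for i in ids)
        elif len(ids) > 1:
            removed.extend((i, "within-partition duplicate") for i in ids[1:])

    removed_ids = {i for i, _ in removed}
    new_records = split.records[~split.records["id"].isin(removed_ids)].reset_index(
        drop=True
    )
    report = pd.DataFrame(removed, columns=["id", "reason"])
    # family_index is kept intact: classes do not disappear with their duplicates
    return DatasetSplit(new_records, dict(split.family_index)), report


def read_split_table(path: str | Path) -> DatasetSplit:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "partition": str, "family": str})
    return DatasetSplit(df[SPLIT_COLUMNS])


def write_split_table(split: DatasetSplit, path: str | Path) -> None:
    split.records[SPLIT_COLUMNS].to_csv(path, sep="\t", index=False)
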