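"""Readers and writers for the formats the pipeline touches.

Supported formats:

* FASTA (multi-line, optionally gzip-compressed, sniffed by ``.gz`` suffix),
  parsed through :mod:`Bio.SeqIO` with strict nucleotide-alphabet validation;
* OrthoFinder-style ``Orthogroups.GeneCount.tsv`` tables (with or without the
  trailing ``Total`` column, which is validated against the row sum and then
  dropped);
* two-column species -> lifestyle-group assignment tables;
* BED-like TSV output for RIP regions (0-based half-open intervals).

All tabular output is TSV with a single header row; floats are written with
six significant digits.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FormatError

#: Uppercase DNA alphabet accepted on read: the four bases plus the IUPAC
#: ambiguity letters (N, R, Y, S, W, K, M, B, D, H, V).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (may be empty). ``seq`` is upper-cased
    on read and restricted to the IUPAC DNA alphabet.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneCountMatrix:
    """Orthogroup x species gene-count table with a species -> group map.

    ``counts`` is a DataFrame indexed by orthogroup id with one integer
    column per species.  ``groups`` maps every species id to a lifestyle
    group label; it may be ``None`` until a group table is attached.
    """

    counts: pd.DataFrame
    groups: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate orthogroup id {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate species id {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("gene counts must be non-negative")
        if self.groups is not None:
            missing = [s for s in self.counts.columns if s not in self.groups]
            if missing:
                raise FormatError(
                    f"species missing from group map: {', '.join(missing)}"
                )

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.counts.columns)

    def with_groups(self, groups: Mapping[str, str]) -> "GeneCountMatrix":
        return GeneCountMatrix(self.counts.copy(), dict(groups))


def _open_text(path: str | Path, allow_gzip: bool = True):
    path = Path(path)
    if allow_gzip and path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, allow_gzip: bool = True) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into :class:`SequenceRecord` s.

    Sequences are upper-cased and validated against the IUPAC DNA alphabet;
    record order is preserved.  An empty file is a format error.
    """
    records: list[SequenceRecord] = []
    with _open_text(path, allow_gzip) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            bad = set(seq) - IUPAC_DNA
            if bad:
                offender = sorted(bad)[0]
                raise FormatError(
                    f"record {rec.id!r} contains invalid character {offender!r}"
                )
            records.append(SequenceRecord(id=rec.id, seq=seq, description=rec.description[len(rec.id):].strip()))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-line FASTA (gzipped when path ends in .gz)."""
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "wt") as handle:
            SeqIO.write(bio, handle, "fasta")
    else:
        SeqIO.write(bio, str(path), "fasta")


def read_genecounts(path: str | Path) -> GeneCountMatrix:
    """Read an OrthoFinder ``Orthogroups.GeneCount.tsv``-style table.

    The first column holds orthogroup ids; the remaining columns are species.
    A trailing ``Total`` column, if present, is checked against the row sums
    and dropped.  Returns a matrix without group assignments.
    """
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
    species = header[1:]
    seen: set[str] = set()
    for s in species:
        if s in seen:
            raise FormatError(f"duplicate species column {s!r} in header")
        seen.add(s)

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        numeric = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric gene count: {exc}") from exc
    if not (numeric.dtypes == "int64").all() or (numeric.to_numpy() < 0).any():
        bad = numeric.columns[
            (numeric.dtypes != "int64") | (numeric < 0).any()
        ][0]
        raise FormatError(f"non-integer or negative gene count in column {bad!r}")

    if numeric.columns[-1] == "Total":
        totals = numeric["Total"]
        body = numeric.drop(columns="Total")
        mismatch = totals != body.sum(axis=1)
        if mismatch.any():
            og = numeric.index[mismatch][0]
            raise FormatError(
                f"Total column does not match row sum for orthogroup {og!r}"
            )
        numeric = body
    return GeneCountMatrix(numeric)


def write_genecounts(matrix: GeneCountMatrix, path: str | Path) -> None:
    """Write a gene-count matrix in the OrthoFinder dialect with a Total column."""
    out = matrix.counts.copy()
    out["Total"] = out.sum(axis=1)
    out.index.name = "Orthogroup"
    out.to_csv(path, sep="\t")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column species/group TSV into a mapping.

    A header line ``species<TAB>group`` is optional.  A species listed twice
    with the same group is deduplicated; conflicting assignments are an error.
    """
    groups: dict[str, str] = {}
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
            species, group = parts
            if lineno == 1 and (species, group) == ("species", "group"):
                continue
            if species in groups and groups[species] != group:
                raise FormatError(
                    f"species {species!r} assigned to both {groups[species]!r} "
                    f"and {group!r}"
                )
            groups[species] = group
    if not groups:
        raise FormatError(f"no group assignments found in {path}")
    return groups


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("species\tgroup\n")
        for species, group in groups.items():
            handle.write(f"{species}\t{group}\n")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Write a TSV with one header row and 6-significant-digit floats."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def write_bed(intervals: Sequence[tuple], path: str | Path) -> None:
    """Write (contig, start, end, score) tuples as 0-based half-open BED."""
    with open(path, "w") as handle:
        for row in intervals:
            handle.write("\t".join(str(x) for x in row) + "\n")
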