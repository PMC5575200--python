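"""Aligned barcode sequences with population labels.

The unit of data throughout the package is an alignment of equal-length
mitochondrial barcode sequences (the ~685 bp CO1 fragment) in which every
record carries a population label. Sequences are stored uppercase over the
alphabet ``A C G T N -``; ``N`` and ``-`` are treated as ambiguous/missing in
every pairwise comparison downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

ALPHABET = frozenset("ACGTN-")

#: integer codes for the four unambiguous bases, in fixed order
BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
#: code used for any ambiguous / missing character
AMBIGUOUS_CODE = 4


class AlignmentError(ValueError):
    """Raised for ragged, empty, or mislabelled alignments."""


@dataclass(frozen=True)
class SequenceRecord:
    """One barcode sequence with its sample id and population label."""

    id: str
    population: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise AlignmentError(f"sequence {self.id!r} is empty")
        bad = set(seq) - ALPHABET
        if bad:
            raise AlignmentError(
                f"sequence {self.id!r} contains characters outside "
                f"A/C/G/T/N/-: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass
class Alignment:
    """An ordered collection of equal-length :class:`SequenceRecord`.

    Attributes
    ----------
    records : list of SequenceRecord
    length : int
        Number of aligned sites, shared by every record.
    """

    records: list[SequenceRecord]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("no sequences")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"ragged alignment: sequence lengths {sorted(lengths)}"
            )
        self.length = lengths.pop()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    @property
    def populations(self) -> list[str]:
        """Distinct population labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.population, None)
        return list(seen)

    def subset(self, populations: Iterable[str]) -> "Alignment":
        wanted = set(populations)
        missing = wanted - set(self.populations)
        if missing:
            raise AlignmentError(f"unknown population(s): {sorted(missing)}")
        return Alignment([r for r in self.records if r.population in wanted])

    def to_matrix(self) -> np.ndarray:
        """Encode as an (n, length) uint8 matrix; ambiguous sites get code 4.

        The encoding is cached on first use (records are immutable).
        """
        cached = getattr(self, "_matrix", None)
        if cached is not None:
            return cached
        raw = np.frombuffer(
            "".join(r.sequence for r in self.records).encode("ascii"), dtype=np.uint8
        ).reshape(len(self.records), self.length)
        out = np.full(raw.shape, AMBIGUOUS_CODE, dtype=np.uint8)
        for code, base in enumerate(BASES):
            out[raw == ord(base)] = code
        self._matrix = out
        return out

    def base_frequencies(self) -> np.ndarray:
        """Empirical A/C/G/T frequencies over all unambiguous sites."""
        mat = self.to_matrix()
        counts = np.bincount(mat[mat < 4].ravel(), minlength=4).astype(float)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total

    def write_fasta(self, path: str | Path) -> None:
        recs = [
            _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.population)
            for r in self.records
        ]
        SeqIO.write(recs, str(path), "fasta")

    def write_population_map(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            for r in self.records:
                w.writerow([r.id, r.population])


def read_population_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping sequence id -> population label."""
    mapping: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise AlignmentError(f"malformed population-map row: {row!r}")
            mapping[row[0].strip()] = row[1].strip()
    return mapping


def read_alignment(fasta_path: str | Path, population_map_path: str | Path) -> Alignment:
    """Read an aligned FASTA and attach population labels from a TSV map.

    Every FASTA id must appear in the map; ragged or empty alignments are
    rejected.
    """
    mapping = read_population_map(population_map_path)
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in mapping:
            raise AlignmentError(
                f"sequence id {rec.id!r} has no entry in the population map"
            )
        records.append(
            SequenceRecord(id=rec.id, population=mapping[rec.id], sequence=str(rec.seq))
        )
    if not records:
        raise AlignmentError("no sequences")
    return Alignment(records)
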