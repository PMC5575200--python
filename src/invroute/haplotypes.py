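"""Haplotype collapsing and population x haplotype count tables.

Identical sequences (character-for-character after uppercasing; no wildcard
matching of ``N`` or ``-``) collapse to one haplotype. Labels are assigned
``H1, H2, ...`` in order of first appearance unless a user label map pins
specific sequences to specific labels.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .alignment import Alignment, AlignmentError


@dataclass
class HaplotypeTable:
    """Haplotype sequences plus a population x haplotype count matrix.

    Attributes
    ----------
    haplotypes : dict
        Label -> representative sequence. Sequences are pairwise distinct.
    counts : pandas.DataFrame
        Rows are populations, columns are haplotype labels, values are
        non-negative integer specimen counts.
    """

    haplotypes: dict[str, str]
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        seqs = list(self.haplotypes.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("haplotype sequences must be pairwise distinct")
        if (self.counts.values < 0).any():
            raise ValueError("haplotype counts must be non-negative")
        self.counts = self.counts.astype(int)

    @property
    def populations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def labels(self) -> list[str]:
        return list(self.counts.columns)

    def total(self) -> int:
        return int(self.counts.values.sum())

    def to_csv(self, path: str | Path) -> None:
        self.counts.to_csv(path, index_label="population")

    def write_haplotype_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, seq in self.haplotypes.items():
                fh.write(f">{label}\n{seq}\n")


def collapse_haplotypes(
    alignment: Alignment, label_map: dict[str, str] | None = None
) -> HaplotypeTable:
    """Collapse an alignment to haplotypes and tally them per population.

    Parameters
    ----------
    alignment : Alignment
    label_map : dict, optional
        Sequence -> label. Sequences not covered by the map get fresh
        ``H<k>`` labels continuing after the mapped ones.

    Returns
    -------
    HaplotypeTable
        Total counts equal the number of input records.
    """
    label_map = dict(label_map or {})
    seq_to_label: dict[str, str] = {s.upper(): l for s, l in label_map.items()}
    used = set(seq_to_label.values())
    next_index = 1

    def fresh_label() -> str:
        nonlocal next_index
        while f"H{next_index}" in used:
            next_index += 1
        lab = f"H{next_index}"
        used.add(lab)
        return lab

    order: list[str] = []  # labels in order of first appearance
    tallies: dict[tuple[str, str], int] = {}
    pops: list[str] = []
    for rec in alignment:
        label = seq_to_label.get(rec.sequence)
        if label is None:
            label = fresh_label()
            seq_to_label[rec.sequence] = label
        if label not in order:
            order.append(label)
        if rec.population not in pops:
            pops.append(rec.population)
        tallies[(rec.population, label)] = tallies.get((rec.population, label), 0) + 1

    counts = pd.DataFrame(0, index=pops, columns=order, dtype=int)
    for (pop, label), n in tallies.items():
        counts.loc[pop, label] = n
    haplotypes = {lab: seq for seq, lab in seq_to_label.items() if lab in order}
    haplotypes = {lab: haplotypes[lab] for lab in order}
    return HaplotypeTable(haplotypes=haplotypes, counts=counts)


@dataclass
class Census:
    """Specimen totals and distinct-haplotype counts for a population subset."""

    per_population: dict[str, int]
    overall: int
    distinct_haplotypes: int
    distinct_per_population: dict[str, int] = field(default_factory=dict)


def census(table: HaplotypeTable, populations: list[str] | None = None) -> Census:
    """Tally specimens and distinct haplotypes over a subset of populations.

    The distinct-haplotype count over a subset is the number of haplotype
    columns with a nonzero sum within that subset.
    """
    if populations is None:
        populations = table.populations
    unknown = set(populations) - set(table.populations)
    if unknown:
        raise KeyError(f"unknown population label(s): {sorted(unknown)}")
    sub = table.counts.loc[populations]
    per_pop = {p: int(sub.loc[p].sum()) for p in populations}
    distinct = int((sub.sum(axis=0) > 0).sum())
    distinct_per_pop = {p: int((sub.loc[p] > 0).sum()) for p in populations}
    return Census(
        per_population=per_pop,
        overall=int(sub.values.sum()),
        distinct_haplotypes=distinct,
        distinct_per_population=distinct_per_pop,
    )


#: countries of the species' native range in the global barcode survey
NATIVE_COUNTRIES = ("China", "Japan", "Republic of Korea")

#: post-2008 western-US collection localities
WESTERN_US_LOCALITIES = ("California", "Oregon", "Washington")


def _placeholder_sequence(label: str, length: int = 685) -> str:
    """Deterministic synthetic stand-in sequence for a haplotype label.

    The real barcode sequences live in GenBank and are not redistributed;
    these placeholders only preserve the label structure (pairwise distinct,
    fixed length). Haplotype ``H<k>`` differs from the backbone at positions
    determined by ``k``.
    """
    k = int(label.lstrip("H"))
    backbone = "ACGT"
    seq = [backbone[i % 4] for i in range(length)]
    flip = {"A": "G", "C": "T", "G": "A", "T": "C"}
    # spread k's binary representation over the first 60 sites
    for bit in range(20):
        if (k >> bit) & 1:
            seq[3 * bit] = flip[seq[3 * bit]]
    pos = 60 + (k % 100)
    seq[pos] = flip[seq[pos]]
    return "".join(seq)


def load_table1_fixture(level: str = "locality") -> HaplotypeTable:
    """Packaged count table of the global barcode survey.

    Counts per locality/country were transcribed from the published survey
    table and reconciled so that locality, country, and global totals agree
    (916 specimens overall, 214 from the native range). Haplotype sequences
    are synthetic placeholders consistent with the label structure; only the
    counts are meaningful.

    Parameters
    ----------
    level : {"locality", "country"}
        Row granularity of the returned table.
    """
    if level not in ("locality", "country"):
        raise ValueError("level must be 'locality' or 'country'")
    ref = importlib.resources.files("invroute.data") / "table1_counts.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    key = "locality" if level == "locality" else "country"
    pivot = df.pivot_table(
        index=key, columns="haplotype", values="count", aggfunc="sum", fill_value=0
    )
    # preserve file order for rows and numeric order for haplotype columns
    row_order = list(dict.fromkeys(df[key]))
    col_order = sorted(pivot.columns, key=lambda h: int(h.lstrip("H")))
    pivot = pivot.loc[row_order, col_order]
    haplotypes = {h: _placeholder_sequence(h) for h in col_order}
    return HaplotypeTable(haplotypes=haplotypes, counts=pivot)


def load_table1_frame() -> pd.DataFrame:
    """The raw fixture rows: country, locality, haplotype, count."""
    ref = importlib.resources.files("invroute.data") / "table1_counts.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def table_from_counts(counts: pd.DataFrame, haplotypes: dict[str, str] | None = None,
                      length: int = 685) -> HaplotypeTable:
    """Build a HaplotypeTable from a count matrix, synthesizing placeholder
    sequences when none are provided."""
    if haplotypes is None:
        haplotypes = {h: _placeholder_sequence(str(h), length) for h in counts.columns}
    return HaplotypeTable(haplotypes=haplotypes, counts=counts)


def alignment_from_table(table: HaplotypeTable) -> Alignment:
    """Expand a count table back into one record per specimen (for network
    building or statistics on fixture data)."""
    from .alignment import SequenceRecord

    records = []
    i = 0
    for pop in table.populations:
        for label in table.labels:
            n = int(table.counts.loc[pop, label])
            for _ in range(n):
                records.append(
                    SequenceRecord(
                        # ids must survive FASTA round-trips: no whitespace
                        id=f"{pop.replace(' ', '-')}_{label}_{i}",
                        population=pop,
                        sequence=table.haplotypes[label],
                    )
                )
                i += 1
    if not records:
        raise AlignmentError("no sequences")
    return Alignment(records)
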