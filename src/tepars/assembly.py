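"""Supermatrix assembly: aligned gene partitions, chimeric OTU mapping
and morphology + molecular concatenation.

Molecular cells are nucleotides; gaps, Ns and IUPAC ambiguity codes are
all scored as missing (full ambiguity) downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from tepars.catalog import (
    INAPPLICABLE,
    MISSING,
    CharacterCatalog,
    MorphMatrix,
)
from tepars.parsimony import Column

DNA_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_DNA_FULL = frozenset(range(4))


class AssemblyError(ValueError):
    pass


@dataclass
class AlignedPartition:
    name: str
    length: int
    rows: dict[str, str]

    def __post_init__(self):
        if self.length <= 0:
            raise AssemblyError(f"partition {self.name}: non-positive length")
        for taxon, seq in self.rows.items():
            if len(seq) != self.length:
                raise AssemblyError(
                    f"partition {self.name}: record {taxon!r} has length "
                    f"{len(seq)}, expected {self.length}"
                )


@dataclass
class OtuMap:
    """OTU label -> list of (source taxon, partition name, accession)."""

    entries: dict[str, list[tuple[str, str, str]]]

    def __post_init__(self):
        for otu, sources in self.entries.items():
            parts = [p for (_, p, _) in sources]
            if len(parts) != len(set(parts)):
                raise AssemblyError(
                    f"OTU {otu!r}: a partition appears more than once"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.entries)

    def sequenced_taxa(self) -> list[str]:
        return [otu for otu, src in self.entries.items() if src]


@dataclass
class CombinedMatrix:
    """Total-evidence matrix: optional morphology block followed by
    molecular partitions. Partition map intervals are 1-based closed,
    matching NEXUS CHARSET conventions."""

    taxa: list[str]
    morphology: Optional[MorphMatrix]
    partitions: list[AlignedPartition]
    partition_map: dict[str, tuple[int, int]]
    total_characters: int
    catalog: Optional[CharacterCatalog] = field(default=None, repr=False)

    @property
    def morph_width(self) -> int:
        return self.morphology.n_characters if self.morphology else 0

    def columns(self) -> list[Column]:
        """All characters as parsimony columns (morphology first)."""
        cols: list[Column] = []
        if self.morphology is not None:
            for cid in self.morphology.char_ids:
                cols.append(self._morph_column(cid))
        for part in self.partitions:
            for i in range(part.length):
                states = {}
                for taxon in self.taxa:
                    seq = part.rows.get(taxon)
                    if seq is None:
                        states[taxon] = _DNA_FULL
                    else:
                        code = DNA_CODES.get(seq[i].upper())
                        states[taxon] = (
                            frozenset((code,)) if code is not None else _DNA_FULL
                        )
                cols.append(Column(states=states, nstates=4))
        return cols

    def _morph_column(self, cid: int) -> Column:
        assert self.morphology is not None
        if self.catalog is not None:
            universe = frozenset(self.catalog.get(cid).state_codes)
        else:
            observed = {
                c
                for t in self.morphology.taxa
                for c in [self.morphology.row(t)[cid]]
                if isinstance(c, int)
            }
            universe = frozenset(observed) if observed else frozenset({0, 1})
        states = {}
        for taxon in self.taxa:
            if taxon in self.morphology.cells:
                cell = self.morphology.row(taxon)[cid]
                states[taxon] = (
                    frozenset((cell,)) if isinstance(cell, int) else universe
                )
            else:
                states[taxon] = universe
        return Column(states=states, nstates=max(universe) + 1)


# ---------------------------------------------------------------------------
# operations


def read_alignment(path: Union[str, Path], name: str) -> AlignedPartition:
    """Read an aligned FASTA file into a partition.

    Sequences are uppercased; all records must share one length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AssemblyError(f"{path}: no FASTA records")
    length = len(records[0].seq)
    rows: dict[str, str] = {}
    for rec in records:
        if len(rec.seq) != length:
            raise AssemblyError(
                f"{path}: record {rec.id!r} has length {len(rec.seq)}, "
                f"expected {length} (ragged alignment)"
            )
        rows[rec.description.strip() or rec.id] = str(rec.seq).upper()
    return AlignedPartition(name=name, length=length, rows=rows)


def load_otu_map(path: Union[str, Path]) -> OtuMap:
    entries: dict[str, list[tuple[str, str, str]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "otu":
                continue
            otu = fields[0]
            entries.setdefault(otu, [])
            if len(fields) >= 3 and fields[1]:
                accession = fields[3] if len(fields) > 3 else ""
                entries[otu].append((fields[2], fields[1], accession))
    return OtuMap(entries=entries)


def load_default_otu_map() -> OtuMap:
    """The shipped study OTU map (34 taxa, one without sequence data)."""
    ref = resources.files("tepars.data").joinpath("otu_map.tsv")
    with resources.as_file(ref) as path:
        return load_otu_map(path)


def assemble_otus(
    otu_map: OtuMap, partitions: list[AlignedPartition]
) -> list[AlignedPartition]:
    """Re-key partition rows by OTU label.

    Every (source taxon, partition) pair in the map must resolve to a
    row. OTUs with no sequenced partition at all are dropped from the
    molecular set (they remain available for the morphology block);
    OTUs missing one gene get an all-missing row for it.
    """
    by_name = {p.name: p for p in partitions}
    out: list[AlignedPartition] = []
    sequenced = otu_map.sequenced_taxa()
    for part in partitions:
        rows: dict[str, str] = {}
        for otu in sequenced:
            source = None
            for src_taxon, part_name, _acc in otu_map.entries[otu]:
                if part_name == part.name:
                    source = src_taxon
            if source is None:
                rows[otu] = MISSING * part.length
                continue
            if source not in part.rows:
                raise AssemblyError(
                    f"OTU {otu!r}: source taxon {source!r} not found in "
                    f"partition {part.name!r}"
                )
            rows[otu] = part.rows[source]
        out.append(AlignedPartition(name=part.name, length=part.length, rows=rows))
    unknown = [
        (otu, p)
        for otu, srcs in otu_map.entries.items()
        for (_, p, _) in srcs
        if p not in by_name
    ]
    if unknown:
        raise AssemblyError(f"OTU map references unknown partitions: {unknown}")
    return out


def concatenate(
    morph: Optional[MorphMatrix],
    partitions: list[AlignedPartition],
    catalog: Optional[CharacterCatalog] = None,
) -> CombinedMatrix:
    """Concatenate a morphology block and molecular partitions into one
    combined matrix. The taxon set is the union; taxa absent from a
    block are padded with missing data."""
    taxa: list[str] = []
    seen = set()
    for source in ([morph.taxa] if morph else []) + [
        list(p.rows) for p in partitions
    ]:
        for taxon in source:
            if taxon not in seen:
                seen.add(taxon)
                taxa.append(taxon)
    names = [p.name for p in partitions]
    if len(set(names)) != len(names):
        raise AssemblyError(f"duplicate partition names: {names}")

    morph_width = morph.n_characters if morph else 0
    partition_map: dict[str, tuple[int, int]] = {}
    pos = morph_width
    for part in partitions:
        partition_map[part.name] = (pos + 1, pos + part.length)
        pos += part.length
    return CombinedMatrix(
        taxa=taxa,
        morphology=morph,
        partitions=partitions,
        partition_map=partition_map,
        total_characters=pos,
        catalog=catalog,
    )
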