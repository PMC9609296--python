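"""Minimal NEXUS DATA/SETS reading and writing for combined
morphology + nucleotide matrices.

The dialect written here is deliberately narrow: one DATA block with
DATATYPE=STANDARD and an explicit SYMBOLS list, MISSING=? and GAP=-
(the gap symbol carries the inapplicable meaning for morphology), and
a SETS block with one CHARSET per partition (1-based closed
intervals). General-purpose NEXUS libraries do not round-trip mixed
morphology/DNA matrices reliably, so the artifact owns this dialect;
the reader accepts exactly what the writer emits.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Union

from tepars.assembly import AlignedPartition, CombinedMatrix
from tepars.catalog import INAPPLICABLE, MISSING, MorphMatrix

MORPH_SYMBOLS = "0123456789"
DNA_SYMBOLS = "ACGT"


class NexusError(ValueError):
    pass


def _cell_char(cell) -> str:
    if cell == MISSING:
        return "?"
    if cell == INAPPLICABLE:
        return "-"
    return str(cell)


def write_nexus(matrix: CombinedMatrix, path: Union[str, Path]) -> None:
    taxa = matrix.taxa
    lines = ["#NEXUS", "", "BEGIN DATA;"]
    lines.append(
        f"    DIMENSIONS NTAX={len(taxa)} NCHAR={matrix.total_characters};"
    )
    symbols = MORPH_SYMBOLS + (DNA_SYMBOLS if matrix.partitions else "")
    lines.append(
        f'    FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;'
    )
    lines.append("    MATRIX")
    for taxon in taxa:
        row = ""
        if matrix.morphology is not None:
            if taxon in matrix.morphology.cells:
                cells = matrix.morphology.row(taxon)
                row += "".join(
                    _cell_char(cells[cid]) for cid in matrix.morphology.char_ids
                )
            else:
                row += "?" * matrix.morphology.n_characters
        for part in matrix.partitions:
            row += part.rows.get(taxon, "?" * part.length)
        lines.append(f"    '{taxon}'  {row}")
    lines.append("    ;")
    lines.append("END;")
    if matrix.partition_map:
        lines.append("")
        lines.append("BEGIN SETS;")
        if matrix.morphology is not None and matrix.morph_width:
            lines.append(f"    CHARSET morphology = 1-{matrix.morph_width};")
        for name, (lo, hi) in matrix.partition_map.items():
            lines.append(f"    CHARSET {name} = {lo}-{hi};")
        lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")


def read_nexus(path: Union[str, Path]) -> CombinedMatrix:
    """Read a matrix previously written by :func:`write_nexus`."""
    text = Path(path).read_text()
    m = re.search(r"DIMENSIONS\s+NTAX=(\d+)\s+NCHAR=(\d+);", text, re.I)
    if not m:
        raise NexusError(f"{path}: missing DIMENSIONS")
    ntax, nchar = int(m.group(1)), int(m.group(2))
    mm = re.search(r"MATRIX\s*(.*?);\s*END;", text, re.S | re.I)
    if not mm:
        raise NexusError(f"{path}: missing MATRIX block")
    rows: dict[str, str] = {}
    for line in mm.group(1).strip().splitlines():
        line = line.strip()
        if not line:
            continue
        tm = re.match(r"'([^']+)'\s+(\S+)$", line) or re.match(
            r"(\S+)\s+(\S+)$", line
        )
        if not tm:
            raise NexusError(f"{path}: unparseable matrix row: {line!r}")
        rows[tm.group(1)] = tm.group(2)
    if len(rows) != ntax:
        raise NexusError(f"{path}: NTAX={ntax} but {len(rows)} rows")
    for taxon, row in rows.items():
        if len(row) != nchar:
            raise NexusError(
                f"{path}: row {taxon!r} has {len(row)} cells, NCHAR={nchar}"
            )
    charsets: list[tuple[str, int, int]] = []
    for cm in re.finditer(r"CHARSET\s+(\S+)\s*=\s*(\d+)-(\d+);", text, re.I):
        charsets.append((cm.group(1), int(cm.group(2)), int(cm.group(3))))

    morph_width = 0
    partitions: list[AlignedPartition] = []
    morph: MorphMatrix | None = None
    for name, lo, hi in charsets:
        if name == "morphology":
            morph_width = hi - lo + 1
            continue
        partitions.append(
            AlignedPartition(
                name=name,
                length=hi - lo + 1,
                rows={t: r[lo - 1 : hi] for t, r in rows.items()},
            )
        )
    if not charsets:
        morph_width = nchar  # bare matrix: all standard characters
    if morph_width:
        cells = {}
        for taxon, row in rows.items():
            cells[taxon] = {}
            for i in range(morph_width):
                ch = row[i]
                if ch == "?":
                    cells[taxon][i + 1] = MISSING
                elif ch == "-":
                    cells[taxon][i + 1] = INAPPLICABLE
                else:
                    cells[taxon][i + 1] = int(ch)
        morph = MorphMatrix(
            taxa=list(rows),
            char_ids=list(range(1, morph_width + 1)),
            cells=cells,
        )
    partition_map: dict[str, tuple[int, int]] = {}
    pos = morph_width
    for part in partitions:
        partition_map[part.name] = (pos + 1, pos + part.length)
        pos += part.length
    return CombinedMatrix(
        taxa=list(rows),
        morphology=morph,
        partitions=partitions,
        partition_map=partition_map,
        total_characters=nchar,
    )


def write_morph_nexus(matrix: MorphMatrix, path: Union[str, Path]) -> None:
    combined = CombinedMatrix(
        taxa=matrix.taxa,
        morphology=matrix,
        partitions=[],
        partition_map={},
        total_characters=matrix.n_characters,
    )
    write_nexus(combined, path)


def read_morph_nexus(path: Union[str, Path]) -> MorphMatrix:
    combined = read_nexus(path)
    if combined.morphology is None:
        raise NexusError(f"{path}: no morphology block")
    return combined.morphology
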