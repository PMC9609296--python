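"""Morphological character catalog with inapplicability dependencies.

A catalog holds numbered multistate characters. A character may declare
"inapplicable if" conditions: when a taxon's score on a controlling
character falls in the controlling state set, the dependent character
cannot be scored for that taxon and must carry the inapplicable symbol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

import yaml

MISSING = "?"
INAPPLICABLE = "-"

Cell = Union[int, str]  # int state code, MISSING or INAPPLICABLE


class CatalogError(ValueError):
    pass


class DependencyCycleError(CatalogError):
    def __init__(self, cycle: list[int]):
        self.cycle = cycle
        super().__init__(
            "cyclic character dependency: " + " -> ".join(map(str, cycle))
        )


@dataclass(frozen=True)
class InapplicabilityCondition:
    """Dependent character is inapplicable when the taxon's score on
    ``controller`` lies in ``states``."""

    controller: int
    states: frozenset[int]


@dataclass(frozen=True)
class CharacterDefinition:
    char_id: int
    locus: str
    statement: str
    states: tuple[tuple[int, str], ...]  # ordered (code, descriptor)
    inapplicable_if: tuple[InapplicabilityCondition, ...] = ()

    def __post_init__(self):
        codes = [code for code, _ in self.states]
        if codes != list(range(len(codes))) or len(codes) < 2:
            raise CatalogError(
                f"character {self.char_id}: state codes must be 0..k-1 "
                f"with k >= 2, got {codes}"
            )

    @property
    def state_codes(self) -> frozenset[int]:
        return frozenset(code for code, _ in self.states)


@dataclass
class CharacterCatalog:
    characters: list[CharacterDefinition]
    provenance: str = ""
    # conditions whose controlling state is not declared by the
    # controller; retained verbatim but they can never match
    undeclared_controlling: list[tuple[int, InapplicabilityCondition]] = field(
        default_factory=list
    )

    def __post_init__(self):
        ids = [c.char_id for c in self.characters]
        if len(set(ids)) != len(ids):
            raise CatalogError("duplicate char_id in catalog")
        by_id = {c.char_id: c for c in self.characters}
        self.undeclared_controlling = []
        for char in self.characters:
            for cond in char.inapplicable_if:
                if cond.controller not in by_id:
                    raise CatalogError(
                        f"character {char.char_id}: unknown controlling "
                        f"character {cond.controller}"
                    )
                undeclared = cond.states - by_id[cond.controller].state_codes
                if undeclared:
                    self.undeclared_controlling.append((char.char_id, cond))
        self._check_acyclic()
        self._by_id = by_id

    def _check_acyclic(self) -> None:
        edges: dict[int, list[int]] = {}
        for char in self.characters:
            edges[char.char_id] = [c.controller for c in char.inapplicable_if]
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {cid: WHITE for cid in edges}
        path: list[int] = []

        def visit(cid: int) -> None:
            colour[cid] = GREY
            path.append(cid)
            for nxt in edges[cid]:
                if colour[nxt] == GREY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise DependencyCycleError(cycle)
                if colour[nxt] == WHITE:
                    visit(nxt)
            path.pop()
            colour[cid] = BLACK

        for cid in edges:
            if colour[cid] == WHITE:
                visit(cid)

    def __len__(self) -> int:
        return len(self.characters)

    def __iter__(self):
        return iter(self.characters)

    def get(self, char_id: int) -> CharacterDefinition:
        try:
            return self._by_id[char_id]
        except KeyError:
            raise CatalogError(f"unknown char_id {char_id}") from None

    def char_ids(self) -> list[int]:
        return [c.char_id for c in self.characters]

    def dependency_order(self) -> list[int]:
        """Character ids ordered so every controller precedes its
        dependents."""
        order: list[int] = []
        seen: set[int] = set()

        def visit(cid: int) -> None:
            if cid in seen:
                return
            seen.add(cid)
            for cond in self.get(cid).inapplicable_if:
                visit(cond.controller)
            order.append(cid)

        for char in self.characters:
            visit(char.char_id)
        return order


@dataclass
class MorphMatrix:
    """Taxa x characters grid of state codes / MISSING / INAPPLICABLE."""

    taxa: list[str]
    char_ids: list[int]
    cells: dict[str, dict[int, Cell]]

    def __post_init__(self):
        for taxon in self.taxa:
            row = self.cells.get(taxon)
            if row is None or set(row) != set(self.char_ids):
                raise CatalogError(
                    f"taxon {taxon!r}: row does not cover exactly the "
                    "matrix characters"
                )

    @property
    def n_characters(self) -> int:
        return len(self.char_ids)

    def row(self, taxon: str) -> dict[int, Cell]:
        return self.cells[taxon]


@dataclass(frozen=True)
class Violation:
    taxon: str
    char_id: int
    kind: str  # SHOULD_BE_INAPPLICABLE | SHOULD_BE_APPLICABLE |
    #            UNDECLARED_STATE | UNDECLARED_CONTROLLING_STATE
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok


# ---------------------------------------------------------------------------
# operations


def load_catalog(source: Union[str, Path]) -> CharacterCatalog:
    """Load a catalog from a YAML file (one record per character)."""
    with open(source) as fh:
        raw = yaml.safe_load(fh)
    return _catalog_from_dict(raw, str(source))


def load_default_catalog() -> CharacterCatalog:
    """The shipped 59-character morphology catalog."""
    ref = resources.files("tepars.data").joinpath("characters.yaml")
    raw = yaml.safe_load(ref.read_text())
    return _catalog_from_dict(raw, "shipped catalog fixture")


def _catalog_from_dict(raw: dict, source: str) -> CharacterCatalog:
    if not isinstance(raw, dict) or "characters" not in raw:
        raise CatalogError(f"{source}: missing top-level 'characters' list")
    chars = []
    for rec in raw["characters"]:
        for key in ("id", "locus", "statement", "states"):
            if key not in rec:
                raise CatalogError(
                    f"{source}: character record missing field {key!r}"
                )
        states = tuple(
            (int(code), str(desc)) for code, desc in
            (sorted(rec["states"].items()) if isinstance(rec["states"], dict)
             else enumerate(rec["states"]))
        )
        conds = []
        for cond in rec.get("inapplicable_if", []):
            conds.append(
                InapplicabilityCondition(
                    controller=int(cond["char"]),
                    states=frozenset(int(s) for s in cond["states"]),
                )
            )
        chars.append(
            CharacterDefinition(
                char_id=int(rec["id"]),
                locus=str(rec["locus"]),
                statement=str(rec["statement"]),
                states=states,
                inapplicable_if=tuple(conds),
            )
        )
    return CharacterCatalog(
        characters=chars, provenance=str(raw.get("provenance", ""))
    )


def is_applicable(
    row: dict[int, Cell], char_id: int, catalog: CharacterCatalog
) -> bool:
    """False iff any inapplicability condition of ``char_id`` matches.

    A MISSING or INAPPLICABLE score on a controlling character cannot
    prove inapplicability, so the character counts as applicable.
    """
    char = catalog.get(char_id)
    for cond in char.inapplicable_if:
        if cond.controller not in row:
            raise CatalogError(
                f"row does not cover controlling character {cond.controller} "
                f"of character {char_id}"
            )
        score = row[cond.controller]
        if isinstance(score, int) and score in cond.states:
            return False
    return True


def validate_matrix(
    matrix: MorphMatrix, catalog: CharacterCatalog
) -> ValidationReport:
    """Check every cell of ``matrix`` against the catalog's state
    declarations and applicability rules.

    Violations are reported in deterministic (taxon, char_id) order.
    Catalog-level undeclared controlling states are surfaced once per
    report with an empty taxon field.
    """
    violations: list[Violation] = []
    for cid, cond in catalog.undeclared_controlling:
        undeclared = sorted(
            cond.states - catalog.get(cond.controller).state_codes
        )
        violations.append(
            Violation(
                taxon="",
                char_id=cid,
                kind="UNDECLARED_CONTROLLING_STATE",
                message=(
                    f"condition on character {cond.controller} references "
                    f"undeclared state(s) {undeclared}; it can never match"
                ),
            )
        )
    for taxon in matrix.taxa:
        row = matrix.row(taxon)
        for cid in matrix.char_ids:
            cell = row[cid]
            char = catalog.get(cid)
            if isinstance(cell, int) and cell not in char.state_codes:
                violations.append(
                    Violation(
                        taxon,
                        cid,
                        "UNDECLARED_STATE",
                        f"state {cell} not declared for character {cid}",
                    )
                )
                continue
            applicable = is_applicable(row, cid, catalog)
            if not applicable and cell != INAPPLICABLE:
                violations.append(
                    Violation(
                        taxon,
                        cid,
                        "SHOULD_BE_INAPPLICABLE",
                        f"character {cid} is inapplicable for {taxon} but "
                        f"scored {cell!r}",
                    )
                )
            elif applicable and cell == INAPPLICABLE:
                violations.append(
                    Violation(
                        taxon,
                        cid,
                        "SHOULD_BE_APPLICABLE",
                        f"character {cid} is applicable for {taxon} but "
                        "scored inapplicable",
                    )
                )
    violations.sort(key=lambda v: (v.taxon, v.char_id, v.kind))
    return ValidationReport(violations)


def load_scores_tsv(path: Union[str, Path]) -> dict[str, dict[int, Cell]]:
    """Read a wide score table: header ``taxon`` + char_ids, one row per
    taxon; cells are state codes, '?' or '-'."""
    rows: dict[str, dict[int, Cell]] = {}
    with open(path) as fh:
        header: list[int] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "taxon":
                header = [int(c) for c in fields[1:]]
                continue
            cells: dict[int, Cell] = {}
            for cid, raw in zip(header, fields[1:], strict=True):
                cells[cid] = raw if raw in (MISSING, INAPPLICABLE) else int(raw)
            rows[fields[0]] = cells
    return rows


def load_example_scores() -> dict[str, dict[int, Cell]]:
    """Shipped reference terminal scores over the morphotype-relevant
    characters (one typical swimmer, two full reversals, one unusual
    long-merus swimmer)."""
    ref = resources.files("tepars.data").joinpath("example_scores.tsv")
    with resources.as_file(ref) as path:
        return load_scores_tsv(path)


def matrix_from_rows(
    rows: dict[str, Iterable[Cell]], char_ids: Iterable[int]
) -> MorphMatrix:
    """Convenience constructor from per-taxon cell sequences."""
    char_ids = list(char_ids)
    cells = {
        taxon: dict(zip(char_ids, list(values), strict=True))
        for taxon, values in rows.items()
    }
    return MorphMatrix(taxa=list(rows), char_ids=char_ids, cells=cells)
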