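"""Rule-based morphotype classification of terminals and reconstructed
ancestors.

A morphotype rule maps character ids to allowed state sets. A terminal
is assigned the morphotype iff every rule character is scored with an
allowed state; a missing score leaves the call open (POSSIBLE), while
an inapplicable score refutes it (the required state cannot hold).
For internal nodes the MPR sets are compared to the allowed sets:
subset everywhere = match, intersection everywhere = possible,
otherwise refuted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Union

from tepars.asr import ASRResult
from tepars.catalog import (
    INAPPLICABLE,
    MISSING,
    Cell,
    CharacterCatalog,
)


class MorphotypeError(ValueError):
    pass


class Verdict(str, enum.Enum):
    SWIMMER = "SWIMMER"
    POSSIBLE = "POSSIBLE"
    NON_SWIMMER = "NON_SWIMMER"


@dataclass(frozen=True)
class MorphotypeRule:
    requirements: dict[int, frozenset[int]]

    def __post_init__(self):
        for cid, allowed in self.requirements.items():
            if not allowed:
                raise MorphotypeError(f"character {cid}: empty allowed set")

    def validate_against(self, catalog: CharacterCatalog) -> None:
        for cid, allowed in self.requirements.items():
            declared = catalog.get(cid).state_codes
            if not allowed <= declared:
                raise MorphotypeError(
                    f"character {cid}: allowed states {sorted(allowed)} not "
                    f"all declared ({sorted(declared)})"
                )


@dataclass(frozen=True)
class MorphotypeCall:
    subject: str
    verdict: Verdict
    failing: tuple[int, ...]

    def __post_init__(self):
        if self.verdict is Verdict.SWIMMER and self.failing:
            raise MorphotypeError("SWIMMER call cannot list failing characters")


def load_rule(path: Union[str, Path]) -> MorphotypeRule:
    requirements: dict[int, frozenset[int]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("char_id"):
                continue
            cid, states = line.split("\t")
            requirements[int(cid)] = frozenset(
                int(s) for s in states.split(",")
            )
    return MorphotypeRule(requirements=requirements)


def load_default_rule() -> MorphotypeRule:
    """The shipped P5-swimmer state-combination rule."""
    ref = resources.files("tepars.data").joinpath("morphotype_rule.tsv")
    with resources.as_file(ref) as path:
        return load_rule(path)


def classify_terminal(
    row: dict[int, Cell], rule: MorphotypeRule, subject: str = ""
) -> MorphotypeCall:
    """Classify one taxon's scores against the rule.

    SWIMMER iff every rule character is scored with an allowed state.
    MISSING on any rule character (with no outright failure elsewhere)
    gives POSSIBLE. Inapplicable scores count as failures: a positively
    required state cannot hold where the character does not apply.
    """
    failing: list[int] = []
    open_call = False
    for cid, allowed in sorted(rule.requirements.items()):
        if cid not in row:
            raise MorphotypeError(f"row does not cover rule character {cid}")
        cell = row[cid]
        if cell == MISSING:
            open_call = True
        elif cell == INAPPLICABLE:
            failing.append(cid)
        elif cell not in allowed:
            failing.append(cid)
    if failing:
        return MorphotypeCall(subject, Verdict.NON_SWIMMER, tuple(failing))
    if open_call:
        return MorphotypeCall(subject, Verdict.POSSIBLE, ())
    return MorphotypeCall(subject, Verdict.SWIMMER, ())


def classify_node(
    asr: ASRResult, node_id: int, rule: MorphotypeRule
) -> MorphotypeCall:
    """Classify a reconstructed ancestor by its MPR sets.

    SWIMMER iff every rule character's MPR set is a non-empty subset of
    the allowed set; POSSIBLE iff every MPR set at least intersects the
    allowed set; NON_SWIMMER otherwise (listing the disjoint
    characters).
    """
    if node_id not in asr.states:
        raise MorphotypeError(f"node {node_id} not in reconstruction")
    node_states = asr.states[node_id]
    failing: list[int] = []
    all_subset = True
    for cid, allowed in sorted(rule.requirements.items()):
        if cid not in node_states:
            raise MorphotypeError(
                f"reconstruction does not cover rule character {cid}"
            )
        mpr = node_states[cid]
        if not mpr or not (mpr & allowed):
            failing.append(cid)
        elif not mpr <= allowed:
            all_subset = False
    label = asr.node_ids[node_id].label or f"node{node_id}"
    if failing:
        return MorphotypeCall(label, Verdict.NON_SWIMMER, tuple(failing))
    if all_subset:
        return MorphotypeCall(label, Verdict.SWIMMER, ())
    return MorphotypeCall(label, Verdict.POSSIBLE, ())


def annotate_tree(asr: ASRResult, rule: MorphotypeRule) -> list[dict]:
    """Verdict plus rule-character state sets for every node (terminals
    and ancestors), serialized for export or plotting."""
    rows = []
    for nid in sorted(asr.node_ids):
        node = asr.node_ids[nid]
        call = classify_node(asr, nid, rule)
        record = {
            "node_id": nid,
            "label": node.label or "",
            "is_leaf": node.is_leaf,
            "verdict": call.verdict.value,
            "failing": ",".join(map(str, call.failing)),
        }
        for cid in sorted(rule.requirements):
            record[f"char_{cid}"] = "/".join(
                map(str, sorted(asr.states[nid][cid]))
            )
        rows.append(record)
    return rows
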