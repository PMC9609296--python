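"""End-to-end run orchestration: validate -> assemble -> search ->
collapse -> consensus -> bootstrap -> root -> ASR -> classify, with a
checksummed manifest of every artifact written."""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from tepars import asr as asr_mod
from tepars import morphotype as morph_mod
from tepars import nexus
from tepars.assembly import (
    assemble_otus,
    concatenate,
    load_otu_map,
    read_alignment,
)
from tepars.catalog import load_catalog, load_default_catalog, validate_matrix
from tepars.search import (
    SearchConfig,
    bootstrap,
    collapse_unsupported,
    mp_search,
    root_on_outgroup,
    strict_consensus,
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    morphology_nexus: str
    out_dir: str
    catalog_path: Optional[str] = None  # None -> shipped catalog
    partition_fastas: dict[str, str] = field(default_factory=dict)
    otu_map_path: Optional[str] = None
    rule_path: Optional[str] = None
    outgroup: Optional[str] = None
    seed: int = 0
    n_addition_replicates: int = 10
    swap: str = "SPR"
    max_trees: int = 20
    bootstrap_reps: int = 0

    # one user-facing seed fans out to fixed per-stage offsets
    @property
    def search_seed(self) -> int:
        return self.seed + 101

    @property
    def bootstrap_seed(self) -> int:
        return self.seed + 202


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str) -> Path:
        path = out / name
        written.append(path)
        return path

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and rethrow
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # -- load + validate ---------------------------------------------------
    catalog = (
        load_catalog(config.catalog_path)
        if config.catalog_path
        else load_default_catalog()
    )
    morphology = stage("load-morphology")(
        nexus.read_morph_nexus, config.morphology_nexus
    )
    report = stage("validate")(validate_matrix, morphology, catalog)
    with open(emit("validation.tsv"), "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["taxon", "char_id", "kind", "message"])
        for v in report.violations:
            writer.writerow([v.taxon, v.char_id, v.kind, v.message])
    hard = [
        v for v in report.violations
        if v.kind != "UNDECLARED_CONTROLLING_STATE"
    ]
    if hard:
        raise PipelineError(
            "validate",
            f"{len(hard)} hard violation(s); see validation.tsv",
        )

    # -- assemble ----------------------------------------------------------
    partitions = [
        stage("read-alignment")(read_alignment, path, name)
        for name, path in config.partition_fastas.items()
    ]
    if config.otu_map_path and partitions:
        otu_map = stage("otu-map")(load_otu_map, config.otu_map_path)
        partitions = stage("assemble-otus")(
            assemble_otus, otu_map, partitions
        )
    combined = stage("concatenate")(
        concatenate, morphology, partitions, catalog
    )
    stage("write-combined")(nexus.write_nexus, combined, emit("combined.nex"))

    # -- search ------------------------------------------------------------
    search_config = SearchConfig(
        n_addition_replicates=config.n_addition_replicates,
        swap=config.swap,
        seed=config.search_seed,
        max_trees=config.max_trees,
    )
    trees, best_length = stage("mp-search")(mp_search, combined, search_config)
    with open(emit("mptrees.nwk"), "w") as fh:
        for t in trees:
            fh.write(t.to_newick(lengths=False) + "\n")
    collapsed = [
        stage("collapse")(collapse_unsupported, t, combined) for t in trees
    ]
    consensus = stage("consensus")(strict_consensus, collapsed)

    # -- bootstrap ---------------------------------------------------------
    supports = {}
    if config.bootstrap_reps > 0:
        boot_config = SearchConfig(
            n_addition_replicates=max(1, config.n_addition_replicates // 3),
            swap=config.swap,
            seed=config.bootstrap_seed,
            max_trees=max(1, config.max_trees // 4),
        )
        supports = stage("bootstrap")(
            bootstrap, combined, boot_config, config.bootstrap_reps
        )
        with open(emit("bootstrap.tsv"), "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["split", "percent"])
            for split in sorted(supports, key=lambda s: (-supports[s], sorted(s))):
                writer.writerow(
                    ["|".join(sorted(split)), f"{supports[split]:.1f}"]
                )
        # map support onto consensus splits
        all_leaves = frozenset(consensus.leaf_labels())
        ref = min(all_leaves)
        for node in consensus.postorder():
            if node.is_leaf or node is consensus.root:
                continue
            side = consensus.leafset(node)
            if ref in side:
                side = all_leaves - side
            if side in supports:
                node.support = round(supports[side], 1)
    with open(emit("consensus.nwk"), "w") as fh:
        fh.write(consensus.to_newick(lengths=False, supports=True) + "\n")

    # -- root + ASR + classify --------------------------------------------
    manifest_extra = {}
    asr_tree = trees[0]
    if config.outgroup:
        asr_tree = stage("root")(root_on_outgroup, asr_tree, config.outgroup)
    else:
        asr_tree = asr_tree.copy()
        asr_tree.rooted = True
    if asr_tree.is_binary:
        result = stage("asr")(
            asr_mod.reconstruct, asr_tree, morphology, catalog, True
        )
        with open(emit("asr.tsv"), "w", newline="") as fh:
            rows = asr_mod.asr_table(result)
            writer = csv.DictWriter(
                fh, fieldnames=list(rows[0]), delimiter="\t"
            )
            writer.writeheader()
            writer.writerows(rows)
        with open(emit("transformations.tsv"), "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(
                ["node_id", "char_id", "parent_states", "child_states"]
            )
            for tr in asr_mod.transformations(result):
                writer.writerow(
                    [
                        tr.node_id,
                        tr.char_id,
                        "/".join(map(str, sorted(tr.parent_states))),
                        "/".join(map(str, sorted(tr.child_states))),
                    ]
                )
        rule = (
            morph_mod.load_rule(config.rule_path)
            if config.rule_path
            else morph_mod.load_default_rule()
        )
        stage("rule-check")(rule.validate_against, catalog)
        annotation = stage("classify")(morph_mod.annotate_tree, result, rule)
        with open(emit("morphotype.tsv"), "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=list(annotation[0]), delimiter="\t"
            )
            writer.writeheader()
            writer.writerows(annotation)
        verdicts = {
            rec["node_id"]: rec["verdict"] for rec in annotation
        }
        with open(emit("annotated.nwk"), "w") as fh:
            id_of = {id(n): nid for nid, n in result.node_ids.items()}
            fh.write(
                result.tree.to_newick(
                    lengths=False,
                    node_comment=lambda n: f"verdict={verdicts[id_of[id(n)]]}",
                )
                + "\n"
            )
    else:
        manifest_extra["asr_skipped"] = (
            "first optimal tree not binary after rooting; supply a "
            "resolved tree"
        )

    manifest = {
        "seed": config.seed,
        "best_length": best_length,
        "n_optimal_trees": len(trees),
        "total_characters": combined.total_characters,
        "artifacts": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in written
        },
        **manifest_extra,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
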