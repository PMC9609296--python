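# tepars

Total-evidence parsimony pipeline for morphology + molecular phylogenetics:

- **character catalog** — a machine-readable catalog of 59 multistate
  morphological characters with hierarchical *inapplicable-if* dependencies
  (a controlling character's state can switch dependent characters off),
  plus validation of scored matrices against it;
- **matrix assembly** — aligned FASTA gene partitions, chimeric OTU mapping
  (morphology of one species combined with sequences of close relatives),
  and concatenation into a combined supermatrix with a NEXUS CHARSET
  partition map;
- **parsimony core** — equal-weights unordered (Fitch) tree length and
  most-parsimonious-reconstruction (MPR) state sets, exact on binary and
  multifurcating trees;
- **tree search** — random-addition-sequence maximum-parsimony search with
  NNI/SPR/TBR branch swapping, collapsing of branches that carry no change
  under any MPR, strict consensus, nonparametric bootstrap with fractional
  split credit, and outgroup rooting;
- **ancestral state reconstruction** — per-node MPR sets for every
  character, unambiguous branch transformations, and stem-species state
  queries for named clades;
- **morphotype classifier** — a rule file of required character states
  (shipped: the P5-swimming-crab state combination) applied to terminals
  and reconstructed ancestors with a three-valued verdict
  (SWIMMER / POSSIBLE / NON_SWIMMER);
- **synthetic data** — Yule trees, dependency-respecting Mk morphology with
  known ancestral states, GTR+G+I nucleotide partitions, and a miniature
  end-to-end study generator, so the whole pipeline is testable offline.

## CLI

The console script `tepars` exposes the pipeline stages:

```sh
# generate a self-contained synthetic study
tepars simulate --seed 1 --out-dir study/

# validate a morphology matrix against the shipped 59-character catalog
tepars validate-matrix --matrix study/morphology.nex

# assemble the combined supermatrix
tepars assemble --morphology study/morphology.nex \
    --partition 16S=study/16S.fasta --partition COI=study/COI.fasta \
    --partition NADH1=study/NADH1.fasta --partition H3=study/H3.fasta \
    --otu-map study/otu_map.tsv --out combined.nex

# search, consensus, bootstrap, rooting, ASR, classification
tepars mpsearch --matrix combined.nex --addseq 10 --swap TBR --seed 2000 --out trees.nwk
tepars consensus --trees trees.nwk --out consensus.nwk
tepars bootstrap --matrix combined.nex --reps 100 --seed 1 --out supports.tsv
tepars root --tree trees.nwk --outgroup T1 --out rooted.nwk
tepars asr --tree rooted.nwk --matrix study/morphology.nex --out asr.tsv
tepars classify --tree rooted.nwk --matrix study/morphology.nex --out verdicts.tsv

# or everything at once, with a checksummed manifest
tepars run --morphology study/morphology.nex \
    --partition 16S=study/16S.fasta --partition COI=study/COI.fasta \
    --partition NADH1=study/NADH1.fasta --partition H3=study/H3.fasta \
    --otu-map study/otu_map.tsv --outgroup T1 --seed 7 \
    --bootstrap-reps 100 --out-dir run/
```

## Data fixtures

`src/tepars/data/` ships plain-text fixtures: the 59-character catalog
(`characters.yaml`), the study OTU map (`otu_map.tsv`, 34 morphological
taxa of which one has no sequence data), the morphotype rule
(`morphotype_rule.tsv`), and reference terminal scores for four taxa
(`example_scores.tsv`).

## Conventions

- Missing data is `?`, inapplicable is `-`; both are scored as full
  ambiguity under the unordered model (gaps as missing).
- Partition intervals are 1-based closed, matching NEXUS CHARSET.
- Every stochastic operation (search, bootstrap, simulation) is
  deterministic given its seed.
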