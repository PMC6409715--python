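# classiphage

Taxon-specific profile-HMM libraries for bacteriophage classification and
prophage detection.

## The problem

Most phage genomes recovered from sequencing projects and metagenomes cannot
be placed in an ICTV family: phages are polyphyletic, there is no universal
marker gene, and pairwise alignment loses sensitivity quickly between
distantly related genomes. `classiphage` implements a profile-HMM approach:
starting from a set of phage genomes already labeled with a family
(e.g. *Ino-*, *Myo-*, *Podo-*, *Siphoviridae*), it learns one profile HMM per
conserved protein family per phage family, and then uses the combined hit
pattern of those models — never a single hit — to

1. **classify** unlabeled phage genomes into families,
2. **recover** protein-coding genes missing from annotations, by scanning
   six-frame translations of intergenic regions, and
3. **identify and classify prophages** inside bacterial host genomes from
   runs of consecutive gene-level hits.

It is aimed at phage genomics and microbiome researchers with a set of
annotated GenBank files and a shell.

## Method

Training, for each phage family *F* with labeled genomes:

- extract all annotated CDS proteins; remove redundant sequences by greedy
  incremental clustering (global identity over the shorter sequence,
  threshold 0.9, longest first);
- build an all-vs-all similarity graph over the representatives (edge weight
  `min(−log₁₀ E, 200)` from a phmmer-style search, edges kept at `E ≤ 1e−5`)
  and partition it with the Markov clustering algorithm (expansion
  `M ← M²`, inflation `M_ij ← M_ij^r` with column renormalization, `r = 2`);
- align each cluster of ≥ 5 proteins (mafft) and build a profile HMM
  (`hmmbuild` semantics via pyhmmer), emitting its consensus sequence;
- prune members whose local alignment covers < 50 % of the consensus, then
  iterate *scan → filter → membership update → merge* on the master protein
  set until a fixpoint: proteins hit but unassigned are added, members no
  longer hit are removed, redundancy-removed proteins are never re-added,
  and models with identical hit ∪ member sets are merged.

Every hit carries the full-sequence E-value and bit score, the best domain's
coordinates, model coverage `(hmm_to − hmm_from + 1)/M`, and a normalized
score `bits/(3M)` (bit score per consensus base pair) that makes models of
different lengths comparable. Hits are rejected unless
`coverage ≥ 0.5`, `bits > 0` and `E ≤ 1.5 × 10⁻⁸`.

Classification aggregates filtered hits per family; the family hitting the
most *distinct* models wins (summed normalized score breaks ties) and must
hit at least 2 distinct models — a single matching protein is never enough.
Prophage loci are runs of > 3 consecutive hit genes (up to 2 intervening
non-hit genes tolerated) on a host replicon, classified by the same rule and
optionally benchmarked against an external prophage-coordinate table.

## Worked example

A fully synthetic run (no downloads): generate two phage families of eight
genomes each, hold out the last two genomes of each family, train on the
rest, and classify the held-out genomes.

```sh
classiphage fixtures --n-families 2 --genomes-per-family 8 --seed 11 --out all
mkdir query && mv all/familyA_g0[67].gbk all/familyB_g0[67].gbk query/ && mv all train
classiphage run --gbk train --classify-gbk query --out out
cat out/calls.tsv
```

```
genome	call	evidence
familyA_g06	familyA	{"familyA": [8, 8, 3.5025], "familyB": [0, 0, 0.0]}
familyA_g07	familyA	{"familyA": [8, 8, 3.4339], "familyB": [0, 0, 0.0]}
familyB_g06	familyB	{"familyA": [0, 0, 0.0], "familyB": [8, 8, 3.4103]}
familyB_g07	familyB	{"familyA": [0, 0, 0.0], "familyB": [7, 7, 3.0484]}
```

Each evidence triple is `[distinct models hit, filtered hits, summed
normalized score]` per family: `familyA_g06` is hit by 8 distinct familyA
models (summed normalized bit score 3.50) and by nothing from familyB, so it
is called familyA. A genome hit by fewer than two distinct models would be
reported `unassigned`; exact ties are `ambiguous`.

The other subcommands (`extract`, `cluster`, `build-hmms`, `refine`,
`classify`, `recover-cds`, `scan-host`) expose the individual stages;
`scan-host` writes prophage loci as GFF3 and, given `--regions`, an overlap
report against an external coordinate table.

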