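# Methods

## Overview

`classiphage` builds family-specific profile-HMM libraries from labeled
phage genomes and applies them to three tasks: family classification of
phage genomes, recovery of unannotated CDS from intergenic DNA, and
prophage locus detection in bacterial hosts. This note records the model,
the tunable parameters and their defaults, what the synthetic benchmark
does and does not show, and the numerical choices made where the design was
genuinely open.

## Model library construction

**Redundancy removal.** Greedy incremental clustering in the CD-hit style:
sequences are processed by decreasing length; each joins the first existing
representative with global identity ≥ `identity_threshold` (default 0.9,
that tool's customary default), where identity is the number of identical
aligned residues divided by the shorter length (BLOSUM62, gap open −10,
extend −1). A shared-4-mer prefilter (≥ 50 % of the query's 4-mers) skips
alignments that cannot reach any threshold above 0.5. We do not reproduce
CD-hit's short-word heuristics bit-for-bit; the contract is the greedy rule,
not the implementation. Removed proteins are retained in a redundancy map
because the refinement rules below must never re-admit them.

**Similarity graph.** The original description names MCL but not the edge
definition. We use an all-vs-all phmmer-style search (pyhmmer), keep pairs
with `E ≤ evalue_cutoff` (default 1e−5, the conventional protein-homology
cutoff), and weight edges `min(−log₁₀ E, 200)`; the cap avoids infinite
weights on identical pairs, and the two search directions are symmetrized by
maximum. Bit-score weighting is available (`weight="bitscore"`).

**MCL.** Implemented on scipy sparse matrices: self-loops of weight 1,
column-stochastic normalization, then alternate expansion (matrix squaring)
and inflation (entrywise power `r`, default 2.0 — the canonical default —
then renormalization), pruning entries below 1e−8, until the largest entry
change is < 1e−6 or 100 iterations. Clusters are the connected components
of the converged flow's support, which yields a partition with deterministic
(lowest-node-id) ordering. The test suite holds this implementation to a
dense brute-force oracle on small random graphs.

**Per-family clustering.** Proteins are clustered within each family label,
so every cluster — and every model — carries exactly one family. Clusters
with fewer than `min_cluster_size = 5` members are dropped with a logged
size; these are the protein families for which no model can be built for
lack of diverse sequences.

**Alignment and model building.** Clusters are aligned with mafft
(`--auto`); member order is fixed, so alignments are deterministic. Models
are plan7 profiles built with pyhmmer's default construction and weighting
and a fixed builder seed, so rebuilding from the same alignment is
byte-identical. Each model stores its emitted consensus (the most probable
match-state residues) and the registry of member proteins.

**Normalized score.** Hit bit scores are divided by the consensus size *in
base pairs*, i.e. `bits/(3M)` for a model of `M` match states. The factor 3
honors the bp unit of the source heatmaps even though consensus sequences
are proteins; `norm_unit="aa"` switches to plain `bits/M`. Coverage is
measured on the model, `(hmm_to − hmm_from + 1)/M`, the standard
profile-search convention. Per (model, target) pair only the best-scoring
domain contributes coordinates; multi-domain accounting is out of scope.

**Hit rejection.** A hit is discarded if model coverage < 0.5, bit score
≤ 0, or E-value > 1.5 × 10⁻⁸. The source phrasing of these three cut-offs is
grammatically ambiguous about direction; we read them as rejection criteria,
which is the only reading under which they are restrictive.

## Refinement

Consensus-coverage pruning runs once at initialization (the alternative —
inside the scan loop — is redundant because the loop's own membership rule
re-tests members): cluster members whose best local alignment to the
consensus covers < `coverage_threshold` (default 0.5) of it are removed, and
models left with < 2 members are retired, since a single-sequence
"alignment" cannot define a meaningful profile.

Each refinement round scans the master protein set, filters hits, and
updates each model's membership to
`(members ∩ hits) ∪ (hits − assigned − redundancy-removed)`; models whose
hit ∪ member sets coincide exactly are merged under the lexicographically
smallest id (exact set equality is required by the stated merge rule; a
Jaccard relaxation exists in the code but is off by default). The loop stops
when a full round changes nothing (`changed=False` on return), when a
bounded 3-state history detects an oscillation, or after `max_rounds`
(default 20) with a warning. Models are processed in id order, so the result
does not depend on dictionary iteration order.

**Intergenic CDS recovery.** Intergenic gaps ≥ `min_intergenic_nt` (default
90 nt; no floor is stated in the source, and 30 codons is a common lower
bound for a detectable domain) are translated in all six frames — a single
frame would miss reverse-strand genes — and every maximal stop-free stretch
≥ `min_orf_aa` (30) becomes a candidate, without a start-codon requirement,
because the target is genes missed by annotation pipelines. Candidates
passing the rejection cut-offs are folded back into the matching model's
alignment and the model rebuilt; a before/after bit-score report on the
previous members lets users verify whether the extra sequences changed
anything (on well-sampled synthetic families they do not — the rebuilt
models hit exactly the same member sets).

On circular replicons the 3′ and 5′ flanking gaps are merged into a single
wrap-around region (phage genomes are frequently circular; whether the
original work did this is unstated, and treating the origin as a hard break
would split any gene spanning it).

## Classification and prophage calling

A model is a **taxonomic indicator** when its own family supplies ≥ 5
filtered hits (consistent with the 5-protein cluster floor) and a strictly
greater mean normalized score than every other family. No formal test
statistic is given in the source; strict mean dominance is the default and a
one-sided Mann–Whitney option (`test="mannwhitney"`) is exposed.

**Genome classification** aggregates filtered hits per family. The primary
criterion is the number of *distinct* models hit — robust against one
promiscuous protein — with summed normalized score as tie-break; the winner
must reach `min_distinct_models = 2` (one matching protein is explicitly
insufficient) and strictly beat the runner-up, else the call is `ambiguous`
(exact tie) or `unassigned`.

**Prophage loci** are runs of hit genes in gene-ordinal space (robust to
intergenic length variation) allowing ≤ `max_gene_gap = 2` intervening
non-hit genes — tolerating unannotated or non-family phage genes inside a
prophage — with at least `min_consecutive = 4` hit genes ("more than
three"); 3 is configurable for small filamentous-phage loci. Runs touching
both ends of a circular replicon are joined across the origin. Locus family
calls use the classification rule restricted to supporting hits, with
`unresolved` replacing both failure modes. External coordinate tables
(replicon, start, end TSV) are compared by interval overlap ≥ 0.5 of the
shorter interval, yielding the confirmed / novel / missed triad.

## Synthetic benchmark

The generator emulates exactly the structure the method exploits: each
family owns `n_protein_families` ancestral proteins drawn i.i.d. from a
uniform amino-acid model (so inter-family identity sits at the ~5 %
background and any cross-family hit is a bug signal, not shared ancestry);
each genome carries each ancestor with probability `presence_prob = 0.9`
and diverges it by uniform point substitutions at rate `divergence = 0.3`;
genes are reverse-translated with random synonymous codons, placed on random
strands with 50–200 nt spacers, and written as GenBank with /translation
qualifiers. Hosts are unrelated background genes with an optional contiguous
implanted phage block; a manifest records all truth coordinates. All
randomness derives from one master seed through named child seeds, so every
fixture regenerates byte-identically.

The standard study is 4 families × 12 genomes with 10 protein families per
family; held-out evaluation removes the last 2 genomes per family (~20 %,
stratified); the prophage benchmark uses 50 hosts of ~30 kb with one 10-gene
implant each plus 50 implant-free hosts. These sizes keep a full training
run around half a minute on one CPU while leaving ≥ 7 members per cluster.

**What passing does not show.** Evolution is substitution-only (indels are
available via `indel_rate` but off by default), so alignment coverage stays
near 1 and the thresholds are exercised in isolation from aligner quality.
Real phage data add domain-level mosaicism, shared gene families across
related tailed-phage taxa (which produce legitimate cross-matches), HGT,
compositional bias, and annotation noise; performance on the synthetic
study is an upper bound, and the cross-match matrix will not be 100 %
exclusive on real families.

## Degenerate inputs and tie-breaks

Records without CDS parse to empty feature lists with a warning; duplicate
locus tags get ordinal suffixes; CDS lacking /translation are translated
from the span with the bacterial code (table 11); non-standard residues map
to `X` and stop symbols are stripped. Overlapping CDS produce no
negative-length intergenic regions. Everywhere a tie could arise —
cluster ordering, merge naming, classification — the lexicographically
smallest id wins, so the pipeline is reproducible without a seed.

## Known limitations

Locus boundaries are gene-span only; no att-site or tRNA-target refinement.
Multi-domain proteins contribute a single best domain per model. The E-value
feeding the rejection cut-off depends on the scanned database size, as in
the original tool chain; bit scores are database-independent and are the
quantity asserted in cross-database tests. Model building requires the
external `mafft` executable.
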