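# Methods

`cd300evo` analyses the evolution of a paired immune-receptor family — an
inhibitory receptor (the CD300A role, gene label `A`) and its activating
partner (the CD300C role, label `C`) — across a set of primate species. The
package has two halves: an analysis pipeline (pseudogene calling, functional
motif conservation, gene-conversion detection, distance phylogenetics,
synteny states) and a birth-and-death sequence simulator that generates
fully ground-truthed inputs for every analysis stage. This note documents
the models, the defaults and why they were chosen, and what the simulator
does and does not emulate.

## Coordinates and conventions

All residue and site positions are 1-based inclusive, in the human-style
reference numbering used for these receptors in the literature (N83, E191,
Y267). FASTA headers are `species|gene|accession`; `gene` ∈ {A, C,
outgroup}. Gene-label semantics matter: the inhibitory paralog is `A`, the
activating paralog is `C`, and the inactivation machinery of the simulator
is (by default) asymmetric between them.

## Alignment

Pairwise alignment is global Needleman–Wunsch/Gotoh with affine gaps; a gap
of length k scores `open + (k−1)·extend`. Protein scoring is BLOSUM62 with
open −10 / extend −1. Traceback ties are resolved in a fixed order
(substitution ≻ gap in the second sequence ≻ gap in the first), so outputs
are bit-identical across platforms. Multiple alignment is progressive:
cosine distances on 3-mer count profiles, UPGMA guide tree, profile–profile
merges under sum-of-pairs scoring, gap-only columns removed. This is a
functional stand-in for a standard progressive aligner, chosen because the
downstream inferences depend on alignment correctness, not on any
particular program's heuristics; on simulated input (which has no indel
evolution) the MSA reproduces the true alignment exactly, which is what the
tests assert.

Nucleotide alignments use match +2 / mismatch −3 / open −16 / extend −4.
The stiff gap costs are deliberate: these alignments compare homologous
coding sequences for frameshift detection, where a real frameshift pays for
its single gap many times over by restoring the downstream reading frame,
while cheap gaps allow compensating gap pairs to masquerade as matches in
diverged regions and generate spurious frameshift calls. With these costs
the frameshift caller measures sensitivity 1.0 and false-positive rate 0.0
on simulated genes at primate-scale divergence (the reproduction script
recomputes this).

Codon alignments are produced by threading CDSs through protein alignments
(back-translation), so translating a codon row always reproduces its
protein row.

## Pseudogene and truncation calling

A sequence is a **pseudogene** iff it carries ≥1 premature stop codon or
frame-breaking indel. A stop is *premature* when it falls before 90% of the
reference length; the terminal stop is never counted. The 90% threshold
(configurable) keeps near-C-terminal polymorphic stops from flagging; any
value in roughly 0.8–0.95 behaves identically on the simulator, whose
lesions are placed mid-gene. A frameshift is any maximal single-row gap run
in the reference/query nucleotide alignment whose length mod 3 ≠ 0 —
in-frame indels (e.g. a clean codon deletion) never change a verdict.

A sequence with an intact frame but a *missing domain* — ≥80% of an
annotated domain span gapped in the query — is **truncated**, deliberately
not a pseudogene: a receptor lacking its transmembrane and cytoplasmic
domains is almost certainly non-functional, but it does not meet the
stop/frameshift criterion and the two kinds of evidence are kept distinct.
**Absent** is an input-level fact (no record supplied), never inferred.

## Motif scanning and conservation

Scanned elements, anchored at their diagnostic residue:

| class | rule | anchor |
|---|---|---|
| classical ITIM | `[ILVS] x Y x x [LV]` | Y |
| non-classical ITIM | `[ILVST] x Y x x [LVI]` | Y |
| TM charge | any of D/E/K/R in the TM span | charged residue |
| sequon | `N x [ST]`, x ≠ P | N |
| cysteine | C in a span | C |

The classical rule is a strict subset of the non-classical one, so every
classical hit is also a non-classical window; scanners report the most
specific class. Wildcard positions admit the 20 standard residues only — a
window containing `X` (ambiguous translation) never matches, which keeps
uncertain translations from creating motifs. The N-x-[S/T] proline
exclusion is the standard biochemical rule and is switchable.

The conservation report projects every annotated reference site onto every
species via the alignment and partitions rows into conserved / substituted
/ gapped (the three counts always sum to the number of rows). Two notes are
attached where relevant: a charged TM residue replaced by one of opposite
sign is a `charge_flip` (the E→K pattern that plausibly breaks
adaptor-protein coupling), and an ITIM tyrosine whose surrounding window
fails the consensus is `anchor_only` — the tyrosine survives but its
context is degraded, and the report makes no functional claim either way.

## Gene-conversion detection

For each species carrying both paralogs, a sliding window (default 30 aa,
step 5) over the protein alignment computes

- `ident_within`: column identity between the species' own A and C copies,
- `ident_between`: mean identity of same-gene (ortholog) comparisons
  against all other species,
- `delta = ident_within − ident_between` (per-column mean contrast).

Columns gapped in either of the species' own paralogs are excluded;
ortholog comparisons gapped in the partner are dropped per comparison;
windows with <50% usable columns are skipped. A converted tract homogenizes
the paralogs locally, producing windows where within-species identity
exceeds the ortholog background.

**Permutation null.** The default null (`method="columns"`) permutes the
columns of the analysis region jointly across all rows and re-reads every
window, asking whether a *contiguous* window carries more within-pair
excess than a random draw of the same number of columns. Under the
simulator's i.i.d.-site substitution model columns are exchangeable, and
the measured type-I error at α = 0.05 is ≈ 0.05 (the reproduction script
recomputes it; the small residual excess traces to codon-level column
dependence introduced by stop-codon rejection). An alternative null that
reshuffles the A/C gene labels within each species (`method="labels"`) is
provided for comparison, but it is not the default: whenever orthologs are
systematically more similar than cross-paralog pairs — i.e. in any dataset
with appreciable post-duplication divergence — relabelling can only lower
the ortholog term, so that null is degenerate (p ≈ 1 everywhere, no power)
and cannot be calibrated. p-values use the add-one estimator
`p = (1 + #{null ≥ obs}) / (n_perm + 1)` with n_perm = 999 by default, and
identical seeds give bit-identical output.

**Shared motifs.** The lineage-level evidence style — a string present in
both paralogs of every member of a family or species while rare outside it
— is formalized as: maximal runs of ≥ `min_len` columns (default 1, since a
single shared residue can be informative) where all member rows carry one
identical state, kept when ≤ 10% of outside species carry the same string
in either gene. Shared in-frame gaps count as shared states, so a deletion
present in both paralogs of one species is reported like any other shared
motif.

## Phylogenetics

Distances are protein p-distances with pairwise deletion, optionally
Poisson-corrected (`−ln(1−p)`; saturation p ≥ 1 is an error, not an
infinity). Trees are standard neighbor joining with Q-matrix ties broken by
the lowest index pair and negative branch lengths clamped to zero; NJ on
Poisson distances stands in for likelihood methods because the inference
the pipeline reads off the tree — whether sequences cluster by species or
by gene — is a topology-level signal that distance methods recover (NJ
reconstructs every additive matrix exactly; the reproduction script
verifies this on 100 random 5–8 leaf trees). Bootstrap is column resampling
with replacement; supports are the percentage of replicate trees containing
each internal bipartition, stored as internal node labels.

The concerted-evolution statistic is the **paralog sister fraction**: the
fraction of two-paralog species whose A and C copies form a cherry (two
leaves adjacent to the same internal node of unrooted degree 3). Under
independent divergence the genes form two clades and the fraction is ~0;
under per-species homogenization it approaches 1. It is a function of the
unrooted topology only.

## Synteny

The canonical locus is the interval between two anchor genes (GPRC5C and
RAB37 for this cluster). A family gene between the anchors (by start
coordinate, strand-agnostic) is `present_in_locus`; elsewhere `relocated`;
unannotated `absent`. `locus_intact` requires both anchors on one
chromosome; split anchors are reported broken with a warning and genes are
judged against the interval around whichever anchor shares their
chromosome. No coordinate liftover or rearrangement-history inference is
attempted — the reasoning is gene-order level, as in the source analyses.

## The simulator

An ancestral CDS (default 897 nt = 299 codons, the inhibitory receptor's
length) is duplicated at the root into A and C, each first diverging along
a stem of 0.2 substitutions/site (the paralogs are an ancient duplication),
then both evolving along a 12-leaf primate-family caricature tree with
root-to-tip depths of ~0.10–0.14 substitutions/site. Per branch, in order:

1. **Substitution** — Jukes–Cantor per site at branch length × scale.
   Substitutions creating an in-frame stop are rejected on functional genes
   (a minimal stand-in for purifying selection); this slightly depresses
   the realized rate (<~2% of identity) and introduces weak codon-level
   column dependence.
2. **Gene conversion** — Poisson(rate) events; each copies a codon-aligned
   tract of geometric length (default mean 45 nt, the scale of the shared
   motifs the analysis looks for) from one paralog to the other, random
   direction. Conversion stops once either paralog is inactivated,
   mirroring the observed breakdown of concerted evolution after
   pseudogenization. A `force_terminal_conversion_nt` mode plants exactly
   one fixed-length tract on every terminal branch for power studies.
3. **Inactivation** (gene C only by default; symmetric mode available) —
   whole-gene loss with probability 0.02/branch, else pseudogenization with
   probability 0.02/branch: a random stop codon or a 1-nt frameshift
   deletion placed mid-gene (5–85% of length). Once a lesion is recorded
   its codon is frozen against later substitution, so truth labels remain
   readable from the sequence; inactivation states inherit to descendants.

The default per-branch inactivation probabilities put the expected number
of pseudogenization/loss events per run at the low single digits across
the tree — the regime of the empirical survey (3 pseudogenes and 4 losses
across 33 species, all in gene C).

No other indel evolution is simulated. This is a deliberate trade: true
alignments stay column-trivial (the root coordinate frame, with gaps only
at frameshift deletions), so every event in the emitted truth table has
exact coordinates and recovery tests are exact. Consequently the simulator
does not exercise alignment quality under indel-rich evolution, rate
heterogeneity across sites or lineages, codon usage or dN/dS structure, or
assembly/annotation artifacts — passing recovery tests demonstrates
correctness of the statistics under the stated generative model, not
robustness to those features of real data. Random streams are split per
branch (seeded by CRC32 of the branch's leaf set), so adding species leaves
existing branches' evolution unchanged.

The packaged reference fixtures are synthetic: inert filler residues
carrying the canonical annotated sites at their human positions — for the
A-like protein (299 aa: signal 1–17, ECD 18–180, TM 181–201, cytoplasmic
202–299) the C36/C103 disulfide pair, N83/N92 sequons and four ITIMs
(classical anchors Y231/Y255/Y267 plus non-classical Y282); for the C-like
protein (224 aa: signal 1–20, ECD 21–183, TM 184–204, cytoplasmic 205–224)
the C43/C110 and C57/C65 pairs, N90/N99 sequons and the single TM glutamate
E191. They exist so the scanners can be exercised against known layouts
without any database access; they are not database sequences.

## Reproduction-script problem sizes

`scripts/acceptance.py` recomputes every headline number from scratch at
these sizes, chosen to give stable estimates at interactive runtimes
(~15 s total): 150 random pairs (length ≤ 6) for the alignment-score
oracle; 1,000 random 300-aa proteins for the scanner/regex comparison; 100
random additive matrices for NJ recovery; 8 conversion-free simulations
(≈5,200 windows, n_perm = 999) for type-I calibration; 10 simulations × 12
forced 45-nt tracts for detection power; 15 elevated-rate symmetric
simulations (≈300 genes) for pseudogene sensitivity/FPR; and a 5-point
conversion-rate grid (0–8 events/branch, 20 replicates each) for the
clustering sweep. The sweep uses 300-nt tracts so the top of the grid
reaches the near-full-homogenization regime that the cherry statistic is
designed to read; with the 45-nt default the fraction stays near zero at
every attainable rate because most of the gene never converts.

## Known limitations

- The label-shuffling permutation null is provided but degenerate outside
  the exchangeable-paralog regime; the column null assumes approximate
  column exchangeability and will be anticonservative under strong,
  spatially structured rate heterogeneity.
- Real-data mode trusts the input alignment; the progressive MSA has no
  iterative refinement, and badly misaligned regions would propagate into
  windows and conservation calls.
- The domain-truncation rule needs a reasonable domain annotation; the
  proportional-scaling fallback used for simulated references is crude for
  real proteins with unusual domain architecture.
- Synteny classification is order-only; it cannot distinguish relocation
  from assembly fragmentation.
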