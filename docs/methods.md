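# Methods

This note documents the models and procedures implemented in `genefam`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical choices that make runs
deterministic.

## Family identification and naming

Membership is decided purely from pre-computed domain hits (HMMER3
per-domain tabular output). A hit supports membership when its
full-sequence E-value is **strictly below 1e-4**; the boundary value is
excluded. Each protein's subfamily is the scheme entry containing its
smallest-E-value diagnostic domain; ties break by scheme order. The
default scheme maps Pfam accessions to the six chaperone subfamilies
(SHSP: PF00011; HSP40: PF00226, PF01556; HSP60: PF00118; HSP70: PF00012;
HSP90: PF00183; HSP100: PF02861, PF10431) and is configurable.

Names are `<stem>.<ordinal>` with ordinals assigned per subfamily by
(chromosome, gene start) using natural numeric chromosome ordering
("chr2" before "chr10"). Assemblies carry no centromere/arm annotation,
so "ordered along the chromosome" is operationalized as ascending
coordinate. Ties at identical coordinates break by protein id and are
logged. Naming is idempotent and independent of input order.

Each subfamily carries an advisory molecular-weight window. A member
falling outside its window is flagged in the log and in the output table
but never reassigned: real families retain such outliers (e.g. a ~97 kDa
protein classified with HSP70s by its domain content), and the domain
evidence outranks the weight heuristic.

Proteins with no diagnostic domain can still be *flagged* for manual
review when they align to an accepted member at ≥ 50 % identity over
≥ 70 % coverage (`flag_homology_candidates`); they are never
auto-accepted. This replaces a database-wide confirmatory BLAST step with
a self-contained homology check.

## Physicochemical statistics

Molecular weight is the sum of average residue masses (Expasy table)
plus one water (18.0153 Da); `X` contributes the mean residue mass.
The isoelectric point is the root of the Henderson–Hasselbalch net-charge
function using the **EMBOSS pKa set** (N-term 8.6, C-term 3.6, C 8.5,
D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1). Net charge is strictly
decreasing in pH, so bisection on [0, 14] to 1e-3 pH finds the unique
root; tests verify agreement with a 1e-3-step grid scan within 2e-3 pH.
Published pI values computed by other programs use different pKa tables
and typically agree only to a few tenths of a pH unit; exact
reproduction of third-party pI columns is therefore not promised.

## Pairwise alignment and duplication classification

The global aligner is Needleman–Wunsch with affine gaps (Gotoh's
three-state recurrence). A gap of length L costs
`gap_open + (L − 1) · gap_extend`; defaults are BLOSUM62 with open 10,
extend 0.5. Traceback is deterministic with tie order diagonal > up >
left. Setting open = extend recovers a linear gap cost. The aligner is
validated against an independent brute-force recursion with memoization
(exact score equality).

From an alignment the package reports, over columns where both rows carry
a residue ("both-residue columns"):

* **coverage** — both-residue columns / length of the longer sequence;
* **similarity** — fraction of both-residue columns with a positive
  substitution score ("similarity" has no universal definition; the
  positive-BLOSUM62 convention is standard and configurable);
* **identity** — fraction with equal residues (identity ≤ similarity).

A pair is paralogous iff coverage > 0.75 **and** similarity > 0.75, both
strict. A paralogous pair is **tandem** iff the genes share a chromosome,
at most 5 annotated genes lie wholly between the two gene spans, and the
start-to-start distance is ≤ 100 kb; otherwise it is **segmental**.
"Wholly between" and "start-to-start" resolve the inherent ambiguity of
"separated by N genes within a region" deterministically; both knobs
(`max_intervening`, `max_span_bp`) are configurable and echoed in run
config output. Criteria are applied to protein sequences.

## Multiple alignment, distances, trees

The progressive aligner builds a UPGMA guide tree on 3-mer count
distances (1 − shared-3-mer fraction), then merges profiles by
profile–profile Needleman–Wunsch with sum-of-pairs column scoring and a
linear per-row gap penalty (default 4.0). It is intended for
moderate-size families; externally computed alignments can be imported
as aligned FASTA for users who need a production MSA tool's output.

Pairwise distances use the Jukes–Cantor correction
`d = −b·ln(1 − p/b)`, where `p` is the mismatch fraction over
both-residue columns (pairwise deletion — gaps never count as
mismatches) and `b = 19/20` for proteins, `3/4` for nucleotides. Pairs
with `p ≥ b` are flagged saturated and cannot enter tree building.

UPGMA joins the closest pair of clusters, with the new height = join
distance / 2 and size-weighted distance updates. Distance ties break on
the lexicographically smallest member ids, and Newick output orders
children canonically (by smallest leaf id) with branch length = parent
height − child height, so identical inputs yield byte-identical trees
regardless of input order. Trees are ultrametric by construction; tests
assert equal leaf depths to 1e-9 and equivalence with a naive oracle
that re-averages all leaf-pair distances at each step. `cut_groups(tree,
k)` removes the k−1 highest joins (ties again by smallest leaf id).

Motif discovery is deliberately not implemented; a per-subfamily
shared-k-mer report (top five length-10 substrings ranked by the number
of members containing them) provides the qualitative "members of a
subfamily share sequence blocks" summary.

## Promoters and heat-shock elements

The promoter is the 1 kb (configurable) immediately upstream of the
gene's translation start on its own strand: for "+" genes the block
ending just before the gene start; for "−" genes the reverse complement
of the block just after the gene end. Chromosome edges truncate with a
warning. The HSE pattern 5′-nGAAC-3′ matches any real base (A/C/G/T,
never N) followed by literal GAAC; overlapping occurrences count, and the
`n` must be an actual base, so a GAAC at the very 5′ end of the promoter
is not a match. Only the sense strand is scanned by default — whether
reverse-strand occurrences should count is genuinely open, so the choice
is an explicit flag (`--both-strands`) recorded in the output summary.
BED output reports each 5-base motif occurrence in genome coordinates.

## Expression

`fpkm(g, s) = counts(g, s) · 1e9 / (length(g) · total(s))`; totals
default to column sums but should be the per-sample mapped-fragment
totals when the matrix covers only a gene family (a family is a tiny,
composition-biased slice of a library). Heatmap standardization z-scales
each gene row with the sample (n−1) standard deviation; constant rows
become zeros with a warning. Genes with zero expression in every sample
are dropped before standardization and the count is logged. Pattern
groups come from UPGMA on Euclidean distances between z-rows, cut to k
(default 3) groups, numbered deterministically by smallest gene id.

qPCR fold change for target *t*, treated sample vs control:
`E_t^(Ct_ctrl − Ct_trt) / NF`, where `NF` is the geometric mean over the
reference genes *r* of `E_r^(Ct_ctrl − Ct_trt)`. Replicate Cts are
arithmetic-averaged before use. Amplification efficiency defaults to 2.0
(perfect doubling) because no standard curves are modeled; it is
settable per gene. Swapping reference genes leaves the ratio unchanged
(geometric-mean symmetry), and control-vs-control is exactly 1. A
one-way ANOVA helper (`replicate_anova`) compares a gene's replicate Cts
across samples.

## Synthetic data: what it emulates, and what passing tests show

`make_genome` builds uniform-background chromosomes (GC 50 %) with
non-overlapping strand-mixed genes (1–3 exons of 100–350 bp, introns
50–150 bp, intergenic gaps 5–8 kb), member proteins as mutated copies of
per-subfamily random templates (140 aa, 40-residue window reported as a
domain hit with log-uniform E-value in [1e-30, 1e-6]) and decoy proteins
with no hits. The default per-residue mutation rate is **0.35**: members
stay clearly homologous within a subfamily while their pairwise
similarity sits well below the 75 % paralog threshold, as in real
families where only a few pairs qualify as duplicates; lower it to
emulate recently expanded, tight families.

`plant_duplicates` inserts tandem copies in the gap right after their
source gene (zero intervening genes, < 100 kb) and segmental copies on a
different chromosome, with protein similarity driven to the target
(default 0.9, ± 2 %) by mutating exactly the required number of
positions to non-positive-scoring residues and verifying by alignment.
`plant_promoter_sites` scrubs a promoter of accidental GAAC text, plants
the exact requested number of non-overlapping nGAAC sites, re-scans to
confirm the count, and refuses overlapping promoter windows.
`make_counts` draws negative-binomial counts with mean
`base_mean · (length/1 kb) · 2^lfc` (defaults: base_mean 200 →
mean ≈ 240 at 1.2 kb, dispersion 0.02 — technical-replicate-level
noise) and records the library size for FPKM. `make_ct` produces
`Ct = 25 − log_E(expression) + N(0, 0.2 cycles)` with three replicates
and two flat reference genes.

Everything is deterministic in (seed, parameters) and serialized next to
the outputs as `truth.json`. The generator does **not** emulate codon
structure, splice signals, GC heterogeneity, or HMM score statistics
(E-values are sampled, not computed), so passing recovery tests
demonstrates the correctness of the pipeline's logic under controlled
conditions — not HMMER-level sensitivity or specificity on real genomes.

## Problem sizes and statistical reading of the recovery numbers

The default world is 3 chromosomes × 10 genes (18 members across six
subfamilies + 12 decoys) plus 2 tandem and 2 segmental planted pairs and
planted promoter counts spanning 0–9 sites, a size at which the full
pipeline runs in a few seconds and recovery checks use 10 seeded
replicates. Fold-change recovery uses 200 genes per planted level
(log2 fc ∈ {0, 1, 2, log2 400}) and reports the per-level mean error:
single-gene log-ratio estimates carry ≈ 0.3 log2 of sampling noise, so
bias is only meaningful as an average. Likewise a single qPCR estimate
with 0.2-cycle noise scatters ≈ 0.2 log2 around the truth; the
planted-400-fold check therefore reports the geometric mean across 20
seeds, which converges to within a few percent of 400.

## Known limitations

* The progressive MSA is a correct but basic implementation; tree
  topologies from it will not match a production aligner on hard cases,
  and no bootstrap support is computed.
* The aligner is O(nm) pure Python — fine for family-scale proteins,
  not for proteome-wide all-vs-all scans.
* The pI model ignores charge interactions between neighboring groups
  and cysteine oxidation state; values are "theoretical" in the usual
  sense.
* Duplication classification depends on annotation completeness: the
  intervening-gene count uses the supplied gene models only.
* No multiple-testing machinery is included; `replicate_anova` is a
  convenience for single-gene questions.
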