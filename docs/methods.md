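# Methods

## Structural model

Every structure is an ordered CA trace: 1-based sequential residue indices,
one-letter codes (X for unknown), and one 3-vector per residue in Å. The
comparisons the package makes are fold-level, for which side chains add
nothing; a CA-only model keeps I/O deterministic and round-trippable to the
0.001 Å precision of PDB coordinate fields. Reading goes through gemmi with
fixed policies: first chain unless one is named, first alternate location,
residues lacking a CA skipped, insertion codes flattened into sequential
numbering. Multi-model files use model 1 only; assemblies and mmCIF are out
of scope.

## Alignment and scoring

`kabsch_superpose` is least-squares rigid superposition (via
scipy's `Rotation.align_vectors`, which guarantees a proper rotation —
reflections are never returned).

`tm_score` implements the length-normalized TM-score,

    TM = (1/L) · Σ_aligned 1 / (1 + (d_i / d0(L))²),
    d0(L) = max(0.5, 1.24·(L − 15)^(1/3) − 1.8),

with the superposition chosen to maximize the score by multi-start
refinement: initial pair subsets of length n, n/2 and n/4 slid across the
alignment, each iterated by superposing on the subset, rescoring all pairs,
and shrinking the subset to pairs closer than max(d0, 1.5 Å) until stable.
The d0 clamp at 0.5 Å keeps short-chain scores finite; it also means short
fragments score intrinsically low (a 21-residue domain aligned to its own
noisy copy sits near TM ≈ 0.45), which is why search queries should be
domain-sized or larger. A `optimize=False` mode scores coordinates as given
and serves as the algebraic oracle in tests.

`align_structures` is a sequential (no crossings) aligner in the TM-align
idiom. Candidate superpositions come from three sources: a gapless
head-to-head seed, Kabsch fits of 8-residue fragment pairs (all registers
for chains up to ~24 residues, 8 evenly spaced starts otherwise), and every
gapless diagonal run — the last guarantees the result never falls below the
best contiguous-block pairing, a property the test suite checks against
exhaustive block enumeration on small structures. Each candidate is scored
by a gap-free dynamic program on S_ij = 1/(1 + (d_ij/d0)²) (gap penalty 0,
the TM-align convention; deterministic match-over-gap tie-breaking) and the
best few are refined by alternating pairing and superposition (≤ 20
iterations, convergence = unchanged pairing). Both the initial and refined
pairings of each candidate are evaluated because refinement can drift off a
good gapless candidate. Internally the pair is processed in canonical
(length, id) order and roles are swapped on output, making
tm_query(a,b) = tm_target(b,a) exact rather than approximate.

Significance is a Z-score against a null of decoys built by permuting
5-residue blocks of the target (local geometry preserved, global fold
destroyed): Z = (TM_obs − mean_null)/sd_null over n_null seeded decoys.
A caveat discovered during testing and worth knowing: for self-similar
folds (an ideal single helix, where every 5-residue block is geometrically
identical) shuffled decoys remain near-perfect matches and the null is
degenerately strong; Z is informative for multi-domain or mixed topologies,
which is the regime the pipeline operates in. A fully degenerate null
(sd = 0) reports +inf with a warning.

## Clustering and two-stage search

Residue geometry is discretized from the CA pseudo-dihedral over residues
(i−1, i, i+1, i+2): helix-like in [30°, 80°], extended-like beyond ±140°,
coil otherwise (sign convention: right-handed helix ≈ +50°). The prefilter
is cosine similarity of geometry 3-mer count vectors. Clustering is greedy
and incremental in longest-first (then lexicographic) order — the CD-HIT
idiom — so membership depends on the ordering rule, not input order.
Search stage 1 ranks representatives by prefilter similarity; stage 2
aligns the top_k (default 50) sensitively; stage 3 expands clusters whose
representative passes the hit rule and aligns all members. The default hit
rule is tm_query ≥ 0.5 OR Z ≥ 8, with the Z-score computed lazily (only
for alignments failing the TM cut) since it costs n_null (default 20)
extra alignments. All thresholds are config and echoed in the report.

## HEPN dimer calling

The motif is exactly R-x(4)-H, scanned with overlap; coordinates are
1-based (the R127/H132 convention of catalytic-mutant nomenclature). Among
all motif pairs the minimum catalytic-His CA distance decides the call;
the site threshold of 12 Å is a CA-level proxy for juxtaposed catalytic
loops in a composite HEPN active site — an explicit, configurable choice,
since no quantitative criterion is standard. Domain spans split the chain
at the midpoint between motif 1's histidine and motif 2's arginine
(deterministic; adequate for extracting domain-sized search queries).
Rearrangement classification collapses each span's geometry string into a
block order (coil dropped, H/E runs shorter than 3 states treated as
encoding noise at block junctions) and compares it to a canonical
reference descriptor, default ("HE", "HE"); spans under 8 residues are
"undetermined". The reference is a user-supplied descriptor because
rearrangement is only meaningful relative to a declared canonical topology.

## CRISPR arrays, ORFs and loci

Array detection is seed-and-extend: an exact 8-mer recurring at
array-like periods (repeat+spacer envelopes, window ≤ 200 bp) seeds a
chain (longest chain preferred, branching on ambiguous next occurrences);
boundaries extend column-by-column while the modal-base fraction across
instances is ≥ 0.75; candidate instances that do not resemble the
consensus are trimmed from the ends and the array rebuilt from the
surviving anchors (a chance seed occurrence in flanking sequence can
otherwise ride along as a fake instance). Two validation rules reject
non-CRISPR periodicity: repeat length must fall in [23, 47] and spacers in
[15, 60] (standard detection envelopes; none are dictated by the biology
of any one system), and spacers must be mutually diverse (mean pairwise
identity ≤ 0.6) — true spacers are acquired from different targets,
whereas the "spacers" of tandem or coding-sequence periodicity resemble
each other. Arrays are maximal and non-overlapping; all coordinates
0-based half-open, GFF3 written 1-based per the format.

ORF calling is ATG-to-stop on both strands, one ORF per terminated
segment (leftmost ATG), standard code. Locus association pairs each array
with the nearest ORF by edge-to-edge distance; a Cas13-like candidate
requires distance ≤ 3000 bp (the paperless "next to" is made explicit
here) and an intramolecular HEPN dimer on the ORF's protein. Spacer-target
search is Hamming-only on both strands (≤ 2 mismatches by default);
indel-tolerant matching is out of scope.

Array orientation (leader end) is not inferred — orientation calling from
genomic signal alone is unreliable — so the spacer-before-repeat guide
architecture enters only through the processing arithmetic:
offset_upstream_of_repeat = spacer_len − fragment_len,
mature_crrna_len = mature_spacer_len + repeat_len. The tool reports both
the mature (23–24 nt) and full (30 nt) spacer lengths where relevant and
does not privilege one.

## Phylogenetics

Structural distance is d = 1 − (TM_query + TM_target)/2, each unordered
pair aligned once (symmetry then holds by construction); failed alignments
contribute d = 1 with a warning. Neighbor joining is delegated to
scikit-bio (labels pre-sorted so ties resolve lexicographically; negative
branch estimates clamped to zero), which is exact on additive matrices —
verified in the suite against 100 random trees. A combined distance
w·d_struct + (1−w)·d_seq (d_seq = 1 − fractional identity from global
pairwise alignment, default w = 0.5) is offered; the weight is an explicit
modelling assumption, logged, with no claim to a canonical value.
Maximum-likelihood tree inference is deliberately not implemented —
ecosystem tools do it better — and there is no bootstrap or rooting.
Newick serialization quotes labels containing spaces or metacharacters.

## Synthetic data: what it emulates and what it does not

The generators produce the study conditions for every test. Toy folds are
an ideal α-helix (1.5 Å rise, 100° twist, 2.3 Å radius → 3.8 Å CA-CA) and
a planar zigzag; domains are block concatenations ("HE" canonical, "EH"
circularly permuted); chimeras place two domains with the catalytic-His
CA distance set exactly (default 8 Å for positives, 50 Å for negatives)
in the first clash-free direction. Genomes are i.i.d. uniform ACGT
(no GC or codon-usage model) with planted arrays (identical repeat
copies — the conserved-repeat regime; 36 nt repeats / 30 nt spacers by
default, 4 repeats) and ORFs encoded with a fixed codon table (alanine
codons drawn from GCG/GCC/GCT so poly-Ala stretches do not themselves form
tandem nucleotide repeats; the A/R/H codons avoid creating ATG on either
strand inside fixture proteins).

Because detectors are scored against exact ground truth, the generator
enforces identifiability: columns flanking the planted repeats are
resampled until no base flanks more than two instances (otherwise the true
boundary is informationally indistinguishable from the repeat and
"boundary-exact" is ill-posed), spacers are redrawn until mutually diverse,
and chance background ORFs at or above the caller's minimum length are
disrupted by inserted stops (or a killed start codon for run-through ORFs
in alternate frames of planted genes). These guarantees are properties of
the fixtures, not of real genomes: passing tests demonstrate correctness
of the algorithms under the planted model — high-identity repeats, clean
boundaries, uniform background — and say nothing about degenerate repeats,
nested arrays, GC-skewed genomes or real fold space. Realistic decoy folds
and phage-genome realism are explicit non-goals.

## Pipeline

`run_discovery` executes cluster → search (one or more queries; per-query
hit lists and their intersection, the shared-hits set, are both reported)
→ dimer filter → genome association (hit proteins located by exact
translated-sequence match, initiator Met optional) → NJ tree over hits.
Locus calls in the report are restricted to ORFs matching dimer-positive
hits, so counts are conserved: hits ≥ dimer-positive ≥ candidates. The
resolved config — every threshold of every stage — is embedded in the
report, outputs are sorted, and reruns are byte-identical. Stage timings
and counts go to a stderr logger.

## Problem sizes and numerics

The shipped tests run on 30-structure databases of 60–100-residue folds,
6–14 kb genomes, 50-genome sweeps and 100 NJ matrices of ≤ 12 taxa —
sizes chosen so the whole suite exercises every oracle in a few minutes on
one core. Alignment determinism comes from fixed seed enumeration and
lexicographic tie-breaking; all randomness flows through explicit
numpy Generators seeded per call; floating-point tolerances are 1e-9 for
exact algebraic recoveries (NJ, additive metrics), 1e-6 for superposition
residuals, and 0.001 Å for PDB round trips.

## Known limitations

- Sequential alignment only: no topology-independent or flexible/hinge
  alignment, so circular permutations score by their best sequential
  sub-alignment rather than being superposed globally.
- The geometry alphabet is three-state and window-based; block
  classification near junctions relies on a minimum-run filter.
- Z-scores are uninformative for self-similar single-topology folds (see
  above) and cost n_null alignments per evaluation.
- The array finder targets high-identity repeats; arrays with degenerate
  repeats or atypical geometry fall outside the envelopes by design.
- Hamming-only spacer matching; no PAM/PFS-preference analysis.
- The combined structure+sequence distance weight has no principled
  default; w = 0.5 is a declared assumption.
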