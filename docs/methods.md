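# Methods

cr1kit re-implements, as a reusable desk-scale pipeline, the comparative
analysis of CR1 (chicken repeat 1) retrotransposon activity in bird
genomes: discovery and structural classification of CR1 copies, iterative
repeat-library expansion, Jukes–Cantor divergence landscapes, and —
centrally — dating of individual insertions onto branches of a species
tree by flank-anchored presence/absence scoring reconciled under Dollo
parsimony. A synthetic genome-evolution module provides ground-truthed
inputs so every stage can be validated end to end without downloading
assemblies.

## The biological model

CR1s are LINE retrotransposons. A retrotransposition-competent copy
carries endonuclease (EN) and reverse transcriptase (RT) domains in a
single ORF and a distinctive 3' structure — a hairpin followed by a short
terminal microsatellite (the octamer `ATTCTRTG` in nearly all avian
CR1s; the CR1-W family of shorebirds carries the extended 10-mer
`AAATTCYGTG`). Integration typically truncates the new copy from the 5'
end but always leaves the 3' tail, which therefore serves as the
universal detection handle, and flanks the copy with a short target-site
duplication (TSD). Insertions are effectively irreversible: a locus
shared by two species predates their divergence, a cleanly empty
orthologous site postdates it. This is the Dollo character on which the
dating rests.

## Structural classification

A candidate copy is classified on an evidence ladder, monotone in
evidence:

* **fragment** — homology only;
* **anchored** — terminal microsatellite array (>= 2 tandem copies; the
  first copy exact under IUPAC degeneracy, later copies tolerating one
  mismatch each; array ending within 100 bp of the 3' terminus) plus an
  inverted repeat (stem 5–15 bp, <= 1 mismatch, loop 3–20 bp) ending
  within 60 bp upstream of the array;
* **full_length** — anchored plus EN and RT domain evidence with EN 5' of
  RT;
* **intact** — full_length with both domains inside one ORF (ATG to stop,
  >= 600 codons by default).

Domain evidence is pluggable: an external domain-hit table is
authoritative when supplied; otherwise bundled canonical-style EN/RT
marker peptides (synthetic stand-ins written in the style of LINE APE
endonuclease and RT cores) are matched by translated local alignment in
all six frames at >= 60% identity over >= 80% of the marker. The protein
aligner scores mismatches at −0.5 (match +1) so that moderately diverged
marker ends are not clipped — with a harsher penalty the coverage test
would measure the best-scoring core rather than the true extent of
homology. Hairpin detection is a string inverted-repeat search, not
thermodynamic folding: the criterion is structural presence, and the
detector provably agrees with an exhaustive scan (tested). The hairpin
geometry and the 600-codon ORF floor are configurable; neither has a
canonical published value.

## Homology search

The internal search is a deterministic seed-and-extend local aligner:
exact 11-mer seeds (2-bit encoded, binary search against a sorted
per-scaffold index), diagonal-band clustering (band 75 bp, gap 700 bp), and
exact affine-gap local DP (match +2, mismatch −3, gap open −5, extend −2
via Biopython's PairwiseAligner) over a window padded 75 bp around each
cluster. Both strands are searched; minus-strand hits are normalised
(start < end, strand flag). Three guards make the output behave like a
conventional search tool's:

* alignments are split into separate hits at internal gaps > 30 bp —
  cheap gap extension would otherwise bridge an entire missing repeat and
  report a spurious full-span hit at an empty orthologous site;
* clusters need >= 2 seeds covering >= 15 bp of the query (two-hit rule),
  and hits must reach raw score >= 50 — a Karlin–Altschul-style
  significance floor; without it, chance ~50 bp locals at ~76% identity
  surface about once per six hundred 1.7 kb x 1 Mb searches and disturb
  the single-anchor rule of the cascade;
* hits nearly contained in higher-scoring hits are dropped.

On planted-motif instances the search matches a full-matrix
Smith–Waterman oracle (top hit within 2 bp, identity within 1 point;
tested on 100 instances). Hit chaining merges collinear same-strand hits
separated by <= 50 bp on both axes.

## Library expansion, clustering, family assignment

The iterative expansion loop searches all assemblies with the current
library, keeps chained hits >= 2,700 bp whose extracted sequence is
3'-anchored, retains those with EN+RT evidence as full-length, clusters
the accumulated full-length set (greedy, length-sorted, global identity
with free end gaps >= 0.9, centroid = founding longest member,
deterministic tie-breaks), and feeds centroids plus the initial library
into the next round, stopping at the first round in which the number of
distinct full-length loci (deduplicated at >= 80% reciprocal overlap)
does not increase. Family labels come from a reciprocal best hit against
the named library (ties: higher identity, then lexicographic; no
qualifying hit: `unassigned`).

Clustering identity counts matches over alignment columns including
internal gaps but excluding terminal overhangs, so 5'-truncated copies
are not penalised for the consensus overhang.

## Divergence landscapes

Each 3'-anchored copy is globally aligned (free end gaps) to its family
representative; p = mismatches / gap-free aligned columns (>= 50 sites
required), corrected to d = −3/4 ln(1 − 4p/3). The closed form is exact
(checked to 1e−12 against high-precision evaluation); p >= 0.75 is a
saturation error, never a silent clamp. Landscapes bin d per family in
half-open 0.01 windows and conserve copy counts. Divergence is measured
to the centroid, as in centroid-library practice; the record carries the
representative's id so the known bias (species distant from the centroid
read as uniformly diverged) stays auditable. CpG sites receive no special
treatment. Divergence is deliberately not converted to absolute time.

## Presence/absence scoring

Candidate loci are 3'-anchored copies of 100–600 bp lying >= 600 bp from
any contig end whose 600 bp flanks contain <= 25% N (strictly more
discards). The query is 5' flank + repeat + 3' flank on the scaffold plus
strand. Against each target species the cascade runs, in order; any
unresolved step yields `unscorable` rather than a guess:

1. a single contiguous hit covering the whole repeat and >= 150 bp of each
   flank → `shared` (FULL_SPAN);
2. hits whose outer query coordinate reaches < 150 bp beyond the
   repeat/flank junction are discarded (paralogous-repeat and
   microsatellite-tail guard); collinear flank sub-hits <= 50 bp apart
   (max two) are chained;
3. exactly one 5'-flank and one 3'-flank anchor, same orientation, same
   scaffold, are required (two anchors for a flank → MULTI_HIT; fewer
   than two usable → NO_ANCHOR);
4. if the anchors sit within 16 bp of each other in the target and the
   unaligned query residue is about the repeat length → `absent`
   (CLEAN_PREINSERTION_SITE). Anchor overlap in the target (the TSD
   aligning under both flanks) counts as adjacency, and a microsatellite
   array inside the target gap is subtracted without penalty — tail
   arrays vary in length between copies;
5. if the target gap is about the query gap between anchors → `shared`
   (GAPPED_SHARED);
6. otherwise AMBIGUOUS_GAP.

"About" means within max(16 bp, 10% of the repeat length) — the 16 bp
precedent generalised proportionally, exposed as config. The boundary
distance is sweepable (50–300 bp); on dense simulated data the sweep
reproduces the published trade-off: at 50 bp, microsatellite-tail false
anchors convert clean absent calls into MULTI_HIT unscorables, while
large distances discard genuine anchors. Unscorable counts are therefore
*not* monotone in the distance — both extremes inflate them for
different reasons.

Insertions are reconciled under Dollo parsimony (single gain, no loss):
candidate gain branches run from the MRCA of the present species rootward
until an absent species would be subtended; unscorables constrain
nothing. The most recent candidate is the point assignment; the full
candidate set is kept as the ambiguous range; an absent species inside
the present clade yields `conflicted`, surfaced rather than resolved.
An insertion present in every sampled species is assigned to the
pseudo-branch `root` and flagged. Per-branch, per-family counts carry a
`reportable` flag for families with strictly more than ten assignments —
a display filter, never applied to stored data.

## The synthetic genome generator

An ancestral random genome (default 1 Mb over 4 scaffolds) evolves down a
rooted tree with branch lengths in Myr. Per branch: Jukes–Cantor
substitutions (each site changes with probability 3/4(1 − e^(−4dt/3)),
uniformly to another base; checked against the closed form within
binomial error), small indels (<= 5 bp, rate per site per Myr), then CR1
insertions. Each insertion draws a family active on that branch, is
full-length with probability 0.2 or 5'-truncated (default truncation
amount uniform over [50, L−300] bp, always preserving the 300 bp tail;
a retained-length range can be set directly), receives a 2–20 bp TSD,
random orientation, and 0–8 slipped extra copies of the terminal
microsatellite motif deposited beyond the annotated element end — the
annotation-boundary effect that makes small boundary distances admit
false anchors in real data. Scaffolds are block lists, so every
insertion's locus is tracked exactly through later edits; nesting splits
the host copy's blocks without relabelling. No excision is simulated,
matching the scoring model's assumption. Families are built as
independently constructed valid elements: ATG-initiated single ORF with
the EN marker at its very 5' end (so any >= 50 bp truncation destroys
EN detection — truncated copies can never classify full-length), the RT
marker mid-ORF, an own hairpin, and four copies of the terminal motif,
alternating the octamer and the 10-mer across families; total ~2.8 kb.

One deliberate scale correction: with `min_insertion_spacing_bp` set,
insertion sites are drawn from a global registry in approximate ancestral
coordinates, keeping all sites (across every lineage) at least that far
apart. Packing a gigabase genome's insertion load into a megabase
inflates the per-locus probability of flank-overlapping insertions and of
two independent insertions hitting the same orthologous site (homoplasy)
about a thousandfold; the registry restores the per-locus rarity these
events have in real genomes. With spacing off (the default) the generator
produces dense, nested, homoplasy-prone cohorts — useful for exercising
the unscorable machinery, not for exact-recovery claims.

What the generator does not emulate: selection, recombination-driven
repeat loss, GC/insertion-site bias, rate variation among sites or
lineages, segmental duplication, and sequencing error other than assembly
fragmentation (random scaffold splitting to a target N50). Passing tests
therefore demonstrate the correctness of the inference machinery under
the stated generative model, not performance on real assemblies, where
repeat density, soft-masked regions and assembly artefacts add failure
modes the unscorable category is designed to absorb.

## Validation experiments and problem sizes

The standard recovery cohort is 5 species on the tree
`(((A:1,B:1):1,C:1):1,(D:1,E:1):1)` (every branch 1 Myr, so per-branch
rates read directly), 2 families, 300 insertions allocated
multinomially by branch length over a 1 Mb ancestral genome, truncated
copies retaining 300–600 bp so most loci fall in the scoreable window,
site spacing 1.3 kb, nesting off. The clean variant has substitution and
indel rates 0; the noisy variant has 1% substitutions/site and 1 indel/kb
per branch with every assembly fragmented to half its N50. At these
sizes the clean cohort scores in ~75 s and the noisy one in ~85 s on one
CPU. Measured at seed 1: clean — 920/920 calls correct, 0 unscorable,
230/230 origin branches recovered; noisy — 957/957 calls correct, 0
false-absent among 120 truly shared pairs, 242/242 branches recovered
(11 pairs unscorable). Unit suites run on 3-species cohorts of 40–50
insertions over 150–250 kb.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open on the plus strand with explicit
strand flags; the 12-column tabular dialect (1-based inclusive,
sstart > send for minus) is converted only at I/O boundaries and the
conversion is involutive. N50 follows the standard definition and is
permutation-free. Ties are broken deterministically everywhere
(clustering: length then label; family assignment: score, identity,
label; hairpins: stem length, loop size, proximity to the array;
microsatellites: proximity to the terminus, then array length). Empty
inputs raise rather than return defaults, except windows clamped at
sequence boundaries, which clamp silently by design. The pipeline is
single-process; rerunning a config is bit-identical, and every output
table is stamped with a hash over the scientific parameters (the output
path is excluded from the hash).

## Known limitations

* The search has no E-value machinery; the raw-score floor plays that
  role and is calibrated to the default scoring only.
* FULL_SPAN requires one contiguous alignment (chained hits do not
  qualify) — stricter than a search tool that reports long gapped hits.
* The iterative expansion accumulates loci but never revises earlier
  centroid assignments; a library poisoned by a chimeric first-round
  centroid stays poisoned (mirrors the original procedure).
* Divergence landscapes inherit the centroid-distance bias discussed
  above.
* The simulator's domain markers are synthetic stand-ins: real EN/RT
  profile variation is broader than what marker alignment models.
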