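# cr1kit

Comparative analysis of CR1 (chicken repeat 1) retrotransposon activity
in genome assemblies: discover and structurally classify CR1 copies,
build clustered repeat libraries, compute Jukes–Cantor divergence
landscapes, and date individual insertions onto branches of a species
tree by flank-anchored presence/absence scoring with Dollo parsimony.

CR1s are the dominant LINE retrotransposons of birds. A competent copy
carries endonuclease (EN) and reverse transcriptase (RT) domains in one
ORF and ends in a hairpin plus a terminal microsatellite (`ATTCTRTG`,
or the extended `AAATTCYGTG` of the CR1-W family); insertion truncates
copies from the 5' end but always leaves that 3' tail, and flanks the
copy with a target-site duplication. Because an insertion happens once
and is never precisely excised, a locus shared between species predates
their divergence and a cleanly empty orthologous site postdates it —
each dated locus is a Dollo character:

* copy classification ladder: fragment < 3'-anchored < full-length
  (EN+RT, EN 5' of RT) < intact (both domains in one >= 600-codon ORF);
* divergence: p = mismatches / aligned sites to the family centroid,
  corrected as d = −¾ ln(1 − 4p/3);
* locus scoring: each 100–600 bp anchored copy with clean 600 bp flanks
  is searched in related species and pushed through a fixed elimination
  cascade (full-span hit → shared; exactly one anchor per flank after a
  150 bp boundary discard; flanks within 16 bp of each other → absent;
  gap matching the query → shared; anything unresolved → unscorable);
* placement: the most recent tree branch consistent with the
  presence/absence vector under Dollo parsimony (single gain, no loss),
  with the full candidate range kept when unscorables widen it.

A synthetic genome-evolution module (`cr1kit.simulate`) generates
assemblies along a tree with per-branch CR1 insertions (truncation,
TSDs, microsatellite tail slippage), Jukes–Cantor substitutions, indels
and assembly fragmentation, together with a per-insertion ground-truth
table — every pipeline stage is validated against it.

## Worked example

```python
import numpy as np
from cr1kit.benchmark import recovery_conditions, score_truth_cohort
from cr1kit.simulate import simulate

config = recovery_conditions(seed=1, noisy=False)   # 5 species, 300 insertions
assemblies, truths = simulate(config)
result = score_truth_cohort(assemblies, truths, config.tree)
print(f"scoreable loci: {result.n_insertions}")
print(f"calls correct: {result.n_correct}/{result.n_scored}, "
      f"unscorable: {result.n_unscorable}")
print(f"branch recovery: {result.n_branch_exact}/{result.n_insertions}")
```

prints

```
scoreable loci: 230
calls correct: 920/920, unscorable: 0
branch recovery: 230/230
```

i.e. of 300 simulated insertions, 230 fall in the scoreable class
(100–600 bp copies with clean flanks away from contig ends); on
substitution-free genomes every one of their 920 cross-species locus
calls matches the simulated truth and every insertion is placed back on
the branch where it was simulated. With 1% substitutions/site/branch,
1 indel/kb and assemblies fragmented to half their N50, accuracy stays
at 100% of scored calls with ~1% of pairs unscorable.

There is also a CLI for file-based work:

```
cr1kit simulate --config sim.yaml --out simdir/
cr1kit discover --assembly simdir/A.fasta --library library.fasta --out copies.tsv
cr1kit run-all --config pipeline.yaml
```

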