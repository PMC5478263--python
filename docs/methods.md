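# Methods

## The poison–antidote model

A spore killer is modeled as an allele that expresses a trans-acting
poison affecting every spore of the ascus and a cis-acting antidote
restricted to spores that inherit the allele.  Two parameters per killer:

- **κ (killing penetrance)** — probability in [0, 1] that an unprotected
  spore exposed to the poison dies.  Default presets use κ = 1, matching
  the near-complete death of non-carrier spores seen in fully active
  killers.
- **π (antidote efficiency)** — probability in [0, 1] that a spore
  carrying a protective allele survives the poison.  π < 1 produces
  partial death of carrier spores (self-killing), the phenotype of
  killers whose upstream/protective sequences are damaged.
- **resistance set** — the poisons the allele's antidote neutralizes;
  defaults to the allele itself.  Two killers with disjoint resistance
  sets kill mutually: in a cross of two different killers at the same
  locus every spore carries exactly one and is killed by the other.

Survival is multiplicative over killers (independent action), and the
protection against one poison is the best available antidote
(`max` over carried alleles whose resistance set covers it).

Truncation presets encode the qualitative separability of killing and
protection: `Ta`/`Tc` (κ=1, π=1), `Td` (κ=0, π=1; protects without
killing), `Tb` (κ=1, π=0.7) and `Te` (κ=1, π=0.4).  The π values for
Tb/Te are placeholders chosen only to preserve the observed ordering
π(Ta) > π(Tb) > π(Te); no quantitative estimates exist for them.

## Tetrad segregation model

Each locus segregates exactly 2:2 within a tetrad (no gene conversion).
The four spores are organized as two fixed pairs, each pair containing
one spore of either parental origin at every locus; for each interval
between adjacent loci, each pair independently swaps origins with
probability equal to the interval's recombination fraction r (0.5 across
chromosome boundaries).  This reproduces the per-spore recombinant
fraction r exactly and keeps both enumeration and simulation closed-form
and mutually consistent.

*Limitation*: this is not a four-strand chiasma model.  At r = 0.5 it
yields tetratype frequency 1/2 rather than the 2/3 expected for loci far
from centromeres under no chromatid interference.  Expected viabilities
and pooled allele frequencies — the quantities this package reports —
depend only on per-spore marginals and are unaffected; tetrad-class
frequencies (PD:NPD:TT) should not be read off the simulator.

Map distances convert to fractions by Haldane's function
r = (1 − e^(−2d))/2 (no interference); fractions may also be supplied
directly.

## Maximum-likelihood fitting

`fit_killer_parameters` maximizes Σ log s over viable spores plus
Σ log(1 − s) over dead spores, with spores collapsed to
(genotype, viability) counts.  Optimization is a deterministic coarse
grid (step 0.05 per parameter) followed by L-BFGS-B refinement with
box bounds [0, 1]; estimates at a boundary are reported as-is and
flagged.  Parameters the data cannot constrain are flagged per
parameter: κ when no non-carrier spores were observed, π when no
carriers were observed.  Identifiability is weakest for π when κ is
small (carrier death is then rare); with 500 tetrads the standard error
of π̂ at κ = 0.25 is ≈ 0.06.

## Synthetic data: what is emulated, what is not

Defaults mirror the experimental regime the pipeline targets: pools of
≥ 150 viable colonies, mean sequencing depth 15×, ≥ 40 tetrads per
cross, SNP density 25/100 kb (a reduced-scale stand-in for the
~3.1 SNPs/kb divergence between wild and laboratory fission-yeast
isolates; full scale would only slow tests without changing behavior),
and a recombination rate of 0.17 cM/kb, the genome-wide fission-yeast
average.

- **Viable-spore pools** simulate each spore as an independent meiotic
  product: crossovers arrive as a Poisson process along the chromosome
  at the cM/kb rate, parental origin alternates across them, and the
  spore is accepted with its survival probability (rejection sampling,
  bounded attempts).  This resolves an allele at every SNP consistent
  with linkage, including decay of distortion with distance from the
  killer — interpolating only between typed loci would leave no decay
  toward the telomeres.
- **Read counts**: depth ~ Poisson(mean_depth) per SNP; reference reads
  ~ Binomial(depth, f), with an optional symmetric per-base error rate
  (default 0, since base-quality filtering happens upstream of the
  count table).
- **Mosaic backcross genomes** mark SNPs inside donor segments; crosses
  against the recipient then segregate only those SNPs.
- **Gene families**: one consensus per family for the 288-bp upstream
  element, the 150-bp intron-1 motif and a 300-bp LTR; genes diverge by
  uniform random substitutions (default 3 %, 4 % inside motifs — safely
  above the 80 % identity detection threshold).  No indel model beyond
  planted lesions, which keeps ground-truth coordinates exact.  After
  mutation the generator repairs constrained features (start/stop
  codons, GT…AG splice sites, internal stops, and the in-frame-ATG
  search window) so planted categories hold by construction; planted
  intron-1 ATGs are placed in frame with the downstream coding sequence
  by adjusting the exon-1 length modulo 3.

Not modeled: read-level artifacts (mapping bias, duplicates), selection
beyond viability in random-spore pools, gene conversion within tetrads,
and aneuploidy.  Passing tests therefore demonstrate correctness of the
analysis logic on idealized data, not robustness to alignment artifacts.

## Scan stage choices

- Frequencies use only reference + variant reads; SNPs below the depth
  threshold (default 10; a lower value such as 7 suits low-coverage
  libraries) are dropped, which also removes zero-depth rows.
- The rolling median (default window 45 SNPs) is computed per
  chromosome and left undefined where a full centered window does not
  fit; no partial windows, avoiding edge bias.  Chromosomes with fewer
  SNPs than the window get no trend and a logged warning.
- Distortion regions are maximal runs of ≥ `min_run` (default 45) SNPs
  whose trend deviates from 0.5 by ≥ `delta` (default 0.15) in one
  direction.  The thresholds are this package's addition — peak calling
  from trend plots is otherwise visual — and were set to flag strong
  single-killer distortions at 15× depth; both are exposed as flags.
  Region direction reports which parent's alleles are depleted; the
  extremum is the position of maximal deviation (ties → leftmost).
- Donor segments are maximal runs of ≥ 20 SNPs with reference frequency
  ≤ 0.95; bounds are the first/last SNP of the run, so boundary error
  is at most one inter-SNP gap.
- Coordinates are 1-based inclusive throughout; BED export converts to
  0-based half-open.

## Exact tests

Both tests use the two-sided "method of small p-values": p is the total
probability of all outcomes whose point probability does not exceed the
observed one, with a relative tie tolerance of 1e-7 to absorb
floating-point equality; if every outcome qualifies, p = 1 exactly.
Degenerate Fisher margins return p = 1 with a warning.  The
genotype-ratio test defaults to viable spores (dead spores usually lack
genotypes); when exactly three spores of a tetrad are typed, the fourth
can be completed assuming 2:2 segregation, and results flag how many
tetrads used inference.

## Annotation stage choices

- Motif detection is an ungapped sliding-window identity scan
  (default threshold 0.8) — the motifs are described as nearly
  identical, and the scan is simple and auditable.  Non-overlapping best
  hits are reported greedily, ties leftmost.
- The first-ATG search treats an intron-1 ATG as in frame when
  translation from it reads into exon 2 in the predicted CDS frame
  (offset ≡ exon-1 CDS length mod 3); an exon-2 ATG must sit on a CDS
  codon boundary.  The exon-2 search depth defaults to 150 bp — the
  extent of the "5′ section of exon 2" is not defined anywhere, so it
  is configurable.
- Pseudogene lesions: lost start (CDS does not begin ATG); frameshift
  (spliced CDS length incongruent with the family consensus mod 3);
  premature stop (in-frame stop before the final 10 % of consensus CDS
  length); segmental deletion (missing exon, or exon < 50 % of its
  consensus length).  The 10 % and 50 % cutoffs are package-defined;
  the lesion categories themselves carry no published numeric bounds.
- Classification precedence: pseudogene → listed-divergent →
  motif-positive (subtype by first in-frame ATG) → antidote-only →
  divergent/unclassified.  A motif-positive gene with no in-frame ATG in
  the window is reported antidote-only with the anomaly in its reasons.
- LTR-deletion detection compares the recipient's solo LTR base-by-base
  against both donor copies; the maximal prefix matching copy 1 and
  suffix matching copy 2 must cover the LTR (a clean hybrid), their
  overlap is the breakpoint homology, and the junction is reported at
  its leftmost consistent position, matching the generator's canonical
  coordinates.  Inverted pairs are rejected with a reason.

## Tree stage choices

- Midpoint rooting places the root halfway along the longest
  leaf-to-leaf path; ties between equally long paths break to the
  lexicographically smallest endpoint pair, making the operation
  deterministic.  All-zero branch lengths raise "midpoint undefined".
  Rooting is implemented on dendropy primitives rather than
  `reroot_at_midpoint` to guarantee the tie-break and support handling.
- Bootstrap supports are treated as properties of bipartitions: they
  are keyed by leaf-set split before re-rooting and re-attached after,
  so neighbor-pair detection is invariant under re-rooting outside the
  cherries.
- A phylogenetic neighbor pair is a cherry (internal node with exactly
  two leaf children) with support ≥ 95 %; cherries lacking a support
  value are excluded with a warning.  A pair is syntenic iff both
  members share a syntenic group and come from different genomes;
  same-genome pairs (tandem duplicates) are non-syntenic by definition.

## Problem sizes in tests and the acceptance script

Simulation-based checks use 500–2000 tetrads, pools of 150–200 colonies
over ~3000 SNPs at 15×, 20 seeded scan replicates, 200 synthetic genes
and 10–20-leaf random trees — sizes at which binomial sampling error is
well below the asserted tolerances while the whole suite runs in
seconds.  All generators take explicit seeds, and the acceptance script
derives every stream from its single `--seed`.
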