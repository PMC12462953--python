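# Methods

## Sketching and the Mash distance

Canonical k-mers (the lexicographic minimum of a window and its reverse
complement) are packed into 2-bit codes; windows containing an ambiguity
letter are skipped, and soft-masked lowercase bases are folded to uppercase
by default (`fold_lowercase=False` instead treats them like masked
sequence). k must be odd so no k-mer equals its own reverse complement, and
k ≤ 31 so a k-mer fits one 64-bit word.

Hashes are a seeded splitmix64 finalizer applied to the packed code XORed
with a mixed seed — a fixed, documented 64-bit non-cryptographic hash.
Hash values are deliberately *not* interchangeable with any external
sketching tool; what matters is that identical parameters give identical
sketches, which the seed in the sketch metadata guarantees. A bottom-s
sketch keeps the s smallest distinct hashes (default s = 5000; `s=None`
keeps all of them, making the Jaccard estimate exact — equivalent to
running with a sketch size exceeding the genome's k-mer count).

For two sketches the estimator takes the `denom = min(s, |union|)` smallest
hashes of the merged sketch and counts how many occur in both;
`j = shared/denom` and `D = −(1/k)·ln(2j/(1+j))`. `j = 0` has no finite
distance, so D is capped at 1.0 and flagged. The Mash p-value is not
computed; the shared/denom counts are reported instead so the evidence
behind every distance is visible. Under a uniform substitution model with
per-site rate p, the expected k-mer survival is (1−p)^k, giving
D ≈ −ln(1−p) ≈ p for small p; the upward bias (p²/2) stays inside a few
percent for p ≤ 0.05, which the rate-recovery validation measures directly.

## Homoeolog pairing

All reference × polyploid chromosome distances are computed per chromosome
(chromosome-level assemblies are the intended input). Pairing is a greedy
global assignment in ascending distance with lexicographic tie-breaks,
which makes the result independent of input order; each reference
chromosome takes up to `copies_per_ref` members (default 2, tetraploid).
On homoeolog-structured matrices — two members per reference well separated
from the background — greedy assignment attains the exhaustive
minimum-total-distance optimum, which the test suite verifies against the
Hungarian algorithm on row-duplicated matrices. Genuine homology from a
collinearity analysis can be supplied as a TSV and overrides the inference;
distances are then filled from the matrix, and labels still follow
distance, not file column order. Unpairable chromosomes (count mismatches,
fusions) are warned about and reported, never silently dropped.

## The partition decision rule

Each pair is decided independently: the member closer to the reference gets
the low-divergence label. Per-pair independence is intentional — it matches
the per-chromosome bar-chart evidence users inspect, and a single bad pair
cannot cascade. The ambiguity statistic is the *relative* gap
`(d_high − d_low)/mean(d_low, d_high)`: divergence scales with reference
distance, so an absolute threshold would need retuning per reference
species while a relative one does not. The default `tau = 0.05` flags pairs
whose distances differ by under 5% of their mean; exact ties are broken
lexicographically and always flagged. A run with more than half its pairs
ambiguous is summarised as "indeterminate" — the expected outcome for
autopolyploids. The 50% convention is this package's own operational
definition of failure, chosen so a clear majority of informative pairs is
required before a verdict is claimed. With several references, per-reference
partitions are combined by majority vote with an agreement fraction.

With the default sketch size the distance noise is set by the Jaccard
sampling error: at s = 5000 and total divergence ≈ 0.1 (the validation
preset) the per-distance standard error is ≈ 0.0025, so the equal-rate
negative control produces relative gaps of a few percent — below tau for
most pairs — while the asymmetric preset produces gaps near 60%. That
separation, not any tuned constant, is what the recovery and negative
control checks exercise.

## Heterozygous k-mer-pair ploidy analysis

Canonical 21-mers are counted from reads with the same conventions as
sketching. The error tail is removed at the first local minimum of the
width-3 smoothed coverage histogram (a user cutoff can be forced, e.g. the
conventional depth-20 cutoff for high-coverage data); a monotone histogram
is an error rather than a guess. One-SNP pairs are found by k wildcard
passes: for each position, k-mers are bucketed by masking that position in
both orientations, so pairs whose members were canonicalised from opposite
strands are still found. Oversized buckets (default > 16) are skipped and
k-mers in more than one pair are discarded — both suppress repeat-family
artifacts. The minor/total ratio convention (in (0, 0.5]) makes genotype
centres unique; the coverage sum and ratio place each pair near
(m·c, b/m).

### Haploid-coverage estimation

The estimator works on the *smudge structure*, not raw pairs. Dominant
modes of the coverage-sum distribution are found on a smoothed histogram
(5% prominence), recentred by an iterative median so error tails do not
bias them, and each mode carries the mode of its members' ratio
distribution (sharper than the mean under the fold at 0.5). A candidate
c (one per mode/multiplicity combination, bounded below by the depth
cutoff) is scored by scaled residuals of the modes against the
(m·c, b/m) comb. Two safeguards make c identifiable:

- **Forbidden-mass veto.** A candidate is rejected when more than 2% of
  pairs lie further than 4σ (coverage axis; σ estimated robustly from the
  heaviest smudge) or 3σ (binomial ratio axis) from every allowed centre.
  This is how minority structure vetoes wrong readings: under an AABB data
  set read at c' = 2c, the residual-heterozygosity AB smudge at 2c and the
  AAAB smudge at ratio 1/4 are inexplicable and kill the candidate. The
  coverage slack is 4σ rather than 3σ because the empirical coverage-sum
  distribution has a narrow core with heavier error-driven tails.
- **Occam tie rule.** Candidates fitting within 0.05 of the best are tied,
  and the largest tied c — the smallest-multiplicity reading — wins, then
  is polished by weighted least squares. A lone smudge at 2c is read as AB,
  not as AABB at half the coverage: the two are mathematically
  indistinguishable, and the low-multiplicity reading is the only one under
  which a diploid data set returns its true coverage. A genuinely pure
  AABB read set (no residual heterozygosity at all) is therefore reported
  at 2× its true 1n coverage — an inherent ambiguity of coverage-only
  evidence, resolved in practice because real allopolyploid read sets
  always carry a minor AB/AAAB component.

Note the estimated c is *k-mer* coverage, which relates to per-base read
coverage by the factor `(read_len − k + 1)/read_len · (1 − e)^k` for error
rate e.

### Genotype classification

Pairs are assigned to genotype classes (AB, AAB, AABB, AAAB, … up to
`max_ploidy = 8`) by posterior probability under a Gaussian mixture whose
components sit at the genotype centres with variances φ·m·c (coverage axis;
φ is a robust dispersion index estimated from the data) and binomial
variance (ratio axis). A few EM rounds estimate the class weights; this
matters because the coverage-axis smudges overlap, and a pure
nearest-centre rule would spill the tails of a dominant smudge into
neighbouring multiplicity classes. Proportions over pairs and the modal
class are reported, plus a 2-D histogram table for external plotting; no
attempt is made to reproduce any particular visualisation.

## The simulator

`make_allotetraploid` draws an ancestor (default GC 0.40, near teleost
genomes), evolves three independent lineages — reference, progenitor B,
progenitor C — and unions the B and C chromosome sets into the tetraploid
with a truth table. Substitutions are uniform-exchange (Jukes–Cantor-like)
applied once per branch; no transition/transversion bias and no
multiple-hit bookkeeping, since only rate *asymmetry* matters for what the
simulator is testing and the bias is negligible at the rates used (≤ 0.1).
Indels are point events (default 5·10⁻⁴/site) with geometric lengths of
mean 3, insertion and deletion equiprobable. Defaults (10 chromosomes ×
200 kb; branch rates 0.02/0.08 vs reference 0.05) put progenitor-reference
divergences at ≈ 0.07 and ≈ 0.13 — the same order as the Ks-scale
divergences reported for real tetraploid cyprinids — while keeping each
validation replicate inside seconds of CPU. `insert_repeats` scatters
mutated copies (2% per-copy divergence) of a single random monomer and
emits a BED of insertions so hard-masked reruns can be compared;
`simulate_reads` draws uniformly placed, error-prone reads from haplotype
copies with integer multiplicities (AB = 2 haplotypes × 1; AABB = 2
haplotypes × 2). Every operation is deterministic given its seed.

What the simulator does *not* emulate — real transposon family dynamics,
homoeologous exchange, segmental allopolyploidy, GC-biased gene conversion,
coverage bias in reads — bounds what passing tests show: they demonstrate
the method's behaviour under its own model assumptions (rate asymmetry,
karyotype conservation, homogeneous coverage), not robustness to every
feature of real data. The validation read sets for the AABB scenario
include low-rate residual heterozygosity (5·10⁻⁴/copy) within each
subgenome alongside ~2% between-subgenome divergence, mirroring the mixed
AB/AABB genotype composition observed in real allotetraploid read sets;
this is also what renders the haploid coverage identifiable (see above).

## Numerical and interface choices

- Distances are symmetric and exactly zero on identical input; `j = 0` caps
  at D = 1.0 with a flag.
- Sketch files are JSON (name, parameters, hash list) — auditable, not
  binary; all tabular output is TSV with headers; every CLI run echoes its
  configuration and the tool version into `run_config.json`.
- `--threads` is accepted for interface compatibility but results never
  depend on it.
- Validation problem sizes (1 Mb sequences for rate recovery; 10 × 200 kb
  chromosomes, 10-20 replicates; 500 kb genomes at 15× per copy for
  ploidy) were chosen to keep the full validation suite within minutes on
  a single CPU while leaving each measured property an order of magnitude
  above its sampling noise.

## Known limitations

- Mash distance ignores gene order, structural variation and sequence
  length; homoeologous exchanges between subgenomes blur the signal and are
  not modelled.
- When progenitor rates are equal (autopolyploids) the method is designed
  to return "indeterminate" rather than a partition; closely related
  references with very small gaps may need the multi-reference consensus.
- Greedy pairing assumes a 2:1 chromosome correspondence; fused or split
  chromosomes surface as warnings and unpaired leftovers, not as a
  rearrangement analysis.
- The ploidy module reports genotype-class proportions only; it does not
  correct for GC bias or non-uniform coverage, and coverage-only evidence
  cannot distinguish a pure AABB genome from an AB genome at twice the
  coverage (see the Occam rule above).
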