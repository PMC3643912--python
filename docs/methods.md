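# Methods

## Design assumptions

The pipeline targets a replicate-free two-genotype × multi-stage design: one
sequencing library per genotype (XX / XY) per developmental stage, with
per-gene mapped read counts and per-library total mapped read counts as the
entry point. Read QC, alignment and read counting are upstream of this
package; whether multi-mapped reads are counted once or per locus is a
property of the user's counting step and is not second-guessed here.

## Quantification

RPKM = 1e9·C/(N·L), with N the library's total mapped reads (stored
explicitly in the library metadata rather than derived from count-column
sums, which differ from N whenever reads multi-map) and L the gene's exonic
length. When a GFF3 annotation is supplied, L is the total length of the
union of the gene's exon intervals in 1-based end-inclusive coordinates
(Σ(end − start + 1) over the merged set); no other coordinate convention is
used anywhere.

"Expressed" means C ≥ `min_count` (default 1, i.e. RPKM > 0). The RPKM ≥ 1
and RPKM ≥ 5 library summaries are reporting conventions, not detection
thresholds: detection is presence of mapped reads.

## The exact two-library test

Counts for one gene in the two libraries are modelled as Poisson; the
Audic–Claverie conditional law of the second count given the first is
negative binomial,

    P(k | x) = C(x+k, k) · r^k · (1−r)^(x+1),   r = N₂/(N₁+N₂),

and the two-sided p-value is p = min(1, 2·min(P(K≤y|x), P(K>y|x))).

*Why the upper tail is strict.* Doubling the smaller of two point-inclusive
tails — the more common discrete-test convention — is **not** symmetric
under exchanging the two libraries when their sizes differ (the point mass
P(y|x) rescales by N₂/N₁ under exchange). The lower-inclusive/upper-strict
split satisfies the exact identity P(K>y | x; N₂/N₁) = P(K≤x | y; N₁/N₂),
verified in exact rational arithmetic over a parameter grid in the test
suite, which makes p(x, y, N₁, N₂) = p(y, x, N₂, N₁) hold to machine
precision. Symmetry is non-negotiable for this statistic: which library is
labelled "first" must not change any call.

*Numerics.* Every term is evaluated in log space via the log-gamma
function. Whichever tail is the smaller one (decided by comparing y to the
conditional mean (x+1)·N₂/N₁) is summed directly in linear space from its
smallest terms upward — the finite lower tail as a max-factored sorted sum,
the infinite upper tail in blocks with a geometric remainder bound
(cut-off at relative 1e-17) — and the other tail is its complement, so no
catastrophic cancellation occurs on the side that decides significance. A
p-value that would underflow is reported as the smallest positive normal
float, keeping p ∈ (0, 1]. The test suite checks the implementation against
integer-arithmetic direct summation over the full x, y ≤ 200 grid at
library-size ratios 0.5, 1 and 2 (relative error ≤ 1e-8) and against the
independent negative-binomial tail route in scipy.

## Multiplicity

q-values come from the Benjamini–Hochberg step-up applied per stage, over
exactly the genes tested at that stage (a gene is tested when detected in at
least one of the stage's two libraries). Per-stage families match how
per-stage differential counts are reported and interpreted downstream;
pooling stages would let a strongly unbalanced stage distort another
stage's calls. Analyses of this kind have used both BH and BY; BH is the
default and Benjamini–Yekutieli is available as
`fdr_method="by"` for users who want validity under arbitrary dependence.
The adjustment itself is delegated to statsmodels; the tests keep an
independent quadratic-time step-up as an oracle.

## Classification

Thresholds: FDR ≤ 1e-2 and |log₂(XX_RPKM/XY_RPKM)| ≥ 1, both configurable.
The ratio convention is log₂(XX/XY) everywhere; positive means XX-biased.

For a gene detected on one side only the ratio is ±∞, so the fold-change
clause of the dual criterion is automatically satisfied and SEG status
reduces to the FDR test — the only reading under which applying "both
criteria" to one-sided genes is coherent. A gene with both RPKMs zero has an
undefined ratio (NA in output files) and is NOT-EXPRESSED.

Enhanced genes: anchor at the earliest stage (5 dah by default) plus at
least `min_other_stages` (default 2) of the remaining stages, all favoring
the same sex, where "favoring" means DIG or SEG for that sex at that stage.
Genes untested or unexpressed at a stage simply fail that stage's criterion
but stay candidates through the other stages. The supporting-stage list is
recorded per gene so stage-pattern partitions (all-four, {5,30,90}, …) can
be tabulated directly.

Two constructions of "sex-specific" are emitted separately, since they
answer different questions: the detection-based sets (detected in one
genotype's libraries only, across all stages — the Venn-diagram semantics)
and the per-stage SEG calls (which additionally demand statistical
significance at a given stage).

## Simulator

The generator emulates the 2 × 4 design: counts are Poisson with mean
q·L·N/1e9 (the RPKM formula inverted), q the planted RPKM-scale expression.
Poisson — not negative binomial — is deliberate: it matches the sampling
model the exact test assumes, so null simulations measure the test's
calibration rather than a dispersion mismatch. Consequences: passing the
null/recovery suites shows the pipeline is correct under its own model, not
that single-library exact tests are well calibrated on biologically
variable replicates — they are known to be anti-conservative under
overdispersion, which is an inherent limit of replicate-free designs, not of
this implementation.

Defaults (all per `SimulationConfig`): 21,000 genes; stages 5/30/90/180
dah; 5×10⁶ mapped reads per library; gene lengths uniform on 500–3000 nt
(lengths only enter RPKM denominators, so the distribution shape is
immaterial); base expression log-uniform on 50–500 RPKM, which at these
depths and lengths puts every expressed gene's mean count ≥ ~125 —
comfortably in the regime where fold-8 effects are detectable; DIG fold 8
applied multiplicatively to the favored sex; class mix 55% co-expressed,
10% / 15% XX-/XY-differential, 1% / 4% XX-/XY-specific, 15% silent (the
male-biased asymmetry mirrors gonadal transcriptomes, where testis programs
recruit more specific genes). Class counts are apportioned by largest
remainder, so planted set sizes are exact, then shuffled. A
`class_schedule` can re-label a planted class at chosen stages to exercise
the enhanced-gene rule. One master seed; each library draws from its own
spawned substream, so adding libraries never perturbs existing columns.

Not emulated: read-level error, alignment artifacts, isoform structure,
between-sample normalization issues, overdispersion (above).

## Problem sizes in the checks

The bundled acceptance checks run at 10,000 genes (null calibration, three
seeds in the test suite) and 3,000 genes (planted-class recovery), with the
defaults above; the exact-oracle grid covers all count pairs up to 200 at
three library-size ratios. These sizes give stable empirical rates (the null
q ≤ 1e-2 fraction is measured over ~40,000 tests per seed) while keeping a
full run in minutes on one core.

## Degenerate inputs and tie-breaks

Zero-length genes, non-positive library sizes, negative or fractional
counts, duplicate identifiers and mismatched gene universes are rejected
with errors naming the offending row or column. Equal p-values receive equal
q-values (stable sort; min-over-suffix construction). An empty test family
returns an empty q-vector. TSV outputs round-trip through the package's own
readers; infinite ratios and undefined values use the `Inf`/`-Inf`/`NA`
tokens.
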