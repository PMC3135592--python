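# Methods

## Scientific setting

During V(D)J recombination the second exon of an antigen-receptor gene is
assembled from V, D and J segments by imprecise non-homologous end joining:
each joining end loses a random number of template nucleotides and each
joint gains random non-templated (N) nucleotides. Because the net length
change is effectively uniform mod 3, two of the three frame outcomes shift
the reading frame of the constant region, creating a premature termination
codon (PTC). Nonsense-mediated decay (NMD) clears such transcripts by two
routes: an exon-junction-complex (EJC)-dependent route, available when an
exon-exon junction lies sufficiently far (50–55 nt) downstream of the PTC,
and an intron-independent "fail-safe" route thought to sense the PTC's
distance from the poly(A) tract.

The package models a matched pair of engineered alleles that isolate the
downstream-intron requirement: an intron-bearing allele (genotype **A**,
six exons, PTCs in the third exon with three downstream introns) and an
exon-fused allele (genotype **F**, identical spliced mRNA, but the four
constant exons fused into a single final exon so the same PTCs have no
downstream intron). The full pipeline simulates thymocyte populations for
both genotypes, samples decaying molecule pools, and estimates how strongly
PTC-containing mRNA is depleted in each.

## The reference fixture (`gene_models`)

No real locus sequence is used; what matters is the constraint set, not the
bases. The fixture builder draws background sequence from the stop-free
alphabet {A, C, G} (every stop codon starts with T, so such sequence is
stop-free in all three frames) and then places exactly three stop codons:

* the canonical termination codon, in frame 0 near the 3′ end (default
  55 nt of 3′ UTR);
* one stop in frame +1 and one in frame +2, both inside constant exon 3,
  4 nt apart.

Placing a stop into a T-free background cannot create a stop in any other
frame, so the design is constructive; an independent verification pass
(naive frame scans, distance checks) still runs inside a bounded retry
loop and raises a named `FixtureDesignError` if any constraint fails.
Default geometry (0-based mRNA coordinates): exons 60/150/200/150/150/260 nt,
junctions at 60, 210, 410, 560, 710; frameshift PTCs at 268 and 272, i.e.
701 and 697 nt from the poly(A) attachment point (target 700 ± one codon —
with the two PTC frames fixed mod 3 and the stops non-overlapping, the
achievable distance pair is {target+1..+3} × {target−3..−1}); canonical stop
at 912. Introns are 90 nt, random ACGT with GT…AG ends; intron content
never enters any statistic. Exon 1 is a non-coding leader; translation
starts at the first base of exon 2.

Coordinates are 0-based half-open throughout; an exon junction is the index
of the first base of the downstream exon in the spliced mRNA.

## Junction simulation and allelic exclusion (`vdj_sim`)

Trims are geometric on {0, 1, …} with mean 2 nt per end (resampled if they
exceed the segment), N-addition lengths Poisson with mean 3 nt, N bases
uniform ACGT. No junction-length statistics exist for these alleles; these
defaults were chosen once because they make the net frame shift uniform
over {0, 1, 2} — the only property the 1/3–2/3 arithmetic requires — and
they are config-exposed.

Cell fate follows sequential rearrangement with feedback: the first allele
(chosen uniformly) rearranges to VDJ; if productive the second allele stays
DJ; otherwise the second rearranges, and the cell dies if both junctions
are non-productive. Among survivors the two-VDJ fraction is
(1 − p)/(2 − p), i.e. 40% at p = 1/3. Dead cells are retained with fate
`DEAD`; selection happens explicitly downstream.

"Productive" in sequence mode means the frame-0 scan reaches the canonical
stop: in frame *and* no stop created inside the junction read-through.
About 8% of in-frame junctions acquire such an internal stop under the
defaults (N additions supply T's into a T-free neighbourhood, and the
stop-free segment alphabet makes the A/G-rich continuations relatively
likely), so the sequence-mode productive fraction is ≈ 0.31 rather than
exactly 1/3. Tests therefore check the frame arithmetic at its binomial
error and the productivity with a 0.05 allowance; the abstract mode, used
for the allelic-exclusion quantities, draws productivity as Bernoulli(1/3)
exactly.

## PTC annotation (`ptc_annotate`)

The annotator scans codons from the CDS start, calls the first stop, and
classifies: `PTC_NEG` (productive), `PTC_EJC` (some junction lies more than
`threshold_nt` downstream), or `PTC_FAILSAFE` (PTC present but no
qualifying downstream junction — in this fixture, last-exon PTCs of the F
allele). The threshold defaults to 55 nt, the conservative end of the
published 50–55 nt range, with strict inequality. The distance is measured
from the last base of the stop codon (`dist = junction − (ptc_pos + 2)`);
measuring from the first base instead (2 nt larger) is available via
`measure_from="first"` since the literature does not fix the origin.
Pre-mRNA molecules carry the class of their spliced product: the
experimental readout types pre-mRNA amplicons by their junction frame, not
by scanning intron-interrupted ORFs. Stop codons are {TAA, TAG, TGA}; no
selenocysteine readthrough.

A per-model `Annotator` memoises results by junction sequence; annotation
depends only on that sequence given a fixed model, and pools re-draw the
same junctions heavily.

## Pool sampling (`decay_pools`)

Pools sample VDJ alleles of surviving cells with replacement, 1:1 per
allele (the relative transcription of the non-productive allele is unknown;
1:1 is the neutral default and is config-exposed). DNA accepts every draw;
RNA pools accept with probability s(genotype, molecule, class) and redraw
otherwise — per-molecule thinning, because NMD acts on transcripts, not
cells. Defaults: survival 1 everywhere except PTC-containing mRNA, where
s_A = 1/12 and s_F = 1/3. Under this model E[RNA odds] = DNA odds × s,
so the odds-normalised fold reduction is an unbiased (in log) estimator of
1/s. PCR bias and sequencing error are not modelled; counts are treated as
unbiased draws. Each pool writes a FASTA of junction sequences plus a truth
table, and the pipeline re-annotates the FASTA and cross-checks it against
the truth table before counting.

## Statistics (`ptc_stats`)

* **Fold reduction** (default *odds* mode):
  F = (n⁺/n⁻)_DNA ÷ (n⁺/n⁻)_RNA, with PTC⁻ molecules acting as the
  internal control; this equals 1/s under the decay model, which is why it
  is the default over the fraction-mode ratio of PTC⁺ fractions (also
  provided). 95% CIs by nonparametric bootstrap of both pools (10,000
  resamples by default); zero cells in a resample get the Haldane +0.5
  correction; a zero PTC⁺ RNA count yields a flagged lower bound, not a
  crash.
* **Binomial test**: exact two-sided (minimum-likelihood convention, as in
  `scipy.stats.binomtest`) of an RNA pool against the DNA PTC⁺ fraction.
  The DNA fraction is treated as fixed, which is mildly anticonservative
  when the DNA pool is small; the report also computes the mRNA-versus-
  pre-mRNA comparison separately, because published descriptions of which
  reference the test used are inconsistent, and labels both.
* **Monte Carlo genotype comparison**: observed statistic
  Δ = log F_A − log F_F. The null resamples each DNA pool binomially at its
  own fraction and each RNA pool at the fraction implied by that genotype's
  DNA odds times the survival odds pooled across both genotypes;
  p = (1 + #{|Δ*| ≥ |Δ|})/(n_iter + 1), floored at 1/(n_iter + 1) and never
  zero. Degenerate resamples are Haldane-corrected and counted. The
  original test's code is not public; this construction is the package's
  own, is fully seed-controlled, and is cross-checked in the tests against
  an independent Wald log-odds-interaction approximation and shown to hold
  its nominal type-I error (rejection rate at p < 0.05 within [0.02, 0.10]
  over 200 null replicates).

## Pipeline and reproducibility (`pipeline`, `cli`)

`run_experiment` chains fixture → per-genotype population simulation →
pool sampling → annotation (with truth-table cross-check) → counting →
statistics, writing every intermediate artifact. Each stage derives its
generator from the master seed via `numpy.random.SeedSequence.spawn`, so a
rerun is bit-identical and the CLI stage subcommands, fed each other's
outputs, reproduce the end-to-end run exactly. Default problem sizes
(3,000 cells, depth 2,000 per pool, 10,000 bootstrap/Monte-Carlo
iterations) run in about a second; the test suite uses 1,000–10,000-deep
pools and 20-seed replicates, sizes at which the estimator variance is a
few percent — comfortably inside the 10% recovery bands it asserts.

## Synthetic reference tables

The study's count tables were published only as images, so
`tables_synthetic.py` ships *synthetic reconstructions*: counts chosen to
match the summary statistics reported in the text (1,592 total sequences;
DNA odds 2; mRNA fold reductions of exactly 12 and 3 in odds mode; 32%/35%
two-VDJ hybridomas). They validate the arithmetic and the I/O shape; they
are not the original data and are labelled accordingly.

## What the generator does and does not emulate

The generator reproduces the logical structure of the experiment: allelic
exclusion, frame arithmetic, matched A/F transcripts, per-class decay, and
multinomial sampling of sequence pools. It does not emulate: the V-segment
repertoire (one V per locus here vs five primers over 34 segments),
receptor editing or secondary rearrangement, β-selection beyond the
live/dead rule, PCR/sequencing artifacts, NMD kinetics, or
nonsense-associated altered splicing. Passing tests therefore demonstrate
correctness of the estimators and annotations under the stated model, not
biological completeness.

## Known limitations

* The fraction-mode fold reduction is not invariant to the DNA PTC⁺
  fraction and will not recover 1/s; it exists for descriptive comparison
  only.
* The fold-reduction point estimate has the usual small upward ratio bias
  (~½·var of the log), visible only at shallow depths.
* With `measure_from` and `threshold_nt` at their extremes (50,
  first-base), classifications can differ for PTCs whose junction distance
  falls inside the 50–55 nt window; the default fixture places its PTCs
  ~140 nt from the nearest downstream junction, far from the ambiguous
  zone.
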