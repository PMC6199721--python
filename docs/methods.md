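# Methods

This note documents the models, conventions and parameter choices behind
`tadcomp` — what each procedure assumes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## Coordinates, gene models, and domain assignment

All interval arithmetic is 0-based half-open. GFF3 input (1-based closed)
is converted on read; BED passes through unchanged. A single internal
convention removes the usual off-by-one ambiguities at domain edges.

A gene belongs to a domain flavor only when **both** of its boundaries lie
inside one domain interval; genes straddling an edge are non-members, and
boundary equality counts as inside (containment is non-strict). Domain
intervals within one flavor are merged (overlapping and book-ended
fragments coalesce) before assignment: the containment rule is otherwise
ill-defined for a gene spanning two abutting fragments, and merging makes
assignment invariant to how a caller fragmented its output. How the
original domain callers would have treated a gene spanning two fragments
of the same flavor is unknowable from the calls alone; merging is our
declared resolution.

Three flavors of repressive call are first-class: LAD (lamina-associated),
"Null" (Hi-C TADs lacking active marks), and "Black" (most repressive
DamID chromatin state). The *repressive overlap* class is the genes in all
supplied flavors; *non-repressive* is the genes in none. Chromosome class
(X vs autosome) is a configurable name list (default `X`, `chrX`) so the
analysis is reference-release independent. By default only
protein-coding polyA+ genes are counted in enrichment and class
statistics; a flag disables the filter.

X-vs-autosome enrichment of domain membership uses Fisher's exact test on
the 2x2 table (in-domain/not x X/autosome). The two-sided p sums
hypergeometric probabilities of tables no more probable than the observed
one, with a 1e-12 relative slack so that mirror-symmetric tables stay on
the inclusive side of floating-point rounding. A zero margin leaves the
odds ratio undefined (reported missing) with p = 1.

## Expression cutoffs: separating low from off

Whether repressive-domain genes are *compensated* is only meaningful if
they are *expressed*; the cutoff estimators quantify the noise floor.

* **Percentile of background** (sequencing: intergenic FPKM windows;
  arrays: non-target control probes). Percentiles interpolate linearly
  between order statistics at rank `1 + (n-1) q/100` (q defaults to 99).
  No universal percentile definition exists; this one is fixed and tested
  against an independent sorted-interpolation oracle.
* **EM mixture** (for bimodal normalized-intensity distributions): a
  two-component Gaussian mixture fitted by EM. Initialization splits at
  the sample median (deterministic — no randomized restarts, so results
  are exactly reproducible); component standard deviations are floored at
  1e-3 to prevent collapse; the log-likelihood is checked to be
  non-decreasing at every step and convergence is declared when the gain
  drops below 1e-8. The background is the lower-mean component and the
  cutoff is its q-th quantile, `mu_bg + z_q sigma_bg` (z = 3.0902 at
  q = 99.9). Degenerate fits are flagged non-converged but still report a
  cutoff: a component weight under 0.01, a floored sigma, or — the
  subtle case — unimodal input, detected when the fit's log-likelihood
  gain over a single Gaussian falls below 0.005 per observation (on a
  genuinely bimodal 10,000-point sample the gain is ~0.2/obs; on pure
  Gaussian data it is under 0.001/obs).

Expression filtering is **strictly greater than** the cutoff in at least
one sample of the declared scope; a gene exactly at the cutoff is out.

## Compensation ratios and median matching

Per-gene log2(male/female) ratios aggregate replicates by arithmetic mean
per sex before the ratio (the alternative — medians — changes nothing at
the replicate counts used here; the mean is declared). Genes with a zero
female mean are dropped and counted. Class medians are reported with a
Mann–Whitney U test against the reference class's ratios re-centered on
zero, so the p-value asks "does this class sit away from the compensated
baseline?" rather than "does it differ from another class's location".

Because ChIP signal correlates with expression, class comparisons of ChIP
are repeated on **median-matched** sets: the highest-expressed
non-repressive genes are removed one at a time (ties broken by gene id)
until the non-repressive median is at or below the repressive median. The
returned set is the largest suffix-trimmed set meeting the condition —
restoring the last-removed gene violates it — and matching fails loudly
if the target would be exhausted first.

Knockdown fold changes use a plain, documented normalization rather than
moderated model fits (which belong to the upstream expression pipeline,
not here): counts are scaled to counts-per-million and replicate-mean
CPMs are log2-ratioed with a +0.5 offset; array intensities (already
log-scale) are replicate-mean differenced.

## ChIP summarization and the sex-difference permutation test

Tracks are non-overlapping scored windows (e.g. 25-bp smoothed log
ChIP/input "M values"). The per-gene summary is the **median score of all
windows overlapping the gene body by >= 1 base**; "within gene
boundaries" does not define partial-window behavior, so any-overlap is
the declared rule (at 25-bp windows against >= 500-bp genes the choice is
numerically irrelevant). Genes with no overlapping window are missing,
never zero.

The sex-difference test asks whether the male-specific signal excess
(male minus female gene-body summary) is concentrated outside repressive
domains. The statistic is `median(diff | non-repressive) − median(diff |
repressive)` — medians for robustness, matching the median-centric
summaries everywhere else — and the null shuffles class labels over
genes. What exactly the original analyses permuted is not recoverable
from "permutation test" alone; this scheme is our declared
reconstruction. Note a lattice caveat: on data with very few distinct
values a median statistic ties with the observed value in a large
fraction of shuffles, so small p-values require continuously distributed
differences (true of real M-values and of the generator's output).

All empirical p-values use the add-one convention
`p = (#{null at least as extreme} + 1)/(n + 1)`, guaranteeing p > 0 and
exact validity under exchangeability; two-sided is twice the smaller
tail, capped at 1. One integer seed reproduces every null sample
bit-for-bit.

## Rank and exact tests

Mann–Whitney U uses midranks. The p-value is exact — full enumeration of
rank assignments — for tie-free samples with `n_x n_y <= 400`, otherwise
a normal approximation with tie and continuity corrections (ties force
the approximation). The scipy implementation backs this surface; the test
suite checks it against an independent enumeration oracle, and invariance
under strictly monotone transforms is property-tested.

## Motif scanning with exact null distributions

The PWM is built **directly from user-supplied aligned site sequences**
(21-mers for the MRE), with an additive pseudocount (default 0.1) per
letter: `p[i][b] = (count + pc)/(n_eff + 4 pc)`; `N` letters are excluded
from counts. De-novo motif discovery is out of scope — the entry-site
alignment is an input.

Scanning scores each window by summed log2-odds against the background
(default uniform, overridable by sequence composition). Significance is
exact under an i.i.d. background: per-position scores are rounded to a
lattice (bin width 0.05 bits) and convolved position-wise, giving the
full null distribution of the window score; a window's p-value is the
lattice tail at its own lattice score, so p is exactly monotone in the
lattice score and matches exhaustive 4^w enumeration on the same lattice.
Halving the bin width moves consensus-level p-values by well under 5%.

The **E-value is p times the number of N-free windows scanned**, both
strands counted when reverse-strand scanning is enabled (the reverse
strand scores each window's reverse complement; hit coordinates refer to
the forward strand). A hit requires E <= 1e-5. Windows containing N are
skipped, not scored. The E-value definition is fixed here because
"expect value threshold" alone does not pin down the window count
convention.

## Interval-shuffle overlap tests

The null repositions each domain independently and uniformly on its
chromosome (start ~ Uniform{0 .. L − len}), preserving lengths exactly;
shuffling never crosses chromosomes. Shuffled domains may overlap one
another: independent placement is the simplest analytically tractable
null, and whether the original shuffling forbade overlaps is unknown — a
strict non-overlapping mode (capped rejection sampling) is available
behind a flag for sensitivity analysis; at the default ~20% coverage the
two modes differ by a few percent in expected overlap. The observed and
null statistics count features overlapping >= 1 base of >= 1 (merged)
domain, each feature once. Defaults: 2000 shuffles, depletion and
enrichment tails both reported.

## The synthetic-data generator

The generator is the package's test bed: it plants known structure so
every downstream statistic has a ground truth.

* **Genome**: X 1.5 Mb (500 genes), autosome arms 2L/2R 2.25 Mb (750
  genes each) — ~2,000 genes total, gene lengths 0.5–2 kb, placed
  non-overlapping by jittered equal slots; ~5% non-coding biotypes to
  exercise the biotype filter. Sizes are chosen so the full pipeline runs
  in seconds while keeping every class populated (tens of expressed
  repressive X genes).
* **Domains**: latent repressive segments (40–120 kb) cover 20% of each
  chromosome; each flavor (LAD/Null/Black) includes each segment with
  concordance 0.9/0.95/0.9. One latent state, not independent flavors, is
  what produces the nested overlap structure seen in real calls; flavor
  boundaries coincide with segment boundaries (no boundary jitter).
* **Expression**: log2 baselines Normal(5, 1.5) outside and Normal(3,
  1.5) inside repressive segments; silent fractions 10%/40% drawn near
  2^−4; intergenic background 2^Normal(−4, 1.6) (99th percentile ~0.8
  FPKM, the intended "~1 FPKM" noise floor); array control probes
  Normal(2.0, 0.3) on the log-intensity scale. Per-sample multiplicative
  log-normal noise, sd 0.2 in log2, three replicates. Array intensities
  are log2(value + 0.5).
* **Compensation** is multiplicative on the linear scale (additive in
  log2): male X genes carry dose 0.5 times a gene-network factor (1.1,
  all one-dose genes), an MSL factor (1.4, occupied non-repressive genes
  only), and a regional derepression factor (repressive genes only). In
  the full-compensation preset the derepression factor (2/1.1 ≈ 1.82)
  and a residual factor on occupied genes (2/(1.4·1.1) ≈ 1.30,
  representing compensation routes beyond MSL and network feedback)
  close both routes to an exact product of 2, so every expressed X gene
  has M/F = 1 in expectation. The derepression value needed to close the
  repressive route exactly is larger than empirical regional-derepression
  estimates (~1.1–1.2-fold); the preset prioritizes a clean planted
  truth (ratio exactly 0 in log2) over that quantitative realism.
  Knockdown conditions (kd_mof, kd_msl1/2/3, rox_null) remove only the
  MSL factor from occupied genes, so the planted factor is recoverable
  as `2^(−median log2FC)` of the occupied class.
* **ChIP**: 25-bp windows tiling every chromosome; window means follow
  the overlapping gene's class (male occupied X 1.5, female occupied X
  0.3, repressive X 0.2/0.1 by sex, everything else 0), Gaussian window
  noise sd 0.3, per-target scale factors. H3K36me3 is generated by the
  same sex/class machinery for interface completeness even though its
  real biology is expression-linked rather than sex-specific.
* **Entry sites and motifs**: 150 entry sites (100 bp) on the X, placed
  in repressive segments with odds 0.25 relative to outside (→ ~6%
  inside at 20% coverage); motif copies of a fixed 21-mer consensus
  planted uniformly every ~10 kb regardless of domains, half on each
  strand. PWM-training site sequences are consensus copies with 2%
  per-base mutation. Planted genomic copies are exact: at E <= 1e-5 over
  ~3M windows only near-perfect matches of a sharp 21-bp PWM can
  qualify, so exact planting makes scan recall deterministic (100% at
  the default threshold). Real MRE motifs are far more degenerate and
  occur in the thousands; the generator trades that realism for an exact
  motif ground truth, which is why genome-scale motif counts from real
  data are not comparable to the synthetic scan.

What the generator does **not** emulate: read-level noise or mapping
artifacts, probe-level array effects, aneuploidy of cultured cells,
boundary jitter between domain flavors, expression-coupled ChIP levels,
or motif degeneracy. Passing tests therefore demonstrate that the
statistics recover planted structure of the stated form at the stated
noise levels — not that real data satisfy those forms.

## Pipeline and determinism

`run_full_analysis` executes: domain assignment → cutoffs and expressed
sets → Table-1-style accounting and class expression → M/F ratios → ChIP
class and sex-difference tests → motif scan and shuffle tests →
median-matched ChIP comparison → knockdown contrasts. Each stage writes a
TSV analog of a figure/table; every statistic lands in `manifest.json`
with the seed and parameters that produced it (stage seeds are fixed
offsets from the run seed). Manifests are byte-identical across repeated
runs with the same config and seeds. Stages whose optional inputs are
missing are skipped with a logged warning; missing required inputs abort.
Raw p-values are reported throughout (the class comparisons are few and
pre-planned); a Benjamini–Hochberg column can be added downstream if a
user multiplies tests.

## Known limitations

* The flavor concordance model cannot represent partially overlapping
  domain boundaries (a flavor includes or excludes a whole latent
  segment), so boundary-straddling genes are rarer than in real calls.
* The EM degeneracy check's 0.005/obs likelihood-gain threshold is a
  heuristic; closely spaced mixtures (separation under ~1 sigma) are
  reported as degenerate by design.
* The median-statistic permutation test loses resolution on few-valued
  data (see the lattice caveat above).
* `shuffle_overlap_test` is confined to one chromosome by construction;
  cross-chromosome or gap-aware shuffles (GC matching, masked regions)
  are out of scope.
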