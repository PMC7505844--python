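# Methods

## Scope and data model

The package analyses paired alpha/beta single-cell TCR data in four stages:
per-cell chain partitioning, clonotype calling with compartment-enrichment
testing, convergence (specificity) grouping of beta-chain CDR3s, and
repertoire/QC summaries. Inputs are 10x-CellRanger-style contig annotation
tables (one row per assembled chain) or AIRR Rearrangement TSVs, a cell
metadata table (barcode → patient, sample, compartment, phenotype cluster), a
per-cell QC metrics table, a naive reference CDR3 set (one amino-acid
sequence per line) and a paired analyte table. Only productive TRA/TRB chains
are analysed; non-productive and off-locus rows are dropped with counters,
and within-barcode duplicate consensus rows (same locus, CDR3 nucleotide
sequence, V and J call) collapse to the highest-UMI record so they can never
fake a multiplet.

## Multiplets and clonotypes

A barcode with more than one beta chain or more than two alpha chains is a
multiplet; with alpha chains only, it is alpha-only. Clonotypes are keyed on
the combined alpha+beta CDR3 *nucleotide* sequences, with the alpha tuple
sorted so chain order never matters. Multi-beta multiplets are, by default,
keyed on their sorted beta set and treated as one clone (pairing is
unknowable); a flag excludes them instead, which is the correct mode whenever
clonality is joined to expression data. Multiplets flagged only for excess
alphas, and alpha-only cells, never join clones: a clone requires at least
one beta chain, and the enrichment denominators count clone-assigned cells
only. Whether alpha-only cells should enter the denominators is genuinely
undecidable from the available protocol descriptions; excluding them keeps
the denominator consistent with the clone universe being tested.

## Enrichment statistics

`fisher_exact_2x2` sums hypergeometric probabilities over the conditional
distribution with fixed margins, including every table whose probability is
at most the observed one within relative tolerance 1e-7 (the conventional
guard against floating-point ties; the pmf values come from
`scipy.stats.hypergeom`). Degenerate margins give p = 1. The reported odds
ratio is the unconditional cross-product ratio ad/bc — not the conditional
MLE — reported as +inf when only the denominator vanishes and NaN when both
products vanish; a Haldane–Anscombe 0.5 correction is available for display.
`bh_adjust` is the standard step-up procedure with a final elementwise
max against the raw p values, because p·m/rank can round one ulp below p
when m = rank. The BH family is all clones of one patient's sample pair,
matching per-patient reporting; pooling across patients is the caller's
choice of family. The significance threshold is inclusive (adjusted
p ≤ 0.05). Cluster association uses the same Fisher statistic with
Bonferroni correction over clusters that contain at least one analysed cell;
equal-depth subsampling (for cross-patient pooling) draws uniform subsets
without replacement under a caller-supplied seed.

## Convergence grouping

Following GLIPH v1 conventions, motifs are contiguous k-mers (k ∈ {2,3,4})
of the CDR3 interior after trimming 3 residues from each end, counted at
most once per sequence. The motif universe is the set of *unique* CDR3
amino-acid sequences: multi-beta cells contribute each beta as a separate
suffixed entry (their pairing is unknown, but each beta is real), yet a
duplicate of an already-seen CDR3 must not double-count motif support.
Enrichment is scored against the naive reference as fold change
(observed/reference carrier frequency) and a resampled p: the fraction of
`n_subsamples` = 1000 random reference subsets, of the unique-sample size,
whose carrier frequency reaches the observed one, floored at 1/1000 — so
0.001 is the smallest reportable p at the default depth. Local edges connect
sequences sharing a motif with fold ≥ 10, p ≤ 0.001 and support ≥ 3
sequences; global edges connect equal-length CDR3s at Hamming distance ≤ 1
(V-gene identity is deliberately not required — the generator and reference
share germline anchors, and requiring it would silently change the published
rule rather than parameterize it). Groups are connected components that span
at least two distinct (patient, CDR3) combinations — a component made of one
clone's duplicate entries is a doublet artifact, not convergence — ordered
by descending size with lexicographic tie-break for determinism. The exact
GLIPH parameter values used in the original synovial study are not recorded;
the defaults here are v1 conventions and all are exposed.

## QC engine

Rules are either absolute (GT/LT, strict as printed in the source protocols:
a cell exactly at a boundary is kept) or MAD-based (median ± k·MAD with the
unscaled MAD, median |x − median|). MAD rules are resolved to absolute
bounds against the cohort passed in, and the resolved bounds are returned;
filtering is idempotent for absolute rules and for resolved bounds, while
re-estimating MAD on an already-filtered cohort would not be. The plate
preset's mitochondrial rule is "above median + 5·MAD"; the alternative
reading of the plate protocol (an absolute 8.35% cutoff recorded alongside
the rule) ships as the `plate_fixed_mito` preset, with neither asserted as
the original intent. V–J usage is computed per cell (a per-clone collapse is
a caller-side `drop_duplicates` on clone keys), normalised per patient and
averaged with equal patient weight. The paired panel test is
`scipy.stats.ttest_rel` per analyte with pairwise-complete subjects,
Bonferroni over analytes, and NaN (with a warning) for zero-variance
differences rather than a fabricated 0 or 1.

## Synthetic cohort generator

The generator emulates paired PBMC/SFMC repertoires per patient:

* **Background clones** (default 300/patient) receive weights from a
  truncated power law (exponent 2.5, max 50), and each compartment's cells
  are drawn multinomially with the *same* weights — the background is null
  by construction, which is what makes the no-enrichment calibration runs
  meaningful.
* **Planted enriched clones** (default 5/patient, 30 cells, ratio 10:1 into
  SFMC) are allocated deterministically: the enriched-compartment count is
  the smallest integer whose realized cell-count ratio is at least the
  configured ratio (30 cells at 10:1 → 28/2). The ratio is the planted
  condition itself; rounding it down (27/3 ≈ 9:1) would silently plant a
  weaker condition than configured.
* **Planted convergence groups** (5 cross-patient groups of 6 clones by
  default, the first biased to TRBV28/TRBJ1-1) carry a fixed interior motif
  placed inside the trimmed region.
* **CDR3s** are germline-anchored: V prefix + insert + J suffix, with the
  nucleotide sequence a random synonymous back-translation (so aa length × 3
  = nt length always holds). Inserts draw 3–9 residues uniformly over the 20
  standard amino acids: near-empty junctions are rare in real beta chains
  (D segment plus N additions) and would dominate chance Hamming-1 identity,
  and there is deliberately no recombination or thymic-selection model —
  the generator tests statistics, not biology.
* **Noise**: 5% droplet doublets (two same-compartment cells merged into one
  barcode, yielding multiplets), 10% per-cell alpha dropout, 10% dual-alpha
  clones, optional non-productive extra contigs. Phenotype cluster labels
  are multinomial over eight synovial T-cell states, with the cells of
  planted enriched clones biased toward HLA-DR-high CD8 at a configured
  odds ratio (default 5).

The naive reference generator shares the germline tables and insert model
(no planted motifs by default; `motif_freqs` can seed carriers at a given
frequency so a configured fold change is realizable). What the generator
does **not** emulate: realistic V(D)J insertion/deletion statistics, amino
acid usage bias, cross-clone CDR3 length correlation with gene segments,
expression counts, or batch effects — so passing tests demonstrate that the
statistics behave correctly under their stated assumptions, not that any
particular biological dataset will satisfy those assumptions.

## Sizing of the validation experiments

Calibration and power runs use one patient with 2×2000 cells and 300
background clones; 200 replicates bound the null false-positive replicate
rate and planted-clone recovery. Convergence recovery uses 3 patients ×
2×150 cells with 25 background clones/patient, the 5 default planted groups
and a fresh 10,000-sequence reference per replicate (50 replicates). That
background size is an explicit operating point: for a random k=3 motif, the
expected number of carriers in a sample-sized reference subset is
λ ≈ n·t/8000 (t ≈ 6 interior 3-mers per sequence), and chance groups require
3 carriers at P(Poisson(λ) ≥ 3) ≤ 0.001, so λ must stay near 0.06 — about a
hundred unique CDR3s — for chance motif groups to stay well below the
planted ones. The bundled default pipeline config (3 patients, 2×300 cells,
25 background clones/patient, 3 planted enriched clones/patient, the 5
planted groups) sits at the same operating point so the end-to-end run is
informative at desk scale. The full-scale study geometry (thousands of
unique CDR3s) would need GLIPH's additional depth/subject criteria to keep
chance motifs controlled; that refinement is out of scope here.

## Determinism

All randomness flows from one top-level seed through stable per-stage
derived seeds (CRC32 of the stage name XOR the seed, kept below 2^31);
outputs are written with fixed float formatting and sorted, insertion-stable
orderings, so a rerun with the same config and seed is byte-identical —
verified by hashing every output of two independent runs.

## Known limitations

Beta-only "fragment" clonotypes created by alpha dropout are counted as
separate clones, exactly as a real pipeline keyed on combined CDR3s would;
they slightly enlarge the BH family. The conditional-MLE odds ratio, HLA
restriction, GLIPH2-style scoring, repertoire diversity indices and any
expression-side processing (normalisation, clustering, differential
expression) are out of scope; cluster labels are consumed as input.
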