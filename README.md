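# synovitcr

Paired-chain single-cell TCR repertoire analysis for inflamed-joint studies:
clonotype calling from 10x-style VDJ contig tables, per-clone tissue
enrichment testing between paired compartments (synovial fluid vs blood),
clone–phenotype-cluster association, GLIPH-style CDR3 convergence grouping
against a naive reference repertoire, V–J usage summaries, single-cell QC
filtering and paired analyte statistics — plus a synthetic-repertoire
generator with planted ground truth so every stage is testable end to end
without patient data.

The intended users are computational immunologists analysing paired
alpha/beta single-cell TCR data (e.g. sorted memory T cells from blood and
synovial fluid of arthritis patients) who want a small, fully tested and
reproducible implementation of the standard clonality statistics.

## The statistics at the core

**Clonotype definition.** A cell's clonotype is the combined alpha- and
beta-chain CDR3 nucleotide sequences. Cells with more than one beta chain or
more than two alpha chains are multiplets; because alpha/beta pairing is
unknowable for multi-beta cells, all cells sharing the same beta-chain set
are optionally treated as a single clone (and excluded entirely whenever
clonality is linked to expression data). Alpha-only cells never form clones.

**Clonal enrichment.** For each clone of a patient with paired samples A and
B, the 2×2 table (a, b, c, d) = (clone cells in A, other cells in A, clone
cells in B, other cells in B) is tested with a two-sided Fisher's exact test:
p = Σ P(X = k) over all hypergeometric tables with the same margins whose
probability is at most that of the observed table. The odds ratio is the
cross-product ratio ad/bc. P values are Benjamini–Hochberg adjusted across
all clones of the patient pair and a clone is called enriched in the
compartment with the higher proportion when adjusted p ≤ 0.05 (inclusive).

**Cluster association.** Cells of enriched clones vs all other clone-assigned
cells, per phenotype cluster: Fisher's exact test with Bonferroni correction
over the number of clusters tested.

**Convergence groups.** Beta-chain CDR3 amino-acid sequences are linked
*globally* (equal length, Hamming distance ≤ 1) or *locally* (shared interior
k-mer, k ∈ {2,3,4}, flanking 3 residues trimmed, enriched ≥ 10-fold over an
unselected naive reference with resampled p ≤ 0.001 and support from ≥ 3
sequences). The resampled p is the fraction of 1000 random reference subsets
(of the sample's unique-CDR3 count) whose motif frequency reaches the
observed one, floored at 1/1000. Convergence groups are connected components
spanning at least two distinct (patient, CDR3) combinations.

**QC and summaries.** Named rule presets (droplet fluid/blood: mito > 10%,
genes < 500 or > 3500, UMIs > 25,000; droplet tissue: mito > 10%, genes < 200
or > 2000, UMIs > 10,000; plate: MAD-based mito/counts rules with absolute
read and gene bounds; all inequalities strict) remove cells with listed
reasons. V–J usage averages per-patient pairing frequencies with equal
patient weight. Paired analyte panels use two-sided paired t tests with
Bonferroni correction.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (3 patients, paired 300-cell PBMC/SFMC compartments, 9
planted synovial-enriched clones, 5 planted cross-patient convergence
groups):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_partition_cells.py
python analysis/03_clonal_enrichment.py
python analysis/04_cluster_association.py
python analysis/05_tcr_convergence.py
```

which prints, among other lines:

```
1704 cells: {'MULTIPLET': 89, 'OK': 1615}
266 clonotypes tested; enriched calls per patient: {'P01': 3, 'P02': 3, 'P03': 3}
planted enriched clones recovered: 9/9
strongest association: HLA-DR-high CD8 (OR 4.94, adjusted p 5.93e-16); planted: HLA-DR-high CD8 at OR 5
5 convergence groups; planted motifs: ['GQGD', 'NQNT', 'PHMR', 'WKDR', 'YRGL']
  NQNT: recovered in CRG-1 (fold inf, p 0.001)
```

Reading: the 5% simulated doublet rate surfaces as an observed multiplet rate
of 0.052; every planted enriched clone is flagged at BH-adjusted p ≤ 0.05 and
none of the ~250 background clones is; the planted 5× cluster odds ratio is
estimated at 4.94; and all five planted motif groups are recovered, with the
resampled motif p at its 1/1000 floor. The same pipeline is available as a
CLI (`synovitcr simulate|partition|enrich|associate|converge|qc|usage|panel|all`),
e.g. `synovitcr all --out run/ --seed 1`.

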