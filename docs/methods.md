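# Methods

## Model and procedure

The pipeline infers kinase activity in a *single* quantified
phosphoproteomics sample. Peptide evidence enters through two tab-separated
MaxQuant-dialect tables: a quantified phosphopeptide table
(modificationSpecificPeptides-like) and a phosphosite table
(Phospho (STY)Sites-like). Multi-gene peptide rows are deconvoluted to one
row per gene symbol; decoy/contaminant-flagged rows and rows without
phospho modifications are dropped. Sites are kept only when the
localization probability strictly exceeds 0.75 (class I); rows linking a
site to several accessions or peptides are split. The two tables join on
(gene symbol, peptide sequence); for each (gene, site) combination a single
best-annotated accession is retained (explicit priority map, ties broken to
the lexicographically smallest accession), and rows made redundant by
symbol mapping collapse to one. The merged table records, per (gene,
peptide), the number of distinct class-I sites inferred for the peptide —
the divisor used in substrate attribution.

Four per-kinase evidence components are computed per sample:

* **kinome** — every observed phosphopeptide of an established kinase
  (KinBase-style catalog); peptide phosphosignal = quantification × number
  of phospho modifications.
* **activation loop** — the subset of kinome peptides annotated (Phomics-
  style list, matched on exact gene + peptide pairs; missed-cleavage
  variants must be enumerated in the annotation file) as lying in the
  activation segment. Summing this component on top of the kinome component
  doubles the weight of activation-loop phosphorylation.
* **PSP** — observed class-I substrate sites matched to curated
  kinase–substrate relations on (official substrate symbol, position,
  residue). The site phosphosignal is the sum over the peptides harboring
  the site of quantification × n_phospho / n_inferred_sites, and is
  credited in full to every kinase linked to the site (no fractional
  splitting; homologous kinases sharing a peptide are likewise each fully
  credited).
* **NWK** — the same for predicted relations, after filtering predictions
  to score ≥ 2.0 that also *strictly* exceed 0.9 × the per-site maximum
  (the maximum itself always survives when it clears the floor; ties at
  exactly 0.9 × max are dropped — the literal reading of "exceeds").
  Predictions carrying STRING identifier ENSP00000376688 are attributed to
  LYN. Our prediction dialect requires an explicit residue column; classic
  prediction output, which carries only substrate and position, needs a
  preprocessing join to add it.

The integrated score is INKA = sqrt(C_kin · C_sub) with
C_kin = C_kinome + C_activation_loop and C_sub = C_PSP + C_NWK. A site
claimed by both relation sources is counted in both components by
construction (the components are summed as defined). The skew parameter is
(2/π)·arctan(sqrt(C_sub/C_kin)) — the normalized angle of the point
(sqrt(C_kin), sqrt(C_sub)) — with limits 0 (all kinase-centric), 1 (all
substrate-centric), 0.5 (balanced), and undefined (NaN) when both sums are
zero. The no-square-root alternative (2/π)·arctan(C_sub/C_kin) hits the
same three anchors and is available as `skew_formula="ratio"`; sqrt is the
default because it parallels the geometric-mean construction of the score
itself.

Ranked outputs per sample: the main ranking (INKA > 0, descending, ties
broken alphabetically for determinism), the scatter-plot set (≥ 10% of the
top score), the top-20 bar graph, and the separate *out-of-scope* bar:
catalog kinases absent from both relation sources — computed from the
loaded resources, not read from a file, because the count depends on
resource versions — ranked on C_kin alone, requiring a raw spectral-count
total ≥ 2 (in intensity mode, where no count total exists: ≥ 2 non-zero
evidence rows), capped at 20. Kinases with substrate evidence but no
observed phosphopeptide keep C_kin = 0, hence a zero score; the reciprocal
(substrate-only) ranking is not performed because overlapping substrate
specificities preclude unequivocal attribution.

## Significance

Each null iteration jointly (i) permutes the sample's non-zero
quantification values among the peptides that had non-zero values —
permutation acts on distinct (peptide, n_phospho) entries so site rows
sharing a peptide stay consistent, zeros stay zero, and the count multiset
is conserved — and (ii) re-attributes every relation to a kinase drawn
uniformly with replacement from the distinct kinases of the pooled relation
tables. Scores recomputed on the randomized data form a sample- and
kinase-specific null; the default is 100,000 iterations (tests and examples
use 1,000). The p-value is one-sided upper-tail with the plus-one
correction, p = (1 + #{null ≥ observed}) / (1 + n) ∈ (0, 1] — standard,
conservative, never zero. No multiple-testing correction is applied by
default; Benjamini–Hochberg adjusted values are available as a labeled
extension (`adjust=True`). Counts are permuted within one sample only.
The iteration loop runs on a compiled index-array representation whose
observed scores are asserted (at run time and in the tests) to match the
reference pandas path exactly.

## Network

Nodes are proteins: observed kinases (hexagon semantics), inferred kinases
lacking direct observation (pentagon), and non-kinase substrates (circle);
kinases with an observed activation-loop phosphosite carry a flag for the
thicker border. Edges run kinase → substrate gene, weighted by the summed
phosphosignal of the linked observed class-I sites (per-site values are
kept via the `n_sites` attribute and the substrate-evidence table), tagged
and colored by source (coral curated, cornflowerblue predicted, forestgreen
both). The edge set comes from the top-20 kinases of the main ranking;
because an unobserved kinase can never enter that ranking (its score is
zero), pentagon nodes are added separately: unobserved kinases whose
targets already appear as substrate nodes, with their edges
(`include_inferred=True`, default). Substrates shown are restricted to
sites observed in the sample. Layout is Fruchterman–Reingold with
size-scaled parameters (niter = 100N, area = N^1.8, repulse.rad = N^1.5,
ncell = N^3); the networkx backend honors the iteration count and area
(through the optimal distance sqrt(area/N) and output scale), while the
grid-variant radius/cell parameters are recorded as graph metadata and
logged as approximated. Export is GraphML plus tidy edge/node TSVs; figure
styling is carried as attributes, not hard-coded drawing.

## Drug impact

Activity lists are normalized by their maximum (KAS, top kinase = 1);
per-cell-line drug logIC50 values are median-centered, negated, and divided
by the maximum absolute value (e_j ∈ [−1, 1], potent drugs positive; zero
spread yields all zeros with a warning). The impact score at list length N
is Σ KAS_i · e_j over top-N kinases i and drugs j targeting them; kinases
untargeted by every drug contribute nothing. Two methods are compared at
every length 2..40 with a paired test over cell lines — the Wilcoxon
signed-rank test on per-sample differences (a "paired Mann–Whitney" is
contradictory; an unpaired Mann–Whitney option exists), identical lists
giving p = 1 — summarized by the median per-length p-value. When cell lines
have replicate samples, impact is computed and paired per sample.

## Synthetic data

The generator emulates a phosphotyrosine-IP experiment at toy scale and is
the ground-truth source for all tests. Defaults define the reference
conditions: 50 kinases, 60 substrate proteins, spectral counts ~ Poisson(2)
per peptide (intensities log-normal in intensity mode), one planted driver
whose own peptides and substrate-site peptides draw from a ×10-boosted
mean, and 70% relation coverage of the kinome (uncovered kinases exercise
the out-of-scope path; drivers are always covered, since an uncovered
driver is unscoreable by construction). Realism choices made once: each
protein carries 1–5 tryptic peptides with 1–2 Tyr sites; each kinase's
first peptide is its activation-loop peptide; localization probabilities
straddle the class-I threshold (15% of sites below it, activation-loop
sites included — so a driver's loop peptide can drop out, as in real data);
each covered kinase gets 1–6 curated and 1–6 predicted relations to shared
substrate sites; sub-threshold prediction rows, non-human curated rows, and
decoy/contaminant peptide rows are planted to exercise the filters.
Regeneration with a fixed seed is byte-identical.

What the generator does *not* emulate: missed-cleavage peptide variants,
multiple modification states of the same plain sequence, isoform position
offsets, Ser/Thr sites, correlated peptide abundances, and
match-between-runs artifacts. Driver-recovery results on this background
therefore show that the integration behaves as designed under sparse
Poisson counts with partial annotation — not that it is robust to every
failure mode of real MS data.

## Numerical and design notes

* All thresholds (class-I 0.75, prediction floor 2.0 and fraction 0.9, plot
  fraction 0.1, top-20, out-of-scope minimum 2, iteration count) are
  parameters defaulting to the published values.
* Quantification mode: identical formulas apply to intensities; only the
  out-of-scope inclusion rule changes (see above).
* Merged-table row identity includes n_phospho, so distinct modification
  states of one plain sequence remain distinct evidence rows.
* Degenerate inputs: empty score tables rank to empty outputs with a
  warning; an all-zero sample permutes to itself; an empty relation pool is
  fatal for randomization; a single-node graph lays out at the origin.
* Determinism: all randomness flows through `numpy.random.Generator` seeds;
  rankings break ties alphabetically; generated files and layouts are
  reproducible bit-for-bit under a fixed seed.
* Test problem sizes: the driver-recovery study uses 100 seeds at the
  reference conditions; permutation calibration uses 1,000 iterations and a
  200-kinase null experiment; oracle-equivalence checks run 200 random
  instances per operation at ≤ 50 rows.

## Known limitations

* Substrate matching is by (official symbol, position, residue) only;
  isoform coordinate offsets are not resolved.
* The "best annotated accession" rule is an explicit priority map rather
  than live UniProt annotation ranking.
* The permutation null treats peptides as exchangeable within a sample;
  structured abundance (e.g., protein loading differences) is not modeled.
* iBAQ-style corrections and substrate-only (KARP-style) scoring are out of
  scope; externally produced score lists can still be compared through the
  drug-impact module.
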