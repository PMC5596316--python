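# Methods

This note documents the models and procedures implemented in `tfcatalog`,
the choices made where the design was genuinely open, and what the
synthetic data does and does not establish.

## Catalog construction

**Translation and frames.**  Transcripts are translated with the standard
genetic code on the three forward frames only; transcript models are
assumed correctly oriented, so reverse-strand ORFs are deliberately not
searched (a mis-stranded model is missed rather than silently rescued).
Codons containing N render `X`; stops render `*`; trailing partial codons
are dropped.  All coordinates are 0-based half-open internally; GFF3 and
scanner tables (1-based inclusive) convert at the I/O boundary.

**Frame selection.**  When protein-alignment evidence exists for a
transcript, the frame of the single best hit wins (bit score descending,
then e-value ascending, then lexicographic subject ID — the same
deterministic tie-break used everywhere in the package).  The frame is
`qstart mod 3` on the 0-based query start.

**ORF rule.**  "Simple codon counting" is implemented as the longest
ATG-initiated, stop-free codon run in the selected frame, terminated by a
stop or the sequence end; without a frame, the longest such run across the
three frames (ties: lowest frame, then lowest start).  A frame with no ATG
falls back to its longest stop-free stretch, recorded via
`OrfCall.atg_anchored = False`.  An ATG-anchored rule was chosen over
start-anywhere because it is the common minimal ORF heuristic and gives a
well-defined start; the fallback keeps hit filtering possible on truncated
models.  The ORF caller is verified against an exhaustive ATG-to-stop
enumerator on random sequences.

**Hit filtering.**  A hit survives iff (significance flag = 1 **or**
e-value < 0.01, strictly — "better than" is read as strict), its frame
equals the ORF frame, its envelope lies inside the ORF protein span, and
its family is accepted.  The scanner's 0/1 significance column is taken as
the "confidence" value: it is the only binary column in the standard
tabular dialect.  Overlapping-but-different-frame hits are dropped;
filtering is monotone in the e-value threshold.

**Families and curation.**  The accepted-family list is a configuration
input (YAML); the package ships a compact default of well-known Pfam DBD
families with `zf-C2H2` (PF00096) and `zf-H2C2_2` (PF13465) as the
zinc-finger-only subset, plus a `cers*` exclusion pattern for ceramide
synthases, whose homeobox-like domains lack the DNA-contacting residues.
Real projects substitute their own curated list; nothing downstream
depends on the default's size.

## Orthology and naming

Best hits are per-species (human and mouse); naming authority is the human
match because frog nomenclature follows human symbols (proposals are
lower-cased), with mouse hits carried as corroboration only.  The e ≤ 1e-8
gate is applied when tables are loaded, not inside comparison logic.
`(q, s)` is a reciprocal best hit iff each is the other's best; expansions
are queries sharing a best subject (≥ 2), of which at most one can be
reciprocal.  Suffixing of expanded-family names is left to the caller —
the package flags, it does not rename.

## Expression and differential expression

**TPM** follows the standard definition; each column sums to 1e6 (exactly,
up to float error) and is invariant to column scaling.  Detection uses the
arithmetic mean of replicate TPMs (the natural reading where replicates
are biological clutches); the threshold ladder keeps the conventional
mixed strictness: > 0, ≥ 1, > 10, ≥ 1000.

**The DE model** is a simplified two-component empirical-Bayes
negative-binomial mixture producing a posterior probability of DE (PPDE)
per gene, with the same output contract as heavier EB engines so the DE
component stays pluggable (`call_poles` accepts an external `ppde_table`):

- *Normalization*: median-of-ratios size factors over the samples in the
  comparison (computed once across all regional samples for the pairwise
  screen).  Note the global consequence: a fold change shared by nearly
  every gene is absorbed into the size factors — the model detects
  *relative*, not absolute, changes.
- *Dispersion*: per-gene method-of-moments estimate from within-group
  moments, averaged across groups, then shrunk halfway to the across-gene
  median and clipped to [1e-3, 5].  With two replicates per group the raw
  estimate has one degree of freedom; without shrinkage the null
  calibration at the 0.95 cutoff degrades badly.
- *Marginal likelihoods*: the unknown mean is integrated over a shared
  log-normal prior fitted to the observed per-gene pooled means (sd
  floored at 0.75), by trapezoid quadrature on 121 log-spaced nodes
  spanning the data ± 3 prior sd.  H0 uses one shared mean; H1 integrates
  each group separately, which builds in the Occam penalty for the extra
  parameter.
- *Mixture weight*: the global DE fraction is fitted by EM over all genes
  (clamped to [1e-4, 1−1e-4]); PPDE follows from Bayes' rule.  Under a
  pure null the weight collapses and almost nothing crosses 0.95; with
  planted signal the weight settles near the planted fraction.
- All-zero genes get PPDE 0; each condition requires ≥ 2 replicates.

Measured behavior (recomputed by `scripts/acceptance.py` and the test
suite, 2000 genes, 2 vs 2, NB size 10): null false-positive rate at
PPDE ≥ 0.95 well under 1%; power ≥ 90% on 8-fold genes at base mean ≥ 100.

**Pole rule.**  Dorsal/ventral compares DMZ vs VMZ; animal/vegetal
compares AC vs VEG.  The lateral marginal zone participates in the
any-pair screen but not in the axes; whole-embryo samples serve detection
only.  Fold changes use replicate-mean TPM with pseudocount ε = 0.01
(zeros are common at this depth), so at most one pole per axis is possible
and a call requires fold ≥ 2 AND pole TPM ≥ 1 AND PPDE ≥ 0.95 jointly.
Whether published 2-fold ratios were taken on TPM means or posterior fold
changes is generally unstated; TPM means were chosen as the directly
observable quantity.

## Clustering

Ward/Euclidean linkage is scipy's; the test suite holds it to an
independent O(n³) sum-of-squares agglomerator.  Flat clusters cut every
edge whose parent-child height gap exceeds 5 (leaves sit at height 0, so a
leaf directly under a high merge is its own cluster); the remaining
components are the clusters.  The threshold applies to the
normalized-profile linkage heights exactly as computed.

Family enrichment builds one 2×2 table per (cluster, family) over the
universe of clustered, family-annotated genes — multi-family genes count
once per family — with two-sided Fisher tests and BH adjustment across all
tested pairs (FDR < 0.1 significant).

The spatial heatmap z-scores each gene across the five region means
(sample sd, ddof = 1; zero-variance genes dropped), Ward-clusters the rows
of the Pearson correlation matrix of z-profiles (a literal reading of
"clustering the correlation of the z-scores"), and orders leaves within
the dendrogram's free rotations by decreasing AC/VEG mean-TPM ratio
(ε = 0.01), putting animally enriched genes at one end and vegetally
enriched ones at the other.

## Synthetic data: what it emulates and what it does not

The generator plants every structure the downstream stages assume, under
one integer seed (children derived deterministically; identical configs
reproduce byte-identical outputs):

- *Transcripts*: each TF gene carries an ATG-initiated, stop-terminated
  ORF (120–250 codons) between random flanks; rejection sampling
  guarantees the planted ORF is the unique longest across frames, so
  closed-loop recovery isolates the filtering logic from ORF-rule
  ambiguity.  Accepted-family hits (e < 0.01 or flag 1) land inside the
  ORF; decoys (for `decoy_frac` of genes, default 0.2) fail the threshold,
  the frame, or the location, and must never survive filtering.
- *Homology*: forward best hits point to planted human partners with
  strictly ordered bitscores (ties only on request); ~10% of mapped humans
  take two frog genes (expansions), exactly one reciprocal.
- *Counts*: NB(mean, size) with size = `nb_dispersion` (default 10, i.e.
  between-clutch CV² ≈ 0.1), gene base means log-normal (median 30,
  sd(log) 1.2, floor 0.5), library factors log-uniform in [0.7, 1.3].
  The regional design is 5 regions + whole embryo × 2 replicates; planted
  pole genes have their pole-region mean multiplied by `pole_fold`
  (default 4).  The time course is one library per timepoint (default 30)
  with Gaussian bursts (width ≈ n/12) over a 3% baseline, centered on one
  of 5 planted windows.

Not emulated: read-level noise (FASTQ/mapping), sequence-level homology
realism, splice isoforms, cross-contamination between dissected regions,
and any correlation between DBD family and burst timing (so family
enrichment on synthetic data is a true null).  Passing tests therefore
demonstrate the correctness of the *computations* under the stated
statistical assumptions — not the biological fidelity of any particular
catalog or enrichment result on real data.

## Problem sizes and determinism

Tests and the acceptance script use 36–2000-gene simulations: large enough
for the Monte-Carlo claims they make (calibration/power at 2000 genes,
contiguity and KS nulls over 20 seeds), small enough to run in seconds.
All stochastic tests are seeded; hypothesis-based property tests run
derandomized.  Acceptance-script randomness derives entirely from
`--seed` (reduced mod 2³¹).

## Known limitations

- The DE model is a deliberate simplification: no isoform-level inference,
  no batch/clutch pairing (replicates are exchangeable), no exact
  replication of heavier EB engines' numerics — only the same contract.
- Forward-strand-only translation misses mis-stranded models by design.
- The dubious set implements curation-pattern demotion; legacy rescue of
  known TFs without detectable DBDs is representable via provenance but no
  automated rescue rule is shipped.
- `detect_expansions` cannot distinguish a frog-side duplication from a
  collapsed mammalian locus; it reports shared-best-hit structure only.
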