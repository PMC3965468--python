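# Methods

This note documents the models, defaults and design choices behind
`barcodeaudit`, in the spirit of a methods appendix: what each stage
assumes, which knobs matter, and what the synthetic-data validation does
and does not establish.

## Input model and quality control

The pipeline consumes one aligned COI barcode sequence per specimen
(IUPAC codes, `-` gaps, `N`) plus a metadata row (species, genus, family,
region, country, origin, host-plant category). Sequences are assumed
pre-aligned to the barcode region — true of amplicon data sequenced with a
standard primer pair — so no aligner is included; shorter records are
right-padded with gaps into a common coordinate frame and the padding is
treated as missing data.

QC drops records on two grounds:

* **Length.** Ungapped length below `min_length` (default 500 nt,
  inclusive retention at exactly 500 — the barcode-compliance convention
  for the 658 nt amplicon).
* **Reading frame.** No forward frame free of internal stop codons under
  the invertebrate mitochondrial code (NCBI table 5). This is a
  pseudogene/frameshift screen: because the amplicon's starting frame is
  not recorded in the data, all three forward frames are tried and one
  open frame suffices. Reverse frames are not tried (inputs are assumed
  oriented).

Both removal lists are reported and the accounting identity
`n_input = n_retained + |removals|` is enforced by construction.
Ambiguity codes are *not* removed at QC; they are excluded pair-by-pair at
distance time (pairwise deletion), which preserves information for the
sites that are resolved.

## Distances

K2P with pairwise deletion, reported in percent. Per pair: transition
proportion *P*, transversion proportion *Q* and compared-site count *n*
are taken over sites where both sequences are unambiguous A/C/G/T;
ambiguity codes count as missing rather than partial matches (the simplest
defensible rule, and the one that keeps *n* interpretable).

Numerical choices:

* `min_overlap` (default 300 sites) guards against distances estimated
  from short overlaps; the matrix builder either raises (default) or masks
  such pairs as missing under a permissive flag.
* A non-positive logarithm argument means saturation; the pair is reported
  as `+inf` with a flag, never as an exception, so one degenerate pair
  cannot abort a library-scale run. Saturated pairs behave as "greater
  than any threshold" in clustering and are excluded from NJ input.
* The all-pairs computation vectorizes substitution counting through
  one-hot indicator matrix products; counts are exact in double precision
  and the result is bit-checked against a per-site double loop in tests.

Species summaries report maximum and mean intraspecific distance
(undefined for singletons) and the nearest-neighbour distance, defined as
the minimum over all heterospecific *specimen* pairs (robust to uneven
specimen lengths). NN ties across species are broken lexicographically and
flagged.

## Clustering

The BIN proxy is pure single-linkage threshold clustering: connected
components of the graph with edges `d ≤ threshold`. The default threshold
is 2.2% — the seed value of the BIN system — and the audit is cheap to
rerun at 2.0% to mirror the 2% divergence conventions. The graph-analytical
refinement that real BINs apply after single linkage is deliberately not
reproduced; cluster counts from this proxy therefore need not match
published BIN counts, and library-scale concordance claims are validated
against synthetic truth instead.

NJ trees use the standard Saitou–Nei agglomeration (via scikit-bio's
implementation, including its internal tie-breaking); negative branch
lengths are clamped to zero and the clamp count logged. On additive
matrices NJ is exact, and the test suite verifies leaf-to-leaf path
lengths against randomly generated additive matrices to 1e−9. Trees are
written per family, which keeps Newick outputs readable for large
libraries.

## Audit definitions

* **Sharing**: minimum interspecific distance ≤ `sharing_epsilon`
  (default 0.0%, i.e. identical haplotypes). Assemblages are connected
  components of the species-level sharing graph, so A–B and B–C sharing
  chains into one assemblage {A, B, C}. A relaxed *overlap* detector
  (minimum interspecific distance below either species' maximum
  intraspecific distance) is available separately and is never folded into
  the headline success metric — keeping that metric crisp and auditable.
* **Low divergence**: not sharing, and 0 < NN distance < `t_low` (2%).
* **Deep divergence**: maximum intraspecific distance > `t_deep` (2%).
  Singletons cannot be deep-divergent (undefined maximum) or split; they
  are classified MATCH or MERGE only.
* **Concordance**: MATCH = one cluster, private; MERGE = one cluster,
  shared; SPLIT = several clusters, all private; MIXED = several clusters,
  at least one shared. These four classes partition the species set, and
  species split at < 2% divergence are captured by the cluster partition
  itself rather than by a second divergence threshold — no extra parameter
  is introduced.
* **Identification success** = 100·(1 − n_sharing/n_species), evaluated
  nationally and per region. The regional audit recomputes sharing within
  the regional specimen pool: this is precisely the mechanism by which
  regional success can exceed national success when sharing partners do
  not co-occur.

Deep divergence is invariant to the cluster threshold (it depends only on
distances); the split set shrinks weakly as the threshold rises. Both are
property-tested.

## Statistics

* **Mood's median test**: pooled median over all groups; per group, counts
  above vs at-or-below the median (ties in the at-or-below cell); Pearson
  chi-square on the k×2 table without continuity correction, df = k−1.
  These two conventions are validated by exact reproduction of the
  published host-plant contingency's chi-square (94.89, df 3). Degenerate
  one-sided tables raise with advice to use an exact test.
* **ANOVA**: explicit between/within sum-of-squares decomposition;
  `F = MS_between/MS_within`; `anova_from_sums` rebuilds the table from
  printed SS/df. All-identical input is reported degenerate with F = 0.
* **Welch t**: scipy's statistic with the Satterthwaite df computed
  explicitly (scipy does not return it).
* **Balanced resampling** draws without replacement — the design is a
  random *sample of cases*, not a bootstrap — and is deterministic per
  seed.
* p-values come from the usual reference distributions; the package's own
  validation anchors on the statistics, not the p-values.

## Synthetic data generator

Sequences evolve along a star-of-stars genealogy (root → genus ancestors →
species ancestors → specimens). A full coalescent would add realism the
audit cannot see — it consumes distances only — so controlled divergence
scales are the design goal. Substitutions are applied per site with a
transition fraction κ/(κ+2) (default κ = 2), matching K2P's rate
structure so the estimator is matched to the generator.

Defaults define the standard validation conditions: 100 species in 25
genera (sizes skewed ∝ 1/rank), 10 specimens per species, 658 nt,
within-species scale 0.3%, congener scale 8%, sharing probability 0.05 per
congeneric pair, deep-split probability 0.1 at offset 4%, three regions
with independent occupancy, host-category frequencies roughly matching a
published noctuoid host-plant breakdown, and a 2% introduced-species rate
whose species receive 4% extra divergence (their sister taxon is "left
behind", inflating NN distance).

Implementation details that matter:

* A **sharing event** gives the recipient congener the donor's ancestral
  haplotype *and* copies one specimen verbatim, so planted events are
  identical-haplotype sharing by construction (recovery failures would
  indicate a pipeline bug, not sampling noise). Events chain into
  assemblages via union-find.
* A **deep split** moves half a species' specimens onto a second ancestor
  at offset `delta_deep`; feasibility requires
  intra < delta_deep < inter, enforced at parameter validation.
* Mutations that would create an in-frame stop codon (TAA/TAG) are
  deterministically rewritten at the third codon position so simulated
  libraries pass the reading-frame QC. At the divergences used this
  touches a handful of sites per lineage and does not measurably bias
  realized distances (realized scales are tested to within 25% of
  targets).
* Same seed ⇒ byte-identical FASTA/metadata output (tested).

What passing synthetic tests shows — and does not. They establish that the
audit's classifications are *correct given their definitions* (planted
sharing and deep splits recovered with zero false positives under
well-separated scales: within-species 0.3% ≪ 2% threshold ≪ 8%
between-species). They do not establish performance on real libraries
where divergence scales overlap, where NUMTs/pseudogenes and sequencing
error exist, or where the true BIN refinement differs from single linkage;
the published-table statistics exercise the statistical toolkit on real
numbers but not the sequence pipeline.

## Problem sizes

The bundled validation runs use 20 seeds × (100 species × 10 specimens)
for recovery metrics and 5 seeds × (60 species × 5–8 specimens) for the
regional contrast — large enough that every event class is planted dozens
of times per batch, small enough that the whole suite and the acceptance
script each complete in well under a minute on one core. The distance
stage scales as O(n²L) via BLAS-backed indicator products (~1 s for 1,000
specimens × 658 sites).

## Known limitations

* The BIN proxy omits cluster refinement; MERGE/SPLIT counts against real
  BIN assignments will differ.
* Sharing at ε = 0 requires exactly identical haplotypes over compared
  sites; near-identical overlap is reported separately, not in the success
  metric.
* The frame screen assumes forward orientation and cannot detect a
  pseudogene that happens to retain an open frame.
* The family-summary totals row uses species-count weights; other
  weightings of per-family percentages are possible and will differ.
* NN tie-breaking and cluster numbering are deterministic conventions, not
  biological claims.
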