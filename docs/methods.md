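# Methods

## Background and scope

In the mouse main olfactory epithelium (MOE), five dorsoventral zones
each permit a distinct subset of the ~1000-gene olfactory receptor (OR)
repertoire, yet every mature olfactory sensory neuron (mOSN) transcribes
a single OR allele.  Two graded, opposing processes are thought to shape
that outcome: low-level *polygenic* OR transcription in progenitor (INP)
cells, which defines the choosable repertoire of each zone, and
*heterochromatic silencing* of OR gene bodies, which increases with the
dorsal offset between an OR's native zone and the cell's zone and prunes
ectopically transcribed dorsal-identity ORs before singular choice.
NFI transcription factors (NFIA/B/X) pattern the ventral arm of both
gradients; their triple knockout dorsalises most of the MOE to a zone-2
identity.  This package implements the analysis suite around those
observations (zonal annotation, single-cell OR profiling, ChIP gene-body
gradients, zone-annotated Hi-C aggregation, single-cell 3D structure
analysis, spatial zonal assignment) together with a generative simulator
that emits every data modality from one latent model, so each analysis
can be validated against a known ground truth.

Out of scope by design: raw read alignment and upstream pipelines,
differential-expression model fitting (a generic DE table is consumed
and thresholded), variance-stabilising normalisation and batch
integration internals, and 3D structure inference from contacts
(structures are consumed, not inferred).

## Zonal annotation

Each OR carries a continuous zonal index in [1, 5]; its integer zone is
the nearest integer, with halves rounded **up** — a deterministic,
monotone choice.  Class I ORs (zone-1-restricted, separately regulated)
are censused as their own category, disjoint from the class II per-zone
counts.  Genomic bins at a fixed resolution (default 50 kb) are labelled
with the set of zones of all ORs overlapping them; a bin's primary label
is the majority zone, ties breaking to the more dorsal zone, with class
I outranked by numeric zones on equal counts.  Downstream Hi-C
aggregation uses the full label sets by default (multi-label bins
contribute to every zone they carry), with a primary-label-only mode for
sensitivity analysis.  Coordinates are 0-based half-open throughout.

The published repertoire census (1011 annotated ORs: 115 class I, 896
class II split 261/283/164/144/44 over zones 1–5) derives from an
external supplementary table that is not redistributed here;
`annotation.synthetic_reference_table` is a clearly-labelled *synthetic
stand-in* whose census matches those totals by construction, used to
exercise the loader, rounding and census machinery end to end.

## The two-rheostat generative model

All functional forms below are this package's own formalisation of a
verbal model; none is fitted to real data.

For a cell of zone `z_c` and a class II OR of zone `z_o`:

* **Permission.** `A = 1` if `z_o <= z_c`, else the ectopic leak
  `epsilon` (default 0).  Class I ORs are permitted only in zone-1 cells
  and are never silenced.  An experimentally induced allele (tetO-style)
  bypasses zonal permission entirely — transgenic drivers are not zonal.
* **Propensity and transcription.** `w = a0 * s(z_o) * A`, where the
  promoter-strength gradient `s(z)` is positive and non-increasing in z
  (default 1.00/0.95/0.90/0.85/0.80, `a0 = 1.5`); the induced allele's
  propensity is multiplied by `(1 + tau)`.  The OR is transcribed with
  probability `1 - exp(-w)`.
* **Silencing.** A transcribed OR at dorsal offset `d = max(z_c - z_o, 0)`
  is silenced with probability
  `sigma(d) = sigma_own + (1 - sigma_own) * (1 - exp(-lambda * d))`,
  multiplied by the induction-escape factor `exp(-w / theta)`.
  Defaults: `sigma_own = 0.1`, `lambda = 3.5`, `theta = 1e6`.
* **Choice.** An mOSN picks among transcribed, un-silenced ORs with
  probability proportional to `w`; an empty survivor set triggers a
  redraw with fresh randomness (hard limit 1000 attempts).
* **NFI knockout.** Class II regulation in cells of zone >= 2 uses the
  effective zone `min(z_c, 2)` for both permission and silencing offset;
  zone-1 and class I behaviour is untouched.

Stages map onto the model as: GBC — no OR transcription; INP — the
polygenic transcribed set; iOSN — transcription plus silencing; mOSN —
plus singular choice.

Parameter rationale.  The repertoire defaults are a ~1/10 scale of the
published census (class I 12; class II 26/28/16/14/5), preserving its
strong dorsal skew.  `lambda = 3.5` makes one zone of dorsal offset
almost sufficient for silencing (sigma(1) ≈ 0.97), which is what lets a
zone-z cell choose a correct-identity OR ~91–97% of the time despite the
dorsal-heavy repertoire — the steepness is forced by the repertoire
composition, not by the ChIP figures, which only require monotonicity.
`theta = 1e6` keeps baseline escape negligible (`w/theta ~ 1e-6`): a
smaller scale lets the escape leak dominate the tiny survival
differences between deeply silenced zones and inverts the dorsoventral
restriction of a weakly induced allele, contradicting the model's own
monotone-silencing premise.  Induction experiments therefore use
`tau ~ 5` (weak, dorsally restricted choice) and `tau ~ 1e7` (strong,
chosen nearly always in every zone).

`choice_frequency` estimates P(choice = target) by Rao–Blackwellised
Monte Carlo: the survivor set of the *competing* repertoire is sampled
and the target's analytic survival and conditional choice probabilities
are averaged, keeping the estimator informative when the target's
survival probability is ~1e-6 (plain counting would return 0/2000).

Determinism: every draw comes from a counter-derived substream of one
master seed (`SeedSequence(seed, spawn_key=...)`), so tissues are
bit-identical across runs and independent of execution order.

## Emission models

* **UMI counts.**  Per-cell Poisson draws: the chosen OR at
  `or_high_mean = 60`; transcribed un-silenced ORs at
  `or_low_mean * w` (INP/iOSN) or `residual_mean = 0.05` (mOSN);
  `ambient = 0.01` background on every gene.  1200 housekeeping genes
  (mean 25), 10 mitochondrial genes (mean 50) and one marker gene per
  stage give QC realism: cells land near 30k UMIs with ~1200 detected
  genes and ~1.6% mitochondrial fraction, so the published QC thresholds
  (1000 genes, 20k UMIs, <5% mito) are meaningful on synthetic data.
* **ChIP densities.**  Per-OR density is the fraction of the zone's
  post-silencing cells in which the OR is silenced, times lognormal
  measurement noise (sd `noise = 0.02`).  With `exact=True` the analytic
  expectation (the infinite-cell limit) is returned instead; the
  noiseless exact table is what makes the "trend exactly −1" property
  well-defined, since finite-cell sampling necessarily produces
  within-zone rank inversions of order 1e-4.  Densities are painted
  uniformly over gene bodies for bedGraph export, so
  `gene_body_density` round-trips them.
* **Hi-C.**  Trans intensity between OR bins is
  `hic_noise + hic_scale * S_i * S_j` with `S` the mean expected
  silencing of residing ORs (silenced ORs co-compartmentalise); cis
  pixels add a `(1+d)^-1.2` decay; pixels are Poisson draws.
  `hic_scale = 200` gives the pronounced trans enrichment of OR
  compartments over background seen in real maps; at the 1/10 repertoire
  scale the zone-5 diagonal averages only ~6 trans bin pairs, and a much
  weaker enrichment would let background noise swamp it.
* **3D structures.**  Each haplotype chromosome is a persistent
  (worm-like) random walk (step 8, direction jitter sd 0.15 rad) from a
  random territory origin; beads of silenced ORs are displaced to
  1+Poisson(2) shared attractor points near the nuclear centre
  (sd 2 around the attractor), so aggregates are interchromosomal and
  their membership is seed-dependent even for a fixed silencing state.
  The stiff backbone plus ~100 kb gene spacing keeps un-silenced OR
  beads out of aggregate radius (10 particle radii) in >95% of cells
  with nothing silenced.  All geometry stays in particle-radius units.
* **Single-cell contacts.**  Bead pairs within radius 6 and
  backbone-adjacent pairs emit Poisson(15) contacts, which puts
  synthetic cells in the 20k–50k contact range so the published
  20k-read QC cutoff is exercised as a contact-count filter.
* **Spatial spots.**  Grid rows map to the five zone bands (rows must be
  a multiple of 5); each spot pools 5–30 mOSN profiles from its band,
  with band-boundary rows drawing 20% of cells from the neighbouring
  band.

What the generator does **not** emulate: doublets, batch effects,
replicate structure, mappability and GC biases, balanced-matrix
artefacts, enhancer-hub (Greek Island) mechanics, and continuous (rather
than banded) spatial gradients.  Passing tests therefore demonstrate
correctness of the analysis kernels and internal consistency of the
model, not performance on real data.

## Analysis conventions and numerical choices

* Single-cell QC uses strict inequalities as stated ("less than 1000
  genes", "< 5% mitochondrial"); "genes" means genes detected at >= 1
  UMI (the 3-UMI rule applies only to OR expression calls).
* The dominant OR of a cell maximises UMIs; ties break to the
  dorsal-most zone, then lexicographic gene id.  DE-table ordering is
  (padj, |fold| descending, gene id).  Dorsal/ventral origin bands are
  zones 1–2 vs 3–5, matching the dissection scheme.
* The dorsoventral ChIP trend is a Spearman rank correlation of class II
  gene-body density against zone with a seeded permutation p-value
  (>= 1e4 shuffles by default; box plots in the original figures imply
  no specific statistic, so it is swappable).  Class I ORs are excluded.
* Contact matrices are normalised to counts/billion using the symmetric
  total (off-diagonal pixels counted twice); normalising twice is an
  error.  Cis blocks aggregate native bins by sum to 100 kb and cap the
  display copy at 150 contacts per bin, leaving the raw block uncapped.
  Unobserved trans pixels count as zeros: at fixed depth an absent
  contact is informative.
* OR aggregates are connected components (size >= 2 — a lone OR is not a
  compartment) of the radius-10 proximity graph over OR beads, loci
  resolved to the nearest bead per haplotype.  Contact density is the
  count of contacts with both ends within a 50 kb neighbourhood of a
  group locus, divided by the number of eligible haplotype-locus pairs.
* The rank-sum test enumerates the exact U null when min(n) <= 8 without
  ties, otherwise uses the normal approximation with tie and continuity
  corrections; both branches are cross-checked against an independent
  implementation in the tests.
* Spot normalisation is log1p of median-depth-scaled counts — a
  documented simple stand-in for variance-stabilising transforms.
  Clustering is seeded k-means on a 5-PC embedding of the OR-restricted
  matrix (k = 5), replacing graph clustering.  Zone assignment is the
  argmax of summed normalised OR counts per zone set, "none" for spots
  without OR transcripts, ties to the dorsal-most zone; class I wins are
  reported merged with zone 1.  Cross-replicate integration is omitted
  (single-batch synthetic data).
* The spot filter keeps spots with >= 2 distinct OR genes **and** >= 3
  OR UMIs, following the operational statement of the thresholds; the
  alternative reading ("more than two") appears in prose only.

## Problem sizes

Defaults are chosen so the full test suite runs in well under a minute
of simulation time and the acceptance script in ~20 s: 48 cells/zone for
directional checks, 2000 cells/zone (three zones) for parameter
recovery, 48 + 48 single-cell structures, a 15-row spot grid, and a
25-cell/zone demo pipeline.

## Known limitations

* The zone-pair map averages over bins that can mix zonal identities;
  with ~100 kb gene spacing and 50 kb bins the mixing is mild, but the
  map's absolute values are not comparable across repertoire scalings.
* Parameter recovery treats the transcription side (a0, s, theta) as
  known acquisition metadata; joint identification of both rheostats
  from densities alone is not attempted.
* sigma(d) saturates quickly at the default lambda, so recovery
  information about lambda comes almost entirely from the d = 1 offset.
* The simulator's spatial tissue has hard band boundaries rather than
  the graded overlaps of real zones; assignment accuracy on real
  sections would be lower near boundaries.
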