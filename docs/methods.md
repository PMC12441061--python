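# Methods

## Locus model

A VNTR locus is modelled as `flank_5p · u_1 u_2 … u_n · flank_3p` with
each `u_i` a 60-nt unit drawn from a motif catalog and `n` between 20 and
125 by default (the documented copy-number range of the *MUC1* VNTR).
The pathogenic lesion is a small insertion inside one unit of one
haplotype (heterozygous, matching dominant inheritance); the canonical
case is a single cytosine, which shifts the reading frame. Insertion
coordinates are 0-based, half-open, "insert before `offset`", used
identically everywhere; comparisons between called and simulated
insertions use the leftmost-equivalent normal form, since an insertion
adjacent to identical bases has several placements rendering the same
string.

The real *MUC1* motif inventory is proprietary; catalogs are user input
(TSV of `motif_id`, 60-nt sequence). The packaged catalog is synthetic —
random sequence at GC ≈ 0.72–0.83 — and is labelled as such.

## k-mer spaces

For k ≤ 60 a window over a tandem array spans at most two adjacent
units, so the k-mers of all ordered pairwise concatenations `u·v` of
catalog units cover everything an insertion-free repeat array can
produce. All ordered junctions are admitted because true unit order is
unobservable from short reads; this is conservative (junction k-mers can
never be mistaken for variant evidence). Diagnostic k-mers for a
candidate insertion are the windows overlapping at least one inserted
base of the mutated unit embedded between every ordered pair of
neighbours, minus the reference space. When the locus flank sequences
are available, the real junction context (`flank·u`, `u·flank`) is also
subtracted: a random flank occasionally spells an insertion pattern at
the junction, and without this filter such loci would produce systematic
low-confidence false calls on variant-free data (observed once in eight
error-free simulations during development). Default k = 25: well under
the 60-nt unit so windows stay informative, and short enough that
100–150-bp reads contribute many windows per read.

## Depth score and confidence

Per candidate: `alt_depth` is the mean count of its diagnostic k-mers
over the screened reads (both orientations), `depth_score =
alt_depth / (alt_depth + total_depth)`, and a call is High confidence iff
`depth_score ≥ 0.00515` (inclusive) and `alt_depth > 20` (strict) —
boundary semantics pinned by tests.

The choice of `total_depth` deserves care. Every repeat k-mer recurs in
all copies of its unit on both haplotypes, so its count confounds
coverage with copy number; the mean repeat-k-mer count is approximately
(per-position depth) × (diploid copy sum), and an alternate fraction
computed against it scales like 1/(copy sum) at *any* coverage —
crossing the 0.00515 floor for diploid copy sums above ≈ 190 regardless
of sequencing depth. Coverage and copy number are not separable from
repeat k-mers alone. The locus flanks, however, are single copy: the
2(k−1) junction positions (each summed over its candidate k-mers across
motifs) measure per-position locus depth directly. When flanks are
supplied (they are fixed primer context in practice, and the CLI and the
validation harness pass them), `total_depth` is the mean junction-anchor
depth, which makes the depth score a coverage-ratio-like quantity
(≈ 1/3 for a balanced heterozygote, near 0 for spurious support) and
independent of repeat-array length. Without flanks the aggregated
repeat-k-mer mean is used and the copy-number dependence is inherited.
Both the formula and the aggregation (mean vs median) are isolated
behind single functions/config switches so alternative definitions can
be swapped.

Calling is candidate-driven — a configured insertion alphabet (default
`C`; `GGCT` addable) tested at every unit offset — not de novo assembly;
unknown motifs or novel lesions outside the alphabet are out of scope by
design. Candidates with identical diagnostic sets are deduplicated, and
for one inserted sequence only the best-supported context (fraction of
diagnostic k-mers observed, then alt depth) is reported, so one true
insertion yields one call. Low-confidence calls whose insertion exceeds
one base are flagged as probable artifacts but retained.

## Read simulator

The generator emulates the two targeted-panel regimes relevant to this
locus: `broad_panel` at 344× and `adtkd_panel` at 2,424× median VNTR
coverage. Defaults: read length 150, single-end (paired mode with
fragment length ~ N(350, 50) truncated is available), substitution error
rate 0.001/base, constant Q30 qualities (the detector ignores them),
flanks of 200 random bases at GC 0.5 shared by both haplotypes, repeat
counts uniform on [20, 125] per allele. Each allele receives half the
target coverage; read starts are uniform, so interior per-base depth
calibrates to the target (verified to 5%). GC bias down-weights a
fragment of GC fraction f by exp(−g·(f−0.5)) via rejection sampling at
fixed read count: composition shifts against GC-rich (VNTR-internal)
fragments while total depth stays at target. Long amplicon reads span a
whole haplotype flank-to-flank, allele chosen fairly, substitution
errors at 0.002/base, random orientation. All outputs are pure functions
of `(seed, inputs)` with per-operation derived streams, so re-running
the read simulation never perturbs the genotype draw.

What the simulator does **not** model: indel sequencing errors, PCR
chimeras, duplicate reads, quality-score structure, instrument-specific
error profiles, and real motif heterogeneity. Passing validation on
these synthetics therefore demonstrates algorithmic correctness
(soundness of the diagnostic k-mer space, coverage dependence of
sensitivity, artifact-rule behaviour), not clinical performance on real
panels.

## Long-read oracle

Flank anchors are located by edlib infix alignment allowing ≤ 10% edits;
the enclosed VNTR is oriented to coding strand. Reads cluster by VNTR
length (exact 1-D 2-means over the sorted lengths; centroids closer than
30 nt — half a unit — merge, so a carrier pair of equal repeat count
stays together and is separated afterwards by exact length, which the
substitution-only error model leaves intact; indel-noisy platforms would
need length binning first). Consensus is per-column majority over reads
of the modal length. `repeat_count = ⌊len/60⌋`; a remainder r ≠ 0
implies an insertion of length r, localized as the leftmost deletion
restoring an in-phase tiling of catalog units (scan for the first
off-catalog 60-nt block, try deletions around it, verify the whole
restored array; minimum-mismatch fallback under noise). The
reconstruction is also rendered 60 bases per line with the
insertion-bearing line longer, the conventional manual layout for these
repeat arrays.

## Validation harness

Scenarios simulate cohorts case by case (sub-seeds derived by counter,
so any case is replayable), run the detector with the locus flanks, and
score against the simulator's truth sidecar; the long-read oracle can be
run as an independent truth channel and is required to agree. By default
a case counts as detected only on a High-confidence non-artifact call —
the conservative reading under which low-confidence positives are
treated as negatives — with a flag for the screening-first reading.
Sensitivity CIs are 95% Clopper–Pearson. Test problem sizes: 50
non-carrier cases at 344×, 20 carrier cases at 2,424×, and 20 cases per
point on the {10, 50, 344, 2424}× curve, with default genotype bounds
throughout.

## Cohort statistics

The cohort table mirrors a 19-case ADTKD-*MUC1* series: age at
diagnosis, sex, family history, biopsy pathology, hypertension,
hyperuricemia, eGFR or an `RRT (<age> y)` marker, urinary protein, and
serum potassium. Conventions: quantiles by linear interpolation of order
statistics; "ND" excluded from affected denominators, never imputed;
proteinuria counted among patients not on RRT for numeric urinary
protein ≥ 0.15 g/gCr (a documented choice — the customary dipstick-trace
equivalent — since the series states no threshold), with
"negative"/"0"/"auria" non-proteinuric.

Renal survival: event at RRT age (which takes precedence over a later
diagnosis age), censoring at age at diagnosis, product-limit estimator
with events before censorings at ties. Confidence bounds use the
log-transformed Greenwood variance, `S(t)·exp(±1.96·σ(t))` with
`σ²(t) = Σ d_i/(n_i(n_i−d_i))` — the default convention of standard
survival software, and the one that reproduces this series' published
interval; bounds are undefined (NA) once the estimate reaches zero. The
median is the smallest observed time with survival ≤ 0.5 (reported
unattained otherwise), and each median CI bound is where the
corresponding confidence curve crosses 0.5, NA when it never does. On
the packaged table this yields median 48 years, 95% CI (46, NA),
cross-checked in development against R `survival::survfit` on the same
records. The test suite additionally checks the estimator against a
brute-force product-limit computation on fuzzed small instances.

## Known limitations

- Candidate-driven calling cannot discover insertions outside the
  configured alphabet, nor any variant class other than insertions.
- Copy number is not genotyped from short reads; without flank
  sequences the depth score inherits an inverse dependence on the
  diploid copy sum.
- The clustering and consensus of the long-read oracle assume
  substitution-dominated noise.
- Catalog completeness bounds recall: units absent from the catalog
  leave reference gaps that screening and diagnostic filtering cannot
  compensate.
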