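# Methods

## Scope and data model

`polyrep` analyzes monoclonal-antibody (hybridoma) libraries: one record per
hybridoma carries strain, age, isotype/subclass, a six-antigen ELISA profile
(dsDNA, histone H1, Ro52, LPS, insulin, ovalbumin), an autoreactivity flag
from a cell-staining assay (consumed as a pre-called boolean; gating is not
re-derived), and nucleotide sequences of the rearranged heavy and kappa
variable regions. Records whose chain could not be sequenced carry the
sentinel `NS` and are excluded from paired-chain analyses. All internal
coordinates are 0-based half-open; human-readable reports are 1-based.

## Reactivity classification

ELISA plate readers give no universal positivity cutoff, so the default
policy is adaptive: a well is positive when OD > blank mean + k·SD with
k = 3 and at least two blank wells; a fixed-cutoff policy is available, and
the threshold used is recorded in the output provenance. Raising k can only
turn positives negative (tested as a monotonicity property). The category
rule is purely count-based — ≥ 3 positive antigens ⇒ polyreactive, 1–2 ⇒
reactive, 0 ⇒ non-reactive — and is checked exhaustively against a
brute-force counter over all 2⁶ positivity patterns. Records with any
missing OD are reported `not-tested` and omitted from frequency
denominators, which therefore count tested antibodies only.

Dilution series (100 → 0.01 µg/mL) are summarized by two scalars: the
endpoint titer (lowest concentration still positive; ∞ sentinel when never
positive) and the AUC of background-subtracted OD over log₁₀ concentration
(trapezoid rule). Both are emitted because neither alone ranks curves
robustly; no 4PL fitting is attempted.

## Germline reference

The bundled reference is synthetic (filenames say so): one realistic murine
framework per locus, reverse-translated with common codons and
deterministically diversified per gene (45 edits heavy, 40 kappa; minimum
pairwise distance 25 nt heavy / 20 nt kappa framework), with IMGT-style gene
names. 15 heavy-V, 5 D (14 nt each, sharing no 5-mer between genes), 4 J;
10 kappa-V, 5 J. Each V ends in the conserved second-cysteine codon plus a
short CDR3 stub; each J carries its Trp/Phe anchor with a sidecar TSV giving
anchor positions and FR/CDR boundaries. A full IMGT directory can be
substituted through the same FASTA + sidecar interface.

## Annotation

V and J are assigned by best local alignment (match +2, mismatch −1, gap
open −4, extend −1 — standard values for the ~95–100 % identity regime of Ig
V genes); ties break on percent identity, then gene name, making annotation
deterministic and order-independent. J is searched 3′ of the V's
second-cysteine anchor rather than 3′ of the V alignment end, and anchors
are projected linearly from the longest aligned block and validated by
residue. Both choices defend against a systematic artifact of optimal local
alignment at the junction: the V alignment happily extends into, or gaps
around, junction nucleotides that coincidentally match the trimmed germline
tail, which would otherwise truncate the J search space or displace the
anchor by a codon. An anchor whose validated position cannot be found
leaves the CDR3 undefined and the record flagged, never silently wrong.

Heavy D genes are assigned by the longest exact match ≥ 5 nt between the
anchors; shorter cores are reported unassigned, as sub-5-nt D calls are
noise. Productivity requires an in-frame junction (anchor-to-anchor distance
divisible by 3) and no stop codon in the V-through-J translation. The CDR3
excludes both anchors (heavy strings therefore begin "AR…"); the
anchor-inclusive junction is also emitted. Mutations are mismatches against
the assigned germline V up to the end of FR3 — junction positions have no
germline to compare against and are not counted — tallied per region, and
split at codon level: every mutation in a codon whose translation changed
counts as replacement, so replacement + silent always equals the total.
Amino-acid replacement counts are the number of changed codons.

## Clonal grouping

Two paired records are clones when they share heavy and kappa V genes,
identical CDR3 strings on both chains, and identical mutation sets; a record
whose mutation sets strictly contain another's (genes and CDR3s equal) is
clonally related. CDR3 identity is required by default because the junction
is the clonal fingerprint and is not covered by V-mutation lists; a relaxed
mode (same length, ≥ 90 % identity) exists but is off. Clone sets are
connected components of these relations (union–find), so
identical → related → related chains form one lineage. Members equal to the
set-wide mutation-set intersection are labelled `identical-clone` when at
least two such members exist; everything else is `clonally-related`, with
extra-mutation counts per chain measured against the intersection. IgM and
IgG are grouped separately by default (expansion is an IgG phenomenon in
this design); a cross-isotype flag exists. Grouping is verified against a
brute-force all-pairs + transitive-closure oracle on small libraries and is
a partition, invariant to row order. Oligoclonality reports, per stratum,
the number of multi-member sets, the fraction of records in them, and the
largest set; zero denominators are flagged undefined rather than dropped.

## Statistics

Category proportions are compared by Pearson's χ² without continuity
correction (Yates optional); expected counts are reported and cells < 5
warn. Mutation loads use the unpaired two-sided t test, pooled variance by
default with a Welch option; two zero-variance groups with equal means give
p = 1 by convention, flagged. Because strain cohorts were sampled at
slightly different ages (28/47/66 vs 26/47/69 weeks), between-strain χ²
tests match strata by age rank, and within-strain age-trend tests are also
emitted — both comparisons, since the design leaves the intended one open.
No multiple-testing correction is applied by default (Benjamini–Hochberg
available). Both tests delegate to scipy; the test suite checks them against
hand-written closed forms, a non-central-t power oracle, and a 2,000-replicate
null simulation whose rejection rate must sit within Monte-Carlo error of α.

## Simulator

The generator draws, per record: isotype and IgG subclass from strain
presets; a latent reactivity category from age-dependent prevalences; and
per-antigen binding strengths (uniform 0.8–4.0 on the positive antigens,
polyreactive records positive on 3–6 antigens, reactive on 1–2). Anti-Ro52
records are polyreactive by construction — the structural feature this kind
of repertoire shows — and reactive records never bind Ro52. Autoreactivity
is polyreactivity plus an extra Bernoulli margin up to the configured
autoreactive fraction.

Rearrangement: uniform segment choice; geometric trimming (mean 2 nt) of the
V 3′ tail, both D ends and the J 5′ region; Poisson N-insertions (mean 3 nt
heavy, 1 nt kappa). Junctions are redrawn until in-frame and stop-free
(configurable fraction forced productive, default 1.0 — hybridomas secrete
by selection). These settings put heavy CDR3 lengths predominantly
(≈ 98 %) in the 7–15 aa window typical of murine IgM repertoires, with the
tails reaching the published 7–21 aa extremes; they were tuned once and
frozen. SHM is a per-site Poisson over the V region through FR3 (rate
1.3 × 10⁻⁴ per nt per week of age, ≈ 2.4 expected mutations at 66 weeks,
IgG × 1.4 / IgM × 0.6), keeping VH amino-acid replacement loads almost
entirely within 0–7 — the near-germline regime reported for polyreactive
antibodies — with optional WRC/GYW hotspot weighting (off by default; only
counts, not spectra, are analyzed downstream). Clonal expansion copies
founder records (drawn from polyreactive paired IgG) into lineages; selected
members receive a fixed number of extra mutations per chain (default 3 heavy
+ 2 kappa, the observed signature), with boosted binding strengths to mirror
affinity maturation.

Two identifiability constraints keep the latent truth recoverable, both
properties of the generator rather than the biology: (1) junctions are
resampled until the surviving D core is unambiguously attributable (no
competing D shares an equal-or-longer substring of the junction); D cores
under 5 nt are recorded as truth-unassignable; (2) SHM never hits V position
0, since a mismatch at the extreme 5′ terminus is clipped by any local
alignment and is unrecoverable in principle. ELISA emission is a saturating
curve OD = OD_max·b/(b+1) with multiplicative log-normal noise (σ = 0.15)
on the specific signal plus Normal background (0.05 ± 0.01) — typical ELISA
behavior; the source study reports no OD distributions, so these defaults
are asserted only through round-trip recovery (noiseless: exact; default
noise: ≥ 95 % category agreement), not against published values.

### What the simulator does and does not emulate

It reproduces the statistical structure the pipeline assumes: segment usage,
junctional diversity, age-scaled mutation load, rare expanded lineages,
age-increasing polyreactive/autoreactive IgG fractions, IgG2b/IgG2c-skewed
subclass usage versus an IgG3-skewed control. It does not model affinity
maturation dynamics, germinal-center selection, class-switch mechanics,
B-cell subpopulations, indel SHM, allelic variation, or realistic antigen
cross-reactivity correlations. Passing round-trip tests therefore
demonstrates correctness of the analysis code under the stated model, not
performance on real sequencing data with primer artifacts, indels or
contamination.

## Numerical and degenerate-input choices

Alignment score floor 80 for V calls (unannotatable records are reported,
not dropped); queries must be ≥ 100 nt. Empty strata and zero denominators
are emitted flagged rather than omitted. Strength series require ≥ 3
strictly decreasing concentrations. Random draws derive from a single
integer seed per configuration (numpy `SeedSequence` spawning for the
multi-library study), making simulated libraries and the pipeline manifest
byte-reproducible; derived seeds stay below 2³¹.

## Problem sizes

Defaults are desk-scale by design: the bundled study preset is 168 + 186
records (as in the emulated design), round-trip validation uses a seeded
1,000-record library, the null-calibration of χ² uses 2,000 replicates, and
the full pipeline completes in seconds on one CPU.

## Known limitations

The clone/related rule keys on exact CDR3 identity, so convergent junctions
with identical strings from independent rearrangements would merge (the
relaxed-identity mode inherits the same limit); with the printed tables,
which lack per-nucleotide mutation lists, extra-mutation members are
indistinguishable from identical clones. The published pie-chart
percentages depend on unpublished per-hybridoma raw data and are emulated
qualitatively by the presets, not asserted numerically. Kappa-only light
chains (no lambda); genes reported without allele suffixes.
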