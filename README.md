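# polyrep

Analysis of autoreactive B-cell repertoires from hybridoma libraries — the
kind of dataset produced when splenocytes of autoimmune-prone and control
mice are fused into monoclonal-antibody-secreting hybridomas, each antibody
is screened by ELISA against a panel of autoantigens, and the rearranged
heavy/kappa variable regions are sequenced.

The package covers the full desk analysis of such a study:

* **Reactivity classification** — per-antigen positivity calls from raw
  optical densities (blank-based adaptive threshold, mean + 3 SD by default),
  and the standard three-level category: an antibody positive on **≥ 3 of the
  6 panel antigens** (dsDNA, histone H1, Ro52/TRIM21, LPS, insulin,
  ovalbumin) is *polyreactive*, on 1–2 *reactive*, otherwise *non-reactive*.
  Dilution-series strength assays are summarized as endpoint titers and
  log-concentration AUCs.
* **V(D)J annotation** — germline V/D/J assignment by local alignment
  against a bundled reference, productive-rearrangement filtering (in-frame
  junction, no stop codons), CDR3 extraction between the conserved V-region
  second cysteine and the J-region Trp/Phe anchor (anchors excluded, so
  heavy CDR3 strings begin "AR…"), and somatic-mutation counting per region
  (FR1–FR3) split into replacement vs silent.
* **Clonal analysis** — hybridomas sharing heavy and kappa V genes, CDR3s
  and identical mutation sets are *clones*; those sharing genes and CDR3s
  but carrying additional mutations are *clonally related*. Clone sets are
  transitive closures of these relations; oligoclonality is reported as the
  fraction of a stratum belonging to expanded sets.
* **Repertoire statistics** — frequency tables by strain × age × isotype,
  Pearson χ² tests on category proportions, unpaired t tests on VH
  replacement-mutation loads, CDR3-length and IgG-subclass summaries.
* **A ground-truth simulator** — V(D)J recombination with junctional
  diversity, age-scaled somatic hypermutation, clonal expansion and noisy
  ELISA emission, so every stage is testable against known truth without
  wet-lab data. Strain presets emulate an autoimmune-prone (Sjögren's-like)
  line whose polyreactive/autoreactive IgG fractions rise with age, versus a
  wild-type control.

The package also bundles the published per-hybridoma annotation tables of
polyreactive IgM and IgG antibodies (gene calls, CDR3 strings, printed
lengths) from an autoimmune-prone mouse strain at three ages; these drive
the analyses that need no raw sequence data.

## Worked example

Group the published 66-week IgG annotations into clone sets:

```python
from polyrep.tables import load_igg_annotations
from polyrep.clones import group_clones

igg = load_igg_annotations()
sets, membership = group_clones(igg[igg.age_weeks == 66])
print(membership[["set_id", "id", "status", "heavy_v", "kappa_v", "heavy_cdr3"]]
      .to_string(index=False))
```

```
set_id        id          status heavy_v kappa_v        heavy_cdr3
   CS1 H2h4.7.50 identical-clone     1-4    4-91    ARSGGGDYGSSLCY
   CS1  H2h4.7.8 identical-clone     1-4    4-91    ARSGGGDYGSSLCY
   CS1 H2h4.7.94 identical-clone     1-4    4-91    ARSGGGDYGSSLCY
   CS2 H2h4.7.21 identical-clone     5-6   12-46 ARQRTRLRRGVRGYFDV
   CS2 H2h4.7.25 identical-clone     5-6   12-46 ARQRTRLRRGVRGYFDV
```

Two expanded IgG lineages emerge among the twelve 66-week records: a
three-member IgG2b set and a two-member IgG2c set — 5/12 of the sequenced
old-age IgG repertoire, the oligoclonality signature of chronic antigen-driven
selection. (The printed tables carry no per-nucleotide mutation lists, so
H2h4.7.94 — which carries extra mutations — is distinguishable as
"clonally-related" only when mutation columns are present, as they are for
annotated sequence data.)

Run the full simulate → classify → annotate → group → stats pipeline from
the shell:

```bash
polyrep -v run --seed 42 --out demo_run
```

```
polyrep INFO simulate: 354 records -> demo_run/library
polyrep INFO reactivity: 354 records classified (threshold 0.0791)
polyrep INFO annotate: 685 chains in, 353 records out
polyrep INFO clones: 332 records in, 2 clone sets
polyrep INFO stats: 11 test results
19 artifacts in demo_run
```

This simulates the two-strain, three-age study design (168 + 186 records),
calls positivity at blank mean + 3 SD (threshold 0.0791 absorbance units
here), annotates every sequenced chain, recovers the two clonal lineages
planted in the oldest autoimmune-prone cohort, and writes per-figure
frequency tables plus χ²/t-test results and a checksummed run manifest.
Individual stages are available as `polyrep simulate | reactivity |
annotate | clones | stats | validate`.

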