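# Methods

This note records the model assumptions, operational definitions, default
parameters and numerical choices behind `rgpscan`, and what the synthetic
benchmark does and does not establish.

## The RGP model

A region of genomic plasticity is defined purely by comparative absence:
the union of overlapping reference-chromosome segments whose genes lack a
syntenic ortholog in at least one genome of the comparison set, with a
5 kb floor (`min_rgp_len`). The definition makes no assumption about
mobility or origin; the 5 kb floor deliberately excludes isolated
insertion sequences while keeping multi-gene regions. All coordinates are
0-based half-open internally; GFF3 output is 1-based inclusive and BED
0-based half-open.

## Orthology and synteny

* **Alignment.** Smith–Waterman local alignment with BLOSUM62, gap open
  −11 / extend −1 (the standard protein-search scoring), via Biopython's
  `PairwiseAligner`. Identity is counted over the aligned columns (gaps
  included); coverage is the aligned span on the shorter protein divided
  by its length. Pairs are admitted at identity ≥ 30% and coverage ≥ 0.8
  (`min_identity`, `min_coverage`). Where two different but correct
  implementations pick different co-optimal tracebacks, the score is
  identical but identity can differ marginally; the test-suite oracle
  therefore demands exact score agreement and identity/coverage agreement
  within 2 points / 0.05.
* **Candidate pruning.** Full alignments are computed for the top-3
  score-ranked partners of each gene (both directions) after an exhaustive
  all-vs-all score pass; every score is still computed exactly, so no
  admitted pair can be missed by seeding heuristics.
* **BBH.** Best hits are ranked by (identity, coverage, lexicographic
  partner id); bidirectional best hits are the ortholog relation used
  downstream. No paralog clustering is attempted.
* **Synteny runs.** BBH pairs sorted along the reference are chained while
  consecutive pairs advance by ≤ `max_gap`+1 ranks on both genomes with a
  consistent direction (whole-run inversions allowed); runs may wrap the
  origin of circular replicons. `max_gap` defaults to 2: colocalization
  granularity is not standardized in the field, so it is an exposed
  parameter; 2 absorbs isolated insertions without bridging real breaks.
* **Backbone vs displaced runs.** Per genome pair, a weighted longest
  monotone subsequence over the runs (weight = run size, position = median
  partner rank, better of the two orientations) defines the dominant
  colinear backbone. A reference gene is *syntenically present in place*
  in a genome only if its BBH pair lies in a backbone run of ≥ 2 pairs.
  This is the key operational choice: a block translocated elsewhere in a
  partner genome forms its own (displaced) run, breaks synteny with its
  original context, and surfaces as an RGP flagged `relocated`, while
  module *conservation* (below) counts runs anywhere. The backbone search
  is linear, not circular; a genome pair whose colinearity wraps the
  origin would split its backbone into two arcs, which is harmless for
  membership because both arcs survive the LIS when no rearrangement
  competes.

## Detection and cleaning

Missing segments need ≥ 2 consecutive non-syntenic genes
(`min_missing_run`); single-gene absences are point noise (annotation
differences, lone tRNAs). Segments from all comparison genomes merge by
gene-rank union; merged regions < 5 kb are dropped. Boundaries then snap
outward to the nearest *core* genes (syntenic in place in **every**
genome of the set), which homogenizes boundaries between references and
matches the flanking-gene bookkeeping used for hotspots; RGPs whose gene
content is > 50% "present elsewhere" are flagged `relocated` but kept.
Manual curation of the original protocol is approximated by exactly these
two automated rules; both thresholds are parameters.

## Composition signals

* Windowed GC% and GC skew (G−C)/(G+C), window 5000 bp, step 1000 bp
  (window matches the RGP size floor; no published value exists), circular
  windows, N bases excluded. A region is GC-deviant when its mean GC
  differs from the genome mean by strictly more than 2 window-SDs
  (`gc_sd_threshold`).
* CAI: geometric mean of relative synonymous-codon adaptiveness *w*
  against the usage of ribosomal-protein CDS (identified by product
  keyword — standard highly-expressed reference); stops and single-codon
  amino acids excluded; unseen codons floored at w = 0.01. CAI is
  reported per CDS but not used as a classification criterion.
* Atypical composition: mean per-base log-odds of the region under a
  region-trained vs genome-trained order-2 Markov model, standardized
  against 200 random same-length genome windows; the flag fires at
  z > 3. This is a deliberately simple stand-in for interpolated
  variable-order compositional scans and feeds classification only as a
  boolean. A region equal to the whole replicon scores 0 by construction.

## Classification

Precedence prophage > GI > RGP_mob > RGP_none. Prophage: an external
prophage call overlapping ≥ 50% of the RGP, or ≥ 5 phage-keyword genes
including ≥ 1 structural keyword (capsid/tail/terminase/portal/baseplate).
GI: any of tRNA adjacency (a tRNA within 2 gene ranks of either boundary,
`trna_flank_window`), integrase gene, GC deviation, atypical composition.
RGP_mob: any recombination-enzyme gene (transposase/IS, resolvase,
invertase, excisionase, other recombinase — integrase is deliberately GI
evidence, not RGP_mob evidence). The keyword lexicons are plain editable
config in `rgpscan.params`. No ICE class exists (no T4SS detection), and
no attL/attR repeat finding is attempted.

## Modules

The conservation state of an RGP gene is the frozen set of
(genome, run-id) memberships over runs of ≥ 2 pairs — anywhere in the
partner genome, displaced runs included, because conserved blocks
commonly sit at different integration sites in different genomes. Modules
are maximal constant-state gene blocks; using run *identity* (not mere
conservedness) splits adjacent conserved blocks with different partner
context. tRNAs and pseudo-genes inherit the neighbouring state so they
never cut a block by themselves. Presence in a genome follows the strict
"more than 80% (25%)" rule on gene fractions (counts, not base pairs,
since conservation is per-gene). Partial presence counts toward
distribution-group membership by default (`GroupScheme.count_partial`);
the distribution class is the widest tier — genus, cross-genus,
pathogens, family — containing any non-self genome where the module is at
least partially present, else "strain". Functional classes are a
plurality vote of per-gene keyword matches over eight classes with a
fixed tie-break priority (recombination > phage > antibiotic synthesis >
drug resistance > host interaction > environment interaction >
metabolism); no informative gene gives "unknown". Module length bounds
are reported, never enforced.

Deletion intervals match a run of modules as a *whole-module* event when
both deletion edges fall within 200 bp (`deletion_tolerance_bp`) of
module boundaries and the covered modules are consecutive within one RGP;
any other overlap is *sub-module*.

## Hotspots

Every RGP registers at the integration site of each flanking core gene;
sites are ortholog groups (BBH connected components) of flank genes, so
an RGP bounded by two conserved flanks registers twice — site counts are
per flank, matching flank-keyed reporting. Occupancy per genome is the
RGP label, "core genome" (flank present, no RGP), or "inside <rgp>"
(flank gene internal to another RGP). Sites with occupants in ≥ 3 genomes
(`hotspot_min_genomes`) are hotspots; a site is a tRNA-site when any
member flank gene has a tRNA within 2 ranks.

## Synthetic benchmark: what it emulates, what it does not

The generator builds each genome as a shared core backbone (default 110
genes, ancestral random proteins diverged by 5% per-site substitution per
genome, giving ~90% pairwise identity) with islands inserted between
designated core genes. Evidence features are planted literally: a tRNA
gene at the island edge, an integrase or transposase product string, a
codon/spacer GC bias shifted by a requested number of points, a phage
product cassette. Shared module blocks are placed in chosen carrier
genomes, optionally at other sites and with carrier-specific intercalated
genes; translocations move core blocks; deletions excise intervals with
coordinate shifting. Everything is deterministic per seed and emitted as
GenBank.

The default study conditions are: 4 genomes (two per genus), 6 islands of
5–21 kb covering every evidence type, one island with a 16-gene block
shared by two genomes and a 3-gene block shared by one. Protein lengths
are 200–350 aa inside islands so that even the smallest 8-gene island
clears 5 kb by construction. Near-threshold ortholog pairs are generated
by planting an exact evenly-spaced match fraction and *verifying* the
realized identity with the pipeline's own alignment measure, redrawing
until the measured value is within 1 point of the target — realized
identity is checked, never assumed.

What passing these tests shows: the detector, classifier, modularizer and
hotspot logic implement their definitions exactly, recover planted
structure perfectly when evidence is unambiguous, and respect every
threshold strictly. What it does not show: performance on real genomes,
where annotation noise, paralogy, repeat-driven misassembly, partial
genes and genuinely ambiguous evidence degrade orthology and blur
boundaries; real proteomes are ~10× larger; and real product strings are
far messier than the planted lexicon. The scaled test sizes (35–110 core
genes, 200–350 aa proteins, 4–8 genomes) were chosen so the whole suite
exercises every path at desk scale; they are structural conditions, not
statistical ones.

## Known limitations

* Orthology is BBH-only: in-paralogs and family expansions are unmodelled.
* The compositional score is order-2 Markov, not an interpolated
  variable-order model; it is auxiliary evidence only.
* The backbone LIS is linear per replicon pair; heavily rearranged genome
  pairs (many equal-weight run orderings) may classify some in-place runs
  as displaced.
* Plasmids are read but excluded from RGP detection unless
  `--include-plasmids` is given; cross-replicon "absence" is otherwise
  ill-defined.
* Circular-origin wrap is handled for gene ranks, flank search and
  windowed profiles, but an RGP spanning the origin is reported as two
  intervals rather than one wrapped interval.
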