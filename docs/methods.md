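# Methods

## Region model and site enumeration

Each target gene is an independent mini-contig of fixed length (default
3000 nt) with a TSS offset (default 2000): `[0, tss)` is the promoter,
`[tss, L)` the gene body. Coordinates are 0-based half-open throughout and
the TSS is the first base of the body, which makes the 60 × 50 bp tiling
exact and matches BED conventions on export.

Every forward-strand C is a `+` site; every forward-strand G is a `-` site
(a C on the reverse complement at the same forward coordinate). Context is
read two bases downstream on the site's own strand: CG → CpG, CHG, CHH
(H ∈ {A, C, T}). Because targets are extracted subsequences, a site whose
2-nt downstream window runs past the region end cannot be resolved from
the flanking genome; such sites, and any whose window touches an N, are
labeled *ambiguous* and excluded from every downstream statistic rather
than guessed. Count rows at coordinates that are not cytosine sites of the
stated strand are treated as a report/sequence mismatch and abort the run:
contexts are always recomputed from the FASTA, never trusted from the
input report.

## Methylation levels

Per site: methylated reads over total reads, *missing* (not zero) below
`min_coverage`. The default `min_coverage` is 1 — any covered site is
interrogated — and the value is echoed into every output header so an
analysis is self-describing. Gene and context means are read-weighted
(total methylated observations over total observations), which weights a
90/100 site appropriately more than a 1/10 site.

The per-context mean has a second, *literal* mode that additionally
divides by the number of interrogated context sites in the gene. With one
site the modes agree; with many sites the literal mode shrinks toward
zero. The read-weighted mean is the field-standard quantity and the
default; the literal mode exists because the double-normalized form is a
plausible alternative reading of how per-context averages can be defined,
and keeping both behind an explicit flag lets users compare them instead
of silently choosing.

## Site classification and shared-context statistics

Replicate counts within a (condition, part) cell are summed before
classification: a pooled site with any methylated read is *methylated*
(methylation level > 0), with coverage but no methylated read
*unmethylated*, otherwise *uninterrogated*. Pooling is the default because
groups, not replicates, are the unit of comparison; a per-replicate
consensus mode (methylated in ≥ k replicates) is available for sensitivity
analysis.

Within each (group, region) stratum the unmethylated sites are decomposed
into per-context shares that sum to 100 across CpG/CHG/CHH, and likewise
for methylated sites — a closure property the tests assert to 1e-9.

Shared-context percentages between two groups exclude sites
uninterrogated in either group, then report sites methylated in *both*
groups over — default — sites methylated in *either* (intersection over
union, symmetric in the two groups), or over the mean of the two groups'
totals (`either_group_mean` mode, kept because the denominator population
of such "commonly methylated" percentages is not standardized). The same
applies to unmethylated sites.

## Window testing and DMR/DMG calls

Windows are half-open 50 bp tiles; the window size must divide the region
length exactly, so every gene contributes a complete grid and the two
groups of a comparison are always on the same grid (mismatch is a hard
error, not a warning). Counts entering the 2×2 Fisher table are
read-level observations pooled across sites, strands and the group's
replicates; read-level pooling is consistent with read-weighted means
upstream, and a site-level alternative (one unit per classified site)
can be obtained by classifying first and aggregating the labels.

The two-tailed p-value follows the standard hypergeometric rule: the sum
of probabilities of all tables with the observed margins whose point
probability is at most that of the observed table, with a relative guard
of 1 + 1e-7 absorbing floating-point ties. Tables sharing margins share
one hypergeometric evaluation, which keeps full-panel sweeps fast. A zero
margin carries no information about association and yields p = 1; windows
where either group has zero coverage are flagged untested rather than
called. The implementation is verified against a brute-force enumeration
(log-factorial point probabilities, explicit summation) exhaustively over
all tables with row margins ≤ 40 and on 10,000 random larger tables, at
1e-9 relative tolerance, and cross-checked against an independent library
implementation.

A window is a DMR iff p < `alpha` (0.05) and |Δ| > `delta_threshold`
(20 percentage points, strictly — a window at exactly 20.0 points is not
called). The threshold is interpreted in percentage points, not relative
percent, because methylation levels are reported as percentages
throughout. No multiple-testing correction drives the call; a BH-adjusted
column is emitted alongside for users who want it. Calls are made per
context and for all contexts pooled ("all"). A gene is a DMG in a context
iff it has ≥ 1 DMR window there, and a DMG overall iff in ≥ 1 of the three
single contexts.

Metaprofiles average each replicate's per-gene window methylation across
genes (windows with no coverage in a gene are excluded from that gene's
contribution, not counted as zero), then average the replicate curves.

## Synthetic data generator

The generator emulates the study design end to end: two conditions (cool,
warm) × two embryo parts (apical, basal) × three replicates = 12 samples
over i.i.d. random sequences at configurable GC content. Each site's true
methylation probability is

    p = base_level[context] · spatial(position) · group factors

clipped to [0, 1], with binomial methylated counts at Poisson (or fixed)
coverage per site per replicate. Defaults, chosen once as a realistic
desk-scale study:

| parameter | default | rationale |
|---|---|---|
| n_genes | 50 | desk-scale panel; tests use 24–100 per study |
| region_length / tss_offset | 3000 / 2000 | 2 kb promoter + 1 kb body |
| gc_content | 0.40 | plant-genome-like |
| base_level CpG/CHG/CHH | 0.35 / 0.12 / 0.03 | high / intermediate / low ordering of plant contexts |
| promoter profile | linear decline, 1.6 → 0.4 | elevated distal promoter falling toward the TSS |
| body_level_multiplier | 0.3 | low gene-body plateau |
| condition_effect | 1.4 | warm hypermethylation |
| part_effect | 1.2 | extra warm–basal hypermethylation |
| unmethylated_site_fraction CpG/CHG/CHH | 0.3 / 0.5 / 0.7 | constitutively unmethylated sites dominate real methylomes, CHH most |
| epimutation_rate | 0.1 | per-group flips of silenced/active status, so methylated site sets differ between groups |
| mean_coverage | 30 | typical capture depth |

The two strands of a CpG dyad are simulated independently: the analysis
treats strands as independent observations, and coupling them would only
flatter the caller. A bisulfite conversion-failure rate can be folded into
p (default 0). In a *planted* window the group factors, silencing and
epimutation are suppressed and the warm groups receive `p_cool + delta`,
so the true between-group difference equals the planted delta exactly —
the property recovery tests rely on. The seed fully determines the output
bundle, byte for byte.

What the generator does **not** emulate: linkage between neighboring sites
(real methylation is spatially autocorrelated within windows), epiallelic
heterogeneity within a sample pool, coverage biases of capture probes, PCR
duplicates, and incomplete-conversion artifacts. Passing recovery tests
therefore demonstrate the pipeline's correctness under the stated
generative model, not the biological fidelity of that model; in
particular, real per-window counts are over-dispersed relative to the
binomial, so real-data false-positive rates of the pooled Fisher test can
exceed the simulated ones.

## Calibration and power studies

Null calibration uses identical surfaces in both conditions
(condition/part effects 1 and epimutation 0 — any group-specific
randomness would be a real difference, not a null) at 34 genes × 60
windows ≥ 2000 windows with ≥ 200 pooled observations each; the fraction
of windows at p < 0.05 stays ≤ 7 % (Fisher is conservative at these
counts; observed ≈ 4 %). The power study plants 500 CpG windows at a true
30-point difference (50 genes × 10 windows, 20 untouched genes, GC 0.5 and
coverage 25 so planted windows typically carry ≥ 300 observations per
group); sensitivity at the stated coverage is ≥ 0.90 (observed ≈ 1.0) with
null-gene DMR rates near zero. Problem sizes for these studies were chosen
to make the binomial noise on the measured rates small relative to the
bounds being checked.

## Numerical and degenerate-input choices

Missing is always NaN, never 0 — a stratum with no interrogated sites is
absent/logged, not zeroed. Output tables are sorted (gene, position/window,
strand) so reruns are byte-identical and diffable. Input positions are
1-based on disk (the de-facto cytosine-report dialect) and 0-based in
memory. Window grids, group labels and every analysis constant are echoed
into output headers. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`.
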