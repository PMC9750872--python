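# Methods

## Scope and data flow

`chemscreen` implements the quantitative core of a pooled CRISPRi
chemical-genetic screen: read counting against an sgRNA library, per-sgRNA
growth (γ) and drug-sensitivity (ρ) phenotypes, gene-level scoring with
negative-control calibration and discriminant hit calling, and — on the
cell-line-panel side — somatic-mutation filtering and Wilcoxon association
with IC50s, plus four-parameter-logistic IC50 fitting from raw viability
plates. A simulator with known ground truth generates all test inputs.

Wet-lab quantities (binding constants, in vivo efficacy, proteomic or
profiling platform outputs) are outside the package's scope: nothing here
re-measures them.

## Phenotype model

Counts are converted to pseudocounted relative frequencies,
f_i(S) = (c_i(S) + ψ) / Σ_j (c_j(S) + ψ), and log2 enrichments
e_i(A, B) = log2(f_i(A) / f_i(B)). Then

- γ_i = ( e_i(untreated, t0) − median_NT e ) / D_u
- ρ_i = ( e_i(treated, untreated) − median_NT e ) / ΔD

with the median taken over non-targeting sgRNAs. Dividing by doublings makes
phenotypes comparable across screens of different length: they are log2
fitness effects per population doubling (γ) or per doubling of separation
between the arms (ρ). ΔD defaults to 6.1 in the simulator, the separation
between a treated and an untreated arm harvested around three weeks apart;
D_u has no universal value and must be supplied (the simulator's default of
10 corresponds to ~19 days at a ~2-day doubling time).

Parameters that matter:

- **pseudocount ψ** (default 10 reads): keeps log-ratios finite and shrinks
  the enrichment of poorly covered sgRNAs toward 0. Exact invariance of e to
  a uniform rescaling of a sample's counts holds only as ψ/depth → 0; at
  ψ = 10 and ≥ 500 reads/sgRNA the distortion is O(ψ/depth) ≈ 2%. The value
  is recorded in output metadata.
- **min_reads** (default 0 = off): optional t0 coverage filter. Filtered
  sgRNAs carry NaN, never 0 — the filter removes rows, it does not edit
  surviving values.
- **median, not mean**, of the non-targeting enrichments is subtracted, and
  the centering iterates (≤ 4 passes, typically 1) so the recomputed
  non-targeting median is exactly 0.0 in floating point even when the median
  interpolates between two values.
- **replicates**: with several samples per role, phenotypes are computed for
  every numerator/denominator pairing and averaged; per-pair values are
  retained in the result for inspection. No replicate-variance model is fit.

## Gene scoring

Per gene and TSS: the gene phenotype is the signed mean of the top-3 sgRNAs
by absolute phenotype (ties broken by sgRNA id for determinism; fewer than 3
available → mean of all, with the count reported). The p-value is a
two-sided Mann-Whitney U of *all* the gene's sgRNAs versus all non-targeting
sgRNAs — the top-3 rule applies to the phenotype only. The test is exact
(full null enumeration) when both groups have ≤ 8 tie-free observations,
otherwise the tie-corrected normal approximation with continuity correction.
The continuity-corrected approximation deviates from exact by < 0.02 only
once both groups reach ~5 members (worst cases: 0.088 at 2v2, 0.037 at 3v3),
which is why the exact path covers the whole ≤ 8 regime.

Negative-control pseudo-genes are random groups of non-targeting sgRNAs,
sampled without replacement within a group, distinct as member sets, scored
exactly like real genes. Defaults: as many pseudo-genes as real gene/TSS
groups, each of the library's modal sgRNAs-per-gene size — this makes their
score distribution directly comparable to the real genes'. The z-score is
(phenotype − μ_NCG)/σ_NCG with both moments estimated from the pseudo-gene
collapsed phenotypes (μ_NCG is empirically ≈ 0 after median normalization
but is not assumed to be); σ_NCG = 0 is a hard error.

The hit statistic is the discriminant |z| · (−log10 p), thresholded at ≥ 7.
Using |z| makes sensitizing (ρ < 0) and protective (ρ > 0) knockdowns both
callable; the direction is reported from the phenotype's sign. No
multiple-testing correction gates hits; a Benjamini-Hochberg column is
emitted for reference only. Multi-TSS genes collapse to the TSS with the
lowest Mann-Whitney p (ties: larger |phenotype|, then TSS label), retaining
that row verbatim.

## Mutation–IC50 association

Variant classes are canonicalized through an extensible mapping (MAF
`Variant_Classification` labels recognized out of the box). Filtering drops
non-coding and silent variants and in-frame insertions; keeps frameshift
indels and in-frame deletions (which can delete binding sites);
keeps SNV classes (missense, nonsense, nonstop, start-lost — and splice-site
variants, which are treated as coding SNVs) iff CADD Phred ≥ 15. SNVs
without a CADD score are dropped with a warning. The filter is idempotent.

The binary matrix marks a gene mutated in a line if ≥ 1 record survives
(multiple mutations count once). Per-gene association uses the same
rank-sum machinery as the screen (exact for small tie-free groups);
genes with fewer than `min_group` (default 2) lines in either group are
reported with a missing p rather than a degenerate one. The combined
Ras/Raf set {KRAS, NRAS, HRAS, NF1, BRAF} marks a line mutant when any
member is; a singleton set reduces exactly to the per-gene test. P-values
are reported raw, sorted; BH-FDR is an optional column.

## Dose-response fitting

Viability is percent-of-vehicle (vehicle mean ≡ 100%). The 4PL
y = bottom + (top − bottom)/(1 + (x/IC50)^hill) is fitted on
log10-concentration by bounded trust-region least squares
(bottom ∈ [0, 100], top ∈ [50, 150], hill ∈ (0, 10], log10 IC50 within the
tested range ± 3 decades) from a 5 × 3 multi-start grid (IC50 initials
across the tested range × hill ∈ {0.5, 1, 2}), keeping the lowest-cost
solution; tolerances are tightened (1e-14) so noise-free curves return the
generating parameters to ~1e-6 relative. An IC50 outside the tested
concentration range is flagged `extrapolated`; an optional RMSE ceiling
withholds the IC50 on non-monotone/unfittable data. At 5% Gaussian noise
with triplicates on a 10-point 3-fold dilution, single-plate IC50 estimates
scatter with mean relative error ~8% but worst-case ~30% — that scatter is
information-theoretic (the best least-squares fit can sit below the true
parameters' residual), not an optimizer artifact.

## Simulator

The generator emulates the statistical structure the scoring assumes:

- library of `n_genes × n_tss_per_gene` groups of `sgrnas_per_gene` unique
  fixed-length protospacers plus `n_nontargeting` controls;
- sparse per-gene true effects: each gene is a hit with probability
  `frac_hit_genes` (default 0.05); hit genes draw ρ from a two-sided
  magnitude distribution (default |ρ| ~ U(0.3, 0.6), 70% sensitizing) and γ
  from a point mass at 0 (a pure sensitivity screen) — both distributions
  are configurable;
- per-sgRNA activity a_i ∈ [0, 1] (default U(0.7, 1.0)) scaling the
  realized effect, as knockdown efficacy does; non-targeting sgRNAs have
  exactly zero effect;
- starting representation skewed log-normally (σ = 0.5);
- selection: expected log2 enrichment D_u·a_i·γ_g (untreated vs t0) and
  ΔD·a_i·ρ_g (treated vs untreated), i.e. the drug acts as a constant
  per-doubling-difference modifier — pulsed dosing schedules are not
  modeled because the scoring only sees ΔD;
- counts: multinomial at `mean_reads_per_sgrna × n_sgrnas` total depth, or
  Dirichlet-multinomial when `dispersion > 0` (bottleneck/PCR overdispersion;
  dispersion = 0 degenerates exactly to multinomial);
- optional FASTQ emission: each sgRNA contributes exactly its count of reads
  with the protospacer at a configured offset inside a constant scaffold,
  with optional per-base substitution errors and placeholder qualities.

All draws flow from one seed through named SeedSequence streams, so outputs
are byte-identical under a fixed seed and row order never affects results
(truth is keyed to sorted gene/sgRNA ids).

What the simulator does **not** emulate — and hence what passing tests do
not certify about real screens: GC/position-dependent sequencing bias and
base-quality structure, PCR jackpotting beyond symmetric overdispersion,
cell-cycle and transduction (MOI, selection) effects, off-target sgRNA
activity, time-varying drug effect, and correlated sgRNA behavior beyond
the shared gene effect. Recovery results on simulated screens bound the
method's statistical behavior under its own assumptions, not platform
artifacts.

Because the estimator measures a_i·ρ_g, gene phenotypes are attenuated by
sub-maximal activity (top-3 collapse selects the most active sgRNAs, giving
expected attenuation ~0.9 under the default activity distribution);
unbiased-recovery checks therefore pin a_i = 1, while detection-sensitivity
checks use the realistic activity spread.

## Calibration conditions and problem sizes

Recovery and calibration runs use 200-gene screens (5 sgRNAs/gene, 100
non-targeting, 500 reads/sgRNA, ΔD = 6.1, D_u = 10) over 20 seeds; null
association uses 2,000 genes × 53 cell lines; dose-response checks use 100
noisy plates. These sizes give stable estimates (Monte-Carlo SE well below
the decision margins) while keeping a full run in tens of seconds.

## Known limitations

- Exact-match counting only (offset or substring scan); no
  mismatch-tolerant alignment or UMIs — counts from heavily error-laden
  reads are conservative.
- The hit threshold (≥ 7) is a conventional decision boundary, not an error
  rate; the pseudo-gene hit rate is the empirical handle on false positives.
- Mutation association treats lines as exchangeable; no correction for
  hypermutated lines, lineage structure, or multiple testing by default.
- 4PL fitting assumes a monotone response; biphasic curves are flagged via
  RMSE rather than modeled.
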