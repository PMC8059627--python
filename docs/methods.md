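# Methods

## The model

foldscan implements the analysis layer of *global computational mutagenesis*
(also called an unfolding mutation screen): a saturating in-silico scan that
evaluates every possible single-residue substitution of a protein for its
effect on fold stability, and then relates those scores to disease variant
cohorts at the domain level.

The primary input is an L×20 matrix of unfolding free-energy changes
ΔΔG = ΔG(mutant) − ΔG(wild type) in kcal/mol (positive destabilizes), one row
per residue and one column per target amino acid in fixed alphabetical
one-letter order. ΔΔG matrices normally come from an external stability
engine (FoldX-class force fields, homology-model pipelines); foldscan reads
them from a simple TSV dialect and treats the engine as a black box.

### Unfolding propensity

Each ΔΔG is rescaled to a dimensionless unfolding propensity

    ρ = 1 / (1 + exp(−ΔΔG / s)),    s > 0

The underlying method literature fixes only two constraints: ρ must be a
monotone [0, 1] rescaling of ΔΔG, and neutral (identity) substitutions must
center on ρ = 0.5. The logistic is the simplest map satisfying both; the
scale `s` (default 1 kcal/mol, configurable everywhere a propensity is
computed) sets how quickly ρ saturates. At s = 1, ΔΔG = ±2.2 kcal/mol maps
to ρ ≈ 0.9 / 0.1, a reasonable match to the usual "strongly
destabilizing / stabilizing" bands in stability prediction. The transform is
strictly monotone and exactly invertible (ΔΔG = s·ln(ρ/(1−ρ))) for ρ
representable inside (0, 1); beyond |ΔΔG/s| ≈ 15 the logistic saturates
below double precision and no inverse exists — irrelevant at physical ΔΔG
magnitudes.

### Foldability

Per-residue foldability is the row sum of all 20 propensities (identity
column included), giving F ∈ [0, 20]. The 20-term sum is an assumption: a
19-term sum over proper substitutions would cap at 19, and the established
0–20 display range forces the 20-column definition. F near 20 marks residues
destabilized by *any* substitution — structurally critical positions; F near
10 is the neutral baseline (all ρ ≈ 0.5).

### Severity classes

A single propensity classifies into one of four categories by half-open
bins: stabilizing (ρ ≤ 0.3), weak (0.3 < ρ ≤ 0.6), moderate
(0.6 < ρ ≤ 0.8), severe (ρ > 0.8), plus an orthogonal *high-destabilizing*
flag at the strict cut ρ > 0.9. The 0.9 cut is the one fixed convention in
the source analyses; the other edges are package defaults chosen so the
neutral level 0.5 is "weak" and the 0.9 rule sits inside "severe". All four
edges are configurable (`SeverityThresholds`).

### Internal control

The quality of the structure model behind a scan is checked by the
statistics of its identity substitutions (each residue "mutated" to itself):
a perfectly packed model scores ΔΔG = 0, hence ρ = 0.5, for all of them;
rotamer imperfections scatter them around 0.5. `internal_control` reports
the mean, sample SD, the two-sided 95% t-interval, and one-sample t-test
p-values. The historical convention reports the test against 0 (which is why
quoted p-values are astronomically small, ~1e-300 at L > 2000); because the
null of interest is arguably the center 0.5, the report carries both
`p_value` (vs 0) and `p_value_vs_half` (vs 0.5) rather than guessing. The
pass rule is |mean − 0.5| ≤ 0.05 and CI half-width ≤ 0.05, both configurable;
a zero-variance sample (noise-free surrogate) degenerates to a point interval
and passes on the mean criterion alone. In the pipeline the control gates
all downstream annotation (strict mode aborts; `--no-strict-qc` downgrades
to a warning).

### Template-quality combiner

Structure-template Z scores for dihedrals, 1D packing and 3D packing reduce
to one number as Overall = 0.145·dihedrals + 0.39·packing1D +
0.465·packing3D. The weights are the established convention and sum to 1.

## Variant annotation and cohort statistics

Variant tables are HGVS protein-change strings plus free-text phenotypes
(HGMD/ClinVar export style). Parsing is total: one- and three-letter forms,
optional `p.` prefix, stop spellings X/*/Ter (termination),
del/ins/dup/fs substrings (indel), wt == mut (synonymous); anything else is
carried as `unparsed`. Only missense records proceed to annotation — the
analysis concerns unfolding, not premature termination — and the exclusion
log preserves the counts by reason. Phenotype labels normalize through a
fixed case-insensitive dictionary onto an 18-category vocabulary; unknown
labels map to `other` with a warning. Genomic/cDNA notation is out of scope.

Domain assignment uses 1-based inclusive ranges with innermost-region-wins
semantics, so nested motifs (the MYO7A ATP-binding motif inside the motor
domain, the single α-helix inside the coiled coil) shadow their parents;
positions in no region report `unassigned`. The bundled MYO7A map (15
regions, protein length 2,215, UniProt coordinates) ships as a versioned
JSON config, so other proteins are first class. Overlapping non-nested
regions are a config validation error. A "low complexity" region sometimes
drawn in MYO7A schematics has no published boundaries and is omitted.

Cohort aggregation produces per-domain rows (count, unweighted mean
propensity, unweighted mean ΔΔG; zero-variant domains omitted), a
phenotype × domain contingency matrix whose grand total equals the cohort
size, severity percentages (half-up rounding at 2 decimals; display
precision is a presentation choice), and an OLS regression of per-domain
mean propensity on per-domain mean ΔΔG with
adj R² = 1 − (1 − R²)(n − 1)/(n − 2). The regression includes nested
sub-region rows (they are separately tabulated in the published MYO7A
summary, 13 usable HGMD rows and 15 ClinVar rows); including them is
required to reproduce the published adjusted R² of 0.69 and 0.35. The
direction of the fit is immaterial for R²; the slope is reported for the
propensity-on-ΔΔG orientation.

Whole-protein averages can be weighted per mutation or per domain; the
published convention is unstated, so the package computes whichever the
caller asks for and asserts neither.

## The surrogate ΔΔG engine

The published per-mutation MYO7A energies derive from a homology model and a
proprietary-pipeline stability engine and are not reproducible at desk
scale. foldscan therefore separates the pipeline from the engine: real scans
enter via TSV, and a transparent surrogate makes the package self-contained:

    ΔΔG(i, b) = b_i·( w_h·(H(wt_i) − H(b)) + w_v·|V(b) − V(wt_i)|/100 )
                + w_p·[b = Pro, wt_i ≠ Pro] + ε_i·[b = wt_i]

with burial b_i = min(1, N_i/n_max), N_i the count of representative atoms
(Cβ, Cα for glycine) of sequence-non-adjacent residues within 10 Å; H the
Kyte–Doolittle hydropathy; V the Zamyatnin residue volume; defaults
w_h = w_v = 0.5, w_p = 1 kcal/mol, n_max = 20. Losing hydrophobicity or
changing side-chain volume in the core costs energy proportionally to
burial; fully exposed positions are free except for proline introduction,
which is penalized burial-independently (backbone, not packing). ε adds
optional Gaussian noise to the identity diagonal only, emulating the rotamer
imperfection the internal control is designed to detect. The surrogate is
deterministic given its seed and makes no claim to reproduce any published
per-mutation value; it exists to exercise everything downstream of ΔΔG.

## Synthetic data

* **Sequences** are uniform over the 20 canonical residues.
* **Structures** are compact self-avoiding random walks on a 3.8 Å
  virtual-bond chain: steps bias toward the origin outside a core radius
  scaling as 2.4·L^⅓ Å (globular core), the final 15% of the chain drifts
  outward (exposed terminus), and candidate positions closer than 3.5 Å to
  existing non-adjacent residues are rejected with bounded retries. This
  yields burial spanning ~0 to 1 at L = 200 for every seed checked, which is
  the property the pipeline needs — it is not a protein-folding model.
* **ΔΔG matrices** draw non-identity entries from Normal(2·b_i, 1) kcal/mol
  (destabilization grows with burial) and identity entries from
  Normal(0, identity_noise_sd).
* **Cohorts** are built from exact per-category counts: each missense record
  draws its propensity uniformly inside its severity bin
  (high-destabilizing from (0.9, 1)), so classification recovers the spec'd
  counts exactly; termination/indel records carry the corresponding HGVS
  notation; phenotypes draw from a given mix. Random streams are seeded per
  generator, so adding a generator never perturbs existing fixtures.

The two bundled cohort recipes mirror the *printed marginal counts* of the
published MYO7A analyses: HGMD-like (213 records, 35 terminations; severe 93
with 77 high-destabilizing, moderate 51, stabilizing 30, weak 4) and
ClinVar-like (530 records, 2 indels; severe 266 with 221 high-destabilizing,
moderate 201, stabilizing 16, weak 45). The published ClinVar per-category
counts sum to 532 against the stated 528 missense total; the weak category
absorbs the −4 residual here so the severe fraction (50.38%) and
high-destabilizing count (221, 41.86%) both match. Likewise the published
HGMD phenotype counts sum to 169, not 178; they are used as proportions, not
asserted totals. These fixtures are synthetic look-alikes and say nothing
about real per-variant data.

What passing tests show: the scoring, QC, filtering, annotation and
aggregation machinery is correct on inputs with the published statistical
structure. What they do not show: agreement with any engine's per-mutation
ΔΔG, or with the unpublished per-variant HGMD/ClinVar lists.

## Numerical choices and limitations

* Propensity/ΔΔG tables round-trip at 6 significant digits.
* Percentages round half-up (decimal arithmetic, not banker's rounding) to
  2 decimals.
* Regression requires ≥ 3 rows (adjusted R² is undefined below) and a
  non-constant predictor.
* Severity bins are half-open on the left; ρ = 0.9 is severe but *not*
  high-destabilizing (the flag is strictly greater-than).
* Internal control problem sizes used in the shipped checks: L = 120–300 for
  unit tests, one full-length L = 2,215 scan for the end-to-end control
  statistics.
* The minimal PDB reader handles ATOM records only (altloc blank/'A',
  no insertion codes) — it is a fixture-scale reader, not a general parser.
* Duplicate variant reports are kept and flagged (databases list recurrent
  reports); de-duplication is an explicit option.
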