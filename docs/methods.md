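# Methods

## PTM-site quantification chain

The site-level chain assumes a wide matrix of modified-peptide intensities
(one row per site: protein, residue, 1-based position, modification tag;
one column per sample) and a sample sheet assigning each sample a group
label and a replicate index that pairs samples across groups.

1. **Centralization.** Each row is divided by the arithmetic mean of its
   non-missing cells, so the relative values $R$ of every site average
   to 1 across samples (enforced to 1e-9 in tests). Rows that are missing
   everywhere cannot be centralized and are dropped with a logged count.
   Missing cells are excluded from all means; no imputation is performed
   on the PTM side.
2. **Protein normalization (optional).** The protein table is centralized
   the same way and each site cell is divided by its protein's relative
   value in the same sample. When the protein is absent or its value is
   missing in a sample, the cell keeps its unnormalized value and the row
   is flagged `protein_normalized=False`; a protein relative value of
   exactly zero would produce an infinite ratio, so that cell is set
   missing instead. Keeping the fallback (rather than dropping the site)
   preserves sites quantified only at the modified-peptide level.
   Normalization is a flag, not a default, because both normalized and
   unnormalized calling are legitimate analyses with different questions
   (occupancy change vs total modified-signal change).
3. **Fold change** is the ratio of the two group means of relative
   values — deliberately *not* the mean of pairwise ratios. The
   **CV statistic**, by contrast, is built from replicate-paired ratios
   $A_i/B_i$ (matched by replicate index): the sample standard deviation
   (n−1) divided by the mean. The asymmetry between the two definitions
   is intentional and follows the printed formulas literally. With two
   ratios the n−1 convention makes the CV a factor $\sqrt{2}$ larger than
   the population convention; the n−1 form is the standard CV definition
   and is what the thresholds here are calibrated against.
4. **Calling** uses strict inequalities: up requires $FC >$ `fc_up` and
   $CV <$ `cv_max`; down requires $FC <$ `fc_down` and $CV <$ `cv_max`.
   Defaults: label-free 1.3/0.77, TMT 1.2/0.833 (looser because reporter
   ratio compression shrinks observed folds), both with `cv_max` 0.1.
   A site with an undefined fold change or fewer than two usable ratio
   pairs is `undetermined`, not `ns`. Unmatched replicates are excluded
   from the CV only; they still contribute to the group means.
5. **Aggregation** counts a protein as up (down) when ≥1 site is up
   (down); a protein can appear in both lists. This is the weakest
   aggregation consistent with site-level evidence; it implies
   protein-direction counts are bounded above by site-direction counts.

### Operating characteristics of the CV gate

The CV criterion is a *consistency* filter, not a variance-calibrated
test. Under independent multiplicative log-normal cell noise with sd
$\sigma$, a between-group replicate ratio has log-sd $\sigma\sqrt{2}$, so
its population CV is $\sqrt{e^{2\sigma^2}-1} \approx \sigma\sqrt{2}$.
At $\sigma = 0.1$ this is $\approx 0.142$ — *above* the 0.1 cutoff — so a
true site passes only when its two ratios agree by chance: with two
replicate pairs the pass probability is ≈ 0.52, independent of effect
size, and it *decreases* toward 0 as replicates are added. The test suite
measures exactly this (sensitivity ≈ 0.52, false-positive rate ≈ 0.005 at
effect fold 2.0, $\sigma = 0.1$, 2 pairs). The gate therefore trades
sensitivity for a very low false-positive rate; meaningful sensitivity
requires cell noise below $\sigma \approx 0.03$ at `cv_max` 0.1, or a
larger `cv_max`.

## OPLS-DA, VIP and validation

Preprocessing floors missing peak areas at half the metabolite's minimum
observed area (a standard detection-limit surrogate), log2-transforms and
mean-centers each metabolite; no unit-variance scaling is applied, so
high-variance metabolites retain more weight. The response is ±1 class
coding.

The fit removes `k_ortho` y-orthogonal components (default 1, exposed as
a flag) by deflating, from the current X, the part of the loading vector
orthogonal to the predictive weights, then extracts a single predictive
component with weights $w \propto X^\top y$. With `k_ortho=0` this is
exactly single-component PLS, which the tests use as a closed-form
oracle. The fit is deterministic — no random initialization.

VIP is computed from the predictive component only (orthogonal variation
is y-uncorrelated by construction): with unit-norm weights,
$VIP_j = \sqrt{p}\,|w_j|$ and mean $VIP^2 = 1$ exactly.

$Q^2 = 1 - PRESS/TSS$ uses stratified k-fold cross-validation (default 7
folds, clamped to the minority class size; `n_folds >= n` gives
leave-one-out), refitting the centering inside each training fold. Fold
assignment is deterministic given the seed. The permutation test refits
$R^2Y$ and $Q^2$ under uniformly random label permutations (default 200)
and reports $p = (1 + \#\{\text{permuted} \ge \text{observed}\})/(1 + n_\text{perm})$,
whose floor is $1/201$ at 200 permutations. The permutation statistic is
reported for both $R^2Y$ and $Q^2$; $Q^2$ is the stricter and is the one
used in the acceptance checks.

## Metabolite calling, classes and rescue

Metabolite fold changes are ratios of raw-area group means (after the
same half-minimum imputation), not log-space means — peak area is the
quantitative unit, and the ratio of means is what ratio thresholds refer
to. Two calling criteria exist and are never inferred implicitly:
`vip` ($VIP \ge 1$ and $|\log_2 FC| \ge 1$, non-strict) and `ratio`
($\ge 1.5$ / $\le 0.67$, non-strict). Note the PTM thresholds are strict
(">") while metabolite thresholds are inclusive ("≥"), matching the two
conventions as stated.

Lipid classes are resolved by curated annotation first, then
longest-prefix match of the display name against
LPC/LPE/LPA/PC/PE/PI/PA/TG/SM (lyso-forms win over their parent class);
anything else is `other`. Composite groupings — phospholipid =
{PC, PE, PI}, lysophospholipid = {LPC, LPE, LPA} — are computed views,
not stored classes. Class summaries report counts plus percentages with
**half-up** rounding at the requested precision (2 decimals by default,
configurable 0–3), matching how such percentages are conventionally
printed.

The rescue analysis is two-step: (1) stress vs control differential under
the ratio criterion; (2) the rescue/stress ratio must reverse the
direction ($\ge 1.5$ for down metabolites, $\le 0.67$ for up ones). Both
gates must hold; recovery is monotone in the rescue thresholds.

Enrichment of user-supplied annotations uses the one-sided hypergeometric
tail with Benjamini–Hochberg adjustment across categories. It is a
generic over-representation test for any id→category map; no external
pathway database is consulted.

## Synthetic data

The generators are first-class, tested code and define the study
conditions the validation suite runs under.

**PTM arm.** Protein baselines are log-normal (natural-log mean 20,
sd 1.0 — arbitrary intensity units at MS scale); each protein carries a
fixed number of sites whose occupancies are Beta-distributed around
`occupancy_mean` (0.3) with concentration 10. Cell intensity = expected
protein abundance × occupancy × group effect × log-normal noise
(default sd 0.15), masked missing-at-random at `missing_rate`.
Differential sites get `effect_fold` (default 2.0) up or down in the
stress group; TMT ratio compression is modeled as exponent shrinkage
(realized fold = fold^(1−compression)), the simplest monotone compression
consistent with reporter-ion behaviour. With `coupled_protein_effect` the
host protein carries the fold and the site tracks it, so raw site FC
shows the effect but protein-normalized FC is 1 — the scenario where a
site-level change drags total protein down with it. If two differential
sites share a protein their protein effects multiply; the default
configuration makes this rare. Replicates are paired in generation order,
giving the paired ratios the CV statistic presumes.

**Metabolite arm.** Members of each declared lipid class share a
per-group multiplicative effect; baselines are log-normal (log-mean 13,
sd 1.0, typical of integrated MRM peak areas), noise log-normal (sd
0.15), ≥3 samples per group (default 6). When `rescue_fraction` is set a
third group is generated that inherits each metabolite's stress effect
except for the rescued share, whose mean is returned to the control
level — so rescue/stress = 1/effect for rescued metabolites in the
noiseless limit.

What the generators do **not** emulate: spectrum-level artifacts,
retention-time/m-z structure, batch effects, missingness that depends on
intensity (censoring), correlated noise across sites of one protein
beyond the shared abundance term, and class-internal heterogeneity of
effects. Passing tests therefore demonstrate correctness of the
computational chain under the stated generative model, not robustness to
every failure mode of real MS data.

**Seeds and sizes.** Every generator takes an explicit seed (package
default 20221124); all simulation-based checks in the tests and the
acceptance script run at deliberately modest sizes — 100–200 proteins,
1–2 sites each, 20 seeds for operating characteristics, 50–100 null runs
at 60 permutations for calibration, 200 permutations for the p-value
floor — sizes at which every property under test is already
well-resolved.

## Numerical choices

- Tables are tab-delimited text; floats are written with 17 significant
  digits and read back with round-trip float parsing, making
  write∘read an exact identity (tested bitwise).
- Empty cells and `NA` are missing; a literal 0 is a value in the
  generic dialect but missing in the MaxQuant sites dialect, where 0
  denotes non-detection.
- Division by zero never propagates: zero denominators in fold changes,
  paired ratios and protein normalization yield undefined/missing values
  with a logged count, never infinities.
- Contrasts are always explicit (numerator group, denominator group);
  nothing is inferred from label names.
- Percentages use decimal half-up rounding, not binary round-half-even.
- Output TSV headers carry version, seed and thresholds but no
  timestamps, so identical config + seed reruns are byte-identical.

## Known limitations

- The CV gate's sensitivity ceiling under realistic noise (see operating
  characteristics above) is a property of the criterion itself; the
  package implements it as defined rather than replacing it with a
  variance-moderated test.
- OPLS-DA is two-class only; multi-class designs must be decomposed into
  pairwise contrasts.
- Lipid classification is prefix/annotation-based; it does not parse
  acyl-chain structure.
- The MaxQuant dialect reads the plain sites-table layout (one row per
  site); collapsing multiply-modified peptides is up to the upstream
  export.
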