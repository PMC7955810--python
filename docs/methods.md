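# Methods

`hdxdyn` implements the analysis layer of a differential HDX-MS study of a
multidomain kinase — the workflow used to show how point mutations and
inhibitors perturb the C-terminal regulatory motif of PI3Kγ p110γ — together
with the ensemble-dynamics metrics used to corroborate those perturbations
in simulation, the assay arithmetic used to quantify their functional
consequences, and a synthetic generator that makes every stage verifiable
against known ground truth.

## Exchange model and the synthetic generator

Backbone amide hydrogens exchange with solvent deuterium.  In the EX2
(Linderstrøm-Lang) regime, structural opening events are fast relative to
the intrinsic chemical exchange step, so each amide exchanges independently
with an observed first-order rate

    k_i = k_int / PF_i ,

where `PF_i >= 1` is the residue's protection factor.  A peptide's
noiseless deuterium content at labeling time `t` in a buffer of D2O
fraction `f` is

    D(t) = f * Σ_i (1 − exp(−k_i t)) ,

summed over the peptide's observable amides.  The generator adds Gaussian
noise to each replicate's centroid-equivalent mass.

Generator defaults are the study conditions of the experiments the pipeline
targets: labeling times 3, 30, 300, 3000 s; 3 replicates; buffer D2O
fraction 0.62 (0.755 for the inhibitor-screen configuration); peptide maps
of mean length 12 advancing by 6 residues (overlapping coverage comparable
to the ~150–180-peptide, ~90%-coverage maps typical of these experiments).
Mass noise defaults to sd 0.05 Da per replicate, a typical TOF centroid
precision.  Protection factors are drawn log-uniformly from [10, 1e6] —
spanning effectively instantaneous exchange at the first timepoint to
essentially no exchange by 3000 s — with a single global intrinsic rate
`k_int = 1/s`.  Residue-specific intrinsic-rate chemistry (sequence,
pH and temperature dependence) is deliberately out of scope: the generator
validates the *pipeline*, whose statistics operate on peptide-level mass
differences and are agnostic to why a residue has the rate it has.  `k_int`
is a plain model field, so a per-residue rate provider can be substituted.

Randomness uses one root seed with independent child streams per
(state, replicate): adding a second state or replicate never perturbs the
draws of existing ones, and two-state datasets share one peptide map and
noise model so any between-state difference is attributable solely to the
protection-factor perturbation.

What the generator does *not* emulate: EX1/mixed exchange kinetics,
isotope-envelope shapes (centroid masses only), back-exchange during quench
and digestion, retention-time drift, charge-state-dependent signal quality,
and peptide misassignment.  Passing tests therefore demonstrate the
correctness of the statistics and bookkeeping on well-behaved input, not
robustness to the failure modes of real LC-MS data.

## Uptake bookkeeping

Max D (theoretical maximum deuteration) of a peptide of length N is
`N − 2 − (prolines at positions ≥ 3)`: the N-terminal residue contributes
no backbone amide after digestion, the second position back-exchanges too
fast to retain label, and prolines have no amide hydrogen.  The exclusion
count is a parameter and the convention string is embedded in all CSV
output metadata.

Deuterium incorporation is the centroid-mass difference against the
undeuterated reference; slightly negative values from noise are preserved
unclipped so replicate means stay unbiased.  The only correction applied is
the buffer D2O fraction: `%D = 100 · #D / (maxD · f)`.  No back-exchange
correction is applied anywhere; all uptake values are relative.  Peptides
observed at several charge states are treated as distinct analytes.

## Differential statistics

A peptide/timepoint difference is significant only if all three criteria
hold strictly: `|Δ%D| > 5 %`, `|Δ#D| > 0.4 Da`, and `p < 0.01` in a Welch
unequal-variance, two-tailed, unpaired t-test on the replicate values
(a paired variant is available behind a flag for genuinely paired designs).
A peptide is called changed if any timepoint passes; the direction is the
shared sign of the passing timepoints, `mixed` if both signs pass.

Numerical choices: replicate variances are floored at (1e−6 Da)² so
identical stored values (e.g. rounded exports) give a finite t statistic;
fewer than two replicates in either state makes p undefined (NaN) and the
record can never pass; timepoint grids are intersected with a warning and
t = 0 reference rows are excluded from comparison; Δ%D uses the corrected
percent scale while Δ#D and the summed profiles use raw deuteron units, and
both scales are carried on every record.

No multiple-testing correction is applied — the three-criterion filter is
evaluated per peptide-timepoint, as is standard in differential HDX-MS
reporting.  The null-control test and acceptance check verify that under
matched-model conditions the familywise false-positive fraction stays below
a few percent, which is an empirical property of the triple filter (the
0.4 Da gate alone sits 8 noise-sd from zero at the default noise), not a
formal guarantee.

Summed #D-difference ("butterfly") profiles add Δ#D over the time course
per peptide and propagate the error in quadrature,
`sd_sum = sqrt(Σ_t (sd_A² + sd_B²))`.  This is the sd of a sum of
single-replicate state differences; the Monte-Carlo check draws exactly
that quantity.  SEM-based pooling is a deliberate non-default alternative.

## Structure mapping

Significant peptides are resolved to residues by painting each peptide's
value — the signed Δ%D of its largest-magnitude passing timepoint — over
its full residue span (matching how peptide-level differences are colored
on structures); a `span="exchangeable"` option restricts to observable
amides.  Residue conflicts resolve by largest magnitude (`max-abs`,
default) or by shortest covering peptide (higher spatial resolution).
Uncovered residues are absent from the map and written as a −1.00 sentinel,
never 0.

B-factor writing is fixed-column text editing: only columns 61–66 of ATOM/
HETATM records in the selected chain change; every other byte is preserved,
making the operation idempotent and diff-friendly.  Author residue
numbering is matched; insertion codes raise an error; when more than half
of the mapped residues are missing from the chain the numbering is presumed
mismatched and the write aborts.  Category bin edges (default ±5/±15/±25 %)
are configuration, not inference — they are recorded in a JSON legend
sidecar next to each written structure.

## Ensemble dynamics

Frames are superposed by least-squares rigid-body fit (Kabsch, SVD form)
with the proper-rotation determinant correction, by default over Cα atoms
of the kinase domain (residues 726–1088).  RMSF is the per-atom
root-mean-square deviation about the ensemble-mean position, summarized
across replicas by quantiles and SD.  Note that superposition absorbs six
rigid-body degrees of freedom, which measurably deflates RMSF on very small
atom selections.

Inter-helical angles use one vector per helix connecting the centers of
mass of its first and last turn; the built-in axis definitions for the
regulatory-motif helices are kα8 1020–1023→1004–1007, kα9 1024–1027→
1034–1037, kα10 1053–1056→1046–1049, kα11 1062–1065→1074–1077.  COMs use
Cα coordinates, unweighted by default (mass weighting is a flag), and the
angle is reported in [0°, 180°] without folding so antiparallel geometries
remain distinguishable.

Hydrogen bonds use the Baker–Hubbard geometric criterion — H···acceptor
distance ≤ 2.5 Å and donor–H···acceptor angle ≥ 120° — on explicitly
provided donor/H/acceptor triplets; occupancy is the formed-frame fraction,
averaged across replicas with SD.  Explicit hydrogens are required (the
code refuses to guess protonation).

PCA fits one `sklearn` decomposition on the concatenated flattened Cα
coordinates of all systems and projects each system with the shared
transformation, so variances are comparable across systems.  Ensembles are
read from multi-model PDB; binary trajectory formats should be converted
upstream — no analysis logic depends on the reader.

Toy "helix pair" ensembles place Cα atoms exactly on the axis line rather
than on a 100°-per-residue spiral: the 4-residue turn COM of a true spiral
carries a small radial phase offset, and the straight-line idealisation is
what makes the constructed-angle oracles exact.

## Assay arithmetic

Plate fluorescence is normalized to a 0–100 % ADP window,
`100 · (F − F0)/(F100 − F0)`, unclipped; % ATP turnover comes from monotone
piecewise-linear interpolation of the standard curve (out-of-range signals
warn and clamp); specific activity is
`(turnover/100 · [ATP])/(t · [E]) − basal`, with below-basal results
preserved and flagged.  Dose-response curves are fitted with the
four-parameter logistic `y = bottom + (top − bottom)/(1 + (x/IC50)^hill)`
by unweighted least squares on the log10-dose axis with an unconstrained
Hill slope (the convention of common plate-analysis software).
Initialization is a deterministic multi-start (5-point log-IC50 grid ×
Hill ∈ {0.5, 1, 2}); the lowest-SSR start wins, so fits are reproducible.
IC50 uncertainty is delta-method-propagated from the log-scale covariance.

## Problem sizes in tests and the acceptance script

Recovery and null-control studies run on a 400-residue (recovery) and a
1220-residue (~200-peptide null) synthetic protein at the default study
conditions; the error-propagation check uses 1e5 Monte-Carlo draws; RMSF
sampling checks use 2 000–10 000 frames.  These sizes put Monte-Carlo error
well inside each check's tolerance while keeping the whole suite inside a
coffee break.  The perturbed region in recovery studies is anchored on a
mapped peptide so that "fully contained peptide" is a non-vacuous category
under the 6-residue tiling grid.

## Known limitations

- Significance calls are only as calibrated as the replicate SD estimates;
  with n = 3 the Welch test is conservative but noisy.
- Residue-level maps inherit peptide-level resolution; no exchange-rate
  deconvolution (HDsite-style) is attempted.
- The structure writer supports fixed-column PDB only (no mmCIF, no
  insertion codes).
- The 4PL fitter assumes doses strictly > 0 and at least 5 distinct doses
  spanning the transition.
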