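# Methods

## Similarity model

A compound's MACCS fingerprint is the 166-bit vector of substructure keys it
contains. Implementations of the MACCS dictionary differ (166 vs 167 slots,
variant SMARTS definitions), so the backend is pluggable: the default is
RDKit's key set (its 167-slot vector with the unused slot 0 dropped), and an
OpenBabel-dialect backend, driven through the `obabel` binary, can be
selected for runs that must match OpenBabel-derived results. Every
fingerprint records its backend, and the network and screening stages refuse
to compare fingerprints from different backends — threshold counts are
dialect-dependent, so silent mixing would corrupt them. Structures are
canonicalized before fingerprinting, which makes the fingerprint a pure
function of the molecule rather than of the input atom ordering; duplicate
detection during pooling uses the canonical SMILES string.

Tanimoto similarity of two fingerprints is |A∩B| / |A∪B| over set keys. Two
all-zero fingerprints compare as 0.0 with a logged warning: a structure that
fires no keys carries no similarity evidence, and any other convention would
invent edges between featureless molecules.

## Network and reference selection

The training library becomes an undirected graph whose edges are exactly the
unordered pairs with Tanimoto ≥ τ (default 0.5); the exact score is kept on
each edge so τ can be swept without refingerprinting. Degree centrality
(incident edge count) measures how structurally typical a toxicant is of the
library; the reference set is the nodes with degree ≥ ⌈max degree / 2⌉.
For odd maxima the cutoff rounds up, and the comparison is inclusive (≥) by
default with a strict (>) option — both choices are recorded in the
provenance sidecar, since selection counts are sensitive to them. An
edgeless network yields an empty reference set with a warning rather than an
error: "nothing resembles anything" is a meaningful outcome. Duplicate
structures in the training library are retained as distinct nodes by
default; an optional canonical-SMILES dedup pass is available at pooling.

## Screening

Matching is bipartite: only the query side's match degrees drive selection,
and the half-of-max cutoff is computed per query library, because each
formulation is screened and reported separately. Formulations are pooled
unions of their herbs' component files, deduplicated by canonical structure
(the same molecule occurring in two herbs is one chemical entity); the
non-dedup behaviour remains available. Components identical to a reference
member (self-hits at Tanimoto 1.0) count as matches and are logged. An
all-zero match table produces an empty selection flagged "no toxic
resemblance", never an exception.

## Dose–response analysis

Inhibition is computed from replicate means, matching the formula's X̄
notation; per-replicate inhibition is retained for dispersion. Stimulation
(negative inhibition) is reported unchanged with a flag. A series needs
controls and at least three distinct concentrations; a four-parameter fit
additionally needs four points.

The fit is a four-parameter logistic on log10 concentration,
`f(x) = bottom + (top − bottom) / (1 + 10^((logmid − x)·hill))`, minimised by
trust-region least squares. Default constraints — bottom ∈ [−20, 20]%,
top ∈ [60, 110]%, hill ∈ [0.1, 10] — stabilise 7-point fits without
materially biasing curves that actually span 0–100%; an unconstrained option
exists. The reported IC50 is the absolute 50%-inhibition crossing
`c50 = midpoint · ((top − 50)/(50 − bottom))^(−1/hill)`, with the curve
midpoint reported alongside; when the fitted curve never crosses 50%, or the
crossing falls outside the tested range, the fit is returned as a diagnosed
failure or flagged out-of-range, never a silent number. The optional CI is a
residual bootstrap on the fitted curve. Published IC50 values in this assay
family are printed unitless; concentrations here are g/mL throughout, and
reports say so. Exposure-time and osmotic-adjustment metadata are carried as
annotations only — no signal correction is applied.

Ranking sorts converged fits by descending IC50 (least toxic first).
Detoxification calls compare each series to a designated base series when
one is given (the base-herb-vs-formulation design), otherwise all pairs are
compared; overlapping bootstrap CIs mark a pair as statistically
indistinguishable. Unconverged fits are excluded with a warning.

## Synthetic data

The generators define the test conditions:

* **Fingerprint libraries** plant clusters directly in key space: each
  cluster is a core of 40 keys (disjoint across clusters where the 166-key
  budget allows) and each member removes 6 of them at random, which bounds
  worst-case within-cluster Tanimoto at (40 − 12)/40 = 0.7 — comfortably
  above the 0.5 threshold — while decoys occupy small disjoint key blocks
  outside every core, giving exactly zero decoy similarity. Removal-only
  perturbation is used because additions could create accidental
  cross-cluster overlap; the worst case under removals is computable by
  enumeration over removal overlaps.
* **SMILES libraries** instantiate scaffold templates (benzene, pyridine,
  linear alkane) with substituent slots. They exercise the real parser and
  fingerprinter; within-scaffold similarity is verified post hoc rather than
  guaranteed, since MACCS similarity of real structures is not analytically
  controllable.
* **Query libraries** are perturbed copies of reference members (mimics)
  plus decoys on key blocks disjoint from the reference's union of keys,
  with truth labels for precision/recall checks.
* **Plates** follow the 7-concentration × 4-replicate design with 4 control
  wells. Expected sample luminescence at concentration c is
  `control_mean · (1 − f(c)/100)` under the true 4PL curve; every well gets
  multiplicative log-normal noise parameterised by its coefficient of
  variation (default CV 5%), the natural model for a strictly positive
  signal with roughly proportional instrument noise. The default
  concentration grid spans a 20-fold range around the true IC50, mirroring
  the published gradients (shipped as `TABLE1_GRIDS`); noise CV 5% is a
  typical luminometer replicate spread. All generators are byte-identical
  under a fixed seed.

What passing tests on these inputs show — and do not show: planted-truth
recovery demonstrates that the network, selection rule and screening logic
are implemented exactly (precision = recall = 1 is achievable because the
synthetic geometry is separable by construction). Real component libraries
are not separable: match-degree distributions are continuous, and the
half-of-max rule's output there depends on the library's similarity
structure and on the MACCS dialect. Likewise the plate generator emulates
measurement noise but not colour/turbidity interference, pH effects, or
bacterial batch variation, so IC50 recovery rates here bound only the
numerical behaviour of the fitting stage.

## Numerical choices and sizes

Network construction uses an integer matrix product over the 166-key matrix;
scores are exact rationals in floating point, and edge lists are emitted in
sorted canonical order, so identical inputs give bit-identical outputs. The
4PL initial guess takes the measured extremes and the grid point nearest the
half-range crossing; the optimiser runs with generous bounds on the midpoint
(±3 decades beyond the tested grid when constrained). Monte-Carlo checks use
100 plates at CV 5% for the fixed-truth recovery and 200 plates across
IC50 ∈ [10⁻⁴, 10⁻²] g/mL, Hill ∈ [0.5, 3] for the sweep — large enough for
stable medians, small enough that the whole suite runs in seconds.

## Known limitations

Only degree centrality is implemented (no betweenness/closeness), only MACCS
keys (no ECFP/FP2), and no 3D or physicochemical descriptors. SDF reading is
limited to what RDKit's V2000 supplier accepts. The CLI's reference loader
refingerprints members from the stored SMILES, so a reference built with a
deregistered backend cannot be reloaded. Reproduction of published screening
counts additionally requires the original training library and component
exports, which are external downloads; with those in hand,
`toxscreen build-reference` and `toxscreen screen` with the
OpenBabel backend selected implement the same procedure end to end.
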