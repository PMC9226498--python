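# Methods

This note documents the models, numerical choices and limitations of
`fingermap`, in the order the pipeline runs them.

## Titration model and its assumptions

A single binding event P + L ⇌ PL with one dissociation constant Kd is
assumed for the whole series. Because NMR works at concentrations
(0.1–0.5 mM) comparable to the Kd of weak complexes, the free-ligand
approximation is invalid; the bound fraction of the labeled protein
follows the quadratic depletion isotherm

    f_b = [PL]/P,  [PL] = ((P + L + Kd) − sqrt((P + L + Kd)² − 4PL)) / 2

evaluated in the cancellation-free form `2PL / (S + sqrt(S² − 4PL))`
(S = P + L + Kd), which stays accurate when Kd ≪ P, L. Fast exchange
(k_off much larger than the shift difference between states) is
assumed throughout: each amide shows one peak at the
population-weighted average position, so peaks move along straight
segments from free to bound. The collinearity statistic emitted by
`peak_trajectories` (maximum perpendicular deviation from a
total-least-squares line in the α-scaled ¹H/¹⁵N plane) is the
diagnostic for that assumption; curved or kinked trajectories indicate
intermediate exchange or a second event, and such residues are flagged
at 3× the noise estimate by default.

Out of scope by design: slow/intermediate exchange line shapes,
multi-site or cooperative binding, and any thermodynamic decomposition
(temperature is metadata only).

## CSP and hotspot calling

Combined amide CSP uses the community-standard weighting
`sqrt(Δδ_H² + (α Δδ_N)²)` with α = 0.14, configurable because
published variants range roughly 0.1–0.2. The endpoint compared
against the apo reference is the highest-ratio point (closest to
saturation). "Relative" CSP (profile divided by its maximum) is
emitted alongside raw ppm because interface figures are usually drawn
on that scale.

Hotspot calling is deliberately explicit rather than buried: the
default is mean + 1·SD over the profile (population SD), with a
quantile alternative; the threshold, method descriptor and the full
ranked profile are always part of the output, since published
interface lists are ranked ("strongest … and less for") rather than
thresholded. A mean + k·SD rule assumes the interface is a minority of
the assigned residues; with half the profile perturbed no global
threshold separates cleanly.

## Global Kd fit

All residues share one Kd; each residue contributes two free
bound-state offsets (¹H, ¹⁵N). Free-state shifts are fixed to the apo
peaks by default (they are directly measured); jointly fitting them is
available for noisy apo data. ¹⁵N residuals carry weight α so both
dimensions are commensurate.

The fit exploits separability: at fixed Kd each residue's offsets are
a one-parameter linear least-squares problem with closed-form
solution, leaving a 1-D profile objective in log₁₀ Kd. A 25-point
log-spaced grid over 10⁻⁷–10⁻¹ M locates the basin; bounded Brent
minimisation polishes it (xatol 1e-10 in log₁₀ units). The procedure
is deterministic given its inputs. When the best-fit model predicts
under 10% saturation at the final point, the fit is flagged as a
lower-bound regime and the CI upper limit reported as +∞ — in that
regime the data genuinely only bound Kd from below.

### Uncertainty

The default 95% CI is a seeded parametric bootstrap: replicate peak
lists are drawn from the fitted model with Gaussian noise at the
residual standard deviation (estimated per dimension with a
degrees-of-freedom correction), each replicate is refit, and the basic
(bias-corrected) interval is formed in log-Kd space. The basic
interval matters because in weakly saturating regimes the estimator is
skewed and replicates inherit that bias; reflecting the replicate
quantiles about the point estimate corrects it.

Residue-level case resampling with a percentile interval is retained
as `method="residue"`. It is the natural check when residues might not
share one event, but with a typical compact interface only ~6 residues
carry Kd information, so its variance is estimated with very few
effective degrees of freedom and its intervals run ~20% narrow; in
calibration simulations at the default study conditions it covered the
truth in 83/100 runs versus 93/100 for the parametric default. That
measured contrast is why the parametric method is the default rather
than the more conventional case bootstrap.

## Synthetic data

`simulate_titration` draws noiseless peaks exactly on the
free-to-bound segment (`δ_free + f_b Δδ_bound`) and adds Gaussian
noise to the observed positions — noise lives in the spectrum, not in
the populations. Defaults emulate a weak (sub-mM) protein–peptide
titration: labeled protein 0.1 mM; ligand ratio ladder 0, 0.25, 0.5,
1, 2, 4, 8 (the real experiment's ladder is described only as reaching
ligand excess, so the ladder is this package's choice); peak noise
0.004 ppm (¹H) / 0.02 ppm (¹⁵N), typical for well-resolved HSQC peaks.
The stock architecture is 30 trackable amides with a 6-residue
interface whose offsets are 0.15–0.25 ppm in ¹H and 6-fold larger in
¹⁵N with alternating sign — comparable magnitudes, as expected when
contacts cluster on one helix face, and a minority interface as in a
construct where only the finger responds.

What the generator does **not** emulate: peak overlap and
mis-tracking, intensity changes and line broadening, ¹⁵N/¹H noise
correlation, slow/intermediate exchange, pH/temperature drifts between
points. Passing tests therefore demonstrate correctness of the
analysis under its stated model, not robustness to every pathology of
real spectra; the collinearity flag is the main guard for the worst of
them.

`sample_alignment` draws alignment columns independently from given
probability vectors (no phylogenetic correlation — adequate for
testing profile mathematics, not for simulating real family
evolution). `simulate_disorder_shifts` writes random-coil reference
values for coil residues and adds canonical helix secondary offsets
(CA +2.6, CB −0.5, C′ +1.8, H −0.25, N −1.5, HA −0.35 ppm at
amplitude 1) for helix residues; noise is specified on the ¹³C scale
with protons receiving one fifth of it.

## Zinc-finger annotation and numbering

The C2H2 scan matches
`C-x(2,4)-C-x(3)-[FYLIVW]-x(5)-[hydrophobic]-x(2)-H-x(3,5)-H`, keeps
two residues of N-terminal and four of C-terminal flanking context
(clipped so tandem fingers never overlap), and resolves overlaps
leftmost-first with greedy (longest) spacers. The recognition-helix
origin is anchored from the first zinc-binding histidine: +1 is
his1 − 6, so his1 sits at +7 and the second histidine at +11. This
anchor reproduces the full set of published labels for the
characterised finger (−1 through +12 with no position 0); a
structure-derived helix start can override it when coordinates are
available. There is deliberately no position 0, following the
zinc-finger community convention.

The position-probability profile replaces profile-HMM machinery:
inputs are fixed-width finger alignments, so insert/delete states add
nothing. Columns use `(n_c(a) + λ q(a)) / (N_c + λ)` with λ = 1 and a
uniform background by default; gaps are excluded from counts, not
treated as a 21st symbol; an all-gap column is flagged and assigned
the background. Information content is relative entropy to background
(bits). Atypicality of a query finger is the sum over the five
DNA-binding positions of `log₂ p/q`, reported with a seeded mid-rank
percentile among profile-sampled position sets so users can read it as
"more/less typical than X% of family draws".

## Disorder readout

Secondary shifts are observed minus residue-type random-coil
reference; the shipped reference follows the widely used random-coil
compilations of Wishart and co-workers, without neighbour-residue
corrections (a documented simplification — adequate for an
ordered/disordered contrast, not for quantitative structure
propensity). Glycine CB and proline amide entries are absent and the
atoms are omitted, never imputed.

Per residue, the weighted mean absolute secondary shift (weights
CA/CB/C′ 1.0, H/HA 5.0, N 0.2 — protons up-weighted onto a
carbon-comparable scale, nitrogen down-weighted for its broad
intrinsic dispersion) is smoothed by a centred 3-residue window, then
`RCI = 1/max(Ā, 0.05 ppm)` and `S² = clamp(1 − 0.05·RCI, 0, 1)`. The
constants place an ideal helix near S² ≈ 0.9 and exact random coil at
S² = 0 (the floor), with the default region cutoff at 0.7 and a
minimum run length of 3 (short runs merge into their neighbours;
numbering gaps always split regions). These S² values are a
structured/disordered readout calibrated only by its monotone
contract — larger secondary shifts, larger S² — not
relaxation-quality order parameters, which is all the downstream
region classification needs.

## Problem sizes and determinism

Calibration-style tests run 20 seeds per condition (the binding
recovery test spans five true Kd values of 0.05–1 mM at 0.1 mM
protein, with 200 bootstrap replicates per fit); profile statistics
use 2 000–5 000 samples. Every stochastic step takes an explicit seed
and identical seeds give bit-identical outputs; the pipeline driver
embeds the package version and a config hash in every run manifest so
reports are reproducible and attributable.

## Known limitations

- Peak tracking/assignment across titration points is assumed given;
  the package never re-assigns peaks.
- One global binding event; competing or sequential binding is not
  modelled.
- The NMR-STAR reader covers only the `Atom_chem_shift` loop needed to
  ingest chemical-shift depositions, not general STAR files.
- B-factor painting works on fixed-column PDB text (byte-preserving
  outside the B-factor field); mmCIF is not supported.
- The lower-bound regime (under ~10% saturation) is detected and
  flagged, but no informative upper CI limit can be produced there.
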