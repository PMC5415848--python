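# Methods

This note documents the models implemented in `helixread`, the conventions
and defaults chosen where the underlying experimental literature leaves
them open, and what the synthetic-data generators do and do not emulate.

## Backbone hydrogen bonds and helicity

Trajectory-viewer secondary-structure plugins differ in their H-bond
criteria, so `helixread` pins one reproducible definition: the
Kabsch–Sander electrostatic model. The amide hydrogen of residue *i* is
reconstructed geometrically, 1.00 Å from N along the direction of the
preceding residue's C→O vector reversed (anti-parallel to that C=O bond);
the interaction energy with a candidate carbonyl is

    E = 27.888 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)  kcal/mol

and a bond is called when E < −0.5 kcal/mol. The first residue (no
preceding carbonyl) and prolines are ineligible donors; donor–acceptor
pairs closer than two residues in sequence are skipped. On ideal
conformations this reproduces an independent reference implementation of
the same criterion exactly (cross-checked in the test suite against
mdtraj's Kabsch–Sander energies and DSSP assignment).

A residue is *helical* when it lies inside a minimal helix of turn length
n ∈ {3, 4, 5} — two consecutive n-turns starting at residues i and i+1
mark residues i+1…i+n — which counts α-, 3₁₀- and π-helical states
together. Helicity profiles over an ensemble discard the first
`burn_in_fraction` (default 0.25, i.e. analyze the last three quarters of
each replica) and report both the frame-weighted pooled fraction and the
median ± interquartile range across replicas; the two answers can differ
when replicas disagree, so both are always available.

Replica comparisons use the two-tailed Mann–Whitney U test: the exact null
distribution when both groups have ≤ 8 values and no ties (a 4-vs-4 fully
separated comparison gives exactly p = 2/70), otherwise the normal
approximation with continuity and tie correction. The test is delegated to
`scipy.stats.mannwhitneyu` with exactly this method selection.

Bound-peptide conformations are classified on the peptide's own geometry:
*helical* if ≥ 3 consecutive segment residues are helix-assigned (one
complete turn), *extended* if the segment has no backbone H-bond of
sequence separation ≥ 3 **and** its CA end-to-end distance is ≥ 0.8 of the
CA contour length, *bent* otherwise. The 0.8 ratio cleanly separates the
ideal extended conformation (≈ 0.91) from kinked geometries (≤ 0.7 for a
right-angle bend) and is configurable.

Sidechain-to-backbone hydrogen bonds (e.g. a Thr hydroxyl to a downstream
amide) are outside the Kabsch–Sander model; they are scored by a
heavy-atom donor–acceptor distance ≤ 3.5 Å with a ≥ 120° angle check at
the donor where the donor's antecedent atom is present.

## Ideal-geometry backbone construction

Synthetic conformations are built from internal coordinates with
Engh–Huber-style ideal values: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
C=O 1.231 Å; angles N-CA-C 111.2°, CA-C-N 116.2°, C-N-CA 121.7°; all
peptide bonds trans (ω = 180°). The ideal helix uses (φ, ψ) = (−57°, −47°)
and the extended/coil state (−139°, 135°) — the latter is a statistical
stand-in for coil, chosen only to be reliably non-helical under the
assignment rule, not a model of coil geometry.

## Planted helicity fractions

`make_ensemble` realizes a per-residue helical fraction f by deterministic
rounding, never sampling: the number of helical frames is
⌊f·n_frames + 1/2⌋, and those frames are interleaved evenly through the
trajectory (a Bresenham-style spread), so zero-noise recovery tests are
exact and remain exact under burn-in whenever f × (retained frames) is
integral. With a constant fraction every frame is wholly helical or wholly
extended; per-residue profiles are honored frame-wise, but a residue only
registers as helical downstream if its block is long enough to host a full
minimal helix. Interior residues (2…L−1 of an L-mer) are the meaningful
ones: chain termini can never satisfy the two-consecutive-turn rule.

## Acidic-wall census

Alignment columns are never inferred: both diagnostic columns are located
through explicit reference anchors (row id, first-residue number of the
construct, target residue number), mirroring how one reads "the position
corresponding to E1689 of BAZ2A" off an alignment. Scoring conventions:

- wall residues are exactly {D, E}; Asn/Gln are not scored as near-acidic;
- a gap at a diagnostic column scores as *absent* — conservation is read
  off the literal column, with no imputation;
- the double acidic patch means two *sequence-adjacent* acidic residues in
  the ungapped sequence (window ±1 around the wall, configurable), after
  the D1688/E1689-style neighbour pattern;
- 1-based columns and residue numbers throughout.

The published census of the human PHD complement (36 of 172 sequences
with an acidic wall; 5 of 36 also carrying the K4me Trp; 22 of 36 with a
double patch) requires the external human PHD sequence set and an
alignment step; reproducing it is an external workflow (align with any
MSA tool, then `helixread census`), not a packaged test. The packaged
tests instead verify exact recovery of planted counts on synthetic
alignments. The synthetic generator always appends a numbering-reference
row (`BAZ2A_ref`); census counts in the planted-truth tests are taken over
the planted rows only, via `SyntheticMsa.planted_msa()`.

## Chemical shift perturbations

Δδ_weighted = |Δδ_H| + 0.14·|Δδ_N|; the 0.14 factor rescales the amide
nitrogen shift range onto the proton range. Classification thresholds are
μ, μ+σ and μ+2σ over *measured* residues (present and assigned in both
spectra; sidechain NH2 pairs and unassigned residues excluded), with
inclusive ("equal or above") comparisons. σ is the sample (n−1) standard
deviation; the choice is recorded in the classification output. When all
shifts are equal, σ = 0 and every residue is ≥ μ + 2σ: the degenerate
all-strong outcome is the rule's own consequence and is documented rather
than special-cased.

The minimal-shift estimate pairs each assigned free-state peak with the
nearest bound-state peak under d = √(Δδ_H² + (0.14·Δδ_N)²); matching is
many-to-one and needs no bound-state assignment. Because the nearest peak
minimizes over all candidates, the estimate is a lower bound on the true
perturbation — asserted against planted assignments in the tests. Exact
ties are broken toward the smaller δ_H, then smaller δ_N, and flagged.

## ITC single-site model

The instrument software used for published fits is closed; `helixread`
implements the algebra explicitly. After injection k with cumulative
injected volume ΔV, running cell concentrations use the standard
displaced-volume (perfusion) correction

    M = M₀ (1 − ΔV/2V₀)/(1 + ΔV/2V₀),    X = X₀ (ΔV/V₀)/(1 + ΔV/2V₀),

site occupancy Θ solves Θ² − Θ(1 + X/(NM) + K_D/(NM)) + X/(NM) = 0
(smaller root), the cell heat content is Q = N·Θ·M·ΔH·V₀, and the
measured injection heat is ΔQ_k = Q_k − Q_{k−1} + (dV_k/V₀)(Q_k+Q_{k−1})/2.
The default schedule is one 0.4 µl pre-injection followed by 19 × 2 µl
into a 200 µl cell. A bisection solver for the binding polynomial serves
as the independent oracle in the tests (agreement < 10⁻⁹ relative).

Note one consequence of the displaced-volume accounting: cumulative heat
approaches N·M₀·V₀·ΔH at saturation only in the tight-binding limit; at
moderate affinity a percent-level shortfall remains because some sites
leave the cell unbound during early injections. The conservation test
therefore pins the tight-binding regime.

Fitting minimizes least squares in (ln K_A, ΔH, N, baseline) —
parameterizing in ln K_A for conditioning — with Levenberg–Marquardt from
three c-value-spanning starts; the first injection is discarded by default
(pre-injection convention); N can be pinned (`fix_n`), in which case its
error is reported as 0. Parameter errors come from the covariance at the
optimum scaled by the residual variance. When c = N·M₀/K_D < 1 the
isotherm is nearly featureless; if the fitted K_D also exceeds the
configured ceiling (default 1000 µM), K_D is reported as a lower bound
(">1000") rather than a point estimate.

Derived quantities use R = 1.9872×10⁻³ kcal/(mol·K) and T = 298.15 K (25 °C)
by default: ΔG = RT·ln(K_D in M), TΔS = ΔH − ΔG, with δΔG = RT·δK_D/K_D
and δTΔS = √(δΔH² + δΔG²). The identity ΔG = ΔH − TΔS is exact before
rounding; customary table precision is two decimals for ΔG and one for
TΔS. Validation of the packaged parameter tables recomputes ΔG and TΔS
from each printed K_D/ΔH and accepts deviations up to 0.03 and
0.1 kcal/mol respectively — the slack introduced by the tables' rounding
of K_D itself. Both packaged tables pass with maximal ΔG deviation
0.029 kcal/mol. One published narrative figure does not match its own
table: the BAZ2B E1944Q mutation is described as weakening binding "up to
8-fold", while the tabulated 660 vs 47 µM gives ≈ 14-fold; the package
reports what the table values give and does not attempt to resolve this.

## Helix propensity

Scoring is a plain window sum of per-residue helix free-energy costs
(kcal/mol, Ala = 0) over a 1-based inclusive window, defaulting to
residues 3–8 of the H3 10-mer — the observed helical span of the bound
peptide. The packaged scale is the Pace–Scholtz consensus scale. A window
sum supports only ordinal claims, which is all this analysis makes: it
ranks the double-Ala variant (1.53 kcal/mol) ahead of wild type (2.18)
ahead of double-Gly (3.53). No nucleation–propagation (Zimm–Bragg /
AGADIR-class) model is attempted, and absolute scores are
scale-dependent; swap the scale file to test robustness of an ordering.

## Problem sizes and determinism

Every generator is a pure function of its arguments and a NumPy seed;
fixture regeneration with the same seed is byte-identical. The packaged
studies use sizes at which the statistical claims are exact or
well-resolved: 100-frame ensembles for planted-fraction recovery, 20-frame
ensembles for trivial limits, 200 seeded replicates at 0.2 µcal heat noise
for the fit-bias study (median relative bias of K_D, N, ΔH each < 5%;
observed ≈ 2.7% for the worst parameter). Molecular-dynamics-scale
helicity percentages (tens of ns across four replicas) are not
reproducible by a desk-scale package and are represented here by the
planted-fraction constructions instead; passing tests demonstrate the
correctness of the measurement machinery, not the physics of any real
trajectory.

## Known limitations

- Conformer ensembles are accepted only as multi-model PDB; binary
  trajectory formats must be converted upstream.
- The coil model is a single extended conformation; real coil ensembles
  are heterogeneous, so synthetic non-helical baselines are cleaner than
  experimental ones.
- Secondary-structure conventions differ between assignment programs by a
  few percentage points of helicity; `helixread` states its criterion
  exactly rather than emulating any particular viewer plugin.
- The CSP module performs no peak picking or assignment transfer; peak
  lists are inputs.
- Only the single-site binding model is implemented — no sequential,
  multi-site or competitive schemes, and no integration of raw power
  traces.
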