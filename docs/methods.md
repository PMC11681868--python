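# Methods

## Scope and data model

`phosphorec` post-processes existing coordinate data; it never runs
molecular dynamics, builds structures or fits ITC isotherms. The in-memory
model is deliberately small: a `Structure` is an ordered list of residues
with PDB-style atom names, author residue numbering (insertion codes sort
after their base number: 95 < 95A < 95B) and coordinates in Å. A
`TrajectoryEnsemble` ties replicate `(n_frames, n_atoms, 3)` arrays to one
topology, a snapshot interval `dt_ps`, a phosphate protonation-state label
(PO3H⁻ or PO3²⁻) and an equilibration fraction. PDB/mmCIF parsing is
delegated to gemmi; altlocs are resolved to the highest-occupancy conformer
(ties: first altloc label). Hydrogens are kept when present: MD topologies
have them, crystal structures usually do not, so contact counts from
crystal structures are slightly sparser — a documented asymmetry, not a
bug. Phosphoserine is recognised by residue code SEP plus a configurable
alias list. Chothia-style display labels (H-R95 and the like) are the
caller's concern: roles are assigned from an explicit chain → role map and
no renumbering is attempted.

## Interaction criteria

* **Contact**: a residue interacts with the phosphoserine in a frame iff
  any of its atoms (any element, hydrogens included) lies **strictly**
  within 4.0 Å of the phosphorus atom. The antigen chain and solvent are
  excluded from the partner set by default.
* **Hydrogen bond**: donor/acceptor heavy atoms (N, O) strictly within
  3.5 Å. The criterion is distance-only by design; an optional
  donor-angle filter (D–H···A ≥ 120°, applicable only when hydrogens
  exist) can be layered on by callers but is off by default.
* **Bidentate clamp**: a frame is bidentate iff among the H-bonds between
  the Arg guanidinium nitrogens (NE, NH1, NH2) and the terminal phosphate
  oxygens there exist two with distinct nitrogens **and** distinct
  oxygens. Terminal oxygens are the O atoms within bonding distance
  (<1.9 Å) of P, excluding the bridging ester OG. Syn/anti coordination
  modes are not distinguished.

Frequencies are computed on the frames retained after discarding the
leading `equilibration_fraction` (default 0.2, the 200 ns of a 1 μs run) of
every replicate, per replicate, then averaged across replicates. Because
averaging per-replicate percentages and pooling all frames can differ when
replicate lengths differ, both numbers are reported (`mean_pct`,
`pooled_pct`); the mean-of-replicates is the headline value.

## Convergence RMSD

`ca_rmsd_series` measures, per replicate, the Cα RMSD of every frame
against that replicate's first snapshot, on a Cα subset the caller defines
by excluding residues (typically an scFv's GS linker and the five terminal
residues at each end — supplied explicitly, never auto-detected). Each
frame is first superposed onto the reference by a least-squares rigid fit
(Kabsch, SVD with a determinant guard so reflections are impossible);
without the fit, raw RMSD against a fixed snapshot is dominated by overall
diffusion. The unfitted variant remains available (`fit=False`). Fitting
and measurement use the same atom set. No mass weighting (Cα only) and no
periodic-boundary imaging (inputs are assumed whole).

## Phosphate torsion analysis

The CB–OG–P–OT torsion is computed with the standard atan2 formulation
under the IUPAC sign convention (cis = 0°, clockwise positive viewed from
the second atom), range (−180°, 180°] with the ±180° tie reported as
+180°. Degenerate geometries (coincident or collinear points) raise
rather than returning a value.

The circular distribution is a normalised histogram over (−180°, 180°]
(default bin width 5°, which must divide 360). Peak detection works on a
circularly boxcar-smoothed copy (window ≈ 15°, an estimator choice that
suppresses shot noise without moving 120°-spaced modes); a local maximum
becomes a peak when its circular topographic prominence exceeds 5 % of the
global maximum **and** its smoothed height exceeds 1.5× the circular
uniform density 1/360 — the second bar is what makes a structureless
series yield zero peaks. Peak mass is the integral of the *raw* density
over the watershed basin bounded by inter-peak minima, so masses sum to 1;
centers are refined to sub-bin accuracy by parabolic interpolation.

Rotamer states are hard cores of half-width 40° (keeping 120°-spaced cores
disjoint) around centers that are either user-supplied or taken from the
detected peaks (3 expected for PO3²⁻ by chemical symmetry); frames outside
every core are UNASSIGNED and act as a hysteresis buffer. A rotation event
is registered only when a *different* state's core is entered, so noise
excursions into the buffer and back are not events — raw nearest-center
labelling would inflate counts. Dwell time is frames-in-state × dt; the
first and last dwell of every replicate are censored (their start or end
is unobserved), reported separately and excluded from mean-dwell
estimates, which gives a mildly conservative (slightly short) mean because
long dwells are likelier to touch an edge. For 3-fold symmetry, transitions
are also tallied by rotation direction (+120° / −120°).

## Thermodynamics

ΔG = RT ln K_D with R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and K_D in molar;
TΔS = ΔH − ΔG; ΔΔG = RT ln(K_D ratio). The analysis temperature defaults
to 298.15 K — the calorimetry temperature was not recorded alongside the
packaged table (the simulations used 298 K), so the value is an assumption
and is echoed in every report. The packaged fixture carries the reported
one-decimal ΔG/TΔS values in separate `*_printed` columns used only for
cross-checking; with the assumed temperature every derived value falls
within the reported ± (the C7 wildtype ΔG reproduces to −10.33 vs the
printed −10.4 ± 0.4 — inside the uncertainty but not within one-decimal
rounding, consistent with a slightly different calorimetry temperature).
Uncertainties propagate to first order (σ_ΔG = RT·σ_K/K; σ_TΔS by
quadrature); the tabulated ± are triplicate SDs and are not re-derived.
Titrations with no measurable binding carry a typed sentinel, never NaN
arithmetic.

## The synthetic generator

The generator emulates the *statistical* structure of the real
simulations with the smallest geometry that exercises every analyser: a
phosphoserine (CB, OG, P, three terminal oxygens), an arginine guanidinium,
single-atom contact-partner pseudo-residues and a jittered Cα backbone.

* The terminal-oxygen tripod rotates rigidly about the OG–P axis so the
  CB–OG–P–OT torsion equals the current rotamer center plus wrapped-normal
  noise (a practical stand-in for von Mises; indistinguishable at the
  σ ≤ 15° used here). Rotamer jumps follow a continuous-time Markov chain
  discretised at `dt_ps`; per-state exit rates scale inversely with the
  configured state weights, so dwell times (and hence stationary
  occupancies) are proportional to the weights.
* Contact partners sit at their in-distance (3.5 Å) from P in frames where
  an independent Bernoulli flag fires, else at their out-distance (6.0 Å);
  the config validates in < cutoff < out.
* Arg nitrogens are placed radially beyond two different terminal oxygens
  (bidentate), beyond one oxygen only (single H-bond) or far away,
  according to mutually exclusive per-frame Bernoulli draws; a schedule
  whose probabilities exceed 1 is rejected as impossible.
* Cα atoms carry i.i.d. Gaussian jitter of configurable σ around a fixed
  helix-like reference, giving the RMSD series a closed-form expectation
  (≈ σ√6 between two independently jittered frames).

Determinism: one global seed; each replicate uses a stream derived from
(seed, replicate index), so extending the ensemble never reshuffles
earlier replicates.

Defaults are scaled to desk scale: 3 replicates × 2500 frames at 100 ps
(250 ns-equivalent each, 2000 retained after the 20 % discard) rather than
triplicate 1 μs runs; the dwell-time recovery configuration uses
3 × 10 000 frames (800 ns retained each) so that a 50 ns mean dwell yields
enough completed dwells for a stable estimate. What passing tests show is
that the analyses recover prescribed occupancies, clamp fractions, dwell
times and mixture masses from data with the right *statistical* shape;
they cannot show anything about force-field physics, solvent, correlated
contact/clamp dynamics (all Bernoulli draws are independent across frames,
unlike genuinely autocorrelated MD observables) or real paratope geometry.
The published per-residue contact percentages and torsion distributions
came from 6 μs of undeposited trajectories and are not reproducible here;
the presets reproduce their qualitative contrasts instead (rigid
single-well clamp vs three-well free rotor, near-100 % vs intermittent
bidentate occupancy).

## Numerical and design choices

* Strict `<` for the 4.0 Å contact criterion (an atom at exactly 4.0 Å is
  out); the H-bond check also uses `<` at 3.5 Å. Both cutoffs are
  configurable everywhere.
* Superposition refuses <3 points or rank-deficient (collinear) spreads
  rather than returning an arbitrary rotation.
* Histogram bin edges place exact −180° into the +180° bin, keeping the
  half-open (−180°, 180°] convention consistent with the torsion kernel.
* The tracked terminal oxygen (OT) is user-specified on real topologies;
  the generator names it OT explicitly. Under PO3²⁻ symmetry the choice
  relabels states but cannot change peak counts or event statistics.
* Report tables are plain TSV/JSON with fixed float formats, so identical
  inputs and config give byte-identical outputs.

## Known limitations

* The H-bond criterion ignores geometry beyond distance; genuinely
  misaligned donors within 3.5 Å are counted.
* Mean dwell estimates are biased short by edge censoring and biased long
  by unobservably fast back-and-forth excursions; at the scales tested the
  net effect stays within ±30 %.
* Water-mediated bridges are detected through single water oxygens only;
  two-water chains are out of scope.
* The generator's independence assumptions (Bernoulli contacts, no
  clamp–rotation coupling) make its ensembles easier than real MD; recovery
  tolerances would widen on strongly autocorrelated data.
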