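# Methods

## Deconvolution model

The measured far-UV CD spectrum b (Δε, M⁻¹cm⁻¹) is modelled as a
non-negative linear combination of reference spectra: Δ² = ‖C·x − b‖²
minimized over x ≥ 0.  The model assumes (i) the basis spans the
measured spectrum's shapes, (ii) basis spectra are linearly independent,
and (iii) amplitude mismatch between experiment and basis can be absorbed
by the weights, which are therefore not bounded above by 1.  The solver is
SciPy's Lawson–Hanson active-set NNLS; it is deterministic and terminates
at the KKT point of this convex problem, which our tests confirm against
an independent bounded-QP route (L-BFGS-B at `ftol=1e-16`) to ≤ 1e-8 in
the residual.

Secondary-structure fractions are d = A·x/‖x‖₁.  The norm is L1 by
design: only the L1 choice makes d a convex combination of the reference
fraction columns, hence non-negative with unit sum.  An L2 variant is
available (`norm="l2"`) for comparison; its four-category output skips the
unit-sum invariant (its sum is ‖x‖₁/‖x‖₂ ≥ 1) and is intended only for
fidelity experiments.  Six categories (helix regular/distorted, strand
regular/distorted, turn, unordered) collapse to four by summing the
regular/distorted pairs; the total is conserved exactly.

Fitting uses the 190–240 nm window at the reference grid's spacing by
default, both endpoints inclusive (51 points at 1 nm); the window is fully
configurable.  A measured spectrum is linearly interpolated onto the
reference grid, never extrapolated.  An all-zero spectrum yields a typed
degenerate result (zero weights, `degenerate=True`) rather than a
division by zero.

Units are Δε throughout; a helper converts mean-residue ellipticity via
Δε = [θ]/3298.  Reference fraction columns must sum to 1 within 0.02;
strict mode rejects violations naming the protein, lenient mode
renormalizes.

## Validation statistics

δ (RMS deviation) and r (Pearson correlation) compare CD-derived and
known four-category fractions.  The index scope is deliberately exposed
twice: per-category (over proteins, N = protein count) and pooled (over
protein × category pairs, N = 4 × count), because the defining index
notation conflates the two readings and both are defensible; the pooled
value is the headline.  The disorder-cutoff sweep recomputes both on the
subsets with known unordered fraction strictly above each cutoff (cutoff 0
means the full set); subsets with fewer than two proteins are flagged
undefined rather than raising, so a sweep over aggressive cutoffs still
completes.

## Frame selection

A pair of frames (i, j), i < j, is accepted when the pair-averaged
fraction vector lies within φ of the CD target in every one of the four
categories (strict inequalities).  φ defaults to 0.035 per category.
φ = 0 is an exact-match mode: because the open interval degenerates to a
point, it keeps exactly the pairs whose average equals the target.  The
refined ensemble is the union of frames in accepted pairs; both the pair
count and the unique-frame count are reported, since either could be
meant by a "number of structures".

Two strategies return identical pair sets (a tested property): exhaustive
enumeration of all N(N−1)/2 pairs, and a sorted-window search that sorts
frames by helix fraction and restricts partners to the contiguous interval
where the helix inequality can hold before checking the remaining
categories.  Exhaustive is the default below 20,000 frames; above that the
quadratic scan's memory/time cost favors the sorted window.

Assignment codes consolidate as: α-helix and 3-10 helix → helix;
β-sheet codes → strand; turn and bend → turn; π-helix, isolated β-bridge
and unassigned/none (including blank, `-`, `.`, `0` from termini or chain
breaks) → unordered.  π-helix is demoted to unordered because it is not a
stable, well-populated category.  The mapping table is user-overridable
per trajectory.

## Contact and hydrogen-bond maps

Contacts: residues i, j with |i − j| ≥ 4 are in contact in a model when
any qualifying atom pair is within 4 Å.  Backbone means N, CA, C, O plus
terminal oxygens; side chain is the complement minus backbone-riding
hydrogens, except glycine, whose α-hydrogen counts as its side chain (it
has no heavy side-chain atom).  Hydrogen bonds: donor–acceptor distance
≤ 4 Å and D–H···A within 30° of linearity (angle at H ≥ 150°) — the
"within 30°" is read as deviation-from-linear, since a literal ∠DHA ≤ 30°
is geometrically impossible for bonded atoms.  The H-bond minimum
sequence separation defaults to 2, not 4: (i, i±3) hydrogen bonds are
structurally meaningful in turns and helices, so the contact rule's
4-residue separation cannot apply to them.  Both separations are
configurable.  Map entries are per-model frequencies; H-bond maps are
max-scaled by convention so the strongest bond is exactly 1 (an all-zero
map stays zero).

Ensembles are biotite `AtomArrayStack`s (multi-model PDB).  Donor/acceptor
chemistry is explicit atom indices; a helper infers backbone amide N–H
donors and carbonyl O acceptors from atom names and refuses structures
without resolvable amide hydrogens.

Ensemble spread is the maximum and standard deviation of all-pairs
best-fit RMSD after Kabsch superposition (SVD with determinant
correction).

## Synthetic generators

The generators exist so every stage can be exercised against known ground
truth.  They emulate the *shape* of real inputs, not their physics:

- **Reference sets**: each spectrum is its fraction vector applied to six
  fixed band-shape templates (sums of Gaussians with far-UV CD morphology:
  helix-like 192+/208−/222− pattern, strand-like 196+/218− couplet, deep
  ~198 nm negative for unordered), plus a small smooth per-protein
  perturbation (three Gaussian bumps, ~0.5 Δε) that makes the columns
  linearly independent — without it all spectra would live in a
  6-dimensional span and weight recovery would be ill-posed.  Fractions
  are Dirichlet draws skewed toward unordered, mimicking a
  soluble-and-denatured population.  The templates are package constants,
  not fits to real data.
- **Assignment trajectories**: independent per-residue Markov chains that
  keep state with probability 0.75 and otherwise redraw from the target
  distribution, giving the prescribed stationary composition with
  realistic frame-to-frame correlation.  Realized means land within 0.02
  of the target by ~5,000 frames.
- **Toy ensembles**: alanine chains (N, H, CA, CB, C, O) with prescribed
  geometry — an antiparallel hairpin (i ↔ n−1−i contacts and hydrogen
  bonds across a 4.6 Å gap), an ideal-helix parametrization (i, i+4
  contacts, i→i−4 amide-to-carbonyl bonds), and self-avoiding random-walk
  coils.  Amide hydrogens are aimed at their intended acceptors, so the
  motifs' hydrogen bonds are near-linear by construction.  Models add
  0.15 Å jitter (hairpin/helix) or are independent walks (coil).

One integer seed threads through all generators via named
`SeedSequence` spawn keys (CRC32 of the stream name), so outputs are
bit-reproducible and sub-generators independent.

What passing tests on these fixtures do **not** show: recovery of real
peptide spectra (real basis sets are far more collinear than the
synthetic one, and measurement error is not white Gaussian noise),
DSSP's actual assignment behavior, or physical hydrogen-bond energetics.
They do show that the algorithmic chain — optimization, normalization,
consolidation, selection, geometry — is correct against independent
oracles.

## Numerical choices and problem sizes

- NNLS termination is SciPy's default (machine-precision KKT residual);
  weights below 1e-12 in sum are treated as a degenerate fit.
- Grid equality for fitting is exact array equality; use
  `restrict_overlap` to align grids first.
- Duplicate wavelengths are an error, not merged.
- Pair selection at φ = 0 uses exact floating-point equality by design.
- Self-tests and the acceptance script use desk-scale sizes chosen to
  exercise every code path with independent oracles: ≤ 51-point grids,
  48-protein bases, 100-seed noise ensembles, 500-frame selection tables,
  8-residue/20-model toy ensembles, a 1,000-frame end-to-end run.
- Map CSV round-trips are exact to ≤ 1e-9 (12 significant digits
  written); reference-set round-trips write 17 significant digits and
  reproduce matrices to ≤ 1e-9 in every dialect.

## Known limitations

- No smoothing, baseline correction, or HT-voltage filtering of raw CD
  data: inputs are assumed preprocessed, in Δε.
- The CSV/JSON reference formats are this package's own documented
  schemas; the fixed-format reader covers a CDPro-style layout but no
  attempt is made to parse every legacy variant.
- Whether experimental amplitudes should be rescaled before fitting is
  left to the user; the unbounded weights tolerate mismatch but cannot
  diagnose it.
- Contact maps are O(atoms²) per model — appropriate for peptides and
  small proteins, not for large complexes.
- Hydrogen-bond chemistry for non-standard residues must be supplied as
  explicit donor/acceptor annotations.
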