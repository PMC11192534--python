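# Methods

This note documents the models, numerical choices and known limitations of
`mcbuild`, in enough detail to reproduce or audit any part of the pipeline.

## Density forward model

Atoms are isotropic multi-Gaussian densities built from tabulated
scattering coefficients: the 4-Gaussian-plus-constant International Tables
X-ray form factors (the constant carried as a fifth Gaussian of zero
width), or 5-Gaussian electron scattering factors in EM mode. Each
Gaussian is broadened by the atomic B plus a resolution blur `B_res`
chosen so a zero-B point atom has FWHM equal to the nominal resolution
`d`: `B_res = 8π²·d²/(2√(2 ln 2))²`. Contributions are truncated at 4σ of
the widest component. In X-ray mode a flat level of 0.3 is added inside a
1.1×van-der-Waals model mask, emulating bulk solvent; EM mode adds no
background. The bulk-solvent parameters `k_sol = 0.4`, `b_sol = 45 Å²` are
recorded in `SyntheticSpec` for provenance but a Fourier-space
flat-mask solvent model is deliberately not implemented.

**Band-limited scoring.** A map synthesized by Fourier truncation at
`d` is not a sum of Gaussians: each atom appears as the spherical low-pass
of its Gaussian profile, ripples included. Scoring Gaussian candidates
against a band-limited target systematically misallocates occupancy (the
mismatch is absorbed asymmetrically by overlapping candidates), so every
density comparison in the fitting path evaluates atoms through cached
radial profiles

ρ(r) = ∫₀^{1/d} 4π s² F(s) j₀(2π s r) ds,  F(s) = Σⱼ aⱼ e^{−(bⱼ+B)s²/4},

computed by trapezoidal quadrature on 512 s-samples and interpolated on a
0.02 Å radial grid (cache keyed by element, B rounded to 0.1 Å², d, mode).
Map *synthesis* keeps the plain Gaussian forward model followed by explicit
Fourier truncation, so scoring and synthesis apply the same operator. A
noise-free synthetic EM map correlates with the direct forward density at
> 0.9999; in X-ray mode the sharp solvent-mask edge is not band-limited
and the correlation is ≈ 0.994.

## Synthetic data generator

The generator emulates resolution degradation of a known ground truth:

1. inflate all B-factors by 1 Å² per 0.1 Å of resolution loss from the
   base resolution (default 0.8 Å);
2. shake a copy of the coordinates with independent zero-mean Gaussian
   displacements, per-atom RMS `0.2·d`;
3. compute structure factors over a P1 box (10 Å margin, grid `d/4`, even
   dimensions) and truncate at `d`;
4. add per-reflection amplitude noise `F ← max(0, F + √F·ε·d·0.5)`,
   ε standard normal, phases untouched;
5. invert back to a real-space map.

The unshaken, B-inflated model is returned as the comparison reference.
All randomness flows through `numpy.random.default_rng(seed)`; a fixed
seed reproduces the map bitwise. What the generator does *not* emulate:
model-phase bias (no refinement of the stripped input against the noisy
amplitudes — such a re-refinement step would require an external
refinement engine and is omitted, so recovery results here are slightly
optimistic about input-model quality), crystal symmetry, anisotropic
noise, bulk-solvent scattering, and radiation damage. Scenario peptides
are extended-chain constructs with ideal template geometry; passing tests
therefore demonstrate correct recovery under idealized, noise-controlled
conditions, not performance on experimental data.

## Sampling

* Backbone: per-axis independent rigid translations at ±0.1, ±0.2, ±0.3 Å
  plus identity — 19 conformers along the Cα–Cβ, C–N and cross-product
  axes (Cβ anisotropic-tensor principal axes when present; an idealized
  virtual Cβ frames glycine). The counts are config-derived
  (`2·(amplitude/step)·3 + 1`).
* Aromatic angle: ±3.75° steps to ±7.5° (5 conformers), rotating the
  γ-moiety about the Cα-Cβ-Cγ plane normal through Cβ — the minimal motion
  realizing the angle change.
* χ sweeps: every 6° for 24° either side of each library rotamer mode;
  duplicate modal values across rotamers are swept once. The packaged
  library is a compact penultimate-style table of modal χ values
  (`data/rotamers.tsv`); proline uses endo/exo χ1 modes at ±24° with the
  Cδ–N ring closure restored per candidate by bounded 1-D minimization
  (candidates that cannot close within 0.1 Å are dropped).
* Pruning: hard-sphere self-clash (overlap factor 0.75 on van der Waals
  radii, 1-2/1-3 pairs exempt) and all-atom RMSD deduplication at 0.01 Å,
  keeping the earlier candidate; idempotent.
* B-factor expansion: multipliers 0.5–1.5 in steps of 0.2 (six variants
  per geometry), coordinates untouched.

## Occupancy fitting

The box/sum-constrained QP `min ‖y − Aw‖²` s.t. `lb ≤ w ≤ ub, Σw ≤ 1` is
solved in Gram space: columns with zero upper bound are eliminated, the
problem is shifted to non-negative variables, a total-occupancy slack is
appended as a penalty row (weight `√(10⁸·max diag G)`) on the Cholesky
factor, scipy's active-set NNLS solves the composite, and an exact KKT
solve on the identified active set polishes the solution (kept only when
feasible and objective-improving; ridge 10⁻¹⁰–10⁻¹² of the diagonal scale
guards singular Grams).

The MIQP adds binary selection: `threshold·zᵢ ≤ wᵢ ≤ zᵢ`, `Σzᵢ ≤
cardinality`. It is solved exactly by best-first branch-and-bound on the
`zᵢ`, using the relaxation that drops threshold/cardinality constraints on
unfixed candidates (a valid lower bound); a relaxed solution that happens
to satisfy the constraints closes its subtree. Warm starts come from
top-weight subsets of the plain QP. The node budget is 20 000; exhaustion
raises a solver error that triggers the degeneracy fallback: repeatedly
remove the lower-QP-weight member of the closest pair of candidates
(all-atom RMSD; ties drop the later index) and retry. On instances with
≤ 12 candidates the branch-and-bound matches exhaustive subset
enumeration to 10⁻⁴ in rss (tested).

BIC uses the voxel count of the candidate-footprint union as `n` — the
voxels informative about the residue — and counts B-variants of one
geometry once (`k = 4·atoms·distinct geometries` at residue level, `k =
conformations` at segment level; the 0.95 scaling acknowledges chemically
correlated coordinates). Ties resolve to the smaller cardinality, then the
smaller candidate index.

After the final BIC selection a fine local sweep re-optimizes each chosen
conformer's χ angles (±6° in 1.5° steps, two rounds, joint QP re-weighting
per trial) — motion only along already-sampled torsions.

## Per-residue map partitioning and context

Each residue is fitted against a sub-box of the map (5 Å padding). The
calculated density of all *other* residues (at their current occupancies)
plus the flat solvent level inside the model mask is subtracted from the
target first, so the linear occupancy model sees only the residue's own
signal. Candidate columns are computed at unit occupancy. Without this
context subtraction the mixture fit degenerates toward a single averaged
conformer.

## Segments, relabeling, finalization

Segments (maximal runs of residues with ≥ 2 backbone conformations;
backbone-distinctness threshold 10⁻³ Å RMSD) are assembled with a sliding
three-residue window advancing one residue at a time; selected
combinations act as frozen prefixes, enumeration is capped at 1024
combinations per window (top prior weights kept, with a warning), and the
final combination weights become shared occupancies, so backbone-connected
neighbors agree exactly.

Altloc letters are assigned by Metropolis Monte Carlo over per-residue
letter permutations (10 000 steps, T₀ = 1 clash unit, ×0.99 cooling every
100 steps, deterministic per seed). The energy counts heavy-atom
hard-sphere overlaps between same-letter conformers of different residues
(peptide-bond 1-2/1-3 pairs exempt) plus a dominant penalty (100 units)
whenever same-letter sequence neighbors fail to form a contiguous peptide
bond (|d(C,N) − 1.33| > 0.5 Å) — without the continuity term, relabeling
could scramble the slot alignment segments rely on. On instances with ≤ 4
multi-residues the result matches exhaustive labeling search (tested).

The finalization loop alternates occupancy-only re-fits with culling of
conformers below 0.10 occupancy and renormalization to residue sums of 1
(never emptying a residue: if all conformers fall below the floor the best
one is kept at occupancy 1, with a warning), stopping when stable or after
50 rounds. In the published protocol this loop interleaves full
crystallographic refinement; here the re-fit is occupancy-only on fixed
coordinates — the coordinates/B refinement itself is outside this
package's scope.

**Occupancy estimator.** Three choices make the final occupancies nearly
unbiased (each was isolated on noise-free data, where the naive estimator
showed systematic equalization of a 0.6/0.4 split):

1. *Segment-level chains*: within a segment the slot-aligned conformers of
   all members are scored as merged units, instead of per-residue fits
   averaged afterwards — near-identical backbone copies have no occupancy
   information of their own and would otherwise dilute the informative
   side-chain signal.
2. *Mode-anchored, B-equalized templates*: estimation templates have each
   χ snapped to its nearest library mode (≤ 30°; proline and χ-less
   residues exempt) and share per-atom mean B-factors across conformers.
   Fitted conformers drift a few degrees and a B-multiplier step to chase
   the particular noise realization; correlated displacement and
   differential sharpening of overlapping templates otherwise transfer
   weight between states.
3. *Discriminating voxels*: the re-fit uses voxels where the column spread
   exceeds half the local maximum (and 5% of the global maximum) — voxels
   where a state lobe is present in one conformer and absent in another.
   Shared density only constrains the total, which renormalization fixes
   at 1. If fewer than 20 such voxels exist the conformers are considered
   indistinguishable and current occupancies are kept.

Residues whose conformers are near-duplicates (< 0.01 Å RMSD) are merged
(occupancies summed) before output.

## Evaluation

* A residue is *multiconformer* when some conformer pair differs by more
  than 0.5 Å side-chain heavy-atom RMSD (all heavy atoms for glycine);
  near-duplicates collapse onto the highest-occupancy representative.
* Match classification pairs distinct conformer sets by optimal assignment
  (Hungarian algorithm on all-heavy-atom RMSD, no superposition — models
  share a frame) and requires equal distinct counts with every paired RMSD
  below the cutoff for a multiconformer match; the four labels are
  exhaustive and mutually exclusive.
* Recovered *state occupancies* assign each test conformer to its nearest
  reference conformer and sum occupancies within the 0.5 Å rule — a
  builder may legitimately split one underlying state into near-duplicate
  alternates (within-rotamer heterogeneity), which per-conformer
  comparison would misread.
* Rotamer names come from the nearest library mode over the first two χ
  (joint nearest rotamer, 40° rejection window → "outlier"; no-χ residues
  → "none"); agreement categories are plain set comparisons.
* The Q-score samples 16 Fibonacci-lattice points per 0.1 Å radial shell
  to 2 Å and Pearson-correlates them with the Gaussian profile the atom
  would produce if perfectly placed (width from its B plus the resolution
  blur). This is a simplified variant used only for the 0.7 sampling gate;
  the original method's nearest-atom point assignment and reference
  constants are not reproduced.
* Occupancy-weighted B is the heavy-atom mean of `occ·(4π/B)^1.5`; the
  real-space residual is 1 − Pearson correlation between calculated
  density and map over the model footprint.

## Problem sizes and replication

The test suite and acceptance script run on tripeptide scenarios
(ALA-SER-ALA, one two-rotamer serine site, B = 15 Å²) at resolutions
1.0–3.0 Å, with 3 replicate noise seeds for recovery statistics and 5 per
resolution for the fall-off curve — a scaled-down version of the
generator's 10-replicate convention. Recovery assertions use
replicate-mean state occupancies: under shake `0.2·d` and amplitude noise,
single-realization occupancies scatter by up to ±0.1 even for an oracle
estimator given the exact ground-truth geometry, so single-seed
assertions would test the noise realization rather than the method.

## Known limitations

* No coordinate/B refinement: fits inherit the 6°-grid (then 1.5°-polish)
  χ quantization and the 0.1 Å backbone translation grid.
* Backbone sampling is pure translation — no backrub or larger backbone
  moves, no loop building.
* Proteins only: no nucleic acids, ligands or waters; single-model PDB
  without insertion codes; P1 only (no crystallographic symmetry).
* The EM occupancy floor of 0.3 caps the cardinality at 3 conformers.
* Occupancy sums below 1 before finalization are deliberate (unexplained
  density is left to later refinement); only finalization renormalizes.
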