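# mcbuild

Automated multiconformer protein model building from real-space density
maps.

X-ray crystallography and cryo-EM maps are ensemble averages: many residues
genuinely occupy several discrete conformations, yet most deposited models
record only one. `mcbuild` takes a well-refined single-conformer model and a
high-resolution map (X-ray or EM, ideally better than ~2 Å) and
automatically builds a *multiconformer* model — alternative conformations
encoded as partially occupied altloc groups within one structure — together
with the synthetic-data generator and the evaluation metrics needed to
benchmark how well known heterogeneity is recovered.

## The method

For each residue the builder:

1. samples rigid **backbone translations** along local axes (or the
   principal axes of the Cβ anisotropic tensor), 0.1 Å steps out to 0.3 Å;
2. bends the **aromatic angle** (Cα–Cβ–Cγ) for His/Tyr/Phe/Trp by ±3.75°
   steps out to ±7.5°;
3. sweeps each **χ dihedral** every 6° for 24° around every idealized
   rotamer mode (endo/exo ring puckers for proline), pruning self-clashing
   and redundant candidates;
4. fits candidate occupancies `w` against the local density by **quadratic
   programming**, `min ‖ρ_obs − Σᵢ wᵢ ρᵢ‖²` with `wᵢ ≥ 0, Σwᵢ ≤ 1`;
   expands survivors over **B-factor multipliers** 0.5–1.5; and selects a
   parsimonious set by **mixed-integer QP** (at most 5 conformers, each with
   occupancy ≥ 0.2, or ≥ 0.3 in EM mode) arbitrated by the Bayesian
   information criterion

   `BIC = n·ln(rss/n) + k·ln(n)·0.95`,  `k = 4 · atoms · conformers`.

Residues are then reconnected: maximal runs of consecutive multi-backbone
residues (**segments**) are assembled by enumerating conformer combinations
over a sliding three-residue window (segment-level `k = conformers`),
altloc letters are assigned by Monte Carlo with a steric + backbone
continuity model, and a finalization loop re-fits occupancies and culls
conformers below 0.10 occupancy until stable, renormalizing each residue to
total occupancy 1.

The MIQP is solved exactly by branch-and-bound (validated against
exhaustive subset enumeration), and the synthetic-data generator follows
the standard degradation recipe: B-factors +1 Å² per 0.1 Å of resolution
loss, coordinate shake with RMS `0.2·d`, P1-box structure factors truncated
at `d`, and amplitude noise `F + √F · ε · d · 0.5`.

## Worked example

```bash
python examples/build_from_synthetic.py
```

builds a tripeptide whose serine occupies two rotamers (p at 0.6, m at
0.4), renders it into a noisy synthetic 1.5 Å map, strips the alternates,
and rebuilds:

```
map: (74, 72, 64) voxels at 0.375 A spacing

serine site: 2 conformer(s)
  altloc A  occupancy 0.465
  altloc B  occupancy 0.535
recovered state occupancies (truth 0.60 / 0.40): 0.535 / 0.465
match label: multiconformer_match
```

The builder found both alternative conformations from the
single-conformer input; under the 0.5 Å side-chain RMSD rule the site
counts as a *multiconformer match*, and the recovered state occupancies are
within a tenth of the ground truth for this noise realization.

The same pipeline is exposed as a command-line tool:

```bash
mcbuild synthesize scenario.json -o scen/
mcbuild build scen/synthetic_map.ccp4 scen/single_conformer_input.pdb -r 1.5 -o out/
mcbuild evaluate scen/ground_truth.pdb out/multiconformer_model.pdb
```

`build` accepts `--em` (electron scattering factors, no flat solvent
level, occupancy floor 0.3), `--only-segment` (occupancy harmonization and
relabeling of a hand-edited model, no sampling), and `--qscore FILE`
(skip multiconformer sampling for residues whose map Q-score is below
0.7).

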