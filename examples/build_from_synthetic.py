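"""Build a multiconformer model from a synthetic two-conformer dataset.

Creates a tripeptide whose serine occupies two rotamers (p at 0.6, m at
0.4), degrades it to a noisy 1.5 A map, strips the alternates to emulate a
conventionally built single-conformer model, and runs the full build
pipeline.  The printed occupancies show how much of each ground-truth state
the builder recovered; the match label applies the 0.5 A side-chain RMSD
rule used for benchmarking.
"""

import warnings

import mcbuild as mc

warnings.simplefilter("ignore")

spec = mc.ScenarioSpec(
    sequence=["ALA", "SER", "ALA"],
    sites={2: mc.SiteSpec(["p", "m"], [0.6, 0.4])},
    resolution=1.5,
    seed=1,
)
ground_truth, single_input, density_map = mc.make_scenario(spec)
print(f"map: {density_map.shape} voxels at {density_map.spacing:.3f} A spacing")

config = mc.RunConfig(resolution=spec.resolution, seed=0)
model, report = mc.build_multiconformer_model(single_input, density_map, config)

site = model.get("A", 2)
truth_site = ground_truth.get("A", 2)
print(f"\nserine site: {len(site.conformers)} conformer(s)")
for conf in site.conformers:
    print(f"  altloc {conf.altloc or '-'}  occupancy {conf.occupancy:.3f}")
states = mc.state_occupancies(truth_site, site)
print(f"recovered state occupancies (truth 0.60 / 0.40): "
      f"{states[0]:.3f} / {states[1]:.3f}")
print(f"match label: {mc.match_classify(truth_site, site).value}")
print(f"wall time: {report['wall_time_s']} s")
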