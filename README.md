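# endodisp

Quantifying how well a brain fills its braincase. In most fishes and
amphibians the brain occupies only a fraction of the endocranial cavity, so
a cranial *endocast* — the mould of that cavity, often the only neural proxy
preserved in fossils — can be a poor stand-in for brain size and shape.
`endodisp` measures that brain–endocast spatial disparity from segmented
surface meshes, and relates it to the surrounding jaw musculature via
anatomical cross-sectional areas (ACSA) from labeled CT volumes.

Given a brain and an endocast surface mesh (STL, mm) of one specimen, the
pipeline computes:

- **Rigid superposition** by iterative closest point (ICP): sampled brain
  vertices are matched to their exact nearest points on the endocast
  surface and the closed-form Kabsch solve is iterated. Rotation +
  translation only — both meshes come from the same scan, so scale is
  physical.
- **Surface disparity**: directed mean and maximum unsigned point-to-surface
  distances in both directions; the *symmetric mean* ½(d̄_{A→B} + d̄_{B→A})
  and the *maximum absolute distance* max(max_{A→B}, max_{B→A}) (symmetric
  Hausdorff). Distance queries are exact (face/edge/vertex regions) and
  KD-tree accelerated with a lossless pruning bound.
- **Distance map**: the unsigned distance from each endocast vertex to the
  brain surface, exported as a vertex-colored PLY for figure rendering.
- **Volume overlap**: divergence-theorem mesh volumes, the brain volume as a
  rounded percentage of endocast volume, and a Dice similarity coefficient
  2|A∩B|/(|A|+|B|) computed by voxelizing both solids on a shared grid
  (voxel occupied ⇔ its center is inside the surface, by ray-crossing
  parity).
- **ACSA**: per-slice areas of a labeled structure (e.g. the adductor
  mandibulae complex) from an anisotropic voxel volume, with the
  repeated-measurement protocol (10 measurements cycled over 5 slices)
  used in manual tracing studies.

Because specimen segmentations are rarely redistributable, the
`synthetic_data` module generates phantoms with closed-form ground truth —
nested icospheres, regionally shrunken capsules, block/cylinder/taper label
volumes — against which every stage is validated.

## Worked example

```python
from endodisp import (PipelineConfig, make_nested_pair,
                      run_disparity_analysis, write_triangle_mesh)

# phantom: brain = unit sphere offset 0.5 mm inside a radius-2 endocast
pair = make_nested_pair(2.0, 1.0, offset=(0.5, 0.0, 0.0), subdivisions=3, seed=7)
write_triangle_mesh(pair.brain, "brain.stl")
write_triangle_mesh(pair.endocast, "endocast.stl")

report = run_disparity_analysis("brain.stl", "endocast.stl",
                                PipelineConfig(register=False), out_dir="out")
```

The report row printed for this pair:

```
specimen brain_volume_mm3 endocast_volume_mm3  percent  dice symmetric_mean_mm max_absolute_mm voxel_size_mm
   brain              4.2                33.2       13 0.222             0.977           1.500        0.0346
```

Every number has a closed form here: the volume ratio is (1/2)³ = 12.5 % →
13; Dice for nested solids is 2·V_in/(V_in+V_out) = 2/9 ≈ 0.222; the
symmetric Hausdorff distance is R − r + |offset| = 1.5 mm. `out/` also
receives `map_brain.ply` (the distance map colored on the endocast, with a
CSV sidecar recording the color range), `transform_brain.json` (the 4×4
superposition matrix) and `run.log` (all resolved parameters).

The same pipeline is scriptable from a shell:

```sh
endodisp run --brain brain.stl --endocast endocast.stl --out out
endodisp batch --manifest specimens.csv --out out
endodisp phantom --kind nested --seed 7 --out phantom
endodisp csa --stack labels/ --label 1 --slices 10,11,12,13,14 --axis z
```

A batch manifest may carry mesh paths, or just printed brain/endocast
volumes per specimen — those rows pass straight through the
percent-occupancy statistic.

## Layout

- `endodisp.mesh_io` — STL reading with vertex welding, mesh validation,
  vertex-colored PLY export
- `endodisp.synthetic_data` — phantom generators with analytic truth
- `endodisp.registration` — Kabsch solve, rigid-transform algebra, ICP
- `endodisp.disparity` — exact point-to-surface distances, summaries, maps
- `endodisp.overlap_volume` — mesh volume, voxelization, Dice, percent
- `endodisp.csa` — label volumes, slice areas, repeated-measurement means
- `endodisp.pipeline` / `endodisp.cli` — orchestration and the `endodisp`
  command

See `docs/methods.md` for the measurement conventions, parameter defaults
and known limitations.
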