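# meshflow

Occlusion-robust recovery of tissue surface deformation from stereo scene
flow, for computer-assisted intervention research: tracking how a soft
surface (a hydrogel phantom, an organ under palpation) changes shape while
a surgical instrument partially hides it from the camera.

Binocular video yields, per frame pair, a 3D displacement field — the
*scene flow* — composed from stereo disparity and optical flow.  Raw scene
flow is unusable directly: stereo and flow mismatches inject gross
outliers, and wherever the tool occludes the tissue the observed motion
belongs to the tool.  `meshflow` represents the surface as a triangle mesh
with fixed connectivity and recovers its per-frame vertex positions with
three ingredients:

1. **Strain-based flow filtering.**  Per vertex, the spatial displacement
   gradient `G = ∂(u,v,w)/∂(x,y,z)` is estimated by vertex-wise least
   squares over the k-ring neighbourhood; the infinitesimal strain tensor
   `ε = (G + Gᵀ)/2` has principal strains `ε₁ ≥ ε₂ ≥ ε₃`, and a vector is
   rejected as an outlier when the maximal absolute principal strain
   (plus a robust deviation term, see `docs/methods.md`) exceeds the
   threshold `ε_t = 1`.  Vertices projecting into the tracked instrument
   mask are rejected outright.

2. **Mesh optimization.**  Each frame solves, in the least-squares sense,

       [ Ĩ  ]       [ C*   ]
       [ αE ] C  =  [ αΔ_E ]

   where the dynamic term `ĨC = C*` anchors vertices with surviving flow
   to their flow-updated positions `C* = ĨC_p + F_s`, and the smoothness
   term `EC = Δ_E` pulls the mesh's differential coordinates back toward
   those of the initial mesh.  `E` is the differential edge matrix (one
   row per edge: +1/−1 on its endpoints), `Δ_E = EC₀` is fixed over the
   sequence, and `α ≈ 1–2` weighs smoothness against data.  A graph
   Laplacian `L = EᵀE` is available as the classical baseline operator.

3. **Instrument depth constraint.**  Occluded vertices must stay at least
   as deep as the reconstructed tool above them: the z column is solved
   as a bound-constrained least-squares problem `Z_o ≥ P_z`, with `P_z`
   the depth of the nearest instrument point (exact primal active-set
   solver).

The package also implements the matching evaluation metrics (three-point
plane-projection surface distance with per-axis decomposition, 95%
Hausdorff distance, per-edge Cauchy strain `(L−L₀)/L₀`, ICP registration)
and a fully seeded synthetic phantom simulator so the entire pipeline is
testable without any external data.

## Worked example

```python
import numpy as np
from meshflow import SyntheticScenario, generate_sequence, MeshDeformationModel

scenario = SyntheticScenario(seed=1)        # 60x60 grid, 10 frames, 5 mm press,
seq = generate_sequence(scenario)           # 10% outliers, tool-shaft occluder
model = MeshDeformationModel(seq.mesh0, alpha=1.5)
result = model.run_sequence(seq.frames)
print(result.summary())
err = np.linalg.norm(result.meshes[-1].vertices - seq.true_vertices[-1], axis=1)
print(f"mean vertex error vs ground truth: {err.mean():.3f} mm")
```

prints

```
Deformation recovery summary
============================
frames               : 10 (incl. initial)
vertices             : 3600
smoothness operator  : edge (alpha=1.5)
skipped frames       : none

frame   valid   occl  dyn res (mm)  smooth res (mm)
    1    2724    347        8.2492           2.0487
    2    2721    347        8.1781           2.7519
    ...
    9    2722    347        8.9334           6.8386
mean vertex error vs ground truth: 0.259 mm
```

Per frame, roughly 2720 of 3600 vertices survive filtering (the rest are
margins, tool pixels, and the injected gross outliers), 347 vertices sit
under the occluder and carry depth bounds, and the dynamic residual stays
at the level of the injected observation noise while the smoothness
residual grows with the accumulated deformation.  The final mesh is within
0.26 mm of the ground truth on average — applying the raw scene flow
directly instead leaves a 6.3 mm error (the failure mode the filtering and
optimization exist to prevent).

The same pipeline is scriptable from the shell:

```sh
meshflow simulate --out scenario/ --seed 1
meshflow recover  --scenario scenario/ --out recovered/
meshflow evaluate --recovered recovered/ --reference scenario/ --out report/
meshflow filter   --scenario scenario/ --frame 1 --out filter.csv
```

`recover` accepts `--alpha`, `--eps-t`, `--smoothness {edge,laplacian}`,
`--no-filter`, `--no-constraint`, and `--raw-update` for ablations.

## Layout

| module | contents |
| --- | --- |
| `meshflow.meshcore` | `TriangleMesh`, edge extraction, `E`/`L` operators, delta coordinates, mesh initialization from points, PLY/OBJ I/O |
| `meshflow.sceneflow` | stereo calibration, triangulation, scene-flow composition and ingestion |
| `meshflow.strainfilter` | VWLS gradients, strain tensors, outlier filtering |
| `meshflow.instrument` | tool mask propagation, occlusion detection, depth bounds |
| `meshflow.meshopt` | `MeshDeformationModel` / `FrameFit` / `SequenceResult`, the constrained solver |
| `meshflow.evaluation` | surface distance, HD95, Cauchy edge strain, ICP |
| `meshflow.synthetic` | seeded scenario generator and analytic image-domain renderer |
| `meshflow.cli` | `meshflow` command-line driver |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
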