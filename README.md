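# splintforge

Scriptable CAD for orthognathic dental splints.

In orthognathic (corrective jaw) surgery, a dental splint is a custom
occlusal wafer that locks the upper and lower dentition into the planned
relative position. splintforge builds printable splints from triangle
meshes of the maxilla and mandible in three steps:

1. **Initial splint base** — a watertight horseshoe solid assembled from
   ruled surfaces over surgeon-picked landmark lines. The lines' inner and
   outer endpoints are interpolated by chord-length Catmull–Rom splines,
   resampled, and connected into four ruled sheets plus end caps.
2. **Boolean molding** — the maxilla and mandible are subtracted from the
   base with a signed-distance-field mesh Boolean: intersected faces are
   split so the intersection curve is embedded as edges, cells are
   classified by the signed distance of their (off-seam) probe points to
   the other solid, and the kept cells are welded into a watertight result.
   The original mesh geometry is carried into the result unchanged, so no
   accuracy is lost to remeshing.
3. **Undercut removal** — teeth wider at the crown than at the neck
   ("big-end-up") would lock the splint in place. The *swept silhouette* of
   the dentition along the removal direction is reconstructed
   (slice → cumulative union → voxelize → morphological closing → marching
   cubes) and subtracted, so the splint seats and unseats along a straight
   path.

Everything is exposed both as a Python library and as a `splintforge`
command-line tool; results are STL (binary or ASCII, mm).

## Worked example

No patient data is required: the package ships deterministic phantoms. The
following designs a splint for a synthetic dental arch with undercut teeth
and removes the undercuts along +z:

```sh
splintforge phantom arch -o maxilla.stl mandible.stl plan.json
splintforge -v design --maxilla maxilla.stl --mandible mandible.stl \
    --plan plan.json -o splint.stl --deundercut --direction 0,0,1 \
    --slice 1.0 --voxel 0.5
```

The run report (`splint.stl.report.json`) records per-stage timings and
mesh sizes; on the default six-tooth arch the final splint is watertight
with roughly

```json
"result": {
  "watertight": true,
  "volume_mm3": 6438.140427827805,
  "cells": 17076,
  "points": 8540
}
```

i.e. a ~6.4 cm³ wafer whose cavities follow every crown but contain no
undercut: translating it along +z by any positive distance no longer
intersects the dentition (the test suite verifies this with the Boolean
engine at 0.5, 1, 2 and 5 mm offsets).

The same stages are available individually (`phantom`, `base`, `boolean`,
`sweep`, `deundercut`, `measure`), and from Python:

```python
from splintforge import phantoms, build_initial_splint, boolean, eliminate_interference

spec = phantoms.ArchPhantomSpec()
maxilla, mandible = phantoms.make_arch_phantom(spec)
base = build_initial_splint(phantoms.make_plan_for_arch(spec))
splint = boolean(boolean(base, maxilla, "difference"), mandible, "difference")
final = eliminate_interference(splint, mandible, removal_direction=[0, 0, 1])
```

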