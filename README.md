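# orthoplan

Digital articulator-equivalent model surgery planning for orthognathic
cases.

From four landmarks on a lateral cephalogram (Pi, Ns, Ie, Dc) the
package derives the face-bow geometry, the mounting angle between the
occlusal plane and the axis-orbital plane, and the position of the
arbitrary hinge axis relative to the upper incisor edge.  Frontal-photo
landmarks yield the transverse occlusal cant and dental midline offset.
Maxilla and mandible surface meshes (STL) are then mounted in a y-up
world frame, planned jaw movements are applied to cloned jaws, pivot
displacements are measured, occlusal contacts are detected by signed
mesh distance, and splint-fabrication STL sets (intermediate/final,
single-jaw or bimaxillary) are exported in their true relative poses.

A fully deterministic synthetic-case generator produces toy dental-arch
meshes with exactly known landmark coordinates and — via a lateral
orthographic projection of a known 3D mounting configuration — 2D
"cephalometric" landmarks whose recovery can be verified against ground
truth.  It is the oracle behind most of the test suite.

## Layout

| Module | Role |
| --- | --- |
| `orthoplan.cephalometrics` | face-bow triangle, occlusal-plane angle, mounting angle, hinge-axis position |
| `orthoplan.photometry` | transverse cant and midline offset from frontal-photo landmarks |
| `orthoplan.mounting` | world-frame alignment, cant correction, hinge pivot, AOP rotation, bite registration |
| `orthoplan.planning` | jaw cloning/moves, displacement reports, contact detection, open rotation, splint export, planning sheet |
| `orthoplan.synthetic` | seeded ground-truth case generation (meshes, projections, truth) |
| `orthoplan.mesh` / `stl` / `scene` / `config` / `cli` | triangle meshes, STL I/O, scene archives, configuration, CLI |

## CLI

All units are millimetres and degrees; every command is reproducible
(fixed float formatting, seeded generation).

```bash
# generate a synthetic case directory (STLs + landmark JSONs + truth)
orthoplan simulate --seed 7 --out case/ --cant 2.5

# cephalometric landmarks -> mounting parameters
orthoplan mount-params --landmarks case/ceph_landmarks.json --out params.json

# mount the jaws in the world frame
orthoplan mount --case case/ --params params.json \
    --frontal case/frontal_landmarks.json --out scene/

# clone jaws and apply planned moves
orthoplan plan --scene scene/ --moves moves.json --out planned/

# measure displacements, detect contacts, export splints, write the sheet
orthoplan measure --scene planned/ --out meas/
orthoplan contacts --scene planned/ --tolerance 0.1
orthoplan export-splints --scene planned/ --scenario bimaxillary --out splints/
orthoplan report --scene planned/ --params params.json --out report/
```

A `moves.json` looks like

```json
{"moves": [
  {"jaw": "maxilla", "translation": [0, 0, 4],
   "rotation": {"axis": [0, 1, 0], "angle_deg": 2.0, "center": "Ie"}},
  {"jaw": "mandible", "translation": [0, 0, -3]}
]}
```

Constants (nasal-rest offset 30 mm, hinge-axis offset 10 mm, open
rotation 2°, contact tolerance 0.1 mm) can be overridden with a JSON
config file passed via `--config`.

## Conventions

* Cephalometric computations run in the radiograph image frame: origin
  top-left, y down, patient facing image-right.
* World frame: y up, +z anterior, +x patient-left; "distally" = -z.
* Angles are degrees at every API surface, radians internally.
* STL is written binary little-endian by default, ASCII with `--ascii`.
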