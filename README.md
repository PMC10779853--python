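# pulpsweep

Locating root-canal orifices in segmented micro-CT scans of multi-rooted
teeth.

Where the pulp chamber ends and the root canals begin is poorly
standardised: the cemento–enamel junction (CEJ) is a stable landmark on
single-rooted teeth, but in molars the pulp floor lies apical to it, and
published canal-configuration counts depend on where each operator put
the cut.  `pulpsweep` automates a landmark-based protocol for first
permanent molars: fit a reference plane to landmarks on the CEJ, sweep a
landmark-anchored cross-sectional plane apically through the segmented
pulp, detect the depths at which the cross-section splits (the
bifurcation/trifurcation zeniths on the pulp floor), and define each
canal's **orifice** as its cross-section on the plane at the split where
it separated from its last sibling — "the entrance of a root canal at
the most apical point on the pulp chamber".  The pulp complex is then
partitioned exactly into chamber, inter-furcation shared regions, and
per-canal radicular spaces.

The package is aimed at dental morphometrists and endodontic researchers
working with segmented micro-CT (or CBCT) volumes.  Because no scan data
can be redistributed, it ships a parametric phantom generator that
renders labeled tooth volumes — two- and three-rooted mandibular molars
(including Radix Entomolaris), maxillary molars with separate, fused,
C-shaped and taurodont morphologies — with exact ground truth, and the
whole pipeline is validated against it.

## Method sketch

For a volume labeled {background, enamel, dentine, pulp}:

1. **CEJ plane** — the CEJ ring is extracted as the external
   enamel–dentine boundary and a total-least-squares plane is fitted
   (the normal is the smallest singular direction of the centred
   points); the normal is oriented occlusally using the pulp centroid.
2. **Re-orientation** — the volume is resampled (nearest-neighbour,
   labels are categorical) so the anchor-slice normal becomes the sweep
   axis; slice index increases apically.
3. **Anchor slice** — the plane through the 3–4 slice-anchor landmarks
   A–D placed at the highest occlusal point of each root on the CEJ
   (exact for 3 anchors, total-least-squares for 4).
4. **Sweep and split detection** — the slice moves apically in steps of
   one voxel; per-slice 8-connected pulp components are tracked by
   maximal overlap.  A component mapping to ≥2 surviving children is a
   furcation event (landmarks D/E/F); its saddle is the midpoint of the
   shortest dentine gap between the children.  Pulp stones and
   resampling debris are suppressed by a minimum-area filter and a
   0.2 mm persistence guard.
5. **Orifices and partition** — each terminal branch's orifice is taken
   at the deepest split on its root-to-leaf path; branches that never
   separate (C-shaped ribbons) share one orifice, written `MB//DB`.
   Every pulp voxel is assigned to exactly one region (asserted on
   every run).

## Worked example

```python
import pulpsweep as ps

spec = ps.preset("mand_radix", seed=1)          # three-rooted mandibular molar
vol, truth = ps.build_phantom(spec)             # labeled volume + ground truth
landmarks = ps.render_landmarks(truth)          # CEJ ring + anchors A-D
result = ps.run_pipeline(vol, landmarks, arch=spec.arch, side=spec.side)

rep = result.report
print(f"configuration: {rep.configuration}")
for e in rep.events:
    print(f"{e.kind} at {e.depth_mm:.2f} mm below the CEJ plane")
for c in rep.canals:
    print(f"canal {'//'.join(c.labels):4s} orifice {c.orifice_depth_mm:.2f} mm, "
          f"area {c.area_mm2:.2f} mm^2, volume {c.volume_mm3:.2f} mm^3")
```

prints

```
configuration: M D DL
bifurcation at 1.85 mm below the CEJ plane
bifurcation at 2.70 mm below the CEJ plane
canal M    orifice 1.85 mm, area 0.48 mm^2, volume 0.80 mm^3
canal D    orifice 2.70 mm, area 0.26 mm^2, volume 0.28 mm^3
canal DL   orifice 2.70 mm, area 0.21 mm^2, volume 0.20 mm^3
```

The phantom's true split depths were 1.804 and 2.676 mm: the mesial
canal's orifice sits at the first bifurcation, the distal and
disto-lingual canals share the second, deeper one, and the chamber
space between the two events is reported separately as the region
shared by the two distal canals.

The same pipeline is available from the shell:

```bash
pulpsweep phantom mand_radix --seed 1 --out-dir work/
pulpsweep run work/mand_radix_1.nrrd work/mand_radix_1_landmarks.json \
    --arch mandibular --side right --out-dir work/
pulpsweep eval --presets mand_radix,max_c_shape --seeds 0,1,2 --out recovery.csv
```

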