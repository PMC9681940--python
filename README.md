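# slnfusion

Fusion of preoperative SPECT/CT with intraoperative CT, and quantitative
evaluation of the resulting augmented-reality (AR) overlay, on a digital
twin of a pelvic sentinel-lymph-node (SLN) phantom.

In endometrial cancer surgery the SLN is localized preoperatively by
lymphoscintigraphy SPECT/CT, but that functional information has to be
brought into the intraoperative frame before it can guide a
laparoscopic dissection. `slnfusion` implements and evaluates that
chain on a synthetic phantom whose ground truth is known exactly:

1. **Phantom generation** — a parametric pelvis-like phantom (radiopaque
   bone arch, tubular iliac-vessel tree, two fillable SLN spheres of
   8 mm (left) and 15 mm (right), and a calibration board of ≥4
   non-coplanar spherical fiducials), voxelized on a fine grid.
2. **Acquisition simulation** — a CT-like render (1 mm voxels, Gaussian
   noise) of the intraoperative session, and a preoperative SPECT/CT
   session under a seeded rigid misalignment (≤10° / ≤20 mm by default):
   its CT arm plus a SPECT-like render (4.4 mm voxels, 10 mm FWHM
   Gaussian PSF, Poisson noise, activity confined to the spheres).
3. **Segmentation** — intensity-window + connected-component extraction
   of SLNs, bone, vessels and fiducials from CT; isocontour hotspot
   extraction from SPECT.
4. **Rigid registration** — closed-form fiducial (Procrustes)
   initialization, refined by maximizing mutual information
   MI = Σ p(a,b) log₂[p(a,b)/(p(a)p(b))] over 6-DOF rigid transforms;
   the result is a 4×4 matrix mapping preoperative to intraoperative
   world coordinates, applied by trilinear resampling.
5. **AR projection and scoring** — each SLN segment is rendered through
   a pinhole camera twice (estimated vs true transform), giving the AR
   surface s1 and ground-truth surface s2, scored by the
   **normalized barycenter distance** d(b1,b2)/r with r = √(area(s1)/π),
   and the **coverage rate** |s1 ∩ s2| / |s2|.

The model, conventions, parameter defaults and their rationale are
documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Run a small experiment from Python:

```python
from slnfusion.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig(seeds=[0, 1, 2, 3, 4], save_volumes=False)
report = run_experiment(config)
for side in ("left", "right"):
    ratio = report.aggregates[f"ratio_{side}"]["median"]
    cov = report.aggregates[f"coverage_{side}_pct"]["median"]
    print(f"{side:5s}  median d/r = {ratio:.4f}   median coverage = {cov:.2f}%")
```

which prints (exact values are deterministic for a given seed list):

```
left   median d/r = 0.0142   median coverage = 99.67%
right  median d/r = 0.0020   median coverage = 100.00%
```

A median d/r of ~0.01 means the AR barycenter lands within ~1% of a
pseudo-radius of the true node center — the registration chain recovers
the simulated patient repositioning to a few hundredths of a millimetre
at the SLNs, so the AR overlay covers essentially the whole visible
node. Per-seed records (true/estimated 4×4 matrices, fiducial
registration error, target registration error at each SLN, per-node
overlay reports) are in `report.records`, and `run_experiment(config,
output_dir=...)` writes NIfTI volumes, plain-text transforms, PNG mask
pairs and JSON/CSV reports.

The same pipeline is scriptable from the shell:

```bash
slnfusion run --outdir out/            # full experiment, default config
slnfusion generate --out phantom.nii.gz
slnfusion simulate --seed 3 --outdir sim/
slnfusion register --fixed sim/intraop_ct.nii.gz --moving sim/preop_ct.nii.gz --out T.txt
slnfusion project --ct sim/preop_ct.nii.gz --transform T.txt --outdir masks/
slnfusion score --s1 masks/sln_left.png --s2 truth.png
```

`slnfusion run` exits 0/1/2 for no / some / all seed failures. Configs
are JSON (`--config`); an empty file means all defaults, unknown keys
are rejected with a full list of violations.

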