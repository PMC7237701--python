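# brachyqa

An independent second-check dose engine for HDR image-guided adaptive
brachytherapy (IGABT) with tandem-and-ring applicators.

Treatment plans for cervix IGABT are re-optimized at every fraction, so each
plan must be verified before delivery. Point-dose spot checks alone miss
volumetric errors; `brachyqa` recomputes the full 3D dose of a plan
independently of the treatment planning system (TPS) and compares doses at
reference points, DVH parameters, EQD2-converted doses, and — when a TPS dose
volume is available — gamma pass rates.

## What it computes

**TG-43U1 line-source dose.** The dose rate around the stepping source is

    D(r, θ) = S_K · Λ · [G_L(r, θ) / G_L(r₀, θ₀)] · g_L(r) · F(r, θ)

with air-kerma strength S_K (U), dose-rate constant Λ (cGy h⁻¹ U⁻¹), the
line-source geometry factor G_L = β/(L·r·sinθ), radial dose function g_L(r)
and anisotropy function F(r, θ), referenced at r₀ = 1 cm, θ₀ = 90°. Plan dose
is the superposition of all dwell contributions weighted by dwell time.

**Ring source orientations by the tangent method.** The kernel needs each
dwell's source axis. Inside a ring applicator the source points along the
local ring tangent, not along the chord to the next dwell. `brachyqa` fits
the ring plane from triples of dwell positions (RMSE-selected), fits the
circle in that plane by least squares, and orients each dwell along the
circle tangent at its position. The chord-chaining baseline is also provided:
for n equally spaced dwells it is provably wrong by half the angular step
(22.5° for 8 dwells on a full circle).

**DVH, applicator exclusion, criteria.** Contours are rasterized at a
selectable grid size (0.5 / 1.0 / 2.5 mm; default 1.0 mm), D100%/D90% and
D10cc/D2cc/D0.1cc are computed from exact sorted voxel doses, the target is
evaluated both with and without the applicator volume, and standard plan
criteria (HR-CTV D90% ≥ 550 cGy; D2cc < 460/420/420 cGy for bladder /
rectum / sigmoid) are checked.

**EQD2.** Per-fraction doses are converted through the linear-quadratic
model, BED = nd(1 + d/(α/β)) and EQD2 = BED/(1 + 2/(α/β)), with α/β = 10 Gy
for the tumour and 3 Gy for organs at risk.

**Gamma analysis.** Two dose distributions are compared with the gamma index
at configurable criteria (default 3%/3 mm, normalized to the reference
maximum), including extraction of the ring's axis plane from a 3D volume.

## Worked example

Everything runs without clinical data: the built-in generator writes a
synthetic tandem-and-ring plan (8 ring dwells on a 15 mm circle plus 8
tandem dwells, S_K = 40700 U, 18 s dwells) and an ellipsoidal phantom
(HR-CTV + bladder/rectum/sigmoid + applicator ROI):

```
$ brachyqa make-fixture --out-dir demo --seed 1 --source ir192-generic
$ brachyqa fit-ring demo/plan.yaml
channel: ring
normal: 0.000000 0.000000 1.000000
center_mm: -0.0000 -0.0000 0.0000
radius_mm: 15.0000
rmse_mm: 0.000000
$ brachyqa verify demo/plan.yaml demo/structures.yaml --grid 1.0 --out demo/report.txt
```

The report shows (excerpt):

```
## reference point doses (cGy per fraction)
A_right: 515.2924
...
## DVH parameters (cGy per fraction)
HR-CTV (applicator excluded): volume_cc=52.615  D100%=435.59  D90%=579.13 ...
## plan criteria
hrctv D90%=579.13 cGy >= 550: pass (margin +29.13 cGy)
bladder D2cc=367.18 cGy < 460: pass (margin +92.82 cGy)
rectum D2cc=388.44 cGy < 420: pass (margin +31.56 cGy)
sigmoid D2cc=316.08 cGy < 420: pass (margin +103.92 cGy)
overall: pass
## EQD2 (Gy)
hrctv D90% (a/b=10): f1=7.6209 ... total=38.1047
```

Reading the numbers: the dose to the hottest 90% of the target (applicator
voxels excluded) is 579 cGy per fraction, above the 550 cGy prescription
level; every organ-at-risk D2cc is under its limit; and the five-fraction
EQD2 of the target D90% is 38.1 Gy. Point A sits 2 cm superior / 2 cm
lateral of the ring centre and receives 515 cGy, while the more lateral
point B receives 124 cGy.

Other subcommands: `compute` (3D dose volume), `points` (doses + %diff at
absolute coordinates), `dvh`, `eqd2`, `gamma`, `make-fixture`. All physical
choices (source table, grid size, α/β map, gamma criteria) come from flags
or a YAML config and are echoed in the report.

## Scope

Water-equivalent TG-43 dose only (no heterogeneity or shielded-applicator
corrections, no transit dose), file-based DICOM (no networking), and
tangent orientations for ring channels with chord-chaining for tandem or
generic channels. See `docs/methods.md` for the model details, numerical
choices and limitations.
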