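# apicodyn

Quantification of cell-cycle-coupled apical constriction in
pseudostratified neuroepithelia.

Neuroepithelial cells shrink ("constrict") or expand ("dilate") their
apical surfaces as they progress through the cell cycle, and on flat
tissue geometries mitotic cells constrict to a minimum apical area at
anaphase. `apicodyn` implements the measurement pipeline behind this kind
of study, for imaging labs analysing en-face confocal data of
neuroepithelia (embryonic neural plate, iPSC-derived neuroepithelial
sheets):

* **Apical morphometry** — per-cell apical polygon areas; apicomedial
  "cap" and junctional "cortex" measurement regions (the cap outline
  offset outward by 0.5 µm with round joins); mean intensities under a
  pixel-center rule; per-embryo normalization of staining intensity
  (each embryo's mean set to 100%); Pearson/OLS area–intensity
  regressions split by mitotic status.
* **Pulse dynamics** — live apical-area traces normalized to each cell's
  mean, aligned to T0 (anaphase frame for mitotic cells, minimum-area
  frame for interphase cells), aggregated as mean ± SEM per timepoint;
  constriction pulse amplitude estimated by nonlinear least-squares sine
  fitting, y = c + A·sin(2πt/T + φ); paired t-test of area at T−30 min
  vs T0; unpaired t-test of mitotic vs interphase amplitudes.
* **Tissue curvature** — arc/chord ratio of apical surface profiles and
  a Taubin algebraic circle fit for the radius of curvature; correlation
  of per-embryo radius with median mitotic apical area.
* **Ki-67 staging** — connected-component focus detection in 3D nuclear
  stacks; rule-based stage calls (many small foci → early G1, two
  condensates → S, one punctum → G2, spread over condensed chromatin →
  M); nuclear volume as a cell-cycle surrogate; apical distance; the
  "nuclear index" pseudo-row count.
* **Synthetic data** — seeded generators for every input modality
  (Voronoi apical mosaics, pulsatile traces with anaphase-locked events,
  circular-arc profiles, staged Ki-67 nuclei) with exported ground
  truth, so the whole pipeline is exercised and validated without any
  external data.
* **Statistics** — pooled/Welch/paired t-tests, one-/two-way ANOVA with
  Bonferroni post-hoc, Pearson correlation.

## Worked example

```sh
python examples/02_pulse_dynamics.py
```

```
mitotic mean curve: minimum 0.608 x own mean at T+0 min (T0 = anaphase)
paired t-test, T-30 vs T0: t = 27.64, p = 7.3e-22
sine amplitudes: mitotic 0.156 vs non-mitotic 0.051 (fraction of own mean area); t-test p = 1.7e-46
-> mitotic constriction is the highest-amplitude apical pulse.
```

The generated cohort (29 mitotic, 54 interphase cells) reproduces the
expected dynamics: the mitotic mean curve bottoms out exactly at the
anaphase frame at ~0.61× each cell's mean area, the 30-minutes-before vs
anaphase paired comparison is strongly significant, and the sine-fit
pulse amplitude of mitotic cells is about three times the interphase
oscillation (the constriction event adds to the doubled sine amplitude).

The other example scripts cover mosaic morphometry
(`01_mosaic_morphometry.py`: negative area–intensity relation confined
to mitotic cells), tissue curvature (`03_tissue_curvature.py`), and
Ki-67 staging (`04_ki67_staging.py`: stage calls and the
earlyG1 < S < G2 volume ordering).

A thin CLI wraps the same library calls:

```sh
apicodyn run --seed 1 --out out/          # simulate + all analyses
apicodyn pulses --traces out/traces.csv --lag 30 --out out/
```

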