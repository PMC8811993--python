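# faleak

Semi-automated quantification of fluorescein-angiography (FA) leakage and
prediction of anti-VEGF treatment response in branch retinal vein
occlusion (BRVO).

Macular edema from BRVO is treated with intravitreal anti-VEGF, but
roughly half of eyes need many repeated injections.  `faleak` implements a
pipeline that turns a single pre-treatment FA frame pair (1 min and 5 min
after dye injection) into a quantitative leakage biomarker, and the
statistical framework for testing how well that biomarker predicts which
eyes will be treatment-refractory.  It is aimed at retina researchers who
want a reproducible, scriptable version of this measurement, complete with
a synthetic-data module so every stage can be validated without patient
images.

## The measurement

For each eye with frames $I_{1\mathrm{min}}, I_{5\mathrm{min}}$ and a
manually picked foveal centre:

1. register $I_{5\mathrm{min}}$ onto $I_{1\mathrm{min}}$ (SIFT keypoints +
   RANSAC similarity transform);
2. subtract the background with a rolling ball of radius 50 px;
3. crop 384×384 px at the fovea;
4. binarize each frame at its iterative-intermeans ("Default") threshold
   $t^\* = \mathrm{round}\big(\tfrac{\mu_{\le t} + \mu_{>t}}{2}\big)$;
5. form the leakage map $L = \max(B_{5} - B_{1}, 0)$ — pixels
   hyperfluorescent at 5 min but not at 1 min;
6. score $\mathrm{MGV} = \overline{L}$ over nested fovea-centred windows:
   parafoveal 120×120 px and perifoveal 240×240 px.  On a binary map,
   $\mathrm{MGV} = 255 \cdot (\text{leak-pixel fraction})$.

Scores from two graders are averaged; agreement is measured with ICC(2,1).
Eyes needing < 5 injections in year one are *responsive*, eyes needing ≥ 5
(or with persistent edema after 3 monthly injections) *refractory*.
Predictors are compared by Mann–Whitney AUC with DeLong inference, and a
backward-stepwise logistic model selects among the baseline predictors.

## Worked example

```bash
python examples/quantify_leakage.py
```

```
responsive-style eye:
  estimated motion: rot +0.00 deg, shift (+3.0, +2.1) px (true: +0.00 deg, (+3.0, +2.0) px)
  thresholds 1min/5min: 15/20
  parafoveal MGV 19.2   perifoveal MGV 6.0
refractory-style eye:
  estimated motion: rot -0.01 deg, shift (+3.1, +1.9) px (true: +0.00 deg, (+3.0, +2.0) px)
  thresholds 1min/5min: 15/53
  parafoveal MGV 38.2   perifoveal MGV 17.2
```

The generator applied a known (3, 2) px inter-frame shift; the aligner
recovers it to ~0.1 px.  The refractory-style scene — more and brighter
leakage blobs across the macula — scores roughly 2–3× higher in both
windows; higher MGV means a larger fraction of the macular window is newly
hyperfluorescent at 5 min.

Other examples, one per capability: `simulate_fa_pair.py` (ground-truth
scene generation), `cohort_analysis.py` (full 89-eye run with report
tables and stepwise selection), `roc_auc_replication.py` (group moments →
implied AUCs), `grader_agreement.py` (ICC calibration and recovery).

A thin CLI mirrors the stages: `faleak simulate`, `faleak quantify`,
`faleak analyze`, `faleak all` (see `faleak --help`).

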