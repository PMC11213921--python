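# locustal

Analysis toolkit for studying social plasticity in desert locusts
(*Schistocerca gregaria*): how crowding reshapes foraging decisions and the
olfactory circuits behind them. Crowded (gregarious) and isolated
(solitarious) locusts weigh food and social cues differently when choosing a
feeding patch, and their antennal-lobe projection neurons (PNs) encode
food/social odor mixtures differently. `locustal` implements the full
computational chain for both arms of such a study — behavioral cue-integration
modeling and calcium-imaging population analysis — together with synthetic
generators that produce inputs with known ground truth, so every stage can be
validated end to end without any recorded data.

## What it computes

**Bayesian patch choice.** An animal choosing among four patches integrates
four information classes (socio-visual, food-visual, socio-olfactory,
food-olfactory), each with a reliability parameter `C_i > 0`:

    P(x is good | C_i) = 1 / (1 + C_i^(-w))        w ∈ {0, 1}
    P_x ∝ Π_i P(x is good | C_i)

where `w` says whether class `i` is on offer at patch `x` under the current
sensory condition. Fitting `log10(C_i) ∈ [-1, 1]` to observed
quarter-occupancy fractions yields an information reliability score per class
(`+1` strong attraction, `0` uninformative, `-1` aversion), with bootstrap
intervals over animals (`locustal.choice_model`, `locustal.behavior`).

**Activity-granule imaging pipeline.** Raw per-stimulus calcium stacks are
median/Gaussian denoised, linearly detrended, rigidly aligned by phase
correlation, box-filtered in time and converted to ΔF/F₀ against the 5-frame
pre-stimulus baseline (`locustal.preproc`). The field of view is then
segmented without manual ROIs: Voronoi regions grown from the regional
extrema of the s.d.-projection, refined by reassigning boundary pixels to the
granule whose mean time course minimizes the root median squared error, and
each granule is called active per stimulus by Otsu's threshold on its
window-mean ΔF/F₀ (`locustal.segmentation`).

**Population analysis.** Response-magnitude matrices are normalized per
animal, projected onto principal components and clustered with k-means; the
cluster count is the elbow of the Variance Ratio Criterion curve
`VRC(k) = SSB·(N−k) / (SSW·(k−1))` (`locustal.responses`). The same machinery
clusters z-scored time courses into temporal response motifs; per-cell motif
triplets over (Lct, Laa, LaaLct) give motif-transition maps that feed a
leave-one-out diagonal-covariance discriminant classifier of the social
phenotype (`locustal.motifs`). Mixture interactions are scored with the Bliss
independence model, `score = 100·(f_observed − [f1/2 + f2/2 − (f1/2)(f2/2)])`
(`locustal.synergy`). Inference uses bootstrap randomization tests with
studentized statistics and a p-value floor of `1/B` (`locustal.stats`).

## Worked example

`examples/patch_choice_model.py` simulates a gregarious-like assay (30 agents
per sensory condition, true scores `[0.3, 0.4, 1.0, 0.6]`) and refits them:

```
Vis+Olf+  mean occupancy: [0.215 0.219 0.484 0.081] for ('Lvs', 'Lct', 'LvsLct', 'Ctr')
Vis-Olf+  mean occupancy: [0.211 0.256 0.399 0.134] for ('Lvs', 'Lct', 'LvsLct', 'Ctr')
Vis+Olf-  mean occupancy: [0.248 0.246 0.337 0.169] for ('Lvs', 'Lct', 'LvsLct', 'Ctr')
fitted socio-visual    score +0.31  95% CI [+0.20, +0.45]
fitted food-visual     score +0.39  95% CI [+0.20, +0.59]
fitted socio-olfactory score +0.90  95% CI [+0.59, +1.00]
fitted food-olfactory  score +0.60  95% CI [+0.34, +0.92]
```

The leaves+locusts patch dominates occupancy exactly when both modalities are
available, and the fitted scores recover the planted reliabilities — the
socio-olfactory cue is correctly identified as the strongest driver. The
other scripts in `examples/` (one per capability) cover granule segmentation
(`imaging_granules.py`, which recovers 20/20 planted cells as active
granules), motif clustering / Bliss synergy / phenotype classification
(`motifs_and_synergy.py`) and the randomization statistics
(`randomization_stats.py`). An end-to-end run over both arms is available as
`locustal simulate --seed 0 --out report/` or via
`locustal.pipeline.run_pipeline`.

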