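# shapesignal

Single-cell morphometry and transcription-factor localization analysis for
high-content screens of NF-κB (p65/RelA) nuclear translocation in breast
epithelial and tumor cell lines — and for anyone who wants to ask, with
synthetic data of known ground truth, whether a cell's shape and
microenvironment predict how strongly it activates a transcription factor.

NF-κB activation is read out per cell as the **NF-κB ratio**

    tf_ratio = mean TF intensity over the nucleus
             / mean TF intensity over the perinuclear ring

and the analysis connects it to a 77-feature morphological profile
(geometry, protrusions, polarity, cell-context, intensity), including the
neighbor fraction NF ∈ [0, 1] (fraction of a cell's boundary in contact
with other cells), ruffliness (CV of membrane-band staining) and
A_nuc/A_cyto (nuclear over cytoplasmic area).

The pipeline has five computational stages, each a module under
`src/shapesignal/` with a numbered driver under `analysis/`:

1. **synthetic** — renders two-channel scenes (colonies of radially
   perturbed elliptical cells with nuclei) with true label masks; draws
   single-cell tables from planted linear-Gaussian structural-equation
   models over multi-modal morphological states; synthesizes damped
   oscillatory ratio traces (first peak ≈ 30 min, period 110–120 min,
   5-min sampling); emits fold-change panels with known coefficients.
2. **features** — nucleus/cell segmentation (Otsu + distance-transform
   watershed), membrane-band and perinuclear-ring regions, and the
   77-feature catalog per cell.
3. **profiling** — well averages, Z-scoring ((value − mean)/SD), PCA
   (first 8 PCs), hierarchical clustering of lines (centered correlation,
   centroid linkage), and the high-vs-low-ratio voting that selects the
   discriminative 17-feature subset.
4. **dependency networks** — per line × condition, quantile-discretized
   features + TF log-ratio; greedy hill-climbing DAG search under the BDeu
   score; bootstrap edge confidence (fraction of resamples recovering an
   adjacency), orientation only when ≥ 70% of supporting resamples agree.
5. **regression & dynamics** — the three-predictor fold-change model
   `Δtf_ratio = c0 + c_NF·ΔNF + c_ruffliness·Δruffliness + c_ratio·ΔA_nuc/A_cyto`
   with tenfold cross-validation and 95%-prediction-interval outliers, and
   Morlet continuous-wavelet analysis of translocation oscillations
   (instantaneous dominant period per time point, cone-of-influence aware).

## Worked example

```python
import numpy as np
from shapesignal import synthetic as syn, dynamics as dyn

trace = syn.simulate_trace(syn.OscillationParams(
    baseline=1.0, amplitude=0.5, period=115.0, first_peak_time=30.0,
    damping_timescale=100.0, noise_sd=0.0, dt=5.0, duration=360.0))
peak = dyn.first_peak_metrics(trace)
spec = dyn.wavelet_periods(trace)
print(f"first peak: {peak.amplitude:.2f} at {peak.time:.0f} min")
print(f"modal oscillation period: {spec.modal_period():.1f} min")
```

prints

```
first peak: 0.50 at 30 min
modal oscillation period: 118.6 min
```

i.e. the first nuclear-entry peak is recovered at its planted time and
height, and the wavelet stage places the oscillation period inside the
110–120 min band characteristic of NF-κB shuttling.

Running the drivers in order reproduces the full synthetic screen:

```sh
python analysis/01_simulate_screen.py      # scenes + planted cell tables
python analysis/02_extract_features.py     # segmentation vs ground truth
python analysis/03_profile_lines.py        # PCA, clustering, feature votes
python analysis/04_dependency_networks.py  # per-line Bayesian networks
python analysis/05_shape_regression.py     # 176-condition fold-change fit
python analysis/06_translocation_dynamics.py
```

e.g. stage 05 prints (seed 20):

```
fold-change model on 176 conditions:
  d_tfratio = 1.256 -0.325*dNF +0.402*druffliness -0.351*dAnuc/Acyto
  R^2 = 0.376, error variance = 0.0446, P = 1.51e-17
  tenfold CV error (MAE) = 0.1676 (+/- 0.0229)
  8 conditions outside the 95% prediction interval
```

recovering the planted signs (NF and A_nuc/A_cyto negative, ruffliness
positive) and the calibrated population R² of 0.37.

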