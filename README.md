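# myotubekit

A quantification toolkit for in-vitro myotube maturation assays — the
kind of experiment where human primary myoblasts are differentiated on a
flat versus a nanopatterned (striated) substrate and maturation is read
out from nuclei organisation, excitation–contraction (EC) coupling,
acetylcholine-receptor (AChR) clustering, sarcomere striations and qPCR
expression profiles. It is aimed at muscle cell biologists and image
analysts who have segmentation masks, fluorescence recordings and Ct
tables in hand and want the downstream quantification to be explicit,
scripted and testable rather than buried in one-off analysis scripts.

## What it computes

**Nuclei-arrangement morphometry** (`myotubekit.nuclei`), on calibrated
label masks (e.g. exported from Cellpose):

* area filter: nuclei kept if 40 μm² ≤ A ≤ 200 μm²;
* clustering: nuclei belong to the same cluster when their
  border-to-border distance is < 3 μm (single linkage, so a cluster may
  span more than 3 μm end to end); singletons are *isolated* nuclei;
* shape of isolated nuclei from central second moments: eccentricity
  e = √(1 − λ₋/λ₊) (0 = round, → 1 = elongated) and major-axis
  orientation θ ∈ [−90°, 90°) versus the image x axis;
* fusion index = (# nuclei whose centroid lies inside a myotube) /
  (# nuclei), and marker-positive fractions (MEF2C, Pax7, MyoD, …);
* per-field summaries (median cluster size, median eccentricity of
  isolated nuclei, orientation histogram) — one field = one
  statistical observation.

**Ca²⁺ transients under electric-field burst stimulation**
(`myotubekit.calcium`), for recordings sampled at ~3.3 Hz during
repeated bursts (1 s at 10 Hz every 10 s, 3 min): F/F₀ normalization to
a pre-stimulus baseline, one peak amplitude ΔF/F₀ per burst,
responder classification (first amplitude > 0.5), decay time of the
first transient (1/e crossing; monoexponential τ fit optional) and
% remaining Ca²⁺ = 100 × (last amplitude)/(first amplitude).

**AChR clusters and sarcomere spacing** (`myotubekit.image_quant`):
clusters retained when area > 5 μm², counted per field and per myotube
(centroid membership); z-line spacing from striation line profiles via
the dominant positive-lag autocorrelation peak with parabolic
sub-sample refinement (mean inter-peak distance as a cross-check).

**geNorm qPCR fold changes** (`myotubekit.qpcr`): relative quantities
Q = E^(Ct_cal − Ct), per-sample normalization factor = geometric mean of
two housekeeping genes (e.g. *B2M*, *EEF1A1*), fold changes relative to
a reference condition (adult muscle), mean ± SEM per condition.

**Statistics** (`myotubekit.stats`): Wilcoxon rank-sum on per-field
medians (midranks, tie-corrected variance, no continuity correction,
p = 2·(1 − Φ(|z|))), two-sample Student t test, mean ± SEM, and the
star notation \*p<0.05, \*\*p<0.01, \*\*\*p<0.001, \*\*\*\*p<0.00001.

**Synthetic data** (`myotubekit.synthetic`): because the quantities
above are usually locked to unpublished raw images and recordings,
every stage has a ground-truth-annotated generator (nuclei fields,
burst-locked traces, AChR blob fields, striation profiles, Ct tables)
so the whole pipeline is verifiable end to end.

## Worked example

```python
import numpy as np
from myotubekit import synthetic as syn, nuclei as nuc, calcium as ca, stats as st

# nuclei morphometry on one synthetic "nanopattern-like" field
params = syn.NucleiFieldParams(n_nuclei=40, mean_eccentricity=0.85,
                               eccentricity_sd=0.05,
                               orientation_concentration=20.0, seed=1)
mask, truth = syn.generate_nuclei_field(params)
records = nuc.filter_nuclei_by_area(mask)           # 40–200 um^2
records = nuc.cluster_nuclei(records, mask)         # < 3 um border-to-border
summary = nuc.summarize_field(records)
print(f"retained nuclei:        {summary.n_nuclei_retained}")
print(f"median cluster size:    {summary.median_cluster_size}")
print(f"median eccentricity:    {summary.median_eccentricity:.3f}")

# one burst-stimulation recording
trace_raw = syn.generate_trace(syn.TraceParams(first_amplitude=1.2,
                                               rundown_fraction=0.8, seed=1))
protocol = ca.StimulationProtocol()
trace = ca.normalize_trace(trace_raw.time, trace_raw.F, protocol)
m = ca.analyze_trace(trace, protocol)
print(f"first amplitude:        {m.first_amplitude:.2f}  (responder: {m.is_responder})")
print(f"decay time:             {m.decay_time:.2f} s")
print(f"remaining Ca2+:         {m.remaining_pct:.1f} %")

# the published z -> p mapping
print(f"p at z = 4.023:         {st.normal_two_sided_p(4.023):.3g}")
```

prints

```
retained nuclei:        40
median cluster size:    2.0
median eccentricity:    0.833
first amplitude:        1.20  (responder: True)
decay time:             2.01 s
remaining Ca2+:         80.5 %
p at z = 4.023:         5.75e-05
```

All 40 generated nuclei fall inside the 40–200 μm² gate; the median
cluster holds 2 nuclei and the isolated nuclei are strongly elongated
(eccentricity ≈ 0.83), as expected for an aligned, nanopattern-like
field. The recording is a responder (ΔF/F₀ = 1.2 > 0.5) whose first
transient decays with ≈ 2 s time constant, and the last burst retains
~80% of the first burst's amplitude.

A thin CLI mirrors the stages, e.g.:

```sh
myotubekit simulate --kind nuclei --seed 3 --out fx
myotubekit nuclei fx_nuclei_mask.tif --pixel-size-um 0.32
```

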