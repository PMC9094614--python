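# sphsurv

Rotation-invariant survival-rate prediction from tumor shape.

`sphsurv` is a research toolkit for predicting patient risk from a segmented
3D tumor (CT image + binary mask, NIfTI) with right-censored outcomes.  It
implements the full pipeline:

1. **Spherical mapping** — the tumor is projected onto signals on the unit
   sphere: the *depth projection* (radial extent of the tumor along each
   direction from its center of mass), the *intensity projection* (windowed
   HU accumulated along each ray), and the *extended Gaussian image* (EGI,
   the area-weighted distribution of surface-normal directions).
2. **Spherical CNN log-risk** — the maps feed a small spherical-harmonic
   CNN: an S² correlation layer lifts the signal onto the rotation group
   SO(3), an SO(3) correlation layer follows, with spherical pooling in
   between, then a rotation-invariant readout, a 40-unit dense layer, and a
   linear scalar output h<sub>θ</sub>(x).
3. **Cox / DeepSurv training** — h<sub>θ</sub> is trained as the log-risk of a
   proportional-hazards model, λ(t|x) = λ₀(t)·exp(h_θ(x)), by minimizing the
   average negative log partial likelihood
   L = −(1/N_E) Σ_{i:E_i=1} [h_i − log Σ_{T_j ≥ T_i} e^{h_j}].
4. **Evaluation** — Harrell's concordance index (C-index) and Kaplan–Meier
   curves of the cohort stratified at the median predicted risk.

Because the convolutions are computed spectrally (spherical-harmonic and
Wigner-matrix domain) and the readout integrates over the rotation group,
the predicted risk does not depend on the tumor's orientation — the reason
to prefer spherical over Cartesian CNNs for shape-driven prognosis.

The package also ships a first-class **phantom generator**: star-shaped
solids r(ω) = r₀(1 + Σ a_lm Ȳ_lm(ω)) with textured interiors and survival
times drawn from a constant-baseline-hazard Cox model whose risk is a pure
function of shape (log tumor volume and an asphericity score).  Phantoms
have closed-form depth maps, giving every projection an analytic oracle, and
make the entire pipeline testable without any clinical data.

Two input configurations are supported: `sphcnn1` (depth channel only — uses
just the segmentation) and `sphcnn2` (EGI + intensity — uses the image
content as well).

## Worked example

```python
import numpy as np
from sphsurv import (PhantomCohortSpec, generate_cohort, SphericalGrid,
                     make_input, ExperimentConfig, train, evaluate_external,
                     concordance_index)

grid = SphericalGrid(16)                       # 32 x 32 spherical maps

def cohort(seed):
    spec = PhantomCohortSpec(n_subjects=120, beta_true=(1.5, 0.0), seed=seed)
    subjects, outcomes = generate_cohort(spec, with_images=False)
    maps = [make_input("sphcnn1", None, s.mask, grid) for s in subjects]
    return maps, outcomes

maps_tr, co_tr = cohort(7)                     # training cohort
maps_ex, co_ex = cohort(8)                     # independent held-out cohort

result = train(maps_tr, co_tr, ExperimentConfig(seed=7, epochs=60))
ev = evaluate_external(result.model, maps_ex, co_ex)
print("held-out C-index:", round(ev["c_index"], 3))
print("ceiling (true risk):", round(concordance_index(co_ex.true_log_risk, co_ex), 3))
```

Output (about two minutes of CPU training):

```
held-out C-index: 0.804
ceiling (true risk): 0.804
```

The cohort's hazard is driven purely by tumor volume (β = 1.5 per SD of log
volume).  The network, seeing only depth maps, ranks the held-out subjects
essentially as well as the true log-risk does — the 0.804 "ceiling" is the
C-index the generating model itself achieves under this censoring level, so
the learned shape feature has recovered the full available signal.  With
β = 0 the same experiment yields a held-out C-index near 0.5 (chance), as it
should.

## Command line

```bash
sphsurv phantom --n 50 --seed 7 --out data/            # synthetic cohort
sphsurv map --image a.nii.gz --mask a_mask.nii.gz \
            --bandwidth 32 --config sphcnn2 --out maps/a.h5
sphsurv train --maps maps/ --cohort data/cohort.csv --seed 7 --out model.h5
sphsurv cv --maps maps/ --cohort data/cohort.csv --out-dir cv/
sphsurv predict --model model.h5 --maps maps/ --cohort data/cohort.csv --out scores.csv
sphsurv evaluate --model model.h5 --maps maps/ --cohort data/cohort.csv --out-dir eval/
```

All commands take a seed and are bit-stable across reruns.

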