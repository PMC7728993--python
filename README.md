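# wcdcm

Dynamic causal modeling (DCM) for fMRI with **Wilson–Cowan** neuronal
state equations.

DCM infers *effective connectivity* — the directed causal influences a
set of brain regions exert on one another — from region-averaged BOLD
time series and a record of the experimental inputs. Classically the
latent neuronal activity `z` of the `l` regions follows the bilinear
state equation

    ż = (A + Σⱼ uⱼ Bʲ) z + C u

where `A` (l×l, Hz) holds the fixed connections, each `Bʲ` the change in
connectivity induced by modulatory input `uⱼ`, and `C` the direct driving
influence of the inputs. This package additionally implements a
firing-rate variant in which the same synaptic drive is passed through a
zero-centred sigmoid and the state relaxes toward it:

    ż = −z + S(x),    S(x) = 1/(1 + e^(−αx)) − 1/2,
    x  = (A + Σⱼ uⱼ Bʲ) z + C u

so `A`, `B`, `C` become synaptic weights proper and the per-region slope
`α` is interpretable as the steepness of the population f–I curve. The
sigmoid's saturation makes the flow globally bounded: strong inputs
cannot destabilize the network, unlike the linear model. Both one-state
and two-state (coupled excitatory/inhibitory sub-populations per region)
forms are provided. Neuronal activity drives BOLD through the standard
balloon/windkessel hemodynamic cascade (vasodilatory signal, inflow,
venous volume, deoxyhemoglobin) per region.

The package is aimed at researchers who already have extracted region
time series (e.g. first eigenvariates of their ROIs) and want to:

- simulate BOLD from any of the four neuronal variants at controlled SNR;
- invert models by **variational Bayes under the Laplace assumption**
  (iterated Gauss–Newton ascent with Levenberg–Marquardt damping,
  shrinkage priors, per-region noise log-precisions), obtaining posterior
  densities, the free energy `F` (accuracy − complexity), the predicted
  response, explained variance and a flat-line diagnosis;
- enumerate model spaces (all `3^(l(l−1))·2^l` models, or the
  input-constrained reachable subset) and partition them into families;
- compare models at the group level: fixed-effects group Bayes factors,
  random-effects Dirichlet inference with expected, exceedance and
  **protected exceedance** probabilities (Bayesian omnibus risk),
  family-level inference, and Bayesian model averaging;
- benchmark the two variants on synthetic ground-truth data: SNR sweeps
  of explained variance, flat-line counts, and connection-detection
  ROC/AUC.

## Worked example

Simulate the three-region validation network (driving input into region
1; connections 1→2, 1→3, 3→2; a contextual input modulating 1→3 and
3→2), add noise at SNR 1, and invert:

```python
import numpy as np
from wcdcm import DCM, make_ground_truth_network, \
    default_input_timeline, simulate_dataset

spec, truth, hemo = make_ground_truth_network(variant="wilson_cowan")
inputs = default_input_timeline(duration=360.0, dt=0.25)
ds = simulate_dataset(spec, truth, hemo, inputs, snr=1.0, n_real=1, seed=42)

model = DCM(ds.noisy[0], inputs, spec, hemo=hemo)
res = model.fit(max_iter=48)
print(res.summary())
```

```
Dynamic Causal Model — VBL inversion
================================================================
variant: wilson_cowan           states: one
regions: R1, R2, R3
samples: 181    TR: 2.0 s
free energy F:            1152.128 nats
explained variance:          47.22 %
iterations: 8  converged: True  flatline: False
----------------------------------------------------------------
parameter                         mean        sd   P(sign)
A[R1<-R1]                       -0.498     0.062     1.000
A[R2<-R1]                        0.366     0.144     0.995
A[R2<-R2]                       -0.492     0.062     1.000
A[R2<-R3]                        0.133     0.239     0.711
A[R3<-R1]                        0.319     0.134     0.991
A[R3<-R3]                       -0.494     0.062     1.000
B2[R2<-R3]                       0.103     0.222     0.679
B2[R3<-R1]                       0.206     0.146     0.921
C[R1<-u1]                        0.509     0.145     1.000
log_alpha[R1]                    1.385     0.248     1.000
...
noise sd [R1]: 0.0409 (log-precision 6.39)
```

The generating values were 0.4 on the three connections, 0.2 on the two
modulations, 0.5 on the driving input and −0.5 on the self-connections:
the posterior means recover them to well within their posterior standard
deviations, `P(sign)` gives the posterior probability that each coupling
has a determinate sign (the edge-detection score), and at SNR 1 the
noise carries half the observed variance, so ~47 % explained variance is
near the attainable ceiling. `A[R2<-R3]` and its modulation, the weakest
and most downstream effects, are — correctly — the least certain.

Everything is also available from the shell:

```sh
wcdcm simulate --variant bilinear --snr 0.1 --reps 10 --seed 1 --out data/
wcdcm invert   --data data/noisy_00.tsv --inputs data/inputs.tsv \
               --model data/model.json --out fit/
wcdcm enumerate --regions 3 --input-region 0 --out space.tsv
wcdcm compare  --evidence F.tsv --method rfx --seed 1
wcdcm sweep    --snr 0.02,0.05,0.1,0.5 --reps 5 --seed 1 --out sweep/
```

Each run writes a `manifest.json`; `wcdcm rerun <manifest>` reproduces
the outputs bit-identically.

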