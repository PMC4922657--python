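# poprf — population receptive-field estimation with a hierarchical structural model

`poprf` estimates the receptive fields (RFs) of a *local population* of V1
neurons simultaneously, under the anatomical assumption that nearby cortical
neurons share input from a small pool of thalamic (LGN-like) afferents.  It is
aimed at visual neuroscientists working with calcium-imaging recordings of
responses to natural images: tens-to-hundreds of neurons, a few thousand
single-trial stimulus presentations, and a small multi-trial validation set.

## The model

The hierarchical structural model (HSM) is a three-layer feed-forward network:

1. **LGN layer** — `s1` linear difference-of-Gaussians (DoG) kernels.  Unit
   *i* responds to image *I* with

   ψ<sub>i</sub> = Σ<sub>k,l</sub> I<sub>kl</sub> [ (α<sub>i</sub>/σ<sub>i</sub>²) e<sup>−((k−μ<sub>ix</sub>)²+(l−μ<sub>iy</sub>)²)/2σ<sub>i</sub>²</sup> − (β<sub>i</sub>/ρ<sub>i</sub>²) e<sup>−((k−μ<sub>ix</sub>)²+(l−μ<sub>iy</sub>)²)/2ρ<sub>i</sub>²</sup> ]

2. **Hidden ("simple cell") layer** — `s2` units, each a weighted sum of LGN
   outputs through the softplus transfer `f(x) = log(1 + exp(x − t))`.
3. **Output layer** — one unit per recorded neuron, a weighted sum of hidden
   activities through the same transfer; its output is the predicted firing
   rate.

The free parameters (6 per LGN unit, a threshold per cortical unit, and the
two weight matrices — `6·s1 + s2 + s3 + s1·s2 + s2·s3` in total) are fitted
jointly to all neurons by maximizing the Poisson log-likelihood
`Σ y·log M − M` with bound-constrained truncated-Newton optimization and an
analytic gradient.  The problem is non-convex, so fitting restarts from many
random initializations and keeps the restart with the best training-set
performance.  Defaults are `s1 = 9` LGN units and a hidden layer of 20% of
the neuron count, where performance saturates.

The package also provides:

* a **regularized linear-nonlinear baseline (rLN)** — a pixel-space kernel
  `k̂ = pinv(SᵀS + αL)Sᵀr` with a squared-Laplacian smoothness penalty `L`,
  `α` selected on a 10% holdout, plus a 20-bin histogram point nonlinearity;
* **evaluation statistics** — per-neuron prediction correlation with
  bootstrap significance, signal/noise power decomposition, noise-corrected
  fraction of explained variance (FEV, neurons above 70% normalized noise
  power excluded), and the non-linearity index
  `NLI = (LC − max(LLC, 0))/LC` comparing each neuron's HSM correlation (LC)
  with that of the model's rLN linearization (LLC);
* a **synthetic-data generator** producing ground-truth populations,
  1/f-spectrum stimuli, and Poisson trial data in exactly the layout of the
  experimental containers, so the whole pipeline is testable offline.

## Worked example

Simulate a small shared-input population, fit the HSM and the rLN baseline,
and compare them on the validation trials:

```sh
poprf simulate --s3 6 --s1 3 --p 12 --n-train 300 --n-val 50 --n-trials 8 \
      --seed 7 --out region.h5
poprf fit region.h5 --s1 3 --gamma 0.4 --restarts 6 --seed 0 --out hsm.h5
poprf fit-rln region.h5 --seed 0 --out rln.h5
poprf evaluate hsm.h5 region.h5 --n-boot 200 --seed 0 --out-prefix hsm_eval
poprf compare region.h5 hsm.h5 rln.h5 --out compare.csv
```

The `evaluate` step prints the population summary for the HSM:

```json
{
  "mean_correlation": 0.9738442175132732,
  "mean_fev_included": 0.9792781890119885,
  "mean_nli": 0.07095442901443459,
  "median_correlation": 0.9827207181798026,
  "n_fev_included": 6,
  "n_neurons": 6,
  "n_significant": 6
}
```

`mean_correlation` is the mean per-neuron Pearson r between predictions and
trial-averaged validation responses; `mean_fev_included` the mean fraction of
explained (signal) variance over the neurons passing the noise-power
exclusion; `mean_nli` says that ~7% of the captured correlation is due to
nonlinear model components (the generator here is mildly nonlinear); all six
neurons have bootstrap-significant predictions.  `compare` then ranks the
archives on the same validation set:

```
        n_neurons  mean_correlation  median_correlation  mean_fev_included  n_fev_included
model
hsm.h5          6          0.973844            0.982721           0.979278               6
rln.h5          6          0.830359            0.873478           0.708042               6
```

The population HSM clearly outperforms the linear-nonlinear baseline — the
same ordering observed on cortical recordings.  `poprf fit --per-neuron`
fits each neuron independently (the ablation that removes the shared-input
constraint) and `poprf sweep` scans `s1` or `gamma` and tabulates training
and validation performance.

All commands are deterministic: rerunning with the same flags and seeds
reproduces output files bit for bit.

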