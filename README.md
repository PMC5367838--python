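# cascade-robustness

Tools for analysing **dynamics robustness** in linear signaling cascades:
how insensitive the *entire relaxation time course* of a phosphorylation
cascade — and in particular its half-life — is to perturbations of kinase
and phosphatase activities.

Signaling cascades (MAPK pathways being the canonical example) encode
information in the *shape and duration* of their responses, not just in
steady-state levels: transient versus sustained activation of the same
pathway can trigger different cell fates. This package asks when the
post-stimulus relaxation profile of such a cascade is robust, simulating
the stimulus-on / stimulus-removed protocol on three model classes and
quantifying robustness with log-log sensitivities.

## Models

**Nonlinear cascade (Heinrich-type).** Each layer `i` is a covalent
modification cycle; the phosphorylated substrate of layer `i-1` is the
kinase of layer `i`. With substrate conservation `M_i + M_i^p = M_i^tot`,
the post-stimulus kinetics are

```
dM_0^p/dt = -β₀ M_0^p
dM_i^p/dt = ᾱ_i M_{i-1}^p (M_i^tot - M_i^p) - β_i M_i^p     (i ≥ 1)
```

started from the stimulated steady state, which obeys the forward
recursion for the phosphorylated fractions `g_i = M̃_i / M_i^tot`:

```
g₀ = 1/(1 + β₀/α₀),     g_i = 1/(1 + (β_i/α_i)/g_{i-1})
```

with effective kinase activities `α₀ = ᾱ₀·E₀` and `α_i = ᾱ_i·M_{i-1}^tot`.

**Linearized cascade.** Linearizing the normalized system about the origin
gives an exponential chain whose output is the closed form
`m₂^p(t) = c₀e^{-β₀t} + c₁e^{-β₁t} + c₂e^{-β₂t}` with `Σcᵢ = 1`
(confluent `t·e^{-βt}` terms when rates tie). The slow mode `k = argmin β`
yields the duration approximation `ϑ ≈ log(2c_k)/β_k` and the gain formula
`∂log ϑ/∂log β_i = (log 2 + log c_k)⁻¹ · ∂log c_k/∂log β_i`.

**Huang–Ferrell mass-action model.** A full three-layer MAPK description
with explicit phosphatases, enzyme–substrate complexes, and double
phosphorylation in the two downstream layers (10 enzymatic steps,
22 species).

## Robustness measures

* **half-life ϑ** — first time the output falls to half its pre-stimulus
  steady value;
* **logarithmic gain** — `∂log(y)/∂log(x)`, the local log-log slope, by
  central differences (step 0.05 decades); `|gain| < 0.3` counts as
  duration-robust, against the magnitude 1 of a bare exponential;
* **consecutive-profile similarity** — the L² distance between output
  profiles at neighbouring sweep points on the `τ = log₁₀ t` axis, scaled
  by the parameter step;
* **duration-robustness conditions** for module `i`: (1) `β_i` is not the
  minimal rate, (2) `(β_N/α_N)(1+β_{N-1}/α_{N-1})⋯(1+β₀/α₀) < 1`,
  (3) some downstream layer has `β_k ≪ α_k`.

## Worked example

```python
import numpy as np
import cascade_robustness as cr

params = cr.heinrich_base(cr.GeneratorSpec(seed=0))   # fast-slow-fast base
result = cr.relax("heinrich", params)
print(f"g2 = {result.g_output:.4f}  theta = {result.duration:.1f}")

spec = cr.SweepSpec(model="heinrich", target="beta.0", base=params)
res = cr.run_sweep(spec)                               # 39-point log sweep
for iv in res.robust_intervals:
    print(f"robust interval for beta_0: [{iv.lower:.3g}, {iv.upper:.3g}]")
print(f"rate-limiting crossover: {res.crossover:.3g}")
```

prints

```
g2 = 0.9880  theta = 445.2
robust interval for beta_0: [0.0251, 1e+04]
rate-limiting crossover: 0.00631
```

The cascade is strongly activated (`g₂ = 0.99`), relaxes with half-life
`ϑ ≈ 445` (set by the slow middle phosphatase, `β₁ = 0.01`), and the
first-layer phosphatase rate can move across almost six decades —
from `0.025` up past `10⁴` — without the duration changing appreciably
(`|gain| < 0.3`). Below the crossover at `β₀ ≈ 0.006` the first module
itself becomes rate limiting and the gain falls to −1. The same sweep for
the slow middle module finds no robust interval at all: the rate-limiting
layer is the sensitive one.

The same protocols run from the shell:

```
cascade-robustness gen --model heinrich --seed 0 --out params.yaml
cascade-robustness sweep --model heinrich --param beta.0 --config params.yaml --out results/
cascade-robustness conditions --config params.yaml --module 0
cascade-robustness demo-fig2            # all three phosphatase sweeps
```

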