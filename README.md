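# larvataxis

Statistical modelling of *Drosophila* larval phototaxis as a biased
Markov chain, with tools to simulate trajectory ensembles, compute the
navigation metrics used in behavioural tracking studies, and calibrate
the model's free parameters against measured navigation indices.

## The model

Third-instar larvae on an agarose plate flee light. Their paths are
stochastic, yet clearly drift away from bright regions and away from the
light source itself — two distinct cues (local intensity gradient vs.
source bearing) that experiments can decouple with projected light
patterns. The package models a larva as a discrete-time Markov chain in
the plate plane: step proposals are isotropic Gaussian displacements
(σ ≈ 0.1 mm), and a proposed step **r** → **r**′ is accepted with the
generalized Metropolis–Hastings probability

```
P = 1               if W(r → r′) ≤ 0
P = exp(−W / T)     if W(r → r′) > 0
```

with step weight

```
W(r → r′) = ΔI(r → r′) + β ⟨I⟩ f(α(r → r′)),      f(α) = 1 − (α/180)⁴
```

where ΔI = I(**r**′) − I(**r**) is the irradiance change over the step,
⟨I⟩ the plate-average irradiance, α ∈ [0°, 180°] the heading relative to
the source bearing (0° toward the source), β the directionality weight,
and T an effective temperature in irradiance units that sets how often
weight-increasing ("risky") moves are taken. Moves toward darker ground
or away from the source are always accepted. Larvae start at the origin
and are absorbed at a radius of 1150 σ ≈ 11.5 cm (the plate edge).

Ensembles are summarised by the navigation index, NI_x = Δx / s (net
displacement over path length): 0 for a random walk, −1 for ballistic
escape along −x, and by heading distributions P(α) in 30° bins. The
three free parameters (T, β, and the angular exponent n) are fitted from
measured indices: T by stochastic bisection against a single index, β
via a "tilted" pattern whose gradient is perpendicular to the source
bearing (so each term of W dominates one axis), and n by ranking
candidate angular models on the RMS deviation between simulated and
reference heading distributions.

## Worked example

Calibrate (β, T) on the tilted pattern against measured indices
(NI_x, NI_y) = (−0.25, −0.07), then validate on a fresh ensemble
(`examples/04_calibrate_tilted.py`):

```
$ python examples/04_calibrate_tilted.py
calibrated beta = 0.0086, T = 6.91 W/m^2
achieved ni_x = -0.240, ni_y = -0.069 (converged: True, 20 ensemble evaluations)
fresh ensemble: ni_x = -0.242, ni_y = -0.069 -- both should sit within ~0.01 of the targets
```

The calibrated β balances the two cues: the directionality term is
roughly three times stronger than the gradient term on this pattern,
which is why the x-index (−0.25) dwarfs the y-index (−0.07) even though
the artificial gradient lies along y. The other example scripts cover
field construction and spectral band integration (`01`), ensemble
simulation and track export (`02`), trajectory metrics and comparison
statistics (`03`), and angular-model selection (`05`), each printing a
few annotated numbers in under a minute.

A thin CLI wraps the same calls:

```
larvataxis simulate --field pos_like -T 10.95 --beta 0.014 --seed 7 \
    --out tracks.csv --summary summary.json
larvataxis metrics --tracks tracks.csv --axis x
larvataxis calibrate --field tilted_like --target-ni-x -0.25 --target-ni-y -0.07 --seed 1
```

Field presets (`uniform`, `pos_like`, `neg_like`, `tilted_like`,
`d90_like`) mirror the experimental pattern geometry; their YAML forms
live in `examples/fields/`.

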