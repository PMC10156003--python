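# abmcal

Calibrating spatial agent-based tumor models to images with learned
low-dimensional representations.

## The problem

Agent-based models (ABMs) of tumors produce rich spatial patterns, but
their phenomenological parameters (killing probabilities, infiltration
depths, death rates, …) are hard to estimate: fitting to scalar time
courses discards the spatial structure that motivates an ABM in the
first place, while comparing a simulation to a tumor image pixel by
pixel is ill-posed — the two live at different scales, resolutions and
formats.  `abmcal` is for modelers who have a segmented tumor image (a
cell table from, e.g., ImageJ *Analyze Particles*) and an ABM, and want
a quantitative objective function connecting the two.

## The method

1. **Common format.** Both ABM snapshots and image-derived cell tables
   are reduced to *simplified images*: cell coordinates are binned onto
   a grid whose pitch is one cell diameter (one channel per cell class
   or per continuous property such as PD-L1), cropped to the tumor
   bounding box, area-resampled to a fixed size (default 32×32), and
   rescaled per channel to [0, 1].  Cropping plus anisotropic resizing
   makes the comparison translation- and scale-free, so a small
   simulated tumor can be compared with a much larger imaged one.
2. **Learned metric.** An ensemble of small convolutional networks is
   trained on Monte-Carlo simulations with the SimCLR objective: two
   random dihedral augmentations of the same image are pulled together
   in a 2-D projection via the NT-Xent loss
   ℓᵢ = −log [exp(sᵢ,ₚ₍ᵢ₎/τ) / Σ_{k≠i} exp(sᵢ,ₖ/τ)], s = cosine
   similarity, τ = 0.5.  The distance between two inputs is the
   ensemble mean of ‖z(a) − z(b)‖₂ in the projected plane.
3. **Calibration.** Parameters are sampled over their widest plausible
   ranges; the n training simulations nearest the target image in
   embedding space set narrowed search bounds; a genetic algorithm
   (tournament selection, blend crossover, Gaussian mutation, elitism)
   then minimizes the embedding distance between the target and
   single-replicate candidate simulations.

Two center-based ABM variants are included: a PD-L1
suppression model (tumor cells suppress infiltrating T cells) and a
hypoxic-core model (persistent dead cells in a central hypoxic disc),
plus synthetic generators for every input the tests and examples use.
See `docs/methods.md` for model equations, update order, defaults and
limitations.

## Worked example

A self-fit: generate a base simulation at known parameters, then ask
the pipeline to recover the T-cell killing probability from the image
alone (`examples/05_self_fit.py`, a few minutes on one CPU):

```
$ python examples/05_self_fit.py
nominal killing probability:   0.02
recovered killing probability: 0.01986
relative error: 0.7%
narrowed bounds: [0.0130, 0.0328]
best objective per generation: [0.413, 0.265, 0.265, 0.255, 0.255, 0.255, 0.255, 0.255, 0.255]
plateau generation: 1
top-10 summary:
      kill_prob
best    0.01986
max     0.02282
min     0.01837
mean    0.01978
cv      0.06990
```

Reading the output: bound narrowing shrank the search from
[0.001, 0.1] to [0.013, 0.033] before any optimization; the GA's best
objective levels off after a single generation; and the ten best
evaluations cluster around the true value 0.02 with a 7% coefficient
of variation — the spread that indicates an identifiable fit rather
than a lucky draw.  Because each candidate is evaluated with a single
stochastic replicate, individual runs scatter around the truth by
~20–30%; medians over master seeds are tighter.

The other examples each exercise one capability: the simulator
(`01`), image processing (`02`), the learned metric on two visually
distinct families (`03`), bound narrowing (`04`) and the image-scale
ring-tumor fixture with its dead-cell core (`06`).

A thin CLI mirrors the library for shell use:
`abmcal simulate | process | train | distance | fixtures | fit`
(see `abmcal --help`).

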