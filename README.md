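# topomorph

Morphological filtrations, cubical persistent homology, and unsupervised
topological denoising for 2-D binary, grayscale, and RGB images.

## The problem

Mathematical morphology processes images with windowed min/max operators —
erosion ε_B, dilation δ_B, opening O_B = δ_B∘ε_B, closing C_B = ε_B∘δ_B —
driven by a *structuring element* B (a finite offset set containing the
origin).  Opening removes white features smaller than B; closing removes
black features smaller than B.  Choosing *which* B, and *how many*
alternating operations to apply, is traditionally done by eye.

This package automates that choice through persistent homology.  For a
nested sequence of square structuring elements B_0 ⊆ B_1 ⊆ … ⊆ B_n (B_i an
(i+1)×(i+1) square), the black sets

- O_{B_0}(f)⁻¹(0) ⊆ O_{B_1}(f)⁻¹(0) ⊆ … (opening filtration), and
- C_{B_n}(f)⁻¹(0) ⊆ … ⊆ C_{B_0}(f)⁻¹(0) (closing filtration, stored reversed)

are filtrations of cubical complexes, and alternating compositions of the
two operator families index a genuine *multi-parameter* filtration:
X_u ⊆ X_v whenever the alternating multi-indices satisfy u ≤ v
componentwise.  Adding a global-threshold axis τ_t extends this to 8-bit
images.  Persistence diagrams computed along these filtrations grade every
connected component and hole by the spatial scale at which morphology
removes it: a hole born at level 0 of the opening filtration with death d
is erased exactly by the d-th opening; an essential component of the
(relabelled) closing filtration with birth b is erased exactly by closing
n + 1 − b.

The denoiser walks a nondecreasing path through this multifiltration,
letting the diagrams pick each step:

    i_c = (n + 1) − max{ b : (b, n+1) ∈ P0 of the closing filtration }
    i_o = min{ d ≤ n : (0, d) ∈ P1 of the opening filtration }

It alternates closing and opening (closing first), skips an operator with
nothing left to remove, and stops when a selected index exceeds a preset
`SizeTol`, when a full round makes no progress, or after `MaxIter`
selections.  Grayscale images are handled by denoising all 256 thresholded
binary images independently and summing; RGB channel-wise.

Intended users: image-analysis researchers who want scale-aware,
training-free cleanup of salt-and-pepper-type noise, and TDA practitioners
who want morphological multifiltrations as first-class objects.

## Worked example

```python
from topomorph import DenoiseParams, betti, denoise_binary, iou
from topomorph.synth import default_phantom_spec, make_phantom, salt_pepper

clean, truth = make_phantom(default_phantom_spec())   # (beta0, beta1) = (6, 5)
noisy = salt_pepper(clean, density=0.3, seed=1)
out, trace = denoise_binary(noisy, DenoiseParams(size_tol=5, max_iter=10))
print(betti(noisy), betti(out), trace.steps, iou(clean, out))
```

prints

```
(1345, 1470) (6, 5) [-1, 1, -2, 2, 3, 5] 0.977
```

At noise density 0.3 the contaminated image has 1345 components and 1470
holes; the denoiser applies closings with B_1, B_2 and openings with B_1,
B_2, B_3, B_5 — each index read off a persistence diagram — and recovers
the phantom's exact Betti pair (6, 5) with an intersection-over-union of
0.977 against the ground truth (up from 0.703 for the noisy image).  The
`examples/` directory walks through the operators, filtrations,
multiparameter levels, and the grayscale/RGB and large-square-noise
variants, each printing the numbers it computes.

A thin CLI mirrors the library: `topomorph denoise|filtration|persist|
score|synth --help`.

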