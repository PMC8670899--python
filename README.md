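# gtvdmri — spatioangular graph total-variation denoising of diffusion MRI

Diffusion MRI (DMRI) acquires, at every voxel **x**ᵢ, a signal for each
diffusion-sensitizing gradient direction **q̂**ⱼ and weighting bⱼ. The data are
heavily corrupted by thermal noise, and classical total-variation (TV)
denoisers smooth only across space — averaging over differently oriented
signals and blurring crossing white-matter structure. This package denoises in
the **joint spatioangular (x–q) domain** instead: every measurement (i, j) is
a node of a weighted graph, linked to its spatial *and* angular neighbors by
the affinity

    w((i,j),(i′,j′)) = exp(−‖xᵢ−xᵢ′‖² / 2σₓ²)
                     · exp(−(1−⟨q̂ⱼ,q̂ⱼ′⟩²) / 2σ_q²)
                     · exp(−(b̃ⱼ−b̃ⱼ′)² / 2σ_b²),

and the clean signal S is recovered from the noisy S′ by minimizing the graph
total-variation (GTV) objective

    min_S  ½‖S − S′‖₂² + λ‖∇_G S‖₁,    (∇_G S)ₑ = wₑ(S_a − S_b) per edge e,

solved exactly as posed (no smoothing of the ℓ1 term) with a forward–backward
primal–dual (Condat–Vũ) iteration. Volumes are processed as overlapping
5×5×5 spatial patches whose estimates are averaged, so memory stays bounded
and patches solve as one batched problem. The intended users are researchers
processing diffusion-weighted NIfTI volumes with FSL-style `.bval`/`.bvec`
gradient files.

The package provides:

- `gtvdmri.io` — NIfTI + bval/bvec reading/writing (`read_dwi`, `write_dwi`);
- `gtvdmri.graph` — spatioangular affinities, k-nearest angular neighborhoods,
  patch graphs and patch grids;
- `gtvdmri.solver` — graph gradient/divergence, GTV objective, soft
  thresholding, the primal–dual solver, and an exact-dual oracle for tiny
  graphs;
- `gtvdmri.pipeline` — end-to-end patch-wise denoising with noise estimation
  and optional Rician variance stabilization;
- `gtvdmri.phantom` — a crossing-fiber multi-tensor phantom generator with
  Gaussian/Rician noise;
- `gtvdmri.metrics` — PSNR, SSIM, RMSE maps, residual maps;
- CLI tools `gtv-denoise`, `gtv-phantom`, `gtv-metrics`.

## Worked example

```python
import numpy as np
from gtvdmri import (PhantomConfig, NoiseSpec, DenoiseConfig, make_gradient_table,
                     simulate_phantom, add_noise, denoise, psnr, ssim)

# 16^3 crossing-fiber phantom: 30 directions at b=1000 s/mm^2 + one b=0,
# 2 mm voxels, baseline signal s0 = 1000; Gaussian noise at 10% of s0.
gtab = make_gradient_table(30, b_value=1000.0, include_b0=True, seed=0)
clean = simulate_phantom(PhantomConfig(dims=(16, 16, 16)), gtab)
noisy = add_noise(clean, NoiseSpec(model="gaussian", sigma=100.0, seed=1))

denoised = denoise(noisy, DenoiseConfig())

print(f"PSNR: {psnr(clean.data, noisy.data):.2f} dB -> {psnr(clean.data, denoised.data):.2f} dB")
print(f"SSIM: {ssim(clean.data, noisy.data):.4f} -> {ssim(clean.data, denoised.data):.4f}")
```

Output:

```
PSNR: 20.01 dB -> 20.36 dB
SSIM: 0.5091 -> 0.5216
```

PSNR (peak signal-to-noise ratio, larger is better) and SSIM (structural
similarity, 1 = identical) are both measured against the noiseless phantom:
denoising with the default λ = 0.1 moves both strictly toward the clean data
while preserving the fiber-crossing structure. λ is scale-dependent (the
fidelity term is quadratic in the signal, the TV term linear); larger values
smooth harder — see `docs/methods.md`.

The same run from the shell:

```sh
gtv-phantom --dims 16 16 16 --noise-model gaussian --sigma 100 --seed 1 --out-prefix noisy
gtv-denoise --in noisy.nii.gz --bval noisy.bval --bvec noisy.bvec --out denoised
gtv-metrics --ref clean.nii.gz --test denoised.nii.gz --out-report report.json
```

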