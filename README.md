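# radrelax

Accelerated quantitative 3D radial MRI relaxometry: simulation of
magnetization-prepared center-out radial (near-zero echo time)
acquisitions of digital phantoms, compressed-sensing reconstruction of
the contrast-weighted image series, voxelwise T1 / T1ρ / T2 map
fitting, and ROI-level tissue-contrast analysis.

## Who this is for

Quantitative-MRI methods developers and preclinical cardiac imaging
groups who want a reproducible, end-to-end desk model of an
ultra-short-TE relaxometry protocol: how saturation-recovery
look-locker T1 and spin-lock T1ρ weighting propagate through radial
under-sampling and regularized reconstruction into parameter maps and
tissue statistics (e.g. distinguishing fibrotic, inflamed and remote
myocardium after infarction).

## The model

**Acquisition.** Center-out radial spokes (duration τ = 3 ms) in a 3D
golden-means order. T1 mode: a saturation pulse every 1024 spokes; the
continuous small-flip-angle readout samples the recovery, and spokes
are binned by position within the curve into 32 frames (65 536 spokes →
64 look-locker curves → 2048 spokes/frame). T1ρ mode: adiabatic
spin-lock preparation (TSL = 0…28 ms in 4 ms steps, one TSL per frame)
repeated every 16 spokes; acceleration by retaining a fraction of the
spokes per frame.

**Reconstruction.** The series is estimated by minimizing

    ½‖A(x) − y‖² + λ Σ_b ‖R_b(x)‖_*

where `A` is the non-uniform Fourier sampling operator (Kaiser–Bessel
gridding NUFFT), `R_b` unfolds non-overlapping 8³ spatial blocks across
the contrast dimension, and ‖·‖_* is the nuclear norm (locally low-rank
regularization). The saturation-recovery series is additionally
constrained to a rank-K temporal subspace from an SVD of a dictionary
of recovery curves. The problem is solved with 70 iterations of a
preconditioned primal-dual proximal splitting (PDPS) scheme.

**Mapping.** T1eff per voxel from the five-parameter saturation-recovery
fit, corrected to T1 via `1/T1 = 1/T1eff + ln(cos α)/τ`; T1ρ from a
mono-exponential fit of the T1-corrected normalized spin-lock decay,
plus the asymptotic (first two TSLs) and slow (remaining TSLs)
log-slope surrogates; 2D T2 / T1ρ from mono-exponential fits of
multi-contrast stacks.

**Analysis.** ROI mean/std tables; relative relaxation time difference
`RRTD = (mean(T_damage) − mean(T_remote)) / mean(T_remote)`;
relaxivity as the slope of relaxation rate 1/T against contrast-agent
(MnCl₂) concentration; t-tests with Bonferroni correction.

## Worked example

Heart-like phantom (remote / inflamed / fibrotic / control
compartments), 8-frame spin-lock protocol at 32³, 10× retrospective
under-sampling (410 of 4096 spokes/frame), SNR 30, LLR-regularized
PDPS reconstruction, T1-corrected T1ρ mapping:

```python
import numpy as np
import radrelax as rr

phantom = rr.build_heart_phantom(matrix=32)
protocol = rr.t1rho_protocol(matrix=32, spokes_per_frame=4096)
spokes = rr.undersample_t1rho(rr.make_t1rho_spokes(protocol), 410, "prefix")
series = rr.frame_images(phantom, protocol, spokes.frame_times)
sigma = rr.noise_sigma_for_snr(30.0, 1.0, protocol.samples_per_spoke)
kspace = rr.sample_kspace(series, spokes, noise_sigma=sigma, seed=0)

recon, info = rr.pdps_solve(
    kspace, rr.make_operator(kspace),
    rr.ReconConfig(llr_lambda=1000.0, iterations=70), mode="framewise_t1rho")

t1_ref = rr.RelaxationMap(np.where(phantom.mask, phantom.maps["t1"], np.nan),
                          "s", mask=phantom.mask, name="T1")
t1rho_map, _, _ = rr.map_t1rho(recon, t1_ref, protocol, phantom.mask)

medians = {name: np.nanmedian(t1rho_map.values[phantom.compartment_mask(name)])
           for name in ("control", "remote", "inflammation", "fibrosis")}
for name, med in medians.items():
    truth = phantom.maps["t1rho"][phantom.compartment_mask(name)][0]
    print(f"{name:>12}: median T1rho {med:6.1f} ms   (ground truth {truth:.0f})")
print("fibrosis/remote RRTD:",
      rr.rrtd(medians["fibrosis"], medians["remote"]).rounded(2))
```

prints

```
     control: median T1rho   30.2 ms   (ground truth 30)
      remote: median T1rho   31.0 ms   (ground truth 31)
inflammation: median T1rho   50.2 ms   (ground truth 50)
    fibrosis: median T1rho   85.5 ms   (ground truth 84)
fibrosis/remote RRTD: 1.8
```

i.e. at tenfold acceleration the per-compartment median T1ρ values are
recovered to within a few percent and the fibrosis/remote contrast is
close to the ground-truth RRTD of 1.71. Compartment medians are
reported because boundary voxels (partial volume + residual
under-sampling artifacts) can inflate plain ROI means at high
acceleration.

The same workflow is available from the shell:

```bash
radrelax run --mode t1rho --phantom heart --matrix 32 --out out/
radrelax simulate --mode t1 --matrix 32 --out k.h5
radrelax reconstruct --mode t1 --kspace k.h5 --lambda 0,1000,3000 --out series
```

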