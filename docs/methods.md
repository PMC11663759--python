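# Methods

## Overview

`smsmap` models one specific quantitative cardiac MRI experiment: joint T1/T2
mapping of up to three short-axis slices acquired *simultaneously* (SMS,
simultaneous multislice) within a single breath-hold. The package contains the
four stages of that experiment and the synthetic data needed to test them:

1. **Signal model** — an electrocardiogram-triggered, 11-heartbeat spoiled
   FLASH acquisition (10 imaging beats + 1 calibration beat) with
   inversion-recovery and T2-preparation weighting, simulated by a
   longitudinal-magnetization Bloch recursion;
2. **Encoding and undersampling** — the 3D Fourier SMS encoding
   `y = D F E x` with a SUPER-CAIPIRINHA sampling pattern;
3. **Reconstruction** — a locally-low-rank + sparsity (LLRS) regularized
   inversion solved by ADMM;
4. **Parameter estimation** — phase-sensitive polarity restoration followed
   by two-stage Bloch-dictionary matching (coarse B1 stage, fine T1/T2
   stage).

## Signal model and schedule

Each cardiac cycle contains an optional magnetization preparation, a trigger
delay, a FLASH readout train, and free recovery. The simulator tracks only
longitudinal magnetization Mz under perfect spoiling (no transverse coherence
across TRs; no echo-path or EPG bookkeeping is needed at a 5° flip angle):

- inversion: `Mz -> -delta * Mz` with inversion efficiency `delta = 0.94`,
  applied so that the inversion time TI elapses between the pulse and the TR
  of the k-space-center line;
- T2 preparation: `Mz -> Mz * exp(-TEprep / T2)` (ideal adiabatic refocusing,
  T1 relaxation during the prep neglected, B1-independent);
- each TR: record `s = Mz sin(b1 * alpha)`, tip `Mz -> Mz cos(b1 * alpha)`,
  relax toward M0 over TR with T1;
- everywhere else: free T1 relaxation.

The per-contrast signal is the center-line sample of the readout train
(linear phase-encode ordering, center line at the middle of the train), which
is the sample that dominates image contrast. The transmit-field scale `b1`
multiplies only the excitation flip angle, not the inversion or the T2prep
(their adiabatic implementations are far less B1-sensitive than the small-tip
excitation).

**Default schedule.** The published protocol defers its preparation timings
to an earlier single-slice implementation without listing them, so the package
defines its own default and documents it as such: beat 1 without preparation,
beat 2 inversion with TI 120 ms, beats 3–5 free-recovery sampling, beat 6
inversion with TI 200 ms, beat 7 free recovery, beats 8–10 T2-preparations
with TE 30/50/80 ms, beat 11 the prep-free single-band calibration (ACS)
beat. Every timing is overridable. Defaults for the readout: TR 4.19 ms, TE
1.73 ms, flip 5°, 47 lines per beat (the largest count keeping the
acquisition window below 200 ms), inversion efficiency 0.94.

The trigger delay defaults to 500 ms and is automatically shortened to at
most 55 % of the R-R interval on fast heart rates, where a fixed 500 ms delay
would push the readout beyond the cardiac cycle; the simulator raises an
error if a configured readout cannot fit.

## Sampling

Simultaneous slices are represented as `nz = MB` Fourier partitions along kz;
CAIPIRINHA RF phase cycling is algebraically identical to this skewed kz
encoding under the 3D Fourier model. The pattern samples outer ky lines where
`(ky - t mod R) mod R == 0` (the SUPER shift cycles the offset across
contrasts t, so the union of any R consecutive contrasts covers every outer
line) and assigns each sampled line the partition
`kz = floor(ky / R) mod MB`. The central 24 ky lines are sampled at
reduction 2 with a two-contrast parity cycle (adjacent contrasts jointly
cover the whole band), plus the DC line at every contrast — the readout
acquires the k-space-center line every heartbeat, so every contrast must
sample it — all with the same kz skew. A strict mode without the dense
center is available for exact rate accounting (with it the per-contrast
sampled fraction is exactly `1/(R*MB)`). The nominal combined acceleration is
reported as `R * MB` — 4, 8, 12 for MB = 1, 2, 3 at R = 4. The calibration
beat samples the 18 central ky lines fully, single-band per slice.

## Reconstruction

The inverse problem is

```
min_x 1/2 ||y - DFEx||_F^2
      + alpha * sum_{q,i} ||B_i x_q||_*   (locally low rank, per slice)
      + beta  * sum_q     ||W x_q||_1     (wavelet sparsity, per slice)
```

where `B_i` extracts the block of voxels centered at voxel i as a Casorati
matrix (block voxels x contrasts) and W is an orthonormal Daubechies-4
wavelet, 3 levels, periodic boundary, applied per 2D contrast image (the
source protocol names no wavelet; this is the package's choice). ADMM
splitting (`z_iq = B_i x_q`, `v_q = W x_q`) gives four steps per iteration:

1. **x update**: solve
   `(E^H F^H D^H D F E + (mu1*b^2 + mu2) I) x = E^H F^H D^H y + mu1 sum_i B_i^H(z - lam/mu1) + mu2 W^H(v - zeta/mu2)`
   by warm-started conjugate gradients. Overlapping blocks with periodic wrap
   make `sum_i B_i^H B_i = b^2 I` exactly, and `W^H W = I`, so the
   regularizer contribution is an exact identity shift. Because the readout
   axis is fully sampled, the kx transforms cancel inside the normal operator
   and the systems decouple along the readout: the CG iteration applies only
   (ky, kz) transforms. The centered-FFT bookkeeping (fftshift pairs) is
   likewise folded into pre-shifted sensitivities and mask, which are unitary
   permutations that leave the solution unchanged.
2. **SVT**: `z_iq = SVT_{alpha/mu1}(B_i x_q + lam_iq/mu1)` — singular value
   soft-thresholding of every Casorati matrix. The batched implementation
   diagonalizes the small Gram matrix `M^H M` (contrasts x contrasts) instead
   of a full SVD; blocks whose Frobenius norm is at most the threshold are
   zeroed outright (exact, since the spectral norm is bounded by the
   Frobenius norm).
3. **Soft-thresholding**: `v_q = ST_{beta/mu2}(W x_q + zeta_q/mu2)`,
   complex magnitude shrinkage.
4. **Dual ascent** on both constraint sets with steps mu1 and mu2.

Defaults (the published prospective settings): block 7, `alpha = 10^-3.75`,
`mu1 = 10^-2.75`, `beta = 10^-4`, `mu2 = 10^-3`, 100 iterations with no early
stopping. These weights presume a fixed data scale that the protocol does not
state; the solver therefore normalizes k-space so the 99th-percentile
magnitude of the zero-filled adjoint image equals one, and undoes the scale
on output.

Numerical choices: the working precision is single complex (the
reconstruction error floor of the regularized problem is far above
single-precision rounding; tests that need stricter accuracy pass
double-precision data and tighter CG settings explicitly). Inner CG uses at
most 15 iterations and stops at a relative residual of 1e-4; warm starting
from the previous ADMM iterate makes the x-updates progressively cheaper, and
the inexact inner solve leaves the ADMM fixed point unchanged. CG reports
divergence if the residual grows over five consecutive iterations. The
`shifted_nonoverlap` block mode (disjoint tiling with a per-iteration random
cyclic shift, `sum B_i^H B_i = I`) is offered as a faster approximation of
the overlapping default and is the solver's only stochastic element; its
shifts derive from the reconstruction seed, so results are reproducible.

## Parameter estimation

Phase-sensitive correction rotates each voxel's contrast vector by the
conjugate phase of its **last** contrast and keeps the real part. The last
imaging beat is a T2-preparation beat late in the recovery train, so its
longitudinal magnetization is positive for physiological tissue — that is the
documented assumption making it a valid polarity reference. Voxels whose
reference magnitude is exactly zero fall back to magnitude images (counted
and logged).

Matching maximizes the normalized real inner product between the voxel
series and l2-normalized dictionary atoms — equivalent to least squares over
a free scale, whose optimum `<s, d>` is retained as M0; `1 - correlation` is
the match residual. Ties break toward smaller T1 then smaller T2 via the
dictionary's lexicographic atom ordering. Correlation is maximized over the
signed value (polarity has already been restored), so anti-correlated atoms
are never matched.

Stage one estimates B1 with the abbreviated dictionary — T1 [500:100:1500]
ms, T2 [40:30:140] ms, B1 [0.5:0.05:1] — and averages the matched B1 over a
reference region (the septum in vivo; in the synthetic vial protocol, a vial
whose T1/T2 lie inside the coarse grid's coverage). One scalar B1 is used for
the whole slice group. Stage two matches against a fine dictionary simulated
at that B1: T1 [1:10:2500] / T2 [1:4:400] ms for the phantom protocol, T1
[200:1:2500] / T2 [1:1:150] ms in vivo. Grid combinations with T1 < T2 are
excluded as non-physical. At a 5° flip angle the normalized signal shape
depends only weakly on B1, which bounds the damage of a residual B1 error but
also makes the B1 stage poorly conditioned for tissues outside the coarse
grid — the reason the reference region must lie inside its coverage.

## Synthetic data

The vial phantom places nine disks (3x3 grid) in a low-signal gel holder,
replicated across slices with a one-voxel offset. Default relaxation times
span the physiological range, T1 301–1801 ms and T2 33–249 ms, chosen on the
fine-dictionary lattice (T1 on 1+10k, T2 on 1+4k ms) so that noiseless
end-to-end recovery is exact — the round endpoints 300/1800/30/250 do not lie
on that lattice. Eroded per-vial ROI masks (radius minus two voxels) are
provided for statistics that should not be diluted by edge partial-volume
and regularization blur. The cardiac phantom provides a three-slice
blood-pool/myocardium/septum geometry shrinking toward the apex, for
plumbing tests.

Coil maps are smooth Gaussian receive profiles centered on the FOV perimeter
with elements staggered deterministically across the slice direction,
emulating an anterior/posterior array — the axial sensitivity variation is
the sole information that conditions slice unaliasing, so clustering the
elements axially (as an unstructured random layout can) makes the multiband
problem needlessly ill-posed. Random smooth phase ramps are added and the
maps are RSS-normalized to one; everything is deterministic per seed. A single coil degenerates to a flat unit map for
oracle tests. These maps stand in for measured sensitivities and contain
none of the calibration error, coupling, or noise correlation of a real
array.

The acquisition simulator evaluates the Bloch recursion once per distinct
(T1, T2, B1) tissue (cached), scales by the voxelwise complex M0, encodes
with `D F E`, and adds i.i.d. complex Gaussian noise of per-component SD
0.005 relative to the normalized image scale to the sampled entries — the
simulation study's noise level. The calibration beat is simulated single-band
per slice at the final-beat magnetization. The synthetic B1 field defaults to
1.0 everywhere so that transmit-field experiments are controlled.

**What the generator does not emulate**: cardiac or respiratory motion,
realistic anatomy, B0 inhomogeneity and off-resonance, slice-profile
imperfections and inter-slice crosstalk, eddy currents, or the
"simulate-SMS-from-reconstructed-single-slice-data" construction of the
original simulation study (the analog here builds k-space from digital
ground truth instead). Passing tests therefore demonstrate correctness of
the algorithmic chain under its own forward model, not robustness to those
physical effects.

## Evaluation

PSNR is `20 log10(max|ref| / RMSE)` with the fully sampled or ground-truth
image as reference; SSIM uses the canonical constants on magnitude images
with the data range taken from the reference; Bland-Altman reports
`mean(a-b)` and `bias ± 1.96 SD(a-b)`; R² comes from the least-squares fit of
estimate on reference. ROI statistics are the arithmetic mean and sample SD
(a single-voxel ROI reports SD 0).

## Problem sizes

The end-to-end accuracy experiment runs the nine-vial phantom at 96x96, MB=3,
in-plane reduction 4, 8 coils, heart rates 40–120 bpm in steps of 20, with
the full 100 ADMM iterations — a desk-scale version of the 192x138 protocol
chosen so the whole sweep completes in minutes on one core. The general test
suite uses a 48x48 standard problem for solver-behavior checks and toy sizes
(8x8 to 32x32) for operator and oracle tests.

## Known limitations

- The preparation timings of the default schedule are a package default, not
  the published protocol (which does not list them); absolute T1/T2 accuracy
  against scanner data would require the true timings.
- The B1 stage estimates one global scalar per slice group; spatial B1
  variation is supported in simulation but not in correction.
- The dense-center sampling mode of the published figure is not specified
  numerically; both a reduction-2 dense center (default) and a strict mode
  are implemented.
- Coil-sensitivity estimation is a simple apodized low-resolution division,
  not a subspace method; it degrades gracefully but is not ESPIRiT.
- The dictionary treats signals as real and signed after phase-sensitive
  correction; complex matching is not implemented.
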