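"""Denoise a noisy phantom with the adaptive HPWF and report the PSNR gain.

The filter first estimates the noise level, picks its window size (3x3
below sigma 20 on the 0-255 scale, else 5x5), then replaces outlier pixels
by their local mean and averages the result.
"""

from skimage.metrics import peak_signal_noise_ratio as psnr

from btfsc.denoise import hpwf_denoise
from btfsc.phantom import PhantomSpec, generate_phantom_pair

spec = PhantomSpec(noise_sigma=15.0, seed=1)
pair = generate_phantom_pair(spec)

trace = hpwf_denoise(pair.mr)
before = psnr(pair.clean_mr, pair.mr, data_range=1.0)
after = psnr(pair.clean_mr, trace.output, data_range=1.0)

print(f"injected sigma      : {spec.noise_sigma:.1f} (0-255 scale)")
print(f"estimated sigma_GN  : {trace.estimate.sigma_gn:.2f}")
print(f"window chosen       : {trace.estimate.mask_size}x{trace.estimate.mask_size}")
print(f"PSNR noisy vs clean : {before:.2f} dB")
print(f"PSNR denoised       : {after:.2f} dB   (gain {after - before:+.2f} dB)")
print("\nA positive gain means the filter moved the image toward the known")
print("clean phantom rather than just blurring it.")
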