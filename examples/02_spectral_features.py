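"""AR-Burg spectra: model fit, band power, and a time-frequency map.

Fits an autoregressive model by the Burg method, evaluates the parametric
power spectral density, and slides it over a chirp to show the spectrogram.
"""

import numpy as np

from eegmanifold import burg_fit, integrated_power, spectrogram
from eegmanifold.spectral import ar_psd

rng = np.random.default_rng(0)

# simulate a known AR(2) process: r(n) = 1.3 r(n-1) - 0.6 r(n-2) + u(n)
a_true = np.array([-1.3, 0.6])
x = np.zeros(10_500)
u = rng.standard_normal(10_500)
for t in range(2, len(x)):
    x[t] = -a_true[0] * x[t - 1] - a_true[1] * x[t - 2] + u[t]
x = x[500:]

est = burg_fit(x, order=2, fs=100.0)
print(f"true AR coefficients    {a_true}")
print(f"Burg-estimated          {np.round(est.ar_coeffs, 4)}  "
      f"(innovation variance {est.sigma2:.3f}, true 1.0)")
print(f"spectrum integrates to  {integrated_power(est):.3f}  "
      f"(sample variance {x.var():.3f})")

freqs = np.arange(0, 50.1, 0.5)
psd = ar_psd(est, freqs)
print(f"spectral peak at        {freqs[psd.argmax()]:.1f} Hz")

# spectrogram of a rising tone: the ridge follows the instantaneous frequency
from scipy.signal import chirp

fs = 200.0
t = np.arange(int(10 * fs)) / fs
sweep = chirp(t, f0=5, t1=10, f1=30) + 0.05 * rng.standard_normal(len(t))
times, fgrid, power = spectrogram(sweep, fs, window=1.0, overlap=0.5,
                                  freqs=np.arange(1.0, 50.0, 0.5))
ridge = fgrid[power.argmax(axis=1)]
print("chirp ridge (Hz):", np.round(ridge[::4], 1),
      "- rises with time as the tone sweeps 5->30 Hz")
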