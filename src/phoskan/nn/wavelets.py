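"""Mother wavelet library for the wavelet-KAN head.

Each wavelet is a bounded, zero-mean oscillatory function psi(t) that
decays as |t| grows; in a Wav-KAN layer every edge applies a scaled and
translated copy, psi((x - tau)/s), weighted by a learnable coefficient
omega.  Five real-valued mother wavelets are registered:

* DoG — first derivative of a Gaussian: psi(t) = t * exp(-t^2 / 2);
* Mexican Hat (Ricker) — the normalized negative second derivative:
  psi(t) = (2 / (sqrt(3) * pi^(1/4))) * (1 - t^2) * exp(-t^2 / 2);
* Morlet — real part with center frequency 5: cos(5 t) * exp(-t^2 / 2);
* Shannon — sinc(t / 2) * cos(3 pi t / 2), under a smooth Gaussian
  window (sigma = 6) to temper the slow sinc tails;
* Meyer — the compact nu-window construction with the standard quartic
  auxiliary polynomial nu(x) = x^4 (35 - 84 x + 70 x^2 - 20 x^3):
  psi(t) = sin(pi t) * aux(|t|), taken odd so it is zero-mean exactly.

All five integrate to (approximately) zero over the real line, the usual
admissibility requirement; the Shannon and Meyer forms satisfy it within
the tolerance of their windowed/truncated construction.

Every form is written once in terms of autograd primitives so the same
code path serves plain numpy evaluation and backpropagation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict

import numpy as np

from phoskan.errors import PhosKANError
from phoskan.nn.autograd import Tensor


def _dog(t):
    return t * (-(t * t) * 0.5).exp()


_MEXICAN_NORM = 2.0 / (math.sqrt(3.0) * math.pi ** 0.25)


def _mexican_hat(t):
    return _MEXICAN_NORM * (1.0 - t * t) * (-(t * t) * 0.5).exp()


def _morlet(t):
    return (5.0 * t).cos() * (-(t * t) * 0.5).exp()


def _shannon(t):
    window = (-(t * t) / 72.0).exp()  # Gaussian window, sigma = 6
    return (t * 0.5).sinc() * (1.5 * math.pi * t).cos() * window


def _meyer_nu(x):
    return x ** 4 * (35.0 - 84.0 * x + 70.0 * x * x - 20.0 * x ** 3)


def _meyer(t):
    v = t.abs()
    raw = v.data
    lowmask = (raw <= 0.5).astype(float)
    mid = ((raw > 0.5) & (raw < 1.0)).astype(float)
    # auxiliary window: 1 for v <= 1/2, cos(pi/2 * nu(2v - 1)) on the
    # transition band 1/2 < v < 1, and 0 beyond; the odd factor sin(pi t)
    # makes the wavelet zero-mean exactly.
    transition = ((math.pi / 2.0) * _meyer_nu(2.0 * v - 1.0)).cos()
    aux = transition * mid + lowmask
    return (math.pi * t).sin() * aux


@dataclass(frozen=True)
class WaveletSpec:
    """A named mother wavelet with its closed form."""

    name: str
    fn: Callable = field(compare=False)

    def __call__(self, t):
        if isinstance(t, Tensor):
            return self.fn(t)
        arr = np.asarray(t, dtype=np.float64)
        return self.fn(Tensor(arr)).data


WAVELETS: Dict[str, WaveletSpec] = {
    "dog": WaveletSpec("dog", _dog),
    "mexican_hat": WaveletSpec("mexican_hat", _mexican_hat),
    "morlet": WaveletSpec("morlet", _morlet),
    "shannon": WaveletSpec("shannon", _shannon),
    "meyer": WaveletSpec("meyer", _meyer),
}


def get_wavelet(name: str) -> WaveletSpec:
    key = name.lower().replace("-", "_").replace(" ", "_")
    aliases = {"ricker": "mexican_hat", "mexicanhat": "mexican_hat",
               "derivative_of_gaussian": "dog"}
    key = aliases.get(key, key)
    if key not in WAVELETS:
        raise PhosKANError(
            f"unknown wavelet {name!r}; available: {sorted(WAVELETS)}"
        )
    return WAVELETS[key]


def wavelet_eval(spec: WaveletSpec | str, t) -> np.ndarray | float:
    """Evaluate a mother wavelet's closed form at ``t`` (scalar or array)."""
    if isinstance(spec, str):
        spec = get_wavelet(spec)
    out = spec(np.asarray(t, dtype=np.float64))
    if np.ndim(t) == 0:
        return float(out)
    return out
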