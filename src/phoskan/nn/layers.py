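"""Network layers: valid 2D convolution, BiGRU, batch norm, Wav-KAN.

All layers hold their parameters as autograd Tensors and expose
``parameters()`` for the optimizer.  Initialization is fully determined
by the generator passed to the constructor.
"""

from __future__ import annotations

from typing import Dict, List, Optional

import numpy as np

from phoskan.errors import ContractError
from phoskan.nn.autograd import Tensor, concatenate, conv2d_valid
from phoskan.nn.wavelets import WaveletSpec, get_wavelet


class Module:
    """Minimal layer base: named parameters + train/eval flag."""

    def __init__(self):
        self._params: Dict[str, Tensor] = {}
        self.training = True

    def _param(self, name: str, value: np.ndarray,
               trainable: bool = True) -> Tensor:
        t = Tensor(np.asarray(value, dtype=np.float64), requires_grad=trainable)
        self._params[name] = t
        return t

    def parameters(self) -> List[Tensor]:
        return [p for p in self._params.values() if p.requires_grad]

    def named_parameters(self) -> Dict[str, Tensor]:
        return dict(self._params)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False


class Conv2dValid(Module):
    """Single-input-channel valid 2D cross-correlation with ReLU.

    ``n_kernels`` filters of ``kernel_size`` x ``kernel_size``, stride 1,
    no padding: an H x W input yields (H - k + 1) x (W - k + 1) maps.
    """

    def __init__(self, n_kernels: int = 16, kernel_size: int = 5,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.n_kernels = n_kernels
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng(0)
        fan_in = kernel_size * kernel_size
        w = rng.standard_normal((n_kernels, kernel_size, kernel_size))
        self.weight = self._param("weight", w * np.sqrt(2.0 / fan_in))
        self.bias = self._param("bias", np.zeros(n_kernels))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ContractError(f"expected (B, H, W) input, got {x.shape}")
        return conv2d_valid(x, self.weight, self.bias).relu()


class GRUCellParams(Module):
    """One direction of a GRU: gate order (reset, update, candidate)."""

    def __init__(self, d_in: int, hidden: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.d_in = d_in
        self.hidden = hidden
        rng = rng or np.random.default_rng(0)
        s_in = 1.0 / np.sqrt(d_in)
        s_h = 1.0 / np.sqrt(hidden)
        self.w_x = self._param("w_x", rng.uniform(-s_in, s_in, (d_in, 3 * hidden)))
        self.w_h = self._param("w_h", rng.uniform(-s_h, s_h, (hidden, 3 * hidden)))
        self.b_x = self._param("b_x", np.zeros(3 * hidden))
        self.b_h = self._param("b_h", np.zeros(3 * hidden))

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        H = self.hidden
        gx = x_t @ self.w_x + self.b_x
        gh = h @ self.w_h + self.b_h
        r = (gx[:, 0:H] + gh[:, 0:H]).sigmoid()
        z = (gx[:, H : 2 * H] + gh[:, H : 2 * H]).sigmoid()
        n = (gx[:, 2 * H : 3 * H] + r * gh[:, 2 * H : 3 * H]).tanh()
        return (1.0 - z) * n + z * h


class BiGRU(Module):
    """Bidirectional GRU over a (B, T, D) sequence.

    Output at step t is the forward hidden state concatenated with the
    backward hidden state, giving (B, T, 2 * hidden).
    """

    def __init__(self, d_in: int, hidden: int = 8,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.fwd = GRUCellParams(d_in, hidden, rng)
        self.bwd = GRUCellParams(d_in, hidden, rng)

    def parameters(self) -> List[Tensor]:
        return self.fwd.parameters() + self.bwd.parameters()

    def named_parameters(self) -> Dict[str, Tensor]:
        out = {f"fwd.{k}": v for k, v in self.fwd.named_parameters().items()}
        out.update(
            {f"bwd.{k}": v for k, v in self.bwd.named_parameters().items()}
        )
        return out

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ContractError(f"expected (B, T, D) input, got {x.shape}")
        B, T, _ = x.shape
        dtype = x.data.dtype
        h_f = Tensor(np.zeros((B, self.hidden), dtype=dtype))
        h_b = Tensor(np.zeros((B, self.hidden), dtype=dtype))
        fwd_states: List[Tensor] = []
        bwd_states: List[Tensor] = [None] * T  # type: ignore[list-item]
        for t in range(T):
            h_f = self.fwd.step(x[:, t, :], h_f)
            fwd_states.append(h_f)
        for t in range(T - 1, -1, -1):
            h_b = self.bwd.step(x[:, t, :], h_b)
            bwd_states[t] = h_b
        rows = [
            concatenate([f, b], axis=1).reshape(B, 1, 2 * self.hidden)
            for f, b in zip(fwd_states, bwd_states)
        ]
        return concatenate(rows, axis=1)


class BatchNorm1d(Module):
    """Feature-wise batch normalization with running statistics.

    Training mode normalizes by batch statistics and updates running
    mean/variance with the configured momentum; eval mode uses the stored
    running statistics, making inference invariant to batch composition.
    """

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self._param("gamma", np.ones(n_features))
        self.beta = self._param("beta", np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self._calib_n = None  # batch counter during precise recalibration

    def begin_calibration(self) -> None:
        """Start a precise-statistics pass: subsequent training-mode
        forwards accumulate a cumulative average of batch statistics
        instead of the exponential moving average."""
        self._calib_n = 0
        self.running_mean = np.zeros_like(self.running_mean)
        self.running_var = np.zeros_like(self.running_var)

    def end_calibration(self) -> None:
        self._calib_n = None

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=0, keepdims=True)
            b = x.shape[0]
            unbiased = var.data[0] * (b / max(b - 1, 1))
            if self._calib_n is not None:
                self._calib_n += 1
                c = self._calib_n
                self.running_mean += (mu.data[0] - self.running_mean) / c
                self.running_var += (unbiased - self.running_var) / c
            else:
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu.data[0])
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * unbiased)
            inv = (var + self.eps) ** -0.5
            return self.gamma * (centered * inv) + self.beta
        dtype = x.data.dtype
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(dtype)
        rm = self.running_mean.astype(dtype)
        return self.gamma * ((x - rm) * inv) + self.beta


class WavKANLayer(Module):
    """A Kolmogorov-Arnold layer with wavelet edge functions.

    Every edge (j, i) carries a learnable univariate function
    ``omega_ji * psi((x_i - tau_ji) / s_ji)``; node j sums its incoming
    edges and adds a linear base term plus bias:

        y_j = sum_i omega_ji * psi((x_i - tau_ji) / s_ji)
              + (W_base x)_j + b_j.

    ``strict_mode`` freezes scale and translation at their init values
    (s = 1, tau = 0), leaving only the wavelet coefficient trainable on
    each edge — the pure "learnable coefficient times mother wavelet"
    parameterization.
    """

    def __init__(self, d_in: int, d_out: int, wavelet: str | WaveletSpec = "dog",
                 strict_mode: bool = False,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.d_in = d_in
        self.d_out = d_out
        self.wavelet = (wavelet if isinstance(wavelet, WaveletSpec)
                        else get_wavelet(wavelet))
        self.strict_mode = strict_mode
        rng = rng or np.random.default_rng(0)
        scale = 1.0 / np.sqrt(d_in)
        self.omega = self._param(
            "omega", rng.standard_normal((d_out, d_in)) * scale
        )
        self.log_s = self._param(
            "log_s", np.zeros((d_out, d_in)), trainable=not strict_mode
        )
        self.tau = self._param(
            "tau", np.zeros((d_out, d_in)), trainable=not strict_mode
        )
        self.w_base = self._param(
            "w_base", rng.uniform(-scale, scale, (d_in, d_out))
        )
        self.bias = self._param("bias", np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 2 or x.shape[1] != self.d_in:
            raise ContractError(
                f"expected (B, {self.d_in}) input, got {x.shape}"
            )
        B = x.shape[0]
        xb = x.reshape(B, 1, self.d_in)
        # s = exp(log_s) keeps the per-edge scale strictly positive.
        s = self.log_s.exp()
        t = (xb - self.tau) * (1.0 / s)
        psi = self.wavelet(t)
        wave = (self.omega * psi).sum(axis=2)
        return wave + x @ self.w_base + self.bias
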