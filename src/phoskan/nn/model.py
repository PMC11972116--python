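"""The window classifier: Conv -> BiGRU -> flatten -> Wav-KAN -> sigmoid.

A W x D window of fused embeddings (default 9 x 1792) passes through a
single-channel valid 2D convolution (16 kernels, 5 x 5, ReLU), shrinking
the window axis to 5 rows and the embedding axis to D - 4 columns.  The
5-row axis is treated as a sequence and fed to a bidirectional GRU with 8
units per direction, yielding a 5 x 16 matrix that flattens to an
80-vector.  A stack of batch-normalized Wav-KAN hidden layers — [128, 32]
for the S+T variant, [24] for the Y variant — feeds a single output unit
whose logit is mapped to a probability with a sigmoid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from phoskan.errors import ContractError, PhosKANError
from phoskan.nn.autograd import Tensor, _sigmoid
from phoskan.nn.layers import BatchNorm1d, BiGRU, Conv2dValid, Module, WavKANLayer

_VARIANT_LAYOUT = {"ST": (128, 32), "Y": (24,)}


@dataclass(frozen=True)
class ModelConfig:
    """Architecture configuration.

    ``variant`` selects the Wav-KAN hidden layout: "ST" (serine/threonine
    model, hidden layers 128 and 32) or "Y" (tyrosine model, a single
    hidden layer of 24).  ``embed_dim`` is the fused embedding width; the
    default 1792 = 1024 + 768.  ``bigru_input_mode`` chooses how the 16
    conv maps become per-step BiGRU features: "flatten" concatenates
    channels x width (the default, using every conv feature), "meanpool"
    averages over the width axis.
    """

    variant: str = "ST"
    wavelet: str = "dog"
    window_size: int = 9
    embed_dim: int = 1792
    n_kernels: int = 16
    kernel_size: int = 5
    gru_hidden: int = 8
    strict_eq2: bool = False
    bigru_input_mode: str = "flatten"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in _VARIANT_LAYOUT:
            raise PhosKANError(f"variant must be ST or Y, got {self.variant!r}")
        if self.window_size % 2 != 1:
            raise PhosKANError("window_size must be odd")
        if self.bigru_input_mode not in ("flatten", "meanpool"):
            raise PhosKANError(
                f"unknown bigru_input_mode {self.bigru_input_mode!r}"
            )
        if self.window_size <= self.kernel_size - 1:
            raise PhosKANError("window smaller than convolution kernel")

    @property
    def hidden_layout(self) -> Tuple[int, ...]:
        return _VARIANT_LAYOUT[self.variant]

    @property
    def conv_out_shape(self) -> Tuple[int, int]:
        return (self.window_size - self.kernel_size + 1,
                self.embed_dim - self.kernel_size + 1)

    @property
    def flatten_dim(self) -> int:
        return self.conv_out_shape[0] * 2 * self.gru_hidden


class PhosKANModel(Module):
    """Conv + BiGRU front end with a wavelet-KAN classification head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.conv = Conv2dValid(config.n_kernels, config.kernel_size, rng)
        oh, ow = config.conv_out_shape
        if config.bigru_input_mode == "flatten":
            gru_in = config.n_kernels * ow
        else:
            gru_in = config.n_kernels
        self.bigru = BiGRU(gru_in, config.gru_hidden, rng)
        dims = [config.flatten_dim, *config.hidden_layout]
        self.norms: List[BatchNorm1d] = []
        self.hidden: List[WavKANLayer] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.norms.append(BatchNorm1d(d_in))
            self.hidden.append(
                WavKANLayer(d_in, d_out, wavelet=config.wavelet,
                            strict_mode=config.strict_eq2, rng=rng)
            )
        self.head = WavKANLayer(dims[-1], 1, wavelet=config.wavelet,
                                strict_mode=config.strict_eq2, rng=rng)
        self._modules: List[Module] = [self.conv, self.bigru, *self.norms,
                                       *self.hidden, self.head]

    # ------------------------------------------------------------------
    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        for m in self._modules:
            out.extend(m.parameters())
        return out

    def named_parameters(self) -> Dict[str, Tensor]:
        names = (["conv", "bigru"]
                 + [f"norm{i}" for i in range(len(self.norms))]
                 + [f"hidden{i}" for i in range(len(self.hidden))]
                 + ["head"])
        out: Dict[str, Tensor] = {}
        for name, m in zip(names, self._modules):
            for k, v in m.named_parameters().items():
                out[f"{name}.{k}"] = v
        return out

    def train(self) -> None:
        self.training = True
        for m in self._modules:
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._modules:
            m.eval()

    # ------------------------------------------------------------------
    def forward(self, windows: np.ndarray | Tensor) -> Tensor:
        """Batch of windows (B, W, D) -> logits (B,)."""
        x = windows if isinstance(windows, Tensor) else Tensor(windows)
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.window_size, cfg.embed_dim):
            raise ContractError(
                f"expected (B, {cfg.window_size}, {cfg.embed_dim}) windows, "
                f"got {x.shape}"
            )
        maps = self.conv.forward(x)  # (B, K, oh, ow)
        B, K, oh, ow = maps.shape
        if cfg.bigru_input_mode == "flatten":
            seq = maps.transpose((0, 2, 1, 3)).reshape(B, oh, K * ow)
        else:
            seq = maps.mean(axis=3).transpose((0, 2, 1))
        gru_out = self.bigru.forward(seq)  # (B, oh, 2*hidden)
        h = gru_out.reshape(B, cfg.flatten_dim)
        for norm, layer in zip(self.norms, self.hidden):
            h = layer.forward(norm.forward(h))
        logit = self.head.forward(h)
        return logit.reshape(B)

    def predict_proba(self, windows: np.ndarray,
                      batch_size: int = 512) -> np.ndarray:
        """Inference probabilities; always uses eval-mode batch norm."""
        was_training = self.training
        self.eval()
        try:
            out = []
            for lo in range(0, len(windows), batch_size):
                z = self.forward(windows[lo : lo + batch_size]).data
                out.append(_sigmoid(np.asarray(z, dtype=np.float64)))
            return np.concatenate(out) if out else np.empty(0)
        finally:
            if was_training:
                self.train()

    # ------------------------------------------------------------------
    def count_parameters(self) -> Dict[str, int]:
        """Trainable scalar counts per component plus the total."""
        per = {
            "conv": self.conv.n_parameters(),
            "bigru": self.bigru.fwd.n_parameters() + self.bigru.bwd.n_parameters(),
            "batch_norm": sum(n.n_parameters() for n in self.norms),
            "wavkan_hidden": sum(h.n_parameters() for h in self.hidden),
            "wavkan_head": self.head.n_parameters(),
        }
        per["total"] = sum(per.values())
        return per

    # ------------------------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        arrays = {k: v.data for k, v in self.named_parameters().items()}
        for i, n in enumerate(self.norms):
            arrays[f"norm{i}.running_mean"] = n.running_mean
            arrays[f"norm{i}.running_var"] = n.running_var
        return arrays

    def load_state_arrays(self, arrays: Dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        for k, v in params.items():
            if k not in arrays:
                raise ContractError(f"checkpoint missing parameter {k}")
            if arrays[k].shape != v.data.shape:
                raise ContractError(
                    f"checkpoint shape mismatch for {k}: "
                    f"{arrays[k].shape} vs {v.data.shape}"
                )
            v.data = np.array(arrays[k])
        for i, n in enumerate(self.norms):
            n.running_mean = np.array(arrays[f"norm{i}.running_mean"])
            n.running_var = np.array(arrays[f"norm{i}.running_var"])

    def save(self, path: str | Path, history: Optional[dict] = None) -> None:
        """Write a checkpoint: npz parameter arrays + JSON manifest."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path.with_suffix(".npz"), **self.state_arrays())
        manifest = {
            "format_version": 1,
            "config": asdict(self.config),
            "history": history or {},
        }
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "PhosKANModel":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        model = cls(ModelConfig(**manifest["config"]))
        with np.load(path.with_suffix(".npz")) as data:
            model.load_state_arrays({k: data[k] for k in data.files})
        return model


def count_parameters(config: ModelConfig) -> Dict[str, int]:
    """Deterministic trainable-parameter totals for a configuration."""
    return PhosKANModel(config).count_parameters()
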