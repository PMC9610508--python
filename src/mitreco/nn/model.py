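"""A feed-forward network as an ordered list of layers/blocks."""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm, Layer

__all__ = ["Network"]


class Network(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    @property
    def sublayers(self) -> list[Layer]:
        out: list[Layer] = []
        for layer in self.layers:
            out.extend(layer.sublayers)
        return out

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode forward pass in batches (deterministic)."""
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.sublayers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.sublayers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- state (de)serialisation -------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        """Copies of every learnable array plus batch-norm running stats."""
        state = [p.copy() for p in self.parameters()]
        for layer in self.sublayers:
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        extra = iter(state[len(params) :])
        for layer in self.sublayers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)
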