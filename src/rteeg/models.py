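"""The emotion classifiers.

Both architectures are a three-layer recurrent stack (64 / 32 / 16 units
by default) over raw preprocessed EEG segments — timesteps x channels,
one 3-s segment per instance — with dropout 0.2 after the first two
recurrent layers and a 2-way softmax head trained with categorical
cross-entropy.  The bidirectional variant runs each layer forward and
backward in time and concatenates the two passes before the next layer.

``count_parameters`` is the closed-form count: each LSTM layer over
inputs of width ``d`` with ``u`` units holds ``4((d + u + 1)u)`` weights,
a bidirectional layer twice that (and doubles the width seen downstream),
and the dense head ``(d_last + 1) * n_classes``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import BiLSTMLayer, Dense, Dropout, LSTMLayer, SequenceClassifier

__all__ = ["ModelSpec", "build_model", "count_parameters"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative architecture description."""

    architecture: str = "bilstm"  # "lstm" | "bilstm"
    layer_units: tuple[int, ...] = (64, 32, 16)
    dropout_rate: float = 0.2
    n_classes: int = 2
    input_timesteps: int = 750
    input_channels: int = 8
    # indices of recurrent layers followed by dropout; entries beyond the
    # stack (e.g. in shallow reduced profiles) simply do not apply
    dropout_after: tuple[int, ...] = (0, 1)

    def __post_init__(self) -> None:
        if self.architecture not in ("lstm", "bilstm"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not self.layer_units or any(u <= 0 for u in self.layer_units):
            raise ValueError("layer_units must be non-empty positive integers")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.input_timesteps <= 0 or self.input_channels <= 0:
            raise ValueError("input dimensions must be positive")

    def to_dict(self) -> dict:
        return {
            "architecture": self.architecture,
            "layer_units": list(self.layer_units),
            "dropout_rate": self.dropout_rate,
            "n_classes": self.n_classes,
            "input_timesteps": self.input_timesteps,
            "input_channels": self.input_channels,
        }


def build_model(
    spec: ModelSpec, rng: np.random.Generator | int | None = 0, dtype=np.float32
) -> SequenceClassifier:
    """Construct a trainable classifier from a spec.

    Recurrent layers 1..n-1 return full sequences; the last returns its
    final state.  Weight initialization draws from ``rng`` (an integer
    seeds a fresh generator), so construction is deterministic.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    layers = []
    width = spec.input_channels
    last = len(spec.layer_units) - 1
    for i, units in enumerate(spec.layer_units):
        return_seq = i < last
        if spec.architecture == "bilstm":
            layer = BiLSTMLayer(width, units, return_seq, rng, dtype)
            width = 2 * units
        else:
            layer = LSTMLayer(width, units, return_seq, rng, dtype)
            width = units
        layers.append(layer)
        if i in spec.dropout_after and spec.dropout_rate > 0 and return_seq:
            layers.append(Dropout(spec.dropout_rate))
    layers.append(Dense(width, spec.n_classes, rng, dtype))
    return SequenceClassifier(layers)


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter count for a spec; equals the built
    model's total."""
    directions = 2 if spec.architecture == "bilstm" else 1
    width = spec.input_channels
    total = 0
    for units in spec.layer_units:
        total += directions * 4 * ((width + units + 1) * units)
        width = directions * units
    total += (width + 1) * spec.n_classes
    return total
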