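"""Trainable-parameter and multiply-accumulate (MAC) profiling.

``trainable_params`` is the brute-force sum of element counts over every
weight tensor.  ``mac_count`` counts one MAC per scalar multiply performed
by convolutional and linear layers at the stated input size; normalization,
activations and pooling contribute nothing, matching the dominant
convention behind printed "FLOPs" figures for convolutional networks.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ShapeError
from .nn import Module


@dataclass
class ModelProfile:
    trainable_params: int
    mac_count: int
    input_size: int
    per_module: list  # (name, params, macs)

    @property
    def params_millions(self) -> float:
        return self.trainable_params / 1e6

    @property
    def macs_giga(self) -> float:
        return self.mac_count / 1e9

    def __str__(self):
        lines = [f"{'module':<18}{'params':>12}{'MACs':>16}"]
        for name, p, m in self.per_module:
            lines.append(f"{name:<18}{p:>12,}{m:>16,}")
        lines.append(f"{'total':<18}{self.trainable_params:>12,}{self.mac_count:>16,}")
        lines.append(
            f"= {self.params_millions:.2f}M parameters, "
            f"{self.macs_giga:.2f}G MACs at {self.input_size}x{self.input_size}")
        return "\n".join(lines)


def profile(model: Module, input_size: int = 512) -> ModelProfile:
    """Profile a built network at a square input of ``input_size`` pixels."""
    if hasattr(model, "profile_components"):
        per_module = model.profile_components(input_size)
    else:
        macs, _ = model.macs(input_size, input_size)
        per_module = [(type(model).__name__, model.num_parameters(), macs)]
    total_p = sum(p for _, p, _ in per_module)
    total_m = sum(m for _, _, m in per_module)
    if total_p != model.num_parameters():
        raise ShapeError("per-module breakdown does not cover all parameters")
    return ModelProfile(trainable_params=total_p, mac_count=total_m,
                        input_size=input_size, per_module=per_module)
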