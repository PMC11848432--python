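"""Minimal NumPy neural-network kernel: parameters and the module protocol.

Modules cache what they need during ``forward`` and return input gradients
from ``backward`` (reverse order of calls). All parameters are plain NumPy
arrays; numerical-gradient tests in the suite pin down every layer's
backward pass.
"""

from __future__ import annotations

import numpy as np

# Default compute dtype. float32 halves memory traffic for training; the
# gradient-check tests switch to float64 for tight finite-difference bounds.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype).type


class Parameter:
    __slots__ = ("data", "grad", "name")

    def __init__(self, data, name: str = ""):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter({self.name or 'unnamed'}, shape={self.data.shape})"


class Module:
    """Base class; subclasses implement forward/backward."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x, train: bool = False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, train: bool = False):
        return self.forward(x, train=train)

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def state_arrays(self) -> dict:
        """Flat name->array mapping of parameters (and buffers) for checkpoints."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"p{i}"] = p.data
        for j, b in enumerate(self.buffers()):
            out[f"b{j}"] = b[1]
        return out

    def load_state_arrays(self, arrays: dict) -> None:
        params = self.parameters()
        for i, p in enumerate(params):
            src = arrays[f"p{i}"]
            if src.shape != p.data.shape:
                raise ValueError(
                    f"checkpoint shape mismatch for parameter {i}: "
                    f"{src.shape} vs {p.data.shape}"
                )
            p.data = np.array(src, dtype=DTYPE, copy=True)
            p.grad = np.zeros_like(p.data)
        for j, ((owner, attr), _) in enumerate(self.buffers()):
            key = f"b{j}"
            if key in arrays:
                setattr(owner, attr, np.array(arrays[key], dtype=DTYPE, copy=True))

    def buffers(self) -> list:
        """Non-trainable state (e.g. batch-norm running stats).

        Returns a list of ``((owner, attr_name), array)`` pairs.
        """
        out = [
            ((self, name), getattr(self, name))
            for name in getattr(self, "_buffer_names", ())
        ]
        for value in vars(self).values():
            out.extend(_collect_buffers(value))
        return out


def _collect(value) -> list[Parameter]:
    if isinstance(value, Parameter):
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out: list[Parameter] = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _collect_buffers(value) -> list:
    if isinstance(value, Module):
        return value.buffers()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_buffers(v))
        return out
    return []


# -- initializers -----------------------------------------------------------

def glorot(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def orthogonal(rng: np.random.Generator, shape):
    a = rng.standard_normal(shape)
    q, r = np.linalg.qr(a if shape[0] >= shape[1] else a.T)
    q = q * np.sign(np.diag(r))
    if shape[0] < shape[1]:
        q = q.T
    return q[: shape[0], : shape[1]].astype(DTYPE)
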