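"""Minimal module system over numpy + autograd.

Modules own their parameters as plain numpy arrays.  For training, the
parameter tree (a nested dict mirroring the module hierarchy) is passed
explicitly through ``forward`` so that ``autograd.grad`` can differentiate
with respect to it; for inference the stored arrays are used.
"""

from __future__ import annotations

from typing import Callable, Dict, Iterator, Optional, Tuple

import numpy as np
from autograd.tracer import getval


class Module:
    """Base class; subclasses register parameters, buffers and children.

    ``forward(x, p)`` receives the module's own parameter subtree ``p``
    (``p[name]`` for a parameter registered as ``name``, ``p[child]`` for a
    child's subtree).  Calling the module without ``p`` uses stored arrays.
    """

    def __init__(self) -> None:
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", False)

    # -- registry ----------------------------------------------------------
    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def add_param(self, name: str, value: np.ndarray) -> np.ndarray:
        self._params[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._params[name])
        return self._params[name]

    def add_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        self._buffers[name] = np.asarray(value, dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])
        return self._buffers[name]

    def set_buffer(self, name: str, value) -> None:
        self._buffers[name] = np.asarray(getval(value), dtype=np.float64)
        object.__setattr__(self, name, self._buffers[name])

    # -- trees -------------------------------------------------------------
    def state(self) -> Dict:
        """Nested dict of parameter arrays (live references)."""
        tree: Dict = dict(self._params)
        for name, child in self._children.items():
            tree[name] = child.state()
        return tree

    def load_state(self, tree: Dict) -> None:
        for name in self._params:
            self.add_param(name, np.asarray(getval(tree[name]), dtype=np.float64))
        for name, child in self._children.items():
            child.load_state(tree[name])

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray]]:
        for name, arr in self._params.items():
            yield prefix + name, arr
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def num_params(self) -> int:
        return sum(int(np.prod(a.shape)) for _, a in self.named_parameters())

    def frozen_param_count(self) -> int:
        """Parameters excluded from training (overridden where relevant)."""
        return sum(c.frozen_param_count() for c in self._children.values())

    def set_training(self, flag: bool) -> None:
        object.__setattr__(self, "training", flag)
        for child in self._children.values():
            child.set_training(flag)

    def apply_modules(self, fn: Callable[["Module"], None]) -> None:
        fn(self)
        for child in self._children.values():
            child.apply_modules(fn)

    # -- forward -----------------------------------------------------------
    def forward(self, x, p):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x, p: Optional[Dict] = None):
        return self.forward(x, self.state() if p is None else p)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.layers = list(modules)
        for i, m in enumerate(modules):
            setattr(self, f"m{i}", m)

    def forward(self, x, p):
        for i in range(len(self.layers)):
            x = self.layers[i](x, p[f"m{i}"])
        return x

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, i: int) -> Module:
        return self.layers[i]


class Identity(Module):
    def forward(self, x, p):
        return x


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)
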