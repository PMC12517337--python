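"""Flat parameter vectors: the unit of client/server exchange.

A model's trainable state is a dict of named numpy arrays. Federated
aggregation operates on a flat, ordered view of that dict; the layout (name,
shape, offset) is shared by every client holding the same architecture, so
element-wise server arithmetic is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParameterVector", "flatten_params", "unflatten_params"]


@dataclass(frozen=True)
class ParameterVector:
    """Ordered flat view of a model's parameters plus its segment layout."""

    values: np.ndarray  # 1-D float64
    layout: tuple[tuple[str, tuple[int, ...]], ...]  # (name, shape) in order

    def __post_init__(self) -> None:
        total = sum(int(np.prod(s)) for _, s in self.layout)
        if self.values.ndim != 1 or len(self.values) != total:
            raise ValueError(
                f"values length {len(self.values)} does not match layout total {total}"
            )

    def copy(self) -> "ParameterVector":
        return ParameterVector(self.values.copy(), self.layout)

    def segment_slice(self, name: str) -> slice:
        off = 0
        for seg, shape in self.layout:
            n = int(np.prod(shape))
            if seg == name:
                return slice(off, off + n)
            off += n
        raise KeyError(name)

    def same_layout(self, other: "ParameterVector") -> bool:
        return self.layout == other.layout


def flatten_params(params: dict[str, np.ndarray]) -> ParameterVector:
    """Flatten a named-array dict into a ParameterVector (insertion order)."""
    layout = tuple((name, tuple(a.shape)) for name, a in params.items())
    if not layout:
        raise ValueError("empty parameter dict")
    values = np.concatenate([np.asarray(a, dtype=float).ravel() for a in params.values()])
    return ParameterVector(values, layout)


def unflatten_params(pv: ParameterVector) -> dict[str, np.ndarray]:
    """Rebuild the named-array dict from a flat vector; inverse of flatten."""
    out: dict[str, np.ndarray] = {}
    off = 0
    for name, shape in pv.layout:
        n = int(np.prod(shape))
        out[name] = pv.values[off:off + n].reshape(shape).copy()
        off += n
    return out
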