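"""Tissue probability map sets.

A :class:`TPMSet` is an ordered mapping from tissue class name (``"gm"``,
``"wm"``, ``"csf"`` and optionally ``"wmh"``) to a probability
:class:`~lesionmorph.volumes.Volume` on a shared grid.  It is the carrier
for priors, per-subject posteriors and group templates alike.
"""

from __future__ import annotations

import numpy as np

from .volumes import Volume

__all__ = ["TPMSet"]


class TPMSet:
    """Ordered set of per-class probability volumes on one grid."""

    def __init__(self, maps: dict[str, Volume], validate: bool = True):
        if not maps:
            raise ValueError("TPMSet requires at least one class map")
        self._maps = dict(maps)
        ref = next(iter(self._maps.values()))
        for name, vol in self._maps.items():
            ref.require_same_grid(vol, f"TPM class '{name}'")
        if validate:
            self.validate()

    # -- mapping interface -------------------------------------------------
    @property
    def classes(self) -> list[str]:
        return list(self._maps)

    def __getitem__(self, name: str) -> Volume:
        return self._maps[name]

    def __contains__(self, name: str) -> bool:
        return name in self._maps

    def __iter__(self):
        return iter(self._maps)

    def items(self):
        return self._maps.items()

    @property
    def reference(self) -> Volume:
        return next(iter(self._maps.values()))

    @property
    def shape(self):
        return self.reference.shape

    # -- helpers -----------------------------------------------------------
    def stack(self) -> np.ndarray:
        """Class-major array of probabilities, shape (K,) + grid."""
        return np.stack([np.asarray(v.data, dtype=float) for v in self._maps.values()])

    def with_stack(self, stack: np.ndarray, classes: list[str] | None = None,
                   validate: bool = True) -> "TPMSet":
        classes = classes or self.classes
        ref = self.reference
        return TPMSet(
            {c: ref.with_data(stack[i]) for i, c in enumerate(classes)},
            validate=validate,
        )

    def argmax_labels(self) -> np.ndarray:
        """Integer label map: 1 + argmax class index, 0 where all classes are 0."""
        stack = self.stack()
        labels = np.argmax(stack, axis=0) + 1
        labels[stack.sum(axis=0) <= 0] = 0
        return labels

    def class_sum(self) -> np.ndarray:
        return self.stack().sum(axis=0)

    def validate(self) -> None:
        for name, vol in self._maps.items():
            d = np.asarray(vol.data)
            if d.min() < -1e-6 or d.max() > 1.0 + 1e-4:
                raise ValueError(f"TPM class '{name}' has values outside [0, 1]")
        if self.class_sum().max() > 1.0 + 1e-4:
            raise ValueError("per-voxel class probabilities sum above 1")
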