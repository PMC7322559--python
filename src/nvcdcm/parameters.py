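"""Named parameter blocks with diagonal Gaussian priors.

All model parameters live in named blocks (e.g. ``theta_Af``, ``beta``,
``theta_eta``).  A :class:`PriorSpec` assigns each block a prior mean and a
diagonal prior variance; a variance of exactly zero marks a parameter as
hard-fixed at its prior mean, which removes it from the estimation vector.
:class:`BlockLayout` handles the bookkeeping between the block dictionaries
used by the forward models and the flat vectors used by the optimiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


def _as_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class PriorSpec:
    """Diagonal Gaussian prior per named parameter block.

    ``variance == 0`` fixes the parameter at its prior mean.
    """

    means: dict[str, np.ndarray] = field(default_factory=dict)
    variances: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, mean, variance) -> "PriorSpec":
        mean = _as_array(mean)
        variance = _as_array(variance)
        if variance.size == 1 and mean.size != 1:
            variance = np.full(mean.shape, variance.item())
        if mean.shape != variance.shape:
            raise ValidationError(f"prior block {name!r}: mean/variance shape mismatch")
        if np.any(variance < 0):
            raise ValidationError(f"prior block {name!r}: negative variance")
        self.means[name] = mean
        self.variances[name] = variance
        return self

    def blocks(self) -> list[str]:
        return list(self.means)

    def copy(self) -> "PriorSpec":
        out = PriorSpec()
        for name in self.means:
            out.add(name, self.means[name].copy(), self.variances[name].copy())
        return out


class BlockLayout:
    """Maps between {block name: array} dictionaries and flat vectors.

    Built from a :class:`PriorSpec`; only entries with non-zero prior variance
    enter the free vector, the rest are pinned at their prior means.
    """

    def __init__(self, prior: PriorSpec):
        self.prior = prior
        self.names = prior.blocks()
        self._shapes = {n: prior.means[n].shape for n in self.names}
        free_mask = []
        labels = []
        for n in self.names:
            v = prior.variances[n].ravel()
            free_mask.append(v > 0)
            labels.extend(f"{n}[{i}]" for i in range(v.size))
        self._free_mask = np.concatenate(free_mask) if free_mask else np.zeros(0, bool)
        self._labels_all = labels
        self.labels = [l for l, f in zip(labels, self._free_mask) if f]
        self.n_free = int(self._free_mask.sum())

    def full_vector(self, values: dict[str, np.ndarray] | None = None) -> np.ndarray:
        parts = []
        for n in self.names:
            if values is not None and n in values:
                arr = np.asarray(values[n], dtype=float)
                if arr.shape != self._shapes[n]:
                    arr = arr.reshape(self._shapes[n])
            else:
                arr = self.prior.means[n]
            parts.append(arr.ravel())
        return np.concatenate(parts) if parts else np.zeros(0)

    def free_means(self) -> np.ndarray:
        return self.full_vector()[self._free_mask]

    def free_variances(self) -> np.ndarray:
        v = np.concatenate([self.prior.variances[n].ravel() for n in self.names])
        return v[self._free_mask]

    def to_blocks(self, free_vector: np.ndarray) -> dict[str, np.ndarray]:
        full = self.full_vector()
        full[self._free_mask] = free_vector
        out = {}
        i = 0
        for n in self.names:
            size = int(np.prod(self._shapes[n])) if self._shapes[n] else 1
            out[n] = full[i:i + size].reshape(self._shapes[n])
            i += size
        return out

    def free_indices(self, block: str) -> np.ndarray:
        """Positions in the free vector occupied by ``block``."""
        offsets = np.cumsum([0] + [self.prior.means[n].size for n in self.names])
        start = offsets[self.names.index(block)]
        stop = offsets[self.names.index(block) + 1]
        full_idx = np.flatnonzero(self._free_mask)
        return np.flatnonzero((full_idx >= start) & (full_idx < stop))
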