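"""Feature-vector container shared by all extractors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FeatureVector"]


@dataclass
class FeatureVector:
    """Ordered real-valued features with named blocks.

    ``block_map`` maps a block name (``color``, ``graytone``, ``graygradient``,
    ``wavelet``, ``lbp``) to the half-open index range it occupies, so the
    provenance of every element is recoverable (needed by the GA selection
    report and the CSV export headers).
    """

    values: np.ndarray
    block_map: dict[str, tuple[int, int]]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("feature values must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains NaN/Inf")
        for name, (start, stop) in self.block_map.items():
            if not 0 <= start <= stop <= len(self.values):
                raise ValueError(f"block {name!r} range ({start}, {stop}) out of bounds")
        if self.names and len(self.names) != len(self.values):
            raise ValueError("names must match values length")

    def __len__(self) -> int:
        return len(self.values)

    def block(self, name: str) -> np.ndarray:
        start, stop = self.block_map[name]
        return self.values[start:stop]

    @staticmethod
    def concatenate(parts: dict[str, "FeatureVector"]) -> "FeatureVector":
        values, names, block_map = [], [], {}
        offset = 0
        for block_name, fv in parts.items():
            values.append(fv.values)
            names.extend(fv.names or [f"{block_name}_{i}" for i in range(len(fv))])
            block_map[block_name] = (offset, offset + len(fv))
            offset += len(fv)
        return FeatureVector(np.concatenate(values), block_map, names)
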