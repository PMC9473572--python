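"""Distance-to-margin x time velocity kymographs.

The same container is produced from PDE fields (model prediction) and from
cell tracks (measurement), so the two can be compared bin by bin.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["Kymograph", "bin_edges_covering"]


def bin_edges_covering(lo: float, hi: float, width: float) -> np.ndarray:
    """Bin edges starting at ``lo`` with the given width, covering ``hi``."""
    if width <= 0:
        raise ConfigurationError("bin width must be positive")
    n = max(1, int(np.ceil((hi - lo) / width - 1e-9)))
    return lo + width * np.arange(n + 1)


@dataclass(frozen=True)
class Kymograph:
    """Mean animal-ward velocity binned by distance to margin and time.

    ``values[i, j]`` is the mean velocity (um/min, or dimensionless when
    normalized) of cells in distance bin ``i`` during time bin ``j``; bins
    with no observations are NaN.  ``counts`` holds the number of pooled
    samples (tracks) or the summed cell mass (fields) per bin.
    """

    dist_edges: np.ndarray
    time_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "dist_edges", np.asarray(self.dist_edges, dtype=float))
        object.__setattr__(self, "time_edges", np.asarray(self.time_edges, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        nd, nt = len(self.dist_edges) - 1, len(self.time_edges) - 1
        if self.values.shape != (nd, nt) or self.counts.shape != (nd, nt):
            raise ConfigurationError("kymograph matrix shape does not match bin edges")

    @property
    def dist_centers(self) -> np.ndarray:
        return 0.5 * (self.dist_edges[:-1] + self.dist_edges[1:])

    @property
    def time_centers(self) -> np.ndarray:
        return 0.5 * (self.time_edges[:-1] + self.time_edges[1:])

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def normalize(self) -> "Kymograph":
        """Rescale so the maximum absolute non-missing entry is 1."""
        vmax = np.nanmax(np.abs(self.values)) if np.any(~self.missing) else 0.0
        if vmax == 0:
            return replace(self, normalized=True)
        return replace(self, values=self.values / vmax, normalized=True)
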