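"""Scratch-buffer bookkeeping for dense per-sample blocks.

The optimizer never materializes a dense genes x total-cells array; the
only dense intermediates it is allowed are per-sample residual blocks
(genes x cells-in-sample).  Every such allocation is routed through
:func:`dense_block` so tests can audit peak dense-block size.
"""
from __future__ import annotations

import threading

import numpy as np
import scipy.sparse as sp


class AllocationTracker:
    """Records the dense scratch blocks requested by the optimizer."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self.reset()

    def reset(self) -> None:
        with getattr(self, "_lock", threading.Lock()):
            self.shapes: list[tuple[int, ...]] = []
            self.max_elements: int = 0
            self.enabled: bool = True

    def record(self, shape: tuple[int, ...]) -> None:
        if not self.enabled:
            return
        n = int(np.prod(shape)) if shape else 0
        with self._lock:
            self.shapes.append(tuple(int(d) for d in shape))
            if n > self.max_elements:
                self.max_elements = n


#: module-level tracker inspected by the memory-contract tests
tracker = AllocationTracker()


def dense_scratch(shape, dtype=np.float64) -> np.ndarray:
    """Allocate (and record) a dense scratch array."""
    tracker.record(tuple(shape))
    return np.empty(shape, dtype=dtype)


def dense_block(values, cols: np.ndarray) -> np.ndarray:
    """Dense copy of a column block of the expression matrix.

    `values` may be sparse (CSC preferred) or dense; the result is always a
    freshly written genes x len(cols) float64 array, recorded by the tracker.
    """
    out = dense_scratch((values.shape[0], len(cols)))
    if sp.issparse(values):
        out[...] = values[:, cols].toarray()
    else:
        out[...] = values[:, cols]
    return out
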