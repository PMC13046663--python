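"""Plain-text I/O for coalescence times.

Coalescence times travel as single-column CSV with header ``coal_time``, one
depth per row, in the order given (which is a valid CPP ladder order when the
file was written from a simulator sample).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import CoalescenceSample

__all__ = ["read_coal_times_csv", "write_coal_times_csv"]


def read_coal_times_csv(path) -> np.ndarray:
    """Read coalescence depths from a ``coal_time`` CSV."""
    frame = pd.read_csv(path, comment="#")
    if "coal_time" not in frame.columns:
        raise ValueError(f"{path}: expected a 'coal_time' column")
    return frame["coal_time"].to_numpy(dtype=float)


def write_coal_times_csv(path, depths) -> None:
    """Write depths (or a :class:`CoalescenceSample`) as a ``coal_time`` CSV."""
    if isinstance(depths, CoalescenceSample):
        depths = depths.depths
    pd.DataFrame({"coal_time": np.asarray(depths, dtype=float)}).to_csv(
        path, index=False
    )
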