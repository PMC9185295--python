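"""Sliding-window stacking of flow sequences into multi-channel images.

A window of T consecutive flow frames produces one 2T-channel image: the T
horizontal (u) fields followed by the T vertical (v) fields, concatenated
along the channel axis.  These stacked tensors are the inputs from which the
PCANet+ layers learn spatiotemporal filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .optical_flow import FlowSequence

logger = logging.getLogger(__name__)


def auto_step(T: int) -> int:
    """Default sliding-window step s = (T-1)/2, floored, but at least 1."""
    return max(1, (T - 1) // 2)


def n_windows(n_flow_frames: int, T: int, s: int) -> int:
    """Number of complete windows of length T at step s inside the sequence."""
    if n_flow_frames < T:
        raise InputError(
            f"flow sequence of {n_flow_frames} frames shorter than window T={T}"
        )
    return (n_flow_frames - T) // s + 1


@dataclass
class StackedSet:
    """Ordered 2T-channel tensors produced from one clip's flow sequence."""

    tensors: list[np.ndarray]
    T: int
    s: int
    source_clip_id: str = ""

    def __post_init__(self) -> None:
        for arr in self.tensors:
            if arr.ndim != 3 or arr.shape[2] != 2 * self.T:
                raise InputError(
                    f"stacked tensor must have 2T={2 * self.T} channels, "
                    f"got shape {arr.shape}"
                )

    def __len__(self) -> int:
        return len(self.tensors)


def stack_flow_sequence(
    flow: FlowSequence, T: int, s: int | None = None, *, clip_id: str = ""
) -> StackedSet:
    """Slide a window of T flow frames with step s and stack u- then v-fields.

    Window i (0-based) covers flow frames ``i*s .. i*s + T - 1``; the window
    count is ``(n_flow - T) // s + 1``, i.e. only complete windows inside the
    flow sequence are produced and trailing frames not covered by any window
    are dropped.  ``s=None`` derives the step as ``max(1, (T-1)//2)``.

    Each output tensor has shape (N, M, 2T): channels 0..T-1 are consecutive
    u-fields, channels T..2T-1 the corresponding v-fields.
    """
    if T < 1:
        raise InputError(f"window length T must be >= 1, got {T}")
    if s is None:
        s = auto_step(T)
    elif s <= 0:
        logger.warning("non-positive step s=%d corrected to s=1", s)
        s = 1
    n_flow = flow.n_fields
    count = n_windows(n_flow, T, s)
    tensors = []
    for i in range(count):
        start = i * s
        u_win = flow.U[:, :, start : start + T]
        v_win = flow.V[:, :, start : start + T]
        tensors.append(np.concatenate([u_win, v_win], axis=2))
    return StackedSet(tensors=tensors, T=T, s=s, source_clip_id=clip_id)
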