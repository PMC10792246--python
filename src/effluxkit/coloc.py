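"""Two-channel Pearson colocalization with nested replicate summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import UndefinedCorrelationError

__all__ = ["ImagePair", "ColocResult", "pearson_coloc", "summarize_coloc"]


@dataclass(frozen=True)
class ImagePair:
    """A registered two-channel image (transporter channel vs membrane marker).

    An optional boolean mask restricts the correlation to a pixel subset;
    at least 2 unmasked pixels are required.
    """

    channel_a: np.ndarray
    channel_b: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        a = np.asarray(self.channel_a, dtype=float)
        b = np.asarray(self.channel_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if a.size < 2:
            raise ValueError("need at least 2 pixels")
        if self.mask is not None and np.asarray(self.mask).shape != a.shape:
            raise ValueError("mask shape must match channels")
        object.__setattr__(self, "channel_a", a)
        object.__setattr__(self, "channel_b", b)

    @property
    def pixel_count(self) -> int:
        if self.mask is None:
            return int(self.channel_a.size)
        return int(np.count_nonzero(self.mask))


@dataclass(frozen=True)
class ColocResult:
    r: float
    n_pixels: int
    experiment_id: Optional[int] = None  # None = standalone image
    replicate_id: int = 1


def pearson_coloc(
    pair: ImagePair, experiment_id: Optional[int] = None, replicate_id: int = 1
) -> ColocResult:
    """Sample Pearson correlation over the unmasked pixels of a pair.

    Raises
    ------
    UndefinedCorrelationError
        If either channel is constant within the mask.
    ValueError
        If fewer than 2 unmasked pixels remain.
    """
    a = pair.channel_a.ravel()
    b = pair.channel_b.ravel()
    if pair.mask is not None:
        keep = np.asarray(pair.mask, dtype=bool).ravel()
        a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least 2 unmasked pixels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedCorrelationError("constant channel: correlation undefined")
    a = a - a.mean()
    b = b - b.mean()
    r = float(a.dot(b) / np.sqrt(a.dot(a) * b.dot(b)))
    r = min(1.0, max(-1.0, r))
    return ColocResult(
        r=r, n_pixels=int(a.size), experiment_id=experiment_id, replicate_id=replicate_id
    )


def summarize_coloc(results: Sequence[ColocResult]) -> tuple[float, float, int]:
    """Nested mean ± sample SD of colocalization coefficients.

    Replicates within each ``experiment_id`` are averaged first; the mean
    and SD are then taken across experiment means (n = number of
    experiments). Results without an experiment id each count as their own
    experiment, which reduces to the flat summary.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 results to summarize")
    by_exp: dict[object, list[float]] = {}
    for i, res in enumerate(results):
        key = ("solo", i) if res.experiment_id is None else ("exp", res.experiment_id)
        by_exp.setdefault(key, []).append(res.r)
    exp_means = np.array([np.mean(v) for v in by_exp.values()])
    if exp_means.size < 2:
        raise ValueError("need at least 2 experiments to summarize")
    return (
        float(exp_means.mean()),
        float(exp_means.std(ddof=1)),
        int(exp_means.size),
    )
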