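"""Densitometry-based protein quantification and treatment-response calls.

Total ABCA1 is the sum of both specific bands normalized to the lane's
β-actin; surface expression is the streptavidin pull-down signal corrected
for the sample's total protein. Treatment responses (proteasome-inhibitor
or chemical-chaperone rescue, ApoA1 stabilization) are one-tailed
F-test-gated t-tests against matched mock-treated arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .errors import BlotMatchError
from .stats import StatResult, auto_t_test

__all__ = [
    "BlotLane",
    "SurfaceMeasurement",
    "TreatmentResponse",
    "quantify_total",
    "surface_expression",
    "treatment_response",
    "stabilization_call",
]

CONDITIONS = ("mock_treated", "epoxomicin", "pba_4", "apoa1")


@dataclass(frozen=True)
class BlotLane:
    """One Western-blot lane: up to two ABCA1 bands plus β-actin."""

    construct: str
    band_intensities: tuple[float, ...]
    actin_intensity: float
    experiment_id: int = 1
    condition: str = "mock_treated"

    def __post_init__(self) -> None:
        if not 1 <= len(self.band_intensities) <= 2:
            raise ValueError("expect 1-2 ABCA1 bands per lane")
        if any(b < 0 for b in self.band_intensities):
            raise ValueError("band intensities must be >= 0")
        if self.actin_intensity <= 0:
            raise ValueError("actin intensity must be > 0")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def abca1_over_actin(self) -> float:
        return sum(self.band_intensities) / self.actin_intensity


@dataclass(frozen=True)
class SurfaceMeasurement:
    """Biotinylation pull-down signal with its matched total-protein level."""

    construct: str
    surface_signal: float
    total_level: float
    condition: str = "mock_treated"
    experiment_id: int = 1

    def __post_init__(self) -> None:
        if self.surface_signal < 0:
            raise ValueError("surface signal must be >= 0")
        if self.total_level <= 0:
            raise ValueError("total level must be > 0")


@dataclass(frozen=True)
class TreatmentResponse:
    construct: str
    condition: str
    fold_change: float
    p_value: float
    responder: bool
    stat: Optional[StatResult] = None


def quantify_total(lane: BlotLane, wt_lane: BlotLane) -> float:
    """Total ABCA1 as percent of the same-blot WT lane.

    100 * (sum(bands)/actin) / (sum(wt bands)/wt actin). Only the band sum
    matters; the split between the two bands is irrelevant.

    Raises
    ------
    BlotMatchError
        If the lanes come from different blots/experiments (cross-blot
        densitometry is not comparable).
    """
    if lane.experiment_id != wt_lane.experiment_id:
        raise BlotMatchError(
            f"lanes from different blots: {lane.experiment_id} vs {wt_lane.experiment_id}"
        )
    wt_ratio = wt_lane.abca1_over_actin
    if wt_ratio <= 0:
        raise ValueError("WT lane has zero ABCA1 signal")
    return 100.0 * lane.abca1_over_actin / wt_ratio


def surface_expression(m: SurfaceMeasurement, wt: SurfaceMeasurement) -> float:
    """Surface ABCA1 as percent of WT, corrected for total protein.

    100 * (surface/total) / (wt_surface/wt_total); invariant to common
    rescaling of a sample's signals.
    """
    if m.experiment_id != wt.experiment_id:
        raise BlotMatchError(
            f"measurements from different experiments: {m.experiment_id} vs {wt.experiment_id}"
        )
    wt_ratio = wt.surface_signal / wt.total_level
    if wt_ratio <= 0:
        raise ValueError("WT surface ratio is zero")
    return 100.0 * (m.surface_signal / m.total_level) / wt_ratio


def treatment_response(
    treated: Sequence[float],
    mock: Sequence[float],
    direction: Literal["increase", "decrease"] = "increase",
    construct: str = "",
    condition: str = "mock_treated",
    alpha: float = 0.05,
) -> TreatmentResponse:
    """Call a treatment response against matched mock-treated replicates.

    fold_change is the ratio of arm means. A responder needs a one-tailed
    p < alpha *and* an effect in the hypothesized direction (the direction
    gate applies regardless of p).
    """
    treated_arr = np.asarray(treated, dtype=float)
    mock_arr = np.asarray(mock, dtype=float)
    mock_mean = mock_arr.mean()
    if mock_mean == 0:
        raise ValueError("mock arm mean is zero; fold change undefined")
    fold = float(treated_arr.mean() / mock_mean)

    t_dir = "greater" if direction == "increase" else "less"
    stat = auto_t_test(treated_arr, mock_arr, tails=1, direction=t_dir)
    in_direction = fold > 1.0 if direction == "increase" else fold < 1.0
    return TreatmentResponse(
        construct=construct,
        condition=condition,
        fold_change=fold,
        p_value=stat.p_value,
        responder=bool(stat.p_value < alpha and in_direction),
        stat=stat,
    )


def stabilization_call(
    apoa1_surface: Sequence[float],
    mock_surface: Sequence[float],
    construct: str = "",
) -> TreatmentResponse:
    """ApoA1 stabilization of surface ABCA1 vs untreated cells.

    A responder (one-tailed increase, p < 0.05) is interpreted as
    retaining the ApoA1 interaction.
    """
    return treatment_response(
        apoa1_surface,
        mock_surface,
        direction="increase",
        construct=construct,
        condition="apoa1",
    )
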