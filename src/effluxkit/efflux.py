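"""Cholesterol-efflux computation: raw wells to WT-normalized activities.

The fixed correction order is

    fraction -> leakage correction -> mock subtraction
             -> (optional renilla adjustment) -> WT normalization

applied per experiment. Fractions, not raw signals, are corrected: mock
and variant wells carry different cell loads, so signal-level subtraction
would mix scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateWellError,
    ExperimentInvalidError,
    InsufficientReplicatesError,
    PairingError,
)

__all__ = [
    "MOCK",
    "WT",
    "WITH_ACCEPTOR",
    "NO_ACCEPTOR",
    "Well",
    "EffluxResult",
    "compute_efflux_fraction",
    "correct_leakage",
    "compute_specific_efflux",
    "normalize_to_wt",
    "renilla_adjust",
    "aggregate_replicates",
    "process_well_table",
    "summarize_activity",
    "read_well_table",
    "write_well_table",
]

MOCK = "MOCK"
WT = "WT"
WITH_ACCEPTOR = "with_acceptor"
NO_ACCEPTOR = "no_acceptor"

WELL_COLUMNS = [
    "construct",
    "condition",
    "medium",
    "lysate",
    "renilla",
    "experiment",
    "replicate",
]


@dataclass(frozen=True)
class Well:
    """One measured plate well."""

    construct: str
    condition: str
    medium_signal: float
    lysate_signal: float
    renilla: Optional[float] = None
    experiment_id: int = 1
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.medium_signal < 0 or self.lysate_signal < 0:
            raise ValueError("signals must be >= 0")
        if self.condition not in (WITH_ACCEPTOR, NO_ACCEPTOR):
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True)
class EffluxResult:
    """Per-construct, per-experiment corrected efflux."""

    construct: str
    experiment_id: int
    raw_fraction: float
    leakage_corrected_fraction: float
    specific_efflux: float
    relative_activity: float  # raw percent of WT, may be negative
    relative_activity_reported: float  # clamped at 0 for reporting
    n_replicates: int


def compute_efflux_fraction(medium: float, lysate: float) -> float:
    """Fraction of label in the medium: medium / (medium + lysate).

    Invariant to rescaling both signals by a common factor.

    Raises
    ------
    DegenerateWellError
        If both signals are zero.
    ValueError
        If either signal is negative.
    """
    if medium < 0 or lysate < 0:
        raise ValueError("signals must be >= 0")
    total = medium + lysate
    if total == 0:
        raise DegenerateWellError("medium + lysate == 0")
    return medium / total


def correct_leakage(fraction: float, leakage_fraction: float) -> float:
    """Subtract the acceptor-independent leakage fraction.

    Negative results are passed through (flagged downstream, never clamped
    here).
    """
    if not (0.0 <= fraction <= 1.0 and 0.0 <= leakage_fraction <= 1.0):
        raise ValueError("fractions must be in [0, 1]")
    return fraction - leakage_fraction


def compute_specific_efflux(construct_fraction: float, mock_fraction: float) -> float:
    """Subtract the unspecific (mock) efflux from a construct's fraction.

    Both inputs must already be leakage-corrected within the same
    experiment; negatives are retained.
    """
    return construct_fraction - mock_fraction


def normalize_to_wt(specific: float, wt_specific: float) -> tuple[float, float]:
    """Express specific efflux as percent of same-experiment WT.

    Returns ``(raw_percent, reported_percent)`` where the reported value
    clamps negatives to 0 while the raw value is retained for statistics.

    Raises
    ------
    ExperimentInvalidError
        If the WT specific efflux is not positive.
    """
    if wt_specific <= 0:
        raise ExperimentInvalidError(
            f"WT specific efflux must be > 0, got {wt_specific}"
        )
    raw = 100.0 * specific / wt_specific
    return raw, max(raw, 0.0)


def renilla_adjust(specific: float, renilla: float, wt_renilla: float) -> float:
    """Rescale specific efflux to common transfection efficiency.

    Multiplies by ``wt_renilla / renilla`` so a well transfected twice as
    efficiently as WT has its ABCA1-specific efflux halved. Optional step,
    off by default in the pipeline.
    """
    if renilla <= 0 or wt_renilla <= 0:
        raise ValueError("renilla luminescence must be > 0")
    return specific * (wt_renilla / renilla)


def aggregate_replicates(values: Sequence[float]) -> tuple[float, float, int]:
    """Mean, sample SD (n-1 denominator) and n across experiments.

    Raises
    ------
    InsufficientReplicatesError
        If fewer than 2 values are supplied.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise InsufficientReplicatesError(f"need n >= 2, got {arr.size}")
    return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)


def _well_fractions(df: pd.DataFrame) -> pd.Series:
    total = df["medium"] + df["lysate"]
    if (total <= 0).any():
        bad = df.loc[total <= 0, ["construct", "experiment", "replicate"]]
        raise DegenerateWellError(f"degenerate wells (zero total signal):\n{bad}")
    return df["medium"] / total


def process_well_table(
    wells: pd.DataFrame, renilla_normalize: bool = False
) -> pd.DataFrame:
    """Run the full correction chain on a well table.

    Parameters
    ----------
    wells : DataFrame
        Columns ``construct, condition, medium, lysate, renilla,
        experiment, replicate``. ``MOCK`` rows with condition
        ``no_acceptor`` supply the leakage estimate; ``MOCK`` with
        acceptor supplies the unspecific efflux; ``WT`` anchors the
        percent scale. Every experiment must contain all three.
    renilla_normalize : bool
        If True, rescale each construct well's specific efflux by the
        WT/construct renilla ratio before normalization.

    Returns
    -------
    DataFrame
        One row per (construct, experiment) with columns
        ``construct, experiment, raw_fraction, leakage_corrected_fraction,
        specific_efflux, relative_activity, relative_activity_reported,
        n_replicates``. WT rows come out at exactly 100 within each
        experiment; MOCK rows are omitted.
    """
    required = {"construct", "condition", "medium", "lysate", "experiment"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"well table missing columns: {sorted(missing)}")
    wells = wells.copy()
    if "replicate" not in wells.columns:
        wells["replicate"] = 1
    wells["fraction"] = _well_fractions(wells)

    rows: list[dict] = []
    for exp_id, exp in wells.groupby("experiment", sort=True):
        is_mock = exp["construct"] == MOCK
        leak_wells = exp[is_mock & (exp["condition"] == NO_ACCEPTOR)]
        mock_wells = exp[is_mock & (exp["condition"] == WITH_ACCEPTOR)]
        if leak_wells.empty:
            raise PairingError(f"experiment {exp_id}: no mock-no-acceptor well")
        if mock_wells.empty:
            raise PairingError(f"experiment {exp_id}: no mock well")

        leakage = float(leak_wells["fraction"].mean())
        mock_corrected = float(mock_wells["fraction"].mean()) - leakage

        constructs = exp[~is_mock & (exp["condition"] == WITH_ACCEPTOR)].copy()
        if WT not in set(constructs["construct"]):
            raise PairingError(f"experiment {exp_id}: no WT well")

        constructs["lc"] = constructs["fraction"] - leakage
        constructs["specific"] = constructs["lc"] - mock_corrected

        wt_rows = constructs[constructs["construct"] == WT]
        if renilla_normalize:
            if "renilla" not in constructs.columns or constructs["renilla"].isna().any():
                raise ValueError("renilla normalization requested but values missing")
            wt_renilla = float(wt_rows["renilla"].mean())
            constructs["specific"] = [
                renilla_adjust(s, r, wt_renilla)
                for s, r in zip(constructs["specific"], constructs["renilla"])
            ]
            wt_rows = constructs[constructs["construct"] == WT]

        wt_specific = float(wt_rows["specific"].mean())
        if wt_specific <= 0:
            raise ExperimentInvalidError(
                f"experiment {exp_id}: WT specific efflux {wt_specific:.4g} <= 0"
            )

        for name, grp in constructs.groupby("construct", sort=True):
            specific = float(grp["specific"].mean())
            raw_pct, reported_pct = normalize_to_wt(specific, wt_specific)
            rows.append(
                {
                    "construct": name,
                    "experiment": exp_id,
                    "raw_fraction": float(grp["fraction"].mean()),
                    "leakage_corrected_fraction": float(grp["lc"].mean()),
                    "specific_efflux": specific,
                    "relative_activity": raw_pct,
                    "relative_activity_reported": reported_pct,
                    "n_replicates": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)


def summarize_activity(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-experiment activities into mean ± SD per construct."""
    out = []
    for name, grp in results.groupby("construct", sort=True):
        mean, sd, n = aggregate_replicates(grp["relative_activity"].to_list())
        out.append(
            {
                "construct": name,
                "mean_activity": mean,
                "sd": sd,
                "n": n,
                "mean_activity_reported": max(mean, 0.0),
            }
        )
    return pd.DataFrame(out)


def read_well_table(path: str) -> pd.DataFrame:
    """Read a TSV well table written by :func:`write_well_table`."""
    df = pd.read_csv(path, sep="\t")
    return df


def write_well_table(wells: pd.DataFrame, path: str) -> None:
    cols = [c for c in WELL_COLUMNS if c in wells.columns]
    wells.to_csv(path, sep="\t", index=False, columns=cols)
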