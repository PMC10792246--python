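"""Synthetic-data generators with known ground truth for every pipeline stage.

All noise is multiplicative lognormal (fluorescence and densitometry are
scale-positive). A single seed is fanned out into independent per-stage
substreams via ``numpy.random.SeedSequence.spawn`` so adding a stage never
perturbs the draws of an earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import AMINO_ACIDS, Variant, parse_hgvs_p
from .efflux import MOCK, NO_ACCEPTOR, WELL_COLUMNS, WITH_ACCEPTOR, WT
from .errors import MsaMappingError, SimBoundsError

__all__ = [
    "SimConfig",
    "simulate_plate",
    "simulate_blots",
    "simulate_surface",
    "simulate_msa",
    "simulate_image_pair",
]

# Substream indices for the per-stage RNG fan-out.
_STREAM_PLATE = 0
_STREAM_BLOTS = 1
_STREAM_MSA = 2
_STREAM_IMAGES = 3
_STREAM_SURFACE = 4

_LOAD_MEAN = 1000.0  # arbitrary RFU scale of total per-well label
_RENILLA_SCALE = 1000.0


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated study.

    ``constructs`` maps construct name to its true relative activity in
    percent of WT. ``treatment_effects`` maps a treatment condition to a
    per-construct ``(total_protein_fold, surface_fold, activity_fold)``
    triple relative to mock-treated.
    """

    seed: int = 0
    n_experiments: int = 4
    constructs: tuple[tuple[str, float], ...] = ()
    wt_true_specific_efflux: float = 0.25
    leakage_fraction: float = 0.05
    mock_unspecific_efflux: float = 0.04
    load_cv: float = 0.15
    noise_cv: float = 0.10
    renilla_cv: float = 0.0
    wells_per_construct: int = 1
    total_protein_levels: Mapping[str, float] = field(default_factory=dict)
    surface_levels: Mapping[str, float] = field(default_factory=dict)
    wt_blot_ratio: float = 1.0  # (band1+band2)/actin for WT at level 1.0
    treatment_effects: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for name, frac in [
            ("wt_true_specific_efflux", self.wt_true_specific_efflux),
            ("leakage_fraction", self.leakage_fraction),
            ("mock_unspecific_efflux", self.mock_unspecific_efflux),
        ]:
            if not 0.0 <= frac < 1.0:
                raise SimBoundsError(f"{name} must be in [0, 1), got {frac}")
        if self.wt_true_specific_efflux + self.leakage_fraction >= 1.0:
            raise SimBoundsError(
                "wt_true_specific_efflux + leakage_fraction must be < 1"
            )
        if self.n_experiments < 2:
            raise SimBoundsError("n_experiments must be >= 2")
        for cv in (self.load_cv, self.noise_cv, self.renilla_cv):
            if cv < 0:
                raise SimBoundsError("CVs must be >= 0")
        for name, activity in self.constructs:
            frac = self._true_fraction(activity)
            if frac >= 1.0:
                raise SimBoundsError(
                    f"construct {name!r}: activity {activity}% implies efflux "
                    f"fraction {frac:.3f} >= 1"
                )

    def _true_fraction(self, activity: float) -> float:
        return (
            self.wt_true_specific_efflux * activity / 100.0
            + self.mock_unspecific_efflux
            + self.leakage_fraction
        )

    def rng(self, stream: int) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(5)
        return np.random.default_rng(children[stream])


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size=None
) -> np.ndarray | float:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size) if size is not None else 1.0
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


def simulate_plate(config: SimConfig) -> pd.DataFrame:
    """Simulate one well table covering all experiments and constructs.

    Per experiment the plate carries each configured construct plus WT
    (activity 100), one mock well with acceptor and one mock well without
    acceptor. The well's total label T is lognormal around a common load;
    the medium/lysate split follows the construct's true efflux fraction
    (ABCA1-specific efflux scaled by a per-well transfection factor that
    is reported as renilla luminescence, plus the unspecific mock efflux
    and the acceptor-independent leakage); each signal then gets
    independent multiplicative measurement noise.
    """
    rng = config.rng(_STREAM_PLATE)
    rows: list[dict] = []
    panel: list[tuple[str, float]] = [(WT, 100.0)] + list(config.constructs)
    for exp in range(1, config.n_experiments + 1):
        for name, activity in panel:
            for rep in range(1, config.wells_per_construct + 1):
                total = _LOAD_MEAN * _lognormal_factor(rng, config.load_cv)
                f = _lognormal_factor(rng, config.renilla_cv)
                specific = f * config.wt_true_specific_efflux * activity / 100.0
                frac = specific + config.mock_unspecific_efflux + config.leakage_fraction
                frac = float(np.clip(frac, 0.0, 0.999))
                rows.append(
                    _well_row(rng, config, name, WITH_ACCEPTOR, total, frac,
                              renilla=_RENILLA_SCALE * f, exp=exp, rep=rep)
                )
        for rep in range(1, config.wells_per_construct + 1):
            total = _LOAD_MEAN * _lognormal_factor(rng, config.load_cv)
            frac = config.mock_unspecific_efflux + config.leakage_fraction
            rows.append(
                _well_row(rng, config, MOCK, WITH_ACCEPTOR, total, frac,
                          renilla=np.nan, exp=exp, rep=rep)
            )
            total = _LOAD_MEAN * _lognormal_factor(rng, config.load_cv)
            rows.append(
                _well_row(rng, config, MOCK, NO_ACCEPTOR, total,
                          config.leakage_fraction, renilla=np.nan, exp=exp, rep=rep)
            )
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


def _well_row(rng, config, construct, condition, total, frac, renilla, exp, rep):
    medium = total * frac * _lognormal_factor(rng, config.noise_cv)
    lysate = total * (1.0 - frac) * _lognormal_factor(rng, config.noise_cv)
    return {
        "construct": construct,
        "condition": condition,
        "medium": float(medium),
        "lysate": float(lysate),
        "renilla": float(renilla) if np.isfinite(renilla) else np.nan,
        "experiment": exp,
        "replicate": rep,
    }


def _total_level(config: SimConfig, name: str) -> float:
    if name == MOCK:
        return 0.0
    return float(config.total_protein_levels.get(name, 1.0))


def simulate_blots(config: SimConfig, conditions: Sequence[str] = ("mock_treated",)) -> pd.DataFrame:
    """Simulate densitometry lanes: two ABCA1 bands plus β-actin per lane.

    The band sum is proportional to the construct's true total-protein
    level (times the condition's total-protein fold, if any); the split
    between the two bands is random and carries no information. Columns:
    ``construct, condition, band1, band2, actin, experiment``.
    """
    rng = config.rng(_STREAM_BLOTS)
    rows = []
    panel = [WT] + [name for name, _ in config.constructs]
    for exp in range(1, config.n_experiments + 1):
        for cond in conditions:
            for name in panel:
                level = _total_level(config, name)
                if cond != "mock_treated":
                    fold = config.treatment_effects.get(cond, {}).get(name, (1.0, 1.0, 1.0))[0]
                    level *= fold
                actin = 1000.0 * _lognormal_factor(rng, config.noise_cv)
                total = (
                    config.wt_blot_ratio
                    * level
                    * 1000.0
                    * _lognormal_factor(rng, config.noise_cv)
                )
                split = rng.uniform(0.3, 0.7) if level > 0 else 0.5
                rows.append(
                    {
                        "construct": name,
                        "condition": cond,
                        "band1": float(total * split),
                        "band2": float(total * (1.0 - split)),
                        "actin": float(actin),
                        "experiment": exp,
                    }
                )
    return pd.DataFrame(rows)


def simulate_surface(
    config: SimConfig, conditions: Sequence[str] = ("mock_treated",)
) -> pd.DataFrame:
    """Simulate surface-biotinylation pull-down measurements.

    The pull-down signal is proportional to the construct's true surface
    level (times the condition's surface fold); the matched ``total``
    column carries the sample's normalized total-protein level so that
    surface/total recovers the configured surface fraction. Columns:
    ``construct, condition, surface, total, experiment``.
    """
    rng = config.rng(_STREAM_SURFACE)
    rows = []
    panel = [WT] + [name for name, _ in config.constructs]
    for exp in range(1, config.n_experiments + 1):
        for cond in conditions:
            for name in panel:
                total = _total_level(config, name)
                surface = float(config.surface_levels.get(name, total))
                if cond != "mock_treated":
                    folds = config.treatment_effects.get(cond, {}).get(name, (1.0, 1.0, 1.0))
                    total *= folds[0]
                    surface *= folds[1]
                if total <= 0:
                    continue
                rows.append(
                    {
                        "construct": name,
                        "condition": cond,
                        "surface": float(
                            1000.0 * surface * _lognormal_factor(rng, config.noise_cv)
                        ),
                        "total": float(total * _lognormal_factor(rng, config.noise_cv)),
                        "experiment": exp,
                    }
                )
    return pd.DataFrame(rows)


def simulate_msa(
    n_species: int = 29,
    variant_support: Mapping[Variant | str, int] | None = None,
    seed: int = 0,
    length: Optional[int] = None,
    human_id: str = "human",
) -> MultipleSeqAlignment:
    """Build a vertebrate-panel-style protein alignment with known support.

    The human row carries the reference residue of every variant at its
    position; for each variant exactly ``variant_support[variant]``
    non-human species carry the alternate residue at the aligned column.

    Parameters
    ----------
    n_species : int
        Number of non-human species (default mirrors the 29-species
        vertebrate panel).
    variant_support : mapping Variant (or hgvs string) -> count
        Desired number of species showing the alt residue as reference.
    """
    rng = np.random.default_rng(seed)
    support: dict[Variant, int] = {}
    for key, count in (variant_support or {}).items():
        var = parse_hgvs_p(key) if isinstance(key, str) else key
        if count > n_species:
            raise ValueError(
                f"support {count} for {var} exceeds n_species={n_species}"
            )
        support[var] = int(count)

    max_pos = max((v.position for v in support), default=10)
    if length is None:
        length = max_pos + 5
    if max_pos > length:
        raise MsaMappingError(f"variant position {max_pos} outside length {length}")

    aa_list = sorted(AMINO_ACIDS)
    human = rng.choice(aa_list, size=length)
    for var in support:
        human[var.position - 1] = var.ref_aa

    rows = np.tile(human, (n_species, 1))
    for var, count in support.items():
        col = var.position - 1
        carriers = rng.choice(n_species, size=count, replace=False)
        rows[:, col] = var.ref_aa
        rows[carriers, col] = var.alt_aa

    records = [SeqRecord(Seq("".join(human)), id=human_id, description="")]
    for i in range(n_species):
        records.append(
            SeqRecord(Seq("".join(rows[i])), id=f"species_{i + 1:02d}", description="")
        )
    return MultipleSeqAlignment(records)


def simulate_image_pair(
    target_r: float,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    exact: bool = False,
    offset: float = 1000.0,
    scale: float = 100.0,
    clip: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two non-negative intensity images with Pearson correlation target_r.

    Default mode draws a shared-component Gaussian mixture whose
    *population* correlation is ``target_r`` (sample correlation varies by
    ~1/sqrt(n_pixels)). With ``exact=True`` the second channel is built
    from the sample-orthogonalized residual so the *sample* correlation
    equals ``target_r`` to numerical precision.

    Intensities are ``offset + scale * z``; with the defaults negative
    pixels are a >5-sigma event, and ``clip`` (off by default, since it
    perturbs the correlation) floors them at 0.
    """
    if not -1.0 <= target_r <= 1.0:
        raise ValueError(f"target_r must be in [-1, 1], got {target_r}")
    n = int(np.prod(shape))
    if n < 2:
        raise ValueError(f"degenerate shape {shape}: need >= 2 pixels")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)

    if exact:
        z1 = (z1 - z1.mean()) / z1.std()
        resid = z2 - z2.mean() - (z1 @ (z2 - z2.mean()) / n) * z1
        norm = resid.std()
        resid = resid / norm if norm > 0 else resid
        y = target_r * z1 + np.sqrt(1.0 - target_r**2) * resid
        x = z1
    else:
        rho = abs(target_r)
        sign = 1.0 if target_r >= 0 else -1.0
        x = np.sqrt(rho) * z1 + np.sqrt(1.0 - rho) * z2
        e = rng.standard_normal(n)
        y = sign * np.sqrt(rho) * z1 + np.sqrt(1.0 - rho) * e

    a = offset + scale * x.reshape(shape)
    b = offset + scale * y.reshape(shape)
    if clip:
        a = np.clip(a, 0.0, None)
        b = np.clip(b, 0.0, None)
    return a, b
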