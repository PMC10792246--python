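"""Study-shaped synthetic fixture: 51 query variants, 5 controls, 29-species MSA.

The panel mirrors the shape of the real study: 45 database-reported
variants, 5 novel patient-derived variants and 1 additional literature
variant (51 queries total), five characterized loss-of-function controls,
four efflux experiments, a 29-species vertebrate alignment in which 10 of
the queries are conservation-supported, and confocal image pairs at four
colocalization levels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from .efflux import write_well_table
from .simulate import SimConfig, simulate_blots, simulate_msa, simulate_plate, simulate_surface

__all__ = [
    "QUERY_PANEL",
    "CONTROL_PANEL",
    "CALIBRATION_SUPPORT",
    "COLOC_TARGETS",
    "make_fixtures",
    "load_variant_table",
]

# (hgvs_p, true_activity %WT, source) — sources: hgmd | novel | literature
_LOF = [
    ("p.E284K", 30.0), ("p.R306C", 35.0), ("p.Y482C", 28.0), ("p.T483P", 22.0),
    ("p.L510R", 8.0), ("p.R579Q", 33.0), ("p.G616V", 18.0), ("p.Q621R", 38.0),
    ("p.G790D", 6.0), ("p.L1379F", 40.0), ("p.H1600R", 12.0), ("p.R1615W", 25.0),
]
_CALIBRATION = [
    ("p.R130K", 79.0), ("p.D176N", 88.0), ("p.R219K", 95.0), ("p.M233V", 101.0),
    ("p.P250L", 80.0), ("p.V380I", 110.0), ("p.V589I", 82.0), ("p.T774P", 97.0),
    ("p.T1427M", 85.0), ("p.R1587K", 93.0),
]
_GATEWAY_VUS = [
    ("p.N567Y", 62.0), ("p.D571G", 58.0), ("p.D575G", 66.0),
    ("p.D585E", 71.0), ("p.G592C", 55.0),
]
_LITERATURE = [("p.Y793C", 68.0)]
_NOVEL = [
    ("p.A141T", 90.0), ("p.S162F", 60.0), ("p.D212Y", 45.0),
    ("p.K475N", 73.0), ("p.N1524S", 96.0),
]
_FILLER_HGMD = [
    ("p.G316R", 52.0), ("p.T349I", 88.0), ("p.R360W", 64.0), ("p.L404P", 35.0),
    ("p.E447K", 92.0), ("p.F527L", 70.0), ("p.M595V", 86.0), ("p.C641Y", 48.0),
    ("p.P685L", 75.0), ("p.H721R", 99.0), ("p.V752M", 83.0), ("p.I815T", 67.0),
    ("p.Q854H", 91.0), ("p.D921N", 57.0), ("p.S1376C", 78.0), ("p.Y1410H", 94.0),
    ("p.E1466G", 61.0), ("p.R1554C", 87.0),
]

QUERY_PANEL: tuple[tuple[str, float, str], ...] = tuple(
    [(v, a, "hgmd") for v, a in _LOF + _CALIBRATION + _GATEWAY_VUS + _FILLER_HGMD]
    + [(v, a, "novel") for v, a in _NOVEL]
    + [(v, a, "literature") for v, a in _LITERATURE]
)

# Five characterized loss-of-function controls; the highest-activity one
# anchors the pathogenic cutoff at 50% of WT.
CONTROL_PANEL: tuple[tuple[str, float, str], ...] = (
    ("p.W590S", 50.0, "pathogenic_control"),
    ("p.R587W", 30.0, "pathogenic_control"),
    ("p.C1477R", 42.0, "pathogenic_control"),
    ("p.Y1767D", 25.0, "pathogenic_control"),
    ("p.K939M", 18.0, "negative_control"),
)

# Conservation support (species carrying the alt residue as reference);
# the 10 calibration variants exceed the >2-species rule, everything else
# stays at or below it.
CALIBRATION_SUPPORT: dict[str, int] = {v: 3 + (i % 7) for i, (v, _) in enumerate(_CALIBRATION)}
_NON_CALIBRATION_SUPPORT: dict[str, int] = {
    "p.E284K": 1, "p.N567Y": 2, "p.Y793C": 0, "p.W590S": 0, "p.K939M": 0,
}

# Confocal colocalization ground truth (construct -> generative r).
COLOC_TARGETS: dict[str, float] = {
    "WT": 0.26,
    "p.H1600R": 0.12,
    "p.C1477R": 0.11,
    "p.L510R": 0.01,
}

_RESCUE_EPOX = {"p.E284K", "p.R306C", "p.Y482C"}
_RESCUE_PBA = _RESCUE_EPOX | {"p.T483P", "p.R579Q", "p.Q621R", "p.L1379F"}
_APOA1_RESPONDERS = {"WT", "p.R306C", "p.Y482C", "p.R579Q", "p.Q621R", "p.L1379F", "p.C1477R"}


def _treatment_effects(constructs: list[str]) -> dict:
    """(total_fold, surface_fold, activity_fold) per condition and construct."""
    effects: dict[str, dict[str, tuple[float, float, float]]] = {
        "epoxomicin": {},
        "pba_4": {},
        "apoa1": {},
    }
    for name in constructs + ["WT"]:
        act_epox = 1.8 if name in _RESCUE_EPOX else 1.0
        act_pba = 1.8 if name in _RESCUE_PBA else 1.0
        effects["epoxomicin"][name] = (2.0, 2.5, act_epox)
        effects["pba_4"][name] = (1.8, 2.0 if name != "p.G790D" else 1.0, act_pba)
        surf_apoa1 = 1.5 if name in _APOA1_RESPONDERS else 1.0
        effects["apoa1"][name] = (1.0, surf_apoa1, 1.0)
    return effects


def build_sim_config(seed: int = 0, noise_cv: float = 0.05, load_cv: float = 0.10) -> SimConfig:
    """SimConfig for the full study-shaped panel (56 constructs + WT)."""
    constructs = [(v, a) for v, a, _ in QUERY_PANEL] + [
        (v, a) for v, a, _ in CONTROL_PANEL
    ]
    names = [v for v, _ in constructs]
    # Total protein roughly tracks activity for LOF variants, normal otherwise.
    totals = {v: max(0.3, min(1.0, a / 100.0 + 0.25)) for v, a in constructs}
    surfaces = {v: max(0.05, a / 100.0 * totals[v]) for v, a in constructs}
    surfaces["p.W590S"] = totals["p.W590S"]  # surface-normal controls
    surfaces["p.K939M"] = totals["p.K939M"]
    return SimConfig(
        seed=seed,
        n_experiments=4,
        constructs=tuple(constructs),
        wt_true_specific_efflux=0.25,
        leakage_fraction=0.05,
        mock_unspecific_efflux=0.04,
        load_cv=load_cv,
        noise_cv=noise_cv,
        renilla_cv=0.08,
        total_protein_levels=totals,
        surface_levels=surfaces,
        treatment_effects=_treatment_effects(names),
    )


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the complete study-shaped fixture set into ``out_dir``.

    Emits: ``wells.tsv``, ``blots.tsv``, ``surface.tsv``, ``variants.tsv``,
    ``msa.fasta``, per-construct 16-bit TIFF image pairs under ``images/``
    and a ``ground_truth.json`` sidecar. Returns the path of every file
    written, keyed by role.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = build_sim_config(seed=seed)

    paths: dict[str, Path] = {}

    wells = simulate_plate(config)
    paths["wells"] = out / "wells.tsv"
    write_well_table(wells, paths["wells"])

    blots = simulate_blots(config, conditions=("mock_treated", "epoxomicin", "pba_4"))
    paths["blots"] = out / "blots.tsv"
    blots.to_csv(paths["blots"], sep="\t", index=False)

    surface = simulate_surface(
        config, conditions=("mock_treated", "epoxomicin", "pba_4", "apoa1")
    )
    paths["surface"] = out / "surface.tsv"
    surface.to_csv(paths["surface"], sep="\t", index=False)

    variants = pd.DataFrame(
        [
            {"hgvs_p": v, "role": "query", "source": src}
            for v, _, src in QUERY_PANEL
        ]
        + [
            {"hgvs_p": v, "role": role, "source": "control"}
            for v, _, role in CONTROL_PANEL
        ]
    )
    paths["variants"] = out / "variants.tsv"
    variants.to_csv(paths["variants"], sep="\t", index=False)

    # Pin every panel variant's reference residue in the alignment (support
    # defaults to 0) so no alt residue appears by coincidence.
    support = {v: 0 for v, _, _ in QUERY_PANEL}
    support.update({v: 0 for v, _, _ in CONTROL_PANEL})
    support.update(CALIBRATION_SUPPORT)
    support.update(_NON_CALIBRATION_SUPPORT)
    msa = simulate_msa(n_species=29, variant_support=support, seed=seed, length=1800)
    paths["msa"] = out / "msa.fasta"
    AlignIO.write(msa, paths["msa"], "fasta")

    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    from .simulate import simulate_image_pair

    img_seed = seed
    image_index = []
    for construct, r in COLOC_TARGETS.items():
        safe = construct.replace("p.", "")
        for exp in range(1, 4):
            for rep in range(1, 4):
                img_seed += 1
                a, b = simulate_image_pair(r, shape=(128, 128), seed=img_seed)
                pa = img_dir / f"{safe}_e{exp}_r{rep}_a.tif"
                pb = img_dir / f"{safe}_e{exp}_r{rep}_b.tif"
                tifffile.imwrite(pa, np.round(a).astype(np.uint16))
                tifffile.imwrite(pb, np.round(b).astype(np.uint16))
                image_index.append(
                    {
                        "construct": construct,
                        "experiment": exp,
                        "replicate": rep,
                        "channel_a": str(pa.relative_to(out)),
                        "channel_b": str(pb.relative_to(out)),
                    }
                )
    paths["image_index"] = out / "images.tsv"
    pd.DataFrame(image_index).to_csv(paths["image_index"], sep="\t", index=False)

    truth = {
        "seed": seed,
        "true_relative_activity": {v: a for v, a, _ in QUERY_PANEL}
        | {v: a for v, a, _ in CONTROL_PANEL},
        "sources": {"hgmd": 45, "novel": 5, "literature": 1},
        "conservation_support": support,
        "coloc_targets": COLOC_TARGETS,
        "treatment_effects": {
            cond: {k: list(v) for k, v in per.items()}
            for cond, per in config.treatment_effects.items()
        },
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2))
    return paths


def load_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variants.tsv (columns hgvs_p, role, optional source)."""
    df = pd.read_csv(path, sep="\t")
    if "hgvs_p" not in df.columns or "role" not in df.columns:
        raise ValueError("variant table needs hgvs_p and role columns")
    return df
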