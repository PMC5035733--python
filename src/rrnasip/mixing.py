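"""Two-pool delta-13C mixing model and carbon-budget bookkeeping.

Quantifies the share of a carbon pool (respired CO2, microbial biomass
carbon, or a PLFA biomarker pool) that derives from an isotopically
distinct substrate amendment:

    % substrate-derived C = (delta_sample - delta_reference)
                            / (delta_substrate - delta_soil) * 100

with delta_reference the mean delta-13C of unamended controls,
delta_substrate the amendment's signature and delta_soil the soil organic
carbon signature at the start of the incubation. The model is linear, so
measurement noise propagates additively; values outside [0, 100] are
reported with a quality flag rather than clipped, since clipping would
hide measurement problems.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_BACTERIAL_MARKERS",
    "DEFAULT_FUNGAL_MARKERS",
    "substrate_derived_fraction",
    "pool_delta13c",
    "cumulative_mineralized_percent",
    "amendment_per_gram",
    "mixing_table",
    "summarize_mixing",
]

# PLFA biomarker defaults; the fungal marker 18:2w6,9 also occurs in plant
# tissue, so plant-biomass treatments get a warning when it is pooled.
DEFAULT_BACTERIAL_MARKERS = (
    "i15:0",
    "a15:0",
    "i16:0",
    "16:1w7",
    "18:1w7",
    "cy17:0",
    "cy19:0",
)
DEFAULT_FUNGAL_MARKERS = ("18:2w6,9",)
PLANT_CONFOUNDED_MARKERS = frozenset({"18:2w6,9"})


def substrate_derived_fraction(
    delta_sample,
    delta_reference: float,
    delta_substrate: float,
    delta_soil: float,
):
    """Percent of pool carbon derived from the amended substrate.

    Accepts a scalar or array of sample delta-13C values (per mil). May fall
    outside [0, 100] with noisy inputs; callers flag rather than clip.
    """
    if delta_substrate == delta_soil:
        raise ValueError(
            "delta_substrate equals delta_soil: the two end-members are "
            "isotopically indistinguishable and the mixing model is undefined"
        )
    d = np.asarray(delta_sample, dtype=float)
    pct = (d - delta_reference) / (delta_substrate - delta_soil) * 100.0
    return float(pct) if pct.ndim == 0 else pct


def pool_delta13c(
    plfa_deltas: Mapping[str, float],
    plfa_concentrations: Mapping[str, float],
    markers: Sequence[str],
) -> float:
    """Concentration-weighted mean delta-13C over a PLFA marker set.

    ``plfa_deltas`` in per mil, ``plfa_concentrations`` in nmol per g soil
    (any common unit works, only relative weights matter). Markers missing
    from the measurements are reported by name.
    """
    if not markers:
        raise ValueError("marker set is empty")
    missing = [m for m in markers if m not in plfa_deltas or m not in plfa_concentrations]
    if missing:
        raise KeyError(f"markers not measured: {missing}")
    w = np.array([plfa_concentrations[m] for m in markers], dtype=float)
    d = np.array([plfa_deltas[m] for m in markers], dtype=float)
    if np.any(w < 0):
        raise ValueError("negative PLFA concentration")
    if w.sum() <= 0:
        raise ValueError("no positive concentration among markers")
    return float(np.sum(w * d) / w.sum())


def cumulative_mineralized_percent(cumulative_co2_c, added_c: float):
    """Percent of added carbon mineralized, per timepoint.

    ``cumulative_co2_c`` is the non-decreasing cumulative substrate-derived
    CO2-C series (mg) and ``added_c`` the amendment carbon (mg).
    """
    if added_c <= 0:
        raise ValueError("added_c must be > 0")
    c = np.asarray(cumulative_co2_c, dtype=float)
    if np.any(c < 0):
        raise ValueError("cumulative CO2-C cannot be negative")
    if c.ndim > 0 and np.any(np.diff(c) < 0):
        raise ValueError("cumulative CO2-C series decreases; data integrity error")
    pct = 100.0 * c / added_c
    return float(pct) if pct.ndim == 0 else pct


def amendment_per_gram(added_c_mg: float, soil_mass_g: float) -> float:
    """Amendment carbon normalized to soil mass (ug C per g dry soil)."""
    if soil_mass_g <= 0:
        raise ValueError("soil_mass_g must be > 0")
    if added_c_mg < 0:
        raise ValueError("added_c_mg cannot be negative")
    return 1000.0 * added_c_mg / soil_mass_g


def mixing_table(
    measurements: pd.DataFrame,
    substrate_deltas: Mapping[str, float],
    delta_soil: float,
    reference_treatment: str = "control",
    plant_treatments: Sequence[str] = (),
) -> pd.DataFrame:
    """Apply the mixing model to a long-format delta-13C measurement table.

    ``measurements`` has columns pool, treatment, timepoint, replicate,
    delta13C; rows with ``treatment == reference_treatment`` define
    delta_reference as the mean over control replicates of the same pool
    and timepoint (timepoint matching absorbs temporal drift of the
    background signature). Returns per-replicate percent substrate-derived
    C with an ``out_of_range`` flag for values outside [0, 100].
    """
    required = {"pool", "treatment", "timepoint", "replicate", "delta13C"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurements missing columns: {sorted(missing)}")
    controls = measurements[measurements["treatment"] == reference_treatment]
    if controls.empty:
        raise ValueError(f"no rows with reference treatment {reference_treatment!r}")
    ref = controls.groupby(["pool", "timepoint"])["delta13C"].mean()

    samples = measurements[measurements["treatment"] != reference_treatment].copy()
    unknown = set(samples["treatment"]) - set(substrate_deltas)
    if unknown:
        raise ValueError(f"no delta_substrate supplied for treatments: {sorted(unknown)}")

    rows = []
    for _, row in samples.iterrows():
        key = (row["pool"], row["timepoint"])
        if key not in ref.index:
            raise ValueError(f"no control measurements for pool/timepoint {key}")
        pct = substrate_derived_fraction(
            row["delta13C"], ref.loc[key], substrate_deltas[row["treatment"]], delta_soil
        )
        plant_confounded = (
            row["treatment"] in set(plant_treatments)
            and str(row["pool"]).startswith("PLFA")
        )
        rows.append(
            {
                "pool": row["pool"],
                "treatment": row["treatment"],
                "timepoint": row["timepoint"],
                "replicate": row["replicate"],
                "delta13C": row["delta13C"],
                "pct_substrate_c": pct,
                "out_of_range": not 0.0 <= pct <= 100.0,
                "plant_plfa_caveat": plant_confounded,
            }
        )
    out = pd.DataFrame(rows)
    if out["plant_plfa_caveat"].any():
        warnings.warn(
            "fungal PLFA markers in plant-biomass treatments may include "
            "plant-derived fatty acids; interpret pooled delta-13C with care",
            stacklevel=2,
        )
    return out


def summarize_mixing(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of percent substrate-derived C per cell."""
    g = per_replicate.groupby(["pool", "treatment", "timepoint"])["pct_substrate_c"]
    out = g.agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
    return out.reset_index()
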