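"""Chip-level assay calculators.

Apparent permeability of the epithelial barrier from tracer transfer,
CFU accounting for effluent/digest bacterial enumeration, epithelial
viability, and cytokine fold-change tables. All functions are pure
arithmetic on bench-unit inputs (cm, mL, s); statistical testing is out of
scope here and done downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PermeabilityInputs",
    "CfuRecord",
    "CfuSummary",
    "apparent_permeability",
    "total_cfu_per_chip",
    "percent_adherence",
    "percent_viability",
    "fold_change_table",
]


@dataclass(frozen=True)
class PermeabilityInputs:
    """One tracer transfer measurement.

    Volumes in mL (== cm^3), area in cm^2, time in s; receiving (C_r) and
    dosing-outlet (C_d_out) tracer concentrations in any common unit.
    """

    V_r_ml: float
    V_d_ml: float
    area_cm2: float
    time_s: float
    C_r: float
    C_d_out: float

    def __post_init__(self) -> None:
        for name in ("V_r_ml", "V_d_ml", "area_cm2", "time_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.C_r < 0 or self.C_d_out < 0:
            raise ValueError("concentrations must be >= 0")
        if self.C_r > self.C_d_out:
            warnings.warn(
                "receiving concentration exceeds dosing-effluent "
                "concentration; check channel assignment", stacklevel=2)


def apparent_permeability(p: PermeabilityInputs) -> float:
    """Apparent permeability P_app (cm/s) of the barrier.

        P_app = (V_r * C_r) / (A * t * C_donor)
        C_donor = (C_d_out * V_d + C_r * V_r) / (V_d + V_r)

    The donor concentration is the volume-weighted mean over both effluents,
    so P_app is invariant to rescaling both concentrations together.
    """
    c_donor = (p.C_d_out * p.V_d_ml + p.C_r * p.V_r_ml) / (p.V_d_ml + p.V_r_ml)
    denom = p.area_cm2 * p.time_s * c_donor
    if denom == 0:
        raise ZeroDivisionError(
            "donor concentration is zero: P_app undefined")
    return (p.V_r_ml * p.C_r) / denom


@dataclass(frozen=True)
class CfuRecord:
    """One enumeration sample: CFU density and the volume it represents."""

    timepoint_h: float | str       # 24, 48, 72 or "T0"
    compartment: str               # effluent | digest | inoculum
    cfu_per_ml: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.compartment not in ("effluent", "digest", "inoculum"):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.cfu_per_ml < 0:
            raise ValueError("cfu_per_ml must be >= 0")
        if self.volume_ml <= 0:
            raise ValueError("volume_ml must be > 0")

    @property
    def cfu(self) -> float:
        return self.cfu_per_ml * self.volume_ml


@dataclass(frozen=True)
class CfuSummary:
    per_record: pd.DataFrame       # timepoint_h, compartment, cfu
    total_effluent: float
    digest: float | None
    total: float | None            # effluents + digest; None without digest
    inoculum: float | None


def total_cfu_per_chip(records: list[CfuRecord],
                       require_digest: bool = True) -> CfuSummary:
    """CFU/chip per record and cumulative totals.

    Each record contributes ``cfu_per_ml * volume_ml``; the cumulative total
    sums all effluent collections plus the 72-h digest. If ``require_digest``
    and no digest record exists, the cumulative total cannot be formed and an
    error is raised.
    """
    if not records:
        raise ValueError("no CFU records")
    df = pd.DataFrame([{
        "timepoint_h": r.timepoint_h, "compartment": r.compartment,
        "cfu_per_ml": r.cfu_per_ml, "volume_ml": r.volume_ml, "cfu": r.cfu,
    } for r in records])
    total_effluent = float(df.loc[df.compartment == "effluent", "cfu"].sum())
    digest_rows = df.loc[df.compartment == "digest", "cfu"]
    inoc_rows = df.loc[df.compartment == "inoculum", "cfu"]
    digest = float(digest_rows.sum()) if len(digest_rows) else None
    inoculum = float(inoc_rows.sum()) if len(inoc_rows) else None
    if digest is None and require_digest:
        raise ValueError(
            "cumulative CFU/chip needs a digest record; pass "
            "require_digest=False for effluent-only accounting")
    total = total_effluent + digest if digest is not None else None
    return CfuSummary(per_record=df, total_effluent=total_effluent,
                      digest=digest, total=total, inoculum=inoculum)


def percent_adherence(digest_cfu: float, inoculum_cfu: float) -> float:
    """Viable bacteria recovered from the 72-h epithelial digest as percent
    of the T0 inoculum."""
    if inoculum_cfu <= 0:
        raise ValueError("inoculum CFU must be > 0")
    if digest_cfu < 0:
        raise ValueError("digest CFU must be >= 0")
    return 100.0 * digest_cfu / inoculum_cfu


def percent_viability(live_count: float, control_live_count: float) -> float:
    """Live cells relative to control (trypan-blue exclusion), in percent."""
    if control_live_count <= 0:
        raise ValueError("control live count must be > 0")
    if live_count < 0:
        raise ValueError("live count must be >= 0")
    return 100.0 * live_count / control_live_count


def fold_change_table(assays: pd.DataFrame, control_label: str) -> pd.DataFrame:
    """Per-analyte, per-condition mean fold change versus control chips.

    Input columns: chip_id, condition, analyte, value. For each analyte the
    fold change of a condition is its mean divided by the control mean;
    per-group dispersion is reported as the s.e.m. of the raw values. A zero
    (or absent) control mean leaves the fold change undefined (NaN).

    Output columns: analyte, condition, n, mean, sem, control_mean,
    fold_change.
    """
    required = {"condition", "analyte", "value"}
    missing = required - set(assays.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    g = (assays.groupby(["analyte", "condition"], sort=True)["value"]
         .agg(n="size", mean="mean", sem="sem")
         .reset_index())
    ctrl = (g.loc[g.condition == control_label, ["analyte", "mean"]]
            .rename(columns={"mean": "control_mean"}))
    out = g.merge(ctrl, on="analyte", how="left")
    with np.errstate(divide="ignore", invalid="ignore"):
        out["fold_change"] = np.where(
            (out["control_mean"].notna()) & (out["control_mean"] != 0),
            out["mean"] / out["control_mean"], np.nan)
    undefined = out.loc[out["fold_change"].isna(), "analyte"].unique()
    if len(undefined):
        logger.warning("fold change undefined (zero/missing control) for "
                       "analytes: %s", list(undefined))
    return out
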