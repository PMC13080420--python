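"""Manually-derived ratio traits and the drought sensitivity index.

Ratios from harvest measurements:

* SLA = TLA / leaf_DW (cm^2 g^-1): specific leaf area
* LWR = leaf_DW / DW (g g^-1): leaf weight ratio
* LAR = TLA / DW (cm^2 g^-1): leaf area ratio
* RWC = (FW - DW) / (SFW - DW) x 100 (%): relative water content
* WUE = DB / water_used (px^2 mL^-1): water use efficiency

The sensitivity index of a trait is the percent reduction of its mean under
drought relative to control:

    SI = (mean_control - mean_drought) / mean_control x 100

so positive SI marks a drought-reduced trait and negative SI a trait that
increased under drought. All ratios propagate invalid inputs to NaN with a
warning, never to exceptions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

CONTROL, DROUGHT = "control", "drought"


def _safe_div(num, den, what: str):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    bad = ~(den > 0)
    if np.any(bad):
        warnings.warn(f"{what}: non-positive divisor -> NaN", stacklevel=3)
    out = np.full(np.broadcast(num, den).shape, np.nan)
    np.divide(num, den, out=out, where=~bad)
    return out if out.ndim else float(out)


def specific_leaf_area(tla, leaf_dw):
    """SLA = total leaf area / leaf dry weight (cm^2 g^-1)."""
    return _safe_div(tla, leaf_dw, "SLA")


def leaf_weight_ratio(leaf_dw, dw):
    """LWR = leaf dry weight / total plant dry weight (g g^-1)."""
    return _safe_div(leaf_dw, dw, "LWR")


def leaf_area_ratio(tla, dw):
    """LAR = total leaf area / total plant dry weight (cm^2 g^-1)."""
    return _safe_div(tla, dw, "LAR")


def relative_water_content(fw, dw, sfw):
    """RWC = (FW - DW) / (SFW - DW) x 100, in [0, 100] when FW <= SFW."""
    fw = np.asarray(fw, dtype=float)
    dw = np.asarray(dw, dtype=float)
    sfw = np.asarray(sfw, dtype=float)
    return _safe_div(fw - dw, sfw - dw, "RWC") * 100.0


def water_use_efficiency(db, water_used):
    """WUE = digital biomass / water used (px^2 mL^-1)."""
    return _safe_div(db, water_used, "WUE")


@dataclass(frozen=True)
class SensitivityResult:
    """Per-condition means and the sensitivity index of one trait."""

    trait: str
    mean_control: float
    mean_drought: float
    si: float
    n_control: int = 0
    n_drought: int = 0


def sensitivity_from_means(mean_control: float, mean_drought: float) -> float:
    """SI (%) from the two condition means; NaN if the control mean is 0."""
    if mean_control == 0:
        warnings.warn("SI undefined: control mean is 0", stacklevel=2)
        return float("nan")
    return (mean_control - mean_drought) / mean_control * 100.0


def _condition_means(table: pd.DataFrame, trait: str,
                     control: str = CONTROL, drought: str = DROUGHT):
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    conds = set(sub["condition"].unique())
    if not {control, drought} <= conds:
        raise ValueError(
            f"trait {trait!r} needs both conditions {control!r} and {drought!r}; found {sorted(conds)}"
        )
    ctrl = sub.loc[sub["condition"] == control, "value"]
    drt = sub.loc[sub["condition"] == drought, "value"]
    return ctrl, drt


def sensitivity_index(table: pd.DataFrame, trait: str,
                      control: str = CONTROL, drought: str = DROUGHT) -> SensitivityResult:
    """Sensitivity index of one trait from a long-format trait table.

    Means are pooled over accessions and replicates within each condition
    (pairwise-complete: NaN records dropped per trait).
    """
    ctrl, drt = _condition_means(table, trait, control, drought)
    mc, md = float(ctrl.mean()), float(drt.mean())
    return SensitivityResult(
        trait=trait, mean_control=mc, mean_drought=md,
        si=sensitivity_from_means(mc, md),
        n_control=len(ctrl), n_drought=len(drt),
    )


def sensitivity_table(table: pd.DataFrame, traits=None,
                      control: str = CONTROL, drought: str = DROUGHT) -> pd.DataFrame:
    """Sensitivity indices for every trait, mirroring the published layout.

    Columns: trait, control_mean, drought_mean, si_percent, n_control,
    n_drought.
    """
    traits = traits if traits is not None else list(table["trait"].unique())
    rows = []
    for trait in traits:
        res = sensitivity_index(table, trait, control, drought)
        rows.append(
            dict(trait=res.trait, control_mean=res.mean_control,
                 drought_mean=res.mean_drought, si_percent=res.si,
                 n_control=res.n_control, n_drought=res.n_drought)
        )
    return pd.DataFrame(rows)


def per_accession_sensitivity(table: pd.DataFrame, trait: str,
                              control: str = CONTROL, drought: str = DROUGHT) -> pd.DataFrame:
    """Per-accession SI (for screening): condition means within accession."""
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    wide = (
        sub.groupby(["accession", "condition"])["value"].mean().unstack("condition")
    )
    if control not in wide or drought not in wide:
        raise ValueError("both conditions required for per-accession SI")
    si = (wide[control] - wide[drought]) / wide[control] * 100.0
    si[wide[control] == 0] = np.nan
    return si.rename("si_percent").reset_index()


def group_reduction_summary(table: pd.DataFrame, trait: str,
                            grouping: dict[str, str] | None = None,
                            control: str = CONTROL, drought: str = DROUGHT) -> pd.DataFrame:
    """Per-species-group percent reduction under drought, plus the grand mean.

    Uses the ``species_group`` column unless an explicit accession -> group
    mapping is given. The returned frame has one row per group and a final
    ``overall`` row holding the unweighted mean reduction across groups (the
    reference line of a per-species reduction plot). Groups missing one of
    the two conditions get NaN.
    """
    sub = table[table["trait"] == trait].dropna(subset=["value"]).copy()
    if grouping is not None:
        sub["species_group"] = sub["accession"].map(grouping)
        if sub["species_group"].isna().any():
            raise ValueError("grouping must cover all accessions in the table")
    elif "species_group" not in sub.columns:
        raise ValueError("table lacks species_group; pass an explicit grouping")

    rows = []
    for group, gdf in sub.groupby("species_group", sort=True):
        conds = set(gdf["condition"].unique())
        if {control, drought} <= conds:
            mc = gdf.loc[gdf["condition"] == control, "value"].mean()
            md = gdf.loc[gdf["condition"] == drought, "value"].mean()
            red = sensitivity_from_means(float(mc), float(md))
        else:
            warnings.warn(f"group {group!r} lacks one condition -> NaN", stacklevel=2)
            red = float("nan")
        rows.append(dict(species_group=group, reduction_percent=red))
    out = pd.DataFrame(rows)
    overall = float(np.nanmean(out["reduction_percent"])) if len(out) else float("nan")
    return pd.concat(
        [out, pd.DataFrame([dict(species_group="overall", reduction_percent=overall)])],
        ignore_index=True,
    )
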