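"""Small-assay quantification: dual-luciferase reporter activity, relative
qPCR expression (2^−ΔΔCt), and standard-curve concentration readout.

Conventions:

* dual-luciferase: the Renilla channel is treated as background and
  subtracted from the firefly channel; group induction is the ratio of
  treated to vehicle mean net signal;
* qPCR: technical Ct replicates are averaged per sample *first*, then
  ΔCt = Ct_target − Ct_reference per sample, ΔΔCt against the control-group
  mean ΔCt, and fold change 2^−ΔΔCt (amplification efficiency fixed at 2;
  the reference gene is configurable, single-gene);
* standard curve: ordinary least-squares line mapping absorbance to
  concentration, result normalised to input tissue mass; absorbances
  outside the standard range are flagged as extrapolated but still
  quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import unpaired_t


class NormalizationError(ValueError):
    """The vehicle/control normaliser is zero or negative."""


@dataclass(frozen=True)
class DualLuciferaseReading:
    sample_id: str
    tissue: str
    treatment: str
    firefly_rlu: float
    renilla_rlu: float

    def __post_init__(self):
        if self.firefly_rlu < 0 or self.renilla_rlu < 0:
            raise ValueError("channel readings must be >= 0")


@dataclass
class NetLuminescence:
    net_rlu: float
    background_exceeds_signal: bool


def net_luminescence(r: DualLuciferaseReading) -> NetLuminescence:
    """Firefly minus Renilla; negative results are returned but flagged."""
    net = r.firefly_rlu - r.renilla_rlu
    return NetLuminescence(net, background_exceeds_signal=net < 0)


def fold_induction(treated_nets, vehicle_nets) -> float:
    """Mean(treated net) / mean(vehicle net), the vehicle-relative induction."""
    treated = np.asarray(treated_nets, float)
    vehicle = np.asarray(vehicle_nets, float)
    v_mean = vehicle.mean()
    if v_mean <= 0:
        raise NormalizationError(f"vehicle mean net luminescence is {v_mean}, cannot normalise")
    return float(treated.mean() / v_mean)


def qpcr_relative_expression(
    records: pd.DataFrame,
    target_gene: str,
    ref_gene: str,
    control_group: str,
) -> pd.DataFrame:
    """Relative expression per sample by the 2^−ΔΔCt method.

    ``records`` is long format: sample_id, group, gene, ct (one row per
    technical replicate).  Returns one row per sample with its ΔCt, ΔΔCt
    and fold change; the frame carries the unpaired-t p-value comparing
    ΔCt between the two groups in ``.attrs["p_value"]`` (pooled-variance
    test on per-sample ΔCt).
    """
    for col in ("sample_id", "group", "gene", "ct"):
        if col not in records.columns:
            raise ValueError(f"qPCR records missing column {col!r}")
    if (records["ct"] <= 0).any():
        raise ValueError("Ct values must be > 0")
    # technical replicates average per (sample, gene) first
    ct = records.groupby(["sample_id", "group", "gene"], sort=True)["ct"].mean().reset_index()
    wide = ct.pivot_table(index=["sample_id", "group"], columns="gene", values="ct")
    for gene in (target_gene, ref_gene):
        if gene not in wide.columns or wide[gene].isna().any():
            raise ValueError(f"gene {gene!r} missing for some sample")
    out = wide.reset_index()[["sample_id", "group"]].copy()
    out["delta_ct"] = (wide[target_gene] - wide[ref_gene]).to_numpy()
    control = out[out["group"] == control_group]
    if control.empty:
        raise ValueError(f"control group {control_group!r} not present")
    ref_delta = control["delta_ct"].mean()
    out["delta_delta_ct"] = out["delta_ct"] - ref_delta
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    groups = sorted(out["group"].unique())
    if len(groups) == 2:
        a = out.loc[out["group"] == groups[0], "delta_ct"]
        b = out.loc[out["group"] == groups[1], "delta_ct"]
        _, _, p = unpaired_t(a, b)
        out.attrs["p_value"] = p
    return out


@dataclass
class StandardCurve:
    """Least-squares line mapping absorbance to concentration."""

    slope: float
    intercept: float
    abs_min: float
    abs_max: float

    @classmethod
    def fit(cls, concentrations, absorbances) -> "StandardCurve":
        conc = np.asarray(concentrations, float)
        ab = np.asarray(absorbances, float)
        if len(conc) < 2:
            raise ValueError("need >= 2 standards")
        if len(np.unique(conc)) < 2:
            raise ValueError("standard concentrations must be distinct")
        slope, intercept = np.polyfit(ab, conc, 1)
        return cls(float(slope), float(intercept), float(ab.min()), float(ab.max()))

    def concentration(self, absorbance: float) -> float:
        return self.slope * absorbance + self.intercept


def standard_curve_quantify(
    standards: pd.DataFrame,
    absorbances,
    tissue_mass_g: float,
) -> pd.DataFrame:
    """Absolute quantification against a standard curve, per unit tissue mass.

    ``standards`` needs columns ``concentration`` and ``absorbance``.
    Returns per-reading concentration (curve units / g) with an
    ``extrapolated`` flag for absorbances outside the standard range.
    """
    if tissue_mass_g <= 0:
        raise ValueError("tissue mass must be > 0")
    curve = StandardCurve.fit(standards["concentration"], standards["absorbance"])
    ab = np.asarray(absorbances, float)
    conc = curve.slope * ab + curve.intercept
    return pd.DataFrame(
        {
            "absorbance": ab,
            "concentration_per_g": conc / tissue_mass_g,
            "extrapolated": (ab < curve.abs_min) | (ab > curve.abs_max),
        }
    )
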