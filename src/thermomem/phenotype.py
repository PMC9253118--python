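"""Phenotype quantification: chlorophyll, fresh-mass ratios, recovery classes.

Chlorophyll concentrations come from DMSO-extract absorbance at 663 and
645 nm.  The default coefficient set is the one used by the emulated
protocol, applied verbatim; note that its Chl_b and total-chlorophyll
coefficients are mutually inconsistent with the classical Arnon set (0.229
vs 0.0229; 0.202/0.00802 alongside 20.2/8.02), so a ``classic_arnon`` switch
provides the standard coefficients for comparison.  No intent is guessed:
the default reproduces the protocol as printed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AbsorbanceRecord",
    "ChlorophyllResult",
    "PhenotypeInputError",
    "chlorophyll",
    "normalize_to_control",
    "fresh_mass_ratio",
    "recovery_class_summary",
]

ALLOWED_DILUTIONS = (1, 10, 100)


class PhenotypeInputError(ValueError):
    """Invalid phenotype measurement input."""


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One chlorophyll extraction measurement."""

    sample_id: str
    genotype: str
    treatment: str
    od663: float
    od645: float
    dilution: int = 1
    fresh_mass_g: float = 1.0

    def __post_init__(self) -> None:
        if self.od663 < 0 or self.od645 < 0:
            raise PhenotypeInputError("absorbance values must be >= 0")
        if self.fresh_mass_g <= 0:
            raise PhenotypeInputError("fresh mass must be > 0")
        if self.dilution not in ALLOWED_DILUTIONS:
            raise PhenotypeInputError(
                f"dilution must be one of {ALLOWED_DILUTIONS}, got {self.dilution}"
            )


@dataclass(frozen=True)
class ChlorophyllResult:
    """Chlorophyll a, b, total (g/L) and total per fresh mass (mg/g)."""

    chl_a_g_per_l: float
    chl_b_g_per_l: float
    total_g_per_l: float
    total_mg_per_g_fm: float
    negative_flag: bool


def chlorophyll(
    record: AbsorbanceRecord, classic_arnon: bool = False
) -> ChlorophyllResult:
    """Chlorophyll concentrations from a single absorbance record.

    Default coefficients (protocol as printed):
        Chl_a = 0.0127*OD663 - 0.00269*OD645
        Chl_b = 0.229*OD645  - 0.00488*OD663
        Total (g/L)   = 0.202*Chl_a + 0.00802*Chl_b
        Total (mg/g)  = (20.2*Chl_a + 8.02*Chl_b) / FM
    ODs are multiplied by the dilution factor before use.  With
    ``classic_arnon=True`` the standard Arnon coefficient set is used
    instead (Chl_b = 0.0229*OD645 - 0.00468*OD663, total = Chl_a + Chl_b).
    Negative computed concentrations are flagged but retained.
    """
    od663 = record.od663 * record.dilution
    od645 = record.od645 * record.dilution
    if classic_arnon:
        chl_a = 0.0127 * od663 - 0.00269 * od645
        chl_b = 0.0229 * od645 - 0.00468 * od663
        total = chl_a + chl_b
        total_mg = (chl_a + chl_b) * 1000.0 / record.fresh_mass_g
    else:
        chl_a = 0.0127 * od663 - 0.00269 * od645
        chl_b = 0.229 * od645 - 0.00488 * od663
        total = 0.202 * chl_a + 0.00802 * chl_b
        total_mg = (20.2 * chl_a + 8.02 * chl_b) / record.fresh_mass_g
    return ChlorophyllResult(
        chl_a_g_per_l=chl_a,
        chl_b_g_per_l=chl_b,
        total_g_per_l=total,
        total_mg_per_g_fm=total_mg,
        negative_flag=(chl_a < 0 or chl_b < 0 or total < 0),
    )


def normalize_to_control(
    values: pd.DataFrame,
    value_col: str = "value",
    control_label: str = "control",
) -> pd.DataFrame:
    """Divide each measurement by its genotype's control mean.

    ``values`` needs columns genotype, treatment and ``value_col``.  Genotypes
    whose control mean is zero get NaN with a flag column set.
    """
    required = {"genotype", "treatment", value_col}
    if missing := required - set(values.columns):
        raise PhenotypeInputError(f"missing columns: {sorted(missing)}")
    out = values.copy()
    ctrl_mean = (
        values[values["treatment"] == control_label]
        .groupby("genotype")[value_col]
        .mean()
    )
    missing_geno = set(values["genotype"]) - set(ctrl_mean.index)
    if missing_geno:
        raise PhenotypeInputError(
            f"genotypes without a control group: {sorted(missing_geno)}"
        )
    denom = out["genotype"].map(ctrl_mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["normalized"] = np.where(
            denom != 0, out[value_col] / denom, np.nan
        )
    out["undefined_control"] = denom == 0
    return out


def fresh_mass_ratio(
    masses: pd.DataFrame,
    stressed_label: str = "stressed",
    control_label: str = "control",
) -> pd.DataFrame:
    """Per-genotype stressed/control fresh-mass ratio with dispersion.

    Each row of ``masses`` (columns: genotype, treatment, mass) is one
    biological replicate (a plate-average mass).  Reports the ratio of means,
    the sd of per-replicate ratios against the control mean, and a Welch
    t statistic between arms (descriptive; significance marks are
    presentation, not pipeline decisions).
    """
    required = {"genotype", "treatment", "mass"}
    if missing := required - set(masses.columns):
        raise PhenotypeInputError(f"missing columns: {sorted(missing)}")
    rows = []
    for geno, sub in masses.groupby("genotype"):
        stressed = sub.loc[sub["treatment"] == stressed_label, "mass"]
        control = sub.loc[sub["treatment"] == control_label, "mass"]
        if len(stressed) == 0 or len(control) == 0:
            raise PhenotypeInputError(f"genotype {geno!r} missing an arm")
        ratio = stressed.mean() / control.mean()
        per_rep = stressed / control.mean()
        if len(stressed) > 1 and len(control) > 1:
            tstat, pval = stats.ttest_ind(stressed, control, equal_var=False)
        else:
            tstat, pval = np.nan, np.nan
        rows.append(
            {"genotype": geno, "ratio": float(ratio),
             "sd": float(per_rep.std(ddof=1)) if len(per_rep) > 1 else np.nan,
             "n_stressed": len(stressed), "n_control": len(control),
             "t": float(tstat), "p": float(pval)}
        )
    return pd.DataFrame(rows).set_index("genotype")


def recovery_class_summary(
    counts: pd.DataFrame,
    class_cols: tuple[str, ...] = ("full", "partial", "none"),
) -> pd.DataFrame:
    """Per-genotype proportions over the three recovery classes.

    ``counts`` has one row per genotype with non-negative integer counts in
    ``class_cols`` (the class labels are an input, not computed from
    images).  Proportions sum to 1 per genotype.
    """
    for col in class_cols:
        if col not in counts.columns:
            raise PhenotypeInputError(f"missing class column {col!r}")
    arr = counts[list(class_cols)].to_numpy(dtype=float)
    if (arr < 0).any():
        raise PhenotypeInputError("class counts must be >= 0")
    totals = arr.sum(axis=1)
    if (totals == 0).any():
        raise PhenotypeInputError("each genotype needs total count > 0")
    props = arr / totals[:, None]
    out = pd.DataFrame(props, index=counts.index, columns=list(class_cols))
    out["total"] = totals.astype(int)
    return out
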