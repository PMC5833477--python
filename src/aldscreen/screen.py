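"""Plate-level screening statistics.

Operates on a per-well summary table (columns ``well, role, compound,
dose_uM, n_cells, fraction_high``) and applies the screen's rule set:

* toxicity masking — wells whose cell number is reduced by strictly more
  than 50% versus the neutral (DMSO / lipid-only) control aggregate are
  masked and can never be hits;
* percent-of-control normalization — the ALDH-high fraction is rescaled so
  the neutral control anchors 0% effect and the full-effect control (DEAB,
  or an ALDH1A3 siRNA in the knockdown variant) anchors 100%;
* hit calling — an unmasked well whose ALDH-high fraction is reduced by
  strictly more than 25% versus the neutral control is a hit;
* fast-acting flagging — a hit that abolishes the reporter signal within
  2 h and rebounds after compound wash-off behaves like a direct ALDH
  enzyme inhibitor (the DEAB pattern) and is a likely false positive;
* robust Z-prime and signal-to-background plate QC.

Control aggregation defaults to the median (robust to a single bad control
well); mean is available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

from aldscreen.dose_response import DoseResponseFit, fit_four_parameter_logistic

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates sigma for a normal

DEFAULT_HIT_REDUCTION_PCT = 25.0
DEFAULT_MASK_FRACTION = 0.5
DEFAULT_T_FAST = 75.0     # percent reduction at 2 h
DEFAULT_T_REBOUND = 25.0  # percent residual effect after wash-off

WELL_SUMMARY_COLUMNS = ["well", "role", "compound", "dose_uM", "n_cells", "fraction_high"]


class ScreenConfigError(ValueError):
    """Plate layout or configuration cannot support the requested statistic."""


class ScreenQCError(ValueError):
    """Degenerate control statistics (e.g. equal anchors) fail plate QC."""


@dataclass(frozen=True)
class NormalizationConfig:
    """Which control roles anchor 0% and 100% effect, and how to aggregate them."""

    neutral_role: str = "dmso"
    full_effect_role: str = "deab"
    aggregation: Literal["median", "mean"] = "median"

    def aggregate(self, values: np.ndarray) -> float:
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ScreenConfigError("no control wells to aggregate")
        return float(np.median(values) if self.aggregation == "median" else np.mean(values))


def _require_columns(wells: pd.DataFrame) -> None:
    missing = [c for c in WELL_SUMMARY_COLUMNS if c not in wells.columns]
    if missing:
        raise ValueError(f"well summary table missing columns {missing}")


def mask_toxic_wells(
    wells: pd.DataFrame,
    cfg: NormalizationConfig = NormalizationConfig(),
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> pd.Series:
    """Mask wells whose cell number is reduced by strictly more than 50%.

    masked <=> n_cells < mask_fraction * aggregate(neutral-control n_cells).
    A well at exactly 50% of the control count is NOT masked (the rule is
    strict: ">50% reduced").
    """
    _require_columns(wells)
    neutral = wells.loc[wells["role"] == cfg.neutral_role, "n_cells"]
    if neutral.empty:
        raise ScreenConfigError(f"no wells with neutral role {cfg.neutral_role!r}")
    ref = cfg.aggregate(neutral.to_numpy())
    return wells["n_cells"] < mask_fraction * ref


def normalize_to_controls(
    wells: pd.DataFrame, cfg: NormalizationConfig = NormalizationConfig()
) -> pd.Series:
    """Percent effect anchored at neutral control = 0% and full-effect = 100%.

    effect = 100 * (f_neutral - f_well) / (f_neutral - f_full). Values
    outside [0, 100] are legitimate over-normalization; callers may flag
    beyond +/-150 (see :func:`analyze_plate`). Equal anchors raise
    :class:`ScreenQCError`.
    """
    _require_columns(wells)
    f_neutral = _control_fraction(wells, cfg, cfg.neutral_role)
    f_full = _control_fraction(wells, cfg, cfg.full_effect_role)
    if f_neutral == f_full:
        raise ScreenQCError(
            f"degenerate anchors: neutral and full-effect controls both at {f_neutral}"
        )
    return 100.0 * (f_neutral - wells["fraction_high"]) / (f_neutral - f_full)


def _control_fraction(wells: pd.DataFrame, cfg: NormalizationConfig, role: str) -> float:
    sub = wells.loc[wells["role"] == role, "fraction_high"]
    if sub.empty:
        raise ScreenConfigError(f"no wells with control role {role!r}")
    return cfg.aggregate(sub.to_numpy())


def reduction_vs_neutral(
    wells: pd.DataFrame, cfg: NormalizationConfig = NormalizationConfig()
) -> pd.Series:
    """Percent reduction of the ALDH-high fraction versus the neutral control.

    reduction = 100 * (f_neutral - f_well) / f_neutral. NaN when the neutral
    aggregate is 0 (not evaluable).
    """
    _require_columns(wells)
    f_neutral = _control_fraction(wells, cfg, cfg.neutral_role)
    if f_neutral == 0:
        return pd.Series(np.nan, index=wells.index)
    return 100.0 * (f_neutral - wells["fraction_high"]) / f_neutral


def call_hits(
    wells: pd.DataFrame,
    masked: pd.Series,
    cfg: NormalizationConfig = NormalizationConfig(),
    reduction_threshold: float = DEFAULT_HIT_REDUCTION_PCT,
) -> pd.Series:
    """hit <=> not masked AND reduction vs. neutral control > threshold (strict).

    Wells whose reduction is not evaluable (neutral control at 0) are never
    hits.
    """
    red = reduction_vs_neutral(wells, cfg)
    return (~masked) & (red > reduction_threshold) & red.notna()


def flag_fast_acting(
    effect_2h: Optional[float],
    effect_washoff: Optional[float],
    t_fast: float = DEFAULT_T_FAST,
    t_rebound: float = DEFAULT_T_REBOUND,
) -> Optional[bool]:
    """Flag the direct-enzyme-inhibitor (false positive) follow-up pattern.

    fast_acting <=> the 2 h effect is >= t_fast percent AND the effect after
    compound wash-off has collapsed below t_rebound percent (the ALDH-high
    population reappears). Returns None when either measurement is missing
    (not evaluable).
    """
    if effect_2h is None or effect_washoff is None:
        return None
    if np.isnan(effect_2h) or np.isnan(effect_washoff):
        return None
    return bool(effect_2h >= t_fast and effect_washoff < t_rebound)


def robust_z_prime(pos: np.ndarray, neg: np.ndarray) -> float:
    """Robust Z-prime: medians and scaled MADs of the two control groups.

    RZ' = 1 - 3 * (1.4826*MAD(pos) + 1.4826*MAD(neg)) / |median(pos) - median(neg)|.
    Equal medians return -inf (QC failure sentinel). Requires >= 3 wells per
    group.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 3 or neg.size < 3:
        raise ScreenQCError("robust Z-prime needs >= 3 wells per control group")
    sep = abs(float(np.median(pos)) - float(np.median(neg)))
    if sep == 0:
        return float("-inf")
    mad_pos = float(np.median(np.abs(pos - np.median(pos))))
    mad_neg = float(np.median(np.abs(neg - np.median(neg))))
    return 1.0 - 3.0 * (MAD_SCALE * mad_pos + MAD_SCALE * mad_neg) / sep


def signal_to_background(
    neutral: np.ndarray,
    full: np.ndarray,
    aggregation: Literal["mean", "median"] = "mean",
) -> float:
    """S/B = aggregate(neutral fractions) / aggregate(full-effect fractions).

    A zero background returns +inf with a warning-level sentinel rather
    than raising: the plate is degenerate but the ratio is well-defined in
    the limit.
    """
    agg = np.mean if aggregation == "mean" else np.median
    num = float(agg(np.asarray(neutral, dtype=float)))
    den = float(agg(np.asarray(full, dtype=float)))
    if den == 0:
        return float("inf")
    return num / den


@dataclass
class PlateResult:
    """Full per-plate screening output."""

    wells: pd.DataFrame            # input columns + masked, normalized_effect,
                                   # reduction_vs_neutral, over_normalized, hit
    rz_prime: float
    s_b: float
    n_masked: int
    n_hits: int
    fast_acting: dict[str, Optional[bool]] = field(default_factory=dict)
    fits: dict[str, DoseResponseFit] = field(default_factory=dict)


def analyze_plate(
    wells: pd.DataFrame,
    cfg: NormalizationConfig = NormalizationConfig(),
    reduction_threshold: float = DEFAULT_HIT_REDUCTION_PCT,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
    followup: Optional[pd.DataFrame] = None,
    t_fast: float = DEFAULT_T_FAST,
    t_rebound: float = DEFAULT_T_REBOUND,
    fit_dose_response: bool = False,
) -> PlateResult:
    """Run the full rule set on one plate.

    ``followup``, when given, is a per-compound table with columns
    ``compound, effect_2h, effect_washoff`` used to flag fast-acting false
    positives among the hits. With ``fit_dose_response=True``, compounds
    measured at >= 4 distinct doses get a 4PL fit of normalized effect vs.
    dose.
    """
    _require_columns(wells)
    out = wells.copy()
    masked = mask_toxic_wells(out, cfg, mask_fraction)
    out["masked"] = masked
    out["normalized_effect"] = normalize_to_controls(out, cfg)
    out["over_normalized"] = out["normalized_effect"].abs() > 150.0
    out["reduction_vs_neutral"] = reduction_vs_neutral(out, cfg)
    # only sample wells are nominatable: control wells never carry a hit flag
    out["hit"] = call_hits(out, masked, cfg, reduction_threshold) & (out["role"] == "sample")

    pos = out.loc[out["role"] == cfg.full_effect_role, "fraction_high"].to_numpy()
    neg = out.loc[out["role"] == cfg.neutral_role, "fraction_high"].to_numpy()
    rz = robust_z_prime(pos, neg) if (pos.size >= 3 and neg.size >= 3) else float("nan")
    sb = signal_to_background(neg, pos) if pos.size and neg.size else float("nan")

    fast: dict[str, Optional[bool]] = {}
    if followup is not None:
        hit_compounds = set(out.loc[out["hit"], "compound"]) - {""}
        fu = followup.set_index("compound")
        for comp in sorted(hit_compounds):
            if comp in fu.index:
                row = fu.loc[comp]
                fast[comp] = flag_fast_acting(
                    row.get("effect_2h"), row.get("effect_washoff"), t_fast, t_rebound
                )
            else:
                fast[comp] = None

    fits: dict[str, DoseResponseFit] = {}
    if fit_dose_response:
        samples = out[(out["role"] == "sample") & (out["compound"] != "")]
        for comp, grp in samples.groupby("compound"):
            if grp["dose_uM"].nunique() >= 4:
                fits[comp] = fit_four_parameter_logistic(
                    grp["dose_uM"].to_numpy(), grp["normalized_effect"].to_numpy()
                )
    return PlateResult(
        wells=out,
        rz_prime=rz,
        s_b=sb,
        n_masked=int(masked.sum()),
        n_hits=int(out["hit"].sum()),
        fast_acting=fast,
        fits=fits,
    )


def summarize_wells(tables: dict[str, pd.DataFrame], platemap: pd.DataFrame,
                    gate) -> pd.DataFrame:
    """Build the per-well summary table from per-well cell tables and a gate.

    ``gate`` is a :class:`aldscreen.gating.GateThreshold`; each well's
    ALDH-high fraction is the strict-above-threshold cell fraction.
    """
    from aldscreen.gating import gate_fraction

    rows = []
    for well, df in sorted(tables.items()):
        meta = platemap.loc[well] if well in platemap.index else None
        summ = gate_fraction(df, gate, well=well)
        rows.append(
            {
                "well": well,
                "role": meta["role"] if meta is not None else "sample",
                "compound": ""
                if meta is None or pd.isna(meta["compound"])
                else str(meta["compound"]),
                "dose_uM": float(meta["dose_uM"]) if meta is not None else 0.0,
                "n_cells": summ.n_cells,
                "fraction_high": summ.fraction_high,
            }
        )
    return pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS)
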