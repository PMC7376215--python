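"""Quantification math for the supporting bench assays.

Competitive ELISA standard-curve fitting and inverse quantification of
free 8-oxoG nucleosides, antibody cross-reactivity correction, dilution
concordance QC, nM <-> pg-per-µg-RNA unit conversion, immunoprecipitation
efficiency from scintillation counts, dot-blot dose linearity, the
reverse-transcription truncation index, and loading-control densitometry
normalization.  All operations are pure closed-form functions of their
inputs.

The competitive curve is linearized as ``logit(B/B0) = a + b*ln(conc)``
with b < 0; within the assay's linear range this coincides with the usual
four-parameter logistic and has an exact inverse,
``conc = exp((logit(B/B0) - a) / b)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

# Molar mass of 8-oxo-7,8-dihydroguanosine (C10H13N5O6), g/mol.
OXOG_MOLAR_MASS = 299.24
# Effective assay volume per µg of RNA (ml/µg) linking pg/ml to pg/µg;
# reconstructed from the matched nM and pg/µg readouts of the assay.
VOLUME_PER_UG_RNA = 0.1505
# Antibody cross-reactivity toward 8-oxoG in RNA relative to the standard.
DEFAULT_CROSS_REACTIVITY = 0.38
# Kit linear range in pg/ml.
DEFAULT_LINEAR_RANGE = (10.3, 3000.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted competitive-ELISA calibration.

    ``a`` and ``b`` are intercept/slope of logit(B/B0) on ln(conc); a valid
    competitive curve has b < 0 (signal falls as analyte rises).
    ``sensitivity_conc`` is the concentration at B/B0 = 0.80 and
    ``midpoint_conc`` at B/B0 = 0.50 (= exp(-a/b)).
    """

    a: float
    b: float
    linear_range: tuple[float, float]
    sensitivity_conc: float
    midpoint_conc: float
    n_points_used: int
    excluded_points: int = 0

    def forward(self, conc: float | np.ndarray) -> float | np.ndarray:
        """Predicted B/B0 at a concentration (pg/ml)."""
        return expit(self.a + self.b * np.log(conc))

    def inverse(self, b_over_b0: float | np.ndarray) -> float | np.ndarray:
        """Concentration (pg/ml) at a B/B0 reading."""
        return np.exp((logit(b_over_b0) - self.a) / self.b)


@dataclass(frozen=True)
class TruncationResult:
    """RT-truncation readout: normalized distal/proximal ratios and the call."""

    ratio_exposed: float
    ratio_control: float
    oxidation_index: float
    call_threshold: float
    oxidized: bool


def fit_standard_curve(
    concentrations: Sequence[float],
    b_over_b0: Sequence[float],
    *,
    linear_range: tuple[float, float] = DEFAULT_LINEAR_RANGE,
) -> StandardCurve:
    """Fit the logit-log competitive curve by ordinary least squares.

    Points outside `linear_range` or with B/B0 >= 1 (logit undefined /
    above maximum binding) are excluded before fitting; at least three
    distinct concentrations must remain.  A non-negative slope raises: the
    readings do not describe a competitive curve.
    """
    conc = np.asarray(concentrations, dtype=float)
    bb0 = np.asarray(b_over_b0, dtype=float)
    if conc.shape != bb0.shape:
        raise ValueError("concentrations and B/B0 must have equal length")
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")
    usable = (bb0 > 0) & (bb0 < 1) & (conc >= linear_range[0]) & (conc <= linear_range[1])
    excluded = int((~usable).sum())
    conc_u, bb0_u = conc[usable], bb0[usable]
    if len(np.unique(conc_u)) < 3:
        raise ValueError("need >= 3 distinct in-range standard concentrations")
    x = np.log(conc_u)
    y = logit(bb0_u)
    b, a = np.polyfit(x, y, 1)
    if b >= 0:
        raise ValueError("not a competitive curve: fitted slope is non-negative")
    midpoint = float(np.exp(-a / b))
    sensitivity = float(np.exp((logit(0.80) - a) / b))
    return StandardCurve(
        a=float(a),
        b=float(b),
        linear_range=linear_range,
        sensitivity_conc=sensitivity,
        midpoint_conc=midpoint,
        n_points_used=int(usable.sum()),
        excluded_points=excluded,
    )


def interpolate_concentration(
    curve: StandardCurve,
    b_over_b0: float,
    dilution_factor: float = 1.0,
) -> tuple[float, bool]:
    """Invert the standard curve for a sample reading.

    Returns ``(apparent_conc_pg_per_ml, in_range)`` where the concentration
    includes the dilution factor and the flag reports whether the
    pre-dilution value sits inside the curve's linear range.
    """
    if not 0.0 < b_over_b0 < 1.0:
        raise ValueError("B/B0 must lie strictly between 0 and 1")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be positive")
    raw = float(curve.inverse(b_over_b0))
    lo, hi = curve.linear_range
    return raw * dilution_factor, bool(lo <= raw <= hi)


def correct_cross_reactivity(
    conc: float,
    factor: float = DEFAULT_CROSS_REACTIVITY,
    mode: str = "divide",
) -> float:
    """Correct an apparent concentration for antibody cross-reactivity.

    Default mode ``divide`` treats the factor as the antibody's relative
    reactivity toward the RNA form of the analyte: a 38%-reactive antibody
    under-reads the true concentration, so the apparent value is divided by
    the factor.  ``multiply`` is provided for the opposite convention.
    """
    if factor <= 0 or factor > 1:
        raise ValueError("cross-reactivity factor must be in (0, 1]")
    if mode == "divide":
        return conc / factor
    if mode == "multiply":
        return conc * factor
    raise ValueError(f"unknown mode {mode!r}")


def dilution_concordance(concs: Sequence[float], max_disparity: float = 20.0) -> dict[str, float | bool]:
    """Disparity QC across per-dilution concentration estimates.

    ``disparity = 100 * (max - min) / mean``; the sample passes when the
    disparity is strictly below `max_disparity` percent.
    """
    values = np.asarray(concs, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two dilution estimates")
    if (values <= 0).any():
        raise ValueError("concentration estimates must be positive")
    disparity = 100.0 * (values.max() - values.min()) / values.mean()
    return {"disparity_percent": float(disparity), "qc_pass": bool(disparity < max_disparity)}


def convert_units(
    conc_nM: float,
    molar_mass_g_per_mol: float = OXOG_MOLAR_MASS,
    volume_per_rna_ml_per_ug: float = VOLUME_PER_UG_RNA,
) -> float:
    """Convert a molar 8-oxoG concentration (nM) to pg per µg of RNA.

    1 nM of a 299.24 g/mol analyte is 299.24 pg/ml; multiplying by the
    effective assay volume per µg RNA yields the mass load per µg.
    """
    if conc_nM <= 0 or molar_mass_g_per_mol <= 0 or volume_per_rna_ml_per_ug <= 0:
        raise ValueError("all arguments must be positive")
    return conc_nM * molar_mass_g_per_mol * volume_per_rna_ml_per_ug


def convert_pg_per_ug_to_nm(
    pg_per_ug: float,
    molar_mass_g_per_mol: float = OXOG_MOLAR_MASS,
    volume_per_rna_ml_per_ug: float = VOLUME_PER_UG_RNA,
) -> float:
    """Exact inverse of :func:`convert_units`."""
    if pg_per_ug <= 0 or molar_mass_g_per_mol <= 0 or volume_per_rna_ml_per_ug <= 0:
        raise ValueError("all arguments must be positive")
    return pg_per_ug / (molar_mass_g_per_mol * volume_per_rna_ml_per_ug)


def ip_efficiency(
    eluted_counts: float,
    input_counts: float,
    background_counts: float = 0.0,
) -> dict[str, float | bool]:
    """Immunoprecipitation efficiency from scintillation counts, percent.

    ``100 * (eluted - background) / (input - background)``, clipped to
    [0, 100] with a flag when clipping occurred.
    """
    if background_counts < 0 or eluted_counts < 0:
        raise ValueError("counts must be non-negative")
    if input_counts <= background_counts:
        raise ValueError("input counts must exceed background")
    raw = 100.0 * (eluted_counts - background_counts) / (input_counts - background_counts)
    clipped = min(max(raw, 0.0), 100.0)
    return {"efficiency_percent": float(clipped), "clipped": bool(clipped != raw)}


def dotblot_linearity(
    marks_per_oligo: Sequence[float],
    signals: Sequence[float],
) -> dict[str, float]:
    """OLS of binding signal on 8-oxoG marks per oligo, with R^2.

    A linear dose-response (high R^2 through the mark counts) indicates
    little sequence bias in antibody binding.
    """
    x = np.asarray(marks_per_oligo, dtype=float)
    y = np.asarray(signals, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.ptp(x) == 0:
        raise ValueError("marks are constant; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = intercept + slope * x
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"slope": float(slope), "intercept": float(intercept), "r_squared": r_squared}


def truncation_index(
    intensities: dict[str, float],
    call_threshold: float = 0.8,
) -> TruncationResult:
    """Reverse-transcription truncation readout for one transcript.

    `intensities` keys are ``{target,norm}_{distal,proximal}_{exposed,control}``
    band densitometry values (all strictly positive).  Per sample the
    target's distal/proximal ratio is normalized by the loading control's
    (e.g. GAPDH) distal/proximal ratio; the oxidation index is the exposed
    over control normalized ratio.  Oxidation truncates reverse
    transcription, depleting the distal (full-length) product, so an index
    below `call_threshold` calls the transcript oxidized.
    """
    keys = [
        f"{probe}_{position}_{condition}"
        for probe in ("target", "norm")
        for position in ("distal", "proximal")
        for condition in ("exposed", "control")
    ]
    missing = [k for k in keys if k not in intensities]
    if missing:
        raise ValueError(f"missing band intensities: {missing}")
    for k in keys:
        if intensities[k] <= 0:
            raise ValueError(f"band {k!r} has non-positive intensity")
    ratios = {}
    for condition in ("exposed", "control"):
        target = intensities[f"target_distal_{condition}"] / intensities[f"target_proximal_{condition}"]
        norm = intensities[f"norm_distal_{condition}"] / intensities[f"norm_proximal_{condition}"]
        ratios[condition] = target / norm
    index = ratios["exposed"] / ratios["control"]
    return TruncationResult(
        ratio_exposed=float(ratios["exposed"]),
        ratio_control=float(ratios["control"]),
        oxidation_index=float(index),
        call_threshold=call_threshold,
        oxidized=bool(index < call_threshold),
    )


def loading_normalize(
    target_control: float,
    loading_control: float,
    target_exposed: float,
    loading_exposed: float,
) -> float:
    """Loading-normalized control/exposed fold change from densitometry.

    ``(target/loading)_control / (target/loading)_exposed``; a value of
    2.5 means the loading-normalized target signal dropped 2.5-fold upon
    exposure.
    """
    for name, value in (
        ("target_control", target_control),
        ("loading_control", loading_control),
        ("target_exposed", target_exposed),
        ("loading_exposed", loading_exposed),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive")
    return (target_control / loading_control) / (target_exposed / loading_exposed)
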