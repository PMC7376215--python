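"""Abundance selectivity of oxidation: expression bins and concordance summaries.

Oxidation of mRNA is reported to be selective — independent of transcript
abundance — so the induced set is profiled across expression bins: detected
transcripts are split into n (default 10) equal-count bins of mean input
expression and the oxidized fraction per bin is computed, together with a
chi-square goodness-of-fit test of the oxidized counts against the
proportional-to-detected expectation (an added uniformity summary; the
per-bin fractions themselves are the primary display).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class SelectivityProfile:
    """Per-bin detection/oxidation counts plus a uniformity statistic."""

    table: pd.DataFrame  # columns bin, expr_lo, expr_hi, n_detected, n_oxidized, fraction
    chi2: float  # NaN when oxidized set empty
    pvalue: float
    n_detected_total: int
    n_oxidized_total: int


def assign_expression_bins(
    base_means: pd.Series,
    n_bins: int = 10,
    scheme: str = "equal_count",
) -> pd.Series:
    """Assign detected transcripts (base_mean > 0) to expression bins.

    ``equal_count``: rank detected transcripts by base_mean (ties broken by
    transcript ID) and split into `n_bins` contiguous groups of near-equal
    size; when the count is not divisible, the remainder is spread one per
    bin starting from the top-expression bin.  ``equal_width``: equal-width
    intervals spanning [min, max] of the detected expressions.

    Returns an integer bin label (0 = lowest expression) per detected
    transcript; undetected transcripts are absent from the result.
    """
    if (base_means < 0).any():
        raise ValueError("base means must be non-negative")
    detected = base_means[base_means > 0]
    n = len(detected)
    if n < n_bins:
        raise ValueError(
            f"only {n} detected transcripts for {n_bins} bins; reduce n_bins"
        )
    if scheme == "equal_count":
        order = detected.reset_index()
        order.columns = ["transcript_id", "base_mean"]
        order = order.sort_values(["base_mean", "transcript_id"], kind="stable")
        base, remainder = divmod(n, n_bins)
        sizes = np.full(n_bins, base, dtype=int)
        if remainder:
            sizes[n_bins - remainder:] += 1  # extras go to the top bins
        labels = np.repeat(np.arange(n_bins), sizes)
        return pd.Series(labels, index=order["transcript_id"].to_numpy(), name="bin")
    if scheme == "equal_width":
        lo, hi = detected.min(), detected.max()
        edges = np.linspace(lo, hi, n_bins + 1)
        labels = np.clip(np.searchsorted(edges, detected.to_numpy(), side="right") - 1, 0, n_bins - 1)
        return pd.Series(labels, index=detected.index, name="bin")
    raise ValueError(f"unknown binning scheme {scheme!r}")


def selectivity_profile(
    bins: pd.Series,
    base_means: pd.Series,
    oxidized: set[str] | frozenset[str],
) -> SelectivityProfile:
    """Per-bin oxidized fraction with a chi-square uniformity test.

    The chi-square goodness of fit compares per-bin oxidized counts with
    the expectation proportional to per-bin detected counts; bins with
    expected count < 1 are pooled into their neighbor before testing.
    """
    universe = set(bins.index)
    extra = set(oxidized) - set(base_means.index)
    if extra:
        raise ValueError(f"oxidized transcripts outside the universe: {sorted(extra)[:5]}")
    n_bins = int(bins.max()) + 1
    rows = []
    for b in range(n_bins):
        members = bins.index[bins == b]
        n_det = len(members)
        n_ox = len(set(members) & set(oxidized))
        expr = base_means.loc[members]
        rows.append(
            (
                b,
                float(expr.min()) if n_det else np.nan,
                float(expr.max()) if n_det else np.nan,
                n_det,
                n_ox,
                n_ox / n_det if n_det else np.nan,
            )
        )
    table = pd.DataFrame(
        rows, columns=["bin", "expr_lo", "expr_hi", "n_detected", "n_oxidized", "fraction"]
    )
    total_ox = int(table["n_oxidized"].sum())
    total_det = int(table["n_detected"].sum())
    if total_ox == 0:
        return SelectivityProfile(table, float("nan"), float("nan"), total_det, 0)
    observed = table["n_oxidized"].to_numpy(dtype=float)
    expected = total_ox * table["n_detected"].to_numpy(dtype=float) / total_det
    observed, expected = _pool_small_bins(observed, expected)
    if len(observed) < 2:
        chi2, pvalue = 0.0, 1.0
    else:
        chi2, pvalue = stats.chisquare(observed, expected)
    return SelectivityProfile(table, float(chi2), float(pvalue), total_det, total_ox)


def _pool_small_bins(observed: np.ndarray, expected: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge bins with expected count < 1 into their right (then left) neighbor."""
    obs = list(observed)
    exp = list(expected)
    i = 0
    while i < len(exp) and len(exp) > 1:
        if exp[i] < 1.0:
            j = i + 1 if i + 1 < len(exp) else i - 1
            exp[j] += exp[i]
            obs[j] += obs[i]
            del exp[i], obs[i]
        else:
            i += 1
    return np.asarray(obs), np.asarray(exp)


def downreg_concordance(induced_members: pd.Index | list[str], de) -> dict[str, float]:
    """Concordance of induced oxidation with expression downregulation.

    Parameters
    ----------
    induced_members
        Transcript IDs of the induced oxidized set.
    de
        A :class:`~oxrip.contrasts.DiffExprSets` (down set + full table).

    Returns a dict with ``n_oxidized_down`` (induced transcripts also
    called significantly downregulated), ``frac_negative_lfc`` (fraction of
    induced transcripts whose expression log2fc is negative, over those
    present in the DE table with a finite estimate) and the denominator
    ``n_with_lfc``.
    """
    members = list(induced_members)
    down = set(de.down)
    n_down = len([t for t in members if t in down])
    lfc = de.table["log2fc"].reindex(members)
    valid = lfc.dropna()
    frac_neg = float((valid < 0).mean()) if len(valid) else float("nan")
    return {
        "n_oxidized_down": n_down,
        "frac_negative_lfc": frac_neg,
        "n_with_lfc": int(len(valid)),
    }
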