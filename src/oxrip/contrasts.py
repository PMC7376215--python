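"""The two applications of the NB machinery: 8-oxoG enrichment and differential expression.

Enrichment compares the immunoprecipitated (RIP) fraction against the
input fraction within one exposure condition; differential expression
compares exposed against control within the input fraction.  Both return
the full per-transcript test table plus a thresholded call set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from oxrip.io_formats import CountMatrix
from oxrip.nb_core import wald_test_table


@dataclass(frozen=True)
class EnrichedSet:
    """Transcripts called 8-oxoG enriched (RIP over input) in one condition.

    Members satisfy ``padj < padj_max`` and ``log2fc > log2(min_fold_change)``
    (so all member effects are positive).
    """

    condition: str
    padj_max: float
    min_fold_change: float
    members: pd.DataFrame  # index transcript_id; columns log2fc, padj

    def __post_init__(self) -> None:
        if len(self.members):
            log2_min = np.log2(self.min_fold_change)
            ok = (self.members["padj"] < self.padj_max) & (self.members["log2fc"] > log2_min)
            if not ok.all():
                raise ValueError("EnrichedSet member violates its own thresholds")

    @property
    def transcript_ids(self) -> frozenset[str]:
        return frozenset(self.members.index)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.members.index


@dataclass(frozen=True)
class DiffExprSets:
    """Up/down differential-expression calls with the full test table."""

    padj_max: float
    up_fc: float
    down_fc: float
    up: frozenset[str]
    down: frozenset[str]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down sets overlap")


def _require_cell(samples, condition: str, fraction: str) -> None:
    frame = samples.frame
    n = ((frame["condition"] == condition) & (frame["fraction"] == fraction)).sum()
    if n < 2:
        raise ValueError(
            f"design cell ({condition}, {fraction}) has {n} sample(s); >= 2 required"
        )


def rip_enrichment(
    counts: CountMatrix,
    condition: str,
    *,
    padj_max: float = 0.1,
    min_fc: float = 2.0,
    min_mean: float = 1.0,
) -> tuple[pd.DataFrame, EnrichedSet]:
    """Test RIP vs input within `condition` and call enriched transcripts.

    Size factors are estimated on the condition's samples only, so the
    contrast is self-contained.  Default thresholds are adjusted p < 0.1
    and fold change > 2; analyses of stronger exposures conventionally
    tighten padj_max to 0.05.
    """
    if condition not in set(counts.samples.frame["condition"]):
        raise ValueError(f"condition {condition!r} not present in sample sheet")
    _require_cell(counts.samples, condition, "rip")
    _require_cell(counts.samples, condition, "input")
    sheet = counts.samples.select(condition=condition)
    sub = counts.subset_samples(sheet)
    groups = sheet.frame["fraction"].to_numpy()
    table = wald_test_table(sub, groups, ("rip", "input"), min_mean=min_mean)
    log2_min = np.log2(min_fc)
    mask = (table["padj"] < padj_max) & (table["log2fc"] > log2_min)
    members = table.loc[mask.fillna(False), ["log2fc", "padj"]].copy()
    enriched = EnrichedSet(condition, padj_max, min_fc, members)
    return table, enriched


def diff_expression(
    counts: CountMatrix,
    *,
    padj_max: float = 0.05,
    up_fc: float = 2.0,
    down_fc: float = 0.5,
    min_mean: float = 1.0,
) -> DiffExprSets:
    """Exposed-vs-control test on the input fraction with fold-change calls.

    Up calls require fold change > `up_fc` (log2fc > log2(up_fc)) and
    adjusted p < `padj_max`; down calls require fold change < `down_fc`.
    """
    _require_cell(counts.samples, "exposed", "input")
    _require_cell(counts.samples, "control", "input")
    sheet = counts.samples.select(fraction="input")
    sub = counts.subset_samples(sheet)
    groups = sheet.frame["condition"].to_numpy()
    table = wald_test_table(sub, groups, ("exposed", "control"), min_mean=min_mean)
    sig = table["padj"] < padj_max
    up = frozenset(table.index[(sig & (table["log2fc"] > np.log2(up_fc))).fillna(False)])
    down = frozenset(table.index[(sig & (table["log2fc"] < np.log2(down_fc))).fillna(False)])
    table = table.copy()
    table.index.name = "transcript_id"
    return DiffExprSets(padj_max, up_fc, down_fc, up, down, table)
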