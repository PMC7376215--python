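"""Discrimination of exposure-induced oxidized transcripts, overlaps and clustering.

A transcript counts as exposure-induced when it is 8-oxoG enriched in the
exposed condition and either absent from the control enriched set
("unique") or more strongly enriched in exposure by a fold-change ratio
above a threshold ("ratio", default > 1.5 on the linear scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from oxrip.contrasts import EnrichedSet


@dataclass(frozen=True)
class InducedSet:
    """Exposure-induced 8-oxoG transcripts with provenance.

    ``members`` is indexed by transcript and carries columns ``provenance``
    ("unique" or "ratio"), ``log2fc_exposed``, ``log2fc_control`` (NaN when
    unique) and ``fc_ratio`` (NaN when unique).  ``min_log2fc`` is the
    minimum exposed-condition enrichment over members — the noise floor of
    the induced set.
    """

    members: pd.DataFrame
    ratio_threshold: float
    min_log2fc: float

    @property
    def transcript_ids(self) -> frozenset[str]:
        return frozenset(self.members.index)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.members.index


@dataclass(frozen=True)
class OverlapResult:
    """Partition of two induced sets into shared / unique-to-A / unique-to-B."""

    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]
    paired_log2fc: pd.DataFrame  # shared members x [log2fc_a, log2fc_b]


@dataclass(frozen=True)
class ClusterOrder:
    """Leaf order and merge tree from hierarchical clustering."""

    leaf_order: tuple[str, ...]
    merges: pd.DataFrame  # columns left, right, height, size
    note: str = ""


def discriminate_induced(
    exposed: EnrichedSet,
    control: EnrichedSet,
    ratio_threshold: float = 1.5,
) -> InducedSet:
    """Apply the induced-transcript rule to exposed/control enriched sets.

    A transcript is induced iff it is in the exposed set and either not in
    the control set, or its linear enrichment fold-change ratio
    ``2**log2fc_exposed / 2**log2fc_control`` strictly exceeds
    `ratio_threshold`.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    rows = []
    control_ids = control.transcript_ids
    for tid, row in exposed.members.iterrows():
        if tid not in control_ids:
            rows.append((tid, "unique", row["log2fc"], np.nan, np.nan))
        else:
            lfc_ctl = control.members.loc[tid, "log2fc"]
            ratio = 2.0 ** (row["log2fc"] - lfc_ctl)
            if ratio > ratio_threshold:
                rows.append((tid, "ratio", row["log2fc"], lfc_ctl, ratio))
    members = pd.DataFrame(
        rows,
        columns=["transcript_id", "provenance", "log2fc_exposed", "log2fc_control", "fc_ratio"],
    ).set_index("transcript_id")
    min_log2fc = float(members["log2fc_exposed"].min()) if len(members) else float("nan")
    return InducedSet(members, ratio_threshold, min_log2fc)


def overlap_conditions(induced_a: InducedSet, induced_b: InducedSet) -> OverlapResult:
    """Intersect two induced sets, pairing effect sizes for shared members."""
    a_ids = induced_a.transcript_ids
    b_ids = induced_b.transcript_ids
    shared = a_ids & b_ids
    paired = pd.DataFrame(
        {
            "log2fc_a": induced_a.members.loc[sorted(shared), "log2fc_exposed"],
            "log2fc_b": induced_b.members.loc[sorted(shared), "log2fc_exposed"],
        }
    )
    paired.index.name = "transcript_id"
    return OverlapResult(
        shared=frozenset(shared),
        unique_a=frozenset(a_ids - b_ids),
        unique_b=frozenset(b_ids - a_ids),
        paired_log2fc=paired,
    )


def cluster_enrichment_profiles(log2fc: pd.DataFrame) -> ClusterOrder:
    """Average-linkage hierarchical clustering of enrichment profiles.

    Rows are transcripts, columns are conditions; Euclidean distance on
    the log2 fold changes, with missing entries imputed as 0 for distance
    purposes (noted in the result).  Input rows are sorted by transcript
    ID first so the merge sequence and leaf order are deterministic
    regardless of input ordering.
    """
    note = ""
    if len(log2fc) < 1:
        raise ValueError("need at least one transcript")
    ordered = log2fc.sort_index(kind="stable")
    if len(ordered) == 1:
        return ClusterOrder(
            leaf_order=(str(ordered.index[0]),),
            merges=pd.DataFrame(columns=["left", "right", "height", "size"]),
            note="single transcript; trivial order",
        )
    values = ordered.to_numpy(dtype=float)
    if np.isnan(values).any():
        note = "missing log2fc entries imputed as 0 for distance computation"
        values = np.nan_to_num(values, nan=0.0)
    linkage = hierarchy.linkage(pdist(values, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(linkage)
    merges = pd.DataFrame(linkage, columns=["left", "right", "height", "size"])
    merges["left"] = merges["left"].astype(int)
    merges["right"] = merges["right"].astype(int)
    merges["size"] = merges["size"].astype(int)
    return ClusterOrder(
        leaf_order=tuple(str(ordered.index[i]) for i in leaves),
        merges=merges,
        note=note,
    )
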