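"""Gene-set over-representation with Fisher exact p-values and a combined score.

For each gene set the overlap k between an input transcript list (size n)
and the set's members restricted to the universe (size K of N) is tested
with the one-sided hypergeometric upper tail.  Sets are ranked by a
combined score ``-ln(p) * z`` where z is the analytic hypergeometric
z-score of the overlap, ``(k - nK/N) / sd``.  The popular web-tool variant
of this score calibrates z against many random input lists; the analytic z
used here is deterministic and requires no calibration corpus, so rankings
(not the Fisher p-values) may differ from that tool.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from oxrip.io_formats import GeneSetCollection
from oxrip.nb_core import bh_adjust


def combined_score(p_fisher: float, k: int, K: int, n: int, N: int) -> dict[str, float]:
    """Analytic hypergeometric z-score and combined score for one overlap.

    ``z = (k - E[k]) / sd[k]`` with ``E = nK/N`` and
    ``var = nK(N-K)(N-n) / (N^2 (N-1))``; ``combined = -ln(p) * z``.
    A degenerate margin (sd = 0) yields z = 0 and combined = 0.
    """
    expected = n * K / N
    var = n * K * (N - K) * (N - n) / (N**2 * (N - 1)) if N > 1 else 0.0
    if var <= 0:
        return {"z_score": 0.0, "combined_score": 0.0}
    z = (k - expected) / np.sqrt(var)
    combined = -np.log(p_fisher) * z if p_fisher < 1.0 else 0.0
    if z == 0.0:
        combined = 0.0
    return {"z_score": float(z), "combined_score": float(combined)}


def fisher_overrepresentation(
    transcript_list: set[str] | frozenset[str] | list[str],
    sets: GeneSetCollection,
    universe: set[str] | frozenset[str] | list[str],
) -> pd.DataFrame:
    """Test each gene set for over-representation in `transcript_list`.

    The one-sided Fisher p is the hypergeometric upper tail
    ``P(X >= k)`` with population N = |universe|, K = |set ∩ universe|,
    draws n = |list|.  BH adjustment is applied across sets; results are
    sorted by combined score (descending), ties broken by p then set name.
    """
    universe = frozenset(universe)
    query = frozenset(transcript_list)
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty transcript list")
    stray = query - universe
    if stray:
        raise ValueError(f"list members outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for name in sets:
        members = sets.members(name) & universe
        K = len(members)
        k = len(members & query)
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(p, 1.0)
        scores = combined_score(p, k, K, n, N)
        rows.append((name, k, K, n, N, p, scores["z_score"], scores["combined_score"]))
    result = pd.DataFrame(
        rows,
        columns=[
            "set_name",
            "overlap_k",
            "set_size_K",
            "list_size_n",
            "universe_N",
            "p_fisher",
            "z_score",
            "combined_score",
        ],
    )
    result["padj"] = bh_adjust(result["p_fisher"].to_numpy()) if len(result) else []
    result = result.sort_values(
        ["combined_score", "p_fisher", "set_name"],
        ascending=[False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    return result
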