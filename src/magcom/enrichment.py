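"""Differential module-prevalence testing across groups.

Each module's per-group presence proportions are compared with a Rao score
statistic,

    score = sum_g n_g (p_g - p_bar)^2 / (p_bar (1 - p_bar)),

referred to a chi-square distribution on (groups - 1) degrees of freedom;
for two groups this is exactly the Pearson chi-square of the 2x2
presence/absence table.  q-values control the false discovery rate by the
Benjamini-Hochberg step-up.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class EnrichmentResult:
    module_id: str
    score: float
    df: int
    p_raw: float
    q_fdr: float
    associated_groups: tuple[str, ...]


def enrichment_score(
    presence_by_group: Mapping[str, tuple[int, int]],
) -> tuple[float, int, float, list[str]]:
    """Score one module from per-group (n_present, n_total) counts.

    Returns (score, df, p_raw, associated_groups), where associated groups
    are those with prevalence above the pooled mean.  A module present in
    all units or absent from all units is maximally uninformative:
    score 0, p 1.
    """
    if len(presence_by_group) < 2:
        raise ValueError("enrichment requires at least 2 groups")
    groups = list(presence_by_group)
    n_present = np.array([presence_by_group[g][0] for g in groups], dtype=float)
    n_total = np.array([presence_by_group[g][1] for g in groups], dtype=float)
    if (n_total < 1).any():
        raise ValueError("every group must contain at least one unit")
    if ((n_present < 0) | (n_present > n_total)).any():
        raise ValueError("n_present must lie in [0, n_total]")

    df = len(groups) - 1
    p_bar = n_present.sum() / n_total.sum()
    if p_bar in (0.0, 1.0):
        return 0.0, df, 1.0, []
    p_g = n_present / n_total
    score = float((n_total * (p_g - p_bar) ** 2).sum() / (p_bar * (1 - p_bar)))
    p_raw = float(stats.chi2.sf(score, df))
    associated = [g for g, p in zip(groups, p_g) if p > p_bar]
    return score, df, p_raw, associated


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich_modules(
    presence: pd.DataFrame,
    grouping: pd.Series,
    mode: str = "by_host",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every module (column) for differential prevalence across groups.

    ``presence`` is a boolean units x modules frame (units are samples in
    ``by_host`` mode, member MAGs in ``by_cluster`` mode) and ``grouping``
    maps each unit to its group.  The ``significant`` column follows the
    mode-specific convention: unadjusted p in ``by_cluster`` mode, BH
    q-value in ``by_host`` mode.
    """
    if mode not in ("by_host", "by_cluster"):
        raise ValueError(f"unknown mode {mode!r}")
    grouping = grouping.loc[presence.index]
    levels = sorted(grouping.unique())
    if len(levels) < 2:
        raise ValueError("enrichment requires at least 2 groups")
    group_masks = {g: (grouping == g).to_numpy() for g in levels}
    group_sizes = {g: int(mask.sum()) for g, mask in group_masks.items()}

    rows = []
    for module in presence.columns:
        calls = presence[module].to_numpy(dtype=bool)
        counts = {
            g: (int(calls[mask].sum()), group_sizes[g])
            for g, mask in group_masks.items()
        }
        score, df, p_raw, associated = enrichment_score(counts)
        rows.append(
            {"module_id": module, "score": score, "df": df, "p_raw": p_raw,
             "associated_groups": ";".join(associated)}
        )
    table = pd.DataFrame(rows).set_index("module_id")
    table["q_fdr"] = bh_fdr(table["p_raw"].tolist())
    crit = table["p_raw"] if mode == "by_cluster" else table["q_fdr"]
    table["significant"] = crit < alpha
    return table[["score", "df", "p_raw", "q_fdr", "significant",
                  "associated_groups"]]
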