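"""Quality gating, ANI dereplication and MAG-cluster assembly.

Genome bins passing the quality gate (>80% completeness, <10% contamination,
both strict) are dereplicated at 98% average nucleotide identity by greedy
centroid clustering: the highest-quality unassigned bin becomes a
representative and absorbs every unassigned bin within the ANI threshold.
Remaining high-quality bins are then attached to the representative they
share the most ANI with, and near-identical members recovered from the same
host and site/colony (ANI > 99.5%) are collapsed to the higher-quality one
to avoid pseudoreplication.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import AniMatrix, MagCluster, MagRecord

ANI_CLUSTER_THRESHOLD = 98.0  # percent; join if ANI >= this
ANI_PSEUDOREPLICATE_THRESHOLD = 99.5  # percent; collapse if ANI > this
MIN_COMPLETENESS = 80.0  # percent, strict >
MAX_CONTAMINATION = 10.0  # percent, strict <


def quality_score(completeness: float, contamination: float) -> float:
    """Composite genome quality: completeness - 5 x contamination (the
    conventional dereplication-tool weighting), both on the percent scale."""
    if not 0 <= completeness <= 100:
        raise ValueError(f"completeness {completeness} outside [0, 100]")
    if not 0 <= contamination <= 100:
        raise ValueError(f"contamination {contamination} outside [0, 100]")
    return completeness - 5.0 * contamination


def quality_gate(
    mags: Iterable[MagRecord],
    min_completeness: float = MIN_COMPLETENESS,
    max_contamination: float = MAX_CONTAMINATION,
) -> list[MagRecord]:
    """Keep bins with completeness > min and contamination < max (strict)."""
    return [
        m for m in mags
        if m.completeness > min_completeness and m.contamination < max_contamination
    ]


def _score_order(mags: Sequence[MagRecord]) -> list[MagRecord]:
    # best quality first; ties broken by mag_id ascending for determinism
    return sorted(mags, key=lambda m: (-quality_score(m.completeness, m.contamination),
                                       m.mag_id))


def dereplicate(
    mags: Sequence[MagRecord],
    ani: AniMatrix,
    threshold: float = ANI_CLUSTER_THRESHOLD,
) -> list[MagCluster]:
    """Greedy centroid dereplication at the given ANI threshold.

    Returns one cluster per representative; at this stage each cluster's
    member list contains only the MAGs absorbed during dereplication (the
    representative plus any bin with ANI >= threshold to it).  Guarantees:
    every member has ANI >= threshold to its representative, and
    representatives of distinct clusters share ANI < threshold.
    """
    for m in mags:
        if m.mag_id not in ani:
            raise KeyError(f"MAG {m.mag_id!r} missing from ANI matrix")
    unassigned = _score_order(mags)
    clusters: list[MagCluster] = []
    while unassigned:
        rep = unassigned[0]
        absorbed = [m for m in unassigned
                    if ani.ani(rep.mag_id, m.mag_id) >= threshold]
        clusters.append(
            MagCluster(rep.mag_id, rep.mag_id, [m.mag_id for m in absorbed])
        )
        absorbed_ids = {m.mag_id for m in absorbed}
        unassigned = [m for m in unassigned if m.mag_id not in absorbed_ids]
    return clusters


def representatives_only(clusters: Sequence[MagCluster]) -> list[MagCluster]:
    """Strip clusters down to their representatives (the read-mapping
    reference set); members are reattached by :func:`assign_members`."""
    return [MagCluster(c.cluster_id, c.representative, [c.representative])
            for c in clusters]


def refine_by_genus(
    contigs: Iterable[tuple[str, str]],
    target_genus: str,
) -> list[str]:
    """Drop contigs assigned to a genus other than the target; contigs with
    an empty (unassigned) genus are retained."""
    return [
        contig_id for contig_id, genus in contigs
        if genus == "" or genus == target_genus
    ]


def assign_members(
    representatives: Sequence[MagCluster],
    extra_mags: Sequence[MagRecord],
    ani: AniMatrix,
    pseudo_ani: float = ANI_PSEUDOREPLICATE_THRESHOLD,
    records: dict[str, MagRecord] | None = None,
) -> list[MagCluster]:
    """Attach each extra MAG to the representative with which it shares the
    highest ANI (ties broken by representative id), then iteratively drop
    the lower-quality member of any non-representative pair from the same
    host and site/colony with ANI strictly above ``pseudo_ani``.

    ``records`` supplies host/site/quality for the pseudoreplication rule;
    it defaults to the extra MAGs themselves (representatives are never
    dropped, so their records are not needed).
    """
    rep_ids = {c.representative for c in representatives}
    if set(m.mag_id for m in extra_mags) & rep_ids:
        raise ValueError("extra MAGs must be disjoint from representatives")
    if records is None:
        records = {m.mag_id: m for m in extra_mags}

    clusters = [MagCluster(c.cluster_id, c.representative, [c.representative])
                for c in representatives]
    by_rep = {c.representative: c for c in clusters}
    for mag in extra_mags:
        if mag.mag_id not in ani:
            raise KeyError(f"MAG {mag.mag_id!r} missing from ANI matrix")
        best = min(
            sorted(rep_ids),
            key=lambda r: (-ani.ani(mag.mag_id, r), r),
        )
        by_rep[best].members.append(mag.mag_id)

    for cluster in clusters:
        _collapse_pseudoreplicates(cluster, ani, pseudo_ani, records)
    return clusters


def _collapse_pseudoreplicates(
    cluster: MagCluster,
    ani: AniMatrix,
    pseudo_ani: float,
    records: dict[str, MagRecord],
) -> None:
    # iterate until no same-host+site pair above the threshold remains
    changed = True
    while changed:
        changed = False
        members = [m for m in cluster.members if m != cluster.representative]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ra, rb = records[a], records[b]
                if (ra.host == rb.host
                        and ra.site_or_colony == rb.site_or_colony
                        and ani.ani(a, b) > pseudo_ani):
                    # keep the higher-quality member; score ties keep the
                    # lexicographically smaller id
                    keep, drop = sorted(
                        (a, b),
                        key=lambda m: (-quality_score(records[m].completeness,
                                                      records[m].contamination),
                                       m),
                    )
                    cluster.members.remove(drop)
                    changed = True
                    break
            if changed:
                break


def relabel_clusters(
    clusters: Sequence[MagCluster],
    display_ids: dict[str, str],
) -> list[MagCluster]:
    """Rename clusters to the taxonomic display id of their representative."""
    return [
        MagCluster(display_ids[c.representative], c.representative,
                   list(c.members))
        for c in clusters
    ]


def cluster_summary(
    clusters: Sequence[MagCluster],
    records: dict[str, MagRecord],
) -> pd.DataFrame:
    """One row per cluster: member count (including the representative) and
    median member completeness/contamination."""
    rows = []
    for c in clusters:
        comp = [records[m].completeness for m in c.members]
        cont = [records[m].contamination for m in c.members]
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "representative": c.representative,
                "n_members": c.n_members,
                "median_completeness": float(np.median(comp)),
                "median_contamination": float(np.median(cont)),
            }
        )
    return pd.DataFrame(rows).set_index("cluster_id")
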