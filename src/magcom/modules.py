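"""Probabilistic inference of community metabolic potential.

A community that contains a MAG cluster must contain at least one of its
member genomes, but which member is unobserved.  If a module's relative
presence in cluster c is p(c, m) (fraction of member MAGs encoding it), the
minimum probability that the module is present in a sample is

    q(s, m) = 1 - prod over present clusters c of (1 - p(c, m)),

the probability that at least one present cluster contributes a carrier
under one-MAG-per-cluster sampling.  A module is called present when
q >= 0.75, and per-host prevalence is the percentage of that host's samples
with a positive call.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    MODULE_COMPLETION_THRESHOLD,
    AbundanceTable,
    MagCluster,
    ModuleCompletenessTable,
)

PRESENCE_CALL_THRESHOLD = 0.75  # q at/above which a module is called present
ABUNDANCE_PRESENCE_THRESHOLD = 1.0  # percent, strict >; cluster counts as present
HIGH_PREVALENCE_THRESHOLD = 75.0  # percent; consistently-present cutoff


def relative_presence(
    clusters: Sequence[MagCluster],
    modules: ModuleCompletenessTable,
    completion_threshold: float = MODULE_COMPLETION_THRESHOLD,
) -> pd.DataFrame:
    """Per-cluster module relative presence: the number of member MAGs with
    the module / the cluster size.  Members absent from the module table
    contribute zero completeness for every module."""
    rows = {}
    for cluster in clusters:
        if cluster.n_members == 0:
            raise ValueError(f"cluster {cluster.cluster_id!r} has no members")
        present = np.zeros(len(modules.modules))
        for member in cluster.members:
            if member in modules.values.index:
                present += (
                    modules.values.loc[member].to_numpy()
                    >= completion_threshold
                )
        rows[cluster.cluster_id] = present / cluster.n_members
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=modules.modules
    ).rename_axis("cluster_id")


def clusters_present(
    profile: pd.Series,
    threshold: float = ABUNDANCE_PRESENCE_THRESHOLD,
) -> set[str]:
    """Clusters whose representative has relative abundance strictly above
    the threshold (percent) in this sample."""
    return set(profile.index[profile > threshold])


def min_presence_probability(p_values: Iterable[float]) -> float:
    """Minimum probability of module presence: 1 - prod(1 - p) over the
    clusters present in the sample; 0 if no such cluster exists."""
    q_complement = 1.0
    empty = True
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"relative presence {p} outside [0, 1]")
        q_complement *= 1.0 - p
        empty = False
    return 0.0 if empty else 1.0 - q_complement


def module_presence_matrix(
    abund: AbundanceTable,
    rel_presence: pd.DataFrame,
    cluster_of_feature: dict[str, str] | None = None,
    abundance_threshold: float = ABUNDANCE_PRESENCE_THRESHOLD,
) -> pd.DataFrame:
    """Samples x modules minimum probability of presence.

    ``cluster_of_feature`` maps abundance-table feature ids (representative
    MAGs) to cluster ids; by default features are assumed to be cluster ids
    already.
    """
    q = np.zeros((len(abund.samples), rel_presence.shape[1]))
    for i, sid in enumerate(abund.samples):
        present = clusters_present(abund.profile(sid), abundance_threshold)
        if cluster_of_feature is not None:
            present = {cluster_of_feature[f] for f in present}
        unknown = present - set(rel_presence.index)
        if unknown:
            raise KeyError(f"clusters without relative-presence rows: {unknown}")
        if present:
            p = rel_presence.loc[sorted(present)].to_numpy()
            q[i] = 1.0 - np.prod(1.0 - p, axis=0)
    return pd.DataFrame(q, index=abund.samples, columns=rel_presence.columns)


def presence_calls(
    q: pd.DataFrame, call_threshold: float = PRESENCE_CALL_THRESHOLD
) -> pd.DataFrame:
    """Boolean module calls: present when q >= threshold (inclusive)."""
    return q >= call_threshold


def host_prevalence(calls: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Hosts x modules percentage of a host's samples carrying the module."""
    missing = [s for s in calls.index if s not in metadata.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    hosts = metadata.loc[calls.index, "host"]
    out = {}
    for host, sample_ids in calls.groupby(hosts).groups.items():
        n = len(sample_ids)
        if n == 0:  # pragma: no cover - groupby never yields empty groups
            warnings.warn(f"host {host!r} has no samples; excluded")
            continue
        out[host] = 100.0 * calls.loc[sample_ids].sum(axis=0) / n
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("host")


def classify_modules(
    q_values: pd.Series,
    prevalence: pd.DataFrame,
    alpha: float = 0.05,
    high_prev: float = HIGH_PREVALENCE_THRESHOLD,
) -> pd.Series:
    """Trichotomize modules: significantly variable across hosts
    (differentially_enriched, q < alpha), else consistently_present when
    mean per-host prevalence >= high_prev percent, else consistently_low."""
    labels = {}
    for module in prevalence.columns:
        if module not in q_values.index:
            raise KeyError(f"module {module!r} has no enrichment q-value")
        if q_values[module] < alpha:
            labels[module] = "differentially_enriched"
        elif prevalence[module].mean() >= high_prev:
            labels[module] = "consistently_present"
        else:
            labels[module] = "consistently_low"
    return pd.Series(labels, name="classification")


def summarize_universal(
    classification: pd.Series, prevalence: pd.DataFrame
) -> tuple[int, int, int | None]:
    """Among consistently-present modules, count those present in every
    sample of every host (prevalence 100 everywhere).

    Returns (n_consistent, n_universal, integer percent rounded half away
    from zero, or None when there are no consistent modules).
    """
    consistent = classification.index[classification == "consistently_present"]
    n_consistent = len(consistent)
    n_universal = int(
        sum((prevalence[m] == 100.0).all() for m in consistent)
    )
    if n_consistent == 0:
        return 0, 0, None
    percent = int(math.floor(100.0 * n_universal / n_consistent + 0.5))
    return n_consistent, n_universal, percent
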