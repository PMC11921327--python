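"""End-to-end orchestration: from interchange tables to community results.

Each stage function takes and returns in-memory objects; the CLI is a thin
wrapper that reads the TSVs, calls these, and writes the outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from . import catalog, enrichment, io, modules as module_inference, profile
from .types import (
    AbundanceTable,
    AniMatrix,
    MagCluster,
    MagRecord,
    ModuleCompletenessTable,
    TaxonomyString,
)

log = logging.getLogger("magcom")


def build_records(
    quality: pd.DataFrame,
    taxonomy: dict[str, TaxonomyString],
    provenance: dict[str, str],
    metadata: pd.DataFrame,
) -> list[MagRecord]:
    """Join quality, taxonomy and provenance tables into MagRecords."""
    records = []
    for mag_id, row in quality.iterrows():
        sid = provenance[mag_id]
        records.append(
            MagRecord(
                mag_id=mag_id,
                sample_id=sid,
                host=metadata.loc[sid, "host"],
                site_or_colony=metadata.loc[sid, "site_or_colony"],
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                taxonomy=taxonomy.get(mag_id),
            )
        )
    return records


@dataclass
class DereplicationOutput:
    clusters: list[MagCluster]  # populated, relabelled with taxonomic ids
    display_ids: dict[str, str]  # mag_id -> taxonomic display id
    representative_of_cluster: dict[str, str]
    summary: pd.DataFrame


def run_dereplication(
    records: list[MagRecord],
    ani: AniMatrix,
    ani_threshold: float = catalog.ANI_CLUSTER_THRESHOLD,
    pseudo_ani: float = catalog.ANI_PSEUDOREPLICATE_THRESHOLD,
) -> DereplicationOutput:
    """Quality-gate, dereplicate at the ANI threshold, assign the remaining
    high-quality MAGs to clusters, and name clusters taxonomically."""
    passing = catalog.quality_gate(records)
    log.info("quality gate: %d of %d MAGs pass", len(passing), len(records))
    derep = catalog.dereplicate(passing, ani, threshold=ani_threshold)
    reps = catalog.representatives_only(derep)
    log.info("dereplication: %d representative MAGs", len(reps))
    rep_ids = {c.representative for c in reps}
    extra = [m for m in passing if m.mag_id not in rep_ids]
    by_id = {m.mag_id: m for m in passing}
    populated = catalog.assign_members(reps, extra, ani, pseudo_ani=pseudo_ani,
                                       records=by_id)
    display_ids = module_display_ids(records, rep_ids)
    relabelled = catalog.relabel_clusters(populated, display_ids)
    summary = catalog.cluster_summary(relabelled, by_id)
    log.info("clusters: %d, %d member MAGs total",
             len(relabelled), sum(c.n_members for c in relabelled))
    return DereplicationOutput(
        clusters=relabelled,
        display_ids=display_ids,
        representative_of_cluster={c.cluster_id: c.representative
                                   for c in relabelled},
        summary=summary,
    )


def module_display_ids(records: list[MagRecord],
                       rep_ids: set[str]) -> dict[str, str]:
    """Taxonomic display ids computed over representative MAGs only (the
    numbered ids the clusters are named after)."""
    taxa = {m.mag_id: m.taxonomy for m in records
            if m.mag_id in rep_ids and m.taxonomy is not None}
    return io.make_taxonomic_ids(taxa)


@dataclass
class ProfileOutput:
    alpha: pd.DataFrame
    distance: profile.DistanceMatrix
    pcoa_coords: pd.DataFrame
    pcoa_eigenvalues: pd.Series
    permanova: profile.PermanovaResult
    dispersion: profile.DispersionResult
    pairwise: pd.DataFrame | None


def run_profiling(
    abund: AbundanceTable,
    metadata: pd.DataFrame,
    n_perm: int = profile.DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    factor: str = "host",
) -> ProfileOutput:
    """Alpha diversity, Bray-Curtis distances, PCoA, PERMANOVA by the given
    factor, dispersion homogeneity, and Bonferroni pairwise contrasts."""
    alpha = profile.alpha_diversity(abund)
    dist = profile.bray_curtis_matrix(abund)
    coords, eigvals = profile.pcoa(dist)
    groups = metadata.loc[dist.ids, factor]
    result = profile.permanova(dist, groups.rename(factor),
                               n_perm=n_perm, seed=seed)
    term = result.terms[0]
    log.info("PERMANOVA %s: F=%.3f R2=%.3f p=%.4g",
             factor, term["F"], term["r2"], term["p"])
    disp = profile.dispersion_test(dist, groups, n_perm=min(n_perm, 999),
                                   seed=seed)
    pairwise = (profile.pairwise_permanova(dist, groups, n_perm=n_perm,
                                           seed=seed)
                if groups.nunique() >= 3 else None)
    return ProfileOutput(alpha, dist, coords, eigvals, result, disp, pairwise)


@dataclass
class ModuleOutput:
    relative_presence: pd.DataFrame  # clusters x modules
    q: pd.DataFrame  # samples x modules minimum probability of presence
    calls: pd.DataFrame  # boolean samples x modules
    prevalence: pd.DataFrame  # hosts x modules percent


def run_module_inference(
    clusters: list[MagCluster],
    module_table: ModuleCompletenessTable,
    abund: AbundanceTable,
    metadata: pd.DataFrame,
    representative_of_cluster: dict[str, str] | None = None,
) -> ModuleOutput:
    """Cluster relative presence -> per-sample minimum probability of
    presence -> presence calls -> per-host prevalence."""
    rel = module_inference.relative_presence(clusters, module_table)
    cluster_of_feature = None
    if representative_of_cluster is not None:
        cluster_of_feature = {rep: cid for cid, rep
                              in representative_of_cluster.items()}
    q = module_inference.module_presence_matrix(
        abund, rel, cluster_of_feature=cluster_of_feature)
    calls = module_inference.presence_calls(q)
    prevalence = module_inference.host_prevalence(calls, metadata)
    log.info("module inference: %d modules x %d samples, %d calls",
             q.shape[1], q.shape[0], int(calls.values.sum()))
    return ModuleOutput(rel, q, calls, prevalence)


@dataclass
class EnrichmentOutput:
    table: pd.DataFrame
    classification: pd.Series
    n_consistent: int
    n_universal: int
    percent_universal: int | None


def run_host_enrichment(
    module_out: ModuleOutput,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> EnrichmentOutput:
    """Host-level module enrichment (q-value significance) and the
    differentially-enriched / consistently-present / consistently-low
    classification with its universal-module summary."""
    hosts = metadata.loc[module_out.calls.index, "host"]
    table = enrichment.enrich_modules(module_out.calls, hosts, mode="by_host",
                                      alpha=alpha)
    classification = module_inference.classify_modules(
        table["q_fdr"], module_out.prevalence, alpha=alpha)
    n_consistent, n_universal, percent = module_inference.summarize_universal(
        classification, module_out.prevalence)
    counts = classification.value_counts()
    log.info(
        "classification: %d enriched, %d consistently present, %d low; "
        "%d/%d universal",
        counts.get("differentially_enriched", 0),
        counts.get("consistently_present", 0),
        counts.get("consistently_low", 0),
        n_universal, n_consistent,
    )
    return EnrichmentOutput(table, classification, n_consistent, n_universal,
                            percent)
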