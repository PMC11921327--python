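"""Host-structured synthetic communities for end-to-end pipeline testing.

The generator emulates the statistical structure of a multi-host bee gut
metagenome survey: ~10 genus-level phylotypes split into ~32
sequence-discrete clusters (within-cluster ANI above the 98% dereplication
threshold, between-cluster below it), host-specific cluster prevalence with
Dirichlet relative abundances plus an unmapped remainder, and a module
catalog built from a functionally redundant core shared by every cluster,
phylotype-level shared pools, and cluster-specific accessory modules.
Member MAGs inherit their cluster's module set minus a dropout whose rate
grows with genome incompleteness.

Every draw flows from one integer seed through a single generator stream,
so identical configurations produce byte-identical tables.  The
distributions are the package's own modeling choices; no generative model
is claimed for any real survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .types import (
    AbundanceTable,
    AniMatrix,
    MagRecord,
    ModuleCompletenessTable,
    TaxonomyString,
)

DEFAULT_HOSTS = (
    "B_impatiens_wild",
    "B_impatiens_Koppert",
    "B_impatiens_Biobest",
    "B_rufocinctus",
    "B_ternarius",
    "B_vagans",
)
COMMERCIAL_HOSTS = ("B_impatiens_Koppert", "B_impatiens_Biobest")

DEFAULT_PHYLOTYPES = (
    "Gilliamella",
    "Snodgrassella",
    "Bifidobacterium",
    "Lactobacillus",
    "Bombilactobacillus",
    "Schmidhempelia",
    "Apibacter",
    "Bombiscardovia",
    "Fructobacillus",
    "Frischella",
)


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the community simulator; defaults emulate a six-host bumble
    bee survey at the scale of roughly 30 clusters and 100 genomes."""

    n_hosts: int = 6
    samples_per_host: tuple[int, int] = (4, 12)
    n_phylotypes: int = 10
    clusters_per_phylotype: tuple[int, int] = (2, 4)
    mags_per_cluster: tuple[int, int] = (1, 5)
    n_modules: int = 100
    core_module_fraction: float = 0.4
    redundancy: float = 0.5  # fraction of non-core modules shared across >=2 phylotypes
    within_cluster_ani: tuple[float, float] = (98.2, 99.4)
    between_cluster_ani: tuple[float, float] = (80.0, 97.5)
    host_cluster_prevalence: np.ndarray | None = None  # hosts x clusters override
    host_inclusion_prob: float = 0.55  # chance a host carries a non-marker cluster
    prevalence_range: tuple[float, float] = (0.5, 0.95)
    abundance_concentration: float = 1.0  # Dirichlet concentration per present cluster
    min_present_abundance: float = 2.0  # percent floor for a present cluster
    unmapped_fraction: tuple[float, float] = (0.05, 0.45)  # fraction of reads unmapped
    fail_fraction: float = 0.15  # chance a non-anchor MAG fails the quality gate
    partial_completeness_prob: float = 0.05  # sub-threshold module noise rate
    ani_threshold: float = 98.0
    seed: int = 0

    def validate(self) -> None:
        def _interval(name, lo, hi, bounds):
            if not bounds[0] <= lo <= hi <= bounds[1]:
                raise ConfigError(
                    f"{name} interval ({lo}, {hi}) invalid within {bounds}"
                )

        if self.n_hosts < 1 or self.n_phylotypes < 1:
            raise ConfigError("need at least one host and one phylotype")
        if self.samples_per_host[0] < 1 or \
                self.samples_per_host[0] > self.samples_per_host[1]:
            raise ConfigError(f"bad samples_per_host {self.samples_per_host}")
        if self.clusters_per_phylotype[0] < 1 or \
                self.clusters_per_phylotype[0] > self.clusters_per_phylotype[1]:
            raise ConfigError(
                f"bad clusters_per_phylotype {self.clusters_per_phylotype}")
        if self.n_phylotypes * self.clusters_per_phylotype[1] < \
                max(1, self.n_hosts):
            raise ConfigError(
                "too few possible clusters: need at least one host-marker "
                "cluster per host")
        if self.mags_per_cluster[0] < 1 or \
                self.mags_per_cluster[0] > self.mags_per_cluster[1]:
            raise ConfigError(f"bad mags_per_cluster {self.mags_per_cluster}")
        if not 0 <= self.core_module_fraction <= 1:
            raise ConfigError("core_module_fraction outside [0, 1]")
        if not 0 <= self.redundancy <= 1:
            raise ConfigError("redundancy outside [0, 1]")
        _interval("within_cluster_ani", *self.within_cluster_ani,
                  (self.ani_threshold, 100.0))
        lo, hi = self.between_cluster_ani
        if not (75.0 <= lo <= hi < self.ani_threshold):
            raise ConfigError(
                f"between_cluster_ani ({lo}, {hi}) must lie in "
                f"[75, {self.ani_threshold})")
        lo, hi = self.unmapped_fraction
        if not (0.0 <= lo <= hi < 1.0):
            raise ConfigError(f"bad unmapped_fraction ({lo}, {hi})")
        if self.host_cluster_prevalence is not None:
            prev = np.asarray(self.host_cluster_prevalence)
            if prev.min() < 0 or prev.max() > 1:
                raise ConfigError("host_cluster_prevalence entries outside [0, 1]")


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    mag_cluster: dict[str, str] = field(default_factory=dict)
    cluster_phylotype: dict[str, str] = field(default_factory=dict)
    cluster_modules: dict[str, set[str]] = field(default_factory=dict)
    cluster_representative: dict[str, str] = field(default_factory=dict)
    sample_clusters: dict[str, set[str]] = field(default_factory=dict)
    core_modules: set[str] = field(default_factory=set)
    marker_cluster_of_host: dict[str, str] = field(default_factory=dict)
    planted_modules: dict[str, dict] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """The five interchange tables plus the ground truth behind them."""

    config: SimConfig
    quality: pd.DataFrame  # name-indexed completeness/contamination
    taxonomy: dict[str, TaxonomyString]
    ani: AniMatrix
    abundance: AbundanceTable  # features are representative MAG ids
    modules: ModuleCompletenessTable
    metadata: pd.DataFrame
    truth: GroundTruth

    def mag_records(self) -> list[MagRecord]:
        records = []
        for mag_id, row in self.quality.iterrows():
            cluster = self.truth.mag_cluster[mag_id]
            sid = self._mag_sample[mag_id]
            records.append(
                MagRecord(
                    mag_id=mag_id,
                    sample_id=sid,
                    host=self.metadata.loc[sid, "host"],
                    site_or_colony=self.metadata.loc[sid, "site_or_colony"],
                    completeness=float(row.completeness),
                    contamination=float(row.contamination),
                    taxonomy=self.taxonomy[mag_id],
                )
            )
        return records

    _mag_sample: dict[str, str] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_quality_table(outdir / "quality.tsv", self.quality)
        io.write_taxonomy_table(outdir / "taxonomy.tsv", self.taxonomy)
        io.write_ani_matrix(outdir / "ani.tsv", self.ani)
        io.write_abundance_table(outdir / "abundance.tsv", self.abundance)
        io.write_module_table(outdir / "modules.tsv", self.modules)
        io.write_metadata(outdir / "metadata.tsv", self.metadata)
        io._write_rows(
            outdir / "mag_provenance.tsv",
            ("mag_id", "sample_id"),
            sorted(self._mag_sample.items()),
        )
        rows = [("mag", m, c) for m, c in sorted(self.truth.mag_cluster.items())]
        rows += [("core_module", m, "") for m in sorted(self.truth.core_modules)]
        rows += [
            ("planted_module", m, ";".join(info["hosts"]))
            for m, info in sorted(self.truth.planted_modules.items())
        ]
        io._write_rows(outdir / "ground_truth.tsv", ("kind", "id", "value"), rows)


def _quality_draw(rng: np.random.Generator, passes: bool) -> tuple[float, float]:
    if passes:
        completeness = float(np.clip(100.0 - rng.exponential(3.0), 80.5, 100.0))
        contamination = float(np.clip(rng.exponential(0.8), 0.0, 9.5))
    elif rng.random() < 0.5:
        completeness = float(rng.uniform(50.0, 80.0))
        contamination = float(np.clip(rng.exponential(0.8), 0.0, 9.5))
    else:
        completeness = float(np.clip(100.0 - rng.exponential(3.0), 80.5, 100.0))
        contamination = float(rng.uniform(10.0, 25.0))
    return round(completeness, 2), round(contamination, 2)


def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic survey from one seeded generator stream."""
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    hosts = list(DEFAULT_HOSTS[: config.n_hosts]) if config.n_hosts <= len(
        DEFAULT_HOSTS) else [f"host_{i + 1}" for i in range(config.n_hosts)]
    phylotypes = list(DEFAULT_PHYLOTYPES[: config.n_phylotypes]) if \
        config.n_phylotypes <= len(DEFAULT_PHYLOTYPES) else \
        [f"Genus{i + 1}" for i in range(config.n_phylotypes)]

    # --- clusters per phylotype (ensure at least one marker per host) ------
    lo, hi = config.clusters_per_phylotype
    while True:
        counts = rng.integers(lo, hi + 1, size=config.n_phylotypes)
        if counts.sum() >= config.n_hosts:
            break
    clusters: list[str] = []
    cluster_phylotype: dict[str, str] = {}
    for genus, k in zip(phylotypes, counts):
        for j in range(k):
            cid = f"{genus}_c{j + 1}"
            clusters.append(cid)
            cluster_phylotype[cid] = genus
    n_clusters = len(clusters)

    # --- host-specific prevalence; first n_hosts clusters are exclusive ----
    # markers (prevalence 1 in their own host, 0 elsewhere), emulating
    # host-specific strains and guaranteeing every sample is non-empty
    if config.host_cluster_prevalence is not None:
        prevalence = np.asarray(config.host_cluster_prevalence, dtype=float)
        if prevalence.shape != (config.n_hosts, n_clusters):
            raise ConfigError(
                f"host_cluster_prevalence shape {prevalence.shape} != "
                f"({config.n_hosts}, {n_clusters})")
        marker_of_host = {}
    else:
        prevalence = np.zeros((config.n_hosts, n_clusters))
        marker_of_host = {hosts[h]: clusters[h] for h in range(config.n_hosts)}
        for h in range(config.n_hosts):
            prevalence[h, h] = 1.0
        p_lo, p_hi = config.prevalence_range
        for c in range(config.n_hosts, n_clusters):
            for h in range(config.n_hosts):
                if rng.random() < config.host_inclusion_prob:
                    prevalence[h, c] = rng.uniform(p_lo, p_hi)

    # --- samples and metadata ----------------------------------------------
    sample_rows = []
    for h, host in enumerate(hosts):
        n_s = int(rng.integers(config.samples_per_host[0],
                               config.samples_per_host[1] + 1))
        origin = "commercial" if host in COMMERCIAL_HOSTS else "wild"
        for _ in range(n_s):
            sid = f"s{len(sample_rows) + 1:03d}"
            pool = ("colony" if origin == "commercial" else "site")
            sample_rows.append(
                (sid, host, f"{pool}{int(rng.integers(1, 4))}", origin))
    metadata = pd.DataFrame(
        sample_rows, columns=["sample_id", "host", "site_or_colony", "origin"]
    ).set_index("sample_id")

    # --- per-sample cluster presence ---------------------------------------
    sample_clusters: dict[str, set[str]] = {}
    for sid, row in metadata.iterrows():
        h = hosts.index(row.host)
        present = {clusters[c] for c in range(n_clusters)
                   if rng.random() < prevalence[h, c]}
        sample_clusters[sid] = present

    # --- MAGs: membership, provenance, quality, taxonomy -------------------
    mag_cluster: dict[str, str] = {}
    mag_sample: dict[str, str] = {}
    quality_rows: dict[str, tuple[float, float]] = {}
    taxonomy: dict[str, TaxonomyString] = {}
    species_named = rng.random(n_clusters) > 0.3  # 30% stop at genus rank
    sample_ids = list(metadata.index)
    for c, cid in enumerate(clusters):
        genus = cluster_phylotype[cid]
        n_mags = int(rng.integers(config.mags_per_cluster[0],
                                  config.mags_per_cluster[1] + 1))
        carriers = [s for s in sample_ids if cid in sample_clusters[s]]
        for k in range(n_mags):
            mag_id = f"mag{len(mag_cluster) + 1:04d}"
            mag_cluster[mag_id] = cid
            pool = carriers if carriers else sample_ids
            mag_sample[mag_id] = pool[int(rng.integers(len(pool)))]
            # the first MAG of each cluster always passes the gate so every
            # cluster keeps a representative after quality filtering
            passes = k == 0 or rng.random() >= config.fail_fraction
            quality_rows[mag_id] = _quality_draw(rng, passes)
            species = f"{genus} sp{c + 1}" if species_named[c] else ""
            taxonomy[mag_id] = TaxonomyString(
                ("Bacteria", f"p_{genus}", f"c_{genus}", f"o_{genus}",
                 f"f_{genus}", genus, species))
    mags = list(mag_cluster)
    quality = pd.DataFrame(
        [quality_rows[m] for m in mags],
        index=pd.Index(mags, name="name"),
        columns=["completeness", "contamination"],
    )

    # --- ANI block matrix ---------------------------------------------------
    n_mags_total = len(mags)
    w_lo, w_hi = config.within_cluster_ani
    b_lo, b_hi = config.between_cluster_ani
    ani_values = np.full((n_mags_total, n_mags_total), 100.0)
    for i in range(n_mags_total):
        for j in range(i + 1, n_mags_total):
            same = mag_cluster[mags[i]] == mag_cluster[mags[j]]
            value = rng.uniform(w_lo, w_hi) if same else rng.uniform(b_lo, b_hi)
            ani_values[i, j] = ani_values[j, i] = round(value, 3)
    ani = AniMatrix(mags, ani_values)

    # --- module catalog: core + phylotype-shared + accessory ----------------
    module_ids = [f"M{i + 1:05d}" for i in range(config.n_modules)]
    n_core = int(round(config.n_modules * config.core_module_fraction))
    core = set(module_ids[:n_core])
    noncore = module_ids[n_core:]
    n_shared = int(round(len(noncore) * config.redundancy))
    cluster_modules: dict[str, set[str]] = {cid: set(core) for cid in clusters}
    for m in noncore[:n_shared]:
        k = int(rng.integers(2, max(3, config.n_phylotypes + 1)))
        chosen = rng.choice(phylotypes, size=min(k, config.n_phylotypes),
                            replace=False)
        for cid in clusters:
            if cluster_phylotype[cid] in chosen:
                cluster_modules[cid].add(m)
    for m in noncore[n_shared:]:
        cluster_modules[clusters[int(rng.integers(n_clusters))]].add(m)

    # --- MAG-level stepwise completeness with completeness-tied dropout ----
    comp_frame = pd.DataFrame(
        0.0, index=pd.Index(mags, name="mag_id"), columns=module_ids)
    for mag_id in mags:
        dropout = (100.0 - quality_rows[mag_id][0]) / 100.0
        owned = cluster_modules[mag_cluster[mag_id]]
        for m in module_ids:
            if m in owned and rng.random() >= dropout:
                comp_frame.loc[mag_id, m] = round(rng.uniform(0.75, 1.0), 4)
            elif rng.random() < config.partial_completeness_prob:
                comp_frame.loc[mag_id, m] = round(rng.uniform(0.0, 0.7), 4)
    modules = ModuleCompletenessTable(comp_frame)

    # --- representatives and abundance --------------------------------------
    representative = {}
    for cid in clusters:
        candidates = [
            m for m in mags
            if mag_cluster[m] == cid
            and quality_rows[m][0] > 80.0 and quality_rows[m][1] < 10.0
        ]
        representative[cid] = min(
            candidates,
            key=lambda m: (-(quality_rows[m][0] - 5.0 * quality_rows[m][1]), m),
        )
    abundance = _draw_abundance(rng, config, metadata, clusters,
                                sample_clusters, representative)

    truth = GroundTruth(
        mag_cluster=mag_cluster,
        cluster_phylotype=cluster_phylotype,
        cluster_modules=cluster_modules,
        cluster_representative=representative,
        sample_clusters=sample_clusters,
        core_modules=core,
        marker_cluster_of_host=marker_of_host,
    )
    dataset = SimulatedDataset(
        config=config, quality=quality, taxonomy=taxonomy, ani=ani,
        abundance=abundance, modules=modules, metadata=metadata, truth=truth,
    )
    dataset._mag_sample = mag_sample
    return dataset


def _draw_abundance(
    rng: np.random.Generator,
    config: SimConfig,
    metadata: pd.DataFrame,
    clusters: list[str],
    sample_clusters: dict[str, set[str]],
    representative: dict[str, str],
) -> AbundanceTable:
    """Dirichlet abundances over present clusters with a guaranteed floor
    above the >1% presence rule, scaled to (100 - unmapped)."""
    features = [representative[c] for c in clusters]
    values = pd.DataFrame(
        0.0, index=metadata.index.copy(), columns=features)
    unmapped = pd.Series(0.0, index=values.index, name="unmapped")
    u_lo, u_hi = config.unmapped_fraction
    for sid in metadata.index:
        present = sorted(sample_clusters[sid])
        unmapped[sid] = round(rng.uniform(u_lo, u_hi) * 100.0, 6)
        mapped = 100.0 - unmapped[sid]
        if not present:
            unmapped[sid] = 100.0
            continue
        k = len(present)
        floor = min(config.min_present_abundance, 0.9 * mapped / k)
        weights = rng.dirichlet(np.full(k, config.abundance_concentration))
        share = floor + weights * (mapped - floor * k)
        for c, v in zip(present, share):
            values.loc[sid, representative[c]] = v
    # make each row close exactly to 100 despite rounding of unmapped
    totals = values.sum(axis=1)
    scale = (100.0 - unmapped) / totals.where(totals > 0, 1.0)
    values = values.mul(scale, axis=0)
    unmapped[totals == 0] = 100.0
    return AbundanceTable(values, unmapped)


def plant_enrichment(
    dataset: SimulatedDataset,
    modules: list[str],
    hosts: list[str],
    contrast: tuple[float, float],
    seed: int | None = None,
) -> SimulatedDataset:
    """Rewire listed modules so their expected per-host prevalence equals
    ``p_high`` in the listed hosts and ``p_low`` elsewhere.

    Each host's exclusive marker cluster becomes the module's sole carrier
    (relative presence 1 there, 0 in every other cluster).  For fractional
    targets the marker's per-sample presence is redrawn Bernoulli(p), which
    is the only channel through which a cluster-level module model can
    realize an expected prevalence strictly between 0 and 1.  Mutates and
    returns the dataset.
    """
    p_high, p_low = contrast
    if not (0 <= p_high <= 1 and 0 <= p_low <= 1):
        raise ValueError(f"contrast {contrast} outside [0, 1]")
    unknown = [m for m in modules if m not in dataset.modules.modules]
    if unknown:
        raise ValueError(f"modules not in catalog: {unknown}")
    host_levels = list(dataset.metadata["host"].unique())
    bad_hosts = [h for h in hosts if h not in host_levels]
    if bad_hosts:
        raise ValueError(f"unknown hosts: {bad_hosts}")
    if not dataset.truth.marker_cluster_of_host:
        raise ValueError(
            "dataset has no host-marker clusters (custom prevalence matrix); "
            "cannot plant enrichment")

    rng = np.random.default_rng(
        dataset.config.seed + 1 if seed is None else seed)
    truth = dataset.truth
    comp = dataset.modules.values

    targets = {h: (p_high if h in hosts else p_low) for h in host_levels}
    # fractional targets need per-sample marker presence at rate p
    for host, p in targets.items():
        if 0.0 < p < 1.0:
            _redraw_marker_presence(dataset, rng, host, p)

    carrier_mags = {
        h: [m for m, c in truth.mag_cluster.items()
            if c == truth.marker_cluster_of_host[h]]
        for h in host_levels
    }
    for module in modules:
        comp[module] = 0.0
        for c in truth.cluster_modules.values():
            c.discard(module)
        for host, p in targets.items():
            if p > 0.0:
                comp.loc[carrier_mags[host], module] = 1.0
                truth.cluster_modules[
                    truth.marker_cluster_of_host[host]].add(module)
        truth.planted_modules[module] = {
            "hosts": list(hosts), "contrast": (p_high, p_low)}
    dataset.modules = ModuleCompletenessTable(comp)
    return dataset


def _redraw_marker_presence(
    dataset: SimulatedDataset, rng: np.random.Generator, host: str, p: float
) -> None:
    """Set the host's marker cluster present in each of the host's samples
    independently with probability p, rebalancing abundance rows in place."""
    truth = dataset.truth
    marker = truth.marker_cluster_of_host[host]
    rep = truth.cluster_representative[marker]
    values, unmapped = dataset.abundance.values, dataset.abundance.unmapped
    floor = dataset.config.min_present_abundance
    for sid in dataset.metadata.index[dataset.metadata["host"] == host]:
        mapped = 100.0 - unmapped[sid]
        want = rng.random() < p
        row = values.loc[sid]
        if want:
            others = row.drop(rep)
            other_total = others.sum()
            share = min(floor, 0.5 * mapped)
            if other_total > 0:
                values.loc[sid, others.index] = \
                    others * (mapped - share) / other_total
            values.loc[sid, rep] = share if other_total > 0 else mapped
        else:
            freed = row[rep]
            values.loc[sid, rep] = 0.0
            others = row.drop(rep)
            if others.sum() > 0 and freed > 0:
                values.loc[sid, others.index] = \
                    others * mapped / others.sum()
            elif freed > 0:
                unmapped[sid] = 100.0
        # presence truth follows the final abundances
        truth.sample_clusters[sid] = {
            c for c in truth.cluster_representative
            if values.loc[sid, truth.cluster_representative[c]] > 1.0
        }
    dataset.abundance = AbundanceTable(values, unmapped)
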