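"""Core data containers shared across the pipeline.

Scale conventions: completeness, contamination and relative abundance are
percentages on the 0-100 scale (as printed by the upstream quality/coverage
tools); module stepwise completeness and all probabilities are on 0-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")

#: stepwise-completeness value at and above which a module counts as encoded
MODULE_COMPLETION_THRESHOLD = 0.75


class FormatError(ValueError):
    """A table does not conform to its declared dialect."""


@dataclass(frozen=True)
class TaxonomyString:
    """A GTDB-style 7-rank lineage (domain ... species); empty = unassigned.

    Ranks must be filled top-down: once a rank is empty every rank below it
    is empty too.
    """

    ranks: tuple[str, str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(f"expected {len(RANKS)} ranks, got {len(self.ranks)}")
        seen_empty = False
        for label in self.ranks:
            if label == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"rank {label!r} is filled below an empty rank in {self.ranks}"
                )

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def lowest_nonempty_rank(self) -> str:
        for label in reversed(self.ranks):
            if label:
                return label
        raise ValueError("taxonomy has no assigned ranks")

    def to_gtdb(self) -> str:
        return ";".join(p + r for p, r in zip(RANK_PREFIXES, self.ranks))


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    host: str
    site_or_colony: str
    origin: str  # "commercial" | "wild"

    def __post_init__(self) -> None:
        if not self.sample_id or not self.host or not self.site_or_colony:
            raise ValueError("sample_id, host and site_or_colony must be non-empty")


@dataclass(frozen=True)
class MagRecord:
    """One genome bin with quality estimates and provenance."""

    mag_id: str
    sample_id: str
    host: str
    site_or_colony: str
    completeness: float  # percent
    contamination: float  # percent
    taxonomy: TaxonomyString | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValueError(f"completeness {self.completeness} outside [0, 100]")
        if not 0 <= self.contamination <= 100:
            raise ValueError(f"contamination {self.contamination} outside [0, 100]")


class AniMatrix:
    """Symmetric pairwise average-nucleotide-identity matrix (percent)."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"ANI matrix shape {values.shape} != ({n}, {n})")
        if len(set(ids)) != n:
            raise ValueError("duplicate ids in ANI matrix")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("ANI matrix is not symmetric")
        if not np.allclose(np.diag(values), 100.0, atol=1e-9):
            raise ValueError("ANI matrix diagonal must be 100")
        if values.min() < 0 or values.max() > 100 + 1e-9:
            raise ValueError("ANI values must lie in [0, 100]")
        self.ids = list(ids)
        self.values = values
        self._index = {m: i for i, m in enumerate(self.ids)}

    def ani(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"MAG {exc.args[0]!r} missing from ANI matrix") from None

    def __contains__(self, mag_id: str) -> bool:
        return mag_id in self._index

    def subset(self, ids: list[str]) -> "AniMatrix":
        idx = [self._index[m] for m in ids]
        return AniMatrix(ids, self.values[np.ix_(idx, idx)])


@dataclass
class MagCluster:
    """A representative MAG plus the members assigned to it.

    ``members`` always includes the representative.
    """

    cluster_id: str
    representative: str
    members: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            self.members = [self.representative] + list(self.members)

    @property
    def n_members(self) -> int:
        return len(self.members)


class AbundanceTable:
    """Samples x features relative abundance (percent) plus unmapped fraction.

    Each sample row sums to 100 including its unmapped percentage.
    """

    def __init__(self, values: pd.DataFrame, unmapped: pd.Series):
        values = values.astype(float)
        unmapped = unmapped.astype(float).reindex(values.index)
        if (values.values < -1e-9).any():
            raise ValueError("negative relative abundance")
        if unmapped.isna().any():
            raise ValueError("unmapped fraction missing for some samples")
        totals = values.sum(axis=1) + unmapped
        if not np.allclose(totals, 100.0, atol=1e-6):
            bad = totals[~np.isclose(totals, 100.0, atol=1e-6)].index.tolist()
            raise ValueError(f"sample rows do not sum to 100%: {bad}")
        self.values = values
        self.unmapped = unmapped

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]


class ModuleCompletenessTable:
    """Dense MAGs x modules stepwise-completeness matrix on [0, 1].

    Missing (mag, module) pairs are completeness 0.  Presence means
    completeness >= the stepwise completion threshold (0.75, inclusive).
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float).fillna(0.0)
        if (values.values < 0).any() or (values.values > 1).any():
            raise ValueError("stepwise completeness outside [0, 1]")
        self.values = values

    @property
    def mags(self) -> list[str]:
        return list(self.values.index)

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)

    def presence(self, threshold: float = MODULE_COMPLETION_THRESHOLD) -> pd.DataFrame:
        return self.values >= threshold
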