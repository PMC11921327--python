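"""Community diversity, ordination and permutation statistics.

Distances (Bray-Curtis on renormalized mapped abundances, Jaccard on
presence/absence) feed classical principal-coordinates analysis, PERMANOVA
with sequential sums of squares (McArdle-Anderson trace partition of the
Gower-centered inner-product matrix), a beta-dispersion homogeneity test
around per-group spatial medians, and Bonferroni-corrected pairwise
PERMANOVAs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AbundanceTable

DEFAULT_PERMUTATIONS = 9999


class DistanceMatrix:
    """Symmetric distance matrix with zero diagonal over labelled samples."""

    def __init__(self, ids: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        n = len(ids)
        if values.shape != (n, n):
            raise ValueError(f"distance matrix shape {values.shape} != ({n}, {n})")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be 0")
        if values.min() < -1e-12:
            raise ValueError("negative distances")
        self.ids = list(ids)
        self.values = values

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# profiles and alpha diversity


def aggregate_phylotypes(
    abund: AbundanceTable, id_map: dict[str, str]
) -> AbundanceTable:
    """Sum MAG-level abundances into genus-level (phylotype) abundances.

    The unmapped fraction is carried through unchanged, so row sums are
    preserved exactly.
    """
    missing = [f for f in abund.features if f not in id_map]
    if missing:
        raise KeyError(f"features not mapped to a phylotype: {missing}")
    grouped = abund.values.T.groupby(
        abund.values.columns.map(id_map)).sum().T
    return AbundanceTable(grouped, abund.unmapped.copy())


def richness(profile: pd.Series | np.ndarray, detection: float = 0.0) -> int:
    """Number of features with abundance strictly above the detection limit."""
    values = np.asarray(profile, dtype=float)
    return int((values > detection).sum())


def shannon(profile: pd.Series | np.ndarray) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over the renormalized
    positive abundances; zero-abundance features do not contribute."""
    values = np.asarray(profile, dtype=float)
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("Shannon diversity undefined for an all-zero profile")
    p = positive / positive.sum()
    return float(-(p * np.log(p)).sum())


def alpha_diversity(abund: AbundanceTable) -> pd.DataFrame:
    """Per-sample richness and Shannon diversity (unmapped excluded)."""
    rows = {}
    for sid in abund.samples:
        profile = abund.profile(sid)
        rows[sid] = {
            "richness": richness(profile),
            "shannon": shannon(profile) if (profile > 0).any() else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / (sum(a) + sum(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    total = a.sum() + b.sum()
    if total == 0:
        raise ValueError("Bray-Curtis undefined when both profiles are all zero")
    return float(1.0 - 2.0 * np.minimum(a, b).sum() / total)


def jaccard_distance(a, b) -> float:
    """Jaccard distance 1 - |A n B| / |A u B| between feature sets; 0 when
    both sets are empty.  Accepts sets or boolean vectors."""
    if isinstance(a, (set, frozenset)) or isinstance(b, (set, frozenset)):
        a, b = set(a), set(b)
        union = len(a | b)
        return 0.0 if union == 0 else 1.0 - len(a & b) / union
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = (a | b).sum()
    return 0.0 if union == 0 else float(1.0 - (a & b).sum() / union)


def bray_curtis_matrix(abund: AbundanceTable) -> DistanceMatrix:
    """All-pairs Bray-Curtis on mapped-only, renormalized compositions."""
    comp = abund.values.to_numpy(dtype=float)
    totals = comp.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        bad = [s for s, t in zip(abund.samples, totals[:, 0]) if t == 0]
        raise ValueError(f"samples with no mapped abundance: {bad}")
    comp = comp / totals
    n = comp.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(comp[i], comp[j])
    return DistanceMatrix(abund.samples, out)


def jaccard_matrix(presence: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Jaccard distance on a boolean units x features frame."""
    values = presence.to_numpy(dtype=bool)
    n = values.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = jaccard_distance(values[i], values[j])
    return DistanceMatrix(list(presence.index), out)


# ---------------------------------------------------------------------------
# ordination


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def pcoa(d: DistanceMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Classical (metric) multidimensional scaling.

    Returns (coordinates, eigenvalues).  Eigenvalues are reported in full,
    negative ones included; coordinate axes are kept only for positive
    eigenvalues (no Lingoes/Cailliez correction is applied).
    """
    g = _gower_center(d.values ** 2)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals[0]), abs(eigvals[-1]), 1.0) * 1e-10
    keep = eigvals > tol
    coords = eigvecs[:, keep] * np.sqrt(eigvals[keep])
    axes = [f"PCo{i + 1}" for i in range(keep.sum())]
    return (
        pd.DataFrame(coords, index=d.ids, columns=axes),
        pd.Series(eigvals, index=[f"PCo{i + 1}" for i in range(len(eigvals))],
                  name="eigenvalue"),
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    terms: list[dict] = field(default_factory=list)  # name, df, ss, F, r2, p
    residual_df: int = 0
    residual_ss: float = 0.0
    total_ss: float = 0.0
    n_permutations: int = 0
    seed: int | None = None

    @property
    def p_values(self) -> dict[str, float]:
        return {t["name"]: t["p"] for t in self.terms}

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(t) for t in self.terms]
        rows.append({"name": "Residual", "df": self.residual_df,
                     "ss": self.residual_ss,
                     "r2": self.residual_ss / self.total_ss
                     if self.total_ss else np.nan})
        rows.append({"name": "Total",
                     "df": self.residual_df + sum(t["df"] for t in self.terms),
                     "ss": self.total_ss, "r2": 1.0})
        return pd.DataFrame(rows).set_index("name")


def _as_design(design, ids: list[str]) -> pd.DataFrame:
    if isinstance(design, pd.Series):
        design = design.to_frame(design.name or "factor")
    if not isinstance(design, pd.DataFrame):
        raise TypeError("design must be a Series or DataFrame of factor levels")
    if design.shape[1] not in (1, 2):
        raise ValueError("design must have 1 or 2 factors")
    missing = [s for s in ids if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")
    return design.loc[ids]


def _dummy(levels: pd.Series) -> np.ndarray:
    cats = pd.Categorical(levels)
    return np.eye(len(cats.categories))[cats.codes]


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto the column space of [1 | x]; the dummy coding is
    # rank-deficient, so build the projector from the SVD range basis
    x = np.column_stack([np.ones(x.shape[0]), x])
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    u = u[:, s > s.max() * 1e-10]
    return u @ u.T


def _sequential_stats(
    g: np.ndarray, hats: list[np.ndarray], dfs: list[int], df_resid: int
) -> tuple[list[float], list[float], float]:
    """Sequential SS per term from nested hat matrices; returns
    (per-term SS, per-term F, residual SS)."""
    total = float(np.trace(g))
    explained_prev = 0.0
    term_ss = []
    for hat in hats:
        explained = float(np.sum(hat * g))  # tr(H G), H symmetric
        term_ss.append(explained - explained_prev)
        explained_prev = explained
    resid_ss = total - explained_prev
    if resid_ss < 1e-12 * max(abs(total), 1.0):  # numerically zero residual
        resid_ss = 0.0
    fs = [
        (ss / df) / (resid_ss / df_resid) if resid_ss > 0 and df > 0 else np.inf
        for ss, df in zip(term_ss, dfs)
    ]
    return term_ss, fs, resid_ss


def permanova(
    d: DistanceMatrix,
    design: pd.DataFrame | pd.Series,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    One or two categorical factors; with two factors, sums of squares are
    sequential in column order (the first factor is entered first).
    Significance is by free permutation of samples, jointly permuting the
    rows and columns of the distance matrix:
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With ``exhaustive`` all
    n! sample orderings are enumerated instead and p is the exact
    proportion attaining F >= F_obs.
    """
    design = _as_design(design, d.ids)
    n = len(d.ids)
    term_names = list(design.columns)
    for name in term_names:
        if design[name].nunique() < 2:
            raise ValueError(f"factor {name!r} has fewer than 2 levels")

    g = _gower_center(d.values ** 2)
    dummies = [_dummy(design[name]) for name in term_names]
    hats, dfs = [], []
    cum = None
    rank_prev = 1
    for x in dummies:
        cum = x if cum is None else np.hstack([cum, x])
        hat = _hat(cum)
        rank = int(round(np.trace(hat)))
        hats.append(hat)
        dfs.append(rank - rank_prev)
        rank_prev = rank
    df_resid = n - rank_prev
    if df_resid <= 0:
        raise ValueError("design leaves no residual degrees of freedom")

    obs_ss, obs_f, resid_ss = _sequential_stats(g, hats, dfs, df_resid)
    total_ss = float(np.trace(g))

    # zero tolerance for an infinite observed F: only permutations that are
    # themselves degenerate (zero residual) can match it
    tol = [1e-9 * max(1.0, abs(f)) if np.isfinite(f) else 0.0 for f in obs_f]
    if exhaustive:
        exceed = [0] * len(term_names)
        count = 0
        for perm in itertools.permutations(range(n)):
            gp = g[np.ix_(perm, perm)]
            _, fs, _ = _sequential_stats(gp, hats, dfs, df_resid)
            count += 1
            for k, f in enumerate(fs):
                if f >= obs_f[k] - tol[k]:
                    exceed[k] += 1
        p_vals = [e / count for e in exceed]
        n_used = count
    else:
        rng = np.random.default_rng(seed)
        exceed = [0] * len(term_names)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            _, fs, _ = _sequential_stats(gp, hats, dfs, df_resid)
            for k, f in enumerate(fs):
                if f >= obs_f[k] - tol[k]:
                    exceed[k] += 1
        p_vals = [(1 + e) / (1 + n_perm) for e in exceed]
        n_used = n_perm

    result = PermanovaResult(
        residual_df=df_resid, residual_ss=resid_ss, total_ss=total_ss,
        n_permutations=n_used, seed=seed,
    )
    for k, name in enumerate(term_names):
        result.terms.append(
            {"name": name, "df": dfs[k], "ss": obs_ss[k], "F": obs_f[k],
             "r2": obs_ss[k] / total_ss if total_ss else np.nan,
             "p": p_vals[k]}
        )
    return result


def pairwise_permanova(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """One PERMANOVA per group pair on the pair's sub-matrix, with
    Bonferroni correction over the number of pairs."""
    groups = groups.loc[d.ids]
    levels = sorted(groups.unique())
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        ids = [s for s in d.ids if groups[s] in (a, b)]
        sub = d.subset(ids)
        res = permanova(sub, groups.loc[ids].rename("group"),
                        n_perm=n_perm, seed=seed)
        term = res.terms[0]
        rows.append(
            {"pair": f"{a} vs {b}", "F": term["F"], "r2": term["r2"],
             "p_raw": term["p"],
             "p_bonferroni": min(1.0, term["p"] * len(pairs))}
        )
    return pd.DataFrame(rows).set_index("pair")


# ---------------------------------------------------------------------------
# beta dispersion


@dataclass
class DispersionResult:
    distances: pd.Series = None  # per-sample distance to its group center
    group_centers: dict = field(default_factory=dict)
    f_statistic: float = np.nan
    df_between: int = 0
    df_within: int = 0
    p_value: float = np.nan
    n_permutations: int = 0


def _spatial_median(points: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 1000) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iterative reweighting."""
    if points.shape[0] == 1:
        return points[0].copy()
    center = points.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(points - center, axis=1)
        at_point = dist < tol
        if at_point.any():
            dist[at_point] = tol
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - center) < tol:
            return new
        center = new
    return center


def dispersion_test(
    d: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersions around spatial medians.

    Samples are embedded by principal coordinates keeping negative-eigenvalue
    axes as an imaginary component; each sample's dispersion is
    sqrt(max(0, |real - median_real|^2 - |imag - median_imag|^2)) with the
    per-group spatial median fitted separately on the real and imaginary
    axes.  The homogeneity F statistic is a one-way ANOVA on those
    distances, with significance from permuting the distances across groups.
    """
    groups = groups.loc[d.ids]
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValueError("dispersion test requires at least 2 groups")

    g = _gower_center(d.values ** 2)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(), 1.0) * 1e-10
    real = eigvecs[:, eigvals > tol] * np.sqrt(eigvals[eigvals > tol])
    imag = eigvecs[:, eigvals < -tol] * np.sqrt(-eigvals[eigvals < -tol])

    distances = np.zeros(len(d.ids))
    centers = {}
    for level in levels:
        mask = (groups == level).to_numpy()
        if mask.sum() == 1:
            warnings.warn(f"group {level!r} has a single sample; dispersion 0")
            distances[mask] = 0.0
            centers[level] = (real[mask][0],
                              imag[mask][0] if imag.size else np.array([]))
            continue
        med_r = _spatial_median(real[mask]) if real.size else np.array([])
        med_i = _spatial_median(imag[mask]) if imag.size else np.array([])
        dr2 = (np.linalg.norm(real[mask] - med_r, axis=1) ** 2
               if real.size else np.zeros(mask.sum()))
        di2 = (np.linalg.norm(imag[mask] - med_i, axis=1) ** 2
               if imag.size else np.zeros(mask.sum()))
        distances[mask] = np.sqrt(np.maximum(0.0, dr2 - di2))
        centers[level] = (med_r, med_i)

    dist_series = pd.Series(distances, index=d.ids, name="distance_to_center")
    f_obs, df_b, df_w = _anova_f(distances, groups.to_numpy())

    rng = np.random.default_rng(seed)
    exceed = 0
    labels = groups.to_numpy()
    for _ in range(n_perm):
        f_perm, _, _ = _anova_f(distances, labels[rng.permutation(len(labels))])
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return DispersionResult(
        distances=dist_series, group_centers=centers, f_statistic=f_obs,
        df_between=df_b, df_within=df_w, p_value=p, n_permutations=n_perm,
    )


def _anova_f(values: np.ndarray, labels: np.ndarray) -> tuple[float, int, int]:
    levels = np.unique(labels)
    grand = values.mean()
    ss_b = sum((values[labels == l].mean() - grand) ** 2 * (labels == l).sum()
               for l in levels)
    ss_w = sum(((values[labels == l] - values[labels == l].mean()) ** 2).sum()
               for l in levels)
    df_b = len(levels) - 1
    df_w = len(values) - len(levels)
    if ss_w <= 0:
        return (math.inf if ss_b > 0 else 0.0), df_b, df_w
    return float((ss_b / df_b) / (ss_w / df_w)), df_b, df_w
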