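"""Correlation-based guild detection and signed co-occurrence networks.

Guilds — metabolite modules and microbial co-abundance groups (CAGs) — are
found by average-linkage hierarchical clustering on the Spearman
correlation distance (1 - rho), with the dendrogram cut at a fixed height
(0.4 for metabolite modules, 0.5 for species CAGs). Each guild's cumulative
abundance is the sum of its members' abundances. The co-occurrence network
keeps feature pairs whose |rho| exceeds a threshold with a
Benjamini–Hochberg-adjusted p below alpha.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import benjamini_hochberg
from .io_core import AbundanceTable

logger = logging.getLogger("guildlink")

_EXACT_N_MAX = 9


@lru_cache(maxsize=None)
def _exact_rho_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of |Spearman rho| for tie-free samples of size n:
    (sorted |rho| values, tail counts of permutations with |rho| >= value)."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    rhos = []
    for perm in itertools.permutations(range(1, n + 1)):
        s = int(((base - np.array(perm)) ** 2).sum())
        rhos.append(1.0 - 6.0 * s / denom)
    abs_rho = np.sort(np.abs(np.array(rhos)))
    # tail_count[i]: permutations with |rho| >= abs_rho[i]
    tail = len(abs_rho) - np.arange(len(abs_rho))
    return abs_rho, tail


def _exact_p(rho: float, n: int) -> float:
    abs_rho, tail = _exact_rho_null(n)
    idx = np.searchsorted(abs_rho, abs(rho) - 1e-12, side="left")
    if idx >= len(abs_rho):
        return 0.0
    return float(tail[idx] / len(abs_rho))


def _approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2)))


def spearman_matrix(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p across samples.

    Ties receive average ranks. For tie-free pairs with at most 9 samples
    the p-value comes from the exact permutation null; otherwise from the
    t-distribution approximation. Constant features get rho 0 / p 1 against
    everything, with a warning.
    """
    x = table.matrix()
    n_feat, n = x.shape
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    constant = x.std(axis=1) == 0
    if constant.any():
        logger.warning("%d constant features: rho set to 0, p to 1",
                       int(constant.sum()))
    has_ties = np.array([len(np.unique(row)) < n for row in x])
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered ** 2).sum(axis=1))
    norms_safe = np.where(norms == 0, 1.0, norms)
    unit = centered / norms_safe[:, None]
    rho = unit @ unit.T
    np.clip(rho, -1.0, 1.0, out=rho)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)

    p = np.ones_like(rho)
    exact_ok = (n <= _EXACT_N_MAX) & ~has_ties[:, None] & ~has_ties[None, :]
    for i in range(n_feat):
        for j in range(i + 1, n_feat):
            if constant[i] or constant[j]:
                pij = 1.0
            elif exact_ok[i, j]:
                pij = _exact_p(rho[i, j], n)
            else:
                pij = _approx_p(rho[i, j], n)
            p[i, j] = p[j, i] = pij
    np.fill_diagonal(p, 0.0)
    ids = table.feature_ids
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


@dataclasses.dataclass
class GuildAssignment:
    """feature -> guild label mapping plus the clustering parameters used."""

    assignment: dict[str, str]
    height: float
    distance: str               # "1-rho" or "1-|rho|"
    linkage: str = "average"
    label_prefix: str = "G"

    def labels(self) -> list[str]:
        seen: list[str] = []
        for lab in self.assignment.values():
            if lab not in seen:
                seen.append(lab)
        return seen

    def members(self, label: str) -> list[str]:
        return [f for f, lab in self.assignment.items() if lab == label]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature_id": list(self.assignment),
                           "guild": list(self.assignment.values())})
        return df.set_index("feature_id")


def cluster_features(
    rho: pd.DataFrame,
    height: float,
    linkage: str = "average",
    distance: str = "1-rho",
    label_prefix: str = "G",
) -> GuildAssignment:
    """Cut an average-linkage dendrogram on correlation distance at ``height``.

    Distance is 1 - rho by default (anti-correlated features stay apart, as
    required when guild abundances are summed); ``distance="1-|rho|"`` is
    available. Guild labels are assigned in decreasing guild size, ties
    broken by the lexicographically first member id.
    """
    if rho.shape[0] != rho.shape[1]:
        raise ValueError("rho must be square")
    arr = rho.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("rho must be symmetric")
    ids = rho.index.tolist()
    if len(ids) == 1:
        return GuildAssignment({ids[0]: f"{label_prefix}1"}, height, distance,
                               linkage, label_prefix)
    if distance == "1-rho":
        d = 1.0 - arr
    elif distance == "1-|rho|":
        d = 1.0 - np.abs(arr)
    else:
        raise ValueError(f"unknown distance {distance!r}")
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    flat = hierarchy.fcluster(z, t=height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for fid, c in zip(ids, flat):
        groups.setdefault(int(c), []).append(fid)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), sorted(m)[0]))
    assignment: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for fid in members:
            assignment[fid] = f"{label_prefix}{k}"
    assignment = {fid: assignment[fid] for fid in ids}
    return GuildAssignment(assignment, height, distance, linkage, label_prefix)


def guild_abundance(table: AbundanceTable, assignment: GuildAssignment) -> AbundanceTable:
    """Guild × sample cumulative abundance: sum of member rows per guild."""
    missing = [f for f in table.feature_ids if f not in assignment.assignment]
    if missing:
        raise ValueError(f"features without a guild assignment: {missing[:10]}")

    def _key(label: str) -> tuple:
        prefix = assignment.label_prefix
        suffix = label[len(prefix):] if label.startswith(prefix) else label
        return (0, int(suffix)) if suffix.isdigit() else (1, suffix)

    labels = sorted(assignment.labels(), key=_key)
    rows = {}
    for lab in labels:
        members = [f for f in table.feature_ids if assignment.assignment[f] == lab]
        rows[lab] = table.values.loc[members].sum(axis=0)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df[table.sample_ids]
    return AbundanceTable(df, table.value_kind)


@dataclasses.dataclass
class CoocNetwork:
    """Signed co-occurrence network of features passing rho/q thresholds."""

    nodes: pd.DataFrame        # index feature_id, column guild
    edges: list[dict]          # source, target, rho, q, sign
    threshold: float
    alpha: float


def cooccurrence_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    threshold: float = 0.46,
    alpha: float = 0.05,
    assignment: GuildAssignment | None = None,
) -> CoocNetwork:
    """Keep edges with BH-adjusted p < alpha and |rho| strictly > threshold.

    BH adjustment runs over the upper-triangle p-values only (each unordered
    pair tested once). Positive edges are labelled "+", negative "-".
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices are not aligned")
    ids = rho.index.tolist()
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    pvals = p.to_numpy()[iu, ju]
    qvals = benjamini_hochberg(pvals) if len(pvals) else np.array([])
    rhos = rho.to_numpy()[iu, ju]
    edges = []
    for i, j, r, q in zip(iu, ju, rhos, qvals):
        if q < alpha and abs(r) > threshold:
            edges.append({"source": ids[i], "target": ids[j],
                          "rho": float(r), "q": float(q),
                          "sign": "+" if r > 0 else "-"})
    if assignment is not None:
        guilds = [assignment.assignment.get(f, "unassigned") for f in ids]
    else:
        guilds = ["unassigned"] * n
    nodes = pd.DataFrame({"guild": guilds}, index=pd.Index(ids, name="feature_id"))
    return CoocNetwork(nodes=nodes, edges=edges, threshold=threshold, alpha=alpha)
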