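"""Cross-omics integration: correlation blocks, ROC/AUC, Sankey chains.

Spearman correlation blocks link guild cumulative abundances (CAGs,
metabolite modules) to each other and to clinical indices; heatmap
annotations use raw-p stars (* p<0.05, ** p<0.01). Sankey link sets chain
significant same-sign correlations CAG → module → clinical index. ROC/AUC
scores single markers or guild abundances against the binary group label or
a clinical flag via the Mann–Whitney identity.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .differential import benjamini_hochberg
from .guilds import _approx_p, _exact_p, _EXACT_N_MAX
from .io_core import AbundanceTable, SampleMetadata

logger = logging.getLogger("guildlink")


@dataclasses.dataclass
class CorrelationBlock:
    """Pairwise Spearman rho/p (optionally q) between two entity sets."""

    rho: pd.DataFrame          # rows × columns
    p: pd.DataFrame
    row_role: str
    col_role: str
    q: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.annotation is None:
            self.annotation = annotate_significance(self.p)


def annotate_significance(p: pd.DataFrame) -> pd.DataFrame:
    """Star annotation: '**' for p < 0.01, '*' for 0.01 <= p < 0.05, else ''."""
    arr = p.to_numpy(dtype=float)
    ann = np.where(arr < 0.01, "**", np.where(arr < 0.05, "*", ""))
    ann = np.where(np.isnan(arr), "", ann)
    return pd.DataFrame(ann, index=p.index, columns=p.columns)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    mask = ~(np.isnan(x) | np.isnan(y))
    n = int(mask.sum())
    if n < 3:
        return np.nan, np.nan
    xv, yv = x[mask], y[mask]
    if xv.std() == 0 or yv.std() == 0:
        return 0.0, 1.0
    rx = stats.rankdata(xv)
    ry = stats.rankdata(yv)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    ties = len(np.unique(xv)) < n or len(np.unique(yv)) < n
    if n <= _EXACT_N_MAX and not ties:
        p = _exact_p(rho, n)
    else:
        p = _approx_p(rho, n)
    return rho, p


def _as_frame(B, sample_axis: str = "columns") -> pd.DataFrame:
    """Coerce an AbundanceTable or DataFrame to entities × samples."""
    if isinstance(B, AbundanceTable):
        return B.values
    df = pd.DataFrame(B)
    if sample_axis == "rows":
        df = df.T
    return df


def correlate_blocks(
    A, B,
    row_role: str = "row",
    col_role: str = "col",
    adjust: bool = False,
) -> CorrelationBlock:
    """Spearman rho/p between every row entity of A and of B.

    Both inputs are entities × samples (AbundanceTable or DataFrame); the
    shared sample set is used and missing values are dropped pairwise.
    Binary clinical indices enter as 0/1 ranks. Pairs with fewer than 3
    overlapping samples are set missing with a warning. ``adjust`` adds a BH
    q matrix over all block entries.
    """
    dfa = _as_frame(A)
    dfb = _as_frame(B)
    shared = [s for s in dfa.columns if s in set(dfb.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    xa = dfa[shared].to_numpy(dtype=float)
    xb = dfb[shared].to_numpy(dtype=float)
    rho = np.empty((xa.shape[0], xb.shape[0]))
    p = np.empty_like(rho)
    n_missing = 0
    for i in range(xa.shape[0]):
        for j in range(xb.shape[0]):
            rho[i, j], p[i, j] = _spearman_pair(xa[i], xb[j])
            if np.isnan(rho[i, j]):
                n_missing += 1
    if n_missing:
        logger.warning("%d block entries missing (<3 overlapping samples)", n_missing)
    rho_df = pd.DataFrame(rho, index=dfa.index, columns=dfb.index)
    p_df = pd.DataFrame(p, index=dfa.index, columns=dfb.index)
    q_df = None
    if adjust:
        flat = p.ravel()
        ok = ~np.isnan(flat)
        qs = np.full_like(flat, np.nan)
        qs[ok] = benjamini_hochberg(flat[ok])
        q_df = pd.DataFrame(qs.reshape(p.shape), index=dfa.index, columns=dfb.index)
    return CorrelationBlock(rho=rho_df, p=p_df, q=q_df,
                            row_role=row_role, col_role=col_role)


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(score, labels, oriented: bool = False) -> tuple[float, str]:
    """AUC via the Mann–Whitney identity, ties counted one half.

    Returns the raw orientation-preserving AUC (probability a random case
    outscores a random control) and whether cases score higher;
    ``oriented=True`` reports max(AUC, 1-AUC) instead.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind not in "fiub":
        labels = (labels == "case").astype(int)
    pos = score[labels == 1]
    neg = score[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(score)
    r_pos = ranks[labels == 1].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    auc = u / (len(pos) * len(neg))
    direction = "case_higher" if auc >= 0.5 else "control_higher"
    if oriented:
        auc = max(auc, 1.0 - auc)
    return float(auc), direction


def guild_roc_table(abund: AbundanceTable, metadata: SampleMetadata,
                    label_column: str | None = None) -> pd.DataFrame:
    """Apparent AUC of each guild's cumulative abundance against the group
    label (default) or a binary clinical index column."""
    samples = [s for s in abund.sample_ids if s in metadata.table.index]
    if label_column is None:
        y = metadata.y_binary(samples)
    else:
        y = metadata.table.loc[samples, label_column].to_numpy(dtype=float)
    ok = ~np.isnan(y)
    rows = []
    for gid in abund.feature_ids:
        scores = abund.values.loc[gid, samples].to_numpy(dtype=float)[ok]
        auc, direction = roc_auc(scores, y[ok])
        rows.append({"guild": gid, "auc": auc, "direction": direction})
    return pd.DataFrame(rows).set_index("guild")


# ---------------------------------------------------------------------------
# Sankey chains
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SankeyLinkSet:
    """Two-leg chain of significant same-sign correlations for Sankey plots."""

    links: list[dict]          # source, target, rho, p, sign, leg
    left_sign: str
    right_sign: str
    alpha: float

    def middle_nodes(self) -> list[str]:
        lefts = {l["target"] for l in self.links if l["leg"] == "left"}
        rights = {l["source"] for l in self.links if l["leg"] == "right"}
        return sorted(lefts & rights)


def build_sankey_links(
    left: CorrelationBlock,
    right: CorrelationBlock,
    left_sign: str = "+",
    right_sign: str = "+",
    alpha: float = 0.05,
) -> SankeyLinkSet:
    """Chain left (e.g. CAG×module) and right (module×clinical) blocks.

    A link survives when its correlation has the required sign and raw
    p < alpha; only middle entities present in both surviving legs are kept.
    An empty result is a valid (empty) link set.
    """
    if left_sign not in "+-" or right_sign not in "+-":
        raise ValueError("signs must be '+' or '-'")

    def _leg(block: CorrelationBlock, sign: str, leg: str) -> list[dict]:
        out = []
        for r in block.rho.index:
            for c in block.rho.columns:
                rho = block.rho.loc[r, c]
                p = block.p.loc[r, c]
                if np.isnan(rho) or np.isnan(p) or p >= alpha:
                    continue
                if (sign == "+" and rho > 0) or (sign == "-" and rho < 0):
                    out.append({"source": str(r), "target": str(c),
                                "rho": float(rho), "p": float(p),
                                "sign": sign, "leg": leg})
        return out

    left_links = _leg(left, left_sign, "left")
    right_links = _leg(right, right_sign, "right")
    mids = ({l["target"] for l in left_links}
            & {l["source"] for l in right_links})
    links = ([l for l in left_links if l["target"] in mids]
             + [l for l in right_links if l["source"] in mids])
    return SankeyLinkSet(links=links, left_sign=left_sign,
                         right_sign=right_sign, alpha=alpha)


# ---------------------------------------------------------------------------
# Bray–Curtis sample ordering
# ---------------------------------------------------------------------------

def bray_curtis(u, v) -> float:
    """BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    denom = (u + v).sum()
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(u - v).sum() / denom)


def braycurtis_order(table: AbundanceTable) -> list[str]:
    """Sample order from the average-linkage Bray–Curtis dendrogram leaves."""
    x = table.matrix().T          # samples × features
    zero = x.sum(axis=1) == 0
    if zero.any():
        bad = [table.sample_ids[i] for i in np.nonzero(zero)[0]]
        raise ValueError(f"all-zero samples have no Bray-Curtis distance: {bad}")
    if x.shape[0] == 1:
        return list(table.sample_ids)
    d = pdist(x, metric="braycurtis")
    z = hierarchy.linkage(d, method="average")
    leaves = hierarchy.leaves_list(z)
    return [table.sample_ids[i] for i in leaves]
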