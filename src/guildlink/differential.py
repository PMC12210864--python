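"""QC filtering, normalization and univariate differential-feature selection.

Implements the feature-selection rules used throughout the pipeline:
metabolites pass on t-test p < 0.05 combined with a multivariate VIP > 1,
species on a Wilcoxon rank-sum p < 0.05 with a mean relative-abundance floor
of 1e-6, and KOs on the rank test alone. All multiplicity adjustment is
Benjamini–Hochberg.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import AbundanceTable, SampleMetadata, ValueKind

logger = logging.getLogger("guildlink")


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter_metabolites(
    table: AbundanceTable,
    qc_sample_ids: list[str],
    cv_threshold: float = 0.30,
) -> AbundanceTable:
    """Keep features whose coefficient of variation over the pooled-QC
    injections is below ``cv_threshold``; the QC columns are then dropped.

    Features with zero QC mean have an undefined CV and are dropped with a
    warning.
    """
    if len(qc_sample_ids) < 2:
        raise ValueError("need at least 2 QC samples to estimate a CV")
    missing = [s for s in qc_sample_ids if s not in table.values.columns]
    if missing:
        raise KeyError(f"QC samples not in table: {missing}")
    qc = table.values[qc_sample_ids].to_numpy(dtype=float)
    means = qc.mean(axis=1)
    sds = qc.std(axis=1, ddof=1)
    zero_mean = means == 0
    if zero_mean.any():
        logger.warning("dropping %d features with zero QC mean (undefined CV)",
                       int(zero_mean.sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(zero_mean, np.inf, sds / np.where(zero_mean, 1.0, means))
    keep = cv < cv_threshold
    biological = [s for s in table.sample_ids if s not in set(qc_sample_ids)]
    kept = table.values.loc[keep, biological]
    return AbundanceTable(kept, table.value_kind)


def autoscale(table: AbundanceTable) -> AbundanceTable:
    """Unit-variance (auto) scaling: per feature subtract the mean and divide
    by the sample standard deviation (n-1 denominator).

    Zero-variance features become all-zero rows (with a warning). Idempotent
    up to floating point.
    """
    if table.shape[1] < 2:
        raise ValueError("auto-scaling needs at least 2 samples")
    x = table.matrix()
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        logger.warning("%d constant features scaled to all-zero rows", int(flat.sum()))
    sd_safe = np.where(sd == 0, 1.0, sd)
    scaled = np.where(flat[:, None], 0.0, (x - mean) / sd_safe)
    return AbundanceTable(pd.DataFrame(scaled, index=table.values.index,
                                       columns=table.values.columns),
                          ValueKind.scaled)


# ---------------------------------------------------------------------------
# univariate tests
# ---------------------------------------------------------------------------

def student_t(x, y) -> tuple[float, float]:
    """Two-sided equal-variance Student's t-test.

    Degenerate zero-pooled-variance inputs: equal means give (0, 1); unequal
    means give (signed inf, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 and sy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.warning("zero pooled variance with unequal means: p set to 0")
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def welch_t(x, y) -> tuple[float, float]:
    """Welch's unequal-variance t-test (alternative to :func:`student_t`)."""
    t, p = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float), equal_var=False)
    return float(t), float(p)


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns ``(U, p)`` with U the Mann–Whitney statistic of ``x``. The exact
    null distribution is used when the combined sample size is at most 25
    and there are no ties; otherwise the normal approximation with tie and
    continuity corrections applies. An all-tied comparison returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= 25 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(combined, return_counts=True)
    tie_term = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u), 1.0
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return float(u), float(p)


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# differential tables
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DifferentialTable:
    """Per-feature differential summary with the applied selection rule."""

    table: pd.DataFrame   # mean_case, mean_control, direction, statistic, p, q,
                          # (vip,) selected; index: feature_id
    omic: str
    rule: str

    def selected_ids(self) -> list[str]:
        return self.table.index[self.table["selected"]].tolist()


def _group_arrays(table: AbundanceTable, metadata: SampleMetadata):
    samples = [s for s in table.sample_ids if s in metadata.table.index]
    case = [s for s in samples if metadata.table.loc[s, "group"] == "case"]
    control = [s for s in samples if metadata.table.loc[s, "group"] == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need >= 2 samples per group")
    return (table.values[case].to_numpy(dtype=float),
            table.values[control].to_numpy(dtype=float))


def differential_metabolites(
    scaled: AbundanceTable,
    metadata: SampleMetadata,
    vip: pd.Series,
    p_threshold: float = 0.05,
    vip_threshold: float = 1.0,
    test: str = "student",
) -> DifferentialTable:
    """Metabolite selection: t-test p < threshold AND VIP > threshold.

    ``vip`` must be indexed exactly by the table's features. Direction is
    the sign of the case-minus-control mean difference.
    """
    if set(vip.index) != set(scaled.feature_ids) or len(vip) != len(scaled.feature_ids):
        raise ValueError("VIP vector is not aligned with the table's features")
    vip = vip.loc[scaled.feature_ids]
    xc, xh = _group_arrays(scaled, metadata)
    test_fn = student_t if test == "student" else welch_t
    rows = []
    for i, fid in enumerate(scaled.feature_ids):
        t, p = test_fn(xc[i], xh[i])
        rows.append((fid, xc[i].mean(), xh[i].mean(), t, p))
    df = pd.DataFrame(rows, columns=["feature_id", "mean_case", "mean_control",
                                     "statistic", "p"]).set_index("feature_id")
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["vip"] = vip
    df["direction"] = np.where(df["mean_case"] >= df["mean_control"],
                               "case_enriched", "case_depleted")
    df["selected"] = (df["p"] < p_threshold) & (df["vip"] > vip_threshold)
    return DifferentialTable(df, omic="metabolite",
                             rule=f"p<{p_threshold} & VIP>{vip_threshold}")


def differential_species(
    table: AbundanceTable,
    metadata: SampleMetadata,
    p_threshold: float = 0.05,
    abundance_floor: float = 1e-6,
) -> DifferentialTable:
    """Key-species selection: Wilcoxon p < threshold AND overall mean
    relative abundance above the floor. Species absent from every sample are
    excluded before testing."""
    if table.value_kind is not ValueKind.relative_abundance:
        raise ValueError("differential_species expects a relative-abundance table")
    present = table.values.sum(axis=1) > 0
    if (~present).any():
        logger.info("excluding %d species absent from all samples", int((~present).sum()))
    sub = AbundanceTable(table.values.loc[present], table.value_kind)
    xc, xh = _group_arrays(sub, metadata)
    rows = []
    for i, fid in enumerate(sub.feature_ids):
        u, p = wilcoxon_rank_sum(xc[i], xh[i])
        rows.append((fid, xc[i].mean(), xh[i].mean(), u, p))
    df = pd.DataFrame(rows, columns=["feature_id", "mean_case", "mean_control",
                                     "statistic", "p"]).set_index("feature_id")
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["mean_abundance"] = sub.values.mean(axis=1)
    df["direction"] = np.where(df["mean_case"] >= df["mean_control"],
                               "case_enriched", "case_depleted")
    df["selected"] = (df["p"] < p_threshold) & (df["mean_abundance"] > abundance_floor)
    return DifferentialTable(df, omic="species",
                             rule=f"p<{p_threshold} & mean_abundance>{abundance_floor}")


def differential_kos(
    table: AbundanceTable,
    metadata: SampleMetadata,
    p_threshold: float = 0.05,
) -> DifferentialTable:
    """Differential KO selection by the Wilcoxon rank-sum test alone."""
    xc, xh = _group_arrays(table, metadata)
    rows = []
    for i, fid in enumerate(table.feature_ids):
        u, p = wilcoxon_rank_sum(xc[i], xh[i])
        rows.append((fid, xc[i].mean(), xh[i].mean(), u, p))
    df = pd.DataFrame(rows, columns=["feature_id", "mean_case", "mean_control",
                                     "statistic", "p"]).set_index("feature_id")
    df["q"] = benjamini_hochberg(df["p"].to_numpy())
    df["direction"] = np.where(df["mean_case"] >= df["mean_control"],
                               "case_enriched", "case_depleted")
    df["selected"] = df["p"] < p_threshold
    return DifferentialTable(df, omic="ko", rule=f"p<{p_threshold}")
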