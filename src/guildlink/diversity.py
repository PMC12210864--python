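"""Alpha-diversity indices on species profiles and their group comparison."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .differential import wilcoxon_rank_sum
from .io_core import AbundanceTable, SampleMetadata


def _normalize(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundance vector must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector has no defined diversity")
    return p / total


def shannon_index(p) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log, zeros contribute 0)."""
    p = _normalize(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def gini_simpson_index(p) -> float:
    """Gini–Simpson index 1 - sum p_i^2 (probability of interspecific encounter)."""
    p = _normalize(p)
    return float(1.0 - (p ** 2).sum())


def simpson_dominance(p) -> float:
    """Simpson concentration D = sum p_i^2 (dominance form)."""
    return 1.0 - gini_simpson_index(p)


@dataclasses.dataclass
class DiversityResult:
    per_sample: pd.DataFrame        # columns: shannon, simpson; index: sample_id
    comparisons: pd.DataFrame       # per index: statistic, p, case/control medians


def compare_alpha_diversity(
    table: AbundanceTable,
    metadata: SampleMetadata,
    simpson_form: str = "gini",
) -> DiversityResult:
    """Per-sample Shannon and Simpson indices plus a two-group rank test.

    ``simpson_form`` selects Gini–Simpson (1 - D, the vegan default) or the
    dominance form D.
    """
    samples = [s for s in table.sample_ids if s in metadata.table.index]
    case = [s for s in samples if metadata.table.loc[s, "group"] == "case"]
    control = [s for s in samples if metadata.table.loc[s, "group"] == "control"]
    if len(case) < 2 or len(control) < 2:
        raise ValueError("need at least 2 samples per group for comparison")
    simpson_fn = gini_simpson_index if simpson_form == "gini" else simpson_dominance
    rows = {
        s: {"shannon": shannon_index(table.values[s].to_numpy()),
            "simpson": simpson_fn(table.values[s].to_numpy())}
        for s in samples
    }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    per_sample.index.name = "sample_id"
    comp_rows = []
    for index_name in ("shannon", "simpson"):
        x = per_sample.loc[case, index_name].to_numpy()
        y = per_sample.loc[control, index_name].to_numpy()
        stat, p = wilcoxon_rank_sum(x, y)
        comp_rows.append({"index": index_name, "statistic": stat, "p": p,
                          "case_median": float(np.median(x)),
                          "control_median": float(np.median(y))})
    comparisons = pd.DataFrame(comp_rows).set_index("index")
    return DiversityResult(per_sample=per_sample, comparisons=comparisons)
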