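"""Synthetic two-group cohorts with planted guild structure.

Generates the three omic layers the analysis pipeline consumes — a serum
metabolite intensity table (with pooled-QC columns), a species
relative-abundance table and a KO relative-abundance table — together with
sample metadata and a ground-truth record for recovery tests.

The generative model is a single-factor equicorrelated block design: each
metabolite module (or species co-abundance group, CAG) has one latent factor
per sample, and each member loads on it with weight ``sqrt(within_rho)`` so
that any two members share Pearson correlation ``within_rho`` on the latent
(log) scale. Group effects are standardized mean shifts applied on the log
scale to designated differential modules/CAGs. Species and KO tables are
closed to relative abundances; species are zero-inflated before closure so
correlations are induced on the scale the analysis actually sees. A binary
clinical flag (cardiac involvement analogue) is drawn from a logistic link
on one designated driver module's latent factor.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io_core import (
    AbundanceTable,
    SampleMetadata,
    ValueKind,
    write_abundance_table,
    write_metadata,
)


@dataclasses.dataclass
class CohortConfig:
    """Knobs of the cohort generator; defaults mirror the 13-vs-22 study design."""

    n_case: int = 13
    n_control: int = 22
    n_metabolites: int = 200
    n_modules: int = 10
    module_size_range: tuple[int, int] = (5, 15)
    within_module_rho: float = 0.7
    module_group_effect: float = 1.5
    n_species: int = 150
    n_cags: int = 12
    cag_size_range: tuple[int, int] = (4, 10)
    within_cag_rho: float = 0.7
    species_group_effect: float = 1.5
    zero_inflation: float = 0.3
    n_kos: int = 300
    ko_differential_fraction: float = 0.1
    ko_group_effect: float = 1.5
    phenotype_slope: float = 2.0
    n_qc: int = 5
    qc_noise_sd: float = 0.05
    differential_module_fraction: float = 0.5
    differential_cag_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_case=self.n_case, n_control=self.n_control,
                      n_metabolites=self.n_metabolites, n_modules=self.n_modules,
                      n_species=self.n_species, n_cags=self.n_cags, n_kos=self.n_kos)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        for name, rho in (("within_module_rho", self.within_module_rho),
                          ("within_cag_rho", self.within_cag_rho)):
            if not 0 < rho < 1:
                raise ValueError(f"{name} must lie in (0,1), got {rho}")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError(f"zero_inflation must lie in [0,1), got {self.zero_inflation}")
        if self.module_size_range[0] > self.module_size_range[1]:
            raise ValueError("module_size_range must be (lo, hi) with lo <= hi")
        if self.module_size_range[1] * self.n_modules > self.n_metabolites and \
                self.module_size_range[0] * self.n_modules > self.n_metabolites:
            raise ValueError("module sizes cannot fit into n_metabolites")
        if self.cag_size_range[0] * self.n_cags > self.n_species:
            raise ValueError("CAG sizes cannot fit into n_species")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        for key in ("module_size_range", "cag_size_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["module_size_range"] = list(self.module_size_range)
        d["cag_size_range"] = list(self.cag_size_range)
        return d


@dataclasses.dataclass
class GroundTruth:
    """What was planted: guild memberships, differential features, drivers."""

    metabolite_modules: dict[str, str]          # feature -> module label ("background" allowed)
    species_cags: dict[str, str]
    differential_metabolites: dict[str, float]  # feature -> signed standardized effect
    differential_species: dict[str, float]
    differential_kos: dict[str, float]
    flag_drivers: dict[str, str]                # binary flag -> driver module label

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)


@dataclasses.dataclass
class Cohort:
    metabolome: AbundanceTable
    microbiome: AbundanceTable
    kos: AbundanceTable
    metadata: SampleMetadata
    truth: GroundTruth
    qc_sample_ids: list[str]
    config: CohortConfig


def _partition_sizes(rng: np.random.Generator, n_guilds: int,
                     size_range: tuple[int, int], n_total: int) -> list[int]:
    """Draw guild sizes that fit inside n_total features."""
    lo, hi = size_range
    for _ in range(200):
        sizes = rng.integers(lo, hi + 1, size=n_guilds).tolist()
        if sum(sizes) <= n_total:
            return sizes
    # shrink deterministically if random draws never fit
    sizes = [lo] * n_guilds
    if sum(sizes) > n_total:
        raise ValueError("guild sizes infeasible for the feature count")
    return sizes


def _block_latent_matrix(rng: np.random.Generator, n_samples: int, sizes: list[int],
                         n_features: int, rho: float,
                         group: np.ndarray, effect: float,
                         differential: list[bool]) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Log-scale matrix (features × samples) with equicorrelated blocks.

    Returns the matrix, the per-block latent factors (blocks × samples), and
    the member index lists. Features beyond the blocks are iid background.
    """
    x = np.empty((n_features, n_samples))
    factors = rng.standard_normal((len(sizes), n_samples))
    members: list[list[int]] = []
    pos = 0
    a, b = np.sqrt(rho), np.sqrt(1.0 - rho)
    for m, size in enumerate(sizes):
        idx = list(range(pos, pos + size))
        members.append(idx)
        noise = rng.standard_normal((size, n_samples))
        x[idx, :] = a * factors[m][None, :] + b * noise
        if differential[m]:
            sign = 1.0 if m % 2 == 0 else -1.0
            x[idx, :] += sign * effect * group[None, :]
        pos += size
    if pos < n_features:
        x[pos:, :] = rng.standard_normal((n_features - pos, n_samples))
    return x, factors, members


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    sample_ids = [f"S{i+1:03d}" for i in range(n)]
    group = np.array([1.0] * config.n_case + [0.0] * config.n_control)

    # ----- metabolome ----------------------------------------------------
    met_ids = [f"met{i+1:04d}" for i in range(config.n_metabolites)]
    mod_sizes = _partition_sizes(rng, config.n_modules, config.module_size_range,
                                 config.n_metabolites)
    n_diff_mod = max(1, round(config.differential_module_fraction * config.n_modules))
    diff_mod = [m < n_diff_mod for m in range(config.n_modules)]
    log_met, met_factors, mod_members = _block_latent_matrix(
        rng, n, mod_sizes, config.n_metabolites, config.within_module_rho,
        group, config.module_group_effect, diff_mod)
    met_values = np.exp(log_met)

    metabolite_modules: dict[str, str] = {}
    for m, idx in enumerate(mod_members):
        for i in idx:
            metabolite_modules[met_ids[i]] = f"M{m+1}"
    for fid in met_ids:
        metabolite_modules.setdefault(fid, "background")
    differential_metabolites: dict[str, float] = {}
    for m, idx in enumerate(mod_members):
        if diff_mod[m]:
            sign = 1.0 if m % 2 == 0 else -1.0
            for i in idx:
                differential_metabolites[met_ids[i]] = sign * config.module_group_effect

    # pooled-QC columns: grand-mean profile with small measurement noise,
    # so genuine features pass a CV filter and pathological ones would not
    qc_ids = [f"QC{i+1}" for i in range(config.n_qc)]
    qc_profile = met_values.mean(axis=1)
    qc_values = qc_profile[:, None] * np.exp(
        config.qc_noise_sd * rng.standard_normal((config.n_metabolites, config.n_qc)))
    metabolome = AbundanceTable(
        pd.DataFrame(np.hstack([met_values, qc_values]), index=met_ids,
                     columns=sample_ids + qc_ids),
        ValueKind.intensity)

    # ----- microbiome ----------------------------------------------------
    sp_ids = [f"sp{i+1:04d}" for i in range(config.n_species)]
    cag_sizes = _partition_sizes(rng, config.n_cags, config.cag_size_range,
                                 config.n_species)
    n_diff_cag = max(1, round(config.differential_cag_fraction * config.n_cags))
    diff_cag = [m < n_diff_cag for m in range(config.n_cags)]
    log_sp, _, cag_members = _block_latent_matrix(
        rng, n, cag_sizes, config.n_species, config.within_cag_rho,
        group, config.species_group_effect, diff_cag)
    # heterogeneous baseline abundances across species
    baseline = rng.normal(0.0, 2.0, size=config.n_species)
    sp_values = np.exp(log_sp + baseline[:, None])
    if config.zero_inflation > 0:
        keep = rng.random((config.n_species, n)) >= config.zero_inflation
        sp_values = sp_values * keep
    col_sums = sp_values.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    sp_values = sp_values / col_sums[None, :]
    microbiome = AbundanceTable(
        pd.DataFrame(sp_values, index=sp_ids, columns=sample_ids),
        ValueKind.relative_abundance)

    species_cags: dict[str, str] = {}
    for m, idx in enumerate(cag_members):
        for i in idx:
            species_cags[sp_ids[i]] = f"CAG{m+1}"
    for fid in sp_ids:
        species_cags.setdefault(fid, "background")
    differential_species: dict[str, float] = {}
    for m, idx in enumerate(cag_members):
        if diff_cag[m]:
            sign = 1.0 if m % 2 == 0 else -1.0
            for i in idx:
                differential_species[sp_ids[i]] = sign * config.species_group_effect

    # ----- KO table ------------------------------------------------------
    ko_ids = [f"K{i+1:05d}" for i in range(config.n_kos)]
    n_diff_ko = round(config.ko_differential_fraction * config.n_kos)
    log_ko = rng.standard_normal((config.n_kos, n))
    differential_kos: dict[str, float] = {}
    for i in range(n_diff_ko):
        sign = 1.0 if i % 2 == 0 else -1.0
        log_ko[i, :] += sign * config.ko_group_effect * group
        differential_kos[ko_ids[i]] = sign * config.ko_group_effect
    ko_values = np.exp(log_ko)
    ko_values = ko_values / ko_values.sum(axis=0)[None, :]
    kos = AbundanceTable(pd.DataFrame(ko_values, index=ko_ids, columns=sample_ids),
                         ValueKind.relative_abundance)

    # ----- metadata ------------------------------------------------------
    # The cardiac flag is driven by a module latent factor. A module whose
    # members also carry the group shift would have its sample ranks
    # dominated by group membership rather than by its latent, so the first
    # non-differential module is designated the driver when one exists.
    driver_idx = next((m for m in range(config.n_modules) if not diff_mod[m]), 0)
    driver_label = f"M{driver_idx + 1}"
    f_driver = met_factors[driver_idx]
    if config.phenotype_slope == 0:
        prob = np.full(n, 0.5)
    else:
        prob = 1.0 / (1.0 + np.exp(-config.phenotype_slope * f_driver))
    cardiac = (rng.random(n) < prob).astype(float)
    subgroup = np.where(group == 1.0,
                        np.where(cardiac == 1.0, "mix", "neurologic"),
                        "healthy")
    age = rng.normal(50.0, 10.0, size=n).round(1)
    meta_df = pd.DataFrame(
        {
            "group": np.where(group == 1.0, "case", "control"),
            "subgroup": subgroup,
            "bin_cardiac": cardiac,
            "cov_age": age,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta_df, binary_indices=["bin_cardiac"],
                              continuous_indices=["cov_age"])

    truth = GroundTruth(
        metabolite_modules=metabolite_modules,
        species_cags=species_cags,
        differential_metabolites=differential_metabolites,
        differential_species=differential_species,
        differential_kos=differential_kos,
        flag_drivers={"bin_cardiac": driver_label},
    )
    return Cohort(metabolome=metabolome, microbiome=microbiome, kos=kos,
                  metadata=metadata, truth=truth, qc_sample_ids=qc_ids,
                  config=config)


def write_cohort(cohort: Cohort, out_dir: str | Path, force: bool = False) -> dict:
    """Write all cohort tables as TSV plus truth/manifest as YAML.

    Returns the manifest (also written to ``manifest.yaml``).
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is non-empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "metabolome": "metabolome.tsv",
        "microbiome": "microbiome.tsv",
        "kos": "kos.tsv",
        "metadata": "metadata.tsv",
        "truth": "truth.yaml",
    }
    write_abundance_table(cohort.metabolome, out / files["metabolome"])
    write_abundance_table(cohort.microbiome, out / files["microbiome"])
    write_abundance_table(cohort.kos, out / files["kos"])
    write_metadata(cohort.metadata, out / files["metadata"])
    with open(out / files["truth"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(cohort.truth.to_dict(), fh, sort_keys=True)
    manifest = {
        "seed": cohort.config.seed,
        "config": cohort.config.to_dict(),
        "qc_sample_ids": cohort.qc_sample_ids,
        "files": files,
    }
    with open(out / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def read_truth(path: str | Path) -> GroundTruth:
    with open(path, encoding="utf-8") as fh:
        return GroundTruth.from_dict(yaml.safe_load(fh))
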