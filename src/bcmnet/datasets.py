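"""Synthetic paired-tissue expression data with planted cross-tissue modules.

Emulates the study design behind tumor-stroma co-expression analysis:
matched tumor and stroma expression profiles from the same specimens, in
which groups of genes in the two compartments co-vary because they share a
latent biological signal, and patient outcome may depend on that signal.

The generator uses a latent-factor model: each planted module m has one
standard-normal factor z_m per sample, and every member gene's profile is
``loading * z_m + noise``.  Because the loading is the same on both tissue
sides, the expected Pearson correlation between any tumor member and any
stroma member is  rho* = loading**2 / (loading**2 + sigma**2),  which is
inverted to choose the loading for a requested rho*.  Non-member genes are
independent noise, so background cross-tissue correlations are centred on
zero.

Survival times are exponential, with the hazard multiplied by
``hazard_ratio`` for the poor-outcome group (samples above the median of
the prognostic module's latent factor); censoring is independent uniform on
[0, T_max] with T_max solved by bisection to hit the requested censoring
fraction in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import WeightedBipartiteGraph
from .preprocess import PairedTissueDataset
from .survival import SurvivalCohort

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_paired_expression",
    "generate_random_bipartite",
    "generate_survival",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the paired-tissue generator.

    modules : list of (tumor_size, stroma_size, target_cross_correlation)
        Planted cross-tissue modules.  target_cross_correlation is the
        expected Pearson correlation between any tumor member and any
        stroma member, strictly in (0, 1).
    n_samples : int
        Number of matched tumor/stroma sample pairs (the study's K; the
        source design had 47 matched pairs).
    background_noise_sd : float
        Standard deviation sigma of the iid Gaussian noise on every gene.
    prognostic_module_index : int or None
        Module whose latent factor drives survival; None gives a null
        cohort with a single shared hazard.
    hazard_ratio : float
        Hazard multiplier (>= 1) for the poor-outcome group.
    censoring_fraction : float
        Expected fraction of samples censored, in [0, 1).
    """

    n_tumor_genes: int = 60
    n_stroma_genes: int = 60
    n_samples: int = 47
    modules: tuple[tuple[int, int, float], ...] = ((15, 15, 0.8),)
    background_noise_sd: float = 1.0
    prognostic_module_index: int | None = None
    hazard_ratio: float = 1.0
    censoring_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "modules", tuple(tuple(m) for m in self.modules))
        if min(self.n_tumor_genes, self.n_stroma_genes, self.n_samples) < 1:
            raise ValueError("gene and sample counts must be positive")
        if self.background_noise_sd <= 0:
            raise ValueError("background_noise_sd must be > 0")
        if sum(m[0] for m in self.modules) > self.n_tumor_genes:
            raise ValueError("module tumor sizes exceed n_tumor_genes")
        if sum(m[1] for m in self.modules) > self.n_stroma_genes:
            raise ValueError("module stroma sizes exceed n_stroma_genes")
        for _, _, rho in self.modules:
            if not (0 < rho < 1):
                raise ValueError("target cross-correlation must be in (0, 1)")
        if self.hazard_ratio < 1:
            raise ValueError("hazard_ratio must be >= 1")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        if self.prognostic_module_index is not None and not (
            0 <= self.prognostic_module_index < len(self.modules)
        ):
            raise ValueError("prognostic_module_index out of range")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    module_memberships: list[tuple[list[str], list[str]]]
    group_labels: np.ndarray = field(repr=False)  # 1 = poor-outcome group
    latent_factors: np.ndarray = field(repr=False)  # modules x samples
    generator_seed: int = 0

    def module_genes(self, index: int) -> set[str]:
        t, s = self.module_memberships[index]
        return set(t) | set(s)


def _loading(rho: float, sigma: float) -> float:
    # rho = L^2 / (L^2 + sigma^2)  =>  L = sigma * sqrt(rho / (1 - rho))
    return sigma * np.sqrt(rho / (1.0 - rho))


def generate_paired_expression(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate matched tumor and stroma expression matrices.

    Returns (tumor, stroma, ground_truth); matrices are genes x samples
    DataFrames with gene ids ``T0000...`` / ``S0000...`` and shared sample
    ids.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    sigma = config.background_noise_sd
    n = config.n_samples
    t_ids = [f"T{i:04d}" for i in range(config.n_tumor_genes)]
    s_ids = [f"S{i:04d}" for i in range(config.n_stroma_genes)]
    sample_ids = [f"P{i:03d}" for i in range(n)]

    z = rng.standard_normal((len(config.modules), n))
    tumor = sigma * rng.standard_normal((config.n_tumor_genes, n))
    stroma = sigma * rng.standard_normal((config.n_stroma_genes, n))

    memberships: list[tuple[list[str], list[str]]] = []
    t_off = s_off = 0
    for m, (t_size, s_size, rho) in enumerate(config.modules):
        L = _loading(rho, sigma)
        tumor[t_off : t_off + t_size] += L * z[m]
        stroma[s_off : s_off + s_size] += L * z[m]
        memberships.append(
            (t_ids[t_off : t_off + t_size], s_ids[s_off : s_off + s_size])
        )
        t_off += t_size
        s_off += s_size

    if config.prognostic_module_index is not None:
        factor = z[config.prognostic_module_index]
        labels = (factor > np.median(factor)).astype(int)
    else:
        labels = np.zeros(n, dtype=int)

    truth = GroundTruth(
        module_memberships=memberships,
        group_labels=labels,
        latent_factors=z,
        generator_seed=config.seed,
    )
    return (
        pd.DataFrame(tumor, index=t_ids, columns=sample_ids),
        pd.DataFrame(stroma, index=s_ids, columns=sample_ids),
        truth,
    )


def generate_paired_dataset(config: SyntheticConfig):
    """Convenience wrapper returning (PairedTissueDataset, GroundTruth)."""
    tumor, stroma, truth = generate_paired_expression(config)
    return PairedTissueDataset(tumor, stroma), truth


def generate_random_bipartite(
    nx: int,
    ny: int,
    edge_probability: float,
    weight_low: float,
    weight_high: float,
    seed: int,
) -> WeightedBipartiteGraph:
    """Erdos-Renyi-style random weighted bipartite graph.

    Each of the nx*ny potential edges is present independently with
    ``edge_probability``; present-edge weights are uniform on
    [weight_low, weight_high] (must satisfy 0 < low <= high <= 1).
    """
    if not (0 < weight_low <= weight_high <= 1):
        raise ValueError("need 0 < weight_low <= weight_high <= 1")
    if not (0 <= edge_probability <= 1):
        raise ValueError("edge_probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((nx, ny)) < edge_probability
    weights = rng.uniform(weight_low, weight_high, size=(nx, ny))
    return WeightedBipartiteGraph(
        [f"X{i:04d}" for i in range(nx)],
        [f"Y{j:04d}" for j in range(ny)],
        np.where(mask, weights, 0.0),
    )


def _expected_censoring(t_max: float, hazards: np.ndarray) -> float:
    # For T ~ Exp(h) and C ~ U(0, t_max):
    # P(C < T) = (1/t_max) * integral_0^t_max exp(-h c) dc
    probs = (1.0 - np.exp(-hazards * t_max)) / (hazards * t_max)
    return float(probs.mean())


def generate_survival(
    ground_truth: GroundTruth,
    config: SyntheticConfig,
    tumor: pd.DataFrame | None = None,
    stroma: pd.DataFrame | None = None,
) -> SurvivalCohort:
    """Exponential survival outcomes tied to the prognostic module.

    The poor-outcome group (median split of the prognostic module's latent
    factor) has its hazard multiplied by ``config.hazard_ratio``; without a
    prognostic module all samples share the baseline hazard.  Censoring is
    independent uniform on [0, T_max] with T_max solved by bisection so the
    expected censored fraction matches ``config.censoring_fraction``.

    If the expression matrices are supplied, their genes (both tissues)
    become the cohort's feature columns.
    """
    rng = np.random.default_rng(config.seed + 1)
    labels = np.asarray(ground_truth.group_labels)
    n = labels.shape[0]
    baseline = 1.0
    hazards = baseline * np.where(labels == 1, config.hazard_ratio, 1.0)
    times = rng.exponential(1.0 / hazards)

    events = np.ones(n, dtype=int)
    if config.censoring_fraction > 0:
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if _expected_censoring(mid, hazards) > config.censoring_fraction:
                lo = mid
            else:
                hi = mid
        t_max = 0.5 * (lo + hi)
        cens = rng.uniform(0.0, t_max, size=n)
        events = (times <= cens).astype(int)
        times = np.minimum(times, cens)

    sample_ids = [f"P{i:03d}" for i in range(n)]
    if tumor is not None and stroma is not None:
        features = pd.concat([tumor, stroma]).T
        features.index = sample_ids
    else:
        features = pd.DataFrame(index=sample_ids)
    return SurvivalCohort(
        sample_ids=sample_ids,
        time=times,
        event=events,
        features=features,
    )
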