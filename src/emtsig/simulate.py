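"""Synthetic cohorts with the statistical structure the pipeline assumes.

Four generators stand in for the data sources the analysis was designed
around, so the whole pipeline is testable offline:

* :func:`simulate_expression_cohort` — tumor/normal TPM-like matrices,
  log-normal per group with per-gene log2 mean shifts in the tumor group
  (stand-in for bulk tumor-vs-normal portal cohorts).
* :func:`simulate_survival_cohort` — proportional-hazards event times with
  a constant baseline hazard, hazard multiplier exp(sum_g beta_g * z_g)
  over standardized expression, and independent uniform administrative
  censoring (stand-in for expression-linked survival cohorts per
  endpoint).
* :func:`simulate_densitometry_panel` — a three-class
  epithelial/hybrid/mesenchymal mixture of Western-blot band intensities:
  log-normal marker intensities around class-specific means, a positive
  latent correlation between the epithelial and mesenchymal channels, an
  independent housekeeping channel, and missing (ND) entries. Default
  class proportions (0.14, 0.63, 0.23) reproduce the 13/60/22-of-95
  composition of the motivating patient panel.
* :func:`simulate_study_lists` — per-study gene lists with a prescribed
  recurrence per gene, for exercising the consensus filter.

Every generator is a pure function of its parameter record, including the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionCohort
from .errors import ParameterError
from .phenotype import DensitometryPanel
from .survival import ENDPOINTS, SurvivalCohort

__all__ = [
    "ExpressionSimParams",
    "SurvivalSimParams",
    "DensitometrySimParams",
    "simulate_expression_cohort",
    "simulate_survival_cohort",
    "simulate_densitometry_panel",
    "simulate_study_lists",
    "DEFAULT_MARKERS",
    "HOUSEKEEPING",
]

HOUSEKEEPING = "ACTB"
DEFAULT_MARKERS = ("VIM", "CDH1", "KRT18", "ACTA2")


@dataclass(frozen=True)
class ExpressionSimParams:
    """Log-normal tumor/normal expression generator parameters.

    ``effect_sizes`` maps gene -> log2 mean shift of the tumor group
    (positive = up in tumor); genes not listed get shift 0.
    """

    n_genes: int = 100
    n_tumor: int = 200
    n_normal: int = 200
    base_log_mean: float = 5.0
    base_log_sd: float = 1.5
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    gene_names: Sequence[str] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumor < 2 or self.n_normal < 2:
            raise ParameterError("need at least 2 samples per group")
        if self.base_log_sd <= 0:
            raise ParameterError("base_log_sd must be positive")
        if self.n_genes < 1:
            raise ParameterError("n_genes must be >= 1")
        if self.gene_names is not None and len(self.gene_names) != self.n_genes:
            raise ParameterError("gene_names length must equal n_genes")


def simulate_expression_cohort(params: ExpressionSimParams) -> ExpressionCohort:
    """TPM-like genes x samples matrix, log-normal within each group."""
    rng = np.random.default_rng(params.rng_seed)
    genes = (
        list(params.gene_names)
        if params.gene_names is not None
        else [f"G{i:04d}" for i in range(params.n_genes)]
    )
    shifts = np.array([params.effect_sizes.get(g, 0.0) for g in genes])
    n_t, n_n = params.n_tumor, params.n_normal
    log_normal_vals = rng.normal(
        params.base_log_mean, params.base_log_sd, size=(params.n_genes, n_n)
    )
    log_tumor_vals = rng.normal(
        params.base_log_mean + shifts[:, None], params.base_log_sd,
        size=(params.n_genes, n_t),
    )
    values = np.concatenate([2.0 ** log_tumor_vals, 2.0 ** log_normal_vals], axis=1)
    samples = [f"T{i:04d}" for i in range(n_t)] + [f"N{i:04d}" for i in range(n_n)]
    group = {s: ("tumor" if s.startswith("T") else "normal") for s in samples}
    return ExpressionCohort(
        values=pd.DataFrame(values, index=genes, columns=samples), group=group
    )


@dataclass(frozen=True)
class SurvivalSimParams:
    """Proportional-hazards survival generator parameters.

    ``log_hr_per_sd`` maps gene -> log hazard ratio per standard deviation
    of that gene's expression; the per-patient hazard is
    baseline_hazard * exp(sum_g beta_g * z_g). Censoring is independent
    uniform on [0, max_follow_up].
    """

    n_patients: int = 500
    baseline_hazard: float = 0.1
    log_hr_per_sd: Mapping[str, float] = field(default_factory=dict)
    censor_rate: float = 0.3
    max_follow_up: float = 120.0
    endpoint: str = "OS"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 20:
            raise ParameterError("n_patients must be >= 20")
        if self.baseline_hazard <= 0:
            raise ParameterError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ParameterError("censor_rate must be in [0, 1)")
        if self.endpoint not in ENDPOINTS:
            raise ParameterError(f"unknown endpoint {self.endpoint!r}")


def simulate_survival_cohort(
    params: SurvivalSimParams, expression: pd.DataFrame
) -> SurvivalCohort:
    """Exponential event times under proportional hazards.

    ``expression`` is patients x genes; every listed effect gene must be a
    column. Event times are exponential with rate
    baseline_hazard * exp(sum_g beta_g * z_g); censoring draws an
    independent uniform [0, max_follow_up] administrative time for a
    ``censor_rate`` fraction of patients (the rest are followed to the
    event). The event flag is 1 when the event precedes censoring.
    """
    if len(expression) != params.n_patients:
        raise ParameterError("expression must have one row per patient")
    missing = [g for g in params.log_hr_per_sd if g not in expression.columns]
    if missing:
        raise ParameterError(f"effect genes absent from expression: {missing}")
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_patients
    lin = np.zeros(n)
    for gene, beta in params.log_hr_per_sd.items():
        x = expression[gene].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        lin += beta * z
    hazard = params.baseline_hazard * np.exp(lin)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = np.full(n, np.inf)
    censored = rng.random(n) < params.censor_rate
    censor_time[censored] = rng.uniform(0.0, params.max_follow_up, censored.sum())
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    assert (time > 0).all()
    return SurvivalCohort(
        endpoint=params.endpoint,
        time=time,
        event=event,
        expression=expression.reset_index(drop=True),
    )


@dataclass(frozen=True)
class DensitometrySimParams:
    """Three-class E/hybrid/M densitometry generator parameters.

    Patients draw a latent class from ``class_proportions`` (epithelial,
    hybrid, mesenchymal). Marker band intensities are log-normal around
    class-specific log-means with a positive correlation
    ``epithelial_mesenchymal_corr`` between the mesenchymal (VIM) and
    epithelial (CDH1) channels; the housekeeping channel has independent
    multiplicative noise. ``nd_rate`` of marker entries (never the
    housekeeping channel) are blanked to ND.

    Default class log-means put the VIM/CDH1 ratio around 0.3 (epithelial),
    3 (hybrid) and 30 (mesenchymal) so the three classes straddle the
    1 and 10 ratio boundaries.
    """

    n_patients: int = 95
    class_proportions: tuple[float, float, float] = (0.14, 0.63, 0.23)
    marker_log_means: Mapping[str, Mapping[str, float]] | None = None
    marker_log_sd: float = 0.35
    epithelial_mesenchymal_corr: float = 0.6
    nd_rate: float = 0.02
    rng_seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.class_proportions, dtype=float)
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("class proportions must be nonnegative and sum to 1")
        if not 0.0 <= self.nd_rate < 0.5:
            raise ParameterError("nd_rate must be in [0, 0.5)")
        if not -1.0 < self.epithelial_mesenchymal_corr < 1.0:
            raise ParameterError("epithelial_mesenchymal_corr must be in (-1, 1)")
        if self.n_patients < 1:
            raise ParameterError("n_patients must be >= 1")

    def resolved_log_means(self) -> dict[str, dict[str, float]]:
        if self.marker_log_means is not None:
            return {k: dict(v) for k, v in self.marker_log_means.items()}
        # natural-log intensity means per class. The class contrast is
        # carried by VIM so the VIM/CDH1 ratio geometric centers are
        # e^{-1.2} ~ 0.30, e^{1.1} ~ 3.0, e^{3.4} ~ 30 — one class per
        # ratio band; CDH1 class means are flat so that the positive
        # shared co-abundance factor (see the generator) dominates the
        # marginal VIM-CDH1 correlation, as observed on real blots.
        return {
            "epithelial": {"VIM": -1.2, "CDH1": 0.0, "KRT18": 0.5, "ACTA2": -0.3},
            "hybrid": {"VIM": 1.1, "CDH1": 0.0, "KRT18": 0.2, "ACTA2": 0.1},
            "mesenchymal": {"VIM": 3.4, "CDH1": 0.0, "KRT18": -0.4, "ACTA2": 0.6},
        }


_CLASSES = ("epithelial", "hybrid", "mesenchymal")


def _solve_shared_variance(
    rho: float, c_v: float, c_c: float, c_cov: float, s2: float
) -> float:
    """Variance u of the shared VIM/CDH1 co-abundance factor such that the
    marginal Pearson correlation of the log-intensities equals rho:

        (u + c_cov) / sqrt((c_v + u + s2)(c_c + u + s2)) = rho

    where c_* are the between-class (co)variances of the marker log-means
    and s2 the residual variance. The left side increases from its u=0
    value to 1, so a solution exists for any attainable rho; rho at or
    below the u=0 correlation yields u = 0.
    """
    from scipy.optimize import brentq

    def f(u: float) -> float:
        return (u + c_cov) / np.sqrt((c_v + u + s2) * (c_c + u + s2)) - rho

    if f(0.0) >= 0:
        return 0.0
    hi = 10.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 10.0
    return float(brentq(f, 0.0, hi))


def simulate_densitometry_panel(
    params: DensitometrySimParams,
) -> tuple[DensitometryPanel, np.ndarray]:
    """Generate a raw densitometry panel plus the latent class labels.

    The returned panel holds *raw* band intensities (housekeeping channel
    included, scaled by a per-patient loading factor) with NaN for ND
    entries; call :func:`emtsig.phenotype.normalize_panel` before
    downstream analysis. Latent labels are returned for recovery tests.

    A positive ``epithelial_mesenchymal_corr`` is induced by a shared
    per-patient co-abundance factor added to the VIM and CDH1
    log-intensities, with its variance solved so that the *marginal*
    VIM-CDH1 Pearson correlation (across the class mixture) matches the
    parameter. The shared factor cancels exactly in the VIM/CDH1 ratio,
    so the phenotype-class composition is unaffected. A negative
    parameter is induced on the residuals instead (approximate at the
    margin once class structure is added).
    """
    rng = np.random.default_rng(params.rng_seed)
    n = params.n_patients
    props = np.asarray(params.class_proportions, float)
    labels = rng.choice(3, size=n, p=props)
    means = params.resolved_log_means()
    markers = list(next(iter(means.values())).keys())
    rho = params.epithelial_mesenchymal_corr
    sd = params.marker_log_sd

    log_int = np.empty((n, len(markers)))
    vim_idx = markers.index("VIM") if "VIM" in markers else None
    cdh_idx = markers.index("CDH1") if "CDH1" in markers else None
    for j, m in enumerate(markers):
        log_int[:, j] = [means[_CLASSES[c]][m] for c in labels]
    noise = rng.normal(0.0, 1.0, size=(n, len(markers)))
    if vim_idx is not None and cdh_idx is not None and rho != 0.0:
        mu_v = np.array([means[c]["VIM"] for c in _CLASSES])
        mu_c = np.array([means[c]["CDH1"] for c in _CLASSES])
        c_v = np.average((mu_v - np.average(mu_v, weights=props)) ** 2, weights=props)
        c_c = np.average((mu_c - np.average(mu_c, weights=props)) ** 2, weights=props)
        c_cov = np.average(
            (mu_v - np.average(mu_v, weights=props))
            * (mu_c - np.average(mu_c, weights=props)),
            weights=props,
        )
        s2 = sd**2
        if rho > 0:
            u = _solve_shared_variance(rho, c_v, c_c, c_cov, s2)
            shared = rng.normal(0.0, np.sqrt(u), size=n)
            log_int[:, vim_idx] += shared
            log_int[:, cdh_idx] += shared
        else:
            a = np.sqrt(abs(rho))
            b = np.sqrt(1.0 - abs(rho))
            resid_shared = rng.normal(0.0, 1.0, size=n)
            noise[:, vim_idx] = a * resid_shared + b * noise[:, vim_idx]
            noise[:, cdh_idx] = -a * resid_shared + b * noise[:, cdh_idx]
    log_int += sd * noise

    # per-patient gel-loading factor multiplies every channel incl. ACTB
    loading = np.exp(rng.normal(0.0, 0.25, size=n))
    housekeeping_raw = loading * np.exp(rng.normal(0.0, 0.15, size=n))
    raw = np.exp(log_int) * loading[:, None]

    if params.nd_rate > 0:
        nd_mask = rng.random(raw.shape) < params.nd_rate
        raw[nd_mask] = np.nan

    patients = [f"P{i:03d}" for i in range(n)]
    frame = pd.DataFrame(raw, index=patients, columns=markers)
    frame[HOUSEKEEPING] = housekeeping_raw
    panel = DensitometryPanel(raw=frame, housekeeping=HOUSEKEEPING)
    return panel, labels


def simulate_study_lists(
    n_studies: int,
    universe: Sequence[str],
    recurrence_profile: Mapping[str, int],
    rng_seed: int = 0,
) -> list[set[str]]:
    """Per-study gene sets where gene g appears in exactly
    ``recurrence_profile[g]`` distinct studies (randomly assigned)."""
    if n_studies < 1:
        raise ParameterError("n_studies must be >= 1")
    rng = np.random.default_rng(rng_seed)
    lists: list[set[str]] = [set() for _ in range(n_studies)]
    for gene in universe:
        k = int(recurrence_profile.get(gene, 0))
        if k < 0 or k > n_studies:
            raise ParameterError(
                f"recurrence {k} for {gene!r} outside [0, {n_studies}]"
            )
        for idx in rng.choice(n_studies, size=k, replace=False):
            lists[idx].add(gene)
    return lists
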