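"""Tumor-vs-normal differential screen by Welch's unequal-variance t-test.

The screen mirrors the box-plot comparison offered by bulk tumor/normal
expression portals: for every gene, log2(TPM + 1) values of the tumor group
are compared with the normal group by Welch's t-test, two-sided, and the
gene is called deregulated at a fixed nominal threshold (default 0.05)
without multiple-testing correction; an optional Benjamini–Hochberg flag is
available for users who want an FDR-controlled call set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import ParameterError, SampleSizeError

__all__ = ["ExpressionCohort", "DifferentialResult", "welch_t", "differential_expression"]

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionCohort:
    """Genes x samples matrix of nonnegative TPM-like values with a
    tumor/normal label per sample.

    ``values`` rows are genes (indexed by symbol), columns are samples.
    """

    values: pd.DataFrame
    group: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ParameterError("duplicate gene identifiers")
        if self.values.columns.has_duplicates:
            raise ParameterError("duplicate sample identifiers")
        labels = {s: self.group.get(s) for s in self.values.columns}
        missing = [s for s, g in labels.items() if g not in (TUMOR, NORMAL)]
        if missing:
            raise ParameterError(f"samples without a valid group label: {missing[:5]}")
        counts = pd.Series(list(labels.values())).value_counts()
        if counts.get(TUMOR, 0) < 2 or counts.get(NORMAL, 0) < 2:
            raise ParameterError("need at least 2 samples per group")
        if (self.values.values < 0).any():
            raise ParameterError("expression values must be nonnegative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group[s] == group]


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    t_statistic: float
    df: float
    p_value: float
    direction: str  # "up" | "down"
    mean_tumor: float  # log2 scale
    mean_normal: float  # log2 scale
    significant: bool
    degenerate: bool = False  # both samples zero-variance with equal means
    testable: bool = True


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float, bool]:
    """Welch's two-sample t-test.

    Returns ``(t, df, p, degenerate)``: t-statistic, Welch–Satterthwaite
    degrees of freedom and two-sided p-value. When both samples have zero
    variance with equal means the statistic is undefined; the test returns
    ``t = 0, p = 1`` with ``degenerate = True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise SampleSizeError("each sample needs at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("non-finite values in input")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0, True
        # separated point masses: infinitely strong evidence
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), float(x.size + y.size - 2), 0.0, True
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue), False


def differential_expression(
    cohort: ExpressionCohort,
    config: AnalysisConfig | None = None,
    bh_correct: bool = False,
) -> list[DifferentialResult]:
    """Per-gene Welch screen on log2(TPM + 1), in input gene order.

    direction is "up" when the tumor log-mean exceeds the normal log-mean.
    ``significant`` compares the (optionally BH-adjusted) p-value against
    ``config.alpha_de``. Genes with fewer than two observations per group
    are flagged untestable and never significant.
    """
    config = config or AnalysisConfig()
    tumor_cols = cohort.samples_in(TUMOR)
    normal_cols = cohort.samples_in(NORMAL)
    logv = np.log2(cohort.values + 1.0)
    xt = logv[tumor_cols].to_numpy()
    xn = logv[normal_cols].to_numpy()

    results: list[DifferentialResult] = []
    pvals: list[float] = []
    for i, gene in enumerate(cohort.genes):
        t_obs = xt[i][np.isfinite(xt[i])]
        n_obs = xn[i][np.isfinite(xn[i])]
        mean_t = float(t_obs.mean()) if t_obs.size else np.nan
        mean_n = float(n_obs.mean()) if n_obs.size else np.nan
        if t_obs.size < 2 or n_obs.size < 2:
            results.append(
                DifferentialResult(
                    gene, np.nan, np.nan, np.nan,
                    direction="up" if mean_t > mean_n else "down",
                    mean_tumor=mean_t, mean_normal=mean_n,
                    significant=False, testable=False,
                )
            )
            pvals.append(np.nan)
            continue
        t, df, p, degen = welch_t(t_obs, n_obs)
        results.append(
            DifferentialResult(
                gene, t, df, p,
                direction="up" if mean_t > mean_n else "down",
                mean_tumor=mean_t, mean_normal=mean_n,
                significant=False, degenerate=degen,
            )
        )
        pvals.append(p)

    p_arr = np.asarray(pvals, dtype=float)
    if bh_correct:
        mask = np.isfinite(p_arr)
        adj = np.full_like(p_arr, np.nan)
        if mask.any():
            adj[mask] = stats.false_discovery_control(p_arr[mask], method="bh")
        p_eff = adj
    else:
        p_eff = p_arr

    out: list[DifferentialResult] = []
    for r, p in zip(results, p_eff):
        sig = bool(r.testable and np.isfinite(p) and p <= config.alpha_de)
        out.append(
            DifferentialResult(
                r.gene, r.t_statistic, r.df, r.p_value, r.direction,
                r.mean_tumor, r.mean_normal, sig, r.degenerate, r.testable,
            )
        )
    return out
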