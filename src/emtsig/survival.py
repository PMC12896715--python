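"""Optimal-cutpoint survival screening.

This module implements the survival half of the signature derivation: for
each gene, patients are dichotomized into high/low expression groups at
every candidate threshold between the first and third expression quartiles,
each split is tested by the two-group log-rank test, and the best-performing
(minimum-p) threshold is retained. Because the minimum over many correlated
candidate splits is strongly anti-conservative, the minimum p-value is
adjusted by a permutation scheme: the scan is re-run on B permutations of
expression against the (time, event) pairs and the adjusted p is the
permutation rank of the observed minimum,

    p_adj = (1 + #{b : min-p_b <= min-p_obs}) / (B + 1).

Hazard ratios are Pike one-step (O/E) estimates derived from the same
log-rank tables, with log-scale confidence intervals. A gene is called
prognostic only when all three endpoints (DMFS, OS, RFS) are significant
with hazard ratios on the same side of 1 — the three-endpoint coherence
rule.

Internals are vectorized over candidate thresholds: at each distinct event
time the low-group at-risk count for *every* candidate is read off a
suffix-cumulative-sum of the candidate-by-patient membership matrix, so a
full scan (and each permutation replicate) costs one pass over that matrix.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import ParameterError, SampleSizeError, ScanEmptyError

__all__ = [
    "SurvivalCohort",
    "KMCurve",
    "LogrankResult",
    "HazardRatioResult",
    "CutpointScanResult",
    "PrognosticCall",
    "ENDPOINTS",
    "km_estimate",
    "logrank_test",
    "hazard_ratio_oe",
    "best_cutoff_scan",
    "adjust_min_p",
    "classify_prognosis",
]

ENDPOINTS = ("DMFS", "OS", "RFS")


@dataclass
class SurvivalCohort:
    """Per-endpoint follow-up records with per-gene expression.

    ``expression`` is a patients x genes DataFrame aligned with ``time``
    and ``event`` (1 = event occurred, 0 = censored).
    """

    endpoint: str
    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.endpoint not in ENDPOINTS:
            raise ParameterError(f"unknown endpoint {self.endpoint!r}")
        n = self.time.size
        if self.event.size != n or len(self.expression) != n:
            raise ParameterError("time, event and expression must be aligned")
        if (self.time <= 0).any():
            raise ParameterError("follow-up times must be positive")
        if self.event.sum() < 1:
            raise ParameterError("cohort must contain at least one event")

    @property
    def n_patients(self) -> int:
        return self.time.size

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival probability after each event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    degenerate: bool = False  # zero pooled variance


@dataclass(frozen=True)
class HazardRatioResult:
    """Pike O/E hazard ratio of group A relative to group B."""

    hr: float
    ci_low: float
    ci_high: float
    boundary: bool = False  # a group had zero observed events


@dataclass(frozen=True)
class CutpointScanResult:
    gene: str
    best_cutoff: float
    candidates_evaluated: int
    logrank_p_min: float
    adjusted_p: float | None
    hazard_ratio: float  # high-vs-low at the best cutoff
    hr_boundary: bool
    n_high: int
    n_low: int


@dataclass(frozen=True)
class PrognosticCall:
    gene: str
    per_endpoint: dict[str, tuple[float, float]]  # endpoint -> (p used, HR)
    direction: str  # "worse" | "better" | "none"
    coherent: bool


# ---------------------------------------------------------------------------
# log-rank machinery

class _LogrankEngine:
    """Precomputed event structure of one (time, event) vector.

    ``stats(member)`` evaluates, for every row of a candidate-by-patient
    boolean membership matrix (rows = candidate group-A assignments, columns
    = patients in time-sorted order), the log-rank O, E and hypergeometric
    variance of group A.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray) -> None:
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        if event.sum() < 1:
            raise ParameterError("need at least one pooled event")
        self.n = time.size
        self.order = np.argsort(time, kind="stable")
        ts = time[self.order]
        es = event[self.order]
        self.ev_pos = np.flatnonzero(es == 1)
        ev_t = ts[self.ev_pos]
        starts = np.flatnonzero(np.r_[True, ev_t[1:] != ev_t[:-1]])
        self.starts = starts
        self.d_j = np.diff(np.r_[starts, ev_t.size]).astype(float)
        t_j = ev_t[starts]
        self.f_j = np.searchsorted(ts, t_j, side="left")
        self.n_j = (self.n - self.f_j).astype(float)
        denom = np.maximum(self.n_j - 1.0, 1.0)
        # coefficient of the hypergeometric variance term per event time
        self.a_j = self.d_j * (self.n_j - self.d_j) / denom
        self.total_events = float(self.d_j.sum())

    def stats(self, member_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        A = np.ascontiguousarray(member_sorted, dtype=float)
        if A.ndim == 1:
            A = A[None, :]
        # suffix sums give the group-A at-risk count at each event time
        suffix = np.cumsum(A[:, ::-1], axis=1)[:, ::-1]
        n_A = suffix[:, self.f_j]
        d_A = np.add.reduceat(A[:, self.ev_pos], self.starts, axis=1) \
            if self.ev_pos.size else np.zeros((A.shape[0], 0))
        frac = n_A / self.n_j
        O = d_A.sum(axis=1)
        E = (self.d_j * frac).sum(axis=1)
        V = (self.a_j * frac * (1.0 - frac)).sum(axis=1)
        return O, E, V

    def chi_square(self, member_sorted: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        O, E, V = self.stats(member_sorted)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(V > 0, (O - E) ** 2 / V, 0.0)
        return chi2, V


class _CutpointScanner:
    """Evaluates the whole cutoff scan for one expression assignment.

    Works in rank space: candidate c's low group is exactly the ``r_c``
    smallest expression ranks, so a scan (observed or permuted) reduces to
    bucketing each patient's rank among the candidate thresholds, one
    bincount over (bucket, risk-segment) cells, and cumulative sums on the
    candidates x event-times grid. This makes the permutation adjustment
    of the minimum p linear in the number of patients per replicate.
    """

    def __init__(
        self, engine: _LogrankEngine, expr: np.ndarray, min_group_size: int
    ) -> None:
        self.engine = engine
        n = engine.n
        q1, q3 = np.quantile(expr, [0.25, 0.75])
        values = np.unique(expr)
        cand = values[(values >= q1) & (values <= q3)]
        if cand.size == 0:
            raise ScanEmptyError("no candidate cutoff between the quartiles")
        n_low = np.searchsorted(np.sort(expr), cand, side="right")
        valid = (n_low >= min_group_size) & (n - n_low >= min_group_size)
        if not valid.any():
            raise ScanEmptyError(
                "every candidate split leaves an arm below the minimum group size"
            )
        self.cutoffs = cand[valid]
        self.r = n_low[valid].astype(np.intp)  # low-group sizes, increasing
        self.n_candidates = int(self.r.size)

        # observed expression ranks in time-sorted patient order
        rank = np.empty(n, dtype=np.intp)
        rank[np.argsort(expr, kind="stable")] = np.arange(n)
        self.y_obs = rank[engine.order]

        # rank v belongs to candidate c's low group iff bucket(v) <= c
        self.bucket_of_rank = np.searchsorted(self.r, np.arange(n), side="right")
        # risk segment of each time-sorted position: in riskset j iff seg >= j+1
        self.seg = np.searchsorted(engine.f_j, np.arange(n), side="right")
        J = engine.f_j.size
        self.J = J
        self.w_e = engine.d_j / engine.n_j
        self.w_v1 = engine.a_j / engine.n_j
        self.w_v2 = engine.a_j / engine.n_j**2

    def evaluate(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """chi-square, observed and expected low-group events for every
        candidate, given expression ranks ``y`` in time-sorted order."""
        C, J = self.n_candidates, self.J
        b = self.bucket_of_rank[y]
        Z = np.bincount(
            b * (J + 1) + self.seg, minlength=(C + 1) * (J + 1)
        ).reshape(C + 1, J + 1)
        # prefix over buckets, suffix over risk segments -> low at-risk counts
        Zb = Z.cumsum(axis=0)[:C]
        n_A = Zb[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:].astype(float)
        O = np.bincount(b[self.engine.ev_pos], minlength=C + 1).cumsum()[:C].astype(float)
        E = n_A @ self.w_e
        V = n_A @ self.w_v1 - (n_A * n_A) @ self.w_v2
        V = np.maximum(V, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(V > 1e-12, (O - E) ** 2 / V, 0.0)
        return chi2, O, E


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan–Meier product-limit estimator.

    Censored observations leave the risk set without producing a step. With
    every observation censored the curve is flat at 1 (no event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise SampleSizeError("empty input")
    if time.size != event.size:
        raise ParameterError("time and event must have equal length")
    order = np.argsort(time, kind="stable")
    ts, es = time[order], event[order]
    ev_t = ts[es == 1]
    t_j = np.unique(ev_t)
    n_at_risk = time.size - np.searchsorted(ts, t_j, side="left")
    d_j = np.array([(ev_t == t).sum() for t in t_j], dtype=float)
    surv = np.cumprod(1.0 - d_j / n_at_risk)
    return KMCurve(event_times=t_j, survival=surv, at_risk=n_at_risk.astype(int))


def _two_group_arrays(timeA, eventA, timeB, eventB):
    tA = np.asarray(timeA, dtype=float)
    eA = np.asarray(eventA, dtype=int)
    tB = np.asarray(timeB, dtype=float)
    eB = np.asarray(eventB, dtype=int)
    if tA.size == 0 or tB.size == 0:
        raise SampleSizeError("each group must be nonempty")
    time = np.r_[tA, tB]
    event = np.r_[eA, eB]
    member = np.r_[np.ones(tA.size, bool), np.zeros(tB.size, bool)]
    return time, event, member


def logrank_test(timeA, eventA, timeB, eventB) -> LogrankResult:
    """Two-group log-rank test (chi-square with 1 df, two-sided p).

    Zero pooled variance (e.g. no events before the groups separate) is
    returned as chi-square 0, p = 1 with a degeneracy flag.
    """
    time, event, member = _two_group_arrays(timeA, eventA, timeB, eventB)
    engine = _LogrankEngine(time, event)
    O, E, V = engine.stats(member[engine.order])
    if V[0] <= 0:
        return LogrankResult(0.0, 1.0, degenerate=True)
    chi2 = float((O[0] - E[0]) ** 2 / V[0])
    return LogrankResult(chi2, float(stats.chi2.sf(chi2, 1)))


def hazard_ratio_oe(timeA, eventA, timeB, eventB) -> HazardRatioResult:
    """Pike (O/E) hazard-ratio estimate of group A versus group B.

    HR = (O_A/E_A) / (O_B/E_B), with expectations from the log-rank
    hypergeometric tables and a log-scale 95% CI using variance
    1/E_A + 1/E_B. Zero observed events in a group yields a flagged
    boundary estimate (0 or +inf).
    """
    time, event, member = _two_group_arrays(timeA, eventA, timeB, eventB)
    engine = _LogrankEngine(time, event)
    O, E, V = engine.stats(member[engine.order])
    return _pike_from_oe(float(O[0]), float(E[0]), engine.total_events)


def _pike_from_oe(O_A: float, E_A: float, total_events: float) -> HazardRatioResult:
    O_B = total_events - O_A
    E_B = total_events - E_A
    if E_A <= 0 or E_B <= 0:
        return HazardRatioResult(np.nan, np.nan, np.nan, boundary=True)
    if O_A == 0 or O_B == 0:
        hr = 0.0 if O_A == 0 else np.inf
        return HazardRatioResult(hr, np.nan, np.nan, boundary=True)
    hr = (O_A / E_A) / (O_B / E_B)
    half = 1.959963984540054 * np.sqrt(1.0 / E_A + 1.0 / E_B)
    return HazardRatioResult(hr, hr * np.exp(-half), hr * np.exp(half), boundary=False)


# ---------------------------------------------------------------------------
# cutpoint scan

def best_cutoff_scan(
    gene: str,
    cohort: SurvivalCohort,
    config: AnalysisConfig | None = None,
    adjust: bool = True,
    rng: np.random.Generator | None = None,
) -> CutpointScanResult:
    """Scan all admissible cutoffs between the expression quartiles.

    Candidates are the distinct observed expression values within
    [Q1, Q3] (linear-interpolation quartiles); each splits patients into
    low (<= cutoff) and high (> cutoff). The returned cutoff minimizes the
    log-rank p (ties to the smaller cutoff). ``adjusted_p`` is the
    permutation-rank adjustment of that minimum (None when ``adjust`` is
    False); the hazard ratio is the Pike high-vs-low estimate at the best
    cutoff.
    """
    config = config or AnalysisConfig()
    if gene not in cohort.expression.columns:
        raise KeyError(gene)
    expr = cohort.expression[gene].to_numpy(dtype=float)
    engine = _LogrankEngine(cohort.time, cohort.event)
    scanner = _CutpointScanner(engine, expr, config.min_group_size)
    chi2, O, E = scanner.evaluate(scanner.y_obs)
    pvals = stats.chi2.sf(chi2, 1)
    best = int(np.argmin(pvals))  # first minimum -> smallest cutoff on ties
    # Pike HR of high vs low: high group = complement of the low mask
    O_high = engine.total_events - float(O[best])
    E_high = engine.total_events - float(E[best])
    hr_res = _pike_from_oe(O_high, E_high, engine.total_events)

    adjusted: float | None = None
    if adjust:
        if rng is None:
            rng = np.random.default_rng(_stable_seed(config.rng_seed, gene, cohort.endpoint))
        adjusted = _permutation_adjust(
            scanner, float(chi2[best]), config.n_permutations, rng
        )

    n_low = int(scanner.r[best])
    return CutpointScanResult(
        gene=gene,
        best_cutoff=float(scanner.cutoffs[best]),
        candidates_evaluated=scanner.n_candidates,
        logrank_p_min=float(pvals[best]),
        adjusted_p=adjusted,
        hazard_ratio=float(hr_res.hr),
        hr_boundary=hr_res.boundary,
        n_high=expr.size - n_low,
        n_low=n_low,
    )


def _permutation_adjust(
    scanner: _CutpointScanner,
    observed_chi2: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """Permutation rank of the observed maximum chi-square (= minimum p).

    Each replicate permutes expression against the (time, event) pairs —
    in rank space, assigns a fresh uniform rank permutation — and repeats
    the full scan. Comparing maximum chi-squares is equivalent to
    comparing minimum p-values since every candidate has 1 df.
    """
    if n_permutations < 100:
        raise ParameterError("n_permutations must be >= 100")
    n = scanner.engine.n
    hits = 0
    for _ in range(n_permutations):
        chi2_b, _, _ = scanner.evaluate(rng.permutation(n))
        if chi2_b.max() >= observed_chi2:
            hits += 1
    return (1.0 + hits) / (n_permutations + 1.0)


def adjust_min_p(
    gene: str,
    cohort: SurvivalCohort,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation-adjusted minimum log-rank p for one gene's scan."""
    res = best_cutoff_scan(gene, cohort, config, adjust=True, rng=rng)
    assert res.adjusted_p is not None
    return res.adjusted_p


def _stable_seed(base_seed: int, gene: str, endpoint: str) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        [int(base_seed) % (2**31), zlib.crc32(gene.encode()), zlib.crc32(endpoint.encode())]
    )


def classify_prognosis(
    gene: str,
    cohorts: Mapping[str, SurvivalCohort],
    config: AnalysisConfig | None = None,
) -> PrognosticCall:
    """Three-endpoint coherence call for one gene.

    Runs the cutpoint scan on each endpoint cohort; the gene is coherent
    when all three endpoints are significant at ``config.alpha_surv``
    (permutation-adjusted p by default; nominal minimum p when
    ``config.use_adjusted_p`` is False) and the hazard-ratio directions
    agree. Direction "worse" means high expression is hazardous (HR > 1).
    """
    config = config or AnalysisConfig()
    missing = [ep for ep in ENDPOINTS if ep not in cohorts]
    if missing:
        raise ParameterError(f"missing endpoint cohort(s): {missing}")
    per_endpoint: dict[str, tuple[float, float]] = {}
    directions: list[str] = []
    significant = True
    for ep in ENDPOINTS:
        res = best_cutoff_scan(gene, cohorts[ep], config, adjust=config.use_adjusted_p)
        p_used = res.adjusted_p if config.use_adjusted_p else res.logrank_p_min
        assert p_used is not None
        per_endpoint[ep] = (float(p_used), float(res.hazard_ratio))
        if not p_used <= config.alpha_surv:
            significant = False
        if res.hr_boundary or not np.isfinite(res.hazard_ratio) or res.hazard_ratio == 1.0:
            directions.append("none")
        else:
            directions.append("worse" if res.hazard_ratio > 1.0 else "better")
    coherent = significant and len(set(directions)) == 1 and directions[0] != "none"
    return PrognosticCall(
        gene=gene,
        per_endpoint=per_endpoint,
        direction=directions[0] if coherent else "none",
        coherent=coherent,
    )
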