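"""Densitometry normalization and hybrid E/M phenotype classification.

Western-blot band intensities are normalized patient-wise against a
housekeeping channel (β-actin) to cancel gel-loading differences. The
mesenchymal/epithelial balance of each patient is summarized by the ratio
of a mesenchymal to an epithelial marker (canonically Vimentin/E-cadherin)
and classified into three phenotype bands:

* ratio < 1  — predominantly epithelial,
* 1 <= ratio <= 10 — hybrid (intermediate) epithelial/mesenchymal,
* ratio > 10 — predominantly mesenchymal.

The boundaries are closed into the hybrid band, the only reading
consistent with "< 1", "1 to 10" and "> 10". ND (not detected) is treated
as missing, with ratio conventions: an undetected denominator with a
positive numerator is an unbounded ratio (mesenchymal side), an undetected
numerator with a positive denominator is ratio 0 (epithelial side), and a
fully undetected pair is unclassifiable.

Markers resolved as several bands (e.g. Vimentin 50 + 40 kDa) enter the
ratio as the summed band intensity by default; band-level values can be
retained for isoform-level correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "DensitometryPanel",
    "PhenotypeCall",
    "CorrelationResult",
    "CorrelationMatrix",
    "normalize_panel",
    "pearson_with_p",
    "marker_ratio",
    "classify_phenotypes",
    "correlation_matrix",
]


@dataclass
class DensitometryPanel:
    """Patient x marker band intensities with a housekeeping channel.

    ``raw`` holds nonnegative intensities with NaN for ND entries; the
    housekeeping column must be present. ``bands`` optionally keeps
    per-band intensities (MultiIndex columns (marker, band_kda)); ``raw``
    marker columns are then the per-marker band sums. ``normalized`` is
    populated by :func:`normalize_panel`.
    """

    raw: pd.DataFrame
    housekeeping: str = "ACTB"
    bands: pd.DataFrame | None = None
    normalized: pd.DataFrame | None = None
    unnormalizable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.housekeeping not in self.raw.columns:
            raise ParameterError(
                f"housekeeping channel {self.housekeeping!r} missing from panel"
            )
        vals = self.raw.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ParameterError("band intensities must be nonnegative")

    @classmethod
    def from_bands(
        cls, long_table: pd.DataFrame, housekeeping: str = "ACTB"
    ) -> "DensitometryPanel":
        """Build a panel from a long table with columns patient, marker,
        band_kda, raw_intensity ("ND" or NaN allowed).

        Per-marker intensity is the sum of detected bands; a marker with
        no detected band is ND.
        """
        required = {"patient", "marker", "band_kda", "raw_intensity"}
        missing = required - set(long_table.columns)
        if missing:
            raise ParameterError(f"long table missing column(s) {sorted(missing)}")
        tab = long_table.copy()
        tab["raw_intensity"] = pd.to_numeric(
            tab["raw_intensity"].replace("ND", np.nan), errors="coerce"
        )
        bands = tab.pivot_table(
            index="patient", columns=["marker", "band_kda"],
            values="raw_intensity", aggfunc="sum",
        )
        summed = tab.groupby(["patient", "marker"])["raw_intensity"].apply(
            lambda s: s.sum() if s.notna().any() else np.nan
        ).unstack("marker")
        return cls(raw=summed, housekeeping=housekeeping, bands=bands)

    @property
    def patients(self) -> list[str]:
        return list(self.raw.index)

    @property
    def markers(self) -> list[str]:
        return [m for m in self.raw.columns if m != self.housekeeping]


@dataclass(frozen=True)
class PhenotypeCall:
    patient: str
    ratio: float  # may be 0, +inf, or NaN (undefined)
    log10_ratio: float
    phenotype: str  # "epithelial" | "hybrid" | "mesenchymal" | "unclassified"


@dataclass(frozen=True)
class CorrelationResult:
    marker_pair: tuple[str, str]
    r: float
    n_pairs: int
    p_value: float
    significant: bool
    degenerate: bool = False  # zero variance in a vector


def normalize_panel(panel: DensitometryPanel) -> DensitometryPanel:
    """Divide every marker channel by the patient's housekeeping signal.

    Patients whose housekeeping signal is ND or zero cannot be normalized;
    they are flagged and all their markers become ND downstream. ND marker
    entries stay ND.
    """
    hk = panel.raw[panel.housekeeping].to_numpy(dtype=float)
    bad = ~np.isfinite(hk) | (hk <= 0)
    denom = np.where(bad, np.nan, hk)
    normalized = panel.raw.div(pd.Series(denom, index=panel.raw.index), axis=0)
    flagged = frozenset(np.asarray(panel.raw.index)[bad])
    return replace(panel, normalized=normalized, unnormalizable=flagged)


def pearson_with_p(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05,
    pair: tuple[str, str] = ("x", "y"),
) -> CorrelationResult:
    """Sample Pearson correlation with two-sided p from the t-transform
    t = r sqrt((n-2)/(1-r^2)) on n-2 df, after pairwise removal of missing
    values. Fewer than 3 complete pairs is an error; zero variance in
    either vector is returned flagged as degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if x.std() == 0.0 or y.std() == 0.0:
        return CorrelationResult(pair, np.nan, n, np.nan, False, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(pair, float(r), n, float(p), bool(p <= alpha))


def marker_ratio(
    panel: DensitometryPanel, patient: str, numerator: str, denominator: str
) -> float:
    """Ratio of normalized marker intensities for one patient.

    Returns +inf when the denominator is ND/zero with a positive
    numerator, 0.0 when the numerator is ND with a positive denominator,
    and NaN (undefined) when both are ND/zero.
    """
    if panel.normalized is None:
        raise ParameterError("panel must be normalized first (normalize_panel)")
    for m in (numerator, denominator):
        if m not in panel.normalized.columns:
            raise KeyError(m)
    num = float(panel.normalized.at[patient, numerator])
    den = float(panel.normalized.at[patient, denominator])
    num_ok = math.isfinite(num) and num > 0
    den_ok = math.isfinite(den) and den > 0
    if num_ok and den_ok:
        return num / den
    if num_ok and not den_ok:
        return math.inf
    if den_ok and not num_ok:
        return 0.0
    return math.nan


def _classify_ratio(ratio: float, config: AnalysisConfig) -> str:
    if math.isnan(ratio):
        return "unclassified"
    if ratio < config.ratio_low:
        return "epithelial"
    if ratio > config.ratio_high:
        return "mesenchymal"
    return "hybrid"


def classify_phenotypes(
    panel: DensitometryPanel,
    numerator: str = "VIM",
    denominator: str = "CDH1",
    config: AnalysisConfig | None = None,
) -> tuple[list[PhenotypeCall], dict[str, int]]:
    """Ternary E/hybrid/M classification of every patient.

    Returns the per-patient calls ordered by increasing ratio
    (unclassified last) and the class counts. The ratio is
    numerator/denominator of housekeeping-normalized intensities; class
    boundaries come from ``config.ratio_low``/``ratio_high`` with the
    boundaries themselves in the hybrid band.
    """
    config = config or AnalysisConfig()
    calls = []
    for patient in panel.patients:
        ratio = marker_ratio(panel, patient, numerator, denominator)
        log10 = math.log10(ratio) if ratio > 0 else (-math.inf if ratio == 0 else math.nan)
        calls.append(
            PhenotypeCall(patient, ratio, log10, _classify_ratio(ratio, config))
        )
    calls.sort(key=lambda c: (math.isnan(c.ratio), c.ratio))
    counts = {k: 0 for k in ("epithelial", "hybrid", "mesenchymal", "unclassified")}
    for c in calls:
        counts[c.phenotype] += 1
    return calls, counts


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson results over panel markers."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha: float = 0.05

    def result(self, a: str, b: str) -> CorrelationResult:
        r = float(self.r.at[a, b])
        p = float(self.p.at[a, b])
        return CorrelationResult(
            (a, b), r, int(self.n.at[a, b]), p,
            bool(np.isfinite(p) and p <= self.alpha),
            degenerate=not np.isfinite(r),
        )


def correlation_matrix(
    panel: DensitometryPanel,
    level: str = "marker",
    alpha: float = 0.05,
) -> CorrelationMatrix:
    """All pairwise Pearson correlations between normalized channels.

    ``level="marker"`` correlates per-marker (band-summed) intensities;
    ``level="band"`` correlates individual isoform bands when the panel
    retains them. Pairs use pairwise-complete observations; the diagonal
    is r = 1, p = 0 by convention. Pairs with fewer than 3 complete
    observations or zero variance get NaN entries.
    """
    if panel.normalized is None:
        raise ParameterError("panel must be normalized first (normalize_panel)")
    if level == "marker":
        data = panel.normalized[panel.markers]
        names = list(data.columns)
    elif level == "band":
        if panel.bands is None:
            raise ParameterError("panel has no band-level data")
        hk = panel.raw[panel.housekeeping]
        data = panel.bands.div(hk.where(hk > 0), axis=0)
        names = [f"{m}_{b}" for m, b in data.columns]
        data = data.set_axis(names, axis=1)
    else:
        raise ParameterError(f"unknown level {level!r}")
    if len(data) < 3:
        raise InsufficientDataError("need at least 3 patients")
    k = len(names)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(data))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                res = pearson_with_p(
                    data.iloc[:, i], data.iloc[:, j], alpha, (names[i], names[j])
                )
                r[i, j] = r[j, i] = res.r
                p[i, j] = p[j, i] = res.p_value
                n[i, j] = n[j, i] = res.n_pairs
            except InsufficientDataError:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                n[i, j] = n[j, i] = 0
    mk = lambda a: pd.DataFrame(a, index=names, columns=names)
    return CorrelationMatrix(mk(r), mk(p), mk(n), alpha)
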