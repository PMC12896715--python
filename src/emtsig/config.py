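"""Analysis configuration shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ParameterError


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and tuning knobs of the signature-derivation pipeline.

    Parameters
    ----------
    alpha_de:
        Two-sided significance threshold for the tumor-vs-normal Welch
        screen. Genes with p <= alpha_de are called deregulated.
    alpha_surv:
        Significance threshold applied per survival endpoint (DMFS, OS,
        RFS) to the optimal-cutpoint log-rank p-value.
    min_studies:
        Minimum number of independent source studies a gene must appear in
        to pass the consensus filter.
    ratio_low, ratio_high:
        Boundaries of the hybrid epithelial/mesenchymal band on the
        mesenchymal/epithelial marker ratio: ratio < ratio_low is
        epithelial, ratio > ratio_high is mesenchymal, the closed interval
        in between is hybrid.
    n_permutations:
        Number of permutations B used to adjust the minimum log-rank
        p-value of the cutpoint scan for the multiplicity of candidate
        thresholds.
    min_group_size:
        Smallest admissible arm after a high/low split; candidate cutoffs
        producing a smaller arm are skipped.
    use_adjusted_p:
        Whether the three-endpoint coherence call compares the
        permutation-adjusted minimum p (True) or the nominal minimum p
        (False) against ``alpha_surv``.
    rng_seed:
        Seed for every stochastic step (permutations, simulations).
    """

    alpha_de: float = 0.05
    alpha_surv: float = 0.05
    min_studies: int = 2
    ratio_low: float = 1.0
    ratio_high: float = 10.0
    n_permutations: int = 1000
    min_group_size: int = 5
    use_adjusted_p: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_de < 1.0:
            raise ParameterError(f"alpha_de must be in (0, 1), got {self.alpha_de}")
        if not 0.0 < self.alpha_surv < 1.0:
            raise ParameterError(f"alpha_surv must be in (0, 1), got {self.alpha_surv}")
        if self.min_studies < 1:
            raise ParameterError(f"min_studies must be >= 1, got {self.min_studies}")
        if not 0.0 < self.ratio_low < self.ratio_high:
            raise ParameterError(
                f"need 0 < ratio_low < ratio_high, got {self.ratio_low}, {self.ratio_high}"
            )
        if self.n_permutations < 100:
            raise ParameterError(
                f"n_permutations must be >= 100, got {self.n_permutations}"
            )
        if self.min_group_size < 1:
            raise ParameterError(
                f"min_group_size must be >= 1, got {self.min_group_size}"
            )
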