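"""Trophic position from compound-specific amino-acid δ15N.

Trophic amino acids (canonically glutamic acid, Glu) enrich strongly in 15N
with each trophic transfer while source amino acids (phenylalanine, Phe) are
nearly conserved.  Their difference in a consumer therefore indexes trophic
position:

    TL = (δ15N_glu − δ15N_phe − β) / (Δ_glu − Δ_phe) + 1

where β is the Glu−Phe offset in primary producers and Δ_glu − Δ_phe the
per-trophic-level enrichment difference.  The aquatic-food-web defaults are
β = +3.4‰ and Δ_glu − Δ_phe = +7.6‰; both are explicit, overridable
parameters.  Replicate means enter at full precision, and the TL uncertainty
propagates the replicate standard errors through the linear formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import IsotopeSummary, ValidationError, summarize_replicates

__all__ = ["AAReplicates", "TLParameters", "TrophicLevelEstimate", "trophic_level"]

DEFAULT_BETA = 3.4
DEFAULT_DELTA_DIFF = 7.6


@dataclass(frozen=True)
class AAReplicates:
    """Replicate δ15N values of a trophic and a source amino acid."""

    organism: str
    trophic_values: Sequence[float]
    source_values: Sequence[float]
    trophic_aa: str = "Glu"
    source_aa: str = "Phe"

    def __post_init__(self) -> None:
        if len(self.trophic_values) < 1 or len(self.source_values) < 1:
            raise ValidationError(
                f"{self.organism!r}: need at least one replicate per amino acid"
            )

    def trophic_summary(self) -> IsotopeSummary:
        return summarize_replicates(self.trophic_values, isotope="N15")

    def source_summary(self) -> IsotopeSummary:
        return summarize_replicates(self.source_values, isotope="N15")


@dataclass(frozen=True)
class TLParameters:
    """β (producer offset, ‰) and Δ_trophic − Δ_source (per-level, ‰)."""

    beta: float = DEFAULT_BETA
    delta_diff: float = DEFAULT_DELTA_DIFF

    def __post_init__(self) -> None:
        if not (math.isfinite(self.beta) and math.isfinite(self.delta_diff)):
            raise ValidationError("beta and delta_diff must be finite")
        if self.delta_diff == 0:
            raise ValidationError(
                "delta_diff must be nonzero: the per-level enrichment "
                "difference is the denominator of the trophic-level formula"
            )


@dataclass(frozen=True)
class TrophicLevelEstimate:
    organism: str
    tl: float
    sd: Optional[float]  # None when either amino acid has a single replicate
    n_trophic: int
    n_source: int


def trophic_level(
    replicates: AAReplicates, params: TLParameters = TLParameters()
) -> TrophicLevelEstimate:
    """Glu/Phe trophic position with propagated replicate uncertainty.

    TL = (mean δ15N_trophic − mean δ15N_source − β) / Δdiff + 1, with
    SD = sqrt(sd_t²/n_t + sd_s²/n_s) / |Δdiff| when both replicate SDs exist.
    """
    ts = replicates.trophic_summary()
    ss = replicates.source_summary()
    tl = (ts.mean - ss.mean - params.beta) / params.delta_diff + 1.0
    sd = None
    if ts.sd is not None and ss.sd is not None:
        sd = math.sqrt(ts.sd ** 2 / ts.n + ss.sd ** 2 / ss.n) / abs(
            params.delta_diff
        )
    return TrophicLevelEstimate(
        organism=replicates.organism,
        tl=tl,
        sd=sd,
        n_trophic=ts.n,
        n_source=ss.n,
    )
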