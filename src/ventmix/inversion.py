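"""End-member inversion: infer an unmeasured food source from a consumer.

Some consumers carry isotope values that no measured source can explain as a
convex mixture (e.g. tissue δ13C heavier than the heaviest measured source).
The mass-balance equations can then be solved backwards: given the consumer's
tissue values X_j, its TDF Δ_j, a known part of its diet (components m_jd
with weights w_d summing to 1 − f), and the fraction f attributed to the
hypothetical source, the source's values are

    h_j = (X_j − Δ_j − Σ_d w_d m_jd) / f

The f = 1 special case (``invert_pure_diet``) is simply h_j = X_j − Δ_j —
a consumer one trophic step above a pure diet of the unknown source.  This is
point algebra: TDF uncertainty is not propagated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

from .core import (
    ISOTOPES,
    ConsumerObservation,
    SourcePool,
    TDFSet,
    ValidationError,
)

__all__ = [
    "DietComponent",
    "InversionProblem",
    "InvertedEndMember",
    "invert_pure_diet",
    "invert_mixed_diet",
    "forward_mix",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class DietComponent:
    """A known diet item: fixed per-isotope δ values and a diet weight."""

    name: str
    d13c: float
    d15n: float
    weight: float

    def value(self, isotope: str) -> float:
        return self.d13c if isotope == "C13" else self.d15n

    @classmethod
    def from_source(cls, source: SourcePool, weight: float) -> "DietComponent":
        return cls(
            name=source.name,
            d13c=source.mean("C13"),
            d15n=source.mean("N15"),
            weight=weight,
        )


def _as_component(item, weight: float) -> DietComponent:
    if isinstance(item, SourcePool):
        return DietComponent.from_source(item, weight)
    if isinstance(item, DietComponent):
        return item
    d13c, d15n = item
    return DietComponent(name="fixed", d13c=d13c, d15n=d15n, weight=weight)


@dataclass
class InversionProblem:
    """A consumer, its TDF, the known part of its diet, and the unknown's
    fraction ``hypothetical_fraction`` (f)."""

    consumer: ConsumerObservation
    tdf: TDFSet
    hypothetical_fraction: float
    known_diet: Sequence[Union[DietComponent, tuple]] = ()

    def __post_init__(self) -> None:
        f = self.hypothetical_fraction
        if not (0.0 < f <= 1.0):
            raise ValidationError(
                f"hypothetical fraction must be in (0, 1], got {f}"
            )
        comps = []
        for item in self.known_diet:
            if isinstance(item, tuple) and len(item) == 2 and not isinstance(
                item[0], (int, float)
            ):
                comps.append(_as_component(item[0], item[1]))
            else:
                comps.append(_as_component(item, getattr(item, "weight", 0.0)))
        self.known_diet = comps
        wsum = sum(c.weight for c in comps)
        if any(c.weight < 0 for c in comps):
            raise ValidationError("diet weights must be >= 0")
        if abs(wsum - (1.0 - f)) > _WEIGHT_TOL:
            raise ValidationError(
                f"known-diet weights sum to {wsum}, expected 1 - f = {1.0 - f}"
            )
        if f < 1.0 and not comps:
            raise ValidationError(
                "a known diet is required when the hypothetical fraction < 1"
            )


@dataclass(frozen=True)
class InvertedEndMember:
    """Inferred per-isotope δ values of the hypothetical source.

    ``flags`` marks, per isotope, whether the inferred value is heavier
    (``"heavier"``) or lighter (``"lighter"``) than every known diet
    component — a sign the reconstruction sits outside the measured range.
    """

    d13c: float
    d15n: float
    flags: dict

    def value(self, isotope: str) -> float:
        return self.d13c if isotope == "C13" else self.d15n


def invert_pure_diet(
    consumer: ConsumerObservation, tdf: TDFSet
) -> InvertedEndMember:
    """The f = 1 case: the source is the consumer minus one trophic step."""
    values = {iso: consumer.value(iso) - tdf.mean(iso) for iso in ISOTOPES}
    return InvertedEndMember(
        d13c=values["C13"], d15n=values["N15"], flags={iso: None for iso in ISOTOPES}
    )


def invert_mixed_diet(problem: InversionProblem) -> InvertedEndMember:
    """Solve h_j = (X_j − Δ_j − Σ_d w_d m_jd) / f for each isotope."""
    f = problem.hypothetical_fraction
    values = {}
    flags = {}
    for iso in ISOTOPES:
        known = sum(c.weight * c.value(iso) for c in problem.known_diet)
        h = (problem.consumer.value(iso) - problem.tdf.mean(iso) - known) / f
        values[iso] = h
        flag = None
        if problem.known_diet:
            comp_vals = [c.value(iso) for c in problem.known_diet]
            if h > max(comp_vals):
                flag = "heavier"
            elif h < min(comp_vals):
                flag = "lighter"
        flags[iso] = flag
    return InvertedEndMember(d13c=values["C13"], d15n=values["N15"], flags=flags)


def forward_mix(
    end_member: InvertedEndMember,
    problem: InversionProblem,
) -> dict:
    """Forward mass balance: tissue values implied by the inverted source.

    Used as the algebraic round-trip check: feeding the inversion result back
    through the same f, weights and TDF must reproduce the consumer exactly.
    """
    f = problem.hypothetical_fraction
    out = {}
    for iso in ISOTOPES:
        known = sum(c.weight * c.value(iso) for c in problem.known_diet)
        out[iso] = f * end_member.value(iso) + known + problem.tdf.mean(iso)
    return out
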