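"""Foundational types for bulk stable-isotope data.

Everything downstream (mixing model, trophic-position estimator, end-member
inversion) is built on a small set of value types: δ values in per-mil (‰)
notation, replicate summaries (mean ± sample SD), food-source pools, trophic
discrimination factors (TDFs) keyed by feeding guild, and per-individual
consumer observations.

Conventions
-----------
* Two isotopes are supported, labelled ``"C13"`` (δ13C vs VPDB) and ``"N15"``
  (δ15N vs atmospheric N2).
* Replicate SDs use the sample (n−1) denominator.  A single replicate has an
  *undefined* SD (``None``), never a silent zero: any variance that enters the
  mixing model must be stated explicitly.
* Guild lookup of a TDF is strict — an unregistered guild raises, it never
  falls back to a default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np

ISOTOPES: tuple[str, str] = ("C13", "N15")

__all__ = [
    "ISOTOPES",
    "ValidationError",
    "GuildLookupError",
    "DegenerateModelError",
    "CapabilityError",
    "DeltaValue",
    "IsotopeSummary",
    "SourcePool",
    "TDFSet",
    "ConsumerObservation",
    "delta_from_ratios",
    "ratio_from_delta",
    "summarize_replicates",
    "tdf_for_guild",
    "kst_tdf_registry",
    "round_half_up",
]


class ValidationError(ValueError):
    """Invalid input data or parameters."""


class GuildLookupError(KeyError):
    """A feeding guild has no registered trophic discrimination factors."""


class DegenerateModelError(ValueError):
    """The model's mixture variance is identically zero."""


class CapabilityError(ValueError):
    """The requested computation exceeds what the method supports."""


def _check_isotope(isotope: str) -> str:
    if isotope not in ISOTOPES:
        raise ValidationError(
            f"unknown isotope label {isotope!r}; expected one of {ISOTOPES}"
        )
    return isotope


@dataclass(frozen=True)
class DeltaValue:
    """A δ value in per-mil (‰) for one isotope system."""

    isotope: str
    value: float

    def __post_init__(self) -> None:
        _check_isotope(self.isotope)
        if not math.isfinite(self.value):
            raise ValidationError(f"δ value must be finite, got {self.value!r}")


@dataclass(frozen=True)
class IsotopeSummary:
    """Mean ± sample SD of replicate δ measurements for one isotope.

    ``sd`` is ``None`` (undefined) when ``n == 1``; with ``n >= 2`` it is the
    n−1-denominator sample standard deviation.
    """

    isotope: str
    mean: float
    sd: Optional[float]
    n: int

    def __post_init__(self) -> None:
        _check_isotope(self.isotope)
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if not math.isfinite(self.mean):
            raise ValidationError("mean must be finite")
        if self.sd is not None:
            if not math.isfinite(self.sd) or self.sd < 0:
                raise ValidationError(f"sd must be finite and >= 0, got {self.sd!r}")


@dataclass(frozen=True)
class SourcePool:
    """A candidate food source: per-isotope mean and SD, optional concentration.

    ``concentration`` maps isotope label to the source's elemental fraction
    (carbon or nitrogen content); when omitted, sources are treated as having
    equal concentrations.
    """

    name: str
    summaries: Mapping[str, IsotopeSummary]
    concentration: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        for iso in ISOTOPES:
            if iso not in self.summaries:
                raise ValidationError(
                    f"source {self.name!r} is missing isotope {iso}"
                )
            if self.summaries[iso].isotope != iso:
                raise ValidationError(
                    f"source {self.name!r}: summary under key {iso} is for "
                    f"{self.summaries[iso].isotope}"
                )
        if self.concentration is not None:
            for iso, c in self.concentration.items():
                _check_isotope(iso)
                if not (0.0 < c <= 1.0):
                    raise ValidationError(
                        f"source {self.name!r}: concentration for {iso} must be "
                        f"in (0, 1], got {c}"
                    )

    def mean(self, isotope: str) -> float:
        return self.summaries[_check_isotope(isotope)].mean

    def sd(self, isotope: str) -> Optional[float]:
        return self.summaries[_check_isotope(isotope)].sd


@dataclass(frozen=True)
class TDFSet:
    """Per-guild trophic discrimination factors Δ (mean) and τ (SD) per isotope."""

    guild: str
    means: Mapping[str, float]
    sds: Mapping[str, float]

    def __post_init__(self) -> None:
        for iso in ISOTOPES:
            if iso not in self.means or iso not in self.sds:
                raise ValidationError(
                    f"TDF set for guild {self.guild!r} is missing isotope {iso}"
                )
            if not math.isfinite(self.means[iso]):
                raise ValidationError("TDF mean must be finite")
            if not (math.isfinite(self.sds[iso]) and self.sds[iso] >= 0):
                raise ValidationError("TDF sd must be finite and >= 0")

    def mean(self, isotope: str) -> float:
        return self.means[_check_isotope(isotope)]

    def sd(self, isotope: str) -> float:
        return self.sds[_check_isotope(isotope)]


@dataclass(frozen=True)
class ConsumerObservation:
    """One consumer's tissue δ13C/δ15N with taxon, feeding guild and location."""

    id: str
    taxon: str
    guild: str
    d13c: float
    d15n: float
    site: Optional[str] = None
    distance_m: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13c) and math.isfinite(self.d15n)):
            raise ValidationError(
                f"consumer {self.id!r}: both δ13C and δ15N must be finite"
            )

    def value(self, isotope: str) -> float:
        return self.d13c if _check_isotope(isotope) == "C13" else self.d15n

    def delta(self, isotope: str) -> DeltaValue:
        return DeltaValue(isotope, self.value(isotope))


def delta_from_ratios(
    r_sample: float, r_standard: float, isotope: str = "C13"
) -> DeltaValue:
    """δ notation: δX = (R_sample / R_standard − 1) × 1000 ‰.

    ``R`` is the heavy/light isotope ratio (13C/12C or 15N/14N); the standards
    are VPDB for carbon and atmospheric N2 for nitrogen.
    """
    if r_standard <= 0:
        raise ValidationError(f"standard ratio must be > 0, got {r_standard}")
    if r_sample < 0:
        raise ValidationError(f"sample ratio must be >= 0, got {r_sample}")
    return DeltaValue(isotope, (r_sample / r_standard - 1.0) * 1000.0)


def ratio_from_delta(delta: DeltaValue | float, r_standard: float) -> float:
    """Invert δ notation: R_sample = R_standard × (δ/1000 + 1)."""
    if r_standard <= 0:
        raise ValidationError(f"standard ratio must be > 0, got {r_standard}")
    value = delta.value if isinstance(delta, DeltaValue) else float(delta)
    return r_standard * (value / 1000.0 + 1.0)


def summarize_replicates(
    values: Sequence[float], isotope: str = "C13"
) -> IsotopeSummary:
    """Arithmetic mean and sample (n−1) SD of replicate δ values.

    With a single replicate the SD is undefined (``None``).
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot summarize an empty replicate list")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("replicate values must be finite")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return IsotopeSummary(isotope=isotope, mean=mean, sd=sd, n=int(arr.size))


# Guild TDFs for the Kueishan Island (KST) shallow-water vent study:
# herbivores and carnivores carry different diet-to-tissue shifts.
_KST_TDFS: dict[str, TDFSet] = {
    "herbivore": TDFSet(
        guild="herbivore",
        means={"C13": -0.41, "N15": 2.52},
        sds={"C13": 1.14, "N15": 2.50},
    ),
    "carnivore": TDFSet(
        guild="carnivore",
        means={"C13": 0.91, "N15": 3.23},
        sds={"C13": 1.04, "N15": 0.41},
    ),
}


def kst_tdf_registry() -> dict[str, TDFSet]:
    """The study's guild → TDF registry (herbivore and carnivore entries)."""
    return dict(_KST_TDFS)


def tdf_for_guild(
    guild: str, registry: Optional[Mapping[str, TDFSet]] = None
) -> TDFSet:
    """Strict lookup of a guild's TDFs; unknown guilds raise, never default."""
    reg = _KST_TDFS if registry is None else registry
    try:
        return reg[guild]
    except KeyError:
        raise GuildLookupError(
            f"no trophic discrimination factors registered for guild {guild!r}; "
            f"known guilds: {sorted(reg)}"
        ) from None


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
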