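"""CSV schemas for sources, consumers, TDFs, amino-acid replicates and diets.

All files are UTF-8 with a header row; per-mil values are plain decimals.

* ``sources.csv``: name, isotope (C13|N15), mean, sd, n[, concentration]
* ``consumers.csv``: id, taxon, guild, d13c, d15n[, site, distance_m]
* ``tdf.csv``: guild, isotope, mean, sd
* ``aa_replicates.csv``: organism, amino_acid (Glu|Phe), d15n
* ``diet.csv``: source, d13c, d15n, weight

Parse failures raise :class:`ventmix.core.ValidationError` naming the file
and the 1-based data line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    ISOTOPES,
    ConsumerObservation,
    IsotopeSummary,
    SourcePool,
    TDFSet,
    ValidationError,
)
from .aa import AAReplicates
from .inversion import DietComponent

__all__ = [
    "read_sources",
    "write_sources",
    "read_consumers",
    "write_consumers",
    "read_tdf_registry",
    "write_tdf_registry",
    "read_aa_replicates",
    "read_diet",
    "write_mixing_summary",
]


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ValidationError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _line(i: int) -> int:
    # 1-based line number in the file (header is line 1)
    return i + 2


def read_sources(path) -> list[SourcePool]:
    """Read source pools; each source needs one row per isotope."""
    df = _read_csv(path, ["name", "isotope", "mean", "sd", "n"])
    pools = []
    for name, grp in df.groupby("name", sort=False):
        summaries = {}
        conc: dict[str, float] = {}
        for i, row in grp.iterrows():
            iso = str(row["isotope"])
            if iso not in ISOTOPES:
                raise ValidationError(
                    f"{path}: line {_line(i)}: unknown isotope {iso!r}"
                )
            sd = None if pd.isna(row["sd"]) else float(row["sd"])
            try:
                summaries[iso] = IsotopeSummary(
                    iso, float(row["mean"]), sd, int(row["n"])
                )
            except (ValidationError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: line {_line(i)}: {exc}"
                ) from exc
            if "concentration" in grp.columns and not pd.isna(
                row.get("concentration")
            ):
                conc[iso] = float(row["concentration"])
        try:
            pools.append(
                SourcePool(
                    name=str(name),
                    summaries=summaries,
                    concentration=conc or None,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: source {name!r}: {exc}") from exc
    return pools


def write_sources(pools: Sequence[SourcePool], path) -> None:
    rows = []
    for p in pools:
        for iso in ISOTOPES:
            s = p.summaries[iso]
            rows.append(
                {
                    "name": p.name,
                    "isotope": iso,
                    "mean": s.mean,
                    "sd": s.sd,
                    "n": s.n,
                    "concentration": (
                        p.concentration[iso] if p.concentration else None
                    ),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_consumers(path) -> list[ConsumerObservation]:
    df = _read_csv(path, ["id", "taxon", "guild", "d13c", "d15n"])
    out = []
    for i, row in df.iterrows():
        site = row.get("site")
        dist = row.get("distance_m")
        try:
            out.append(
                ConsumerObservation(
                    id=str(row["id"]),
                    taxon=str(row["taxon"]),
                    guild=str(row["guild"]),
                    d13c=float(row["d13c"]),
                    d15n=float(row["d15n"]),
                    site=None if pd.isna(site) else str(site),
                    distance_m=None if dist is None or pd.isna(dist) else float(dist),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {_line(i)}: {exc}") from exc
    return out


def write_consumers(consumers: Sequence[ConsumerObservation], path) -> None:
    pd.DataFrame(
        [
            {
                "id": c.id,
                "taxon": c.taxon,
                "guild": c.guild,
                "d13c": c.d13c,
                "d15n": c.d15n,
                "site": c.site,
                "distance_m": c.distance_m,
            }
            for c in consumers
        ]
    ).to_csv(path, index=False)


def read_tdf_registry(path) -> dict[str, TDFSet]:
    df = _read_csv(path, ["guild", "isotope", "mean", "sd"])
    registry = {}
    for guild, grp in df.groupby("guild", sort=False):
        means = {}
        sds = {}
        for i, row in grp.iterrows():
            iso = str(row["isotope"])
            if iso not in ISOTOPES:
                raise ValidationError(
                    f"{path}: line {_line(i)}: unknown isotope {iso!r}"
                )
            means[iso] = float(row["mean"])
            sds[iso] = float(row["sd"])
        try:
            registry[str(guild)] = TDFSet(guild=str(guild), means=means, sds=sds)
        except ValidationError as exc:
            raise ValidationError(f"{path}: guild {guild!r}: {exc}") from exc
    return registry


def write_tdf_registry(registry: Mapping[str, TDFSet], path) -> None:
    rows = []
    for guild, tdf in registry.items():
        for iso in ISOTOPES:
            rows.append(
                {"guild": guild, "isotope": iso, "mean": tdf.mean(iso), "sd": tdf.sd(iso)}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_aa_replicates(path) -> list[AAReplicates]:
    """Group replicate rows by organism into Glu/Phe replicate sets."""
    df = _read_csv(path, ["organism", "amino_acid", "d15n"])
    out = []
    for organism, grp in df.groupby("organism", sort=False):
        glu = grp.loc[grp["amino_acid"] == "Glu", "d15n"].astype(float).tolist()
        phe = grp.loc[grp["amino_acid"] == "Phe", "d15n"].astype(float).tolist()
        if not glu or not phe:
            raise ValidationError(
                f"{path}: organism {organism!r} needs both Glu and Phe rows"
            )
        out.append(
            AAReplicates(
                organism=str(organism), trophic_values=glu, source_values=phe
            )
        )
    return out


def read_diet(path) -> list[DietComponent]:
    df = _read_csv(path, ["source", "d13c", "d15n", "weight"])
    return [
        DietComponent(
            name=str(r["source"]),
            d13c=float(r["d13c"]),
            d15n=float(r["d15n"]),
            weight=float(r["weight"]),
        )
        for _, r in df.iterrows()
    ]


def write_mixing_summary(rows: pd.DataFrame, path) -> None:
    rows.to_csv(path, index=False)
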