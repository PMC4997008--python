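"""Fossil first-occurrence (FO) tables and per-dataset covariate metrics.

Ages increase into the past: the Recent is 0 and larger values are older.
Ages may be expressed either in unit stratigraphic intervals (the default
scale is the 77 series-and-stages coding, 0 = Recent .. 76 = oldest) or in
millions of years; every downstream index is scale-covariant, so the choice
only affects the units tag carried on reported gap sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StratScale",
    "FOTable",
    "FOTableError",
    "CovariateRecord",
    "read_fo_table",
    "center_of_gravity",
    "gap_variability",
    "dataset_covariates",
]


class FOTableError(ValueError):
    """Invalid first-occurrence table."""


@dataclass(frozen=True)
class StratScale:
    """A stratigraphic age scale.

    ``unit`` is ``"interval"`` for unit-length stage/series codes (in which
    case gap sums are reported as MIGu) or ``"Ma"`` for ages in millions of
    years.  Interval codes are ordered integers, 0 = Recent, larger = older.
    """

    unit: str = "interval"
    codes: tuple[int, ...] = tuple(range(77))
    names: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.unit not in ("interval", "Ma"):
            raise ValueError("unit must be 'interval' or 'Ma'")
        if list(self.codes) != sorted(set(self.codes)):
            raise ValueError("interval codes must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, unit: str = "interval") -> "StratScale":
        """Read a sidecar scale file with columns ``code,name[,age]``."""
        df = pd.read_csv(path)
        codes = tuple(int(c) for c in df["code"])
        names = dict(zip(codes, df["name"].astype(str))) if "name" in df else None
        return cls(unit=unit, codes=codes, names=names)


_BOOL_MAP = {
    "1": True, "0": False, "true": True, "false": False,
    "t": True, "f": False, "yes": True, "no": False, "y": True, "n": False,
}


def _as_bool(value, default: bool) -> bool:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return default
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    key = str(value).strip().lower()
    if key in _BOOL_MAP:
        return _BOOL_MAP[key]
    raise FOTableError(f"cannot interpret {value!r} as a boolean")


class FOTable:
    """Per-taxon first-occurrence ages with optional record metadata.

    Backed by a :class:`pandas.DataFrame` indexed by taxon label with columns
    ``fo`` (age before present), and optional ``lo`` (last occurrence),
    ``extant``, ``has_fossil``, ``rank`` (ordinal code 1-6) and ``group``.
    """

    def __init__(self, data: pd.DataFrame, scale: StratScale | None = None) -> None:
        self.scale = scale or StratScale()
        df = data.copy()
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise FOTableError(f"duplicate taxon labels: {dups}")
        if "fo" not in df.columns:
            raise FOTableError("missing required column 'fo'")
        df["fo"] = pd.to_numeric(df["fo"], errors="raise").astype(float)
        if "lo" in df.columns:
            df["lo"] = pd.to_numeric(df["lo"], errors="raise").astype(float)
            bad = df.index[df["fo"] < df["lo"]]
            if len(bad):
                raise FOTableError(
                    f"last occurrence older than first occurrence for: {list(bad)}"
                )
        if "extant" not in df.columns:
            if "lo" in df.columns:
                df["extant"] = df["lo"] == 0
            else:
                df["extant"] = False
        else:
            default = df["lo"] == 0 if "lo" in df.columns else False
            df["extant"] = df["extant"].where(df["extant"].notna(), default)
        df["extant"] = df["extant"].astype(bool)
        if "has_fossil" not in df.columns:
            df["has_fossil"] = True
        else:
            df["has_fossil"] = df["has_fossil"].where(
                df["has_fossil"].notna(), True
            ).astype(bool)
        no_fossil_old = df.index[(~df["has_fossil"]) & (df["fo"] != 0)]
        if len(no_fossil_old):
            raise FOTableError(
                "taxa flagged has_fossil=false must carry the Recent (0) "
                f"placeholder FO: {list(no_fossil_old)}"
            )
        self.data = df

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_ages(
        cls, ages: Mapping[str, float], scale: StratScale | None = None, **columns
    ) -> "FOTable":
        df = pd.DataFrame({"fo": pd.Series(dict(ages), dtype=float)})
        for name, values in columns.items():
            df[name] = pd.Series(values)
        return cls(df, scale=scale)

    # -- accessors ---------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def __contains__(self, label: str) -> bool:
        return label in self.data.index

    def age_of(self, label: str) -> float:
        try:
            return float(self.data.at[label, "fo"])
        except KeyError:
            raise FOTableError(f"no FO age for taxon {label!r}") from None

    def ages_for(self, labels: Sequence[str]) -> np.ndarray:
        missing = [x for x in labels if x not in self.data.index]
        if missing:
            raise FOTableError(f"no FO age for taxa: {missing}")
        return self.data["fo"].reindex(labels).to_numpy(dtype=float)

    @property
    def fo_ages(self) -> np.ndarray:
        return self.data["fo"].to_numpy(dtype=float)

    @property
    def fo_oldest(self) -> float:
        return float(self.data["fo"].max())

    @property
    def fo_youngest(self) -> float:
        return float(self.data["fo"].min())

    def subset(self, labels: Sequence[str]) -> "FOTable":
        missing = [x for x in labels if x not in self.data.index]
        if missing:
            raise FOTableError(f"no FO age for taxa: {missing}")
        return FOTable(self.data.loc[list(labels)], scale=self.scale)


def read_fo_table(path: str | Path, scale: StratScale | None = None) -> FOTable:
    """Read a delimited FO table (CSV or TSV, sniffed) into an :class:`FOTable`.

    Required columns: ``taxon``, ``fo``.  Optional: ``lo``, ``extant``,
    ``has_fossil``, ``rank``, ``group``.  Booleans default to
    extant = (lo == 0) when ``lo`` is given, and has_fossil = true.
    Errors carry the 1-based data row number.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, skipinitialspace=True)
    raw.columns = [str(c).strip().lower() for c in raw.columns]
    for required in ("taxon", "fo"):
        if required not in raw.columns:
            raise FOTableError(f"missing required column {required!r} in {path}")

    records: dict[str, dict] = {}
    for pos, row in enumerate(raw.itertuples(index=False), start=1):
        rec = dict(zip(raw.columns, row))
        label = str(rec["taxon"]).strip()
        if not label or label.lower() == "nan":
            raise FOTableError(f"row {pos}: empty taxon label")
        if label in records:
            raise FOTableError(f"row {pos}: duplicate taxon label {label!r}")
        try:
            fo = float(rec["fo"])
        except (TypeError, ValueError):
            raise FOTableError(
                f"row {pos}: non-numeric FO age {rec['fo']!r} for {label!r}"
            ) from None
        out: dict = {"fo": fo}
        if "lo" in raw.columns and not _is_blank(rec.get("lo")):
            try:
                out["lo"] = float(rec["lo"])
            except (TypeError, ValueError):
                raise FOTableError(
                    f"row {pos}: non-numeric LO age {rec['lo']!r} for {label!r}"
                ) from None
            if fo < out["lo"]:
                raise FOTableError(
                    f"row {pos}: LO ({out['lo']}) older than FO ({fo}) for {label!r}"
                )
        if "extant" in raw.columns and not _is_blank(rec.get("extant")):
            out["extant"] = _as_bool(rec["extant"], default=False)
        if "has_fossil" in raw.columns and not _is_blank(rec.get("has_fossil")):
            out["has_fossil"] = _as_bool(rec["has_fossil"], default=True)
        if "rank" in raw.columns and not _is_blank(rec.get("rank")):
            out["rank"] = float(rec["rank"])
        if "group" in raw.columns and not _is_blank(rec.get("group")):
            out["group"] = str(rec["group"]).strip()
        records[label] = out

    df = pd.DataFrame.from_dict(records, orient="index")
    return FOTable(df, scale=scale)


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() == ""


# -- covariate metrics ------------------------------------------------------


def center_of_gravity(
    fo: FOTable | Sequence[float], include_extant_only: bool = True
) -> tuple[float, float | None]:
    """Occurrence-weighted mean FO age (CG) and its rescaled form.

    CG = sum(N_i t_i) / sum(N_i) over intervals i (equivalently the mean of
    the per-taxon FO ages); CGscaled = (FOoldest - CG) / (FOoldest -
    FOyoungest).  CGscaled > 0.5 indicates FO dates crowded toward the
    youngest terminal (top-heavy), < 0.5 bottom-heavy.  When all FOs are
    equal the rescaling is undefined and ``None`` is returned in its place.

    ``include_extant_only=False`` drops taxa with no fossil record (FO
    placeholder at the Recent) from the calculation.
    """
    ages = _fo_age_vector(fo, include_extant_only)
    if len(ages) < 2:
        raise FOTableError("center of gravity needs at least two taxa")
    cg = float(np.mean(ages))
    span = float(np.max(ages) - np.min(ages))
    if span == 0:
        return cg, None
    return cg, float((np.max(ages) - cg) / span)


def gap_variability(
    fo: FOTable | Sequence[float], ddof: int = 1, include_extant_only: bool = True
) -> float:
    """Standard deviation of successive FO gaps divided by the gap range.

    FOs are ordered in time and the differences between successive FOs are
    the gaps (ties contribute zero-length gaps, which are retained).  The
    statistic is scale-free: it measures regularity of spacing, not absolute
    gap size.  Sample sd (``ddof=1``) is the default; pass ``ddof=0`` for the
    population flavour.  When all gaps are equal (including a zero range) the
    variability is 0 by definition.
    """
    ages = _fo_age_vector(fo, include_extant_only)
    if len(ages) < 3:
        raise FOTableError("gap variability needs at least three taxa (two gaps)")
    ordered = np.sort(ages)[::-1]
    gaps = -np.diff(ordered)
    rng = float(gaps.max() - gaps.min())
    # equal gaps mean zero variability; tolerate float drift from
    # arithmetically spaced ages (e.g. linspace output)
    if rng <= 1e-9 * max(1.0, float(np.abs(gaps).max())):
        return 0.0
    return float(np.std(gaps, ddof=ddof) / rng)


def _fo_age_vector(fo, include_extant_only: bool) -> np.ndarray:
    if isinstance(fo, FOTable):
        if include_extant_only:
            return fo.fo_ages
        mask = fo.data["has_fossil"].to_numpy(dtype=bool)
        return fo.fo_ages[mask]
    return np.asarray(list(fo), dtype=float)


@dataclass
class CovariateRecord:
    """The per-dataset covariates used alongside the congruence indices."""

    n_taxa: int
    colless_ic: float | None
    percent_resolution: float
    mean_fo_age: float
    fo_range: float
    cg: float
    cg_scaled: float | None
    gap_variability: float | None
    percent_extant: float
    percent_no_fossil: float
    median_rank: int | None = None
    group: str | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_taxa": self.n_taxa,
            "colless_ic": self.colless_ic,
            "percent_resolution": self.percent_resolution,
            "mean_fo_age": self.mean_fo_age,
            "fo_range": self.fo_range,
            "cg": self.cg,
            "cg_scaled": self.cg_scaled,
            "gap_variability": self.gap_variability,
            "percent_extant": self.percent_extant,
            "percent_no_fossil": self.percent_no_fossil,
            "median_rank": self.median_rank,
            "group": self.group,
            "flags": ";".join(self.flags),
        }


def dataset_covariates(tree, fo: FOTable) -> CovariateRecord:
    """Assemble the tree-shape and FO-distribution covariates in one record.

    The Colless index is reported only for binary trees (``None`` otherwise,
    flagged); the rank is the median of per-tip ordinal rank codes, rounded
    half-up to the nearer integer code.
    """
    from . import trees as _trees  # local import to avoid a cycle

    labels = tree.tip_labels
    table = fo.subset(labels)
    n = len(labels)
    flags: list[str] = []

    if tree.is_binary and n >= 3:
        ic: float | None = _trees.colless_index(tree)
    else:
        ic = None
        flags.append("colless_undefined")

    cg, cg_scaled = center_of_gravity(table)
    if cg_scaled is None:
        flags.append("cg_scaled_undefined")
    if n >= 3:
        gv: float | None = gap_variability(table)
    else:
        gv = None
        flags.append("gap_variability_undefined")

    extant = table.data["extant"].to_numpy(dtype=bool)
    no_fossil = ~table.data["has_fossil"].to_numpy(dtype=bool)

    median_rank: int | None = None
    if "rank" in table.data.columns and table.data["rank"].notna().any():
        med = float(table.data["rank"].dropna().median())
        median_rank = int(math.floor(med + 0.5))

    group = None
    if "group" in table.data.columns:
        groups = table.data["group"].dropna().unique()
        if len(groups) == 1:
            group = str(groups[0])
        elif len(groups) > 1:
            group = str(groups[0])
            flags.append("mixed_groups")

    return CovariateRecord(
        n_taxa=n,
        colless_ic=ic,
        percent_resolution=_trees.percent_resolution(tree) if n >= 3 else 100.0,
        mean_fo_age=float(np.mean(table.fo_ages)),
        fo_range=float(table.fo_oldest - table.fo_youngest),
        cg=cg,
        cg_scaled=cg_scaled,
        gap_variability=gv,
        percent_extant=float(extant.mean() * 100.0),
        percent_no_fossil=float(no_fossil.mean() * 100.0),
        median_rank=median_rank,
        group=group,
        flags=flags,
    )
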