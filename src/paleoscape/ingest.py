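"""Reading and screening of geolocated collagen δ15N records.

Records arrive as CSV/XLSX tables of dated, geolocated herbivore collagen
δ15N measurements with quality metadata (C/N atomic ratio, taxon certainty,
age class, skeletal element, duplicate keys).  Screening applies, in a
fixed order, the exclusion rules used when compiling continental-scale
collagen datasets: collagen-quality C/N bounds, uncertain taxonomy,
juveniles, seasonally biased cervid antler/tooth samples, duplicate
analyses, and the geographic study window.  The order is fixed so per-rule
tallies are reproducible; a record failing several rules is logged under
the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MANDATORY_COLUMNS",
    "CANONICAL_COLUMNS",
    "ScreeningConfig",
    "ScreenedDataset",
    "read_samples",
    "screen_samples",
    "summarize_dataset",
]

#: Columns that must be present (after column mapping).
MANDATORY_COLUMNS = ("sample_id", "latitude", "longitude", "taxon", "d15N")

#: Full canonical schema; optional columns are filled with missing values.
CANONICAL_COLUMNS = (
    "sample_id",
    "site_id",
    "latitude",
    "longitude",
    "taxon",
    "element",
    "age_class",
    "d15N",
    "cn_atomic",
    "cn_unreliable",
    "taxon_certain",
    "duplicate_group",
    "dating_basis",
    "c14_age",
    "c14_error",
    "context_age_bin",
    "context_secure",
    "source_flag",
)

_NUMERIC = ("latitude", "longitude", "d15N", "cn_atomic", "c14_age", "c14_error")
_BOOLEAN = ("cn_unreliable", "taxon_certain", "context_secure")
_BOOL_DEFAULT = {"cn_unreliable": False, "taxon_certain": True, "context_secure": True}


@dataclass(frozen=True)
class ScreeningConfig:
    """Exclusion-rule parameters.

    Defaults follow the compilation conventions for late Pleistocene /
    early Holocene European ungulate collagen: well-preserved collagen has
    C/N atomic ratio in [2.9, 3.6]; the study window is 35–60°N, 10°W–30°E;
    antler and tooth samples from cervids are excluded to limit seasonal
    biasing.
    """

    cn_min: float = 2.9
    cn_max: float = 3.6
    lat_window: tuple[float, float] = (35.0, 60.0)
    lon_window: tuple[float, float] = (-10.0, 30.0)
    cervid_taxa: frozenset[str] = frozenset(
        {
            "Alces alces",
            "Capreolus capreolus",
            "Cervus elaphus",
            "Megaloceros giganticus",
            "Rangifer tarandus",
            "Rupicapra rupicapra",
        }
    )
    excluded_elements_for_cervids: frozenset[str] = frozenset({"antler", "tooth"})

    def __post_init__(self) -> None:
        if not self.cn_min < self.cn_max:
            raise ValueError("cn_min must be < cn_max")
        if not (self.lat_window[0] < self.lat_window[1] and self.lon_window[0] < self.lon_window[1]):
            raise ValueError("lat/lon windows must be ordered (min, max)")


#: Rule names in application order.
SCREENING_RULES = (
    "cn_ratio",
    "taxon_uncertain",
    "juvenile",
    "cervid_antler_tooth",
    "duplicate",
    "outside_window",
)


@dataclass
class ScreenedDataset:
    """Retained samples plus a per-rule exclusion log.

    ``samples`` is the retained table (canonical schema, original row
    numbers preserved); ``exclusion_counts`` maps rule name to count;
    ``exclusion_reasons`` lists every excluded row with the first rule it
    failed.  Counts always sum to input minus retained.
    """

    samples: pd.DataFrame
    exclusion_counts: dict[str, int] = field(default_factory=dict)
    exclusion_reasons: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_retained(self) -> int:
        return len(self.samples)

    @property
    def n_excluded(self) -> int:
        return int(sum(self.exclusion_counts.values()))


def _parse_bool(v):
    """Lenient truthiness for spreadsheet booleans; NaN stays missing."""
    if isinstance(v, str):
        s = v.strip().lower()
        if s in {"true", "t", "yes", "y", "1"}:
            return True
        if s in {"false", "f", "no", "n", "0"}:
            return False
        return np.nan
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    return bool(v)


def read_samples(
    path: str | Path,
    fmt: str | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read an isotope sample table into the canonical schema.

    Parameters
    ----------
    path : path to a CSV (UTF-8, header row) or XLSX file.
    fmt : "csv" or "xlsx"; inferred from the suffix when None.
    column_map : mapping of canonical name -> source column name for files
        whose headers differ from the canonical schema.

    Missing optional fields are kept missing (NaN / <NA>), never zeroed.
    The original row number is preserved in ``row_number`` for the
    exclusion log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
    if fmt == "xlsx":
        raw = pd.read_excel(path)
    elif fmt == "csv":
        raw = pd.read_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")

    column_map = column_map or {}
    out = pd.DataFrame(index=raw.index)
    for canon in CANONICAL_COLUMNS:
        src = column_map.get(canon, canon)
        if src in raw.columns:
            out[canon] = raw[src]
        else:
            out[canon] = np.nan
    missing = [c for c in MANDATORY_COLUMNS if column_map.get(c, c) not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    for c in _NUMERIC:
        out[c] = pd.to_numeric(out[c], errors="coerce")
    for c in _BOOLEAN:
        out[c] = np.array(
            [_BOOL_DEFAULT[c] if pd.isna(b) else bool(b) for b in out[c].map(_parse_bool)],
            dtype=bool,
        )
    out["dating_basis"] = out["dating_basis"].fillna("direct")
    out["row_number"] = np.arange(len(out))

    bad_lat = out["latitude"].notna() & ~out["latitude"].between(-90, 90)
    bad_lon = out["longitude"].notna() & ~out["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        raise ValueError("latitude/longitude outside valid geographic range")
    return out


def screen_samples(samples: pd.DataFrame, config: ScreeningConfig | None = None) -> ScreenedDataset:
    """Apply the exclusion rules in fixed order and log every exclusion.

    Rules, in order: (1) C/N atomic ratio outside [cn_min, cn_max], missing,
    or flagged unreliable; (2) uncertain taxonomic identification;
    (3) juvenile age class; (4) cervid antler/tooth; (5) duplicate analyses
    of one individual (first occurrence kept, in file order); (6) outside
    the geographic study window.  Screening never fails; it logs.
    """
    config = config or ScreeningConfig()
    df = samples.copy()
    if "row_number" not in df.columns:
        df["row_number"] = np.arange(len(df))

    reason = pd.Series("", index=df.index, dtype=object)

    cn = df["cn_atomic"]
    bad = cn.isna() | (cn < config.cn_min) | (cn > config.cn_max) | df["cn_unreliable"].fillna(False).astype(bool)
    reason[bad & (reason == "")] = "cn_ratio"

    bad = ~df["taxon_certain"].fillna(True).astype(bool)
    reason[bad & (reason == "")] = "taxon_uncertain"

    bad = df["age_class"].astype(str).str.lower() == "juvenile"
    reason[bad & (reason == "")] = "juvenile"

    is_cervid = df["taxon"].isin(config.cervid_taxa)
    bad = is_cervid & df["element"].astype(str).str.lower().isin(config.excluded_elements_for_cervids)
    reason[bad & (reason == "")] = "cervid_antler_tooth"

    # duplicates are resolved among rows surviving rules 1-4, keeping the
    # first occurrence in file order
    alive = reason == ""
    dup_keyed = alive & df["duplicate_group"].notna() & (df["duplicate_group"].astype(str) != "")
    dups = df.loc[dup_keyed].sort_values("row_number").duplicated(subset="duplicate_group", keep="first")
    reason[dups[dups].index] = "duplicate"

    in_window = (
        df["latitude"].between(*config.lat_window)
        & df["longitude"].between(*config.lon_window)
    )
    reason[~in_window & (reason == "")] = "outside_window"

    retained = df[reason == ""].copy()
    excluded = df[reason != ""]
    counts = {r: int((reason == r).sum()) for r in SCREENING_RULES}
    reasons = pd.DataFrame(
        {
            "row_number": excluded["row_number"].to_numpy(),
            "sample_id": excluded["sample_id"].to_numpy(),
            "rule": reason[reason != ""].to_numpy(),
        }
    )
    return ScreenedDataset(samples=retained, exclusion_counts=counts, exclusion_reasons=reasons)


def summarize_dataset(samples: pd.DataFrame, by_bin: bool = True) -> dict:
    """Descriptive statistics of δ15N: overall, per bin, and per taxon.

    SD uses the n−1 denominator and is reported missing for n = 1.  Taxon
    percentages are rounded to the nearest integer percent.
    """
    if len(samples) == 0:
        raise ValueError("empty dataset")

    def _stats(x: pd.Series) -> dict:
        x = x.dropna()
        return {
            "n": int(len(x)),
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if len(x) > 1 else None,
            "min": float(x.min()),
            "max": float(x.max()),
        }

    out: dict = {"overall": _stats(samples["d15N"])}
    if by_bin and "bin" in samples.columns:
        out["by_bin"] = {
            name: _stats(g["d15N"]) for name, g in samples.groupby("bin", sort=True)
        }
    counts = samples["taxon"].value_counts()
    out["by_taxon"] = {
        str(t): {"n": int(c), "percent": int(round(100.0 * c / len(samples)))}
        for t, c in counts.items()
    }
    return out
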