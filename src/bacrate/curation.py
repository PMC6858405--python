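"""Loading, filtering and aggregation of accumulation-rate and trait tables.

Rate tables hold one row per literature-style estimate (species, rate in
substitutions/site/year, sampling time in years, site class, hypermutator
flag, study id).  Trait tables hold one row per species with genomic and
life-history covariates.  Curation applies three exclusion rules — sampling
time at most 1500 years, all-sites estimates only, no hypermutator strains —
then averages the surviving estimates per species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RATE_COLUMNS",
    "TRAIT_COLUMNS",
    "load_rate_table",
    "load_trait_table",
    "write_rate_table",
    "write_trait_table",
    "filter_estimates",
    "average_by_species",
    "log_transform",
    "fold_range",
]

#: mandatory columns of a per-estimate rate table
RATE_COLUMNS = ["species", "rate", "sampling_time", "site_class", "hypermutator", "study"]

#: mandatory columns of a per-species trait table
TRAIT_COLUMNS = ["species", "genome_size", "gc"]

#: optional, recognised trait columns (extras are preserved untouched)
OPTIONAL_TRAIT_COLUMNS = [
    "pin_pis",
    "lab_dt",
    "rrn_copies",
    "trna_count",
    "lifestyle",
    "mutation_rate",
]

SITE_CLASSES = {"all", "synonymous"}

DEFAULT_MAX_SAMPLING_TIME = 1500.0  # years


@dataclass
class ExclusionRecord:
    """One excluded estimate and the rule that removed it."""

    index: int
    species: str
    reason: str


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing mandatory column(s): {missing}")


def load_rate_table(path) -> pd.DataFrame:
    """Read a per-estimate rate CSV; validates types and value domains."""
    df = pd.read_csv(path)
    return validate_rate_table(df)


def validate_rate_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, RATE_COLUMNS, "rate table")
    df = df.copy()
    for col in ("rate", "sampling_time"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index.tolist()
            raise ValueError(f"non-numeric {col!r} in rows {bad}") from exc
        if (df[col] <= 0).any():
            bad = df.index[df[col] <= 0].tolist()
            raise ValueError(f"{col!r} must be > 0; offending rows {bad}")
    unknown = set(df["site_class"]) - SITE_CLASSES
    if unknown:
        raise ValueError(f"unknown site_class values: {sorted(unknown)}")
    df["hypermutator"] = df["hypermutator"].astype(bool)
    return df


def load_trait_table(path) -> pd.DataFrame:
    """Read a per-species trait CSV; validates ranges, keeps extras opaque."""
    df = pd.read_csv(path)
    _require_columns(df, TRAIT_COLUMNS, "trait table")
    df = df.copy()
    if (pd.to_numeric(df["genome_size"]) <= 0).any():
        raise ValueError("genome_size must be > 0 (Mb)")
    gc = pd.to_numeric(df["gc"])
    if ((gc <= 0) | (gc >= 100)).any():
        raise ValueError("gc must lie in (0, 100) percent")
    if "pin_pis" in df.columns and (pd.to_numeric(df["pin_pis"]) < 0).any():
        raise ValueError("pin_pis must be >= 0")
    if df["species"].duplicated().any():
        dups = df["species"][df["species"].duplicated()].tolist()
        raise ValueError(f"duplicate species in trait table: {dups}")
    return df


def write_rate_table(df: pd.DataFrame, path) -> None:
    validate_rate_table(df).to_csv(path, index=False)


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def filter_estimates(
    df: pd.DataFrame, max_sampling_time: float = DEFAULT_MAX_SAMPLING_TIME
) -> tuple[pd.DataFrame, list[ExclusionRecord]]:
    """Apply the three curation rules; returns (kept, audit log).

    Keeps estimates with sampling time <= ``max_sampling_time`` years
    (inclusive), all-sites rates only, and non-hypermutator strains.  Row
    order is preserved and every exclusion is recorded with its reason.
    """
    _require_columns(df, RATE_COLUMNS, "rate table")
    audit: list[ExclusionRecord] = []
    keep = np.ones(len(df), dtype=bool)
    for pos, (idx, row) in enumerate(df.iterrows()):
        if row["sampling_time"] > max_sampling_time:
            reason = f"sampling_time {row['sampling_time']} > {max_sampling_time} years"
        elif row["site_class"] != "all":
            reason = f"site_class {row['site_class']!r} (synonymous-only estimate)"
        elif bool(row["hypermutator"]):
            reason = "hypermutator strain"
        else:
            continue
        keep[pos] = False
        audit.append(ExclusionRecord(index=idx, species=row["species"], reason=reason))
    return df.loc[keep].copy(), audit


def average_by_species(df: pd.DataFrame, method: str = "arithmetic") -> pd.DataFrame:
    """Per-species mean accumulation rate from (filtered) estimates.

    ``method`` is ``"arithmetic"`` (mean of raw rates, the default) or
    ``"geometric"``.  Returns one row per species with ``mean_rate``,
    ``log_rate`` (log10) and ``n_estimates``.
    """
    if method not in ("arithmetic", "geometric"):
        raise ValueError("method must be 'arithmetic' or 'geometric'")
    grouped = df.groupby("species", sort=True)["rate"]
    if method == "arithmetic":
        mean = grouped.mean()
    else:
        mean = np.exp(grouped.apply(lambda r: np.log(r).mean()))
    out = pd.DataFrame(
        {
            "species": mean.index,
            "mean_rate": mean.to_numpy(),
            "n_estimates": grouped.size().to_numpy(),
        }
    ).reset_index(drop=True)
    out["log_rate"] = log_transform(out["mean_rate"].to_numpy())
    return out


def log_transform(rates) -> np.ndarray:
    """Base-10 logarithm of positive rates."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0 for log transformation")
    return np.log10(rates)


def fold_range(rates) -> float:
    """Ratio of the largest to the smallest rate (1.0 for a singleton)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("fold_range of an empty set is undefined")
    if np.any(rates <= 0):
        raise ValueError("rates must be > 0")
    return float(rates.max() / rates.min())
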