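"""Variable constructions for registry analyses.

Population-referenced decile ranks, stratum-wise PGI standardization,
dominance-principle parental education and the pooled median split.  All
operations take and return pandas objects; decile references serialize to
JSON so a registry can be ranked against an external reference population.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DecileReference",
    "build_decile_reference",
    "decile_rank",
    "decile_rank_frame",
    "standardize_pgi",
    "parental_dominance",
    "median_split",
]


@dataclass
class DecileReference:
    """Per-group interior decile boundaries (9 values per group).

    Groups are keyed by tuples, e.g. ``(birth_year, sex)``.  Boundaries are
    the 10th..90th empirical percentiles of the reference population under
    linear (NumPy default, "type 7") interpolation.
    """

    boundaries: dict[tuple, np.ndarray] = field(default_factory=dict)
    by: tuple[str, ...] = ("birth_year", "sex")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "by": list(self.by),
            "boundaries": {
                "|".join(map(str, k)): list(map(float, v))
                for k, v in self.boundaries.items()
            },
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "DecileReference":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        bounds = {}
        for key, vals in payload["boundaries"].items():
            parts = key.split("|")
            parts = tuple(int(p) if p.lstrip("-").isdigit() else p for p in parts)
            bounds[parts] = np.asarray(vals, dtype=float)
        return cls(boundaries=bounds, by=tuple(payload["by"]))


def build_decile_reference(
    reference: pd.DataFrame,
    value_col: str = "edu_years",
    by: tuple[str, ...] = ("birth_year", "sex"),
    min_group: int = 10,
) -> DecileReference:
    """Compute per-group interior decile boundaries from a reference
    population.

    Each group must contribute at least ``min_group`` non-missing values;
    an undersized group raises with the offending key named.
    """
    ref = DecileReference(by=by)
    for key, grp in reference.groupby(list(by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp[value_col].dropna().to_numpy()
        if len(vals) < min_group:
            raise ValueError(
                f"group {key} has {len(vals)} values; need >= {min_group} "
                "to estimate decile boundaries"
            )
        ref.boundaries[key] = np.percentile(vals, np.arange(10, 100, 10))
    return ref


def decile_rank(value: float, group: tuple, ref: DecileReference) -> float:
    """Decile (1..10) of ``value`` within its reference group.

    The decile is 1 + the number of boundaries strictly below the value, so
    a value tied with a boundary falls in the lower decile.  Missing values
    yield a missing decile; an unknown group raises.
    """
    if group not in ref.boundaries:
        raise KeyError(f"no decile reference for group {group}")
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    return 1.0 + float(np.sum(ref.boundaries[group] < value))


def decile_rank_frame(
    df: pd.DataFrame,
    ref: DecileReference,
    value_col: str,
    by: tuple[str, ...] = ("birth_year", "sex"),
) -> pd.Series:
    """Vectorised :func:`decile_rank` over a frame."""
    out = np.full(len(df), np.nan)
    for key, grp in df.groupby(list(by), observed=True):
        key = key if isinstance(key, tuple) else (key,)
        if key not in ref.boundaries:
            raise KeyError(f"no decile reference for group {key}")
        vals = grp[value_col].to_numpy(dtype=float)
        ranks = 1.0 + np.searchsorted(ref.boundaries[key], vals, side="left")
        ranks[np.isnan(vals)] = np.nan
        out[grp.index.to_numpy()] = ranks
    return pd.Series(out, index=df.index, name=f"{value_col}_decile")


def standardize_pgi(
    df: pd.DataFrame,
    col: str = "pgi",
    strata: tuple[str, ...] = ("birth_year", "batch"),
    out_col: str | None = None,
    singleton_policy: str = "merge",
) -> pd.DataFrame:
    """Standardize the PGI to mean 0, SD 1 (ddof=1) within each stratum.

    Standardizing within birth year × genotyping batch removes additive
    batch offsets (and any birth-year level shift) by construction.
    Strata with fewer than 2 non-missing values are handled per
    ``singleton_policy``: ``"merge"`` pools the stratum with the nearest
    birth year in the same batch; ``"drop"`` sets the PGI missing.  Either
    path warns.
    """
    if singleton_policy not in ("merge", "drop"):
        raise ValueError("singleton_policy must be 'merge' or 'drop'")
    out = df.copy()
    out_col = out_col or col
    key = df[list(strata)].apply(tuple, axis=1)
    counts = key.map(key.value_counts())
    small = counts < 2
    if small.any():
        warnings.warn(
            f"{int(small.sum())} record(s) in singleton {strata} strata; "
            f"policy={singleton_policy}", RuntimeWarning,
        )
        if singleton_policy == "merge" and "birth_year" in strata:
            # pool with the nearest year in the same batch
            other = [s for s in strata if s != "birth_year"]
            adj_year = df["birth_year"].copy()
            ok_keys = set(key[~small])
            for idx in df.index[small]:
                yr = df.at[idx, "birth_year"]
                rest = tuple(df.at[idx, s] for s in other)
                candidates = sorted(
                    (abs(k[strata.index("birth_year")] - yr), k)
                    for k in ok_keys
                    if tuple(k[strata.index(s)] for s in other) == rest
                )
                if candidates:
                    adj_year.at[idx] = candidates[0][1][strata.index("birth_year")]
            tmp = df.assign(birth_year=adj_year)
            key = tmp[list(strata)].apply(tuple, axis=1)
            counts = key.map(key.value_counts())
            small = counts < 2

    grouped = out[col].groupby(key)
    z = (out[col] - grouped.transform("mean")) / grouped.transform("std")
    z[small] = np.nan
    out[out_col] = z
    return out


def parental_dominance(mother_edu, father_edu):
    """Household education as the higher of the two parents' levels.

    Missing values are ignored; both missing gives missing.  Symmetric in
    its arguments.  Accepts scalars or aligned Series.
    """
    if np.isscalar(mother_edu) or mother_edu is None:
        vals = [v for v in (mother_edu, father_edu)
                if v is not None and not (isinstance(v, float) and np.isnan(v))]
        return max(vals) if vals else np.nan
    return pd.concat([pd.Series(mother_edu), pd.Series(father_edu)], axis=1).max(axis=1)


def median_split(parent_edu: pd.Series) -> pd.Series:
    """Above-median indicator for parental education.

    The median is computed once on the non-missing values of the full
    analysis sample; values strictly above it are coded 1, ties at the
    median 0.  Missing stays missing.  All-missing input raises.
    """
    s = pd.Series(parent_edu, dtype=float)
    if s.notna().sum() == 0:
        raise ValueError("median_split: all parental-education values missing")
    med = s.median()
    out = (s > med).astype(float)
    out[s.isna()] = np.nan
    return out
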