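"""Measurement-table I/O and replicate grouping.

The on-disk dialect is a TSV with columns ``sample_id``, ``pool``,
``replicate``, ``time_days``, ``value``, ``value_type``, ``sd``.  Pools are
named ``CH4``, ``DIC``, ``MEOH``, ``LIPID:<moiety>`` or ``RNA``; values are
either ``delta_permil`` (per mil vs VPDB) or ``atom_fraction`` (F in
[0,1)).  All internal computation is in atom fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .isotope import delta_to_fraction, fraction_to_delta

COLUMNS = ["sample_id", "pool", "replicate", "time_days", "value",
           "value_type", "sd"]
VALUE_TYPES = {"delta_permil", "atom_fraction"}


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement TSV, validating columns and value types."""
    df = pd.read_csv(path, sep="\t")
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"measurement table missing columns: {sorted(missing)}")
    bad = set(df["value_type"].unique()) - VALUE_TYPES
    if bad:
        raise SchemaError(f"unknown value_type entries: {sorted(bad)}")
    return df[COLUMNS].copy()


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table in the same TSV dialect the reader accepts."""
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"measurement table missing columns: {sorted(missing)}")
    df[COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def _to_fraction(values: pd.Series, value_types: pd.Series) -> np.ndarray:
    out = np.empty(len(values), dtype=float)
    for i, (v, t) in enumerate(zip(values.to_numpy(), value_types.to_numpy())):
        out[i] = v if t == "atom_fraction" else delta_to_fraction(v)
    return out


@dataclass
class ReplicateSet:
    """Replicate atom-fraction measurements per pool at one time point.

    ``pools`` maps pool name to an array of per-replicate F values (n >= 1,
    same replicate structure for every pool).  ``pools_sd_delta`` optionally
    carries the reported per-measurement precision in delta space (per mil),
    the convention instruments quote; NaN means not reported.
    """

    key: str
    pools: dict[str, np.ndarray]
    harvest_time: float
    pools_sd_delta: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        for name, vals in self.pools.items():
            vals = np.asarray(vals, dtype=float)
            if vals.size < 1:
                raise SchemaError(f"pool {name!r}: need at least one replicate")
            self.pools[name] = vals
        if self.pools_sd_delta is not None:
            for name, vals in self.pools_sd_delta.items():
                self.pools_sd_delta[name] = np.asarray(vals, dtype=float)

    def sd_delta(self, pool: str) -> np.ndarray | None:
        """Reported measurement sd (per mil) per replicate, or None."""
        if self.pools_sd_delta is None or pool not in self.pools_sd_delta:
            return None
        vals = self.pools_sd_delta[pool]
        return None if np.any(~np.isfinite(vals)) else vals

    def mean(self, pool: str) -> float:
        return float(self.require(pool).mean())

    def sd(self, pool: str) -> float:
        vals = self.require(pool)
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    def require(self, pool: str) -> np.ndarray:
        if pool not in self.pools:
            raise SchemaError(
                f"replicate set {self.key!r} lacks pool {pool!r}; "
                f"has {sorted(self.pools)}"
            )
        return self.pools[pool]

    @property
    def lipid_moieties(self) -> list[str]:
        return sorted(p.split(":", 1)[1] for p in self.pools
                      if p.startswith("LIPID:"))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, sample_id: str | None = None,
                   time_days: float | None = None) -> "ReplicateSet":
        """Build a replicate set from measurement rows.

        Defaults to the latest time point (harvest) of the single sample in
        the frame; replicates are ordered by their ``replicate`` column.
        """
        sub = df
        if sample_id is not None:
            sub = sub[sub["sample_id"] == sample_id]
        if sub.empty:
            raise SchemaError(f"no rows for sample_id {sample_id!r}")
        ids = sub["sample_id"].unique()
        if len(ids) > 1:
            raise SchemaError(
                f"ambiguous sample_id: {sorted(ids)}; pass sample_id explicitly"
            )
        t = float(sub["time_days"].max()) if time_days is None else time_days
        at_t = sub[sub["time_days"] == t]
        if at_t.empty:
            raise SchemaError(f"no rows at time_days == {t}")
        pools: dict[str, np.ndarray] = {}
        sds: dict[str, np.ndarray] = {}
        for pool, grp in at_t.groupby("pool"):
            grp = grp.sort_values("replicate")
            pools[pool] = _to_fraction(grp["value"], grp["value_type"])
            # keep sd in delta space; atom_fraction rows carry no delta sd
            sd = grp["sd"].to_numpy(dtype=float)
            sd[grp["value_type"].to_numpy() != "delta_permil"] = np.nan
            sds[pool] = sd
        return cls(str(ids[0]), pools, t, sds)


def frame_from_fractions(sample_id: str, rows: list[dict]) -> pd.DataFrame:
    """Assemble a measurement frame from dicts with F values.

    Each row dict needs ``pool``, ``replicate``, ``time_days`` and
    ``fraction_13c``; values are exported in delta notation, the dialect
    instruments actually report.
    """
    recs = []
    for r in rows:
        recs.append({
            "sample_id": sample_id,
            "pool": r["pool"],
            "replicate": r["replicate"],
            "time_days": r["time_days"],
            "value": fraction_to_delta(r["fraction_13c"]),
            "value_type": "delta_permil",
            "sd": r.get("sd", np.nan),
        })
    return pd.DataFrame.from_records(recs, columns=COLUMNS)
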