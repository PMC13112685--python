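"""Draw matrices: the uncertainty currency of the pipeline.

Every estimated quantity (prevalence, PAF, attributable YLL rate) is carried
through the pipeline as a matrix of posterior/uncertainty draws, one row per
stratum and one column per draw.  Point estimates and intervals are only
taken at the very end, and any aggregation (over counties, sexes, ages, ...)
is performed draw-by-draw so that uncertainty propagates correctly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, SchemaError

#: Canonical stratum key columns, in canonical order.
STRATUM_KEYS = ["year", "county", "age_group", "sex", "race"]


@dataclass
class DrawMatrix:
    """A (keys x draws) array of one quantity.

    Parameters
    ----------
    keys : DataFrame with one row per key (e.g. stratum identifiers).
    values : array of shape (len(keys), n_draws); must be finite.
    name, units : metadata describing the quantity.
    draw_info : optional per-draw provenance (e.g. crosswalk set index).
    """

    keys: pd.DataFrame
    values: np.ndarray
    name: str = ""
    units: str = ""
    draw_info: pd.DataFrame | None = None

    def __post_init__(self):
        self.keys = self.keys.reset_index(drop=True)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != len(self.keys):
            raise AlignmentError(
                f"{self.values.shape[0]} value rows for {len(self.keys)} keys"
            )
        if not np.all(np.isfinite(self.values)):
            raise SchemaError(f"non-finite draws in {self.name or 'DrawMatrix'}")

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    @property
    def key_columns(self) -> list[str]:
        return list(self.keys.columns)

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "DrawMatrix":
        return DrawMatrix(
            self.keys.copy(), values, name if name is not None else self.name,
            self.units, self.draw_info,
        )

    def assert_probability(self):
        if self.values.min() < 0 or self.values.max() > 1:
            raise SchemaError(f"{self.name}: values outside [0, 1]")

    # ------------------------------------------------------------------
    def _check_aligned(self, other: "DrawMatrix"):
        if self.n_draws != other.n_draws:
            raise AlignmentError(
                f"draw counts differ: {self.n_draws} vs {other.n_draws}"
            )
        if self.key_columns != other.key_columns or not self.keys.equals(other.keys):
            raise AlignmentError("key frames differ between draw matrices")

    def multiply(self, other: "DrawMatrix", name: str = "") -> "DrawMatrix":
        """Elementwise product per draw (e.g. P(>=25) * P(>=30 | >=25))."""
        self._check_aligned(other)
        return self.copy_with(self.values * other.values, name)

    def sort_keys(self, by: list[str] | None = None) -> "DrawMatrix":
        by = by or self.key_columns
        order = self.keys.sort_values(by, kind="mergesort").index.to_numpy()
        return DrawMatrix(
            self.keys.iloc[order], self.values[order], self.name, self.units,
            self.draw_info,
        )

    # ------------------------------------------------------------------
    def aggregate(
        self,
        weights: np.ndarray | pd.Series,
        over: list[str],
        kind: str = "rate",
        name: str = "",
    ) -> "DrawMatrix":
        """Collapse key columns ``over``, draw by draw.

        Rates/probabilities are combined by weighted mean (weights are
        populations); counts by plain sums (``kind='count'``).
        """
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != len(self.keys):
            raise AlignmentError("weights length does not match keys")
        if not np.all(np.isfinite(w)):
            raise SchemaError("missing/non-finite aggregation weight")
        if (w < 0).any():
            raise SchemaError("negative aggregation weight")
        missing = [c for c in over if c not in self.key_columns]
        if missing:
            raise SchemaError(f"cannot aggregate over unknown columns {missing}")
        keep = [c for c in self.key_columns if c not in over]
        if keep:
            codes, uniques = pd.factorize(
                pd.MultiIndex.from_frame(self.keys[keep]), sort=True
            )
            out_keys = pd.DataFrame([tuple(u) for u in uniques], columns=keep)
        else:
            codes = np.zeros(len(self.keys), dtype=int)
            out_keys = pd.DataFrame({"all": ["all"]})
        n_groups = len(out_keys)
        if kind == "count":
            num = np.zeros((n_groups, self.n_draws))
            np.add.at(num, codes, self.values)
            out = num
        elif kind == "rate":
            num = np.zeros((n_groups, self.n_draws))
            np.add.at(num, codes, self.values * w[:, None])
            den = np.bincount(codes, weights=w, minlength=n_groups)
            if (den <= 0).any():
                raise SchemaError("zero total weight in an aggregation group")
            out = num / den[:, None]
        else:
            raise ValueError(f"unknown aggregation kind {kind!r}")
        return DrawMatrix(out_keys, out, name or self.name, self.units, self.draw_info)

    # ------------------------------------------------------------------
    def to_long(self, value_name: str = "value") -> pd.DataFrame:
        """Long-format frame: key columns + draw index + value."""
        frames = []
        for d in range(self.n_draws):
            f = self.keys.copy()
            f["draw"] = d
            f[value_name] = self.values[:, d]
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(
        cls, frame: pd.DataFrame, key_cols: list[str], value_col: str, **meta
    ) -> "DrawMatrix":
        wide = frame.pivot_table(
            index=key_cols, columns="draw", values=value_col, sort=True
        )
        if wide.isna().any().any():
            raise SchemaError("missing (key, draw) combinations in long frame")
        keys = wide.index.to_frame(index=False)
        return cls(keys, wide.to_numpy(), **meta)


def population_weights(keys: pd.DataFrame, population: pd.DataFrame) -> np.ndarray:
    """Population for each key row, for weighted aggregation.

    ``population`` must contain the key columns plus a ``population`` column.
    Raises SchemaError if any key row has no population entry.
    """
    key_cols = [c for c in keys.columns if c in population.columns]
    merged = keys.merge(
        population[key_cols + ["population"]], on=key_cols, how="left"
    )
    if len(merged) != len(keys):
        raise SchemaError("population table has duplicate stratum entries")
    if merged["population"].isna().any():
        bad = merged[merged["population"].isna()].iloc[0][key_cols].to_dict()
        raise SchemaError(f"population missing for stratum {bad}")
    return merged["population"].to_numpy(dtype=float)
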