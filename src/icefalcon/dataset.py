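"""Twin-pair data model: validation, CSV I/O, standardization, double entry.

A :class:`TwinPairDataset` holds long-format data, one row per individual,
grouped into complete monozygotic (MZ) or dizygotic (DZ) pairs.  The
regression machinery consumes a :class:`RegressionTable` built by *double
entry*: every individual appears once as "self" with the partner's exposure
as the "cotwin" value, clustered by pair, so that twin ordering is
immaterial and generalized estimating equations can absorb the within-pair
outcome correlation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

ZYGOSITIES = ("MZ", "DZ")

#: canonical structural columns of the long format
ID_COLUMNS = ("pair_id", "twin_index", "zygosity")


class TwinDataError(ValueError):
    """Raised when twin data violate the pairing/zygosity contract."""


@dataclasses.dataclass(frozen=True)
class TwinPairDataset:
    """Long-format twin data with one validated row per individual.

    Parameters
    ----------
    data
        DataFrame with columns ``pair_id``, ``twin_index`` (1 or 2),
        ``zygosity`` ("MZ"/"DZ") plus one column per trait/covariate.
    trait_names
        Analysis variables (exposures and outcomes).
    covariate_names
        Adjustment variables (e.g. age in years, height in cm).
    standardization
        Mapping variable -> (mean, sd) recorded by :func:`standardize`,
        empty for raw data.
    """

    data: pd.DataFrame
    trait_names: tuple[str, ...]
    covariate_names: tuple[str, ...] = ()
    standardization: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=dict
    )

    def __post_init__(self):
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        _validate(self.data, self.trait_names + self.covariate_names)

    # -- convenience accessors -------------------------------------------------
    @property
    def variables(self) -> tuple[str, ...]:
        return self.trait_names + self.covariate_names

    @property
    def n_pairs(self) -> int:
        return self.data["pair_id"].nunique()

    def pair_counts(self) -> dict[str, int]:
        """Number of pairs per zygosity, e.g. ``{"MZ": 98, "DZ": 54}``."""
        per = self.data.drop_duplicates("pair_id")["zygosity"].value_counts()
        return {z: int(per.get(z, 0)) for z in ZYGOSITIES}

    def subset_zygosity(self, zygosity: str) -> "TwinPairDataset":
        zygosity = _norm_zygosity(zygosity)
        sub = self.data[self.data["zygosity"] == zygosity].reset_index(drop=True)
        if sub.empty:
            raise TwinDataError(f"no {zygosity} pairs in dataset")
        return dataclasses.replace(self, data=sub)

    def to_csv(self, path) -> None:
        cols = list(ID_COLUMNS) + [v for v in self.variables]
        self.data[cols].to_csv(path, index=False)


@dataclasses.dataclass(frozen=True)
class RegressionTable:
    """Double-entered design ready for pair-clustered regression.

    Exactly two rows per cluster; within a cluster the two rows swap the
    roles of self and cotwin, so ``x_self`` of one equals ``x_cotwin`` of
    the other.
    """

    data: pd.DataFrame  # y_self, x_self, x_cotwin, covariates, cluster_id, zygosity
    outcome_name: str
    exposure_name: str
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        d = self.data
        sizes = d.groupby("cluster_id").size()
        if not (sizes == 2).all():
            bad = sizes.index[sizes != 2].tolist()
            raise TwinDataError(f"clusters without exactly 2 rows: {bad}")
        # swap consistency
        g = d.sort_values(["cluster_id"]).reset_index(drop=True)
        a = g["x_self"].to_numpy().reshape(-1, 2)
        b = g["x_cotwin"].to_numpy().reshape(-1, 2)
        if not np.allclose(a, b[:, ::-1], equal_nan=True):
            raise TwinDataError("x_self/x_cotwin are not mutual within clusters")

    @property
    def n_clusters(self) -> int:
        return self.data["cluster_id"].nunique()

    def design(self, terms: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (y, X with leading intercept, cluster codes) for ``terms``."""
        d = self.data
        y = d["y_self"].to_numpy(float)
        X = np.column_stack(
            [np.ones(len(d))] + [d[t].to_numpy(float) for t in terms]
        )
        clusters = pd.factorize(d["cluster_id"])[0]
        return y, X, clusters


# ---------------------------------------------------------------------------
# validation helpers


def _norm_zygosity(z) -> str:
    s = str(z).strip().upper()
    if s not in ZYGOSITIES:
        raise TwinDataError(f"unknown zygosity code: {z!r} (expected MZ or DZ)")
    return s


def _validate(df: pd.DataFrame, variables: Sequence[str]) -> None:
    missing_cols = [c for c in ID_COLUMNS if c not in df.columns]
    if missing_cols:
        raise TwinDataError(f"missing structural columns: {missing_cols}")
    for v in variables:
        if v not in df.columns:
            raise TwinDataError(f"declared variable not in data: {v!r}")
        vals = df[v]
        if not np.issubdtype(vals.dtype, np.number):
            raise TwinDataError(f"variable {v!r} is not numeric")
        finite = np.isfinite(vals.to_numpy(float))
        if not (finite | vals.isna().to_numpy()).all():
            raise TwinDataError(f"variable {v!r} contains non-finite values")
    if not df["twin_index"].isin([1, 2]).all():
        raise TwinDataError("twin_index must be 1 or 2")
    bad_z = set(df["zygosity"]) - set(ZYGOSITIES)
    if bad_z:
        raise TwinDataError(f"unknown zygosity code: {sorted(bad_z)!r} (expected MZ or DZ)")

    counts = df.groupby("pair_id").size()
    unpaired = counts.index[counts != 2].tolist()
    if unpaired:
        raise TwinDataError(f"pair_ids without exactly two members: {unpaired}")
    dup = df.duplicated(subset=["pair_id", "twin_index"])
    if dup.any():
        bad = df.loc[dup, "pair_id"].unique().tolist()
        raise TwinDataError(f"duplicated (pair_id, twin_index) in pairs: {bad}")
    nz = df.groupby("pair_id")["zygosity"].nunique()
    mixed = nz.index[nz > 1].tolist()
    if mixed:
        raise TwinDataError(f"pairs with inconsistent zygosity: {mixed}")


# ---------------------------------------------------------------------------
# operations


def read_twin_csv(
    path,
    schema: Mapping[str, str] | None = None,
    trait_names: Sequence[str] | None = None,
    covariate_names: Sequence[str] = ("age", "height"),
) -> TwinPairDataset:
    """Read a long-format twin CSV into a validated :class:`TwinPairDataset`.

    Parameters
    ----------
    path
        CSV file with a header row (RFC 4180, "." decimal).
    schema
        Optional mapping from canonical roles/variables to the file's
        column names, e.g. ``{"pair_id": "FamilyID", "lean_mass": "LM_kg"}``.
        Roles absent from the map are assumed to use canonical names.
    trait_names, covariate_names
        Variables to declare on the dataset.  By default every non-structural
        column that is not a covariate is treated as a trait.
    """
    df = pd.read_csv(Path(path))
    if schema:
        rename = {src: dst for dst, src in schema.items() if src in df.columns}
        df = df.rename(columns=rename)
    df["zygosity"] = [_norm_zygosity(z) for z in df["zygosity"]]
    df["twin_index"] = pd.to_numeric(df["twin_index"], errors="raise")
    if trait_names is None:
        trait_names = [
            c for c in df.columns if c not in ID_COLUMNS and c not in covariate_names
        ]
    covariate_names = [c for c in covariate_names if c in df.columns]
    return TwinPairDataset(
        data=df.reset_index(drop=True),
        trait_names=tuple(trait_names),
        covariate_names=tuple(covariate_names),
    )


def drop_incomplete_pairs(
    dataset: TwinPairDataset, required: Sequence[str]
) -> tuple[TwinPairDataset, int]:
    """Keep only pairs where both members have all ``required`` variables.

    Mirrors complete-pair exclusion: an individual with a missing value
    removes the whole pair from the analysis sample.  Returns the filtered
    dataset and the number of pairs removed.
    """
    for v in required:
        if v not in dataset.variables:
            raise TwinDataError(f"required variable not declared: {v!r}")
    df = dataset.data
    ok_row = df[list(required)].notna().all(axis=1)
    ok_pair = ok_row.groupby(df["pair_id"]).transform("all")
    removed = df.loc[~ok_pair, "pair_id"].nunique()
    kept = df[ok_pair].reset_index(drop=True)
    if kept.empty:
        raise TwinDataError("no complete pairs after exclusion")
    return dataclasses.replace(dataset, data=kept), int(removed)


def standardize(
    dataset: TwinPairDataset, variables: Sequence[str]
) -> TwinPairDataset:
    """Center and scale each variable to mean 0, SD 1 over the pooled sample.

    Moments are computed over all non-missing individuals of both
    zygosities (the analysis is pooled across MZ and DZ pairs), with the
    usual n-1 denominator, and are recorded on the returned dataset.
    """
    df = dataset.data.copy()
    recorded = dict(dataset.standardization)
    for v in variables:
        if v not in dataset.variables:
            raise TwinDataError(f"cannot standardize undeclared variable: {v!r}")
        x = df[v].to_numpy(float)
        obs = x[~np.isnan(x)]
        if np.unique(obs).size < 2:
            raise TwinDataError(f"zero variance, cannot standardize: {v!r}")
        mean, sd = float(np.mean(obs)), float(np.std(obs, ddof=1))
        df[v] = (x - mean) / sd
        recorded[v] = (mean, sd)
    return dataclasses.replace(dataset, data=df, standardization=recorded)


def build_regression_table(
    dataset: TwinPairDataset,
    outcome: str,
    exposure: str,
    covariates: Sequence[str] = (),
) -> RegressionTable:
    """Double-enter a complete-pair dataset for one exposure/outcome pair.

    Each individual contributes one row as "self" (their own outcome,
    exposure and covariates) with the partner's exposure as ``x_cotwin``;
    ``cluster_id`` is the pair id.
    """
    if outcome == exposure:
        raise TwinDataError("outcome and exposure must differ")
    needed = [outcome, exposure, *covariates]
    ds, _ = drop_incomplete_pairs(dataset, needed)
    df = ds.data.sort_values(["pair_id", "twin_index"]).reset_index(drop=True)
    x = df[exposure].to_numpy(float).reshape(-1, 2)
    rows = pd.DataFrame(
        {
            "cluster_id": df["pair_id"].to_numpy(),
            "zygosity": df["zygosity"].to_numpy(),
            "y_self": df[outcome].to_numpy(float),
            "x_self": x.ravel(),
            "x_cotwin": x[:, ::-1].ravel(),
        }
    )
    for c in covariates:
        rows[c] = df[c].to_numpy(float)
    return RegressionTable(
        data=rows,
        outcome_name=outcome,
        exposure_name=exposure,
        covariate_names=tuple(covariates),
    )
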