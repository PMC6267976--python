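"""Core data containers and community-weighted mean (CWM) computation.

The containers are thin, validated wrappers around :class:`pandas.DataFrame`
in the wide-format conventions of vegetation ecology: trait tables are long
(one species per row), community matrices are wide (one sample per row, one
species per column).

Abundance semantics
-------------------
A :class:`CommunityMatrix` carries a ``kind`` tag:

``cover``
    percent foliar cover per species (field quadrats),
``count``
    individuals per species (e.g. emerged seedlings per pot),
``relative``
    relative abundances; every non-empty row lies on the probability simplex.

:func:`relativize` converts cover or counts to relative abundances by
dividing each row by its row total. Rows with zero total (communities where
nothing emerged) are kept and flagged rather than dropped, so downstream
stages can exclude them explicitly.

The community-weighted mean of trait :math:`t` in a sample with relative
abundances :math:`p_i` is :math:`\\bar T = \\sum_i p_i t_i`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, SpeciesLookupError, ValidationError

TRAIT_COLUMNS = ("seed_mass", "srl", "flowering_date")

_SIMPLEX_ATOL = 1e-9


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


@dataclass(frozen=True)
class TraitTable:
    """Species-level functional traits.

    Wraps a DataFrame indexed by species id with columns ``seed_mass``
    (oven-dry seed mass, mg, > 0), ``srl`` (specific root length,
    m g^-1, > 0) and ``flowering_date`` (mean Julian day, in [1, 366]).
    Extra numeric trait columns are allowed and carried through.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species_id values: {dups}")
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = df.index[~np.isfinite(values).all(axis=1)].tolist()
            raise ValidationError(f"non-finite trait values for species: {bad}")
        for col, lo, hi in (
            ("seed_mass", 0.0, None),
            ("srl", 0.0, None),
            ("flowering_date", 1.0, 366.0),
        ):
            if col not in df.columns:
                continue
            v = df[col].to_numpy(dtype=float)
            if col == "flowering_date":
                bad = df.index[(v < lo) | (v > hi)].tolist()
            else:
                bad = df.index[v <= lo].tolist()
            if bad:
                raise ValidationError(f"invalid {col} for species: {bad}")

    @property
    def species(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def trait_names(self) -> list[str]:
        return self.data.columns.tolist()

    def subset(self, species) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise SpeciesLookupError(missing)
        return TraitTable(self.data.loc[list(species)])

    def to_csv(self, path) -> None:
        self.data.rename_axis("species_id").to_csv(path)


@dataclass(frozen=True)
class CommunityMatrix:
    """Sample x species abundance matrix with a ``kind`` tag."""

    data: pd.DataFrame
    kind: str  # cover | count | relative

    def __post_init__(self):
        if self.kind not in ("cover", "count", "relative"):
            raise ValidationError(f"unknown abundance kind {self.kind!r}")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("community matrix contains non-finite values")
        if (values < 0).any():
            raise ValidationError("community matrix contains negative abundances")
        if self.kind == "relative":
            sums = values.sum(axis=1)
            nonzero = sums > 0
            if not np.allclose(sums[nonzero], 1.0, atol=_SIMPLEX_ATOL, rtol=0):
                bad = self.data.index[nonzero][
                    ~np.isclose(sums[nonzero], 1.0, atol=_SIMPLEX_ATOL, rtol=0)
                ].tolist()
                raise ValidationError(
                    f"relative-abundance rows do not sum to 1: {bad}"
                )

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def species(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def zero_rows(self) -> pd.Series:
        """Boolean flag per sample: True where the row total is zero."""
        return self.data.sum(axis=1) == 0

    def drop_zero_rows(self) -> "CommunityMatrix":
        return CommunityMatrix(self.data.loc[~self.zero_rows], self.kind)

    def to_csv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path)


@dataclass(frozen=True)
class EnvironmentTable:
    """Per-sample environment: soil pH and ponderosa pine basal area (m2 ha-1)."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dups}")
        values = self.data[["soil_ph", "pine_ba"]].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("environment table contains non-finite values")
        if (self.data["pine_ba"].to_numpy(dtype=float) < 0).any():
            raise ValidationError("pine_ba must be >= 0")

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    def to_csv(self, path) -> None:
        self.data.rename_axis("sample_id").to_csv(path)


@dataclass(frozen=True)
class CWMTable:
    """Community-weighted mean traits per sample (or per treatment).

    Rows corresponding to empty communities hold NaN: a CWM is undefined
    when no species is present.
    """

    data: pd.DataFrame

    @property
    def units(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def trait_names(self) -> list[str]:
        return self.data.columns.tolist()

    def to_csv(self, path) -> None:
        self.data.rename_axis("unit_id").to_csv(path)


# ---------------------------------------------------------------------------
# CSV I/O


def read_trait_table(path) -> TraitTable:
    """Read a long-format species trait CSV (columns: species_id + traits)."""
    df = pd.read_csv(path)
    _require_columns(df, ("species_id",) + TRAIT_COLUMNS, path)
    df = df.set_index("species_id")
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ].tolist()
    if non_numeric:
        raise FormatError(f"{path}: non-numeric trait column(s) {non_numeric}")
    return TraitTable(df)


def read_community_matrix(path, kind: str) -> CommunityMatrix:
    """Read a wide-format sample x species abundance CSV."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric abundance values ({exc})") from exc
    return CommunityMatrix(df, kind)


def read_environment_table(path) -> EnvironmentTable:
    df = pd.read_csv(path)
    _require_columns(df, ("sample_id", "soil_ph", "pine_ba"), path)
    return EnvironmentTable(df.set_index("sample_id"))


def read_cwm_table(path) -> CWMTable:
    df = pd.read_csv(path)
    if "unit_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'unit_id'")
    return CWMTable(df.set_index("unit_id").astype(float))


# ---------------------------------------------------------------------------
# Operations


def relativize(m: CommunityMatrix) -> CommunityMatrix:
    """Convert cover or count abundances to relative abundances.

    Each row is divided by its total; all-zero rows are left as zeros
    (query them via :attr:`CommunityMatrix.zero_rows`). Idempotent on
    ``relative`` input.
    """
    if m.kind == "relative":
        return m
    values = m.data.to_numpy(dtype=float)
    sums = values.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(sums > 0, values / sums, 0.0)
    return CommunityMatrix(pd.DataFrame(rel, index=m.data.index, columns=m.data.columns), "relative")


def compute_cwm(rel: CommunityMatrix, traits: TraitTable) -> CWMTable:
    """Community-weighted mean traits, one row per sample.

    Only the species present (positive abundance) in a row need trait
    records in principle, but the matrix columns as a whole must be
    covered so that the matrix product is defined; species columns that
    are everywhere zero are dropped before the lookup. Empty rows give
    NaN CWMs.
    """
    if rel.kind != "relative":
        raise ValidationError("compute_cwm expects kind='relative'; call relativize first")
    data = rel.data.loc[:, (rel.data > 0).any(axis=0)]
    missing = [s for s in data.columns if s not in traits.data.index]
    if missing:
        raise SpeciesLookupError(missing)
    t = traits.data.loc[data.columns]
    cwm = data.to_numpy() @ t.to_numpy(dtype=float)
    out = pd.DataFrame(cwm, index=data.index, columns=t.columns)
    out[rel.zero_rows.to_numpy()] = np.nan
    return CWMTable(out)
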