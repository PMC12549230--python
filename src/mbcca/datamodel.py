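"""Shared data model for the host-microbiome integration pipeline.

The universal carrier between analysis stages is the :class:`FeatureTable`,
a validated samples x features abundance matrix (16S ASV/taxon counts,
per-organism gene abundances on the RPK scale, or normalized host
expression) with optional per-sample and per-feature metadata.
:class:`GroupDesign` maps samples to experimental groups (e.g. control /
DSS day-3 / DSS day-6) and :class:`PipelineConfig` bundles every tunable
threshold of the pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

VALUE_KINDS = ("count", "rpk", "normalized", "log2")


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class DuplicateIdError(ValidationError):
    """A sample or feature identifier occurs more than once."""


class NonNumericValueError(ValidationError):
    """A table cell could not be parsed as a number."""


class MissingValueError(ValidationError):
    """A table cell is empty / NA."""


class NegativeValueError(ValidationError):
    """A table cell is negative where only non-negative values are allowed."""


class RaggedTableError(ValidationError):
    """Rows of an on-disk table have inconsistent field counts."""


def split_composite_id(feature_id: str) -> tuple[str, str | None]:
    """Split a HUMAnN3-style ``gene|taxon`` composite feature id.

    Returns ``(gene, taxon)``; ``taxon`` is None when the id carries no
    ``|`` separator.
    """
    if "|" in feature_id:
        gene, taxon = feature_id.split("|", 1)
        return gene, taxon
    return feature_id, None


@dataclass
class FeatureTable:
    """Samples x features abundance matrix with metadata.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature ids as columns.
        Values must be finite and non-negative.
    value_kind:
        Advisory tag in ``{"count", "rpk", "normalized", "log2"}``
        describing what the numbers mean; arithmetic does not enforce it.
    sample_meta:
        Optional per-sample metadata (e.g. ``group``, ``timepoint``),
        indexed by sample id.
    feature_meta:
        Optional per-feature metadata (e.g. ``taxon``, ``gene_family``,
        ``is_aaRS``), indexed by feature id.
    """

    data: pd.DataFrame
    value_kind: str = "count"
    sample_meta: pd.DataFrame | None = None
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            raise ValidationError("data must be a pandas DataFrame")
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind {self.value_kind!r} not in {VALUE_KINDS}"
            )
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise DuplicateIdError(f"duplicate feature ids: {dupes}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise NonNumericValueError("table contains non-numeric values")
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise MissingValueError(
                f"missing value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if not np.isfinite(values).all():
            raise ValidationError("table contains non-finite values")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise NegativeValueError(
                f"negative value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        self.data = self.data.astype(float)
        for meta, idx, what in (
            (self.sample_meta, self.data.index, "sample"),
            (self.feature_meta, self.data.columns, "feature"),
        ):
            if meta is not None and not meta.index.isin(idx).all():
                extra = meta.index[~meta.index.isin(idx)].tolist()
                raise ValidationError(f"{what}_meta has unknown ids: {extra}")

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    # -- derived metadata ------------------------------------------------
    def taxon_labels(self) -> pd.Series:
        """Per-feature taxon labels.

        Taken from ``feature_meta["taxon"]`` when present; otherwise
        derived by splitting HUMAnN3-style ``gene|taxon`` composite ids.
        Features with neither source get NA.
        """
        labels = pd.Series(
            [split_composite_id(f)[1] for f in self.feature_ids],
            index=self.data.columns,
            dtype=object,
        )
        if self.feature_meta is not None and "taxon" in self.feature_meta:
            meta = self.feature_meta["taxon"].reindex(self.data.columns)
            labels = meta.combine_first(labels)
        return labels

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, ids: Sequence[str]) -> "FeatureTable":
        missing = [s for s in ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[self.sample_meta.index.isin(ids)]
        return FeatureTable(
            self.data.loc[list(ids)], self.value_kind, meta, self.feature_meta
        )

    def subset_features(self, ids: Sequence[str]) -> "FeatureTable":
        missing = [f for f in ids if f not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing}")
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.loc[self.feature_meta.index.isin(ids)]
        return FeatureTable(
            self.data[list(ids)], self.value_kind, self.sample_meta, meta
        )

    def with_values(
        self, values: np.ndarray, value_kind: str | None = None
    ) -> "FeatureTable":
        """Copy of this table with the matrix replaced (shape-preserving)."""
        df = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.data.index,
            columns=self.data.columns,
        )
        return FeatureTable(
            df, value_kind or self.value_kind, self.sample_meta, self.feature_meta
        )


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to experimental groups."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValidationError("empty group design")
        object.__setattr__(self, "assignments", dict(self.assignments))

    @classmethod
    def from_sample_meta(
        cls, meta: pd.DataFrame, column: str = "group"
    ) -> "GroupDesign":
        if column not in meta:
            raise ValidationError(f"sample metadata lacks a {column!r} column")
        return cls(meta[column].astype(str).to_dict())

    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples(self, group: str) -> list[str]:
        return [s for s, g in self.assignments.items() if g == group]

    def group_of(self, sample: str) -> str:
        try:
            return self.assignments[sample]
        except KeyError:
            raise ValidationError(f"sample {sample!r} has no group") from None

    def labels_for(self, sample_ids: Iterable[str]) -> np.ndarray:
        return np.array([self.group_of(s) for s in sample_ids])

    def require_groups(self, groups: Sequence[str], min_size: int = 2) -> None:
        for g in groups:
            n = len(self.samples(g))
            if n < min_size:
                raise ValidationError(
                    f"group {g!r} has {n} samples; at least {min_size} required"
                )


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with study defaults.

    ``alpha`` is the BH-adjusted significance threshold shared by the
    differential tests and the sCCA permutation test; ``p_max``/``rho_min``
    are the Spearman edge filters of the association networks; the penalty
    grid spans ``grid_lo``..``grid_hi`` in ``grid_n`` equal steps.
    """

    alpha: float = 0.05
    p_max: float = 0.05
    rho_min: float = 0.5
    rho_mode: str = "signed"
    grid_lo: float = 0.02
    grid_hi: float = 0.5
    grid_n: int = 20
    n_permutations: int = 999
    seed: int = 0
    pseudocount: float = 1.0
    taxon_scale_constant: float = 1e6
    hub_quantile: float = 0.90
    hub_min_degree: int = 2
    loocv_retention: float = 1.0
    n_components: int | None = None
    max_go_term_size: int = 100

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.p_max < 1:
            raise ValidationError(f"p_max must be in (0,1), got {self.p_max}")
        if not 0 < self.grid_lo <= self.grid_hi <= 1:
            raise ValidationError(
                f"penalty grid must satisfy 0<lo<=hi<=1, got "
                f"[{self.grid_lo}, {self.grid_hi}]"
            )
        if self.grid_n < 2:
            raise ValidationError("penalty grid needs n >= 2 values")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not 0 < self.loocv_retention <= 1:
            raise ValidationError("loocv_retention must be in (0,1]")
        if not 0 <= self.hub_quantile <= 1:
            raise ValidationError("hub_quantile must be in [0,1]")
        if self.rho_mode not in ("signed", "absolute"):
            raise ValidationError("rho_mode must be 'signed' or 'absolute'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
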