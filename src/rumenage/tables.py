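"""Feature tables, metadata, rarefaction and prevalence/abundance filters.

The central container is :class:`FeatureTable`, a samples x features matrix
of non-negative integer read counts for one microbial kingdom (bacteria,
archaea, anaerobic fungi or ciliate protozoa).  Samples come from animals
assigned to one of fourteen ordered age groups spanning 7 days to 12 years.

Filters implemented here reproduce the two detection regimes used in
lifetime rumen-community surveys:

* "detected" taxa: mean group relative abundance above a floor AND present
  in strictly more than half of a group's samples;
* "core" taxa: prevalent (>50%) in *every* age group, above an overall
  abundance floor; "age-specific" taxa are prevalent (>=50%) within a
  single group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AGE_GROUPS",
    "AGE_GROUP_DAYS",
    "DEFAULT_RAREFACTION_DEPTHS",
    "KINGDOMS",
    "FeatureTable",
    "SampleMetadata",
    "TaxonomyMap",
    "RarefactionSpec",
    "read_feature_table",
    "rarefy",
    "relative_abundance",
    "detected_taxa",
    "core_taxa",
    "age_specific_taxa",
    "goods_coverage",
    "chao1",
    "observed_features",
]

#: Ordered age-group labels of the sampling design (d = day, m = month, y = year).
AGE_GROUPS: tuple[str, ...] = (
    "7d", "14d", "1m", "2m", "3m", "4m", "6m",
    "1y", "2y", "3y", "5y", "8y", "10y", "12y",
)

#: Fixed injective mapping from age-group label to chronological age in days.
AGE_GROUP_DAYS: dict[str, int] = {
    "7d": 7, "14d": 14, "1m": 30, "2m": 60, "3m": 90, "4m": 120, "6m": 180,
    "1y": 365, "2y": 730, "3y": 1095, "5y": 1825, "8y": 2920, "10y": 3650,
    "12y": 4380,
}

KINGDOMS: tuple[str, ...] = ("bacteria", "archaea", "fungi", "protozoa")

#: Per-kingdom rarefaction depths at which rarefaction curves plateau.
DEFAULT_RAREFACTION_DEPTHS: dict[str, int] = {
    "bacteria": 7158, "archaea": 3794, "fungi": 4761, "protozoa": 1818,
}

#: Canonical lineage rank names, shallow to deep.
LINEAGE_RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)


@dataclass
class FeatureTable:
    """Samples x features integer count matrix for one kingdom.

    Parameters
    ----------
    counts
        DataFrame with sample ids as index and feature ids as columns;
        entries are non-negative integers.
    kingdom
        One of ``bacteria``, ``archaea``, ``fungi``, ``protozoa``.
    """

    counts: pd.DataFrame
    kingdom: str

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValueError(f"unknown kingdom {self.kingdom!r}; expected one of {KINGDOMS}")
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame (samples x features)")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
            if bad.size:
                i, j = bad[0]
                raise ValueError(
                    "counts must be non-negative integers; offending cell "
                    f"sample={self.counts.index[i]!r} feature={self.counts.columns[j]!r} "
                    f"value={arr[i, j]!r}"
                )
            zero = self.counts.sum(axis=1) == 0
            if zero.any():
                raise ValueError(
                    f"samples with zero total count: {self.counts.index[zero].tolist()}"
                )
        self.counts = self.counts.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def filter_samples(self, keep: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(keep)].copy(), self.kingdom)

    def filter_features(self, keep: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.counts[list(keep)].copy(), self.kingdom)

    def write_tsv(self, path: str | Path) -> None:
        """Write as TSV with samples as rows; first header cell ``#SampleID``."""
        out = self.counts.copy()
        out.index.name = "#SampleID"
        out.to_csv(path, sep="\t")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.kingdom == other.kingdom and self.counts.equals(other.counts)


def read_feature_table(path: str | Path, kingdom: str) -> FeatureTable:
    """Read a TSV count table.

    Orientation is declared, not guessed: the first header cell must be
    ``#SampleID`` (rows are samples) or ``#FeatureID`` (rows are features;
    the table is transposed on read).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    flag = str(df.index.name)
    if flag == "#SampleID":
        counts = df
    elif flag == "#FeatureID":
        counts = df.T
    else:
        raise ValueError(
            f"first header cell must be '#SampleID' or '#FeatureID', got {flag!r}"
        )
    counts.index = counts.index.astype(str)
    counts.index.name = None
    counts.columns = counts.columns.astype(str)
    return FeatureTable(counts, kingdom)


class SampleMetadata:
    """Per-sample animal id, age group and chronological age in days."""

    REQUIRED = ("sample_id", "animal_id", "age_group", "age_days")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        frame = frame.copy()
        frame["sample_id"] = frame["sample_id"].astype(str)
        if frame["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in metadata")
        bad = ~frame["age_group"].isin(AGE_GROUPS)
        if bad.any():
            raise ValueError(
                f"unknown age groups: {sorted(frame.loc[bad, 'age_group'].unique())}"
            )
        expected = frame["age_group"].map(AGE_GROUP_DAYS)
        mism = frame["age_days"].astype(int) != expected
        if mism.any():
            raise ValueError(
                "age_days inconsistent with age_group for samples "
                f"{frame.loc[mism, 'sample_id'].tolist()}"
            )
        self.frame = frame.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def age_group_of(self, sample_id: str) -> str:
        return self.frame.loc[sample_id, "age_group"]

    def age_days_of(self, sample_id: str) -> int:
        return int(self.frame.loc[sample_id, "age_days"])

    def groups_for(self, sample_ids: Iterable[str]) -> pd.Series:
        """Age-group label per sample, raising on samples without metadata."""
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.frame.loc[ids, "age_group"]

    def ages_for(self, sample_ids: Iterable[str]) -> pd.Series:
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.frame.loc[ids, "age_days"].astype(float)

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "animal_id": str}))


class TaxonomyMap:
    """Feature id -> ordered lineage (domain ... genus/species).

    Unassigned deep ranks inherit the deepest assigned rank with an
    ``uncl_`` prefix so that aggregation by any rank partitions features.
    """

    def __init__(self, lineages: Mapping[str, Sequence[str]]) -> None:
        clean: dict[str, tuple[str, ...]] = {}
        for fid, lineage in lineages.items():
            ranks = [str(r).strip() for r in lineage]
            ranks = [r for r in ranks if r]
            if not ranks:
                raise ValueError(f"feature {fid!r} has an empty lineage")
            if len(ranks) > len(LINEAGE_RANKS):
                ranks = ranks[: len(LINEAGE_RANKS)]
            # fill missing deep ranks by inheriting the deepest assigned one
            while len(ranks) < len(LINEAGE_RANKS):
                ranks.append(f"uncl_{ranks[-1]}" if not ranks[-1].startswith("uncl_") else ranks[-1])
            clean[str(fid)] = tuple(ranks)
        self.lineages = clean

    def rank_of(self, feature_id: str, rank: str) -> str:
        idx = LINEAGE_RANKS.index(rank)
        try:
            return self.lineages[feature_id][idx]
        except KeyError:
            raise KeyError(f"feature {feature_id!r} not in taxonomy") from None

    def aggregate(self, table: FeatureTable, rank: str) -> FeatureTable:
        """Sum counts of features sharing the same lineage label at `rank`."""
        if rank not in LINEAGE_RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {LINEAGE_RANKS}")
        labels = [self.rank_of(f, rank) for f in table.feature_ids]
        agg = table.counts.T.groupby(pd.Index(labels, name=rank), sort=True).sum().T
        return FeatureTable(agg, table.kingdom)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tlineage\n")
            for fid, lin in self.lineages.items():
                fh.write(f"{fid}\t{';'.join(lin)}\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls({r.feature_id: r.lineage.split(";") for r in df.itertuples()})


@dataclass(frozen=True)
class RarefactionSpec:
    """Target depth and seed for subsampling without replacement."""

    depth: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("rarefaction depth must be positive")


def rarefy(table: FeatureTable, spec: RarefactionSpec) -> FeatureTable:
    """Subsample each sample to exactly ``spec.depth`` reads without replacement.

    Samples with fewer total reads than the depth are dropped (with a
    warning listing their ids), mirroring standard amplicon practice.
    Deterministic given ``spec.seed``.
    """
    totals = table.sample_totals()
    keep = totals[totals >= spec.depth].index.tolist()
    dropped = totals[totals < spec.depth].index.tolist()
    if not keep:
        raise ValueError(
            f"nothing survives rarefaction: all {table.n_samples} samples have "
            f"fewer than {spec.depth} reads"
        )
    if dropped:
        warnings.warn(
            f"rarefaction to depth {spec.depth} dropped {len(dropped)} sample(s): {dropped}",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    out = np.empty((len(keep), table.n_features), dtype=np.int64)
    for i, sid in enumerate(keep):
        row = table.counts.loc[sid].to_numpy()
        out[i] = rng.multivariate_hypergeometric(row, spec.depth)
    return FeatureTable(
        pd.DataFrame(out, index=keep, columns=table.feature_ids), table.kingdom
    )


def relative_abundance(table: FeatureTable | pd.DataFrame) -> pd.DataFrame:
    """Row-normalise counts to proportions (each row sums to 1)."""
    counts = table.counts if isinstance(table, FeatureTable) else table
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError(
            f"zero-total samples: {totals.index[totals == 0].tolist()}"
        )
    return counts.div(totals, axis=0)


def _group_samples(table: FeatureTable, metadata: SampleMetadata) -> dict[str, list[str]]:
    groups = metadata.groups_for(table.sample_ids)
    out: dict[str, list[str]] = {}
    for g in AGE_GROUPS:
        ids = groups.index[groups == g].tolist()
        if ids:
            out[g] = ids
    return out


def detected_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyMap | None = None,
    rank: str | None = None,
    min_relabund: float = 0.001,
    min_prevalence_fraction: float = 0.5,
) -> dict[str, set[str]]:
    """Per-age-group taxa passing the detection regime.

    A taxon is detected in a group when its mean group relative abundance
    exceeds ``min_relabund`` AND it is present (count > 0) in strictly more
    than ``min_prevalence_fraction`` of the group's samples.
    """
    if taxonomy is not None and rank is not None:
        table = taxonomy.aggregate(table, rank)
    rel = relative_abundance(table)
    present = table.counts > 0
    result: dict[str, set[str]] = {}
    for group, ids in _group_samples(table, metadata).items():
        mean_ab = rel.loc[ids].mean(axis=0)
        prev = present.loc[ids].mean(axis=0)
        mask = (mean_ab > min_relabund) & (prev > min_prevalence_fraction)
        result[group] = set(mask.index[mask])
    return result


def core_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    min_relabund: float = 0.0001,
) -> set[str]:
    """Taxa prevalent (>50%) in every age group, above an overall abundance floor."""
    by_group = _group_samples(table, metadata)
    if len(by_group) < 2:
        raise ValueError("core taxa require at least two age groups")
    rel = relative_abundance(table)
    present = table.counts > 0
    overall = rel.mean(axis=0) > min_relabund
    mask = overall.copy()
    for ids in by_group.values():
        mask &= present.loc[ids].mean(axis=0) > 0.5
    return set(mask.index[mask])


def age_specific_taxa(
    table: FeatureTable,
    metadata: SampleMetadata,
    age_group: str,
    min_relabund: float = 0.0001,
    exclusive: bool = False,
) -> set[str]:
    """Taxa prevalent (>=50%) within one age group, above an abundance floor.

    With ``exclusive=True`` the taxon must additionally fail the 50%
    prevalence bar in every other age group (a stricter reading of
    group-restricted detection).
    """
    by_group = _group_samples(table, metadata)
    if age_group not in by_group:
        raise KeyError(f"age group {age_group!r} has no samples in this table")
    rel = relative_abundance(table)
    present = table.counts > 0
    ids = by_group[age_group]
    mask = (present.loc[ids].mean(axis=0) >= 0.5) & (rel.loc[ids].mean(axis=0) > min_relabund)
    if exclusive:
        for g, other_ids in by_group.items():
            if g != age_group:
                mask &= present.loc[other_ids].mean(axis=0) < 0.5
    return set(mask.index[mask])


def _as_counts(sample: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(sample) if not isinstance(sample, np.ndarray) else sample)
    arr = arr[arr > 0]
    if arr.size == 0 or arr.sum() <= 0:
        raise ValueError("sample has no reads")
    return arr


def goods_coverage(sample: Iterable[float]) -> float:
    """Good's coverage 1 - F1/N (F1 = singletons, N = total reads)."""
    arr = _as_counts(sample)
    f1 = int((arr == 1).sum())
    return 1.0 - f1 / arr.sum()


def chao1(sample: Iterable[float]) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1)/(2(F2+1))."""
    arr = _as_counts(sample)
    s_obs = arr.size
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def observed_features(sample: Iterable[float]) -> int:
    """Number of features with nonzero count."""
    return int((np.asarray(list(sample)) > 0).sum())
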