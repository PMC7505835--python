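"""Reading, validation and pairing of species-by-plot incidence data.

The analysis unit is a pair of species-by-plot matrices from the same
naturally disturbed forest: one from the unlogged (reference) portion and
one from the salvage-logged portion, together with study metadata.  Counts
are reduced to incidence frequencies (the number of plots in which each
species occurs), which is all the downstream rarefaction machinery uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "PairingError",
    "MetadataError",
    "SpeciesPlotMatrix",
    "StudyMetadata",
    "IncidenceFrequencies",
    "PairedDataset",
    "read_species_matrix",
    "write_species_matrix",
    "to_incidence",
    "pair_datasets",
    "read_metadata",
    "load_paired_collection",
    "DISTURBANCE_TYPES",
    "HABITATS",
]

logger = logging.getLogger(__name__)

DISTURBANCE_TYPES = ("fire", "windstorm", "insect_outbreak")
HABITATS = ("unlogged", "logged")

#: sanity bound on years since disturbance (field data span up to a few decades)
MAX_YEARS_SINCE_DISTURBANCE = 100.0


class FormatError(ValueError):
    """Malformed matrix file: duplicate labels, negative or fractional counts."""


class PairingError(ValueError):
    """Two matrices cannot form a paired dataset (e.g. overlapping plot ids)."""


class MetadataError(ValueError):
    """Metadata row violates a validity or sanity constraint."""


@dataclass(frozen=True)
class SpeciesPlotMatrix:
    """A species-by-plot count matrix for one habitat.

    ``counts[i, j]`` is the count of species ``species_ids[i]`` in plot
    ``plot_ids[j]``.  Any count > 0 is treated as an occurrence downstream;
    fractional counts are rejected at construction rather than thresholded.
    """

    species_ids: tuple[str, ...]
    plot_ids: tuple[str, ...]
    counts: np.ndarray  # (n_species, n_plots) non-negative ints
    habitat_label: str

    def __post_init__(self) -> None:
        if self.habitat_label not in HABITATS:
            raise ValueError(f"habitat_label must be one of {HABITATS}, got {self.habitat_label!r}")
        if len(self.plot_ids) < 1:
            raise FormatError("matrix must have at least one plot")
        if len(set(self.species_ids)) != len(self.species_ids):
            raise FormatError("duplicate species labels")
        if len(set(self.plot_ids)) != len(self.plot_ids):
            raise FormatError("duplicate plot labels")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.species_ids), len(self.plot_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.species_ids)} species x {len(self.plot_ids)} plots"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.asarray(counts) == np.floor(counts)):
                raise FormatError("non-integer counts")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise FormatError("negative counts")
        object.__setattr__(self, "counts", np.ascontiguousarray(counts, dtype=np.int64))
        object.__setattr__(self, "species_ids", tuple(str(s) for s in self.species_ids))
        object.__setattr__(self, "plot_ids", tuple(str(p) for p in self.plot_ids))
        if len(self.species_ids) == 0:
            logger.warning("matrix (%s) has zero species", self.habitat_label)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    def incidence_bool(self) -> np.ndarray:
        """Boolean occurrence matrix (count > 0)."""
        return self.counts > 0


@dataclass(frozen=True)
class StudyMetadata:
    dataset_id: str
    study_id: str
    taxon_group: str
    saproxylic: bool
    disturbance_type: str
    years_since_disturbance: float

    def __post_init__(self) -> None:
        if self.disturbance_type not in DISTURBANCE_TYPES:
            raise MetadataError(
                f"disturbance_type must be one of {DISTURBANCE_TYPES}, "
                f"got {self.disturbance_type!r} (dataset {self.dataset_id})"
            )
        y = float(self.years_since_disturbance)
        if not np.isfinite(y) or y < 0:
            raise MetadataError(f"years_since_disturbance must be >= 0 (dataset {self.dataset_id})")
        if y > MAX_YEARS_SINCE_DISTURBANCE:
            raise MetadataError(
                f"years_since_disturbance {y} exceeds sanity bound "
                f"{MAX_YEARS_SINCE_DISTURBANCE} (dataset {self.dataset_id})"
            )
        object.__setattr__(self, "years_since_disturbance", y)
        object.__setattr__(self, "saproxylic", bool(self.saproxylic))


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Reference-sample incidence summary for one habitat.

    ``T`` is the number of plots; ``Q`` maps each detected species to its
    incidence frequency (number of plots it occurs in, 1..T).  ``Q1`` and
    ``Q2`` count uniques and duplicates, the inputs to the Chao2 estimator.
    """

    T: int
    Q: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        for sp, q in self.Q.items():
            if not (1 <= q <= self.T):
                raise ValueError(f"incidence frequency of {sp!r} out of range 1..{self.T}: {q}")
        object.__setattr__(self, "Q", dict(self.Q))

    @property
    def S_obs(self) -> int:
        return len(self.Q)

    @property
    def Q1(self) -> int:
        return sum(1 for q in self.Q.values() if q == 1)

    @property
    def Q2(self) -> int:
        return sum(1 for q in self.Q.values() if q == 2)

    def frequencies(self, species: Iterable[str] | None = None) -> np.ndarray:
        """Frequency vector over ``species`` (0 for species not detected here)."""
        if species is None:
            return np.asarray(list(self.Q.values()), dtype=np.int64)
        return np.asarray([self.Q.get(s, 0) for s in species], dtype=np.int64)


@dataclass(frozen=True)
class PairedDataset:
    unlogged: SpeciesPlotMatrix
    logged: SpeciesPlotMatrix
    meta: StudyMetadata
    unlogged_freqs: IncidenceFrequencies = field(init=False)
    logged_freqs: IncidenceFrequencies = field(init=False)

    def __post_init__(self) -> None:
        if self.unlogged.habitat_label != "unlogged" or self.logged.habitat_label != "logged":
            raise PairingError("habitat labels do not match their slots")
        overlap = set(self.unlogged.plot_ids) & set(self.logged.plot_ids)
        if overlap:
            raise PairingError(f"plot ids occur in both habitats: {sorted(overlap)}")
        object.__setattr__(self, "unlogged_freqs", to_incidence(self.unlogged))
        object.__setattr__(self, "logged_freqs", to_incidence(self.logged))

    @property
    def species_universe(self) -> tuple[str, ...]:
        """Pooled observed species, unlogged-detected first, stable order."""
        seen = dict.fromkeys(self.unlogged_freqs.Q)
        seen.update(dict.fromkeys(self.logged_freqs.Q))
        return tuple(seen)

    @property
    def T1(self) -> int:
        return self.unlogged_freqs.T

    @property
    def T2(self) -> int:
        return self.logged_freqs.T


# ---------------------------------------------------------------------------
# file formats

_LONG_COLUMNS = {"species", "plot", "count"}


def read_species_matrix(path: str | Path, habitat_label: str) -> SpeciesPlotMatrix:
    """Read a wide or long CSV into a validated :class:`SpeciesPlotMatrix`.

    Wide format: first column ``species``, remaining columns plot ids,
    integer cells.  Long format (autodetected from the header): columns
    ``species,plot,count``; the species/plot universe is every distinct
    label appearing in the file and missing combinations are zero, so a
    zero-count row can declare a plot with no detections.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header = pd.read_csv(path, nrows=0)
    cols = [str(c).strip().lower() for c in header.columns]
    if set(cols) == _LONG_COLUMNS:
        return _read_long(path, habitat_label)
    return _read_wide(path, habitat_label)


def _check_integer(values: pd.Series | pd.DataFrame, path: Path) -> None:
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr != np.floor(arr)):
        raise FormatError(f"{path}: non-integer counts")
    if np.any(arr < 0):
        raise FormatError(f"{path}: negative counts")


def _read_wide(path: Path, habitat_label: str) -> SpeciesPlotMatrix:
    # pandas mangles duplicate header names, so check the raw header first
    raw_header = pd.read_csv(path, header=None, nrows=1).iloc[0].astype(str).tolist()
    if len(set(raw_header[1:])) != len(raw_header[1:]):
        raise FormatError(f"{path}: duplicate plot columns")
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide matrix needs a species column and at least one plot")
    plot_ids = [str(c) for c in df.columns[1:]]
    species = df.iloc[:, 0].astype(str).tolist()
    if len(set(species)) != len(species):
        raise FormatError(f"{path}: duplicate species rows")
    body = df.iloc[:, 1:]
    _check_integer(body, path)
    counts = np.asarray(body, dtype=np.int64)
    return SpeciesPlotMatrix(tuple(species), tuple(plot_ids), counts, habitat_label)


def _read_long(path: Path, habitat_label: str) -> SpeciesPlotMatrix:
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    df["species"] = df["species"].astype(str)
    df["plot"] = df["plot"].astype(str)
    _check_integer(df["count"], path)
    dup = df.duplicated(subset=["species", "plot"])
    if dup.any():
        raise FormatError(f"{path}: duplicate (species, plot) rows")
    species = list(dict.fromkeys(df["species"]))
    plots = list(dict.fromkeys(df["plot"]))
    wide = (
        df.pivot(index="species", columns="plot", values="count")
        .reindex(index=species, columns=plots)
        .fillna(0)
    )
    counts = np.asarray(wide, dtype=np.int64)
    return SpeciesPlotMatrix(tuple(species), tuple(plots), counts, habitat_label)


def write_species_matrix(matrix: SpeciesPlotMatrix, path: str | Path) -> None:
    """Write the wide-CSV form (first column ``species``)."""
    df = pd.DataFrame(matrix.counts, columns=list(matrix.plot_ids))
    df.insert(0, "species", list(matrix.species_ids))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reductions and pairing


def to_incidence(matrix: SpeciesPlotMatrix) -> IncidenceFrequencies:
    """Reduce counts to incidence frequencies; all-zero species are dropped."""
    occ = matrix.incidence_bool()
    q = occ.sum(axis=1)
    Q = {sp: int(qi) for sp, qi in zip(matrix.species_ids, q) if qi > 0}
    return IncidenceFrequencies(T=matrix.n_plots, Q=Q)


def pair_datasets(
    unlogged: SpeciesPlotMatrix, logged: SpeciesPlotMatrix, meta: StudyMetadata
) -> PairedDataset:
    """Pair two habitat matrices; species universes merge by exact label."""
    paired = PairedDataset(unlogged=unlogged, logged=logged, meta=meta)
    uq = set(paired.unlogged_freqs.Q)
    lq = set(paired.logged_freqs.Q)
    if not uq - lq:
        logger.warning(
            "dataset %s has no species unique to the unlogged habitat", meta.dataset_id
        )
    if not lq:
        logger.warning("dataset %s: logged matrix has no detected species", meta.dataset_id)
    return paired


# ---------------------------------------------------------------------------
# metadata tables and collection loading

METADATA_COLUMNS = [
    "dataset_id",
    "study_id",
    "taxon_group",
    "saproxylic",
    "disturbance_type",
    "years_since_disturbance",
    "unlogged_file",
    "logged_file",
]

_TRUTHY = {"true", "1", "yes", "t", "y"}
_FALSY = {"false", "0", "no", "f", "n"}


def _parse_bool(value: object) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise MetadataError(f"cannot parse boolean saproxylic flag: {value!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a metadata table, checking the required columns are present."""
    df = pd.read_csv(path, dtype={"dataset_id": str, "study_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing metadata columns {missing}")
    if df["dataset_id"].duplicated().any():
        raise MetadataError(f"{path}: duplicate dataset_id values")
    return df


def load_paired_collection(
    metadata_path: str | Path, data_dir: str | Path
) -> tuple[list[PairedDataset], list[tuple[str, str]]]:
    """Load every dataset listed in a metadata table.

    Datasets whose metadata fails the sanity bounds or whose files fail
    validation are excluded, each with a logged reason; the second return
    value lists ``(dataset_id, reason)`` for the exclusions.
    """
    data_dir = Path(data_dir)
    table = read_metadata(metadata_path)
    datasets: list[PairedDataset] = []
    excluded: list[tuple[str, str]] = []
    for row in table.itertuples(index=False):
        dataset_id = str(row.dataset_id)
        try:
            meta = StudyMetadata(
                dataset_id=dataset_id,
                study_id=str(row.study_id),
                taxon_group=str(row.taxon_group),
                saproxylic=_parse_bool(row.saproxylic),
                disturbance_type=str(row.disturbance_type),
                years_since_disturbance=float(row.years_since_disturbance),
            )
            unlogged = read_species_matrix(data_dir / str(row.unlogged_file), "unlogged")
            logged = read_species_matrix(data_dir / str(row.logged_file), "logged")
            datasets.append(pair_datasets(unlogged, logged, meta))
        except (MetadataError, FormatError, PairingError, FileNotFoundError, ValueError) as exc:
            logger.warning("excluding dataset %s: %s", dataset_id, exc)
            excluded.append((dataset_id, str(exc)))
    return datasets, excluded
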