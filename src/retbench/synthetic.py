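"""Synthetic paired incidence datasets with analytically known structure.

The generating model mimics the shape of field data from salvage-logging
studies: two habitats (unlogged disturbed / salvage-logged) share a species
pool split into a unique-to-unlogged class, a unique-to-logged class and a
shared class.  Each species is detected independently in each plot of a
habitat with a species- and habitat-specific probability drawn from a
logit-normal distribution whose low median makes rare species (incidence
frequency 1-2) common, as in real plot surveys.  Because detections are
independent Bernoulli draws per plot, the expected unique-to-unlogged
richness of ``t1`` plots is available in closed form, which gives the
parameter-recovery tests an exact truth to target.

Two subsampling oracles (exhaustive enumeration for tiny designs,
Monte-Carlo otherwise) verify the analytic mixture components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .data_io import (
    METADATA_COLUMNS,
    PairedDataset,
    SpeciesPlotMatrix,
    StudyMetadata,
    pair_datasets,
    write_species_matrix,
)
from .mixture import partition_species

__all__ = [
    "CommunityModel",
    "SyntheticStudy",
    "generate_community",
    "simulate_incidence",
    "true_unique_curve",
    "true_retention",
    "true_fraction_at_retention",
    "subsample_oracle_exact",
    "subsample_oracle_mc",
    "packaged_collection",
    "write_collection",
    "DEFAULT_COLLECTION_SEED",
]

#: fixed base seed of the packaged 24-dataset collection
DEFAULT_COLLECTION_SEED = 20240901

#: default logit-normal detection-probability distribution: median 0.15, shape 1.0
DEFAULT_DETECTION_MEDIAN = 0.15
DEFAULT_DETECTION_SIGMA = 1.0


@dataclass(frozen=True)
class CommunityModel:
    """Generating model: per-species detection probability in each habitat.

    Species ids encode their true class (``uu`` unique-to-unlogged, ``ul``
    unique-to-logged, ``sh`` shared) so tests can introspect the truth.
    """

    species_ids: tuple[str, ...]
    p_unlogged: np.ndarray
    p_logged: np.ndarray
    T1: int
    T2: int
    seed: int

    def __post_init__(self) -> None:
        pU = np.asarray(self.p_unlogged, dtype=float)
        pL = np.asarray(self.p_logged, dtype=float)
        if pU.shape != pL.shape or len(pU) != len(self.species_ids):
            raise ValueError("probability vectors must match the species list")
        if np.any(pU < 0) or np.any(pU > 1) or np.any(pL < 0) or np.any(pL > 1):
            raise ValueError("detection probabilities must lie in [0, 1]")
        object.__setattr__(self, "p_unlogged", pU)
        object.__setattr__(self, "p_logged", pL)

    def class_mask(self, prefix: str) -> np.ndarray:
        return np.array([s.startswith(prefix) for s in self.species_ids])


@dataclass(frozen=True)
class SyntheticStudy:
    paired: PairedDataset
    model: CommunityModel


def generate_community(
    n_unique_unlogged: int = 30,
    n_unique_logged: int = 20,
    n_shared: int = 50,
    T1: int = 15,
    T2: int = 12,
    detection_median: float = DEFAULT_DETECTION_MEDIAN,
    detection_sigma: float = DEFAULT_DETECTION_SIGMA,
    seed: int = 0,
) -> CommunityModel:
    """Draw a community model; reproducible for a fixed seed."""
    for name, v in (
        ("n_unique_unlogged", n_unique_unlogged),
        ("n_unique_logged", n_unique_logged),
        ("n_shared", n_shared),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if n_unique_unlogged + n_unique_logged + n_shared == 0:
        raise ValueError("community must contain at least one species")
    if T1 < 2 or T2 < 2:
        raise ValueError("T1 and T2 must be >= 2")
    if not 0 < detection_median < 1:
        raise ValueError("detection_median must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    def draw(k: int) -> np.ndarray:
        return expit(rng.normal(logit(detection_median), detection_sigma, size=k))

    ids, pU, pL = [], [], []
    for prefix, k, in_unlogged, in_logged in (
        ("uu", n_unique_unlogged, True, False),
        ("ul", n_unique_logged, False, True),
        ("sh", n_shared, True, True),
    ):
        ids.extend(f"{prefix}{i:04d}" for i in range(k))
        pU.append(draw(k) if in_unlogged else np.zeros(k))
        pL.append(draw(k) if in_logged else np.zeros(k))
    return CommunityModel(
        species_ids=tuple(ids),
        p_unlogged=np.concatenate(pU),
        p_logged=np.concatenate(pL),
        T1=T1,
        T2=T2,
        seed=seed,
    )


def simulate_incidence(
    model: CommunityModel, seed: int, meta: StudyMetadata | None = None
) -> PairedDataset:
    """Draw one paired incidence dataset from the model.

    Each species-by-plot cell is an independent Bernoulli draw with the
    species' habitat detection probability.
    """
    rng = np.random.default_rng(seed)
    occ_U = (rng.random((len(model.species_ids), model.T1)) < model.p_unlogged[:, None]).astype(
        np.int64
    )
    occ_L = (rng.random((len(model.species_ids), model.T2)) < model.p_logged[:, None]).astype(
        np.int64
    )
    if meta is None:
        meta = StudyMetadata(
            dataset_id=f"sim{seed}",
            study_id=f"study{seed}",
            taxon_group="synthetic_taxon",
            saproxylic=False,
            disturbance_type="windstorm",
            years_since_disturbance=5.0,
        )
    unlogged = SpeciesPlotMatrix(
        species_ids=model.species_ids,
        plot_ids=tuple(f"U{j + 1:03d}" for j in range(model.T1)),
        counts=occ_U,
        habitat_label="unlogged",
    )
    logged = SpeciesPlotMatrix(
        species_ids=model.species_ids,
        plot_ids=tuple(f"L{j + 1:03d}" for j in range(model.T2)),
        counts=occ_L,
        habitat_label="logged",
    )
    return pair_datasets(unlogged, logged, meta)


# ---------------------------------------------------------------------------
# analytic truth


def true_unique_curve(model: CommunityModel, t1) -> float:
    """Expected richness of true unique-to-unlogged species in ``t1`` plots:
    ``sum_i 1 - (1 - p_i)^t1`` — continuous in ``t1``."""
    t1 = float(t1)
    if not 0.0 <= t1 <= model.T1:
        raise ValueError(f"t1={t1} outside [0, T1={model.T1}]")
    p = model.p_unlogged[model.class_mask("uu")]
    return float(np.sum(1.0 - (1.0 - p) ** t1))


def true_fraction_at_retention(model: CommunityModel, p: float) -> float:
    """Normalized analytic unique curve at retention proportion ``p``."""
    denom = true_unique_curve(model, model.T1)
    if denom == 0:
        raise ValueError("model has no detectable unique-to-unlogged species")
    return true_unique_curve(model, p * model.T1) / denom


def true_retention(model: CommunityModel, q: float = 0.9) -> float:
    """Analytic retention proportion maintaining a fraction ``q`` of the
    model's expected unique-to-unlogged richness at full sampling."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    return float(brentq(lambda p: true_fraction_at_retention(model, p) - q, 0.0, 1.0, xtol=1e-12))


# ---------------------------------------------------------------------------
# subsampling oracles

MAX_EXACT_PAIRS = 10**6


def _class_detection_matrices(paired: PairedDataset):
    part = partition_species(paired)
    uu = sorted(part.unique_unlogged)
    ul = sorted(part.unique_logged)
    sh = sorted(part.shared)

    def rows(matrix, species):
        idx = {s: i for i, s in enumerate(matrix.species_ids)}
        occ = matrix.incidence_bool()
        return occ[[idx[s] for s in species], :] if species else np.zeros((0, matrix.n_plots), bool)

    return {
        "uu_U": rows(paired.unlogged, uu),
        "ul_L": rows(paired.logged, ul),
        "sh_U": rows(paired.unlogged, sh),
        "sh_L": rows(paired.logged, sh),
    }


def _component_counts(det, selU, selL):
    """Observed per-class richness for one subset pair (column index arrays)."""
    uu = int(det["uu_U"][:, selU].any(axis=1).sum()) if det["uu_U"].size else 0
    ul = int(det["ul_L"][:, selL].any(axis=1).sum()) if det["ul_L"].size else 0
    if det["sh_U"].shape[0]:
        in_U = det["sh_U"][:, selU].any(axis=1)
        in_L = det["sh_L"][:, selL].any(axis=1)
        sh = int((in_U | in_L).sum())
    else:
        sh = 0
    return uu, ul, sh


def subsample_oracle_exact(paired: PairedDataset, t1: int, t2: int) -> dict:
    """Exact mean of each mixture component over all ``C(T1,t1) * C(T2,t2)``
    subset pairs, by enumeration.  Classes are fixed at the reference level."""
    T1, T2 = paired.T1, paired.T2
    if not (0 <= t1 <= T1 and 0 <= t2 <= T2):
        raise ValueError("subset sizes out of range")
    n_pairs = math.comb(T1, t1) * math.comb(T2, t2)
    if n_pairs > MAX_EXACT_PAIRS:
        raise ValueError(
            f"{n_pairs} subset pairs exceeds the enumeration budget "
            f"{MAX_EXACT_PAIRS}; use subsample_oracle_mc"
        )
    det = _class_detection_matrices(paired)
    sums = np.zeros(3)
    for selU in combinations(range(T1), t1):
        selU = list(selU)
        for selL in combinations(range(T2), t2):
            sums += _component_counts(det, selU, list(selL))
    means = sums / n_pairs
    return {
        "unique_unlogged": means[0],
        "unique_logged": means[1],
        "shared": means[2],
        "total": float(means.sum()),
    }


def subsample_oracle_mc(
    paired: PairedDataset, t1: int, t2: int, reps: int = 2000, seed: int = 0
) -> tuple[dict, dict]:
    """Monte-Carlo component means and standard errors over ``reps`` random
    subset pairs (plots drawn without replacement within each habitat)."""
    if reps < 100:
        raise ValueError("reps must be >= 100")
    T1, T2 = paired.T1, paired.T2
    if not (0 <= t1 <= T1 and 0 <= t2 <= T2):
        raise ValueError("subset sizes out of range")
    rng = np.random.default_rng(seed)
    det = _class_detection_matrices(paired)
    # random t-subsets via argsort of uniform keys, vectorized over reps
    selU = np.argsort(rng.random((reps, T1)), axis=1)[:, :t1]
    selL = np.argsort(rng.random((reps, T2)), axis=1)[:, :t2]

    def per_rep(occ, sel):
        if occ.shape[0] == 0:
            return np.zeros((reps, 0), dtype=bool)
        if sel.shape[1] == 0:
            return np.zeros((reps, occ.shape[0]), dtype=bool)
        return occ[:, sel].any(axis=2).T  # (reps, n_species)

    uu = per_rep(det["uu_U"], selU).sum(axis=1)
    ul = per_rep(det["ul_L"], selL).sum(axis=1)
    sh = (per_rep(det["sh_U"], selU) | per_rep(det["sh_L"], selL)).sum(axis=1)
    total = uu + ul + sh
    samples = {"unique_unlogged": uu, "unique_logged": ul, "shared": sh, "total": total}
    means = {k: float(np.mean(v)) for k, v in samples.items()}
    ses = {k: float(np.std(v, ddof=1) / np.sqrt(reps)) for k, v in samples.items()}
    return means, ses


# ---------------------------------------------------------------------------
# packaged collection

_SAPROXYLIC_TAXA = (
    "saproxylic_beetles",
    "wood_inhabiting_fungi",
    "epixylic_lichens",
    "bark_beetles",
)
_NON_SAPROXYLIC_TAXA = (
    "ground_beetles",
    "epigeic_spiders",
    "vascular_plants",
    "birds",
)
_DISTURBANCES = ("fire", "windstorm", "insect_outbreak")


def packaged_collection(seed: int = DEFAULT_COLLECTION_SEED) -> list[SyntheticStudy]:
    """The 24-dataset reference collection used in end-to-end tests and docs.

    Design: 3 disturbance types x (saproxylic / non-saproxylic) x 4 taxon
    labels; plot counts 5-30 per habitat; saproxylic communities get rarer
    species (lower detection median), which makes their unique-richness
    curves closer to linear and their retention demands higher, echoing how
    deadwood-dependent taxa behave in field data.  Studies are nested within
    disturbance type (two studies per type).
    """
    studies: list[SyntheticStudy] = []
    i = 0
    for disturbance in _DISTURBANCES:
        for saproxylic, taxa in ((True, _SAPROXYLIC_TAXA), (False, _NON_SAPROXYLIC_TAXA)):
            for taxon in taxa:
                rng = np.random.default_rng([seed, i])
                T1 = int(rng.integers(8, 31))
                T2 = int(rng.integers(5, 26))
                model = generate_community(
                    n_unique_unlogged=int(rng.integers(12, 41)),
                    n_unique_logged=int(rng.integers(6, 26)),
                    n_shared=int(rng.integers(20, 81)),
                    T1=T1,
                    T2=T2,
                    detection_median=0.08 if saproxylic else 0.18,
                    detection_sigma=DEFAULT_DETECTION_SIGMA,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                meta = StudyMetadata(
                    dataset_id=f"ds{i:03d}",
                    study_id=f"study_{disturbance}_{i % 2 + 1}",
                    taxon_group=taxon,
                    saproxylic=saproxylic,
                    disturbance_type=disturbance,
                    years_since_disturbance=float(rng.integers(1, 26)),
                )
                paired = simulate_incidence(model, seed=int(rng.integers(0, 2**31 - 1)), meta=meta)
                studies.append(SyntheticStudy(paired=paired, model=model))
                i += 1
    return studies


def write_collection(studies: list[SyntheticStudy], out_dir: str | Path) -> pd.DataFrame:
    """Write a collection in the data_io formats: one wide CSV per matrix,
    ``meta.csv``, and ``truth.csv`` with the analytic benchmark truths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows, truth_rows = [], []
    for st in studies:
        meta = st.paired.meta
        uf = f"{meta.dataset_id}_unlogged.csv"
        lf = f"{meta.dataset_id}_logged.csv"
        write_species_matrix(st.paired.unlogged, out_dir / uf)
        write_species_matrix(st.paired.logged, out_dir / lf)
        meta_rows.append(
            {
                "dataset_id": meta.dataset_id,
                "study_id": meta.study_id,
                "taxon_group": meta.taxon_group,
                "saproxylic": meta.saproxylic,
                "disturbance_type": meta.disturbance_type,
                "years_since_disturbance": meta.years_since_disturbance,
                "unlogged_file": uf,
                "logged_file": lf,
            }
        )
        truth_rows.append(
            {
                "dataset_id": meta.dataset_id,
                "true_p_star": true_retention(st.model, 0.9),
                "true_frac_at_half": true_fraction_at_retention(st.model, 0.5),
            }
        )
    meta_df = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    meta_df.to_csv(out_dir / "meta.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False, float_format="%.10g")
    return meta_df
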