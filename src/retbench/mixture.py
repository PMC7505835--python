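"""Proportional mixture of two within-habitat rarefaction/extrapolation curves.

When a proportion of an unlogged, naturally disturbed area is salvage
logged, the expected richness of the resulting landscape sample can be
obtained analytically by replacing ``t`` of the ``T1`` unlogged reference
plots with the same number of plots drawn from the logged reference sample
of ``T2`` plots.  The total sample size stays fixed at ``T1`` and the
retention proportion is ``p = t1 / T1``, where ``t1`` is the number of
unlogged plots kept.  The expected richness decomposes into species unique
to the unlogged sample, species unique to the logged sample, and shared
species; the unique-to-unlogged component is the quantity the retention
benchmarks are built on.

Species classes are fixed at the reference-sample level by default: a
species is "unique to unlogged" when it was detected in the unlogged
reference sample and never in the logged one.  An alternative
subsample-level definition (classified by detection within the mixed
subsample) is available via ``unique_definition="subsample"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import PairedDataset
from .rarefaction import extrapolated_richness, miss_probability

__all__ = [
    "SpeciesClassPartition",
    "MixtureDecomposition",
    "partition_species",
    "unique_unlogged_curve",
    "mixture_components",
    "compute_mixture_decomposition",
]

COMPONENTS = ("unique_unlogged", "unique_logged", "shared", "total")


@dataclass(frozen=True)
class SpeciesClassPartition:
    """Pooled observed species split by reference-sample detection pattern."""

    unique_unlogged: frozenset[str]
    unique_logged: frozenset[str]
    shared: frozenset[str]

    def __post_init__(self) -> None:
        sets = (self.unique_unlogged, self.unique_logged, self.shared)
        total = sum(len(s) for s in sets)
        if len(self.unique_unlogged | self.unique_logged | self.shared) != total:
            raise ValueError("species classes must be disjoint")


def partition_species(paired: PairedDataset) -> SpeciesClassPartition:
    """Classify every pooled observed species by where it was detected."""
    uq = set(paired.unlogged_freqs.Q)
    lq = set(paired.logged_freqs.Q)
    return SpeciesClassPartition(
        unique_unlogged=frozenset(uq - lq),
        unique_logged=frozenset(lq - uq),
        shared=frozenset(uq & lq),
    )


def _class_frequencies(paired: PairedDataset):
    """Sorted per-class frequency vectors (sorted ids for determinism)."""
    part = partition_species(paired)
    uu = sorted(part.unique_unlogged)
    ul = sorted(part.unique_logged)
    sh = sorted(part.shared)
    qU = paired.unlogged_freqs
    qL = paired.logged_freqs
    return {
        "uu_U": qU.frequencies(uu),
        "ul_L": qL.frequencies(ul),
        "sh_U": qU.frequencies(sh),
        "sh_L": qL.frequencies(sh),
    }


def unique_unlogged_curve(paired: PairedDataset, t1) -> float:
    """Expected number of unique-to-unlogged species detected in ``t1`` of the
    ``T1`` unlogged plots.  Never requires extrapolation for ``t1 in [0, T1]``."""
    t1 = float(t1)
    T1 = paired.T1
    if not 0.0 <= t1 <= T1:
        raise ValueError(f"t1={t1} outside [0, T1={T1}]")
    part = partition_species(paired)
    q = paired.unlogged_freqs.frequencies(sorted(part.unique_unlogged))
    if q.size == 0:
        return 0.0
    return float(np.sum(1.0 - miss_probability(T1, q, t1)))


def _components_at(paired: PairedDataset, t1: float, t2: float, unique_definition: str) -> dict:
    """Expected richness components for ``t1`` unlogged and ``t2`` logged plots
    (both within their reference samples; no extrapolation here)."""
    T1, T2 = paired.T1, paired.T2
    f = _class_frequencies(paired)
    m_uu = miss_probability(T1, f["uu_U"], t1) if f["uu_U"].size else np.empty(0)
    m_ul = miss_probability(T2, f["ul_L"], t2) if f["ul_L"].size else np.empty(0)
    m_sh_U = miss_probability(T1, f["sh_U"], t1) if f["sh_U"].size else np.empty(0)
    m_sh_L = miss_probability(T2, f["sh_L"], t2) if f["sh_L"].size else np.empty(0)

    if unique_definition == "reference":
        uu = float(np.sum(1.0 - m_uu))
        ul = float(np.sum(1.0 - m_ul))
        sh = float(np.sum(1.0 - m_sh_U * m_sh_L))
    elif unique_definition == "subsample":
        # detected in exactly one of the two subsamples vs both
        uu = float(np.sum(1.0 - m_uu)) + float(np.sum((1.0 - m_sh_U) * m_sh_L))
        ul = float(np.sum(1.0 - m_ul)) + float(np.sum(m_sh_U * (1.0 - m_sh_L)))
        sh = float(np.sum((1.0 - m_sh_U) * (1.0 - m_sh_L)))
    else:
        raise ValueError(f"unknown unique_definition {unique_definition!r}")
    return {
        "unique_unlogged": uu,
        "unique_logged": ul,
        "shared": sh,
        "total": uu + ul + sh,
    }


def mixture_components(
    paired: PairedDataset,
    t1,
    *,
    unique_definition: str = "reference",
    extrapolation_policy: str = "unique_logged",
) -> dict:
    """Expected richness components of the mixture keeping ``t1`` unlogged
    plots out of ``T1`` (so ``t2 = T1 - t1`` logged plots).

    When ``t2 > T2`` (unbalanced designs with fewer logged plots), the logged
    side is evaluated at its full reference sample and the Chao2-driven
    extrapolation increment of the logged curve is added to the
    ``unique_logged`` component and the total.
    """
    t1 = float(t1)
    T1, T2 = paired.T1, paired.T2
    if not 0.0 <= t1 <= T1:
        raise ValueError(f"t1={t1} outside [0, T1={T1}]")
    t2 = T1 - t1
    comps = _components_at(paired, t1, min(t2, T2), unique_definition)
    if t2 > T2:
        if extrapolation_policy != "unique_logged":
            raise ValueError(f"unknown extrapolation_policy {extrapolation_policy!r}")
        delta = extrapolated_richness(paired.logged_freqs, t2 - T2) - paired.logged_freqs.S_obs
        comps["unique_logged"] += delta
        comps["total"] += delta
        comps["extrapolated"] = True
    else:
        comps["extrapolated"] = False
    return comps


@dataclass(frozen=True)
class MixtureDecomposition:
    """Component curves over the retention-proportion grid ``p = t1 / T1``."""

    dataset_id: str
    p_grid: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    components: dict[str, np.ndarray]  # keys: COMPONENTS
    extrapolation_flag: np.ndarray  # bool, True where t2 > T2

    def to_frame(self) -> pd.DataFrame:
        """Long form: ``dataset_id,p,component,value,extrapolated``."""
        frames = []
        for name in COMPONENTS:
            frames.append(
                pd.DataFrame(
                    {
                        "dataset_id": self.dataset_id,
                        "p": self.p_grid,
                        "component": name,
                        "value": self.components[name],
                        "extrapolated": self.extrapolation_flag,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def compute_mixture_decomposition(
    paired: PairedDataset,
    n_grid: int = 201,
    *,
    unique_definition: str = "reference",
    extrapolation_policy: str = "unique_logged",
) -> MixtureDecomposition:
    """Evaluate the mixture components on a uniform retention grid over [0, 1]."""
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    T1 = paired.T1
    p_grid = np.linspace(0.0, 1.0, n_grid)
    t1 = p_grid * T1
    t2 = T1 - t1
    values = {name: np.empty(n_grid) for name in COMPONENTS}
    flag = np.empty(n_grid, dtype=bool)
    for i in range(n_grid):
        comps = mixture_components(
            paired,
            t1[i],
            unique_definition=unique_definition,
            extrapolation_policy=extrapolation_policy,
        )
        for name in COMPONENTS:
            values[name][i] = comps[name]
        flag[i] = comps["extrapolated"]
    return MixtureDecomposition(
        dataset_id=paired.meta.dataset_id,
        p_grid=p_grid,
        t1=t1,
        t2=t2,
        components=values,
        extrapolation_flag=flag,
    )
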