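import numpy as np
import pytest

from retbench.data_io import (
    PairedDataset,
    SpeciesPlotMatrix,
    StudyMetadata,
    pair_datasets,
)


@pytest.fixture
def meta():
    return StudyMetadata(
        dataset_id="d1",
        study_id="s1",
        taxon_group="ground_beetles",
        saproxylic=False,
        disturbance_type="fire",
        years_since_disturbance=3.0,
    )


@pytest.fixture
def tiny_paired(meta) -> PairedDataset:
    """Unlogged T1=2 with frequencies {a:2, b:1}; logged T2=2 with {a:1}.

    Small enough that every mixture quantity can be enumerated by hand:
    the 2x2 subset pairs at (t1=1, t2=1) have pooled richness 2,1,2,1.
    """
    unlogged = SpeciesPlotMatrix(
        ("a", "b"), ("u1", "u2"), np.array([[1, 1], [0, 2]]), "unlogged"
    )
    logged = SpeciesPlotMatrix(("a",), ("l1", "l2"), np.array([[3, 0]]), "logged")
    return pair_datasets(unlogged, logged, meta)


@pytest.fixture
def linear_paired(meta) -> PairedDataset:
    """One unique-to-unlogged species with incidence frequency 1 out of
    T1=10 plots: its normalized detection curve is exactly linear in the
    retention proportion."""
    counts_u = np.array([[1] + [0] * 9, [1] * 10])
    unlogged = SpeciesPlotMatrix(
        ("uniq", "everywhere"), tuple(f"u{i}" for i in range(10)), counts_u, "unlogged"
    )
    logged = SpeciesPlotMatrix(("everywhere",), ("l1", "l2", "l3"), np.array([[1, 1, 0]]), "logged")
    return pair_datasets(unlogged, logged, meta)


def random_small_paired(rng: np.random.Generator, meta: StudyMetadata) -> PairedDataset:
    """Random fixture with T1, T2 <= 6 and <= 12 pooled species, guaranteed
    at least one detection in each habitat."""
    while True:
        T1 = int(rng.integers(2, 7))
        T2 = int(rng.integers(2, 7))
        n_sp = int(rng.integers(2, 13))
        species = tuple(f"sp{i}" for i in range(n_sp))
        occ_u = (rng.random((n_sp, T1)) < rng.uniform(0.1, 0.7, (n_sp, 1))).astype(int)
        occ_l = (rng.random((n_sp, T2)) < rng.uniform(0.1, 0.7, (n_sp, 1))).astype(int)
        if occ_u.any() and occ_l.any():
            break
    unlogged = SpeciesPlotMatrix(
        species, tuple(f"u{j}" for j in range(T1)), occ_u, "unlogged"
    )
    logged = SpeciesPlotMatrix(species, tuple(f"l{j}" for j in range(T2)), occ_l, "logged")
    return pair_datasets(unlogged, logged, meta)


@pytest.fixture(scope="session")
def collection():
    from retbench.synthetic import packaged_collection

    return packaged_collection()
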