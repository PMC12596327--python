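import numpy as np
import pandas as pd
import pytest

from solvselect import (
    CatalogSimSpec,
    autoscale,
    filter_catalog,
    nipals_pca,
    pc_window,
    project,
    simulate_catalog,
)
from solvselect.errors import SchemaError


def spectral_pca(x: np.ndarray, k: int):
    """Independent oracle: PCA via eigendecomposition of the Gram matrix,
    sign-aligned to the largest-|.|-positive convention."""
    cov = x.T @ x
    eigenvalues, eigenvectors = np.linalg.eigh(cov)
    order = np.argsort(eigenvalues)[::-1]
    loadings = eigenvectors[:, order[:k]].T
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    scores = x @ loadings.T
    ev = eigenvalues[order] / eigenvalues.sum()
    return loadings, scores, ev[:k]


def frame(x: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        x,
        index=[f"row{i}" for i in range(x.shape[0])],
        columns=[f"col{j}" for j in range(x.shape[1])],
    )


def test_autoscale_centres_and_scales():
    scaled = autoscale(frame(np.array([[1.0], [2.0], [3.0]])))
    assert scaled.data["col0"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
    assert scaled.column_means["col0"] == pytest.approx(2.0)
    assert scaled.column_sds["col0"] == pytest.approx(1.0)


def test_autoscale_drops_constant_column_with_warning():
    data = frame(np.column_stack([np.array([5.0, 5.0, 5.0]), np.arange(3.0)]))
    with pytest.warns(UserWarning, match="zero variance"):
        scaled = autoscale(data)
    assert scaled.columns == ["col1"]
    assert scaled.dropped == (("col0", "zero variance"),)


def test_autoscale_moments_on_simulated_block(sim_catalog):
    catalog, _ = sim_catalog
    scaled = autoscale(filter_catalog(catalog).descriptor_matrix())
    means = scaled.data.mean(axis=0, skipna=True)
    sds = scaled.data.std(axis=0, ddof=1, skipna=True)
    assert np.allclose(means, 0.0, atol=1e-9)
    assert np.allclose(sds, 1.0, atol=1e-9)
    # missing cells stay missing
    assert scaled.data.isna().to_numpy().sum() > 0


@pytest.mark.parametrize("n, p, seed", [(6, 4, 0), (20, 10, 1), (50, 30, 2)])
def test_nipals_matches_spectral_oracle_on_complete_data(n, p, seed):
    rng = np.random.default_rng(seed)
    scaled = autoscale(frame(rng.standard_normal((n, p))))
    k = min(5, min(n, p))
    model = nipals_pca(scaled, n_components=k, tol=1e-12, max_iter=20000)
    loadings, scores, ev = spectral_pca(scaled.data.to_numpy(), k)
    assert np.abs(model.loadings.to_numpy() - loadings).max() < 1e-6
    assert np.abs(model.scores.to_numpy() - scores).max() < 1e-6
    assert np.abs(model.explained_variance_fraction - ev).max() < 1e-9


def test_rank_one_matrix_has_unit_first_component():
    u = np.array([1.0, -2.0, 0.5, 3.0, -1.5, 0.2])
    v = np.array([0.3, -0.7, 1.1, 0.4])
    model = nipals_pca(frame(np.outer(u, v)), n_components=1)
    assert model.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-9)


def test_explained_variance_sums_to_one_over_full_rank():
    rng = np.random.default_rng(5)
    scaled = autoscale(frame(rng.standard_normal((8, 5))))
    model = nipals_pca(scaled, n_components=5, tol=1e-13, max_iter=50000)
    assert model.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)
    diffs = np.diff(model.explained_variance_fraction)
    assert (diffs <= 1e-9).all()
    # score columns mutually orthogonal on complete data
    gram = model.scores.to_numpy().T @ model.scores.to_numpy()
    off = gram - np.diag(np.diag(gram))
    assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()


def test_missing_cells_preserve_leading_structure():
    """Deleting 10% of cells leaves the first loading nearly unchanged."""
    rng = np.random.default_rng(11)
    scores = rng.standard_normal((40, 2)) * np.array([3.0, 1.0])
    loadings, _ = np.linalg.qr(rng.standard_normal((8, 2)))
    x = scores @ loadings.T + 0.05 * rng.standard_normal((40, 8))
    complete = nipals_pca(autoscale(frame(x)), 1, tol=1e-12, max_iter=5000)
    x_missing = x.copy()
    mask = rng.random(x.shape) < 0.10
    x_missing[mask] = np.nan
    incomplete = nipals_pca(autoscale(frame(x_missing)), 1, tol=1e-12, max_iter=5000)
    corr = np.corrcoef(
        complete.loadings.to_numpy()[0], incomplete.loadings.to_numpy()[0]
    )[0, 1]
    assert abs(corr) > 0.99


def test_row_and_column_permutation_permutes_results():
    rng = np.random.default_rng(13)
    data = frame(rng.standard_normal((12, 6)))
    model = nipals_pca(autoscale(data), 2, tol=1e-12, max_iter=5000)
    row_order = rng.permutation(data.index)
    col_order = rng.permutation(data.columns)
    permuted = nipals_pca(
        autoscale(data.loc[row_order, col_order]), 2, tol=1e-12, max_iter=5000
    )
    assert np.allclose(
        permuted.scores.loc[data.index].to_numpy(),
        model.scores.to_numpy(),
        atol=1e-8,
    )
    assert np.allclose(
        permuted.loadings[data.columns].to_numpy(),
        model.loadings.to_numpy(),
        atol=1e-8,
    )


def test_projection_reproduces_training_scores():
    rng = np.random.default_rng(17)
    scaled = autoscale(frame(rng.standard_normal((15, 6))))
    model = nipals_pca(scaled, 3, tol=1e-12, max_iter=5000)
    projected = project(model, scaled)
    assert np.abs(projected.to_numpy() - model.scores.to_numpy()).max() < 1e-6


def test_projection_of_column_means_is_zero():
    rng = np.random.default_rng(19)
    scaled = autoscale(frame(rng.standard_normal((10, 4))))
    model = nipals_pca(scaled, 2, tol=1e-12, max_iter=5000)
    zeros = pd.DataFrame(
        np.zeros((1, 4)), index=["centre"], columns=scaled.data.columns
    )
    assert np.allclose(project(model, zeros).to_numpy(), 0.0, atol=1e-12)


def test_projection_rejects_descriptor_mismatch():
    rng = np.random.default_rng(23)
    scaled = autoscale(frame(rng.standard_normal((10, 4))))
    model = nipals_pca(scaled, 2)
    other = pd.DataFrame(np.zeros((1, 3)), columns=["a", "b", "c"])
    with pytest.raises(SchemaError):
        project(model, other)


def test_component_window_selects_planted_cluster():
    """The PC1 window around the reference recovers exactly the planted
    cluster members of a synthetic catalog."""
    catalog, truth = simulate_catalog(
        CatalogSimSpec(seed=29, missing_fraction=0.0, noise_sd=0.02)
    )
    scaled = autoscale(catalog.descriptor_matrix())
    model = nipals_pca(scaled, 2, tol=1e-10, max_iter=2000)
    scores = model.scores
    offsets = (scores["PC1"] - scores.at[truth.reference_name, "PC1"]).abs()
    members = offsets[list(truth.cluster_members)]
    outsiders = offsets.drop(list(truth.cluster_members) + [truth.reference_name])
    half_width = (members.max() + outsiders.min()) / 2
    selected = pc_window(scores, truth.reference_name, axis=1, half_width=half_width)
    assert set(selected) == set(truth.cluster_members)


def test_component_window_trivial_half_widths(sim_catalog):
    catalog, truth = sim_catalog
    scaled = autoscale(filter_catalog(catalog).descriptor_matrix())
    scores = nipals_pca(scaled, 2).scores
    everyone = pc_window(scores, truth.reference_name, 1, half_width=np.inf)
    assert len(everyone) == len(scores) - 1
    nobody = pc_window(scores, truth.reference_name, 1, half_width=0.0)
    assert nobody == []
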