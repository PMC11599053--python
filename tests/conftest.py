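import numpy as np
import pandas as pd
import pytest

from isletnet import GenerationConfig, IsletArchitecture, generate_islet


def make_arch(positions, types, islet_id="toy"):
    """Build an architecture directly from coordinates and type labels."""
    pts = np.asarray(positions, dtype=float)
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(len(pts)),
            "cell_type": list(types),
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
        }
    )
    return IsletArchitecture(islet_id=islet_id, cells=cells)


def random_arch(rng, n_cells=None, box=120.0):
    """Random architecture with unconstrained positions, for oracle checks.

    Positions are uniform in a cube (no minimum-separation guarantee): the
    contact and ablation code must not rely on generator guarantees.
    """
    n = n_cells or int(rng.integers(20, 201))
    pts = rng.uniform(-box / 2, box / 2, size=(n, 3))
    types = rng.choice(["beta", "alpha", "delta"], size=n, p=[0.5, 0.35, 0.15])
    # oracle tests need at least one of each relevant type
    types[0], types[1] = "beta", "delta"
    return make_arch(pts, types, islet_id=f"rand_{n}")


def brute_force_edges(arch, threshold):
    """Independent all-pairs contact oracle: strict Euclidean distance."""
    pts = arch.positions
    ids = arch.cells["cell_id"].to_numpy()
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    i, j = np.where(np.triu(d < threshold, k=1))
    return {(int(ids[a]), int(ids[b])) for a, b in zip(i, j)}


def brute_force_connected_fraction(arch, threshold, removed_beta_ids=()):
    """Delta-to-beta connected fraction recomputed from raw coordinates."""
    cells = arch.cells
    removed = set(removed_beta_ids)
    deltas = cells[cells.cell_type == "delta"]
    betas = cells[
        (cells.cell_type == "beta") & ~cells.cell_id.isin(removed)
    ]
    dp = deltas[["x_um", "y_um", "z_um"]].to_numpy()
    if len(betas) == 0:
        return 0.0
    bp = betas[["x_um", "y_um", "z_um"]].to_numpy()
    d = np.linalg.norm(dp[:, None, :] - bp[None, :, :], axis=-1)
    return float(np.mean((d < threshold).any(axis=1)))


@pytest.fixture(scope="session")
def human_islet():
    """One human-preset islet, shared across tests (generation is pure)."""
    return generate_islet(GenerationConfig(seed=42), islet_id="human_42")


@pytest.fixture
def small_config():
    return GenerationConfig(n_cells=120, seed=7)
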