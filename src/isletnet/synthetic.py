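"""Synthetic islet architectures and secretion datasets.

Real 3-D islet reconstructions (one nuclear coordinate per cell, typed
beta/alpha/delta) are rarely redistributable, so this module generates
stand-ins with the geometric and compositional statistics reported for human
and mouse islets: densely packed spheroids of hundreds to thousands of cells,
either with the intermingled cell-type arrangement typical of human islets or
the beta-core / alpha-delta-mantle arrangement typical of mouse islets.

Cells are placed by random sequential addition (RSA) inside a sphere: candidate
nuclear positions are drawn uniformly and rejected when closer than
``min_separation`` to an accepted nucleus. The islet radius follows from the
cell count, the minimum separation (read as a typical cell diameter) and a
target packing fraction. RSA in 3-D saturates near a volume fraction of 0.38,
so feasible packing fractions are well below the crystalline bound of 0.74.

The module also generates secretion datasets — per-islet-group insulin content
with glucagon and somatostatin secretion — by evaluating Hill dose-response
models forward and adding truncated Gaussian noise, mirroring the structure of
published content-versus-secretion point clouds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .secretion import HillModel, hill_eval

CELL_TYPES = ("beta", "alpha", "delta")

Layout = Literal["intermingled", "core_mantle"]

#: Cap on RSA rejection attempts per cell before declaring the packing
#: unsatisfiable.
MAX_ATTEMPTS_PER_CELL = 5000


class UnsatisfiablePackingError(RuntimeError):
    """Raised when RSA cannot place all cells at the requested density."""


@dataclass(frozen=True)
class GenerationConfig:
    """Parameters of one synthetic islet.

    Parameters
    ----------
    n_cells:
        Total number of cells in the islet.
    composition:
        Fractions of (beta, alpha, delta) cells; must sum to 1.
    layout:
        ``"intermingled"`` assigns types at random positions (human-like);
        ``"core_mantle"`` places beta cells innermost by radial rank
        (mouse-like).
    min_separation:
        Minimum pairwise nuclear distance, um. Doubles as the nominal cell
        diameter when deriving the islet radius.
    packing_fraction:
        Target volume fraction of ``min_separation``-diameter spheres within
        the islet sphere. Must lie in (0, 0.74]; values above ~0.38 are
        geometrically unreachable by RSA and will raise
        :class:`UnsatisfiablePackingError` at generation time.
    seed:
        Seed for the placement and type-assignment RNG.
    """

    n_cells: int = 1000
    composition: tuple[float, float, float] = (0.50, 0.35, 0.15)
    layout: Layout = "intermingled"
    min_separation: float = 10.0
    packing_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        comp = tuple(float(c) for c in self.composition)
        if len(comp) != 3 or any(c < 0 or c > 1 for c in comp):
            raise ValueError("composition must be three fractions in [0, 1]")
        if abs(sum(comp) - 1.0) > 1e-9:
            raise ValueError("composition fractions must sum to 1")
        if self.layout not in ("intermingled", "core_mantle"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not (0 < self.packing_fraction <= 0.74):
            raise ValueError("packing_fraction must lie in (0, 0.74]")
        object.__setattr__(self, "composition", comp)

    @property
    def islet_radius_um(self) -> float:
        """Islet sphere radius implied by count, separation and packing."""
        return (self.min_separation / 2.0) * (
            self.n_cells / self.packing_fraction
        ) ** (1.0 / 3.0)


@dataclass(frozen=True)
class IsletArchitecture:
    """One islet: typed 3-D nuclear positions plus the generating config.

    ``cells`` is a DataFrame with columns ``cell_id`` (int), ``cell_type``
    (one of beta/alpha/delta) and ``x_um``, ``y_um``, ``z_um`` (float, um).
    """

    islet_id: str
    cells: pd.DataFrame
    generation_params: GenerationConfig | None = None

    def __post_init__(self) -> None:
        required = {"cell_id", "cell_type", "x_um", "y_um", "z_um"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValueError(f"cells table missing columns {sorted(missing)}")
        if len(self.cells) < 1:
            raise ValueError("architecture must contain at least one cell")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_id values must be unique within an islet")
        bad = set(self.cells["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise ValueError(f"unknown cell types {sorted(bad)}")
        coords = self.cells[["x_um", "y_um", "z_um"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("nuclear coordinates must be finite")

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) array of nuclear coordinates in um."""
        return self.cells[["x_um", "y_um", "z_um"]].to_numpy(float)

    def type_counts(self) -> dict[str, int]:
        vc = self.cells["cell_type"].value_counts()
        return {t: int(vc.get(t, 0)) for t in CELL_TYPES}


#: Default presets. The "human" preset emulates the intermingled architecture
#: and literature-typical composition of human islets; "mouse" the
#: beta-core / alpha-delta-mantle layout of rodent islets.
PRESETS: dict[str, GenerationConfig] = {
    "human": GenerationConfig(
        n_cells=1000,
        composition=(0.50, 0.35, 0.15),
        layout="intermingled",
        min_separation=10.0,
        packing_fraction=0.35,
        seed=0,
    ),
    "mouse": GenerationConfig(
        n_cells=1000,
        composition=(0.75, 0.19, 0.06),
        layout="core_mantle",
        min_separation=10.0,
        packing_fraction=0.35,
        seed=0,
    ),
}


def _type_labels(n_cells: int, composition: Sequence[float]) -> list[str]:
    """Integer type counts by largest-remainder apportionment."""
    exact = [n_cells * c for c in composition]
    counts = [int(math.floor(e)) for e in exact]
    short = n_cells - sum(counts)
    remainders = sorted(
        range(3), key=lambda i: (exact[i] - counts[i]), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    labels: list[str] = []
    for t, c in zip(CELL_TYPES, counts):
        labels.extend([t] * c)
    return labels


def _rsa_positions(
    n: int, radius: float, min_sep: float, rng: np.random.Generator
) -> np.ndarray:
    """Random sequential addition of points in a sphere.

    Uniform candidates inside the sphere of the given radius are rejected when
    within ``min_sep`` of an accepted point; occupancy is tracked on a cubic
    grid of side ``min_sep`` so each candidate checks only 27 grid cells.
    """
    pts = np.empty((n, 3))
    grid: dict[tuple[int, int, int], list[int]] = {}
    sep2 = min_sep * min_sep
    inv = 1.0 / min_sep
    neighbor_offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    for i in range(n):
        for _ in range(MAX_ATTEMPTS_PER_CELL):
            # uniform point in a ball: isotropic direction, radius ~ U^(1/3)
            v = rng.normal(size=3)
            norm = math.sqrt(v @ v)
            if norm == 0.0:
                continue
            r = radius * rng.random() ** (1.0 / 3.0)
            p = v * (r / norm)
            kx = int(math.floor(p[0] * inv))
            ky = int(math.floor(p[1] * inv))
            kz = int(math.floor(p[2] * inv))
            ok = True
            for dx, dy, dz in neighbor_offsets:
                for j in grid.get((kx + dx, ky + dy, kz + dz), ()):
                    d = pts[j] - p
                    if d @ d < sep2:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                pts[i] = p
                grid.setdefault((kx, ky, kz), []).append(i)
                break
        else:
            raise UnsatisfiablePackingError(
                f"placed {i}/{n} cells before exceeding "
                f"{MAX_ATTEMPTS_PER_CELL} attempts; the packing_fraction "
                "(with this min_separation) is too high for random "
                "sequential addition — reduce packing_fraction"
            )
    return pts


def generate_islet(
    config: GenerationConfig, islet_id: str = "islet_0"
) -> IsletArchitecture:
    """Generate one synthetic islet architecture.

    Placement is RSA inside a sphere whose radius follows from the config (see
    :attr:`GenerationConfig.islet_radius_um`); type assignment respects the
    requested composition exactly up to integer rounding. Deterministic for a
    fixed config (seed included).

    Raises
    ------
    UnsatisfiablePackingError
        If a cell cannot be placed within the per-cell attempt cap.
    """
    rng = np.random.default_rng(config.seed)
    pts = _rsa_positions(
        config.n_cells, config.islet_radius_um, config.min_separation, rng
    )
    labels = _type_labels(config.n_cells, config.composition)
    n_beta = labels.count("beta")
    if config.layout == "intermingled":
        types = np.array(labels)
        rng.shuffle(types)
    else:  # core_mantle: beta cells innermost by radial rank
        radii = np.linalg.norm(pts, axis=1)
        order = np.argsort(radii, kind="stable")
        types = np.empty(config.n_cells, dtype=object)
        types[order[:n_beta]] = "beta"
        mantle = np.array([t for t in labels if t != "beta"])
        rng.shuffle(mantle)
        types[order[n_beta:]] = mantle
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(config.n_cells, dtype=int),
            "cell_type": pd.array(types, dtype=str),
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "z_um": pts[:, 2],
        }
    )
    return IsletArchitecture(
        islet_id=islet_id, cells=cells, generation_params=config
    )


def generate_islet_cohort(
    config: GenerationConfig, n_islets: int, seed: int
) -> list[IsletArchitecture]:
    """Generate ``n_islets`` architectures with sub-seeds ``seed + i``.

    Every islet shares the config apart from its seed; islet ids are
    ``islet_000`` ... zero-padded.
    """
    if n_islets < 1:
        raise ValueError("n_islets must be >= 1")
    cohort = []
    for i in range(n_islets):
        cfg = replace(config, seed=seed + i)
        cohort.append(generate_islet(cfg, islet_id=f"islet_{i:03d}"))
    return cohort


def generate_secretion_dataset(
    glucagon_model: HillModel,
    somatostatin_model: HillModel,
    n_groups: int,
    content_range: tuple[float, float] = (5.0, 500.0),
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a per-islet-group secretion dataset from two Hill models.

    Insulin contents are drawn log-uniformly over ``content_range`` (nmol per
    islet group) so both limbs of the sigmoids are sampled; glucagon and
    somatostatin secretion are the Hill-model evaluations plus additive
    Gaussian noise of standard deviation ``noise_sd``, truncated at zero.

    Returns a DataFrame with columns ``group_id``, ``insulin_content_nmol``,
    ``glucagon``, ``somatostatin``.
    """
    if n_groups < 3:
        raise ValueError("n_groups must be >= 3 (required for any fit)")
    low, high = content_range
    if not (0 < low < high):
        raise ValueError("content_range must satisfy 0 < low < high")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    content = np.exp(
        rng.uniform(math.log(low), math.log(high), size=n_groups)
    )
    glucagon = hill_eval(glucagon_model, content)
    somatostatin = hill_eval(somatostatin_model, content)
    if noise_sd > 0:
        glucagon = glucagon + rng.normal(0.0, noise_sd, size=n_groups)
        somatostatin = somatostatin + rng.normal(0.0, noise_sd, size=n_groups)
    return pd.DataFrame(
        {
            "group_id": np.arange(n_groups, dtype=int),
            "insulin_content_nmol": content,
            "glucagon": np.maximum(glucagon, 0.0),
            "somatostatin": np.maximum(somatostatin, 0.0),
        }
    )
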