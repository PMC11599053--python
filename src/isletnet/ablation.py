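"""Progressive random beta-cell ablation and connectivity decay.

Type-1 diabetes destroys beta-cells while sparing delta-cells. This module
mimics that progression on a contact graph: beta-cells are deleted one at a
time in a uniformly random order and, after every deletion, the fraction of
delta-cells still contacting at least one beta-cell is recorded. Because
delta-cells typically touch many beta-cells, this connectivity stays high
until the large majority of beta-cells are gone, then collapses — the network
analogue of the clinical observation that a small residual beta-cell mass
suffices to keep the delta-cell "electric brake" engaged.

Trajectories from islets with different beta-cell counts are aligned on a
common deleted-fraction grid by last-observation-carried-forward, averaged
over random deletion orders within each islet, then averaged across islets
with a t-distribution 95% confidence interval over the islet means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactGraph, build_contact_graph
from .synthetic import IsletArchitecture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AblationCurve:
    """Connectivity-decay summary over a cohort of islets.

    ``fraction_deleted`` is the common grid f in [0, 1]; ``mean`` the
    across-islet mean of per-islet mean connected fractions C(f);
    ``ci_low``/``ci_high`` the 95% t-interval over islet means (equal to the
    mean when only one islet contributes). ``islet_means`` has one row per
    islet.
    """

    fraction_deleted: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    islet_means: np.ndarray
    islet_ids: tuple[str, ...]
    n_replicates_per_islet: int
    seed: int

    @property
    def n_islets(self) -> int:
        return len(self.islet_ids)

    def value_at(self, fraction: float) -> float:
        """Mean connected fraction at the grid point nearest ``fraction``."""
        idx = int(np.argmin(np.abs(self.fraction_deleted - fraction)))
        return float(self.mean[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_deleted": self.fraction_deleted,
                "mean_connected_fraction": self.mean,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


class CrossingResult(NamedTuple):
    """First grid fraction at which the mean curve drops below a level."""

    fraction_deleted: float
    crossed: bool


def _delta_beta_adjacency(
    contact: ContactGraph,
) -> tuple[list[int], list[int], dict[int, list[int]], np.ndarray]:
    """Index the delta/beta structure of a graph for incremental updates.

    Returns beta ids, delta ids, a map beta id -> indices of its delta
    neighbours (positions in the delta list), and the per-delta beta-neighbour
    counts.
    """
    g = contact.graph
    betas = contact.cells_of_type("beta")
    deltas = contact.cells_of_type("delta")
    delta_index = {d: i for i, d in enumerate(deltas)}
    counts = np.zeros(len(deltas), dtype=int)
    beta_to_deltas: dict[int, list[int]] = {b: [] for b in betas}
    for b in betas:
        for nb in g.neighbors(b):
            i = delta_index.get(nb)
            if i is not None:
                beta_to_deltas[b].append(i)
                counts[i] += 1
    return betas, deltas, beta_to_deltas, counts


def ablate_trajectory(
    contact: ContactGraph, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """One random beta-cell deletion trajectory.

    Deletes beta-cells one at a time in a uniformly random order; after each
    deletion the delta-to-beta connected fraction is recomputed (incrementally,
    via per-delta beta-neighbour counts, which is exactly equivalent to a full
    recomputation). Returns an (n_beta + 1, 2) array of
    (fraction_deleted, connected_fraction), from no deletions through all
    beta-cells removed; the final point is always exactly 0.
    """
    betas, deltas, beta_to_deltas, counts = _delta_beta_adjacency(contact)
    if not betas:
        raise ValueError("graph contains no beta cells to ablate")
    if not deltas:
        raise ValueError("graph contains no delta cells: fraction undefined")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    order = rng.permutation(len(betas))
    n_beta, n_delta = len(betas), len(deltas)
    connected = int(np.count_nonzero(counts))
    out = np.empty((n_beta + 1, 2))
    out[0] = (0.0, connected / n_delta)
    for step, bi in enumerate(order, start=1):
        for di in beta_to_deltas[betas[bi]]:
            counts[di] -= 1
            if counts[di] == 0:
                connected -= 1
        out[step] = (step / n_beta, connected / n_delta)
    return out


def _on_grid(traj: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Step-interpolate a trajectory onto the grid (last value carried)."""
    n_beta = len(traj) - 1
    idx = np.floor(grid * n_beta + 1e-9).astype(int)
    return traj[idx, 1]


def run_ablation(
    cohort: Iterable[IsletArchitecture],
    threshold_um: float = 30.0,
    n_replicates: int = 20,
    grid_step: float = 0.01,
    seed: int = 0,
) -> AblationCurve:
    """Monte-Carlo ablation over a cohort of islet architectures.

    Per islet, ``n_replicates`` independent random deletion orders are run and
    averaged; the across-islet mean and its 95% t-interval summarise the
    cohort. Islets lacking beta or delta cells are skipped with a warning;
    if all are skipped an error is raised.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("cohort is empty")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if not (0 < grid_step <= 0.5):
        raise ValueError("grid_step must lie in (0, 0.5]")
    n_grid = int(round(1.0 / grid_step)) + 1
    grid = np.linspace(0.0, 1.0, n_grid)
    ss = np.random.SeedSequence(seed)
    islet_means: list[np.ndarray] = []
    islet_ids: list[str] = []
    for k, arch in enumerate(cohort):
        contact = build_contact_graph(arch, threshold_um)
        counts = arch.type_counts()
        if counts["beta"] == 0 or counts["delta"] == 0:
            logger.warning(
                "skipping islet %s: needs >=1 beta and >=1 delta cell "
                "(beta=%d, delta=%d)",
                arch.islet_id,
                counts["beta"],
                counts["delta"],
            )
            continue
        reps = np.empty((n_replicates, n_grid))
        # one spawned stream per (islet, replicate), order-stable
        children = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(k,)
        ).spawn(n_replicates)
        for r in range(n_replicates):
            traj = ablate_trajectory(
                contact, np.random.default_rng(children[r])
            )
            reps[r] = _on_grid(traj, grid)
        islet_means.append(reps.mean(axis=0))
        islet_ids.append(arch.islet_id)
    if not islet_means:
        raise ValueError("no islet in the cohort had both beta and delta cells")
    im = np.vstack(islet_means)
    mean = im.mean(axis=0)
    n = im.shape[0]
    if n > 1:
        sem = im.std(axis=0, ddof=1) / np.sqrt(n)
        tcrit = stats.t.ppf(0.975, df=n - 1)
        lo, hi = mean - tcrit * sem, mean + tcrit * sem
    else:
        lo, hi = mean.copy(), mean.copy()
    return AblationCurve(
        fraction_deleted=grid,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        islet_means=im,
        islet_ids=tuple(islet_ids),
        n_replicates_per_islet=n_replicates,
        seed=seed,
    )


def threshold_crossing(
    curve: AblationCurve, level: float = 0.9
) -> CrossingResult:
    """Smallest grid fraction at which the mean curve drops below ``level``.

    Returns fraction 1.0 with ``crossed=False`` when the curve never drops
    below the level.
    """
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    if len(curve.fraction_deleted) == 0:
        raise ValueError("curve is empty")
    below = curve.mean < level
    if not below.any():
        return CrossingResult(1.0, False)
    idx = int(np.argmax(below))
    return CrossingResult(float(curve.fraction_deleted[idx]), True)
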