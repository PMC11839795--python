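"""Synthetic labelled phantoms and toy planning fixtures.

Real inputs to the pipeline are atlas-parcellated brain volumes (hundreds of
named regions at 0.8 mm isotropic spacing) overlaid with vessel and tract
masks. The phantom generator emulates that product at desk scale: a 3D label
map partitioned into Voronoi regions around seeded points, each region given
a clinician-style risk score, plus optional tube-shaped high-risk structures
standing in for vessels/tracts, an optional low-risk corridor channel from a
surface entry point to a deep target, and a designated target region. The
geometry is deliberately non-anatomical — the downstream pipeline only needs
named labels with scores on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidSpecError
from .planner import QLearningConfig, dijkstra_oracle
from .risk import RiskTable
from .volume import LabeledVolume, RiskVolume

#: risk levels seen in clinician-rated parcellation tables
SCORE_LEVELS = (0.1, 0.3, 0.5, 0.6, 0.7, 1.0)


@dataclass(frozen=True)
class CorridorSpec:
    """A low-risk channel from a boundary entry voxel to an interior target."""

    entry: tuple[int, int, int]
    target_center: tuple[int, int, int]
    channel_radius_mm: float = 2.0
    channel_score: float = 0.05

    def __post_init__(self):
        if self.channel_radius_mm <= 0:
            raise InvalidSpecError("channel radius must be > 0")
        if not 0.0 <= self.channel_score <= 0.1:
            raise InvalidSpecError("corridor channel score must be <= 0.1")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic labelled volume.

    Defaults mirror the scale of a high-resolution T1 parcellation grid
    (0.8 mm isotropic spacing) shrunk to desk size.
    """

    dims: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)
    n_regions: int = 12
    n_tubes: int = 2
    corridor: CorridorSpec | None = None
    background_score: float | None = None
    tube_radius_mm: float = 1.2
    seed: int = 0

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing_mm)
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing_mm", spacing)
        if len(dims) != 3 or any(d < 8 for d in dims):
            raise InvalidSpecError(f"dims must be 3 values each >= 8, got {dims}")
        if any(s <= 0 for s in spacing):
            raise InvalidSpecError(f"spacing must be > 0, got {spacing}")
        if self.n_regions < 1:
            raise InvalidSpecError("n_regions must be >= 1")
        if self.n_regions > int(np.prod(dims)):
            raise InvalidSpecError("n_regions exceeds the voxel count")
        if self.n_tubes < 0:
            raise InvalidSpecError("n_tubes must be >= 0")
        if self.corridor is not None:
            entry = tuple(int(c) for c in self.corridor.entry)
            center = tuple(int(c) for c in self.corridor.target_center)
            if any(not 0 <= c < d for c, d in zip(entry, dims)):
                raise InvalidSpecError(f"corridor entry {entry} outside volume")
            if not any(c in (0, d - 1) for c, d in zip(entry, dims)):
                raise InvalidSpecError(
                    f"corridor entry {entry} must lie on the volume boundary")
            if any(not 1 <= c < d - 1 for c, d in zip(center, dims)):
                raise InvalidSpecError(
                    f"corridor target center {center} must be interior")
        if self.background_score is not None and not 0.0 <= self.background_score <= 1.0:
            raise InvalidSpecError("background_score must be in [0, 1]")


def _dist_to_polyline_mm(centers: np.ndarray, points_mm: np.ndarray) -> np.ndarray:
    """Min distance from every voxel centre to a polyline (both in mm)."""
    best = np.full(centers.shape[:-1], np.inf)
    for a, b in zip(points_mm[:-1], points_mm[1:]):
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(centers - a, axis=-1)
        else:
            t = np.clip(((centers - a) @ ab) / denom, 0.0, 1.0)
            d = np.linalg.norm(centers - (a + t[..., None] * ab), axis=-1)
        np.minimum(best, d, out=best)
    return best


def generate_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, RiskTable]:
    """Build a labelled phantom volume and a matching risk table.

    Layers, painted in order (later wins): Voronoi base regions; high-risk
    tubes (score 1.0); the optional low-risk corridor channel; the corridor's
    target region (its own label). Every label present in the volume has an
    entry in the returned table, and identical specs give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    dims = spec.dims
    spacing = np.asarray(spec.spacing_mm)
    extent = (np.asarray(dims) - 1) * spacing

    centers = np.stack(
        np.meshgrid(*(np.arange(d) * s for d, s in zip(dims, spacing)),
                    indexing="ij"),
        axis=-1,
    )
    flat_centers = centers.reshape(-1, 3)

    # Voronoi base parcellation
    seeds = rng.uniform(0.0, 1.0, size=(spec.n_regions, 3)) * extent
    _, nearest = cKDTree(seeds).query(flat_centers)
    labels = (nearest + 1).astype(np.int32).reshape(dims)
    names = {i + 1: f"region_{i + 1:02d}" for i in range(spec.n_regions)}
    if spec.background_score is not None:
        scores = {n: float(spec.background_score) for n in names.values()}
    else:
        scores = {n: float(rng.choice(SCORE_LEVELS)) for n in names.values()}

    next_label = spec.n_regions + 1

    # high-risk tubes (vessel/tract stand-ins): voxels within a fixed radius
    # of a random polyline
    for t in range(spec.n_tubes):
        n_pts = int(rng.integers(3, 6))
        pts = rng.uniform(0.0, 1.0, size=(n_pts, 3)) * extent
        d = _dist_to_polyline_mm(centers, pts)
        labels[d <= spec.tube_radius_mm] = next_label
        names[next_label] = f"tube_{t + 1:02d}"
        scores[names[next_label]] = 1.0
        next_label += 1

    target: set = set()
    if spec.corridor is not None:
        cor = spec.corridor
        entry_mm = np.asarray(cor.entry) * spacing
        center_mm = np.asarray(cor.target_center) * spacing
        d = _dist_to_polyline_mm(centers, np.stack([entry_mm, center_mm]))
        labels[d <= cor.channel_radius_mm] = next_label
        names[next_label] = "corridor"
        scores["corridor"] = float(cor.channel_score)
        next_label += 1
        # target region: the channel-radius ball around the target centre
        tdist = np.linalg.norm(centers - center_mm, axis=-1)
        tmask = tdist <= cor.channel_radius_mm
        tmask[tuple(cor.target_center)] = True
        labels[tmask] = next_label
        names[next_label] = "target"
        scores["target"] = 0.0
        target = set(map(tuple, np.argwhere(tmask).tolist()))
        next_label += 1

    volume = LabeledVolume(labels, spec.spacing_mm, names)
    # drop names painted over entirely so the table matches the volume 1:1
    present = {names[int(v)] for v in volume.present_labels()}
    table = RiskTable({n: s for n, s in scores.items() if n in present})
    volume.names = {k: v for k, v in names.items() if v in present}
    if spec.corridor is not None:
        volume.target_voxels = target  # type: ignore[attr-defined]
    return volume, table


@dataclass
class ToyCase:
    """A tiny named planning problem with a brute-force-verified optimum."""

    risk_volume: RiskVolume
    entry: tuple[int, int, int]
    target: frozenset
    oracle_cost: float
    description: str
    config: QLearningConfig = field(default_factory=QLearningConfig)

    def __post_init__(self):
        self.target = frozenset(tuple(int(c) for c in t) for t in self.target)
        if not self.target:
            raise InvalidSpecError("toy case target must be non-empty")
        if tuple(self.entry) in self.target:
            raise InvalidSpecError("toy case entry must lie outside the target")
        if self.oracle_cost < 0:
            raise InvalidSpecError("oracle cost must be >= 0")


def two_corridor_benchmark(low: float = 0.05, high: float = 0.5, n: int = 16):
    """A ranking benchmark: hostile background (risk 1.0) pierced by two
    straight channels of unequal risk meeting at a shared deep target.

    Returns ``(risk_volume, cases)`` where the two
    :class:`~qpath.report.ApproachCase` entries use the channels themselves
    as their hand corridors. The low-risk channel's approach should win any
    lowest-Q ranking.
    """
    from .report import ApproachCase

    if not 8 <= n:
        raise InvalidSpecError("benchmark grid must be at least 8 wide")
    risk = np.ones((n, n, n))
    mid = n // 2
    risk[: mid + 1, mid, mid] = float(low)   # channel A, from face i=0
    risk[mid, : mid + 1, mid] = float(high)  # channel B, from face j=0
    risk[mid, mid, mid] = 0.0
    rv = RiskVolume(risk, (1.0, 1.0, 1.0))
    target = frozenset({(mid, mid, mid)})
    cases = [
        ApproachCase("low-risk corridor",
                     {(i, mid, mid) for i in range(mid + 1)},
                     (0, mid, mid), target),
        ApproachCase("high-risk corridor",
                     {(mid, j, mid) for j in range(mid + 1)},
                     (mid, 0, mid), target),
    ]
    return rv, cases


def _toy_grids() -> dict:
    free_line = np.zeros((1, 1, 5))

    center_block = np.zeros((3, 3, 1))
    center_block[1, 1, 0] = 1.0

    wall = np.zeros((5, 5, 1))
    wall[:, 2, 0] = 1.0
    wall[3, 2, 0] = 0.0  # the gap

    return {
        "free_line": (
            free_line, (0, 0, 0), {(0, 0, 4)},
            "1x1x5 zero-risk corridor; the only path is the straight line",
        ),
        "center_block": (
            center_block, (0, 0, 0), {(2, 2, 0)},
            "3x3 grid with a risk-1 centre; detouring beats the diagonal",
        ),
        "wall_with_gap": (
            wall, (0, 0, 0), {(4, 4, 0)},
            "5x5 grid with a risk-1 wall pierced by one gap voxel",
        ),
    }


TOY_CASE_NAMES = tuple(_toy_grids())


def generate_toy_case(name: str, config: QLearningConfig | None = None) -> ToyCase:
    """Build a named regression fixture; its ``oracle_cost`` is recomputed by
    the Dijkstra oracle under the given config (default: 26-connectivity,
    step cost 0.01), so configuration changes propagate rather than staling a
    stored constant."""
    registry = _toy_grids()
    if name not in registry:
        raise KeyError(
            f"unknown toy case {name!r}; available: {', '.join(registry)}")
    grid, entry, target, description = registry[name]
    config = config or QLearningConfig()
    rv = RiskVolume(grid, (1.0, 1.0, 1.0))
    _, cost = dijkstra_oracle(rv, entry, target, config)
    return ToyCase(rv, entry, frozenset(target), cost, description, config)
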