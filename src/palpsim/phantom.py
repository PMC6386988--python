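"""Virtual silicone phantom: stiffness field, contact force, indentation protocol.

The phantom is a cuboidal soft-silicone block (default 100 x 100 x 15 mm)
with hemispherical inclusions of stiffer polymers buried under the surface.
Each material is characterized by a single vertical stiffness value
(slope of normal force vs. indentation depth, N/mm); the inclusion's
surface footprint disk carries the inclusion material's stiffness directly,
with an optional linear blend band at the disk margin.

Coordinates: origin at one block corner, X-Y in [0, size] mm on the surface,
indentation depth z >= 0 measured into the surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MaterialSpec",
    "Inclusion",
    "Phantom",
    "IndentationSeries",
    "StiffnessSummary",
    "PhantomGenerationError",
    "DEFAULT_MATERIALS",
    "DEFAULT_MATRIX",
    "DEFAULT_INCLUSION_MATERIALS",
    "generate_phantom",
    "local_stiffness",
    "contact_force",
    "simulate_indentation",
    "characterize_stiffness",
    "save_phantom",
    "load_phantom",
    "save_indentation_series",
    "load_indentation_series",
]


@dataclass(frozen=True)
class MaterialSpec:
    """A polymer with its measured vertical stiffness (N/mm)."""

    name: str
    stiffness_k: float

    def __post_init__(self) -> None:
        if not self.stiffness_k > 0:
            raise ValueError(f"stiffness_k must be > 0, got {self.stiffness_k}")


# Measured vertical stiffnesses of the cast polymers, N/mm.
DEFAULT_MATERIALS: dict[str, MaterialSpec] = {
    "DS10": MaterialSpec("DS10", 2.14),  # Dragon Skin 10 (matrix, softest)
    "DS20": MaterialSpec("DS20", 2.74),  # Dragon Skin 20
    "DS30": MaterialSpec("DS30", 2.88),  # Dragon Skin 30
    "PDMS": MaterialSpec("PDMS", 3.68),  # Sylgard 184
    "SC": MaterialSpec("SC", 3.69),      # Sorta Clear 40 (stiffest)
}

DEFAULT_MATRIX = DEFAULT_MATERIALS["DS10"]
DEFAULT_INCLUSION_MATERIALS = ("DS20", "DS30", "PDMS", "SC")


@dataclass(frozen=True)
class Inclusion:
    """Hemispherical stiff inclusion, described by its surface footprint."""

    center_xy: tuple[float, float]
    material: MaterialSpec
    radius: float = 5.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be > 0, got {self.radius}")


@dataclass
class Phantom:
    """Cuboidal block with a soft matrix and stiffer hemispherical inclusions."""

    size_xyz: tuple[float, float, float] = (100.0, 100.0, 15.0)
    matrix: MaterialSpec = DEFAULT_MATRIX
    inclusions: list[Inclusion] = field(default_factory=list)
    blend_width: float = 0.0

    @property
    def footprint(self) -> tuple[float, float]:
        return (self.size_xyz[0], self.size_xyz[1])

    def material_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for inc in self.inclusions:
            counts[inc.material.name] = counts.get(inc.material.name, 0) + 1
        return counts

    def validate(self, margin: float = 0.0) -> None:
        """Check containment and pairwise non-overlap of inclusions."""
        sx, sy = self.footprint
        for inc in self.inclusions:
            x, y = inc.center_xy
            r = inc.radius + margin
            if not (r <= x <= sx - r and r <= y <= sy - r):
                raise ValueError(
                    f"inclusion {inc.material.name} at {inc.center_xy} "
                    f"violates the {margin} mm edge margin"
                )
        centers = np.array([i.center_xy for i in self.inclusions], dtype=float)
        radii = np.array([i.radius for i in self.inclusions], dtype=float)
        for i in range(len(self.inclusions)):
            for j in range(i + 1, len(self.inclusions)):
                d = float(np.hypot(*(centers[i] - centers[j])))
                if d <= radii[i] + radii[j]:
                    raise ValueError(
                        f"inclusions {i} and {j} overlap (center distance {d:.2f} mm)"
                    )


@dataclass
class IndentationSeries:
    """Paired indentation depths (mm) and vertical forces (N), strictly increasing in depth."""

    depths: np.ndarray
    forces: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.depths.shape != self.forces.shape or self.depths.ndim != 1:
            raise ValueError("depths and forces must be 1-D arrays of equal length")
        if len(self.depths) > 1 and not np.all(np.diff(self.depths) > 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.forces < 0):
            raise ValueError("forces must be non-negative")

    def __len__(self) -> int:
        return len(self.depths)


class PhantomGenerationError(RuntimeError):
    """Rejection sampling failed to place an inclusion."""


def generate_phantom(
    *,
    size_xyz: tuple[float, float, float] = (100.0, 100.0, 15.0),
    matrix: MaterialSpec = DEFAULT_MATRIX,
    inclusion_materials: dict[str, MaterialSpec] | None = None,
    replicas: int = 3,
    radius: float = 5.0,
    edge_margin: float = 5.0,
    blend_width: float = 0.0,
    max_attempts: int = 10_000,
    seed: int = 0,
) -> Phantom:
    """Place ``replicas`` hemispherical inclusions of each material uniformly
    at random on the block surface, by rejection sampling.

    Placement respects an edge margin of ``radius + edge_margin`` and pairwise
    non-overlap (center distance > sum of radii).  The layout is a pure
    function of the arguments and ``seed``.

    Raises
    ------
    PhantomGenerationError
        If an inclusion cannot be placed within ``max_attempts`` draws.
    """
    if inclusion_materials is None:
        inclusion_materials = {
            n: DEFAULT_MATERIALS[n] for n in DEFAULT_INCLUSION_MATERIALS
        }
    sx, sy = size_xyz[0], size_xyz[1]
    lo, hi_x, hi_y = radius + edge_margin, sx - radius - edge_margin, sy - radius - edge_margin
    if lo >= hi_x or lo >= hi_y:
        raise ValueError("inclusions of the requested radius/margin do not fit the block")

    rng = np.random.default_rng(seed)
    placed: list[Inclusion] = []
    for name in sorted(inclusion_materials):
        mat = inclusion_materials[name]
        for rep in range(replicas):
            for _ in range(max_attempts):
                x = rng.uniform(lo, hi_x)
                y = rng.uniform(lo, hi_y)
                ok = all(
                    np.hypot(x - inc.center_xy[0], y - inc.center_xy[1])
                    > radius + inc.radius
                    for inc in placed
                )
                if ok:
                    placed.append(Inclusion((x, y), mat, radius))
                    break
            else:
                raise PhantomGenerationError(
                    f"could not place replica {rep + 1} of material {name} "
                    f"after {max_attempts} attempts"
                )
    return Phantom(size_xyz=size_xyz, matrix=matrix, inclusions=placed,
                   blend_width=blend_width)


def local_stiffness(phantom: Phantom, point_xy: tuple[float, float]) -> float:
    """Vertical stiffness (N/mm) of the phantom surface at ``point_xy``.

    Inside an inclusion footprint disk (horizontal distance to center
    <= radius, boundary inclusive) the inclusion material's stiffness applies;
    beyond radius + blend_width the matrix stiffness applies; in between the
    two are linearly interpolated.
    """
    x, y = point_xy
    sx, sy = phantom.footprint
    if not (0.0 <= x <= sx and 0.0 <= y <= sy):
        raise ValueError(f"point {point_xy} outside the block footprint")
    k = phantom.matrix.stiffness_k
    # non-overlapping inclusions: at most one can be within radius + blend
    best = None
    for inc in phantom.inclusions:
        d = float(np.hypot(x - inc.center_xy[0], y - inc.center_xy[1]))
        excess = d - inc.radius
        if best is None or excess < best[0]:
            best = (excess, inc)
    if best is None:
        return k
    excess, inc = best
    if excess <= 0.0:
        return inc.material.stiffness_k
    if phantom.blend_width > 0.0 and excess < phantom.blend_width:
        w = excess / phantom.blend_width
        return (1.0 - w) * inc.material.stiffness_k + w * k
    return k


def contact_force(stiffness: float, indentation_depth: float) -> float:
    """Linear-elastic normal contact force F = k * z (N)."""
    if indentation_depth < 0:
        raise ValueError(f"indentation_depth must be >= 0, got {indentation_depth}")
    return stiffness * indentation_depth


def simulate_indentation(
    phantom: Phantom,
    point_xy: tuple[float, float],
    force_stop: float = 0.5,
    speed: float = 0.125,
    sample_rate: float = 100.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> IndentationSeries:
    """Simulate a constant-speed vertical indentation until ``force_stop``.

    Depth advances by ``speed / sample_rate`` per sample; force follows the
    local linear stiffness with optional additive Gaussian load-cell noise
    (clipped at zero).  The series ends at the first sample whose force
    reaches ``force_stop``.
    """
    if not force_stop > 0:
        raise ValueError("force_stop must be > 0")
    if not speed > 0:
        raise ValueError("speed must be > 0")
    k = local_stiffness(phantom, point_xy)
    dz = speed / sample_rate
    rng = np.random.default_rng(seed)
    depths: list[float] = []
    forces: list[float] = []
    z = 0.0
    while True:
        z += dz
        f = contact_force(k, z)
        if noise_sd > 0:
            f = max(0.0, f + rng.normal(0.0, noise_sd))
        depths.append(z)
        forces.append(f)
        if f >= force_stop:
            break
        if z > phantom.size_xyz[2]:
            raise RuntimeError("indentation exceeded block thickness before force_stop")
    return IndentationSeries(np.array(depths), np.array(forces))


@dataclass
class StiffnessSummary:
    """Per-trial stiffness estimates pooled across indentation trials."""

    estimates: np.ndarray  # slope per series, N/mm
    median: float
    iqr: float
    range: tuple[float, float]


def characterize_stiffness(series_set: list[IndentationSeries]) -> StiffnessSummary:
    """Estimate vertical stiffness from indentation trials.

    Per-series estimate is the ordinary least-squares slope of force against
    depth; the pooled summary reports the median, interquartile range and full
    range across trials.
    """
    if len(series_set) < 1:
        raise ValueError("need at least one indentation series")
    slopes = []
    for s in series_set:
        if len(s) < 2:
            raise ValueError("each series needs >= 2 points for a slope estimate")
        slope = np.polyfit(s.depths, s.forces, 1)[0]
        slopes.append(float(slope))
    est = np.array(slopes)
    q1, med, q3 = np.percentile(est, [25, 50, 75])
    return StiffnessSummary(
        estimates=est,
        median=float(med),
        iqr=float(q3 - q1),
        range=(float(est.min()), float(est.max())),
    )


# ---------------------------------------------------------------------------
# serialization

def phantom_to_dict(phantom: Phantom) -> dict:
    return {
        "size_xyz": list(phantom.size_xyz),
        "blend_width": phantom.blend_width,
        "matrix": {"name": phantom.matrix.name,
                   "stiffness": phantom.matrix.stiffness_k},
        "inclusions": [
            {
                "name": inc.material.name,
                "center_xy": list(inc.center_xy),
                "radius": inc.radius,
                "stiffness": inc.material.stiffness_k,
            }
            for inc in phantom.inclusions
        ],
    }


def phantom_from_dict(d: dict) -> Phantom:
    return Phantom(
        size_xyz=tuple(d["size_xyz"]),
        matrix=MaterialSpec(d["matrix"]["name"], d["matrix"]["stiffness"]),
        inclusions=[
            Inclusion(
                center_xy=tuple(i["center_xy"]),
                material=MaterialSpec(i["name"], i["stiffness"]),
                radius=i["radius"],
            )
            for i in d["inclusions"]
        ],
        blend_width=d.get("blend_width", 0.0),
    )


def save_phantom(phantom: Phantom, path: str | Path) -> None:
    """Write the layout as JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(phantom_to_dict(phantom), indent=2) + "\n")


def load_phantom(path: str | Path) -> Phantom:
    return phantom_from_dict(json.loads(Path(path).read_text()))


def save_indentation_series(series: IndentationSeries, path: str | Path) -> None:
    lines = ["depth_mm,force_N"]
    lines += [f"{float(z)!r},{float(f)!r}" for z, f in zip(series.depths, series.forces)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_indentation_series(path: str | Path) -> IndentationSeries:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return IndentationSeries(data[:, 0], data[:, 1])
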