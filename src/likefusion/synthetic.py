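"""Seeded generator of labeled phantoms and deformed atlas populations.

The phantom emulates a T1-weighted subcortical scene: ellipsoidal gray-matter
structures and a CSF-dark ventricle embedded in a white-matter "brain"
ellipsoid with a gray-matter shell and CSF exterior.  Atlas populations are
made by warping the phantom with random diffeomorphisms (smoothed white-noise
stationary velocity fields) plus per-atlas intensity jitter, so registration
and fusion can be exercised against known ground truth with no download.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from likefusion.lddmm import (
    Diffeomorphism,
    VelocityField,
    integrate_flow,
    warp_image,
    warp_labels,
)
from likefusion.volumes import IntensityVolume, LabelVolume, VoxelGrid

__all__ = [
    "StructureSpec", "PhantomSpec", "PopulationSpec", "Atlas",
    "generate_phantom", "random_diffeomorphism", "generate_population",
    "corrupt_atlas", "default_phantom_spec", "csf_adjacent_phantom_spec",
]

# reserved generic-tissue label ids (structures use 1..99)
CSF_LABEL, GM_LABEL, WM_LABEL = 101, 102, 103
TISSUE_NAMES = {CSF_LABEL: "csf", GM_LABEL: "gray_matter", WM_LABEL: "white_matter"}


@dataclass(frozen=True)
class StructureSpec:
    """One ellipsoidal structure: closed-form membership enables exhaustive oracles."""

    name: str
    center: tuple[float, float, float]  # vox
    radii: tuple[float, float, float]   # vox
    mean: float                          # intensity
    adjacency_offset: tuple[float, float, float] | None = None  # translate to touch a neighbor

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")

    @property
    def effective_center(self) -> tuple[float, float, float]:
        if self.adjacency_offset is None:
            return self.center
        return tuple(c + o for c, o in zip(self.center, self.adjacency_offset))


@dataclass(frozen=True)
class PhantomSpec:
    dims: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (0.9375, 0.9375, 1.2)
    structures: tuple[StructureSpec, ...] = ()
    tissue_means: tuple[float, float, float] = (30.0, 70.0, 100.0)  # CSF, GM, WM
    tissue_sds: tuple[float, float, float] = (7.0, 7.0, 7.0)
    noise_sd: float = 7.0
    brain_radius_frac: float = 0.44      # outer brain ellipsoid, fraction of dims
    gm_shell_frac: float = 0.09          # GM shell thickness, fraction of dims
    csf_pockets: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structures) < 1:
            raise ValueError("at least one structure required")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    n_atlases: int = 5
    amplitude: float = 4.0     # max displacement, vox
    smoothness: float = 6.0    # Gaussian width of the velocity field, vox
    jitter_sd: float = 3.0     # per-atlas intensity jitter, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_atlases < 1:
            raise ValueError("n_atlases must be >= 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class Atlas:
    """An intensity volume with co-registered labels; synthetic atlases also
    carry their ground-truth deformation for recovery tests."""

    atlas_id: str
    image: IntensityVolume
    labels: LabelVolume
    true_deformation: Diffeomorphism | None = None


def phantom_spec_to_yaml(spec: PhantomSpec, path) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh, default_flow_style=None)


def phantom_spec_from_yaml(path) -> PhantomSpec:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["structures"] = tuple(
        StructureSpec(**{**s, "center": tuple(s["center"]), "radii": tuple(s["radii"]),
                         "adjacency_offset": tuple(s["adjacency_offset"])
                         if s.get("adjacency_offset") else None})
        for s in raw.get("structures", ()))
    raw["csf_pockets"] = tuple((tuple(c), tuple(r)) for c, r in raw.get("csf_pockets", ()))
    for key in ("dims", "spacing", "tissue_means", "tissue_sds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return PhantomSpec(**raw)


def population_spec_to_yaml(spec: PopulationSpec, path) -> None:
    import dataclasses

    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(spec), fh)


def population_spec_from_yaml(path) -> PopulationSpec:
    import yaml

    with open(path) as fh:
        return PopulationSpec(**yaml.safe_load(fh))


def _ellipsoid_mask(dims: Sequence[int], center: Sequence[float],
                    radii: Sequence[float]) -> np.ndarray:
    idx = np.indices(tuple(dims), dtype=np.float64)
    q = sum(((idx[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    return q <= 1.0


def default_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Standard desk-scale fixture: 48^3 grid, 5 subcortical-like structures.

    Four gray-matter structures and one CSF-dark lateral-ventricle stand-in,
    all inside the white-matter ellipsoid; the ventricle touches the
    hippocampus the way the inferior horn does, and an unlabeled CSF pocket
    abuts both (the ambiguous boundary that intensity alone cannot resolve).
    """
    structures = (
        StructureSpec("hippocampus", (31.0, 22.0, 22.0), (6.0, 4.0, 4.0), 65.0),
        StructureSpec("amygdala", (31.0, 22.0, 30.5), (3.5, 3.5, 3.5), 68.0),
        StructureSpec("caudate", (16.0, 28.0, 27.0), (4.0, 5.5, 4.0), 72.0),
        StructureSpec("putamen", (16.0, 18.0, 22.0), (5.0, 4.0, 4.0), 78.0),
        StructureSpec("lateral_ventricle", (24.0, 30.0, 18.0), (4.5, 6.0, 4.5), 30.0),
    )
    return PhantomSpec(structures=structures, seed=seed,
                       csf_pockets=(((28.0, 28.0, 19.0), (3.5, 4.5, 3.5)),))


def csf_adjacent_phantom_spec(seed: int = 0) -> PhantomSpec:
    """Alias of the standard fixture emphasizing its CSF-adjacent ventricle."""
    return default_phantom_spec(seed)


def generate_phantom(spec: PhantomSpec) -> tuple[IntensityVolume, LabelVolume]:
    """Rasterize the phantom: later structures overwrite earlier on overlap.

    Intensity = per-voxel structure/tissue mean + Gaussian noise; tissue
    voxels use the tissue sd, structure voxels the spec noise sd.
    Deterministic given the spec seed.
    """
    dims = spec.dims
    grid = VoxelGrid.from_spacing(dims, spec.spacing)
    center = tuple((d - 1) / 2.0 for d in dims)
    outer = tuple(spec.brain_radius_frac * d for d in dims)
    inner = tuple((spec.brain_radius_frac - spec.gm_shell_frac) * d for d in dims)
    brain = _ellipsoid_mask(dims, center, outer)
    wm_core = _ellipsoid_mask(dims, center, inner)

    csf_m, gm_m, wm_m = spec.tissue_means
    csf_sd, gm_sd, wm_sd = spec.tissue_sds
    mean = np.full(dims, csf_m, dtype=np.float64)
    sd = np.full(dims, csf_sd, dtype=np.float64)
    mean[brain] = gm_m
    sd[brain] = gm_sd
    mean[wm_core] = wm_m
    sd[wm_core] = wm_sd
    for c, r in spec.csf_pockets:
        pocket = _ellipsoid_mask(dims, c, r)
        mean[pocket] = csf_m
        sd[pocket] = csf_sd

    labels = np.zeros(dims, dtype=np.int32)
    dictionary: dict[int, str] = {}
    for i, s in enumerate(spec.structures, start=1):
        c = s.effective_center
        if any(c[d] - s.radii[d] < 0 or c[d] + s.radii[d] > dims[d] - 1 for d in range(3)):
            raise ValueError(f"structure {s.name!r} does not fit within the grid")
        mask = _ellipsoid_mask(dims, c, s.radii)
        labels[mask] = i
        mean[mask] = s.mean
        sd[mask] = spec.noise_sd
        dictionary[i] = s.name

    rng = np.random.default_rng(spec.seed)
    values = mean + sd * rng.standard_normal(dims)
    return (IntensityVolume(grid, values.astype(np.float32)),
            LabelVolume(grid, labels, dictionary))


def random_diffeomorphism(dims: Sequence[int], amplitude: float, smoothness: float,
                          seed: int, n_steps: int = 8) -> Diffeomorphism:
    """Sample a random diffeomorphism from a smoothed white-noise velocity.

    White-noise vector field -> Gaussian smoothing of width ``smoothness`` ->
    rescaled to max displacement ``amplitude`` -> integrated as a stationary
    velocity over ``n_steps`` steps.  If the interior Jacobian determinant is
    not positive everywhere the amplitude is halved (at most 3 retries).
    """
    dims = tuple(int(d) for d in dims)
    if amplitude == 0:
        return Diffeomorphism.identity(dims)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((3, *dims))
    smooth = np.stack([gaussian_filter(noise[c], smoothness, mode="wrap") for c in range(3)])
    mag = np.sqrt((smooth ** 2).sum(axis=0)).max()
    if mag == 0:
        return Diffeomorphism.identity(dims)
    amp = amplitude
    for _ in range(4):
        v = (smooth * (amp / mag)).astype(np.float32)
        try:
            return integrate_flow(VelocityField(np.repeat(v[None], n_steps, axis=0)))
        except ValueError:
            amp *= 0.5
    raise ValueError("could not generate an invertible map after 3 amplitude halvings")


def generate_population(phantom: tuple[IntensityVolume, LabelVolume],
                        pop_spec: PopulationSpec) -> list[Atlas]:
    """Warp the phantom into a reproducible population of atlases."""
    image, labels = phantom
    dims = image.grid.dims
    seeds = np.random.SeedSequence(pop_spec.seed).generate_state(2 * pop_spec.n_atlases)
    atlases = []
    for i in range(pop_spec.n_atlases):
        diffeo = random_diffeomorphism(dims, pop_spec.amplitude, pop_spec.smoothness,
                                       seed=int(seeds[2 * i] % (2 ** 31)))
        warped_img = warp_image(image, diffeo)
        warped_lbl = warp_labels(labels, diffeo, mode="nearest")
        if pop_spec.jitter_sd > 0:
            rng = np.random.default_rng(int(seeds[2 * i + 1] % (2 ** 31)))
            jittered = warped_img.values + pop_spec.jitter_sd * rng.standard_normal(dims).astype(np.float32)
            warped_img = IntensityVolume(warped_img.grid, jittered)
        atlases.append(Atlas(f"atlas_{i:02d}", warped_img, warped_lbl, diffeo))
    return atlases


def corrupt_atlas(atlas: Atlas, mode: str, seed: int = 0) -> Atlas:
    """Make a deliberately wrong atlas for outlier-rejection tests.

    shift_labels: translate the label field by 6 voxels (image untouched);
    invert_contrast: reverse the intensity scale, labels untouched;
    large_warp: warp image and labels by an extra large random deformation.
    """
    if mode == "shift_labels":
        shifted = np.roll(atlas.labels.labels, 6, axis=0)
        labels = LabelVolume(atlas.labels.grid, shifted, atlas.labels.dictionary)
        return Atlas(atlas.atlas_id + "_shift", atlas.image, labels, None)
    if mode == "invert_contrast":
        vals = atlas.image.values
        inverted = (float(vals.max()) + float(vals.min())) - vals
        image = IntensityVolume(atlas.image.grid, inverted)
        return Atlas(atlas.atlas_id + "_invert", image, atlas.labels, None)
    if mode == "large_warp":
        dims = atlas.image.grid.dims
        diffeo = random_diffeomorphism(dims, amplitude=8.0, smoothness=8.0, seed=seed)
        image = warp_image(atlas.image, diffeo)
        labels = warp_labels(atlas.labels, diffeo, mode="nearest")
        return Atlas(atlas.atlas_id + "_warp", image, labels, None)
    raise ValueError(f"unknown corruption mode {mode!r}")
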