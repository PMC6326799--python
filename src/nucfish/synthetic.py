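"""Ground-truthed synthetic data for every pipeline stage.

The simulator emulates the raw material of the smFISH export experiments:

* :func:`generate_cell_scene` builds a cell as nested ellipsoids — cytoplasm,
  a DAPI-bright nucleus, a DAPI-dark nucleolus — and populates it with mRNA
  molecules of known species (intact / 5' part / 3' part / read-through /
  single probe), location class (nucleus / periphery / cytoplasm) and 5'->3'
  export orientation.
* :func:`render_image` is the optical forward model: structural channels
  (DAPI, a nuclear-pore ring marker, a cytoplasmic marker) plus
  diffraction-limited probe spots rendered as 3D Gaussians, with optional
  Poisson or Gaussian noise.
* :func:`generate_lfq_dataset` builds two-condition triplicate log-normal LFQ
  matrices with abundance-dependent (missing-not-at-random) missingness and
  planted enriched proteins.
* :func:`generate_protein_sequences` builds protein sequences with planted
  Q-rich 60-mers; :func:`generate_hit_tables` builds reciprocal homology hit
  tables with known orthology ground truth.

All randomness flows from explicit integer seeds; there is no global random
state. Channel names are fixed: ``dapi``, ``nup`` (pore ring), ``cyto``
(cytoplasmic marker) and the probe colours ``red`` (5'), ``ir`` (internal,
shown pink in the field's figures) and ``green`` (3').
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from nucfish.images import ImageStack

# probe colours and which species carries which (three-colour intramolecular
# probing: red = 5' end, ir = internal body, green = 3' end)
CHANNEL_DAPI = "dapi"
CHANNEL_PORE = "nup"
CHANNEL_CYTO = "cyto"
PROBE_CHANNELS = ("red", "ir", "green")

SPECIES_CHANNELS: dict[str, tuple[str, ...]] = {
    "intact": ("red", "ir", "green"),
    "five_prime_part": ("red", "ir"),
    "three_prime_part": ("ir", "green"),
    # a read-through molecule spans two adjacent genes; it carries all three
    # colours and is told apart from "intact" only by the probe map in use
    "readthrough": ("red", "ir", "green"),
    "single_probe": ("red",),
}

LOCATIONS = ("nucleus", "periphery", "cytoplasm")


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class SceneGeometry:
    """Nested-ellipsoid cell geometry, all lengths in micrometres.

    Defaults approximate a procyclic trypanosome around its nucleus: a
    ~1 um-radius nucleus with a ~0.35 um nucleolus, inside a cytoplasm
    ellipsoid a few micrometres across.
    """

    cell_radii: tuple[float, float, float] = (1.8, 2.6, 2.6)
    nucleus_radii: tuple[float, float, float] = (1.0, 1.1, 1.1)
    nucleolus_radius: float = 0.35
    nucleolus_offset: tuple[float, float, float] = (0.0, 0.3, 0.0)

    def validate(self) -> None:
        if any(r <= 0 for r in self.cell_radii + self.nucleus_radii):
            raise ValueError("all radii must be positive")
        if self.nucleolus_radius <= 0:
            raise ValueError("nucleolus_radius must be positive")
        # nucleolus strictly inside nucleus
        off = np.asarray(self.nucleolus_offset)
        nuc = np.asarray(self.nucleus_radii)
        u = np.sqrt(np.sum((off / nuc) ** 2))
        if u + self.nucleolus_radius / min(self.nucleus_radii) >= 1.0:
            raise ValueError("nucleolus must lie strictly inside the nucleus")
        # nucleus strictly inside cell (concentric)
        if any(n >= c for n, c in zip(self.nucleus_radii, self.cell_radii)):
            raise ValueError("nucleus must lie strictly inside the cell")


def ellipsoid_u(points, center, radii) -> np.ndarray:
    """Scaled radial coordinate: u < 1 inside, u = 1 on the surface."""
    p = np.atleast_2d(points).astype(float)
    d = (p - np.asarray(center)) / np.asarray(radii)
    return np.sqrt(np.sum(d * d, axis=-1))


def surface_normal(point, center, radii) -> np.ndarray:
    """Outward unit normal of the ellipsoid at (the radial projection of) a point."""
    g = (np.asarray(point, float) - np.asarray(center)) / np.asarray(radii) ** 2
    n = np.linalg.norm(g)
    if n == 0:
        raise ValueError("normal undefined at the ellipsoid centre")
    return g / n


def ray_surface_crossing(origin, direction, center, radii) -> float:
    """Distance t >= 0 with origin + t*direction on the ellipsoid surface.

    Solves the quadratic ``|((o + t d) - c) / r|^2 = 1`` and returns the
    smallest non-negative root; raises if the ray misses the surface.
    """
    o = (np.asarray(origin, float) - np.asarray(center)) / np.asarray(radii)
    d = np.asarray(direction, float) / np.asarray(radii)
    a = float(d @ d)
    b = 2.0 * float(o @ d)
    c = float(o @ o) - 1.0
    disc = b * b - 4 * a * c
    if disc < 0:
        raise ValueError("ray does not intersect the ellipsoid")
    roots = [(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)]
    valid = [t for t in roots if t >= 0]
    if not valid:
        raise ValueError("ellipsoid surface lies behind the ray origin")
    return min(valid)


# ---------------------------------------------------------------------------
# scene ground truth


@dataclass
class GroundTruthMolecule:
    """One mRNA molecule with per-colour probe positions (um, (z, y, x))."""

    species: str
    probe_positions: dict[str, np.ndarray]
    true_location: str
    oriented_5prime_out: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES_CHANNELS:
            raise ValueError(f"unknown species {self.species!r}")
        expected = set(SPECIES_CHANNELS[self.species])
        if set(self.probe_positions) != expected:
            raise ValueError(
                f"species {self.species!r} requires channels {sorted(expected)}, "
                f"got {sorted(self.probe_positions)}"
            )
        if self.true_location not in LOCATIONS:
            raise ValueError(f"unknown location {self.true_location!r}")


@dataclass
class CellScene:
    """Synthetic ground truth for one cell."""

    geometry: SceneGeometry
    nucleus_center: np.ndarray
    molecules: list[GroundTruthMolecule] = field(default_factory=list)
    pore_marker: bool = True
    cytoplasm_marker: bool = True
    compaction_um: float = 0.5

    @property
    def nucleolus_center(self) -> np.ndarray:
        return self.nucleus_center + np.asarray(self.geometry.nucleolus_offset)

    def validate(self) -> None:
        self.geometry.validate()
        for mol in self.molecules:
            pos = np.array(list(mol.probe_positions.values()))
            if np.any(ellipsoid_u(pos, self.nucleus_center, self.geometry.cell_radii) >= 1):
                raise ValueError("molecule position outside the cell")
            # compaction: pairwise probe distances within one molecule
            for i in range(len(pos)):
                for j in range(i + 1, len(pos)):
                    if np.linalg.norm(pos[i] - pos[j]) > self.compaction_um + 1e-9:
                        raise ValueError("probe positions exceed compaction distance")


def _place_periphery(rng, center, radii, species, oriented_out, sep=0.2, jitter=0.04):
    """Place one molecule straddling the nuclear surface.

    The anchor sits on the ellipsoid surface; probes are laid out along the
    outward normal so the 5'-most probe is outside the nucleus when the
    molecule is oriented 5'-out (head-first export) and inside otherwise.
    """
    # random point on the surface via a random direction
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    t = ray_surface_crossing(center, d, center, radii)
    anchor = np.asarray(center) + t * d
    normal = surface_normal(anchor, center, radii)
    channels = SPECIES_CHANNELS[species]
    # radial offsets in 5'->3' channel order: 5'-most probe farthest out
    k = len(channels)
    offsets = np.linspace(sep * (k - 1) / 2.0, -sep * (k - 1) / 2.0, k)
    if not oriented_out:
        offsets = -offsets
    positions = {}
    for ch, off in zip(channels, offsets):
        tangential = rng.normal(scale=jitter, size=3)
        tangential -= (tangential @ normal) * normal
        positions[ch] = anchor + off * normal + tangential
    return positions


def _place_interior(rng, center, radii, species, u_lo, u_hi, compaction):
    """Place a molecule with its anchor at scaled radius u in [u_lo, u_hi]."""
    while True:
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        u = rng.uniform(u_lo, u_hi)
        # point at scaled radius u along direction d
        t = u * ray_surface_crossing(center, d, center, radii)
        anchor = np.asarray(center) + t * d
        channels = SPECIES_CHANNELS[species]
        positions = {
            ch: anchor + rng.normal(scale=compaction / 6.0, size=3) for ch in channels
        }
        pos = np.array(list(positions.values()))
        uu = ellipsoid_u(pos, center, radii)
        if (u_lo == 0.0 and np.all(uu < u_hi)) or (u_lo > 0.0 and np.all(uu > u_lo) and np.all(uu < u_hi)):
            return positions


def _resolvable(positions, existing_molecules, min_sep: float,
                psf_sigma=(0.30, 0.13, 0.13)) -> bool:
    """Same-channel spots of different molecules must be separable by the
    optics: distance measured in a PSF-scaled metric (the axial direction
    counts for less because axial resolution is correspondingly worse)."""
    sigma = np.asarray(psf_sigma)
    scale = sigma / sigma[1:].mean()  # lateral sigma defines the unit
    for mol in existing_molecules:
        for ch, pos in positions.items():
            other = mol.probe_positions.get(ch)
            if other is None:
                continue
            d = (np.asarray(pos) - np.asarray(other)) / scale
            if np.linalg.norm(d) < min_sep:
                return False
    return True


def generate_cell_scene(
    counts: dict[tuple[str, str], int],
    orientation_fraction: float = 0.5,
    seed: int = 0,
    geometry: SceneGeometry | None = None,
    compaction_um: float = 0.5,
    periphery_sep_um: float = 0.2,
    min_separation_um: float = 0.6,
    pore_marker: bool = True,
    cytoplasm_marker: bool = True,
) -> CellScene:
    """Generate a ground-truthed cell scene.

    Parameters
    ----------
    counts
        Mapping ``(species, location) -> number of molecules``, e.g.
        ``{("intact", "cytoplasm"): 10, ("five_prime_part", "periphery"): 5}``.
    orientation_fraction
        Fraction of periphery molecules oriented 5'-out (exported head
        first); each periphery molecule draws its orientation independently
        (Bernoulli), so realized fractions carry binomial spread.
    seed
        Seed for the scene's private random generator.
    min_separation_um
        Minimum distance between same-channel spots of *different* molecules.
        Two foci of one colour closer than roughly the PSF are optically one
        focus; the generator keeps distinct molecules resolvable so that the
        ground truth remains recoverable (crowded fields are out of scope).
    """
    if not 0.0 <= orientation_fraction <= 1.0:
        raise ValueError("orientation_fraction must lie in [0, 1]")
    geometry = geometry or SceneGeometry()
    geometry.validate()
    rng = np.random.default_rng(seed)
    center = np.array(geometry.cell_radii, dtype=float)  # cell corner at origin
    scene = CellScene(
        geometry=geometry,
        nucleus_center=center,
        pore_marker=pore_marker,
        cytoplasm_marker=cytoplasm_marker,
        compaction_um=compaction_um,
    )
    nuc = geometry.nucleus_radii
    cell = geometry.cell_radii
    # interior margins keep non-periphery molecules clear of the surface band
    margin_u = (periphery_sep_um + 2 * 0.13) / min(nuc)
    for (species, location), n in sorted(counts.items()):
        if n < 0:
            raise ValueError("molecule counts must be non-negative")
        if species not in SPECIES_CHANNELS:
            raise ValueError(f"unknown species {species!r}")
        if location not in LOCATIONS:
            raise ValueError(f"unknown location {location!r}")
        for _ in range(n):
            if location == "periphery":
                oriented = bool(rng.random() < orientation_fraction)
            else:
                oriented = False
            for _attempt in range(500):
                if location == "periphery":
                    positions = _place_periphery(
                        rng, center, nuc, species, oriented, sep=periphery_sep_um
                    )
                elif location == "nucleus":
                    positions = _place_interior(
                        rng, center, nuc, species, 0.0, 1.0 - margin_u, compaction_um
                    )
                else:  # cytoplasm: inside the cell, clear of the nuclear band
                    while True:
                        positions = _place_interior(
                            rng, center, cell, species, 0.05, 0.9, compaction_um
                        )
                        pos = np.array(list(positions.values()))
                        if np.all(ellipsoid_u(pos, center, nuc) > 1.0 + margin_u):
                            break
                if _resolvable(positions, scene.molecules, min_separation_um):
                    break
            else:
                raise ValueError(
                    "could not place molecules at the requested density while "
                    "keeping same-channel spots resolvable; lower the counts or "
                    "min_separation_um"
                )
            scene.molecules.append(
                GroundTruthMolecule(species, positions, location, oriented)
            )
    scene.validate()
    return scene


# ---------------------------------------------------------------------------
# optical forward model


@dataclass(frozen=True)
class OpticsParams:
    """Acquisition parameters of the forward model.

    ``photon_scale`` is the integrated (above-background) intensity of one
    probe spot in counts; the field's literature gives no spot-intensity
    statistics, so this is a free parameter of the simulator.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    psf_sigma: tuple[float, float, float] = (0.30, 0.13, 0.13)
    background_level: float = 10.0
    photon_scale: float = 5000.0
    noise_model: str = "poisson"
    dapi_falloff: float = 0.15
    structure_scale: float = 200.0
    nucleolus_dapi: float = 0.35

    def validate(self) -> None:
        if any(v <= 0 for v in self.voxel_size + self.psf_sigma):
            raise ValueError("voxel_size and psf_sigma must be positive")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.photon_scale <= 0 or self.dapi_falloff <= 0:
            raise ValueError("photon_scale and dapi_falloff must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


def _voxel_grids(shape, voxel_size):
    axes = [np.arange(n) * v for n, v in zip(shape, voxel_size)]
    return np.meshgrid(*axes, indexing="ij")


def _add_spot(channel_img, pos_um, psf_sigma, voxel_size, photons):
    """Add one 3D Gaussian spot, integrated intensity = photons."""
    shape = channel_img.shape
    lo, hi, axes_vals = [], [], []
    for ax in range(3):
        half = 4.0 * psf_sigma[ax]
        a = int(np.floor((pos_um[ax] - half) / voxel_size[ax]))
        b = int(np.ceil((pos_um[ax] + half) / voxel_size[ax])) + 1
        a, b = max(a, 0), min(b, shape[ax])
        if a >= b:
            return
        coords = np.arange(a, b) * voxel_size[ax]
        axes_vals.append(np.exp(-((coords - pos_um[ax]) ** 2) / (2 * psf_sigma[ax] ** 2)))
        lo.append(a)
        hi.append(b)
    kernel = axes_vals[0][:, None, None] * axes_vals[1][None, :, None] * axes_vals[2][None, None, :]
    s = kernel.sum()
    if s > 0:
        channel_img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += photons * kernel / s


def render_image(
    scene: CellScene,
    optics: OpticsParams | None = None,
    seed: int = 0,
    shape_zyx: tuple[int, int, int] | None = None,
) -> ImageStack:
    """Render a scene into a multi-channel stack.

    Structural channels: DAPI (smoothed nucleus ellipsoid with a dimmer
    nucleolus), an optional pore-ring shell on the nuclear surface, and an
    optional cytoplasmic fill. Each probe position becomes a 3D Gaussian of
    ``psf_sigma`` integrating to ``photon_scale`` counts. With
    ``noise_model="none"`` the voxel argmax of an isolated spot is the voxel
    containing its true position.
    """
    optics = optics or OpticsParams()
    optics.validate()
    vs = np.asarray(optics.voxel_size)
    geom = scene.geometry
    if shape_zyx is None:
        extent = 2 * np.asarray(geom.cell_radii) + 1.0  # 0.5 um margin per side
        shape_zyx = tuple(int(np.ceil(e / v)) + 1 for e, v in zip(extent, vs))
    # the scene must fit: every molecule and the cell ellipsoid inside bounds
    hi_um = (np.asarray(shape_zyx) - 1) * vs
    if np.any(scene.nucleus_center + np.asarray(geom.cell_radii) > hi_um + 1e-9) or np.any(
        scene.nucleus_center - np.asarray(geom.cell_radii) < -1e-9
    ):
        raise ValueError("scene exceeds stack bounds")

    channels = [CHANNEL_DAPI]
    if scene.pore_marker:
        channels.append(CHANNEL_PORE)
    if scene.cytoplasm_marker:
        channels.append(CHANNEL_CYTO)
    channels += list(PROBE_CHANNELS)

    grids = _voxel_grids(shape_zyx, vs)
    pts = np.stack([g.ravel() for g in grids], axis=-1)
    u_nuc = ellipsoid_u(pts, scene.nucleus_center, geom.nucleus_radii).reshape(shape_zyx)
    u_cell = ellipsoid_u(pts, scene.nucleus_center, geom.cell_radii).reshape(shape_zyx)
    d_nucleolus = np.linalg.norm(pts - scene.nucleolus_center, axis=-1).reshape(shape_zyx)

    smooth_sigma_vox = optics.dapi_falloff / vs
    stack = np.zeros((len(channels),) + tuple(shape_zyx), dtype=float)

    # DAPI: bright nucleoplasm, dimmer nucleolus, dark cytoplasm, soft edge
    dapi = np.where(u_nuc < 1.0, 1.0, 0.0)
    dapi = np.where(d_nucleolus < geom.nucleolus_radius, optics.nucleolus_dapi, dapi)
    dapi = ndi.gaussian_filter(dapi, smooth_sigma_vox)
    stack[channels.index(CHANNEL_DAPI)] = optics.structure_scale * dapi

    if scene.pore_marker:
        # thin shell on the nuclear surface; width ~ lateral PSF
        r_mean = float(np.mean(geom.nucleus_radii))
        shell_sigma = float(np.mean(optics.psf_sigma[1:]))
        shell = np.exp(-(((u_nuc - 1.0) * r_mean) ** 2) / (2 * shell_sigma**2))
        stack[channels.index(CHANNEL_PORE)] = optics.structure_scale * shell

    if scene.cytoplasm_marker:
        cyto = np.where((u_cell < 1.0) & (u_nuc > 1.0), 1.0, 0.0)
        cyto = ndi.gaussian_filter(cyto, smooth_sigma_vox)
        stack[channels.index(CHANNEL_CYTO)] = optics.structure_scale * cyto

    for mol in scene.molecules:
        for ch, pos in mol.probe_positions.items():
            _add_spot(
                stack[channels.index(ch)], np.asarray(pos), optics.psf_sigma,
                vs, optics.photon_scale,
            )

    stack += optics.background_level
    if optics.noise_model != "none":
        rng = np.random.default_rng(seed)
        if optics.noise_model == "poisson":
            stack = rng.poisson(stack).astype(float)
        else:  # gaussian, variance = mean for comparability with poisson
            stack = np.clip(stack + rng.normal(scale=np.sqrt(stack)), 0, None)
    return ImageStack(stack, tuple(vs), channels)


# ---------------------------------------------------------------------------
# LFQ proteomics simulator


@dataclass(frozen=True)
class LfqGroundTruth:
    """Planted truth for a two-condition, triplicate LFQ experiment.

    ``missingness_steepness`` is the logistic slope of P(missing) against
    log2 abundance (per log2 unit); larger values concentrate missingness in
    low-abundance proteins (missing-not-at-random).
    """

    n_proteins: int = 200
    n_enriched: int = 20
    log2_effect_size: float = 2.0
    base_mean: float = 25.0
    base_sd: float = 2.0
    replicate_sd: float = 0.3
    missingness_steepness: float = 1.0
    missingness_midpoint: float = 22.0
    n_flagged: int = 9
    enriched_ids: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_enriched > self.n_proteins:
            raise ValueError("n_enriched must not exceed n_proteins")
        if self.missingness_steepness < 0:
            raise ValueError("missingness_steepness must be >= 0")


def generate_lfq_dataset(truth: LfqGroundTruth | None = None, seed: int = 0):
    """Simulate a proteinGroups-style LFQ matrix.

    Returns ``(matrix, record)`` where ``matrix`` is an
    :class:`nucfish.enrichment.LfqMatrix` (2 conditions x 3 replicates,
    missing values as NaN, planted reverse/contaminant/only-by-site rows) and
    ``record`` is a dict with the planted ground truth (enriched ids, flagged
    ids, per-protein true log2 abundances).
    """
    from nucfish.enrichment import LfqMatrix  # local import to avoid a cycle

    truth = truth or LfqGroundTruth()
    truth.validate()
    rng = np.random.default_rng(seed)
    ids = [f"P{i:04d}" for i in range(truth.n_proteins)]
    if truth.enriched_ids is None:
        enriched = sorted(rng.choice(ids, size=truth.n_enriched, replace=False).tolist())
    else:
        enriched = sorted(truth.enriched_ids)
        if not set(enriched) <= set(ids):
            raise ValueError("enriched_ids must be a subset of generated protein ids")
    enriched_set = set(enriched)

    conditions = ["ctrl", "treat"]
    samples = [f"{c}_{r}" for c in conditions for r in (1, 2, 3)]
    base = rng.normal(truth.base_mean, truth.base_sd, size=truth.n_proteins)
    log2 = np.empty((truth.n_proteins, 6))
    for j, s in enumerate(samples):
        shift = np.where(
            [pid in enriched_set for pid in ids],
            truth.log2_effect_size if s.startswith("treat") else 0.0,
            0.0,
        )
        log2[:, j] = base + shift + rng.normal(0, truth.replicate_sd, truth.n_proteins)

    # logistic MNAR missingness on the per-value log2 abundance
    p_miss = 1.0 / (
        1.0 + np.exp(truth.missingness_steepness * (log2 - truth.missingness_midpoint))
    )
    missing = rng.random(log2.shape) < p_miss
    values = np.power(2.0, log2)
    values[missing] = np.nan

    # planted flagged rows (removed by the downstream filter)
    flag_kinds = ["reverse", "contaminant", "only_by_site"]
    n_flag = truth.n_flagged
    flag_ids = [f"FLAG{i:03d}" for i in range(n_flag)]
    flag_vals = np.power(2.0, rng.normal(truth.base_mean, truth.base_sd, (n_flag, 6)))
    all_ids = ids + flag_ids
    df = pd.DataFrame(
        np.vstack([values, flag_vals]) if n_flag else values,
        index=all_ids, columns=samples,
    )
    flags = pd.DataFrame(False, index=all_ids, columns=flag_kinds)
    for i, fid in enumerate(flag_ids):
        flags.loc[fid, flag_kinds[i % 3]] = True

    matrix = LfqMatrix(
        values=df,
        condition_of={s: s.split("_")[0] for s in samples},
        flags=flags,
    )
    record = {
        "enriched_ids": enriched,
        "flagged_ids": flag_ids,
        "true_log2_base": dict(zip(ids, base)),
        "log2_effect_size": truth.log2_effect_size,
    }
    return matrix, record


# ---------------------------------------------------------------------------
# protein sequences with planted Q-rich windows

_AA = "ACDEFGHIKLMNPRSTVWY"  # 19 letters; the scored residue is added separately


def generate_protein_sequences(
    n: int,
    mean_length: int = 400,
    planted_qrich_per_protein: int | list[int] = 0,
    residue: str = "Q",
    window: int = 60,
    min_count: int = 7,
    background_freq: float = 0.02,
    seed: int = 0,
):
    """Generate protein sequences with planted residue-rich 60-mers.

    Returns ``(records, truth)`` where records is a list of ``(id, sequence)``
    pairs and truth maps protein id to its number of planted windows. Planted
    windows are aligned to the scanning frame (offsets that are multiples of
    ``window``) and contain at least ``min_count`` of ``residue``; every
    background window is post-edited to contain fewer than ``min_count``.
    """
    rng = np.random.default_rng(seed)
    if isinstance(planted_qrich_per_protein, int):
        planted = [planted_qrich_per_protein] * n
    else:
        planted = list(planted_qrich_per_protein)
        if len(planted) != n:
            raise ValueError("planted_qrich_per_protein list must have length n")
    alphabet = np.array(list(_AA + residue))
    probs = np.full(len(_AA), (1 - background_freq) / len(_AA))
    probs = np.append(probs, background_freq)
    records, truth = [], {}
    for i in range(n):
        k = planted[i]
        length = max(int(rng.normal(mean_length, mean_length / 4)), window * max(k, 1))
        seq = rng.choice(alphabet, p=probs, size=length)
        n_windows = length // window
        if k > n_windows:
            raise ValueError("more planted windows requested than fit the protein")
        chosen = rng.choice(n_windows, size=k, replace=False) if k else np.array([], int)
        chosen_set = set(int(c) for c in chosen)
        for w in range(n_windows):
            sl = slice(w * window, (w + 1) * window)
            win = seq[sl]
            count = int(np.sum(win == residue))
            if w in chosen_set:
                need = int(rng.integers(min_count, min_count + 6))
                if count < need:
                    idx = rng.choice(
                        np.flatnonzero(win != residue), size=need - count, replace=False
                    )
                    win[idx] = residue
            elif count >= min_count:
                idx = rng.choice(
                    np.flatnonzero(win == residue),
                    size=count - (min_count - 1), replace=False,
                )
                win[idx] = "A"
            seq[sl] = win
        # trailing remainder: keep it below threshold too, for tidiness
        pid = f"SYN{i:04d}"
        records.append((pid, "".join(seq)))
        truth[pid] = k
    return records, truth


# ---------------------------------------------------------------------------
# homology hit tables with known orthology


def generate_hit_tables(
    protein_ids: list[str],
    taxa: list[str],
    homolog_of: dict[str, set[str]],
    seed: int = 0,
):
    """Build forward/reverse best-hit tables with planted reciprocity.

    ``homolog_of[taxon]`` is the set of protein ids that genuinely have a
    reciprocal homologue in that taxon (reverse top hit points back, e-value
    below 1e-5). Other proteins receive either no hit or a non-reciprocal /
    weak hit. Returns ``(forward, reverse)`` dicts of taxon -> DataFrame with
    columns query, subject, evalue, bitscore.
    """
    rng = np.random.default_rng(seed)
    forward, reverse = {}, {}
    for taxon in taxa:
        frows, rrows = [], []
        genuine = homolog_of.get(taxon, set())
        for pid in protein_ids:
            subj = f"{taxon}|{pid}"
            if pid in genuine:
                e_f = 10.0 ** rng.uniform(-50, -10)
                e_r = 10.0 ** rng.uniform(-50, -6)
                frows.append((pid, subj, e_f, rng.uniform(100, 500)))
                rrows.append((subj, pid, e_r, rng.uniform(100, 500)))
            else:
                mode = rng.integers(3)
                if mode == 0:
                    continue  # no hit at all
                elif mode == 1:  # non-reciprocal: reverse points elsewhere
                    frows.append((pid, subj, 10.0 ** rng.uniform(-30, -8), 80.0))
                    rrows.append((subj, pid + "_other", 10.0 ** rng.uniform(-30, -8), 90.0))
                else:  # reciprocal but weak reverse e-value
                    frows.append((pid, subj, 10.0 ** rng.uniform(-30, -8), 80.0))
                    rrows.append((subj, pid, 10.0 ** rng.uniform(-4, -1), 40.0))
        cols = ["query", "subject", "evalue", "bitscore"]
        forward[taxon] = pd.DataFrame(frows, columns=cols)
        reverse[taxon] = pd.DataFrame(rrows, columns=cols)
    return forward, reverse
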