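"""The %DAPI profile coordinate system and nuclear-border calibration.

Positions near the nuclear border are expressed on an intensity profile
sampled along a line running from the cytoplasm, across the nuclear rim,
towards the nucleolus. The DAPI channel of the profile is rescaled to a
0-100% scale (minimum -> 0, peak -> 100); a query position is then reported
as the *percent of peak DAPI* at that point, together with a side flag saying
whether it lies on the cytoplasmic or the nucleolar flank of the peak. The
nuclear border itself is calibrated against this scale in two independent
ways: the profile position of a nuclear-pore marker's intensity peak, and the
crossing point of a cytoplasmic marker with the rising DAPI flank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from nucfish.images import ImageStack

DAPI = "dapi"


@dataclass
class Profile:
    """Intensities sampled along one line, cytoplasm first.

    ``arc`` holds strictly increasing distances (um) from the profile start;
    ``raw`` maps channel name to sampled intensity; ``normalized`` holds the
    0-100 rescaled values once :func:`normalize_profile` has run.
    """

    arc: np.ndarray
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.arc = np.asarray(self.arc, dtype=float)
        if self.arc.ndim != 1 or len(self.arc) < 2:
            raise ValueError("profile needs at least two sample points")
        if np.any(np.diff(self.arc) <= 0):
            raise ValueError("arc positions must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.arc[1] - self.arc[0])


@dataclass(frozen=True)
class DapiCoordinate:
    """Percent-of-peak DAPI at a point, plus which flank it lies on.

    ``side`` is ``"cytoplasmic"`` for queries before the DAPI peak along the
    profile, ``"nucleolar"`` after it, and ``None`` exactly at the peak.
    """

    percent: float
    side: str | None

    @property
    def depth(self) -> float:
        """Monotone coordinate along the profile: 0 (cytoplasm) .. 100 (peak)
        .. 200 (deep nucleolar side). Lets positions on the two flanks be
        ordered by distance travelled from the cytoplasm."""
        if self.side == "nucleolar":
            return 200.0 - self.percent
        return self.percent


@dataclass
class BorderCalibration:
    """Aggregate of per-profile border-proxy %DAPI values."""

    values: np.ndarray
    mean: float
    sd: float
    n: int
    fraction_below_33: float
    threshold: float = 33.3


def find_focus_plane(stack: ImageStack, channel: str = DAPI) -> int:
    """Index of the z-plane with maximal intensity variance in a channel.

    This mirrors the common focus heuristic of picking the slice with 100% of
    the maximum variance; ties resolve to the lowest index.
    """
    img = stack.channel(channel)
    if img.shape[0] < 1:
        raise ValueError("stack has no planes")
    variances = img.reshape(img.shape[0], -1).var(axis=1)
    return int(np.argmax(variances))


def extract_profile(
    stack: ImageStack,
    start_um,
    end_um,
    sampling_step: float | None = None,
    channels: list[str] | None = None,
    smooth_sigma_um: float | None = None,
) -> Profile:
    """Sample intensities along the segment start -> end by interpolation.

    The start should lie on the cytoplasmic side and the end towards the
    nucleolus. All requested channels are sampled at identical, evenly spaced
    arc positions using trilinear interpolation. The default sampling step is
    half the smallest voxel dimension. ``smooth_sigma_um`` applies a 1-D
    Gaussian along the profile (useful on noisy, undeconvolved stacks where
    argmax/crossing estimators would otherwise chase single-sample noise).
    """
    start = np.asarray(start_um, dtype=float)
    end = np.asarray(end_um, dtype=float)
    if sampling_step is None:
        sampling_step = min(stack.voxel_size) / 2.0
    if sampling_step <= 0:
        raise ValueError("sampling_step must be positive")
    length = float(np.linalg.norm(end - start))
    if length == 0:
        raise ValueError("degenerate profile: start equals end")
    for p, name in ((start, "start"), (end, "end")):
        if not stack.contains_um(p):
            raise ValueError(f"{name} point {p} lies outside the stack")
    n = int(np.floor(length / sampling_step)) + 1
    arc = np.arange(n) * sampling_step
    direction = (end - start) / length
    points_um = start[None, :] + arc[:, None] * direction[None, :]
    coords = (points_um / np.asarray(stack.voxel_size)).T  # (3, n) index space
    channels = channels or stack.channel_names
    raw = {
        ch: ndi.map_coordinates(stack.channel(ch), coords, order=1, mode="nearest")
        for ch in channels
    }
    if smooth_sigma_um:
        raw = {
            ch: ndi.gaussian_filter1d(v, smooth_sigma_um / sampling_step)
            for ch, v in raw.items()
        }
    return Profile(arc=arc, raw=raw)


def normalize_profile(
    profile: Profile, channel: str, robust_min: bool = True
) -> np.ndarray:
    """Rescale a channel to 0-100 (min -> 0, max -> 100) in place.

    With ``robust_min`` the floor is the 1st percentile of the profile, which
    damps single-sample noise; values below the floor clip to 0. The result
    is invariant under positive affine transforms of the raw intensities, and
    normalizing twice is the identity.
    """
    if channel not in profile.raw:
        raise KeyError(f"channel {channel!r} not in profile")
    v = np.asarray(profile.raw[channel], dtype=float)
    lo = float(np.percentile(v, 1)) if robust_min else float(v.min())
    hi = float(v.max())
    if hi <= lo:
        raise ValueError(f"channel {channel!r} has no dynamic range on this profile")
    norm = np.clip((v - lo) / (hi - lo) * 100.0, 0.0, 100.0)
    profile.normalized[channel] = norm
    return norm


def _normalized(profile: Profile, channel: str) -> np.ndarray:
    if channel not in profile.normalized:
        normalize_profile(profile, channel)
    return profile.normalized[channel]


def percent_dapi(
    profile: Profile, query_arc: float, dapi_channel: str = DAPI
) -> DapiCoordinate:
    """%DAPI coordinate of a position (arc distance, um) on the profile."""
    arc = profile.arc
    if query_arc < arc[0] or query_arc > arc[-1]:
        raise ValueError(
            f"query {query_arc} outside profile support [{arc[0]}, {arc[-1]}]"
        )
    norm = _normalized(profile, dapi_channel)
    percent = float(np.interp(query_arc, arc, norm))
    peak_arc = float(arc[int(np.argmax(norm))])  # ties -> lowest index
    if query_arc < peak_arc:
        side = "cytoplasmic"
    elif query_arc > peak_arc:
        side = "nucleolar"
    else:
        side = None
    return DapiCoordinate(percent=percent, side=side)


def marker_peak_position(
    profile: Profile, marker_channel: str, dapi_channel: str = DAPI
) -> DapiCoordinate:
    """%DAPI at the marker channel's intensity maximum.

    Used with a punctate nuclear-pore marker this reads off where the pores
    sit on the DAPI scale. Ties resolve to the sample nearest the profile
    start; a monotone marker (argmax on the boundary) triggers a warning and
    returns the boundary value.
    """
    marker = np.asarray(profile.raw[marker_channel], dtype=float)
    idx = int(np.argmax(marker))
    if idx in (0, len(marker) - 1):
        warnings.warn(
            f"marker channel {marker_channel!r} peaks at the profile boundary; "
            "no interior maximum",
            stacklevel=2,
        )
    return percent_dapi(profile, float(profile.arc[idx]), dapi_channel)


def channel_intersection(
    profile: Profile, marker_channel: str, dapi_channel: str = DAPI
) -> DapiCoordinate:
    """%DAPI where a falling cytoplasmic marker crosses the rising DAPI flank.

    Both channels are normalized to 0-100 on this profile; the crossing is
    the first sign change of (marker - DAPI) walking in from the cytoplasmic
    end, located by linear interpolation between samples.
    """
    dapi = _normalized(profile, dapi_channel)
    marker = _normalized(profile, marker_channel)
    diff = marker - dapi
    # restrict to the cytoplasmic flank (up to and including the DAPI peak)
    peak = int(np.argmax(dapi))
    crossing_arc = None
    for j in range(1, peak + 1):
        if diff[j - 1] > 0 >= diff[j]:
            t = diff[j - 1] / (diff[j - 1] - diff[j])
            crossing_arc = float(profile.arc[j - 1] + t * (profile.arc[j] - profile.arc[j - 1]))
            break
    if crossing_arc is None:
        raise ValueError(
            "no transversal marker/DAPI crossing on the cytoplasmic flank"
        )
    return percent_dapi(profile, crossing_arc, dapi_channel)


def calibrate_border(
    profiles: list[Profile],
    method: str = "marker_peak",
    marker_channel: str = "nup",
    dapi_channel: str = DAPI,
    threshold: float = 33.3,
) -> BorderCalibration:
    """Aggregate per-profile border-proxy values into a calibration.

    ``method`` is ``"marker_peak"`` (pore-marker maximum) or
    ``"intersection"`` (cytoplasmic-marker crossing). Profiles on which the
    estimator fails (e.g. no crossing) are dropped; at least one profile must
    be accepted.
    """
    if method not in ("marker_peak", "intersection"):
        raise ValueError(f"unknown method {method!r}")
    estimator = marker_peak_position if method == "marker_peak" else channel_intersection
    values = []
    for prof in profiles:
        try:
            coord = estimator(prof, marker_channel, dapi_channel)
        except ValueError:
            continue
        values.append(coord.percent)
    if not values:
        raise ValueError("no accepted profiles")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return BorderCalibration(
        values=arr,
        mean=float(arr.mean()),
        sd=sd,
        n=len(arr),
        fraction_below_33=float(np.mean(arr < threshold)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# per-spot rays


def dapi_centroid(stack: ImageStack, dapi_channel: str = DAPI) -> np.ndarray:
    """DAPI-weighted centroid (um) of the nucleus.

    The DAPI channel is thresholded at half its (background-subtracted)
    maximum and the centroid taken with intensity weights — a deliberately
    simple nucleus locator adequate for one-nucleus fields.
    """
    img = np.asarray(stack.channel(dapi_channel), dtype=float)
    lo = float(np.percentile(img, 5))
    thr = lo + 0.5 * (float(img.max()) - lo)
    mask = img >= thr
    if not mask.any():
        raise ValueError("no DAPI signal above threshold")
    w = np.where(mask, img - lo, 0.0)
    idx = np.array(ndi.center_of_mass(w))
    return idx * np.asarray(stack.voxel_size)


def nucleus_mask(stack: ImageStack, dapi_channel: str = DAPI) -> np.ndarray:
    """Boolean nucleus mask from half-max DAPI thresholding."""
    img = np.asarray(stack.channel(dapi_channel), dtype=float)
    lo = float(np.percentile(img, 5))
    thr = lo + 0.5 * (float(img.max()) - lo)
    return img >= thr


def spot_profile(
    stack: ImageStack,
    point_um,
    centroid_um,
    sampling_step: float | None = None,
    channels: list[str] | None = None,
) -> tuple[Profile, float]:
    """Build the per-spot profile ray and locate the spot on it.

    The ray runs along the line through the nucleus centroid and the spot:
    from the far cytoplasmic side (clipped to the stack bounds) inward to the
    centroid, so the profile starts in the cytoplasm and ends near the
    nucleolus. Returns the profile and the spot's arc position on it.
    """
    point = np.asarray(point_um, dtype=float)
    centroid = np.asarray(centroid_um, dtype=float)
    d = point - centroid
    norm = float(np.linalg.norm(d))
    if norm == 0:
        raise ValueError("spot coincides with the nucleus centroid; ray undefined")
    u = d / norm
    # farthest t with centroid + t*u still inside the stack bounds
    hi = (np.array(stack.shape_zyx) - 1) * np.asarray(stack.voxel_size)
    t_max = np.inf
    for ax in range(3):
        if u[ax] > 0:
            t_max = min(t_max, (hi[ax] - centroid[ax]) / u[ax])
        elif u[ax] < 0:
            t_max = min(t_max, (0.0 - centroid[ax]) / u[ax])
    t_max = float(t_max) * (1 - 1e-9)
    if t_max <= norm:
        raise ValueError("spot lies outside the stack along its ray")
    start = centroid + t_max * u
    profile = extract_profile(stack, start, centroid, sampling_step, channels)
    query_arc = t_max - norm  # distance of the spot from the profile start
    return profile, min(query_arc, float(profile.arc[-1]))


def spot_percent_dapi(
    stack: ImageStack,
    point_um,
    centroid_um,
    sampling_step: float | None = None,
    dapi_channel: str = DAPI,
) -> DapiCoordinate:
    """%DAPI coordinate of an arbitrary point via its centroid ray."""
    profile, query_arc = spot_profile(
        stack, point_um, centroid_um, sampling_step, channels=[dapi_channel]
    )
    return percent_dapi(profile, query_arc, dapi_channel)
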