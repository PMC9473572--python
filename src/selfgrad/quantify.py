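"""Measurement procedures for cell tracks, intensity profiles, and cell images.

These mirror how gastrulation migration data are quantified: per-track speed,
straightness and net displacement; correction of tracks to a margin-relative
(epiboly-corrected) frame; 30-degree rose histograms of polarity angles with
left/right mirror folding about the animal--vegetal axis; velocity kymographs
from tracks using a 10-min moving window of distance-to-margin; background
subtraction / max normalization of 1D staining profiles; the membrane-to-
cytoplasm fluorescence ratio with a 1.25-um membrane band; and diffusion
coefficient estimation from mean squared displacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .kymo import Kymograph, bin_edges_covering

__all__ = [
    "CellTrack",
    "RoseHistogram",
    "LabeledCellImage",
    "track_length",
    "mean_speed",
    "track_straightness",
    "net_displacement_toward",
    "epiboly_correct",
    "rose_histogram",
    "velocity_kymograph_from_tracks",
    "normalize_intensity_profile",
    "membrane_cytoplasm_ratio",
    "estimate_Dc_msd",
]

MARGIN_TRACK_ID = "margin"

#: Rose bin centers: twelve 30-degree bins centered on the cardinal
#: directions (90 = animal pole, 0 = dorsal/ventral, -90 = vegetal pole);
#: the 180 bin wraps across +/-180.
ROSE_CENTERS = np.arange(-150, 181, 30)
#: Mirror-fold classes after combining left and right sides about the
#: animal--vegetal axis; the on-axis bins (+/-90) are their own class.
ROSE_FOLDED_CENTERS = np.arange(-90, 91, 30)


@dataclass(frozen=True)
class CellTrack:
    """One cell's time-stamped positions.

    ``y_um`` is the animal--vegetal coordinate (animal pole positive) and
    ``x_um`` the margin-parallel coordinate (may be None for 1D tracks).
    """

    track_id: str
    t_min: np.ndarray
    y_um: np.ndarray
    x_um: np.ndarray | None = None
    contact_t_min: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "y_um", y)
        if self.x_um is not None:
            x = np.asarray(self.x_um, dtype=float)
            object.__setattr__(self, "x_um", x)
            if x.shape != t.shape:
                raise ConfigurationError("x_um length mismatch")
        if t.ndim != 1 or len(t) < 2 or y.shape != t.shape:
            raise ConfigurationError("a track needs >= 2 (t, position) samples")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError("track times must be strictly increasing")

    # -- shorthand used throughout ----------------------------------------
    @property
    def t(self) -> np.ndarray:
        return self.t_min

    @property
    def y(self) -> np.ndarray:
        return self.y_um

    @property
    def ndim(self) -> int:
        return 1 if self.x_um is None else 2

    def coords(self) -> np.ndarray:
        """(n, d) position array."""
        if self.x_um is None:
            return self.y_um[:, None]
        return np.column_stack([self.x_um, self.y_um])


def track_length(track: CellTrack) -> float:
    """Summed Euclidean step length along the track, in um."""
    steps = np.diff(track.coords(), axis=0)
    return float(np.sum(np.sqrt(np.sum(steps**2, axis=1))))


def mean_speed(track: CellTrack) -> float:
    """Track length divided by track duration, um/min."""
    duration = track.t[-1] - track.t[0]
    if duration <= 0:
        raise DegenerateInputError("zero track duration")
    return track_length(track) / duration


def track_straightness(track: CellTrack) -> float:
    """Net displacement over path length, in [0, 1]; 1 for a straight
    monotone track, 0 for a closed loop."""
    length = track_length(track)
    if length <= 0:
        raise DegenerateInputError("straightness undefined for a zero-length track")
    disp = np.linalg.norm(track.coords()[-1] - track.coords()[0])
    return float(disp / length)


def net_displacement_toward(track: CellTrack, target_axis_sign: int,
                            truncate_min: float = 120.0) -> float:
    """Signed start-to-end displacement along the AV axis toward a target.

    ``target_axis_sign`` is +1 for a target in the animal (positive-y)
    direction, -1 for vegetal.  The end point is the first source contact
    (``track.contact_t_min``) or the last sample within ``truncate_min``
    minutes of imaging, whichever comes first.
    """
    if target_axis_sign not in (-1, 1):
        raise ConfigurationError("target_axis_sign must be +1 or -1")
    t0 = track.t[0]
    t_cut = t0 + truncate_min
    if track.contact_t_min is not None:
        t_cut = min(t_cut, track.contact_t_min)
    idx = np.nonzero(track.t <= t_cut + 1e-9)[0]
    end = idx[-1] if len(idx) else 0
    return float(target_axis_sign * (track.y[end] - track.y[0]))


def epiboly_correct(tracks: Sequence[CellTrack], margin_track: CellTrack) -> list[CellTrack]:
    """Subtract the margin (epiboly) displacement from each track's AV coordinate.

    The margin reference is interpolated linearly in time; each track is
    shifted by the margin displacement accumulated since the track's own
    first sample, so a cell co-moving with the margin becomes stationary and
    the margin track corrected by itself is a zero-displacement track.
    """
    mt, my = margin_track.t, margin_track.y
    out = []
    for tr in tracks:
        if tr.t[0] < mt[0] - 1e-9 or tr.t[-1] > mt[-1] + 1e-9:
            raise ConfigurationError(
                f"margin track does not cover the time range of track {tr.track_id!r}")
        ref = np.interp(tr.t, mt, my)
        out.append(replace(tr, y_um=tr.y - (ref - ref[0])))
    return out


@dataclass(frozen=True)
class RoseHistogram:
    """30-degree orientation histogram with mirror folding about the AV axis.

    ``counts`` follows :data:`ROSE_CENTERS`; ``folded_counts`` follows
    :data:`ROSE_FOLDED_CENTERS` after combining mirror-image bins
    (theta -> 180 - theta), which merges the left and right sides of the
    rose plot into dorsal/ventral orientation classes.
    """

    counts: np.ndarray
    folded_counts: np.ndarray
    fractions: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return ROSE_CENTERS.copy()

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(-165.0, 196.0, 30.0)

    @property
    def folded_centers(self) -> np.ndarray:
        return ROSE_FOLDED_CENTERS.copy()


def _wrap_deg(angles: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    w = np.mod(np.asarray(angles, dtype=float), 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    return w


def fold_angle(angle_deg: float) -> float:
    """Mirror an angle about the animal--vegetal (90/-90 degree) axis onto
    the [-90, 90] half-plane; idempotent."""
    w = float(_wrap_deg(np.array([angle_deg]))[0])
    if abs(w) > 90.0:
        w = float(_wrap_deg(np.array([180.0 - w]))[0])
    return w


def rose_histogram(angles_deg) -> RoseHistogram:
    """Count angles into twelve 30-degree bins and fold left onto right.

    Angles may be any real values; they are wrapped to (-180, 180].  Bins are
    centered on multiples of 30 degrees, so the animal pole (90) sits at a
    bin center and the on-axis bins are their own mirror class.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    counts = np.zeros(len(ROSE_CENTERS))
    if angles.size:
        w = _wrap_deg(angles)
        idx = np.round(w / 30.0).astype(int)
        idx[idx == -6] = 6  # the 180 bin wraps
        counts += np.bincount(idx + 5, minlength=12).astype(float)
    folded = np.zeros(len(ROSE_FOLDED_CENTERS))
    for center, n in zip(ROSE_CENTERS, counts):
        fc = fold_angle(float(center))
        folded[int(round((fc + 90) / 30))] += n
    total = counts.sum()
    fractions = counts / total if total > 0 else counts.copy()
    return RoseHistogram(counts=counts, folded_counts=folded, fractions=fractions)


# ---------------------------------------------------------------------------
# velocity kymographs from tracks
# ---------------------------------------------------------------------------

def velocity_kymograph_from_tracks(tracks: Sequence[CellTrack], window_min: float = 10.0,
                                   dist_bin_um: float = 25.0, time_bin_min: float = 10.0,
                                   margin_track: CellTrack | None = None,
                                   dist_max_um: float | None = None,
                                   time_max_min: float | None = None,
                                   normalize: bool = False,
                                   require_full_window: bool = True) -> Kymograph:
    """Bin per-sample animal-ward velocities by distance-to-margin and time.

    The per-sample velocity is the change in distance-to-margin over a
    centered moving window of ``window_min`` minutes (10 min by default,
    matching a 14-frame window at ~0.7 min/frame).  With
    ``require_full_window`` (default) samples closer than half a window to a
    track end are dropped: a shrunk window divides the same diffusive
    position noise by a smaller time span, which inflates the velocity
    variance without bound.  Set it to False to instead shrink the window
    symmetrically at the ends.  Tracks shorter than the window are skipped
    with a warning.  If ``margin_track`` is given, distance to margin is the
    difference between the cell and margin AV coordinates at each time;
    otherwise tracks are assumed margin-relative already (margin at y = 0).
    """
    if window_min <= 0:
        raise ConfigurationError("window must be positive")
    if dist_bin_um <= 0 or time_bin_min <= 0:
        raise ConfigurationError("kymograph bin sizes must be positive")
    ds, ts, vs = [], [], []
    for tr in tracks:
        if tr.track_id == MARGIN_TRACK_ID:
            continue
        duration = tr.t[-1] - tr.t[0]
        if duration < window_min:
            warnings.warn(f"track {tr.track_id!r} shorter than the velocity window; skipped")
            continue
        if margin_track is not None:
            d = tr.y - np.interp(tr.t, margin_track.t, margin_track.y)
        else:
            d = tr.y.copy()
        for i, ti in enumerate(tr.t):
            h = min(window_min / 2.0, ti - tr.t[0], tr.t[-1] - ti)
            if h <= 0 or (require_full_window and h < window_min / 2.0):
                continue
            v = (np.interp(ti + h, tr.t, d) - np.interp(ti - h, tr.t, d)) / (2 * h)
            ds.append(d[i])
            ts.append(ti)
            vs.append(v)
    ds, ts, vs = map(np.asarray, (ds, ts, vs))
    if dist_max_um is None:
        dist_max_um = float(ds.max()) if ds.size else dist_bin_um
    if time_max_min is None:
        time_max_min = float(ts.max()) if ts.size else time_bin_min
    dist_edges = bin_edges_covering(0.0, dist_max_um, dist_bin_um)
    time_edges = bin_edges_covering(0.0, time_max_min, time_bin_min)
    nd, nt = len(dist_edges) - 1, len(time_edges) - 1
    vsum = np.zeros((nd, nt))
    nsum = np.zeros((nd, nt))
    if ds.size:
        keep = (ds >= dist_edges[0]) & (ds <= dist_edges[-1]) & (ts <= time_edges[-1])
        di = np.clip(np.digitize(ds[keep], dist_edges) - 1, 0, nd - 1)
        ti = np.clip(np.digitize(ts[keep], time_edges) - 1, 0, nt - 1)
        np.add.at(nsum, (di, ti), 1.0)
        np.add.at(vsum, (di, ti), vs[keep])
    with np.errstate(invalid="ignore"):
        values = np.where(nsum > 0, vsum / np.maximum(nsum, 1), np.nan)
    kym = Kymograph(dist_edges=dist_edges, time_edges=time_edges, values=values, counts=nsum)
    return kym.normalize() if normalize else kym


# ---------------------------------------------------------------------------
# intensity profiles and cell images
# ---------------------------------------------------------------------------

def normalize_intensity_profile(values) -> np.ndarray:
    """Background-subtract (minimum) and normalize to the maximum (= 1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DegenerateInputError("need at least two profile values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise DegenerateInputError("constant intensity profile cannot be normalized")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class LabeledCellImage:
    """Intensity image plus a per-cell boolean mask."""

    intensity: np.ndarray
    full_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        mask = np.asarray(self.full_mask, dtype=bool)
        object.__setattr__(self, "intensity", inten)
        object.__setattr__(self, "full_mask", mask)
        if inten.shape != mask.shape:
            raise ConfigurationError("intensity and mask shapes differ")
        if not mask.any():
            raise ConfigurationError("empty cell mask")
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel size must be positive")


def membrane_cytoplasm_ratio(image: LabeledCellImage, band_um: float = 1.25) -> float:
    """Mean membrane-band intensity over mean cytoplasm intensity.

    The full cell mask is eroded by ``band_um`` (Euclidean distance
    transform thresholded at the band width, so the erosion is pixel-size
    independent); the removed rim of constant ``band_um`` thickness is the
    membrane mask and the remainder the cytoplasm mask.  The ratio is a
    proxy for receptor internalization: low ratio = more internalized.
    """
    dist = ndimage.distance_transform_edt(image.full_mask,
                                          sampling=image.pixel_size_um)
    cyto = dist > band_um
    if not cyto.any():
        raise DegenerateInputError("erosion by the membrane band empties the cell mask")
    membr = image.full_mask & ~cyto
    mean_cyto = float(image.intensity[cyto].mean())
    if mean_cyto == 0:
        raise DegenerateInputError("zero cytoplasm mean intensity")
    return float(image.intensity[membr].mean()) / mean_cyto


# ---------------------------------------------------------------------------
# diffusion coefficient from MSD
# ---------------------------------------------------------------------------

def estimate_Dc_msd(tracks: Sequence[CellTrack], max_lag_min: float = 10.0):
    """Estimate the random-motility coefficient from short-term displacements.

    Pools squared displacements across tracks for every lag up to
    ``max_lag_min`` and fits ``MSD(tau) = 2 d D tau`` through the origin
    (d = spatial dimension of the tracks).  Ballistic motion (MSD growing
    quadratically) is detected with a curvature diagnostic and flagged.

    Returns a :class:`selfgrad.fitting.FitResult` whose ``estimate`` is D in
    um^2/min and whose diagnostics include ``linear_ok``.
    """
    from .fitting import FitResult

    if len(tracks) < 5:
        raise DegenerateInputError("need at least 5 tracks for an MSD estimate")
    dim = tracks[0].ndim
    lag_sq: dict[float, list] = {}
    for tr in tracks:
        if tr.ndim != dim:
            raise ConfigurationError("tracks mix 1D and 2D coordinates")
        pos = tr.coords()
        t = tr.t
        n = len(t)
        for j in range(1, n):
            lags = t[j:] - t[:-j]
            disp2 = np.sum((pos[j:] - pos[:-j]) ** 2, axis=1)
            for lag, d2 in zip(np.round(lags, 6), disp2):
                if lag <= max_lag_min:
                    lag_sq.setdefault(float(lag), []).append(float(d2))
    if len(lag_sq) < 2:
        raise DegenerateInputError("insufficient lag coverage below max_lag_min")
    taus = np.array(sorted(lag_sq))
    msd = np.array([np.mean(lag_sq[tau]) for tau in taus])
    slope = float(np.sum(msd * taus) / np.sum(taus * taus))
    D = slope / (2.0 * dim)
    resid = msd - slope * taus
    dof = max(len(taus) - 1, 1)
    se_slope = float(np.sqrt(np.sum(resid**2) / dof / np.sum(taus**2)))
    # curvature diagnostic: MSD = a tau + b tau^2; ballistic if the quadratic
    # part dominates the linear one at the largest lag
    A = np.column_stack([taus, taus**2])
    a, b = np.linalg.lstsq(A, msd, rcond=None)[0]
    tmax = taus[-1]
    linear_ok = not (abs(b) * tmax**2 > max(abs(a) * tmax, 1e-12))
    return FitResult(
        estimate=D,
        standard_error=se_slope / (2.0 * dim),
        residual_norm=float(np.linalg.norm(resid)),
        diagnostics={"linear_ok": linear_ok, "dimension": dim, "n_lags": len(taus)},
    )
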