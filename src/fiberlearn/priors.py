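"""Handcrafted single-fiber biomarkers used as priors.

Four quantities summarize fiber morphology:

* **Cosine angle sum (CAS)** — mean cosine of the angle between the local
  striation normal and the fiber main axis (``y``); 1 means perfectly parallel
  myofibrils. Estimated from a structure-tensor orientation field. Computed on
  one z-plane (2D-CAS) or over the volume (3D-CAS).
* **Sarcomere length (SL)** — the dominant axial banding period in µm, from
  the averaged axial power spectrum with parabolic sub-bin refinement.
* **Vernier density (VD)** — count of Y-shaped phase-dislocation defects in
  the striation per µm² of fiber area, detected as ridge-skeleton branch
  points after band-pass filtering at the sarcomere frequency.
* **Cross-sectional area (CSA)** — three estimators (morphological pixel
  counting, PCA ellipse, robust elliptic envelope) combined by a concordance
  rule: the mean of the two most concordant estimates is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from fiberlearn.io import FiberImage

MAIN_AXIS = 1  # y, after registration to the canonical reference
SL_SEARCH_BAND_UM = (1.5, 4.0)
MIN_FOREGROUND_VOXELS = 100


@dataclass
class PriorVector:
    """The four biomarkers (five values: CAS in 2D and 3D) with availability flags."""

    cas2d: float = math.nan
    cas3d: float = math.nan
    vd: float = math.nan  # count / µm²
    sl: float = math.nan  # µm
    csa: float = math.nan  # µm²
    available: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cas2d", "cas3d", "vd", "sl", "csa"):
            self.available.setdefault(name, not math.isnan(getattr(self, name)))

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "available"}

    names = ("cas2d", "cas3d", "vd", "sl", "csa")


@dataclass
class OrientationField:
    """Per-voxel unit striation-normal vectors with a coherence measure.

    ``vectors`` holds (z, y, x) components of the dominant structure-tensor
    eigenvector on foreground voxels; ``coherence`` in [0, 1] is the relative
    eigenvalue gap (λ1 − λ2) / (λ1 + λ2).
    """

    vectors: np.ndarray  # (nz, ny, nx, 3)
    coherence: np.ndarray  # (nz, ny, nx)
    foreground: np.ndarray  # bool (nz, ny, nx)


def foreground_mask(img: FiberImage) -> np.ndarray:
    """Foreground: nonzero voxels if the background was zeroed, else Otsu."""
    voxels = np.asarray(img.voxels)
    steps = {h.get("step") for h in img.meta.get("history", [])}
    if "zero_background_otsu" in steps or "standard_score" in steps:
        return voxels != 0
    if np.ptp(voxels) == 0:
        raise ValueError("constant image has no foreground")
    return voxels > threshold_otsu(voxels)


def estimate_orientations(img: FiberImage, scale: float = 1.0,
                          mask: np.ndarray | None = None) -> OrientationField:
    """Structure-tensor orientation analysis at Gaussian scale ``scale`` µm.

    The dominant eigenvector of the smoothed gradient outer product points
    along the striation normal (the direction of strongest intensity change).
    """
    voxels = np.asarray(img.voxels, dtype=np.float64)
    if mask is None:
        mask = foreground_mask(img)
    if not mask.any():
        raise ValueError("empty foreground")
    # keep clear of the fiber surface: the envelope edge has a strong radial
    # gradient that would contaminate the striation-normal estimate; small
    # fibers fall back to progressively lighter erosion
    for margin in (2.0 * scale, scale, 0.5 * scale):
        erode_vox = [max(1, int(round(margin / s))) for s in img.spacing]
        interior = ndimage.binary_erosion(
            mask, structure=np.ones([2 * e + 1 for e in erode_vox]))
        if interior.sum() >= MIN_FOREGROUND_VOXELS:
            mask = interior
            break
    sigma = tuple(scale / s for s in img.spacing)
    # derivative-of-Gaussian gradients: for a plane wave all components share
    # the same spectral attenuation, so the gradient DIRECTION is unbiased
    # (finite differences tilt it by up to several degrees at this band period)
    sigma_d = [max(0.8, s / 2) for s in sigma]
    grads = []
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        grads.append(ndimage.gaussian_filter(voxels, sigma=sigma_d, order=order)
                     / img.spacing[ax])
    tensor = np.empty(voxels.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            comp = ndimage.gaussian_filter(grads[i] * grads[j], sigma=sigma)
            tensor[..., i, j] = comp
            tensor[..., j, i] = comp
    tfg = tensor[mask]
    evals, evecs = np.linalg.eigh(tfg)  # ascending
    lam1, lam2 = evals[:, 2], evals[:, 1]
    total = lam1 + lam2
    coh_fg = np.where(total > 1e-30, (lam1 - lam2) / np.where(total > 0, total, 1.0), 0.0)
    vec_fg = evecs[:, :, 2]

    vectors = np.zeros(voxels.shape + (3,))
    coherence = np.zeros(voxels.shape)
    vectors[mask] = vec_fg
    coherence[mask] = coh_fg
    return OrientationField(vectors=vectors, coherence=coherence, foreground=mask)


def cosine_angle_sum(fld: OrientationField, mode: str = "3D",
                     plane: int | None = None) -> float:
    """Mean cos(theta) between striation normal and main axis over the foreground.

    theta is taken in [0, pi/2] (orientations are axial, sign-free). Returns
    NaN when fewer than 100 foreground voxels contribute.
    """
    if mode not in ("2D", "3D"):
        raise ValueError("mode must be '2D' or '3D'")
    if mode == "2D":
        if plane is None:
            plane = fld.foreground.shape[0] // 2
        if not 0 <= plane < fld.foreground.shape[0]:
            raise ValueError(f"plane {plane} outside volume")
        sel = np.zeros_like(fld.foreground)
        sel[plane] = fld.foreground[plane]
    else:
        sel = fld.foreground
    if sel.sum() < MIN_FOREGROUND_VOXELS:
        return math.nan
    cos_theta = np.abs(fld.vectors[sel][:, MAIN_AXIS])
    return float(cos_theta.mean())


def sarcomere_length(img: FiberImage, mask: np.ndarray | None = None,
                     band_um: tuple[float, float] = SL_SEARCH_BAND_UM,
                     peak_snr: float = 3.0) -> float:
    """Dominant axial banding period in µm; NaN when no credible spectral peak.

    Averages the power spectrum of mean-removed axial intensity lines over
    foreground columns, restricts the search to the physiological band, and
    refines the peak with parabolic interpolation. The peak must exceed
    ``peak_snr`` times the median in-band power.
    """
    voxels = np.asarray(img.voxels, dtype=np.float64)
    if mask is None:
        mask = foreground_mask(img)
    spacing_axis = img.spacing[MAIN_AXIS]
    n = voxels.shape[MAIN_AXIS]
    # columns with enough axial foreground extent
    col_counts = mask.sum(axis=MAIN_AXIS)
    good = col_counts >= max(16, int(0.5 * n))
    if not good.any():
        return math.nan
    lines = np.moveaxis(voxels, MAIN_AXIS, -1)[good]  # (n_lines, n)
    line_masks = np.moveaxis(mask, MAIN_AXIS, -1)[good]
    lines = np.where(line_masks, lines, np.nan)
    means = np.nanmean(lines, axis=1, keepdims=True)
    lines = np.where(line_masks, lines - means, 0.0)
    window = np.hanning(n)
    pad = 4 * n
    power = np.abs(np.fft.rfft(lines * window, n=pad, axis=1)) ** 2
    spectrum = power.mean(axis=0)
    freqs = np.fft.rfftfreq(pad, spacing_axis)
    lo, hi = 1.0 / band_um[1], 1.0 / band_um[0]
    band = (freqs >= lo) & (freqs <= hi)
    if band.sum() < 3:
        return math.nan
    band_power = spectrum[band]
    floor = np.median(band_power)
    k_local = int(np.argmax(band_power))
    if floor <= 0 or band_power[k_local] < peak_snr * floor:
        return math.nan
    k = np.where(band)[0][k_local]
    # parabolic sub-bin refinement
    if 0 < k < len(spectrum) - 1:
        y0, y1, y2 = spectrum[k - 1], spectrum[k], spectrum[k + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-30 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_peak = freqs[k] + delta * (freqs[1] - freqs[0])
    return float(1.0 / f_peak)


def _branch_points(skel: np.ndarray) -> np.ndarray:
    """Coordinates of skeleton pixels with 3+ skeleton neighbours (8-connectivity)."""
    neighbours = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                                  mode="constant") - skel
    pts = np.argwhere(skel & (neighbours >= 3))
    return pts


def _merge_close(points: np.ndarray, min_dist: float) -> list[np.ndarray]:
    """Greedy clustering: points closer than min_dist count as one defect."""
    merged: list[np.ndarray] = []
    for p in points:
        if all(np.linalg.norm(p - q) >= min_dist for q in merged):
            merged.append(p)
    return merged


def vernier_density(img: FiberImage, mask: np.ndarray | None = None,
                    sl: float | None = None) -> tuple[float, dict]:
    """Y-defect count per µm² of fiber area, with diagnostics.

    Per z-plane the banding frequency is isolated by a difference-of-Gaussians
    band-pass along the axis, positive band ridges are skeletonized, and
    skeleton branch points (where one band forks into two — the vernier's Y)
    are counted after merging detections closer than SL/2. The total count is
    normalized by the summed foreground area. Requires a valid SL estimate.
    """
    if mask is None:
        mask = foreground_mask(img)
    if sl is None:
        sl = sarcomere_length(img, mask=mask)
    if not math.isfinite(sl):
        return math.nan, {"reason": "sarcomere length unavailable"}
    sz, sy, sx = img.spacing
    voxels = np.asarray(img.voxels, dtype=np.float64)
    period_vox = sl / sy
    sigma_fine = period_vox / 6.0
    sigma_coarse = period_vox / 2.0
    min_dist_vox = (sl / 2) / sy

    per_plane: list[int] = []
    all_points: list[np.ndarray] = []
    max_area_px = 0
    n_contributing = 0
    selem = morphology.disk(max(3, int(round(period_vox))))
    for z in range(voxels.shape[0]):
        m = mask[z]
        if m.sum() < MIN_FOREGROUND_VOXELS:
            continue
        # stay one banding period clear of the fiber surface: the envelope edge
        # bends the band-pass ridges and spawns spurious junctions
        interior = ndimage.binary_erosion(m, structure=selem)
        if not interior.any():
            continue
        n_contributing += 1
        max_area_px = max(max_area_px, int(m.sum()))
        plane = voxels[z]
        bp = (ndimage.gaussian_filter(plane, (sigma_fine, sigma_fine * 2))
              - ndimage.gaussian_filter(plane, (sigma_coarse, sigma_coarse * 2)))
        # a terminating bright band makes the adjacent dark bands merge (and
        # vice versa), so the Y-junction may sit in either polarity's skeleton;
        # a fraction of the band-pass amplitude gates out noise-born junctions
        gate = 0.2 * float(np.std(bp[interior])) if interior.sum() > 1 else 0.0
        pts = []
        for ridges in ((bp > gate) & m, (bp < -gate) & m):
            skel = morphology.skeletonize(ridges)
            pts.extend(p for p in _branch_points(skel) if interior[tuple(p)])
        merged = _merge_close(np.asarray(pts), min_dist_vox) if len(pts) else []
        per_plane.append(len(merged))
        all_points.extend(merged)
    if max_area_px == 0:
        return math.nan, {"reason": "empty foreground"}
    # a vernier is a dislocation line: its Y-junction recurs at the same (y, x)
    # in successive planes (bright- and dark-band junctions straddle the
    # terminating band, half a period apart), so distinct defects = clusters
    # of detections within one period
    defects = _merge_close(np.asarray(all_points), period_vox) if all_points else []
    area_um2 = max_area_px * sy * sx  # projected fiber area
    vd = len(defects) / area_um2
    diag = {
        "detected_count": len(defects),
        "per_plane": per_plane,
        "planes_counted": n_contributing,
        "projected_area_um2": area_um2,
    }
    return float(vd), diag


# ---------------------------------------------------------------------------
# cross-sectional area
# ---------------------------------------------------------------------------

EDGE_SLICES_EXCLUDED = 10  # top and bottom slices dropped before averaging
MIN_RETAINED_SLICES = 3
ENVELOPE_COVERAGE = 0.8  # 1 - contamination


def _slice_stack(mask: np.ndarray, axis: int = MAIN_AXIS) -> np.ndarray:
    """Binary cross-section stack (n_slices, h, w) along the fiber axis."""
    return np.moveaxis(np.asarray(mask, dtype=bool), axis, 0)


def _retained(stack: np.ndarray) -> np.ndarray:
    n = stack.shape[0]
    return stack[EDGE_SLICES_EXCLUDED:n - EDGE_SLICES_EXCLUDED]


def csa_exact_counting(mask: np.ndarray, spacing: tuple[float, float],
                       axis: int = MAIN_AXIS) -> float:
    """Mean per-slice pixel count after 2D opening and closing, in µm².

    ``spacing`` is the in-plane pixel size (rows, cols) of a cross-section.
    """
    stack = _retained(_slice_stack(mask, axis))
    if stack.shape[0] < MIN_RETAINED_SLICES:
        return math.nan
    radius = max(1, int(round(1.0 / min(spacing))))  # 1 µm disk
    selem = morphology.disk(radius)
    pixel_area = spacing[0] * spacing[1]
    areas = []
    for sl in stack:
        cleaned = ndimage.binary_closing(ndimage.binary_opening(sl, structure=selem),
                                         structure=selem)
        areas.append(cleaned.sum() * pixel_area)
    return float(np.mean(areas))


def _slice_coords(sl: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    pts = np.argwhere(sl).astype(np.float64)
    pts[:, 0] *= spacing[0]
    pts[:, 1] *= spacing[1]
    return pts


def csa_pca_ellipse(mask: np.ndarray, spacing: tuple[float, float],
                    axis: int = MAIN_AXIS) -> float:
    """Mean per-slice PCA-ellipse area in µm².

    Radii use the uniform-ellipse second-moment relation a = 2·sqrt(λ), which
    makes the estimator unbiased on solid elliptical cross-sections.
    """
    stack = _retained(_slice_stack(mask, axis))
    if stack.shape[0] < MIN_RETAINED_SLICES:
        return math.nan
    areas = []
    for sl in stack:
        pts = _slice_coords(sl, spacing)
        if len(pts) < 8:
            continue
        cov = np.cov(pts.T)
        evals = np.linalg.eigvalsh(cov)
        if evals[0] <= 0:
            continue  # degenerate (collinear) slice
        r = 2.0 * np.sqrt(evals)
        areas.append(math.pi * r[0] * r[1])
    if len(areas) < MIN_RETAINED_SLICES:
        return math.nan
    return float(np.mean(areas))


def csa_elliptic_envelope(mask: np.ndarray, spacing: tuple[float, float],
                          axis: int = MAIN_AXIS,
                          contamination: float = 0.2,
                          n_iter: int = 3) -> float:
    """Mean per-slice robust-ellipse area in µm² (contamination 0.2).

    Iterated Mahalanobis trimming keeps the most central (1 − contamination)
    fraction of pixels; the trimmed covariance is rescaled by the
    uniform-ellipse factor (trimmed λ = coverage × full λ), so a clean solid
    ellipse is estimated without bias while up to 20% gross outliers are
    rejected.
    """
    coverage = 1.0 - contamination
    stack = _retained(_slice_stack(mask, axis))
    if stack.shape[0] < MIN_RETAINED_SLICES:
        return math.nan
    areas = []
    for sl in stack:
        pts = _slice_coords(sl, spacing)
        if len(pts) < 10:
            continue
        keep = pts
        n_keep = max(10, int(coverage * len(pts)))
        for _ in range(n_iter):
            mu = keep.mean(axis=0)
            cov = np.cov(keep.T)
            if np.linalg.det(cov) <= 0:
                break
            # re-select the most central coverage fraction of ALL points
            d2 = np.einsum("ni,ij,nj->n", pts - mu, np.linalg.inv(cov), pts - mu)
            keep = pts[np.argsort(d2)[:n_keep]]
        cov = np.cov(keep.T)
        evals = np.linalg.eigvalsh(cov / coverage)
        if evals[0] <= 0:
            continue
        r = 2.0 * np.sqrt(evals)
        areas.append(math.pi * r[0] * r[1])
    if len(areas) < MIN_RETAINED_SLICES:
        return math.nan
    return float(np.mean(areas))


def smart_combine(estimates: dict[str, float]) -> tuple[float, dict]:
    """Concordance rule: mean of the two most agreeing estimates.

    With only one finite estimate the value is returned with
    ``low_confidence``; with none, NaN.
    """
    valid = {k: v for k, v in estimates.items() if math.isfinite(v)}
    diag: dict = {"estimates": estimates, "low_confidence": False}
    if not valid:
        diag["low_confidence"] = True
        return math.nan, diag
    if len(valid) == 1:
        diag["low_confidence"] = True
        ((k, v),) = valid.items()
        diag["used"] = [k]
        return float(v), diag
    names = list(valid)
    best_pair, best_gap = None, math.inf
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            gap = abs(valid[names[i]] - valid[names[j]])
            if gap < best_gap:
                best_gap, best_pair = gap, (names[i], names[j])
    diag["used"] = list(best_pair)
    diag["discarded"] = [k for k in names if k not in best_pair]
    return float((valid[best_pair[0]] + valid[best_pair[1]]) / 2.0), diag


def csa_smart(mask: np.ndarray, spacing: tuple[float, float],
              axis: int = MAIN_AXIS) -> tuple[float, dict]:
    """Combined CSA: all three algorithms, concordance-selected pair mean."""
    estimates = {
        "exact_counting": csa_exact_counting(mask, spacing, axis),
        "pca_ellipse": csa_pca_ellipse(mask, spacing, axis),
        "elliptic_envelope": csa_elliptic_envelope(mask, spacing, axis),
    }
    return smart_combine(estimates)


def compute_priors(img: FiberImage, mask: np.ndarray | None = None,
                   orientation_scale: float = 1.0) -> PriorVector:
    """Assemble the full prior vector; per-prior failures set availability flags."""
    if mask is None:
        try:
            mask = foreground_mask(img)
        except ValueError:
            mask = np.zeros(img.shape, dtype=bool)

    cas2d = cas3d = math.nan
    if mask.sum() >= MIN_FOREGROUND_VOXELS:
        fld = estimate_orientations(img, scale=orientation_scale, mask=mask)
        cas3d = cosine_angle_sum(fld, "3D")
        cas2d = cosine_angle_sum(fld, "2D", plane=img.shape[0] // 2)

    sl = sarcomere_length(img, mask=mask)
    vd, _ = vernier_density(img, mask=mask, sl=sl) if math.isfinite(sl) else (math.nan, {})
    spacing_plane = (img.spacing[0], img.spacing[2])  # cross-section is (z, x)
    csa, _ = csa_smart(mask, spacing_plane)
    return PriorVector(cas2d=cas2d, cas3d=cas3d, vd=vd, sl=sl, csa=csa)
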