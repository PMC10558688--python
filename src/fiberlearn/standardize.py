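"""Cross-study image standardization.

The fixed pipeline order is: resample to isotropic spacing → median denoise →
Otsu background zeroing → (contrast enhancement, used only to estimate the
registration transform) → rigid registration to a canonical reference →
probability-atlas cropping → sample-wise standard score. The enhanced image
never propagates downstream: the estimated transform is applied to the
non-enhanced volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage import exposure
from skimage.filters import threshold_otsu

from fiberlearn.io import FiberImage, Labbook


@dataclass
class StandardizationConfig:
    target_spacing: float = 0.5  # µm, isotropic
    median_size: float = 1.0  # µm
    atlas_threshold: float = 0.85  # probability
    enhancement: bool = True
    clahe_tile_um: float = 16.0
    clahe_clip_limit: float = 0.01
    registration_method: str = "mutual_information"  # or "principal_axes"

    def __post_init__(self) -> None:
        if not 0 < self.atlas_threshold < 1:
            raise ValueError("atlas_threshold must be in (0, 1)")
        if self.target_spacing <= 0:
            raise ValueError("target_spacing must be > 0")


@dataclass
class RigidTransform:
    """Euler rotation (degrees) + translation (µm) about a physical center."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # about (z, y, x) axes
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # (z, y, x) µm
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    converged: bool = True

    def to_sitk(self) -> sitk.Euler3DTransform:
        t = sitk.Euler3DTransform()
        # SimpleITK works in (x, y, z) physical coordinates
        t.SetCenter(tuple(self.center[::-1]))
        rz, ry, rx = np.deg2rad(self.rotation)
        t.SetRotation(rx, ry, rz)
        t.SetTranslation(tuple(self.translation[::-1]))
        return t

    @classmethod
    def from_sitk(cls, t: sitk.Euler3DTransform, converged: bool = True) -> "RigidTransform":
        rx, ry, rz = t.GetAngleX(), t.GetAngleY(), t.GetAngleZ()
        tx, ty, tz = t.GetTranslation()
        cx, cy, cz = t.GetCenter()
        return cls(
            rotation=tuple(np.rad2deg([rz, ry, rx])),
            translation=(tz, ty, tx),
            center=(cz, cy, cx),
            converged=converged,
        )


def _to_sitk(img: FiberImage) -> sitk.Image:
    out = sitk.GetImageFromArray(np.asarray(img.voxels, dtype=np.float32))
    out.SetSpacing(tuple(img.spacing[::-1]))
    out.SetOrigin(tuple(img.origin[::-1]))
    return out


def resample_isotropic(img: FiberImage, target: float) -> FiberImage:
    """Linear resampling onto an isotropic grid preserving physical extent."""
    if target <= 0:
        raise ValueError("target spacing must be > 0")
    if any(n <= 1 for n in img.shape):
        raise ValueError(f"degenerate axis in shape {img.shape}")
    zoom = tuple(s / target for s in img.spacing)
    if all(abs(z - 1.0) < 1e-12 for z in zoom):
        return img.with_voxels(img.voxels.copy(), step="resample_isotropic", target=target)
    voxels = ndimage.zoom(np.asarray(img.voxels, dtype=np.float32), zoom, order=1,
                          mode="nearest", grid_mode=True)
    out = FiberImage(voxels=voxels, spacing=(target,) * 3, origin=img.origin,
                     meta={k: v for k, v in img.meta.items()})
    out.meta["history"] = list(img.meta.get("history", []))
    out.record("resample_isotropic", target=target)
    return out


def denoise_median(img: FiberImage, size: float = 1.0) -> FiberImage:
    """Median filter with an odd window of physical size ``size`` µm per axis."""
    if size < max(img.spacing):
        raise ValueError("median size must be >= voxel spacing")
    window = []
    for s in img.spacing:
        w = int(round(size / s))
        w = max(w, 3)
        if w % 2 == 0:
            w += 1
        window.append(w)
    voxels = ndimage.median_filter(img.voxels, size=tuple(window))
    return img.with_voxels(voxels, step="denoise_median", size=size, window=window)


def zero_background_otsu(img: FiberImage) -> tuple[FiberImage, np.ndarray]:
    """Zero voxels below the Otsu threshold; return image and foreground mask."""
    voxels = np.asarray(img.voxels)
    if np.ptp(voxels) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    thr = threshold_otsu(voxels)
    mask = voxels > thr
    out = img.with_voxels(np.where(mask, voxels, 0.0), step="zero_background_otsu",
                          threshold=float(thr))
    return out, mask


def enhance_contrast_clahe3d(
    img: FiberImage, tile_size: float = 16.0, clip_limit: float = 0.01
) -> FiberImage:
    """3D contrast-limited adaptive histogram equalization on the foreground.

    Output is rescaled to [0, 1]; exact-zero background voxels stay zero.
    """
    voxels = np.asarray(img.voxels, dtype=np.float64)
    fg = voxels != 0
    if not fg.any():
        raise ValueError("empty foreground")
    lo, hi = voxels.min(), voxels.max()
    if hi == lo:
        return img.with_voxels(voxels, step="enhance_contrast_clahe3d",
                               tile_size=tile_size, clip_limit=clip_limit)
    scaled = (voxels - lo) / (hi - lo)
    kernel = tuple(max(4, int(round(tile_size / s))) for s in img.spacing)
    kernel = tuple(min(k, n) for k, n in zip(kernel, img.shape))
    out = exposure.equalize_adapthist(scaled, kernel_size=kernel, clip_limit=clip_limit)
    out = np.where(fg, out, 0.0)
    omin, omax = out[fg].min(), out.max()
    if omax > omin:
        out = np.where(fg, (out - omin) / (omax - omin), 0.0)
    return img.with_voxels(out, step="enhance_contrast_clahe3d",
                           tile_size=tile_size, clip_limit=clip_limit)


def _principal_axes_transform(moving: FiberImage, reference: FiberImage) -> RigidTransform:
    """Fast fallback: align centroids and in-plane principal axis (about z)."""

    def _stats(img: FiberImage):
        v = np.clip(np.asarray(img.voxels, dtype=np.float64), 0, None)
        total = v.sum()
        if total <= 0:
            raise ValueError("cannot align an empty image")
        grids = np.meshgrid(*[(np.arange(n) * s) for n, s in zip(img.shape, img.spacing)],
                            indexing="ij")
        com = np.array([(g * v).sum() / total for g in grids])  # (z, y, x) µm
        dy = grids[1] - com[1]
        dx = grids[2] - com[2]
        cyy = (v * dy * dy).sum() / total
        cxx = (v * dx * dx).sum() / total
        cxy = (v * dx * dy).sum() / total
        angle = 0.5 * np.arctan2(2 * cxy, cyy - cxx)  # main axis tilt from y, about z
        return com, angle

    com_m, ang_m = _stats(moving)
    com_r, ang_r = _stats(reference)
    rot_z = np.rad2deg(ang_m - ang_r)
    if rot_z > 90:
        rot_z -= 180
    elif rot_z < -90:
        rot_z += 180
    return RigidTransform(rotation=(rot_z, 0.0, 0.0),
                          translation=tuple(com_m - com_r), center=tuple(com_r))


def register_rigid(
    moving: FiberImage,
    reference: FiberImage,
    method: str = "mutual_information",
    iterations: int = 600,
    bins: int = 32,
    levels: int = 6,
) -> RigidTransform:
    """Estimate the rigid transform mapping reference coordinates onto the moving image.

    Default: multi-resolution Euler registration of a Mattes mutual-information
    metric (32 bins, up to 6 levels, ≤600 iterations per level), initialized at
    the centers of gravity. ``method="principal_axes"`` is a fast moment-based
    fallback. On non-convergence the identity is returned with a warning flag.
    """
    if moving.spacing != reference.spacing:
        raise ValueError("moving and reference must share a common spacing")
    if method == "principal_axes":
        return _principal_axes_transform(moving, reference)

    fixed_itk = _to_sitk(reference)
    moving_itk = _to_sitk(moving)
    initial = sitk.CenteredTransformInitializer(
        fixed_itk, moving_itk, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.MOMENTS,
    )

    def _metric(transform) -> float:
        m = sitk.ImageRegistrationMethod()
        m.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
        m.SetInterpolator(sitk.sitkLinear)
        m.SetInitialTransform(transform, inPlace=False)
        return m.MetricEvaluate(fixed_itk, moving_itk)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=bins)
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=iterations,
        relaxationFactor=0.6, gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    max_levels = int(np.floor(np.log2(min(reference.shape) / 8))) + 1
    n_levels = max(1, min(levels, max_levels))
    shrink = [2 ** (n_levels - 1 - i) for i in range(n_levels)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([max(0, s // 2) for s in shrink])
    reg.SetInitialTransform(initial, inPlace=False)
    try:
        final = reg.Execute(fixed_itk, moving_itk)
        converged = np.isfinite(reg.GetMetricValue())
    except RuntimeError as err:  # pragma: no cover - ITK failure path
        warnings.warn(f"registration failed ({err}); returning identity")
        return RigidTransform(converged=False)
    if not converged:
        warnings.warn("registration did not converge; returning identity")
        return RigidTransform(converged=False)
    euler = final.Downcast()
    if isinstance(euler, sitk.CompositeTransform):
        euler = euler.GetBackTransform().Downcast()
    # never degrade the metric: the striation is periodic along the axis, so the
    # optimizer can settle on a band-shifted local optimum worse than its start
    candidates = [
        (RigidTransform(), sitk.Euler3DTransform()),
        (RigidTransform.from_sitk(initial.Downcast()), initial),
        (RigidTransform.from_sitk(euler), euler),
    ]
    scored = [(_metric(t_itk), i) for i, (_, t_itk) in enumerate(candidates)]
    best = min(scored)[1]
    result = candidates[best][0]
    result.converged = True
    return result


def apply_transform(img: FiberImage, transform: RigidTransform,
                    reference: FiberImage) -> FiberImage:
    """Resample ``img`` through the rigid transform onto the reference grid."""
    moving_itk = _to_sitk(img)
    ref_itk = _to_sitk(reference)
    out = sitk.Resample(moving_itk, ref_itk, transform.to_sitk(), sitk.sitkLinear, 0.0)
    arr = sitk.GetArrayFromImage(out)
    res = FiberImage(voxels=arr, spacing=reference.spacing, origin=reference.origin,
                     meta={k: v for k, v in img.meta.items() if k != "history"})
    res.meta["history"] = list(img.meta.get("history", []))
    res.record("apply_transform", rotation=list(transform.rotation),
               translation=list(transform.translation))
    return res


def similarity_mutual_information(a: FiberImage, b: FiberImage, bins: int = 32) -> float:
    """Mutual information between two images on a common grid (higher = more similar)."""
    x = np.asarray(a.voxels).ravel()
    y = np.asarray(b.voxels).ravel()
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def build_presence_atlas(masks: list[np.ndarray]) -> np.ndarray:
    """Voxelwise presence probability: mean of binarized registered masks."""
    if len(masks) < 2:
        raise ValueError("need at least 2 masks")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("masks must share a common grid")
    stack = np.stack([(np.asarray(m) > 0).astype(np.float64) for m in masks])
    return stack.mean(axis=0)


def probability_box(atlas: np.ndarray, threshold: float) -> tuple[slice, slice, slice]:
    """Axis-aligned bounding box (half-open slices) of {atlas > threshold}."""
    sel = atlas > threshold
    if not sel.any():
        raise ValueError(
            f"no voxel exceeds probability {threshold}; lower the atlas threshold"
        )
    slices = []
    for ax in range(atlas.ndim):
        proj = sel.any(axis=tuple(i for i in range(atlas.ndim) if i != ax))
        idx = np.where(proj)[0]
        slices.append(slice(int(idx[0]), int(idx[-1]) + 1))
    return tuple(slices)


def crop_to_probability_box(img: FiberImage, atlas: np.ndarray, threshold: float = 0.85) -> FiberImage:
    """Crop to the bounding box of voxels whose presence probability exceeds the threshold."""
    if atlas.shape != img.shape:
        raise ValueError("atlas grid does not match image")
    box = probability_box(atlas, threshold)
    voxels = np.asarray(img.voxels)[box]
    origin = tuple(o + s.start * sp for o, s, sp in zip(img.origin, box, img.spacing))
    out = FiberImage(voxels=voxels, spacing=img.spacing, origin=origin,
                     meta={k: v for k, v in img.meta.items() if k != "history"})
    out.meta["history"] = list(img.meta.get("history", []))
    out.record("crop_to_probability_box", threshold=threshold,
               box=[[s.start, s.stop] for s in box])
    return out


def standard_score(img: FiberImage, foreground_only: bool = True) -> FiberImage:
    """Sample-wise standard score (mean 0, sd 1), over foreground voxels by default.

    Background is exact zero by construction after Otsu zeroing, so including
    it would let the background fraction dominate the score.
    """
    voxels = np.asarray(img.voxels, dtype=np.float64)
    sel = voxels != 0 if foreground_only else np.ones_like(voxels, dtype=bool)
    if not sel.any():
        raise ValueError("empty foreground")
    mu = voxels[sel].mean()
    sd = voxels[sel].std()
    if sd < 1e-12:
        raise ValueError("zero variance: standard score undefined")
    out = np.where(sel, (voxels - mu) / sd, 0.0)
    return img.with_voxels(out, step="standard_score", mean=float(mu), sd=float(sd),
                           foreground_only=foreground_only)


PIPELINE_ORDER = [
    "resample_isotropic",
    "denoise_median",
    "zero_background_otsu",
    "apply_transform",
    "crop_to_probability_box",
    "standard_score",
]


def standardize_cohort(
    images: list[FiberImage],
    reference: FiberImage,
    config: StandardizationConfig | None = None,
    labbook: Labbook | None = None,
) -> list[FiberImage]:
    """Run the full standardization pipeline over a cohort.

    The contrast-enhanced variant is used only to estimate each rigid
    transform; the transform is applied to the non-enhanced image. The
    presence atlas and its crop box are computed once from all registered
    foreground masks and applied identically to every image.
    """
    config = config or StandardizationConfig()
    ref = resample_isotropic(reference, config.target_spacing)
    ref = denoise_median(ref, config.median_size)
    ref, _ = zero_background_otsu(ref)
    ref_enh = (enhance_contrast_clahe3d(ref, config.clahe_tile_um, config.clahe_clip_limit)
               if config.enhancement else ref)

    registered: list[FiberImage] = []
    masks: list[np.ndarray] = []
    for img in images:
        x = resample_isotropic(img, config.target_spacing)
        x = denoise_median(x, config.median_size)
        x, _ = zero_background_otsu(x)
        enh = (enhance_contrast_clahe3d(x, config.clahe_tile_um, config.clahe_clip_limit)
               if config.enhancement else x)
        transform = register_rigid(enh, ref_enh, method=config.registration_method)
        x = apply_transform(x, transform, ref)  # transform estimated on enhanced, applied to plain
        registered.append(x)
        masks.append(np.asarray(x.voxels) > 0)
        if labbook is not None:
            labbook.log("standardize", sample_id=img.meta.get("sample_id"),
                        transform=transform, checksum=x.checksum())

    atlas = build_presence_atlas(masks)
    out: list[FiberImage] = []
    for x in registered:
        x = crop_to_probability_box(x, atlas, config.atlas_threshold)
        x = standard_score(x)
        out.append(x)
        if labbook is not None:
            labbook.log("finalize", sample_id=x.meta.get("sample_id"),
                        shape=list(x.shape), checksum=x.checksum())
    return out
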