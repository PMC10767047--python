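"""Register a fluorescence image to the spot frame and find genes whose
spatial expression tracks image-derived latent features.

The registration chain is rigid -> affine (-> optional nonlinear), each
stage run over a 3-level multi-resolution pyramid with a mean-squared-
error metric and Powell optimization.  The nonlinear stage is a
Gaussian-regularized demons update, a deliberately simple stand-in for
diffeomorphic methods that is adequate for the small residual warps in
this pipeline.

Downstream, 32x32 patches centred at spot positions are reduced to a
training-free feature bank, PCA gives per-spot latent components
("ImageLatent_1", ...), and each gene's log-normalized expression is
regressed on a latent component; the top genes by regression coefficient
are the image-associated set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize
from skimage.color import rgb2gray
from skimage.filters import gaussian as sk_gaussian
from skimage.filters import threshold_otsu
from skimage.transform import rescale

from .transforms import (AffineTransform, DisplacementField, RigidTransform,
                         Transform, TransformChain, warp_image)


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_image(image: np.ndarray, mask_sigma: float = 5.0):
    """Grayscale conversion, Otsu brain mask, Gaussian smoothing (sigma 5).

    Returns ``(gray, mask, smoothed)``; the original image is untouched
    and smoothing is applied to a pipeline copy only.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        gray = rgb2gray(img)
    elif img.ndim == 2:
        gray = img.copy()
    else:
        raise ValueError("image must be 2-D grayscale or RGB")
    if gray.max() > 1.0:
        gray = gray / gray.max()
    if gray.max() == 0:
        raise ValueError("all-zero image: empty mask")
    thresh = threshold_otsu(gray)
    mask = gray > thresh
    smoothed = sk_gaussian(gray, sigma=mask_sigma, preserve_range=True)
    return gray, mask, smoothed


# ---------------------------------------------------------------------------
# registration


@dataclass
class RegistrationResult:
    chain: TransformChain           # maps moving -> fixed coordinates
    metric_value: float
    converged: bool
    landmark_rmse: float | None = None
    stage_metrics: dict = field(default_factory=dict)


def _mse(fixed: np.ndarray, warped: np.ndarray) -> float:
    return float(np.mean((fixed - warped) ** 2))


def _masked_warp_mse(moving: np.ndarray, W: Transform,
                     fixed: np.ndarray, min_overlap: float = 0.5) -> float:
    """MSE over pixels whose sampling point falls inside the moving image.

    Restricting to validly-sampled pixels keeps zero-padded wedges (from
    rotation/translation) out of the metric; a minimum-overlap guard
    stops the optimizer from shrinking the valid region instead of
    aligning content.
    """
    h, w = fixed.shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    src = W.apply(pts)
    valid = ((src[:, 0] >= 0) & (src[:, 0] <= moving.shape[1] - 1)
             & (src[:, 1] >= 0) & (src[:, 1] <= moving.shape[0] - 1))
    frac = valid.mean()
    if frac < min_overlap:
        return 1e6 * (1 + min_overlap - frac)
    sampled = ndimage.map_coordinates(moving, [src[:, 1], src[:, 0]],
                                      order=1, mode="constant", cval=0.0)
    diff = (fixed.ravel() - sampled)[valid]
    return float(np.mean(diff ** 2))


def _pyramid(image: np.ndarray, levels):
    out = []
    for f in levels:
        if f == 1:
            out.append(image)
        else:
            out.append(rescale(image, 1.0 / f, anti_aliasing=True,
                               preserve_range=True))
    return out


def _rigid_from_params(params, center) -> RigidTransform:
    return RigidTransform(params[0], params[1:3], center=center)


def _affine_from_params(params) -> AffineTransform:
    return AffineTransform(np.array(params[:4]).reshape(2, 2), params[4:6])


def register(moving: np.ndarray, fixed: np.ndarray, *,
             stages=("rigid", "affine"), landmarks=None,
             pyramid_levels=(4, 2, 1), demons_iter: int = 30,
             demons_sigma: float = 2.0) -> RegistrationResult:
    """Estimate the transform chain mapping ``moving`` onto ``fixed``.

    Internally the optimizer parameterizes the *resampling* map W (fixed
    frame -> moving frame); the returned chain is its inverse, mapping
    moving coordinates into the fixed (spot) frame.  When ``landmarks``
    (a pair of matched (n, 2) point arrays, moving then fixed) are given,
    the landmark RMSE of the recovered chain is reported.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    mov_pyr = _pyramid(moving, pyramid_levels)
    fix_pyr = _pyramid(fixed, pyramid_levels)
    stage_metrics: dict = {}
    converged = True

    # --- linear stages: optimize W = fixed -> moving ------------------
    w_linear: Transform | None = None
    if "rigid" in stages or "affine" in stages:
        params = np.array([0.0, 0.0, 0.0])  # theta, tx, ty at coarsest level
        for level, (mv, fx) in enumerate(zip(mov_pyr, fix_pyr)):
            factor = pyramid_levels[level]
            center = np.array([fx.shape[1] / 2.0, fx.shape[0] / 2.0])

            def cost_rigid(p):
                return _masked_warp_mse(mv, _rigid_from_params(p, center), fx)

            if level > 0:
                scale_up = pyramid_levels[level - 1] / factor
                params = np.array([params[0], params[1] * scale_up,
                                   params[2] * scale_up])
            res = minimize(cost_rigid, params, method="Powell",
                           options={"xtol": 1e-4, "ftol": 1e-7,
                                    "maxiter": 2000})
            converged &= bool(res.success)
            params = res.x
        center = np.array([fixed.shape[1] / 2.0, fixed.shape[0] / 2.0])
        w_linear = _rigid_from_params(params, center)
        stage_metrics["rigid"] = _masked_warp_mse(moving, w_linear, fixed)

    if "affine" in stages:
        H = w_linear.as_affine() if isinstance(w_linear, RigidTransform) \
            else w_linear
        ap = np.concatenate([H.matrix.ravel(), H.translation])
        for level, (mv, fx) in enumerate(zip(mov_pyr, fix_pyr)):
            factor = pyramid_levels[level]
            scale = 1.0 / factor

            def cost_affine(p):
                # translation stored at full resolution; rescale per level
                W = AffineTransform(np.array(p[:4]).reshape(2, 2),
                                    np.array(p[4:6]) * scale)
                return _masked_warp_mse(mv, W, fx)

            res = minimize(cost_affine, ap, method="Powell",
                           options={"xtol": 1e-5, "ftol": 1e-8,
                                    "maxiter": 4000})
            converged &= bool(res.success)
            ap = res.x
        w_linear = _affine_from_params(ap)
        stage_metrics["affine"] = _masked_warp_mse(moving, w_linear, fixed)

    if w_linear is None:
        w_linear = AffineTransform(np.eye(2), np.zeros(2))

    transforms_w = [w_linear]
    if "nonlinear" in stages:
        resampled = warp_image(moving, w_linear, fixed.shape)
        disp = _demons(resampled, fixed, n_iter=demons_iter,
                       sigma=demons_sigma)
        # W_total(q) = W_linear(q + u(q)); the displacement acts first in
        # the fixed frame, then the linear map carries into moving frame.
        linear_mse = _masked_warp_mse(moving, w_linear, fixed)
        nl_mse = _masked_warp_mse(moving, TransformChain([disp, w_linear]),
                                  fixed)
        if nl_mse < linear_mse:
            transforms_w = [disp, w_linear]
            stage_metrics["nonlinear"] = nl_mse
        else:
            warnings.warn("nonlinear stage did not improve the metric; "
                          "keeping the linear transform")
            stage_metrics["nonlinear"] = linear_mse

    w_chain = TransformChain(transforms_w, domain="fixed", codomain="moving")
    chain = w_chain.inverse()
    chain.domain, chain.codomain = "moving", "fixed"
    metric = stage_metrics[list(stage_metrics)[-1]] if stage_metrics else \
        _mse(fixed, moving)
    if not converged:
        warnings.warn("registration optimizer did not fully converge; "
                      "returning best-so-far transform")
    rmse = None
    if landmarks is not None:
        pts_moving, pts_fixed = landmarks
        mapped = chain.apply(np.asarray(pts_moving, dtype=float))
        rmse = float(np.sqrt(np.mean(np.sum(
            (mapped - np.asarray(pts_fixed, dtype=float)) ** 2, axis=1))))
    return RegistrationResult(chain, metric, converged, rmse, stage_metrics)


def _demons(moving: np.ndarray, fixed: np.ndarray, n_iter: int = 30,
            sigma: float = 2.0, step_cap: float = 2.0) -> DisplacementField:
    """Gaussian-regularized demons: additive updates smoothed each step."""
    u = np.zeros(fixed.shape + (2,))
    h, w = fixed.shape
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    for _ in range(n_iter):
        sample_x, sample_y = xs + u[..., 0], ys + u[..., 1]
        warped = ndimage.map_coordinates(moving, [sample_y, sample_x],
                                         order=1, mode="nearest")
        diff = fixed - warped
        gy, gx = np.gradient(warped)
        denom = gx ** 2 + gy ** 2 + diff ** 2 + 1e-9
        du_x = np.clip(diff * gx / denom, -step_cap, step_cap)
        du_y = np.clip(diff * gy / denom, -step_cap, step_cap)
        u[..., 0] = ndimage.gaussian_filter(u[..., 0] + du_x, sigma)
        u[..., 1] = ndimage.gaussian_filter(u[..., 1] + du_y, sigma)
    return DisplacementField(u)


def resample_to_fixed(moving: np.ndarray, chain: TransformChain,
                      fixed_shape) -> np.ndarray:
    """Express the moving image in the fixed frame using a moving->fixed
    chain (sampling goes through the chain's inverse)."""
    return warp_image(moving, chain.inverse(), fixed_shape)


# ---------------------------------------------------------------------------
# patches, features, latents


def extract_patches(image: np.ndarray, spot_xy, size: int = 32,
                    border: str = "pad") -> np.ndarray:
    """Stack of ``size x size`` patches centred at spot (x, y) positions.

    Even-size convention: the patch for centre (x, y) covers rows
    ``[y - size//2, y + size//2)`` and columns ``[x - size//2,
    x + size//2)``.  With ``border="pad"`` out-of-image pixels are 0; with
    ``border="error"`` an out-of-bounds spot raises, naming the spot.
    """
    img = np.asarray(image, dtype=float)
    xy = np.asarray(spot_xy, dtype=float)
    half = size // 2
    patches = np.zeros((len(xy), size, size))
    h, w = img.shape
    for i, (x, y) in enumerate(xy):
        r0, c0 = int(round(y)) - half, int(round(x)) - half
        r1, c1 = r0 + size, c0 + size
        if border == "error" and (r0 < 0 or c0 < 0 or r1 > h or c1 > w):
            raise ValueError(f"spot {i} at ({x}, {y}) has an out-of-bounds "
                             f"patch")
        rr0, cc0 = max(r0, 0), max(c0, 0)
        rr1, cc1 = min(r1, h), min(c1, w)
        patches[i, rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0] = img[rr0:rr1,
                                                               cc0:cc1]
    return patches


FEATURE_NAMES = ["mean", "sd", "q10", "q50", "q90", "grad_mean", "grad_sd",
                 "gauss1", "gauss2", "gauss4"]


def patch_features(patches: np.ndarray, extractor: str = "bank") -> np.ndarray:
    """Fixed-length feature vector per patch (training-free bank).

    The default bank: mean, sd, 10/50/90% quantiles, gradient-magnitude
    mean and sd (central differences via ``np.gradient``), and mean
    Gaussian responses at sigma in {1, 2, 4}.  The extractor argument is a
    plug point; only "bank" ships with the package.
    """
    if extractor != "bank":
        raise ValueError(f"unknown extractor {extractor!r}")
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[0] < 1:
        raise ValueError("need a (n, h, w) stack with >= 1 patch")
    if np.isnan(patches).any():
        raise ValueError("NaN pixels in patches")
    n = patches.shape[0]
    feats = np.zeros((n, len(FEATURE_NAMES)))
    for i, p in enumerate(patches):
        gy, gx = np.gradient(p)
        gmag = np.sqrt(gx ** 2 + gy ** 2)
        feats[i] = [
            p.mean(), p.std(),
            np.quantile(p, 0.10), np.quantile(p, 0.50), np.quantile(p, 0.90),
            gmag.mean(), gmag.std(),
            ndimage.gaussian_filter(p, 1).mean(),
            ndimage.gaussian_filter(p, 2).mean(),
            ndimage.gaussian_filter(p, 4).mean(),
        ]
    return feats


@dataclass
class ImageLatent:
    """Per-spot latent components of patch features, PCA-ordered.

    Component names are "ImageLatent_1", "ImageLatent_2", ...; the first
    is sign-fixed to correlate positively with patch mean intensity.
    """

    components: pd.DataFrame       # spots x components
    loadings: np.ndarray           # features x components
    explained_variance_ratio: np.ndarray
    feature_names: list

    def __getitem__(self, name: str) -> np.ndarray:
        return self.components[name].to_numpy()


def latent_pca(features: np.ndarray, n_components: int | None = None,
               feature_names=None, spot_ids=None) -> ImageLatent:
    """Standardize features per column, then PCA across spots."""
    F = np.asarray(features, dtype=float)
    if F.shape[0] < 2:
        raise ValueError("need >= 2 spots")
    feature_names = list(feature_names) if feature_names is not None else \
        [f"f{i}" for i in range(F.shape[1])]
    sd = F.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if keep.sum() < 1:
        raise ValueError("need >= 1 feature with variance")
    if not keep.all():
        warnings.warn(
            f"zero-variance features dropped: "
            f"{[feature_names[i] for i in np.flatnonzero(~keep)]}")
    Z = (F[:, keep] - F[:, keep].mean(axis=0)) / sd[keep]
    from sklearn.decomposition import PCA
    k = min(Z.shape) if n_components is None else min(n_components,
                                                      *Z.shape)
    pca = PCA(n_components=k, svd_solver="full")
    comps = pca.fit_transform(Z)
    loadings = pca.components_.T
    mean_intensity = F[:, 0]  # feature bank puts the patch mean first
    for j in range(k):
        anchor = mean_intensity if j == 0 else None
        if anchor is not None:
            c = np.corrcoef(comps[:, j], anchor)[0, 1]
            flip = c < 0
        else:
            flip = loadings[np.argmax(np.abs(loadings[:, j])), j] < 0
        if flip:
            comps[:, j] *= -1
            loadings[:, j] *= -1
    cols = [f"ImageLatent_{j + 1}" for j in range(k)]
    index = spot_ids if spot_ids is not None else pd.RangeIndex(Z.shape[0])
    table = pd.DataFrame(comps, columns=cols, index=index)
    return ImageLatent(table, loadings, pca.explained_variance_ratio_,
                       [feature_names[i] for i in np.flatnonzero(keep)])


# ---------------------------------------------------------------------------
# gene <-> latent association


@dataclass
class GeneImageAssociation:
    table: pd.DataFrame            # gene, coef, se, rank
    top_genes: list
    k: int


def associate_genes(normalized, latent_component: np.ndarray,
                    k: int = 100) -> GeneImageAssociation:
    """Per-gene OLS slope of log-normalized expression on the latent.

    The latent is standardized (mean 0, sd 1) first, so the slope equals
    ``cov(expr, latent) / var(latent)``.  Genes are ranked by descending
    coefficient; the top ``k`` form the image-associated set.  Constant
    genes get coefficient 0.
    """
    z = np.asarray(latent_component, dtype=float)
    X = normalized.matrix if hasattr(normalized, "matrix") else normalized
    gene_ids = (normalized.gene_ids if hasattr(normalized, "gene_ids")
                else np.arange(X.shape[0]))
    import scipy.sparse as sp
    Xd = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X,
                                                                   dtype=float)
    n = Xd.shape[1]
    if z.shape[0] != n:
        raise ValueError("latent component is not aligned to spots")
    if z.std(ddof=0) <= 0:
        raise ValueError("latent component is constant")
    z = (z - z.mean()) / z.std(ddof=0)
    xbar = Xd.mean(axis=1, keepdims=True)
    slope = (Xd - xbar) @ z / n          # var(z) = 1 after standardization
    resid = (Xd - xbar) - slope[:, None] * z[None, :]
    dof = max(n - 2, 1)
    se = np.sqrt((resid ** 2).sum(axis=1) / dof / n)
    const = Xd.std(axis=1, ddof=0) <= 1e-15
    slope[const] = 0.0
    order = np.argsort(-slope, kind="stable")
    rank = np.empty(len(slope), dtype=int)
    rank[order] = np.arange(1, len(slope) + 1)
    table = pd.DataFrame({"gene": gene_ids, "coef": slope, "se": se,
                          "rank": rank}).sort_values("rank")
    top = table["gene"].head(min(k, len(table))).tolist()
    return GeneImageAssociation(table.reset_index(drop=True), top, k)
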