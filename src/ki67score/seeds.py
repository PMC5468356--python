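"""Nucleus seed-point detection by mixture-model pixel labeling.

The detector labels every pixel of an RGB field as immunopositive nucleus
(DAB brown), immunonegative nucleus (hematoxylin blue) or background by
fitting a Gaussian mixture to pixel colors with expectation-maximization
and then assigning labels under a MAP criterion: a unary (likelihood)
energy per pixel, optionally coupled to its neighbours by a Potts prior
optimized with iterated conditional modes (ICM). Connected components of
each nucleus label become candidate nuclei; their centroids are the seed
points that drive patch cropping.

The mixture density is Gaussian; the density family sits behind the
:class:`DensityFamily` interface so a per-channel Gamma variant could be
added without touching the EM loop.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

IMMUNOPOSITIVE = "immunopositive"
IMMUNONEGATIVE = "immunonegative"
BACKGROUND = "background"

#: Fixed label order used everywhere: integer label = index into this tuple.
CLASS_ORDER = (IMMUNOPOSITIVE, IMMUNONEGATIVE, BACKGROUND)
NUCLEUS_CLASSES = (IMMUNOPOSITIVE, IMMUNONEGATIVE)

#: Reference class colors (RGB) used to assign mixture components to
#: biological classes: DAB-brown nuclei, hematoxylin-blue nuclei, pale
#: eosinophilic background. Overridable wherever they are consumed.
DEFAULT_REFERENCE_COLORS = {
    IMMUNOPOSITIVE: (150.0, 100.0, 60.0),
    IMMUNONEGATIVE: (70.0, 80.0, 150.0),
    BACKGROUND: (235.0, 230.0, 240.0),
}


@dataclass(frozen=True)
class SeedPoint:
    """Centroid of one detected nucleus candidate (0-based row, col)."""

    row: int
    col: int
    klass: str
    component_area: int = 0

    def __post_init__(self):
        if self.klass not in NUCLEUS_CLASSES:
            raise ValueError(
                f"seed class must be one of {NUCLEUS_CLASSES}, got {self.klass!r}"
            )


@dataclass
class SeedDetectionConfig:
    """Tunables for EM fitting and MAP labeling."""

    components_per_class: int = 1
    em_tol: float = 1e-5  # relative log-likelihood change
    em_max_iter: int = 200
    covariance_floor: float = 1.0  # added to covariance diagonals (intensity^2)
    beta: float = 0.0  # Potts coupling; 0 = pure maximum-likelihood labeling
    icm_max_iter: int = 10
    min_component_area: int = 30  # pixels
    fit_subsample: int = 100_000  # max pixels used for EM fitting
    rng_seed: int = 0
    reference_colors: dict = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_COLORS)
    )

    def __post_init__(self):
        if self.em_tol <= 0:
            raise ValueError("em_tol must be > 0")
        if self.beta < 0:
            raise ValueError("Potts coupling beta must be >= 0")
        if self.min_component_area < 1:
            raise ValueError("min_component_area must be >= 1")
        if self.components_per_class < 1:
            raise ValueError("components_per_class must be >= 1")


class DensityFamily:
    """Component density interface for the EM loop."""

    def log_pdf(self, X, mean, cov):  # pragma: no cover - interface
        raise NotImplementedError

    def mstep_cov(self, X, resp_c, mean, floor):  # pragma: no cover - interface
        raise NotImplementedError


class GaussianFamily(DensityFamily):
    """Full-covariance multivariate Gaussian components."""

    @staticmethod
    def log_pdf(X, mean, cov):
        d = X.shape[1]
        diff = X - mean
        chol = np.linalg.cholesky(cov)
        sol = np.linalg.solve(chol, diff.T)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        return -0.5 * (maha + logdet + d * np.log(2.0 * np.pi))

    @staticmethod
    def mstep_cov(X, resp_c, mean, floor):
        diff = X - mean
        w = resp_c[:, None]
        cov = (diff * w).T @ diff / max(resp_c.sum(), 1e-300)
        cov.flat[:: cov.shape[0] + 1] += floor
        return 0.5 * (cov + cov.T)


@dataclass
class MixtureFit:
    """A fitted mixture: flat component list, before class grouping."""

    weights: np.ndarray  # (K,)
    means: np.ndarray  # (K, 3)
    covariances: np.ndarray  # (K, 3, 3)

    @property
    def n_components(self) -> int:
        return len(self.weights)


@dataclass
class GMMParams:
    """Per-class mixture parameters for the three pixel classes.

    ``classes`` is ordered (immunopositive, immunonegative, background);
    integer pixel labels index into it. Per class: mixture ``weights``
    (summing to 1 within each class), RGB ``means`` and full
    ``covariances``; ``class_priors`` carries each class's share of the
    total mixture mass.
    """

    classes: tuple = CLASS_ORDER
    weights: dict = None  # class -> (c,)
    means: dict = None  # class -> (c, 3)
    covariances: dict = None  # class -> (c, 3, 3)
    class_priors: dict = None  # class -> scalar

    def validate(self):
        for k in self.classes:
            w = np.asarray(self.weights[k])
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"class {k!r} weights sum to {w.sum()}, not 1")
            m = np.asarray(self.means[k])
            if m.min() < 0 or m.max() > 255:
                raise ValueError(f"class {k!r} means outside [0, 255]")
            for cov in np.asarray(self.covariances[k]):
                np.linalg.cholesky(cov)  # raises if not positive-definite
        return self

    def dominant(self, klass):
        """(mean, cov) of the heaviest component of one class (single-
        Gaussian reading of the likelihood energy)."""
        i = int(np.argmax(self.weights[klass]))
        return np.asarray(self.means[klass][i]), np.asarray(self.covariances[klass][i])


@dataclass
class PixelLabelMap:
    """Integer label image (indices into ``classes``) plus optional
    per-class posterior responsibilities."""

    labels: np.ndarray  # (H, W) int
    classes: tuple = CLASS_ORDER
    posteriors: np.ndarray | None = None  # (H, W, n_classes)


# ---------------------------------------------------------------------------
# EM fitting


def _kmeans_init(X, n_components, rng_seed):
    km = KMeans(n_clusters=n_components, n_init=1, random_state=rng_seed)
    lab = km.fit_predict(X)
    return km.cluster_centers_, lab


def fit_gmm_em(
    pixels: np.ndarray,
    n_components: int,
    config: SeedDetectionConfig | None = None,
    family: DensityFamily | None = None,
    init_means: np.ndarray | None = None,
):
    """Fit a mixture of ``n_components`` densities to RGB pixels by EM.

    Parameters
    ----------
    pixels : (N, 3) array
        Pixel colors (any float/int dtype; treated as float64).
    n_components : int
        Number of mixture components.
    config : SeedDetectionConfig
        Supplies tolerance, iteration cap, covariance floor, seed.
    family : DensityFamily
        Component density family; Gaussian by default.

    Returns
    -------
    (MixtureFit, list of float)
        The fitted parameters and the per-iteration mean log-likelihood
        trace (non-decreasing up to the covariance-floor regularization).
    """
    config = config or SeedDetectionConfig()
    family = family or GaussianFamily()
    X = np.asarray(pixels, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"pixels must be (N, 3), got {X.shape}")
    if len(X) == 0:
        raise ValueError("empty pixel set")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    n_distinct = len(np.unique(X, axis=0))
    if n_distinct < n_components:
        warnings.warn(
            f"only {n_distinct} distinct pixels for {n_components} components; "
            "components will collapse onto the covariance floor"
        )

    K, d = n_components, X.shape[1]
    floor = config.covariance_floor
    if init_means is not None:
        means = np.array(init_means, dtype=np.float64)
        if means.shape != (K, d):
            raise ValueError(f"init_means must be ({K}, {d}), got {means.shape}")
    elif K == 1:
        means = X.mean(axis=0, keepdims=True)
    else:
        means, _ = _kmeans_init(X, K, config.rng_seed)
    covs = np.empty((K, d, d))
    base = np.cov(X.T) if len(X) > 1 else np.zeros((d, d))
    base = np.atleast_2d(base) + floor * np.eye(d)
    covs[:] = base
    weights = np.full(K, 1.0 / K)

    trace = []
    prev = -np.inf
    for _ in range(config.em_max_iter):
        # E step
        log_comp = np.empty((len(X), K))
        for c in range(K):
            log_comp[:, c] = family.log_pdf(X, means[c], covs[c]) + np.log(
                max(weights[c], 1e-300)
            )
        m = log_comp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
        ll = float(lse.mean())
        trace.append(ll)
        resp = np.exp(log_comp - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        weights = nk / nk.sum()
        for c in range(K):
            if nk[c] < 1e-12:
                continue
            means[c] = (resp[:, c : c + 1] * X).sum(axis=0) / nk[c]
            covs[c] = family.mstep_cov(X, resp[:, c], means[c], floor)
        if np.isfinite(prev) and abs(ll - prev) <= config.em_tol * max(abs(prev), 1.0):
            break
        prev = ll
    return MixtureFit(weights=weights, means=means, covariances=covs), trace


def group_components(
    fit: MixtureFit, reference_colors: dict | None = None
) -> GMMParams:
    """Assign fitted mixture components to the three pixel classes.

    Each component goes to the class whose reference color is nearest
    (Euclidean in RGB) to the component mean; a class left empty adopts a
    point mass at its reference color with a broad covariance so labeling
    stays defined.
    """
    refs = reference_colors or DEFAULT_REFERENCE_COLORS
    ref_mat = np.array([refs[k] for k in CLASS_ORDER])
    assign = np.argmin(
        np.linalg.norm(fit.means[:, None, :] - ref_mat[None, :, :], axis=2), axis=1
    )
    weights, means, covs, priors = {}, {}, {}, {}
    for i, k in enumerate(CLASS_ORDER):
        idx = np.where(assign == i)[0]
        if len(idx) == 0:
            log.warning("no mixture component assigned to class %r; using reference color", k)
            weights[k] = np.array([1.0])
            means[k] = ref_mat[i : i + 1].copy()
            covs[k] = np.eye(3)[None] * 400.0
            priors[k] = 1e-6
            continue
        w = fit.weights[idx]
        priors[k] = float(w.sum())
        weights[k] = w / w.sum()
        means[k] = fit.means[idx].copy()
        covs[k] = fit.covariances[idx].copy()
    total = sum(priors.values())
    priors = {k: v / total for k, v in priors.items()}
    return GMMParams(
        classes=CLASS_ORDER, weights=weights, means=means, covariances=covs,
        class_priors=priors,
    ).validate()


def fit_pixel_model(
    image: np.ndarray, config: SeedDetectionConfig | None = None
) -> tuple[GMMParams, list]:
    """Fit the full three-class pixel model to one image.

    Fits ``3 * components_per_class`` Gaussian components by EM on a pixel
    subsample and groups them into classes by reference color.
    """
    config = config or SeedDetectionConfig()
    X = np.asarray(image, dtype=np.float64).reshape(-1, 3)
    if len(X) > config.fit_subsample:
        rng = np.random.default_rng(config.rng_seed)
        X = X[rng.choice(len(X), config.fit_subsample, replace=False)]
    # Initialize EM at the reference class colors (replicated with small
    # deterministic offsets when several components per class are used);
    # plain k-means initialization lets the dominant background mode
    # swallow a nucleus color mode on background-heavy fields.
    c = config.components_per_class
    refs = np.array([config.reference_colors[k] for k in CLASS_ORDER])
    offsets = np.linspace(-10.0, 10.0, c) if c > 1 else np.zeros(1)
    init = np.clip(
        np.concatenate([refs[i : i + 1] + offsets[:, None] for i in range(3)]),
        0, 255,
    )
    fit, trace = fit_gmm_em(X, 3 * c, config, init_means=init)
    return group_components(fit, config.reference_colors), trace


# ---------------------------------------------------------------------------
# Energies and MAP labeling


def likelihood_energy(
    image: np.ndarray, labels: PixelLabelMap | np.ndarray, params: GMMParams
) -> float:
    """Likelihood energy of a labeling: sum over pixels Q of
    ``1/2 (I_Q - mu_K)^T Sigma_K^{-1} (I_Q - mu_K) + 1/2 ln |Sigma_K|``
    with (mu_K, Sigma_K) the dominant Gaussian of pixel Q's class."""
    lab = labels.labels if isinstance(labels, PixelLabelMap) else np.asarray(labels)
    img = np.asarray(image, dtype=np.float64)
    if img.shape[:2] != lab.shape:
        raise ValueError("image and label map dimensions disagree")
    if lab.size and (lab.min() < 0 or lab.max() >= len(params.classes)):
        raise ValueError("label map contains a label without parameters")
    X = img.reshape(-1, 3)
    L = lab.reshape(-1)
    energy = 0.0
    for i, k in enumerate(params.classes):
        sel = L == i
        if not sel.any():
            continue
        mean, cov = params.dominant(k)
        diff = X[sel] - mean
        sol = np.linalg.solve(np.linalg.cholesky(cov), diff.T)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            raise ValueError(f"covariance for class {k!r} is not positive-definite")
        energy += 0.5 * float(np.sum(sol**2)) + 0.5 * logdet * int(sel.sum())
    return energy


def _unary_energies(image: np.ndarray, params: GMMParams) -> np.ndarray:
    """Per-pixel, per-class unary energy = -ln(class prior x class mixture
    density). Shape (H, W, n_classes)."""
    img = np.asarray(image, dtype=np.float64)
    X = img.reshape(-1, 3)
    fam = GaussianFamily()
    out = np.empty((len(X), len(params.classes)))
    for i, k in enumerate(params.classes):
        ws = np.asarray(params.weights[k])
        prior = params.class_priors[k] if params.class_priors else 1.0
        comp = np.stack(
            [
                fam.log_pdf(X, params.means[k][c], params.covariances[k][c])
                + np.log(max(ws[c] * prior, 1e-300))
                for c in range(len(ws))
            ],
            axis=1,
        )
        m = comp.max(axis=1, keepdims=True)
        out[:, i] = -(m[:, 0] + np.log(np.exp(comp - m).sum(axis=1)))
    return out.reshape(img.shape[0], img.shape[1], -1)


def _potts_neighbor_energy(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """For each pixel and candidate class, the count of 4-neighbours with a
    different label (Potts disagreement count)."""
    H, W = labels.shape
    disagree = np.zeros((H, W, n_classes))
    onehot = np.eye(n_classes)[labels]  # (H, W, C)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.roll(onehot, (dr, dc), axis=(0, 1))
        valid = np.ones((H, W, 1))
        if dr == 1:
            shifted[0], valid[0] = 0, 0
        elif dr == -1:
            shifted[-1], valid[-1] = 0, 0
        if dc == 1:
            shifted[:, 0], valid[:, 0] = 0, 0
        elif dc == -1:
            shifted[:, -1], valid[:, -1] = 0, 0
        disagree += valid - shifted
    return disagree


def map_label(
    image: np.ndarray,
    params: GMMParams,
    config: SeedDetectionConfig | None = None,
) -> PixelLabelMap:
    """MAP pixel labeling.

    With ``beta = 0`` every pixel independently takes the class of maximum
    weighted likelihood (minimum unary energy). With ``beta > 0`` a Potts
    pairwise prior couples 4-neighbours and the labeling is optimized by
    iterated conditional modes from the unary initialization until no pixel
    changes or ``icm_max_iter`` sweeps. Ties break toward the lowest label
    index.
    """
    config = config or SeedDetectionConfig()
    unary = _unary_energies(image, params)
    labels = np.argmin(unary, axis=2)
    if config.beta > 0:
        for _ in range(config.icm_max_iter):
            total = unary + config.beta * _potts_neighbor_energy(
                labels, unary.shape[2]
            )
            new = np.argmin(total, axis=2)
            if np.array_equal(new, labels):
                break
            labels = new
    neg = -unary
    neg -= neg.max(axis=2, keepdims=True)
    post = np.exp(neg)
    post /= post.sum(axis=2, keepdims=True)
    return PixelLabelMap(labels=labels, classes=params.classes, posteriors=post)


def labeling_energy(
    image: np.ndarray, labels: np.ndarray, params: GMMParams, beta: float
) -> float:
    """Total MAP objective (unary + Potts pairwise) of a labeling; the
    quantity ICM descends."""
    unary = _unary_energies(image, params)
    lab = np.asarray(labels)
    H, W = lab.shape
    e = float(np.take_along_axis(unary.reshape(H * W, -1), lab.reshape(-1, 1), 1).sum())
    pair = np.count_nonzero(lab[1:] != lab[:-1]) + np.count_nonzero(
        lab[:, 1:] != lab[:, :-1]
    )
    return e + beta * pair


# ---------------------------------------------------------------------------
# Seed extraction


def extract_seed_points(
    labels: PixelLabelMap, config: SeedDetectionConfig | None = None
) -> list[SeedPoint]:
    """Seed points from a label map: 8-connected components per nucleus
    class, small components dropped, one seed at each rounded centroid.
    Deterministic ordering: (class order, row, col)."""
    config = config or SeedDetectionConfig()
    lab = labels.labels
    structure = np.ones((3, 3), dtype=int)  # 8-connectivity
    seeds: list[SeedPoint] = []
    for i, k in enumerate(labels.classes):
        if k not in NUCLEUS_CLASSES:
            continue
        mask = lab == i
        comp, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        areas = ndimage.sum_labels(mask, comp, index=np.arange(1, n + 1))
        cents = ndimage.center_of_mass(mask, comp, index=np.arange(1, n + 1))
        cls_seeds = [
            SeedPoint(
                row=int(round(r)), col=int(round(c)), klass=k,
                component_area=int(a),
            )
            for (r, c), a in zip(cents, areas)
            if a >= config.min_component_area
        ]
        cls_seeds.sort(key=lambda s: (s.row, s.col))
        seeds.extend(cls_seeds)
    return seeds


def detect_seeds(
    image: np.ndarray, config: SeedDetectionConfig | None = None
) -> tuple[list[SeedPoint], PixelLabelMap, GMMParams]:
    """Full detection on one image: fit pixel model, MAP-label, extract."""
    config = config or SeedDetectionConfig()
    params, _ = fit_pixel_model(image, config)
    labels = map_label(image, params, config)
    return extract_seed_points(labels, config), labels, params
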