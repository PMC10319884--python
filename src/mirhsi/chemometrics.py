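"""Hyperspectral-cube chemometrics.

Implements the four mapping methods used to identify chemical
components in the imaged scenes -- additive averaging (band-window
mean), the normalized difference spectral index (NDSI), the spectral
angle mapper (SAM) and Fisher linear discriminant analysis -- together
with constrained random sampling of teaching regions and the 10-90%
edge-response estimator of spatial resolution.

Classification operates on whatever spectra the caller provides
(typically retrieved transmittance, optionally restricted to a set of
diagnostic peak bands).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


class RegionSamplingError(RuntimeError):
    """Could not place the requested number of non-overlapping regions."""

    def __init__(self, requested: int, achieved: int):
        super().__init__(
            f"placed only {achieved} of {requested} requested regions"
        )
        self.requested = requested
        self.achieved = achieved


# ---------------------------------------------------------------------------
# scalar band maps
# ---------------------------------------------------------------------------

def additive_averaging(data: np.ndarray, band_range: tuple[int, int],
                       intensity_thresholds: tuple[float, float] = (-np.inf, np.inf)):
    """Band-window average intensity map, I_ave = S/n.

    `band_range` is a half-open (start, stop) slice of band indices;
    the mask selects pixels whose average lies inside the thresholds.
    """
    b0, b1 = band_range
    if b1 <= b0:
        raise ValueError("empty band selection")
    window = np.asarray(data, dtype=float)[..., b0:b1]
    i_ave = window.sum(axis=-1) / window.shape[-1]
    lo, hi = intensity_thresholds
    return i_ave, (i_ave >= lo) & (i_ave <= hi)


def ndsi_map(data: np.ndarray, band_1: int, band_2: int,
             ndsi_thresholds: tuple[float, float] = (-1.0, 1.0)):
    """Normalized difference spectral index (I1 - I2)/(I1 + I2) per pixel.

    Pixels with I1 + I2 = 0 are set to 0 and flagged; identical band
    indices trivially give an all-zero map (a warning is emitted).
    """
    if band_1 == band_2:
        import warnings

        warnings.warn("identical bands: NDSI is identically zero", stacklevel=2)
    d = np.asarray(data, dtype=float)
    i1, i2 = d[..., band_1], d[..., band_2]
    total = i1 + i2
    degenerate = total == 0
    ndsi = np.zeros_like(total)
    np.divide(i1 - i2, total, out=ndsi, where=~degenerate)
    lo, hi = ndsi_thresholds
    mask = (ndsi >= lo) & (ndsi <= hi) & ~degenerate
    return ndsi, mask, degenerate


# ---------------------------------------------------------------------------
# teaching regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionConstraint:
    """Strict-inequality bounds on rectangle side lengths and area.

    A rectangle of width x and height y (pixels) is admissible when
    x_min < x < x_max, y_min < y < y_max and area_min < x*y < area_max.
    """

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    area_min: int
    area_max: int
    n_regions: int

    def admits(self, x: int, y: int) -> bool:
        return (self.x_min < x < self.x_max and self.y_min < y < self.y_max
                and self.area_min < x * y < self.area_max)


@dataclass
class Region:
    row: int
    col: int
    height: int
    width: int

    def slices(self):
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)

    def overlaps(self, other: "Region") -> bool:
        return not (self.row + self.height <= other.row
                    or other.row + other.height <= self.row
                    or self.col + self.width <= other.col
                    or other.col + other.width <= self.col)


@dataclass
class TeachingSet:
    """Per-class teaching regions and their mean spectra."""

    classes: dict[str, list[Region]] = field(default_factory=dict)
    spectra: dict[str, np.ndarray] = field(default_factory=dict)  # (n_regions, bands)
    constraint: RegionConstraint | None = None
    seed: int | None = None

    def class_names(self) -> list[str]:
        return list(self.classes)

    def mean_spectra(self) -> np.ndarray:
        """(n_classes, bands) stack of per-class means over region spectra."""
        return np.stack([self.spectra[c].mean(axis=0) for c in self.classes])

    def restrict_bands(self, band_idx) -> "TeachingSet":
        out = TeachingSet(dict(self.classes),
                          {c: s[:, band_idx] for c, s in self.spectra.items()},
                          self.constraint, self.seed)
        return out


def sample_teaching_regions(
    shape_or_data,
    constraint: RegionConstraint,
    seed: int = 0,
    label_map: np.ndarray | None = None,
    class_labels: dict[str, int] | None = None,
    max_attempts: int = 20000,
) -> TeachingSet:
    """Rejection-sample non-overlapping axis-aligned teaching rectangles.

    `shape_or_data` is either a (rows, cols) shape tuple or a cube-like
    array (rows, cols, bands) from which per-region mean spectra are
    extracted.  With a `label_map` and `class_labels`
    ({class name: label value}) regions are constrained to lie entirely
    inside pixels of their class; otherwise all regions belong to one
    anonymous class "all".  Reproducible for a given seed.
    """
    if isinstance(shape_or_data, tuple):
        rows, cols = shape_or_data
        data = None
    else:
        data = np.asarray(shape_or_data, dtype=float)
        rows, cols = data.shape[:2]
    rng = np.random.default_rng(seed)
    if class_labels is None:
        class_labels = {"all": None}

    xs = [x for x in range(constraint.x_min + 1, min(constraint.x_max, cols + 1))]
    ys = [y for y in range(constraint.y_min + 1, min(constraint.y_max, rows + 1))]
    sizes = [(x, y) for x in xs for y in ys if constraint.admits(x, y)]
    if not sizes:
        raise RegionSamplingError(constraint.n_regions, 0)

    placed_all: list[Region] = []
    ts = TeachingSet(constraint=constraint, seed=seed)
    for cname, lab in class_labels.items():
        placed: list[Region] = []
        attempts = 0
        while len(placed) < constraint.n_regions:
            attempts += 1
            if attempts > max_attempts:
                raise RegionSamplingError(constraint.n_regions, len(placed))
            x, y = sizes[rng.integers(len(sizes))]
            r0 = int(rng.integers(0, rows - y + 1))
            c0 = int(rng.integers(0, cols - x + 1))
            reg = Region(r0, c0, y, x)
            if lab is not None:
                rs, cs = reg.slices()
                if not np.all(label_map[rs, cs] == lab):
                    continue
            if any(reg.overlaps(p) for p in placed_all):
                continue
            placed.append(reg)
            placed_all.append(reg)
        ts.classes[cname] = placed
        if data is not None:
            ts.spectra[cname] = np.stack(
                [data[reg.slices()].mean(axis=(0, 1)) for reg in placed]
            )
    return ts


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

@dataclass
class ClassMap:
    """Per-pixel integer labels; 0 means unclassified."""

    labels: np.ndarray
    legend: dict[int, str]
    colors: dict[int, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if not self.colors:
            palette = [(31, 119, 180), (255, 127, 14), (44, 160, 44),
                       (214, 39, 40), (148, 103, 189), (140, 86, 75),
                       (227, 119, 194), (127, 127, 127)]
            self.colors = {k: palette[(k - 1) % len(palette)] for k in self.legend}

    def accuracy(self, truth: np.ndarray, where: np.ndarray | None = None) -> float:
        """Fraction of pixels (optionally restricted) whose label matches truth."""
        sel = np.ones_like(self.labels, bool) if where is None else where
        return float(np.mean(self.labels[sel] == truth[sel]))

    def save_png(self, path) -> None:
        """Indexed pseudo-colour PNG plus a JSON legend sidecar."""
        import json

        try:
            from PIL import Image
        except ImportError:  # pragma: no cover
            raise RuntimeError("saving class maps as PNG requires pillow")
        h, w = self.labels.shape
        rgb = np.zeros((h, w, 3), np.uint8)
        for k, c in self.colors.items():
            rgb[self.labels == k] = c
        Image.fromarray(rgb).save(path)
        with open(str(path) + ".json", "w") as fh:
            json.dump({str(k): {"name": v, "color": list(self.colors[k])}
                       for k, v in self.legend.items()}, fh, indent=2)


def sam_classify(data: np.ndarray, teaching: TeachingSet,
                 band_idx=None) -> ClassMap:
    """Spectral angle mapper: assign the class with the smallest angle.

    Pixel spectra and teaching spectra are normalized to unit length, so
    classification is invariant to per-pixel brightness; the class with
    the maximum normalized inner product (minimum angle) wins, ties
    resolved toward the lowest class index.  Zero-norm pixels get 0.
    """
    if not teaching.classes:
        raise ValueError("teaching set is empty")
    d = np.asarray(data, dtype=float)
    refs = teaching.mean_spectra()
    if band_idx is not None:
        d = d[..., band_idx]
        refs = refs[:, band_idx]
    refs = refs / np.linalg.norm(refs, axis=1, keepdims=True)
    flat = d.reshape(-1, d.shape[-1])
    norms = np.linalg.norm(flat, axis=1)
    ok = norms > 0
    cos = np.zeros((flat.shape[0], refs.shape[0]))
    cos[ok] = (flat[ok] / norms[ok, None]) @ refs.T
    labels = np.zeros(flat.shape[0], dtype=np.int32)
    labels[ok] = np.argmax(cos[ok], axis=1) + 1
    legend = {i + 1: c for i, c in enumerate(teaching.class_names())}
    return ClassMap(labels.reshape(d.shape[:-1]), legend)


@dataclass
class LDAModel:
    """Fisher linear discriminant: projection vectors and class centroids."""

    w: np.ndarray                    # (bands, n_components)
    s_b: np.ndarray
    s_w: np.ndarray
    centroids: np.ndarray            # (n_classes, n_components)
    class_names: list[str]
    fisher_j: float
    band_idx: np.ndarray | None = None
    ridge: float = 0.0


def fisher_criterion(w: np.ndarray, s_b: np.ndarray, s_w: np.ndarray) -> float:
    """J(w) = (w^T S_B w) / (w^T S_W w)."""
    w = np.asarray(w, dtype=float).ravel()
    return float(w @ s_b @ w) / float(w @ s_w @ w)


def scatter_matrices(teaching: TeachingSet, band_idx=None):
    """Between-class and within-class scatter of the teaching spectra."""
    names = teaching.class_names()
    groups = [np.asarray(teaching.spectra[c], dtype=float) for c in names]
    if band_idx is not None:
        groups = [g[:, band_idx] for g in groups]
    n_bands = groups[0].shape[1]
    overall = np.vstack(groups).mean(axis=0)
    s_b = np.zeros((n_bands, n_bands))
    s_w = np.zeros((n_bands, n_bands))
    for g in groups:
        mu = g.mean(axis=0)
        dm = mu - overall
        s_b += len(g) * np.outer(dm, dm)
        centred = g - mu
        s_w += centred.T @ centred
    return s_b, s_w, names, [g.mean(axis=0) for g in groups]


def lda_train(teaching: TeachingSet, band_idx=None, n_components: int | None = None,
              ridge_scale: float = 1e-8) -> LDAModel:
    """Fit Fisher LDA by the generalized eigenproblem S_B w = J S_W w.

    Up to C-1 projection vectors are returned, ordered by decreasing
    criterion; a ridge proportional to trace(S_W) is added when S_W is
    singular (logged on the model).  With a single class no direction
    separates anything and an error is raised.
    """
    if len(teaching.classes) < 2:
        raise ValueError("LDA needs at least two classes")
    for c, s in teaching.spectra.items():
        if len(s) < 2:
            raise ValueError(f"class {c!r} needs at least two teaching spectra")
    s_b, s_w, names, means = scatter_matrices(teaching, band_idx)
    n = s_w.shape[0]
    ridge = 0.0
    s_w_reg = s_w
    # regularize if singular / badly conditioned
    if np.linalg.matrix_rank(s_w) < n or np.linalg.cond(s_w) > 1e12:
        ridge = ridge_scale * (np.trace(s_w) / n if np.trace(s_w) > 0 else 1.0)
        s_w_reg = s_w + ridge * np.eye(n)
    evals, evecs = scipy.linalg.eigh(s_b, s_w_reg)
    order = np.argsort(evals)[::-1]
    k = min(len(teaching.classes) - 1, n) if n_components is None else n_components
    w = evecs[:, order[:k]]
    bands = np.asarray(band_idx) if band_idx is not None else None
    proj_means = np.stack([m @ w for m in means])
    j = fisher_criterion(w[:, 0], s_b, s_w_reg)
    return LDAModel(w=w, s_b=s_b, s_w=s_w, centroids=proj_means,
                    class_names=names, fisher_j=j, band_idx=bands, ridge=ridge)


def lda_classify(data: np.ndarray, model: LDAModel) -> ClassMap:
    """Project pixels with w and assign the nearest class centroid."""
    d = np.asarray(data, dtype=float)
    if model.band_idx is not None:
        d = d[..., model.band_idx]
    if d.shape[-1] != model.w.shape[0]:
        raise ValueError(
            f"pixel spectra have {d.shape[-1]} bands, model expects {model.w.shape[0]}"
        )
    proj = d.reshape(-1, d.shape[-1]) @ model.w
    d2 = ((proj[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    labels = (np.argmin(d2, axis=1) + 1).astype(np.int32)
    legend = {i + 1: c for i, c in enumerate(model.class_names)}
    return ClassMap(labels.reshape(d.shape[:-1]), legend)


# ---------------------------------------------------------------------------
# spatial resolution from an edge profile
# ---------------------------------------------------------------------------

def extract_line_profile(image: np.ndarray, start, end, n: int | None = None):
    """Sample an image along the line from `start` to `end` (row, col)."""
    from scipy.ndimage import map_coordinates

    r0, c0 = start
    r1, c1 = end
    if n is None:
        n = int(np.hypot(r1 - r0, c1 - c0)) + 1
    rr = np.linspace(r0, r1, n)
    cc = np.linspace(c0, c1, n)
    return map_coordinates(np.asarray(image, dtype=float), [rr, cc], order=1)


def edge_response_resolution(profile: np.ndarray, pixel_pitch_um: float) -> float:
    """10-90% distance (um) of a monotone edge profile.

    The low and high plateaus are the profile end values; crossing
    positions at 10% and 90% of the span are linearly interpolated.
    Raises ValueError when the profile is not monotone up to small
    ripple.
    """
    p = np.asarray(profile, dtype=float)
    if p[-1] < p[0]:
        p = p[::-1]
    span = p[-1] - p[0]
    if span <= 0:
        raise ValueError("profile has no edge")
    backstep = np.max(-np.diff(p), initial=0.0)
    if backstep > 0.05 * span:
        raise ValueError("profile is not monotone across the edge")
    lo = p[0] + 0.1 * span
    hi = p[0] + 0.9 * span
    x = np.arange(p.size, dtype=float)

    def crossing(level):
        above = np.where(p >= level)[0]
        i = above[0]
        if i == 0:
            return 0.0
        return x[i - 1] + (level - p[i - 1]) / (p[i] - p[i - 1])

    return (crossing(hi) - crossing(lo)) * pixel_pitch_um


#: 10-90% width of an ideal Gaussian-blurred step is 2 sqrt(2) erfinv(0.8) sigma
GAUSSIAN_EDGE_FACTOR = 2.5631031310892007
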