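"""MALDI mass spectrometry imaging processing and single-vessel statistics.

The processing chain mirrors the standard workflow for imaging of vascular
amyloid at 10 μm pitch: total-ion-current (TIC) normalization, bisecting
k-means spatial segmentation to find amyloid-positive vessel areas, peak and
peak-width detection on average spectra, area-under-curve integration within
peak bins, and then the quantification statistics reported per vessel:

* relative abundance of every proteoform against a full-length reference
  (e.g. ADan1-34 for the Danish-dementia case),
* intensity-weighted fractions of the full-length / C-terminally truncated /
  N-terminally truncated / pyroglutamate-modified subgroups,
* fractional contribution of Abeta signal to the total amyloid signal and
  fractional coverage of the vessel area by Abeta-positive pixels,
* the single-pixel signal correlation (SPSC) matrix, a co-deposition
  statistic: pairwise Pearson correlation between ion images within a mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.cluster import KMeans
from skimage import measure

from .proteoforms import ProteoformSpecies, SubgroupLabel, classify_subgroups, mz

log = logging.getLogger(__name__)

__all__ = [
    "MSIDataset",
    "PeakBin",
    "SegmentationResult",
    "MsiQuantConfig",
    "tic_normalize",
    "make_uniform_bins",
    "annotate_bins",
    "mean_spectrum",
    "detect_peaks",
    "integrate_bins",
    "ion_image",
    "bisect_kmeans_segment",
    "vessel_rois",
    "roi_species_table",
    "run_msi_pipeline",
    "MsiResult",
    "relative_quant",
    "subgroup_fractions",
    "fractional_contribution_and_coverage",
    "spsc_matrix",
]


@dataclass
class MSIDataset:
    """Per-pixel centroid mass spectra on a regular 2D grid.

    ``coords`` holds integer (x, y) grid positions; ``mzs``/``intensities``
    hold one pair of aligned arrays per pixel (m/z strictly ascending).
    Missing grid positions are allowed (sparse acquisition regions).
    """

    coords: np.ndarray  # (n_pixels, 2) int
    mzs: list[np.ndarray]
    intensities: list[np.ndarray]
    pitch_um: float = 10.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        n = len(self.coords)
        if n == 0:
            raise ValueError("dataset has no pixels")
        if len(self.mzs) != n or len(self.intensities) != n:
            raise ValueError("coords, mzs and intensities lengths differ")
        seen = {tuple(c) for c in self.coords}
        if len(seen) != n:
            raise ValueError("duplicate pixel coordinates")
        for i, (m, y) in enumerate(zip(self.mzs, self.intensities)):
            m = np.asarray(m, dtype=float)
            y = np.asarray(y, dtype=float)
            if m.shape != y.shape:
                raise ValueError(f"pixel {i}: m/z and intensity lengths differ")
            if m.size > 1 and np.any(np.diff(m) <= 0):
                order = np.argsort(m, kind="stable")
                m, y = m[order], y[order]
                log.warning("pixel %d: m/z not ascending; sorted on load", i)
            if np.any(y < 0):
                raise ValueError(f"pixel {i}: negative intensity")
            self.mzs[i], self.intensities[i] = m, y

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def tic(self) -> np.ndarray:
        return np.array([y.sum() for y in self.intensities])

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) of the bounding grid, y down / x right."""
        x, y = self.coords[:, 0], self.coords[:, 1]
        return int(y.max() - y.min() + 1), int(x.max() - x.min() + 1)


@dataclass(frozen=True)
class PeakBin:
    """One integration bin: [left, right] around a peak centre m/z."""

    center: float
    left: float
    right: float
    species: str | None = None  # annotated proteoform display name

    def __post_init__(self) -> None:
        if not (self.left < self.center < self.right):
            raise ValueError(f"bin edges must satisfy left < center < right, got {self}")


@dataclass
class SegmentationResult:
    """Per-pixel cluster labels with the bisecting history.

    ``history`` records each bisection as (parent_label, child_a, child_b);
    ``vessel_labels`` holds the leaf labels designated as amyloid-positive.
    """

    labels: np.ndarray  # (n_pixels,) int leaf labels
    history: list[tuple[int, int, int]]
    vessel_labels: frozenset[int]


@dataclass
class MsiQuantConfig:
    n_leaf_clusters: int = 2
    n_vessel_clusters: int = 1
    snr_threshold: float = 3.0
    bin_halfwidth_frac: float = 0.0035  # cap on bin half-width, fraction of centre m/z
    coverage_n_sigma: float = 2.0  # Abeta-positive if > bg mean + n_sigma * bg sd
    correlation: str = "pearson"
    kmeans_restarts: int = 10
    min_roi_pixels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaf_clusters < 1 or self.kmeans_restarts < 1 or self.min_roi_pixels < 1:
            raise ValueError("cluster/restart/ROI-size parameters must be positive")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def tic_normalize(dataset: MSIDataset, target: float | None = None) -> MSIDataset:
    """Scale each pixel so its total ion current equals a common constant.

    The constant defaults to the dataset-mean pre-normalization TIC, which
    preserves the overall intensity scale; within-pixel peak ratios are
    untouched.  Zero-TIC pixels are dropped with a warning.
    """
    tics = dataset.tic()
    keep = tics > 0
    if not keep.any():
        raise ValueError("all pixels have zero total ion current")
    if not keep.all():
        log.warning("dropping %d zero-TIC pixel(s)", int((~keep).sum()))
    if target is None:
        target = float(tics[keep].mean())
    idx = np.flatnonzero(keep)
    return MSIDataset(
        coords=dataset.coords[idx].copy(),
        mzs=[dataset.mzs[i].copy() for i in idx],
        intensities=[dataset.intensities[i] * (target / tics[i]) for i in idx],
        pitch_um=dataset.pitch_um,
    )


# ---------------------------------------------------------------------------
# bins, spectra, peaks, integration
# ---------------------------------------------------------------------------


def make_uniform_bins(mz_min: float, mz_max: float, width: float) -> list[PeakBin]:
    """Equal-width contiguous bins covering [mz_min, mz_max] (for clustering)."""
    if width <= 0 or mz_max <= mz_min:
        raise ValueError("need mz_max > mz_min and width > 0")
    edges = np.arange(mz_min, mz_max + width, width)
    return [
        PeakBin(center=(a + b) / 2, left=float(a), right=float(b))
        for a, b in zip(edges[:-1], edges[1:])
    ]


def annotate_bins(
    bins: list[PeakBin],
    species: list[ProteoformSpecies],
    tol: float = 2.0,
    charge: int = 1,
) -> list[PeakBin]:
    """Attach proteoform names to bins whose centre lies near a species m/z.

    Each species is assigned to the single closest bin within ``tol`` Da (or
    whose span contains the species m/z).
    """
    out = list(bins)
    for sp in species:
        target = mz(sp, charge=charge)
        best, best_d = None, np.inf
        for i, b in enumerate(out):
            d = abs(b.center - target)
            if (b.left <= target <= b.right or d <= tol) and d < best_d:
                best, best_d = i, d
        if best is not None:
            out[best] = replace(out[best], species=sp.display_name)
        else:
            log.warning("no bin found for species %s at m/z %.2f", sp.display_name, target)
    return out


def mean_spectrum(
    dataset: MSIDataset,
    grid_width: float = 0.25,
    pixel_indices: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Average spectrum on a regular m/z grid.

    Centroid peaks of every (selected) pixel are accumulated onto equal-width
    grid cells and divided by the pixel count, giving the per-pixel-average
    intensity profile used for peak detection.
    """
    idx = np.arange(dataset.n_pixels) if pixel_indices is None else np.asarray(pixel_indices)
    if idx.size == 0:
        raise ValueError("no pixels selected")
    lo = min(dataset.mzs[i][0] for i in idx if dataset.mzs[i].size)
    hi = max(dataset.mzs[i][-1] for i in idx if dataset.mzs[i].size)
    edges = np.arange(lo - grid_width, hi + 2 * grid_width, grid_width)
    acc = np.zeros(edges.size - 1)
    for i in idx:
        if dataset.mzs[i].size:
            acc += np.histogram(dataset.mzs[i], bins=edges, weights=dataset.intensities[i])[0]
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, acc / idx.size


def detect_peaks(
    mzs: np.ndarray,
    intensity: np.ndarray,
    snr_threshold: float = 3.0,
    bin_halfwidth_frac: float = 0.0035,
) -> list[PeakBin]:
    """Local-maxima peak picking with flanking-minimum bin borders.

    The noise level is estimated robustly as 1.4826 x the median absolute
    deviation of the first-difference-detrended spectrum; peaks must exceed
    the baseline (median intensity) by ``snr_threshold`` times that level.  Each peak's bin edges sit at the
    nearest flanking local minima, truncated at half the distance to the
    neighbouring peak and capped at ``bin_halfwidth_frac`` x centre m/z, so
    bins never overlap.
    """
    mzs = np.asarray(mzs, dtype=float)
    y = np.asarray(intensity, dtype=float)
    if mzs.size == 0:
        raise ValueError("empty spectrum")
    if y.max() == y.min():
        return []
    d = np.diff(y)
    noise = 1.4826 * float(np.median(np.abs(d - np.median(d))))
    baseline = float(np.median(y))
    height = baseline + snr_threshold * noise if noise > 0 else np.finfo(float).tiny
    peak_idx, _ = _signal.find_peaks(y, height=height)
    if peak_idx.size == 0:
        return []

    bins: list[PeakBin] = []
    for k, p in enumerate(peak_idx):
        # walk outward to the flanking local minima
        li = p
        while li > 0 and y[li - 1] < y[li]:
            li -= 1
        ri = p
        while ri < y.size - 1 and y[ri + 1] < y[ri]:
            ri += 1
        center = float(mzs[p])
        left, right = float(mzs[li]), float(mzs[ri])
        # truncate at half-distance to neighbouring peaks
        if k > 0:
            left = max(left, (center + float(mzs[peak_idx[k - 1]])) / 2)
        if k < peak_idx.size - 1:
            right = min(right, (center + float(mzs[peak_idx[k + 1]])) / 2)
        cap = bin_halfwidth_frac * center
        left = max(left, center - cap)
        right = min(right, center + cap)
        if not (left < center < right):  # degenerate (peak at array edge)
            eps = (mzs[1] - mzs[0]) / 2 if mzs.size > 1 else 0.01
            left, right = min(left, center - eps), max(right, center + eps)
        bins.append(PeakBin(center=center, left=left, right=right))
    return bins


def _check_non_overlapping(bins: list[PeakBin]) -> None:
    for a, b in zip(sorted(bins, key=lambda t: t.left), sorted(bins, key=lambda t: t.left)[1:]):
        if b.left < a.right:
            raise ValueError(f"overlapping bins: {a} and {b}")


def integrate_bins(dataset: MSIDataset, bins: list[PeakBin]) -> np.ndarray:
    """Area-under-curve integration of each bin in every pixel.

    For centroid spectra this is the sum of peak intensities with m/z inside
    [left, right]; returns an (n_pixels, n_bins) matrix.
    """
    _check_non_overlapping(bins)
    lefts = np.array([b.left for b in bins])
    rights = np.array([b.right for b in bins])
    out = np.zeros((dataset.n_pixels, len(bins)))
    for i in range(dataset.n_pixels):
        m, y = dataset.mzs[i], dataset.intensities[i]
        if m.size == 0:
            continue
        c = np.cumsum(y)
        lo = np.searchsorted(m, lefts, side="left")
        hi = np.searchsorted(m, rights, side="right")
        tot = np.where(hi > 0, c[hi - 1], 0.0) - np.where(lo > 0, c[lo - 1], 0.0)
        out[i] = np.where(hi > lo, tot, 0.0)
    return out


def ion_image(dataset: MSIDataset, values: np.ndarray) -> np.ndarray:
    """Fold one per-pixel value vector onto the 2D grid (NaN where missing)."""
    values = np.asarray(values, dtype=float)
    x, y = dataset.coords[:, 0], dataset.coords[:, 1]
    img = np.full(dataset.grid_shape(), np.nan)
    img[y - y.min(), x - x.min()] = values
    return img


# ---------------------------------------------------------------------------
# spatial segmentation
# ---------------------------------------------------------------------------


def bisect_kmeans_segment(
    dataset: MSIDataset,
    bins: list[PeakBin],
    config: MsiQuantConfig | None = None,
) -> SegmentationResult:
    """Bisecting k-means segmentation of the pixel grid.

    Pixels are represented by their bin-integrated intensity vectors.  The
    cluster with the largest within-cluster sum of squares is repeatedly
    split by 2-means (``kmeans_restarts`` restarts, seeded) until
    ``n_leaf_clusters`` leaves exist.  Leaves with the highest mean signal
    over species-annotated bins (or over all bins when none are annotated)
    are designated as the amyloid/vessel clusters.
    """
    config = config or MsiQuantConfig()
    if dataset.n_pixels < 2 and config.n_leaf_clusters > 1:
        raise ValueError("need at least 2 pixels to bisect")
    if config.n_leaf_clusters > dataset.n_pixels:
        raise ValueError("more leaf clusters requested than pixels")
    if not bins:
        raise ValueError("need at least one bin")

    features = integrate_bins(dataset, bins)
    labels = np.zeros(dataset.n_pixels, dtype=int)
    history: list[tuple[int, int, int]] = []
    next_label = 1
    rng = np.random.default_rng(config.seed)

    def sse(lab: int) -> float:
        pts = features[labels == lab]
        return float(((pts - pts.mean(axis=0)) ** 2).sum()) if len(pts) else 0.0

    while len(np.unique(labels)) < config.n_leaf_clusters:
        # bisect the leaf with the largest within-cluster SSE (splittable only)
        leaves = [l for l in np.unique(labels) if (labels == l).sum() >= 2]
        if not leaves:
            break
        parent = max(leaves, key=sse)
        idx = np.flatnonzero(labels == parent)
        km = KMeans(
            n_clusters=2,
            n_init=config.kmeans_restarts,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(features[idx])
        a, b = next_label, next_label + 1
        next_label += 2
        labels[idx[km.labels_ == 0]] = a
        labels[idx[km.labels_ == 1]] = b
        history.append((int(parent), a, b))

    amyloid_cols = [i for i, b in enumerate(bins) if b.species is not None]
    score_cols = amyloid_cols if amyloid_cols else list(range(len(bins)))
    leaf_labels = np.unique(labels)
    scores = {
        int(l): float(features[labels == l][:, score_cols].sum(axis=1).mean())
        for l in leaf_labels
    }
    ranked = sorted(scores, key=scores.get, reverse=True)
    vessel = frozenset(ranked[: config.n_vessel_clusters])
    return SegmentationResult(labels=labels, history=history, vessel_labels=vessel)


def vessel_rois(
    dataset: MSIDataset,
    segmentation: SegmentationResult,
    min_pixels: int = 5,
) -> list[np.ndarray]:
    """Single-vessel ROIs: connected components of the vessel cluster(s).

    Returns a list of pixel-index arrays (indices into the dataset's pixel
    list), 8-connected on the grid, smallest components dropped.
    """
    is_vessel = np.isin(segmentation.labels, list(segmentation.vessel_labels))
    x, y = dataset.coords[:, 0], dataset.coords[:, 1]
    grid = np.zeros(dataset.grid_shape(), dtype=bool)
    grid[y - y.min(), x - x.min()] = is_vessel
    lab = measure.label(grid, connectivity=2)
    pix_label = lab[y - y.min(), x - x.min()]
    rois = []
    for l in range(1, lab.max() + 1):
        idx = np.flatnonzero(pix_label == l)
        if idx.size >= min_pixels:
            rois.append(idx)
    return rois


# ---------------------------------------------------------------------------
# quantification statistics
# ---------------------------------------------------------------------------


def roi_species_table(
    dataset: MSIDataset,
    matrix: np.ndarray,
    bins: list[PeakBin],
    rois: list[np.ndarray],
) -> pd.DataFrame:
    """Per-ROI mean integrated intensity of every annotated species bin.

    Long-format table with columns (roi, species, intensity).
    """
    rows = []
    for r, idx in enumerate(rois):
        for j, b in enumerate(bins):
            if b.species is None:
                continue
            rows.append(
                {"roi": r, "species": b.species, "intensity": float(matrix[idx, j].mean())}
            )
    if not rows:
        raise ValueError("no annotated species bins")
    return pd.DataFrame(rows)


@dataclass
class MsiResult:
    """Everything a finished end-to-end MSI quantification run produced."""

    dataset: MSIDataset  # TIC-normalized
    segmentation: SegmentationResult
    rois: list[np.ndarray]
    bins: list[PeakBin]
    matrix: np.ndarray  # (n_pixels, n_bins) integrated intensities
    quant: pd.DataFrame
    reference: str


def run_msi_pipeline(
    dataset: MSIDataset,
    species: list[ProteoformSpecies],
    config: MsiQuantConfig | None = None,
    reference: str | None = None,
    seg_bin_width: float = 3.0,
) -> MsiResult:
    """Full chain: TIC-normalize, segment, detect peaks, integrate, quantify.

    Spatial segmentation runs on coarse uniform bins (``seg_bin_width`` Da);
    peak bins for quantification are then detected on the average spectrum
    of the vessel pixels and annotated against the species roster.  The
    reference for relative quantification defaults to the annotated species
    with the highest mean per-ROI intensity (the largest peptide peak).
    """
    config = config or MsiQuantConfig()
    ds = tic_normalize(dataset)
    lo = min(m[0] for m in ds.mzs if m.size)
    hi = max(m[-1] for m in ds.mzs if m.size)
    seg_bins = annotate_bins(make_uniform_bins(lo, hi, seg_bin_width), species)
    seg = bisect_kmeans_segment(ds, seg_bins, config)
    rois = vessel_rois(ds, seg, config.min_roi_pixels)
    if not rois:
        raise ValueError("segmentation found no vessel ROIs")
    vessel_idx = np.concatenate(rois)
    grid_mz, mean_int = mean_spectrum(ds, pixel_indices=vessel_idx)
    bins = annotate_bins(
        detect_peaks(grid_mz, mean_int, config.snr_threshold, config.bin_halfwidth_frac),
        species,
    )
    matrix = integrate_bins(ds, bins)
    table = roi_species_table(ds, matrix, bins, rois)
    if reference is None:
        reference = str(table.groupby("species")["intensity"].mean().idxmax())
    quant = relative_quant(table, reference)
    return MsiResult(ds, seg, rois, bins, matrix, quant, reference)


def relative_quant(table: pd.DataFrame, reference: str | ProteoformSpecies) -> pd.DataFrame:
    """Express per-ROI species intensities relative to a reference species.

    ROIs in which the reference has no signal are dropped with a warning.
    Adds a ``relative`` column; the reference row is exactly 1 in every
    retained ROI.
    """
    ref_name = reference.display_name if isinstance(reference, ProteoformSpecies) else reference
    ref = table[table["species"] == ref_name].set_index("roi")["intensity"]
    ref = ref[ref > 0]
    if ref.empty:
        raise ValueError(f"reference species {ref_name!r} absent from every ROI")
    dropped = table["roi"].nunique() - ref.size
    if dropped:
        log.warning("dropping %d ROI(s) lacking reference %s", dropped, ref_name)
    out = table[table["roi"].isin(ref.index)].copy()
    out["relative"] = out["intensity"] / out["roi"].map(ref).to_numpy()
    return out


def subgroup_fractions(
    table: pd.DataFrame,
    species_lookup: dict[str, ProteoformSpecies],
    pe1_counts_as_n_truncated: bool = True,
    by_family: bool = True,
) -> pd.DataFrame:
    """Intensity-weighted subgroup percentages per ROI, averaged per family.

    For each of FULL_LENGTH / C_TRUNCATED / N_TRUNCATED / PYROGLU the
    fraction is 100 x (summed intensity of member species) / (summed
    intensity of all species), per ROI, then averaged over ROIs.  Categories
    overlap, so columns need not sum to 100.  With ``by_family`` the
    statistic is computed separately per precursor family (e.g. ADan vs
    Abeta), mirroring how the subgroup bar charts are reported.
    """
    if table.empty:
        raise ValueError("empty quantification table")
    t = table.copy()
    t["family"] = [species_lookup[s].precursor.value for s in t["species"]]
    groups = list(SubgroupLabel)
    member = {
        s: classify_subgroups(sp, pe1_counts_as_n_truncated)
        for s, sp in species_lookup.items()
    }
    fam_col = "family" if by_family else None
    rows = []
    keys = t["family"].unique() if by_family else [None]
    for fam in keys:
        sub = t[t["family"] == fam] if by_family else t
        per_roi = []
        for _, roi_t in sub.groupby("roi"):
            total = roi_t["intensity"].sum()
            if total <= 0:
                continue
            per_roi.append(
                {
                    g.value: 100.0
                    * roi_t[
                        [g in member[s] for s in roi_t["species"]]
                    ]["intensity"].sum()
                    / total
                    for g in groups
                }
            )
        mean = pd.DataFrame(per_roi).mean()
        row = {"family": fam, "n_rois": len(per_roi)}
        row.update(mean.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def fractional_contribution_and_coverage(
    matrix: np.ndarray,
    bins: list[PeakBin],
    vessel_pixels: np.ndarray,
    is_target_species,
    background_pixels: np.ndarray | None = None,
    coverage_n_sigma: float = 2.0,
) -> tuple[float, float]:
    """Signal fraction and area coverage of a species subset within vessels.

    ``is_target_species`` is a predicate on bin species names (e.g. "is this
    an Abeta species").  Returns percentages:

    * signal fraction — 100 x target-bin intensity over vessel pixels /
      all annotated amyloid-bin intensity over vessel pixels;
    * area coverage — 100 x number of vessel pixels whose summed target
      intensity exceeds (background mean + ``coverage_n_sigma`` x background
      SD) / number of vessel pixels, the background statistics being taken
      from off-vessel pixels (or a zero threshold when none are given).
    """
    vessel_pixels = np.asarray(vessel_pixels)
    if vessel_pixels.size == 0:
        raise ValueError("empty vessel mask")
    annotated = [j for j, b in enumerate(bins) if b.species is not None]
    target = [j for j in annotated if is_target_species(bins[j].species)]
    total = matrix[np.ix_(vessel_pixels, annotated)].sum()
    tgt_sum = matrix[np.ix_(vessel_pixels, target)].sum() if target else 0.0
    signal_pct = 100.0 * tgt_sum / total if total > 0 else 0.0

    per_pixel = matrix[:, target].sum(axis=1) if target else np.zeros(matrix.shape[0])
    if background_pixels is not None and len(background_pixels):
        bg = per_pixel[np.asarray(background_pixels)]
        thr = float(bg.mean() + coverage_n_sigma * bg.std())
    else:
        thr = 0.0
    covered = per_pixel[vessel_pixels] > thr
    area_pct = 100.0 * covered.mean() if target else 0.0
    return float(signal_pct), float(area_pct)


def spsc_matrix(
    images: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    species_names: list[str] | None = None,
    method: str = "pearson",
) -> pd.DataFrame:
    """Single-pixel signal correlation between species ion images.

    ``images`` is an (n_species, rows, cols) stack (or list of 2D images);
    ``mask`` selects the pixels entering the statistic (e.g. the
    Abeta-positive vessel area).  Pearson by default; Spearman computes the
    same statistic on ranks.  A species with zero variance inside the mask
    yields NaN in its row/column (undefined, not zero).
    """
    stack = np.asarray(images, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if stack.ndim != 3:
        raise ValueError("images must be an (n_species, rows, cols) stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if mask.sum() < 3:
        raise ValueError("mask must contain at least 3 pixels")
    data = stack[:, mask]  # (n_species, n_masked)
    if np.isnan(data).any():
        keep = ~np.isnan(data).any(axis=0)
        data = data[:, keep]
    if method == "spearman":
        data = np.apply_along_axis(lambda v: pd.Series(v).rank().to_numpy(), 1, data)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    sd = data.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    names = species_names or [f"species_{i}" for i in range(stack.shape[0])]
    return pd.DataFrame(corr, index=names, columns=names)
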