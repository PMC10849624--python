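"""Image-based quantification of intra-condensate demixing.

Works on two-channel time-lapse series of condensates: a *scaffold* channel
(the condensate-forming species) and a *client* channel (the species that
may demix into puncta inside the condensates).  The analysis follows the
standard colocalization recipe: segment condensates on the scaffold channel,
compute the Pearson correlation between the two channels *within* each
condensate, average area-weighted across condensates, and call the series
"demixed" once the correlation drops below a threshold (default 0.85) for a
sustained number of frames.  The first sustained crossing time is the
demixing time t_demix; the correlation at the final timepoint is R_end
(R_10h for a 10-hour series).

Phase intensities report the background-subtracted mean client intensity in
the mixed region (condensate minus puncta) and the demixed region (puncta),
plus their ratio, i.e. the relative client enrichment of the demixed phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import filters, measure

__all__ = [
    "CondensateMask",
    "DemixTimecourse",
    "ImageSeries",
    "PhaseIntensities",
    "SegmentationParams",
    "UndefinedCorrelationError",
    "demix_timecourse",
    "pearson_within_mask",
    "phase_intensities",
    "segment_condensates",
]

DEMIX_THRESHOLD_DEFAULT = 0.85


class UndefinedCorrelationError(ValueError):
    """Pearson correlation undefined (zero variance or <2 pixels)."""


@dataclass
class ImageSeries:
    """Two-channel time-lapse: frames (T, 2, H, W), timestamps in hours."""

    frames: np.ndarray
    timestamps: np.ndarray  # hours
    pixel_size_um: float = 1.0
    scaffold_channel: int = 0
    client_channel: int = 1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[1] != 2:
            raise ValueError("frames must have shape (T, 2, H, W)")
        if self.frames.shape[0] != self.timestamps.shape[0]:
            raise ValueError("one timestamp per frame required")
        if (self.frames < 0).any():
            raise ValueError("intensities must be non-negative")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def scaffold(self, t: int) -> np.ndarray:
        return self.frames[t, self.scaffold_channel]

    def client(self, t: int) -> np.ndarray:
        return self.frames[t, self.client_channel]


@dataclass
class SegmentationParams:
    """Smoothing + automatic threshold + area filter.

    Puncta are smaller than condensates, so they get their own (lighter)
    smoothing scale to avoid blurring their boundaries into the mixed phase.
    """

    smoothing_sigma: float = 2.0  # px, scaffold/condensate channel
    punctum_smoothing_sigma: float = 1.0  # px, client channel
    min_area: int = 20  # px, condensates
    min_punctum_area: int = 4  # px, client puncta
    threshold_method: str = "otsu"


@dataclass
class CondensateMask:
    """Per-frame labelled condensate masks and client-puncta masks."""

    condensates: list[np.ndarray]  # labelled int arrays, 0 = background
    puncta: list[np.ndarray]  # labelled, nonzero only inside condensates

    def __post_init__(self) -> None:
        for cond, punc in zip(self.condensates, self.puncta):
            if np.any((punc > 0) & (cond == 0)):
                raise ValueError("client puncta must lie inside condensates")


@dataclass
class DemixTimecourse:
    """Pearson r(t), threshold classification and kinetics summary."""

    timestamps: np.ndarray  # hours
    r: np.ndarray  # area-weighted mean Pearson per frame (NaN = undefined)
    threshold: float
    persistence: int
    t_demix: float | None  # hours, first sustained crossing; None if never
    r_end: float  # correlation at the final timepoint (R_10h for 10 h series)
    per_condensate: list[dict[int, float]] = field(default_factory=list)

    @property
    def demixed(self) -> bool:
        return self.t_demix is not None


@dataclass
class PhaseIntensities:
    """Background-subtracted client intensity in mixed vs demixed regions."""

    timestamps: np.ndarray
    mixed_mean: np.ndarray  # condensate minus puncta (NaN when undefined)
    demixed_mean: np.ndarray  # puncta (NaN when no puncta at that timepoint)
    enrichment_ratio: np.ndarray  # demixed / mixed
    background: np.ndarray  # per-frame background level subtracted


def _drop_small(binary: np.ndarray, min_area: int) -> np.ndarray:
    lab = measure.label(binary)
    counts = np.bincount(lab.ravel())
    keep = np.where(counts >= min_area)[0]
    keep = keep[keep > 0]
    return np.isin(lab, keep)


def _threshold(img: np.ndarray, method: str) -> float:
    if img.max() == img.min():
        return np.inf  # uniform frame: nothing to segment
    if method == "otsu":
        return float(filters.threshold_otsu(img))
    if method == "li":
        return float(filters.threshold_li(img))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_condensates(
    series: ImageSeries, params: SegmentationParams | None = None
) -> CondensateMask:
    """Segment scaffold condensates and client puncta within them.

    Both channels get the same operator chain: Gaussian smoothing, automatic
    threshold, small-object removal, connected-component labelling.  The
    client threshold is computed from client pixels inside condensates only,
    and puncta are clipped to condensate interiors.  An all-zero frame
    yields an empty mask, not an error.
    """
    if params is None:
        params = SegmentationParams()
    cond_masks = []
    punc_masks = []
    for t in range(series.n_frames):
        sc = filters.gaussian(series.scaffold(t), sigma=params.smoothing_sigma,
                              preserve_range=True)
        thr = _threshold(sc, params.threshold_method)
        binary = _drop_small(sc > thr, params.min_area)
        cond = measure.label(binary)
        cond_masks.append(cond)

        cl = filters.gaussian(series.client(t), sigma=params.punctum_smoothing_sigma,
                              preserve_range=True)
        inside = cond > 0
        punc = np.zeros_like(cond)
        if inside.any():
            vals = cl[inside]
            if vals.max() > vals.min():
                # puncta are client-enriched relative to the condensate mean
                thr_c = float(filters.threshold_otsu(vals))
                pb = _drop_small((cl > thr_c) & inside, params.min_punctum_area)
                punc = measure.label(pb)
        punc_masks.append(punc)
    return CondensateMask(condensates=cond_masks, puncta=punc_masks)


def pearson_within_mask(frame: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation between the two channels over masked pixels.

    ``frame`` has shape (2, H, W); ``mask`` is boolean or labelled (nonzero
    = included).  Raises :class:`UndefinedCorrelationError` when fewer than
    two pixels are selected or either channel has zero variance.
    """
    frame = np.asarray(frame, dtype=float)
    sel = np.asarray(mask) > 0
    if sel.sum() < 2:
        raise UndefinedCorrelationError("mask must cover at least 2 pixels")
    x = frame[0][sel]
    y = frame[1][sel]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a channel within the mask")
    xm = x - x.mean()
    ym = y - y.mean()
    r = float(np.dot(xm, ym) / np.sqrt(np.dot(xm, xm) * np.dot(ym, ym)))
    return float(np.clip(r, -1.0, 1.0))


def demix_timecourse(
    series: ImageSeries,
    masks: CondensateMask,
    threshold: float = DEMIX_THRESHOLD_DEFAULT,
    persistence: int = 2,
) -> DemixTimecourse:
    """Pearson r(t), demixing classification and t_demix.

    r(t) is the area-weighted mean of per-condensate Pearson correlations
    (scaffold vs client); t_demix is the first timestamp at which r drops
    below ``threshold`` and stays below it for ``persistence`` consecutive
    frames.  Condensates with undefined correlation are skipped; a frame
    where every condensate is undefined gets r = NaN, which never counts as
    below threshold.
    """
    if len(masks.condensates) != series.n_frames:
        raise ValueError("masks must align with the series")
    r = np.full(series.n_frames, np.nan)
    per_cond: list[dict[int, float]] = []
    for t in range(series.n_frames):
        cond = masks.condensates[t]
        frame = np.stack([series.scaffold(t), series.client(t)])
        values: dict[int, float] = {}
        weights = []
        vals = []
        for lbl in np.unique(cond[cond > 0]):
            sel = cond == lbl
            try:
                rv = pearson_within_mask(frame, sel)
            except UndefinedCorrelationError:
                continue
            values[int(lbl)] = rv
            vals.append(rv)
            weights.append(sel.sum())
        per_cond.append(values)
        if vals:
            r[t] = np.average(vals, weights=weights)

    below = (r < threshold) & ~np.isnan(r)
    t_demix = None
    run = 0
    for t in range(series.n_frames):
        run = run + 1 if below[t] else 0
        if run >= persistence:
            t_demix = float(series.timestamps[t - persistence + 1])
            break
    finite = np.where(~np.isnan(r))[0]
    r_end = float(r[finite[-1]]) if len(finite) else np.nan
    return DemixTimecourse(
        timestamps=series.timestamps.copy(),
        r=r,
        threshold=threshold,
        persistence=persistence,
        t_demix=t_demix,
        r_end=r_end,
        per_condensate=per_cond,
    )


def phase_intensities(
    series: ImageSeries, masks: CondensateMask
) -> PhaseIntensities:
    """Client intensity in the mixed vs demixed phases per timepoint.

    Background (median client intensity outside all condensates) is
    subtracted.  The mixed region is the condensate interior minus puncta;
    the demixed region is the puncta.  When a region is empty at a
    timepoint its mean is NaN.
    """
    T = series.n_frames
    mixed = np.full(T, np.nan)
    demixed = np.full(T, np.nan)
    bg = np.zeros(T)
    for t in range(T):
        cond = masks.condensates[t] > 0
        punc = masks.puncta[t] > 0
        client = series.client(t)
        outside = ~cond
        bg[t] = float(np.median(client[outside])) if outside.any() else 0.0
        mixed_sel = cond & ~punc
        if mixed_sel.any():
            mixed[t] = float(client[mixed_sel].mean() - bg[t])
        if punc.any():
            demixed[t] = float(client[punc].mean() - bg[t])
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = demixed / mixed
    return PhaseIntensities(
        timestamps=series.timestamps.copy(),
        mixed_mean=mixed,
        demixed_mean=demixed,
        enrichment_ratio=ratio,
        background=bg,
    )
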