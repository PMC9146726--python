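"""Chrominance-based remote photoplethysmography (CHROM rPPG).

Turns a face video into one heart-rate (HR) estimate per 3.3 s window and
per cheek.  The pulse signal is recovered from the subtle colour modulation
of skin: per-window cheek regions give spatially averaged RGB traces, which
are locally normalized, projected onto two chrominance axes

    Xs = 3 Rn - 2 Gn
    Ys = 1.5 Rn + Gn - 1.5 Bn,

band-pass filtered to the physiological band 0.67-3.67 Hz (40-220 bpm), and
combined as Sf = Xf - alpha * Yf with alpha = std(Xf)/std(Yf), which cancels
the dominant specular/illumination component.  Overlapping Hann-weighted
sub-segments are summed (overlap-add) to one pulse signal per window, and
the HR is the frequency of the highest in-band spectral peak.

Face detection is pluggable: any callable ``frame -> (x0, y0, x1, y1) or
None`` can stand in for the default pretrained cascade, so the signal path
is testable without any detector at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Optional, Tuple

import numpy as np
from scipy.signal import firls
from scipy.signal.windows import hann

from .errors import DegenerateSignalError, InputError, VideoIOError

logger = logging.getLogger("rppgstress")

#: Analysis window length in seconds; one HR value is produced per window.
WINDOW_SECONDS = 3.3
#: Physiological pass band in Hz (40 bpm .. 220 bpm).
BAND_HZ = (0.67, 3.67)
#: Sub-segment length (frames) for the overlap-add pulse reconstruction.
SUBSEGMENT_FRAMES = 33
#: Fractional overlap between consecutive sub-segments.
SUBSEGMENT_OVERLAP = 0.5
#: FIR length at the 30 fps reference rate; scaled linearly with fps.
FIR_TAPS_AT_30FPS = 31

BoxT = Tuple[int, int, int, int]  # (x0, y0, x1, y1), 0-based, half-open
FaceDetectorT = Callable[[np.ndarray], Optional[BoxT]]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FrameWindow:
    """A fixed-duration block of RGB frames.

    ``frames`` has shape (n, height, width, 3), dtype uint8; ``fps`` must be
    at least 20 and ``n`` must equal ``floor(WINDOW_SECONDS * fps)``.
    """

    frames: np.ndarray
    fps: float
    start_index: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        if f.ndim != 4 or f.shape[-1] != 3:
            raise InputError(f"frames must be (n, h, w, 3), got {f.shape}")
        if self.fps < 20:
            raise InputError(f"fps must be >= 20, got {self.fps}")
        expected = window_length_frames(self.fps)
        if f.shape[0] != expected:
            raise InputError(
                f"window must hold {expected} frames at {self.fps} fps, "
                f"got {f.shape[0]}")
        self.frames = f


@dataclass(frozen=True)
class CheekROIPair:
    """Left/right cheek rectangles, 0-based half-open (x0, y0, x1, y1)."""

    left: BoxT
    right: BoxT

    def __post_init__(self) -> None:
        for name, (x0, y0, x1, y1) in (("left", self.left),
                                       ("right", self.right)):
            if x1 <= x0 or y1 <= y0:
                raise InputError(f"{name} cheek ROI is empty: "
                                 f"{(x0, y0, x1, y1)}")


@dataclass
class HRSeries:
    """Per-window HR values in bpm; 0 marks a window with no usable signal."""

    values: np.ndarray
    source: str = "left"          # left | right | averaged
    status: str = "raw"           # raw | clean
    window_seconds: float = WINDOW_SECONDS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        nz = v[v != 0]
        if nz.size and (nz.min() < 40.0 - 1e-9 or nz.max() > 220.0 + 1e-9):
            raise InputError("nonzero HR values must lie in [40, 220] bpm")
        self.values = v


def window_length_frames(fps: float) -> int:
    """Number of frames per analysis window: floor(3.3 * fps)."""
    return int(np.floor(WINDOW_SECONDS * fps + 1e-9))


# ---------------------------------------------------------------------------
# Face detection (pluggable) and cheek geometry
# ---------------------------------------------------------------------------

class CascadeFaceDetector:
    """Pretrained multi-scale cascade face detector (scikit-image backend).

    ``xml_path`` may point at any OpenCV-format cascade file; by default the
    LBP frontal-face model shipped with scikit-image is used.  Returns the
    largest detection as a half-open (x0, y0, x1, y1) box.
    """

    def __init__(self, xml_path: Optional[str] = None,
                 min_size: Tuple[int, int] = (24, 24),
                 scale_factor: float = 1.2):
        from skimage.feature import Cascade
        if xml_path is None:
            from skimage.data import lbp_frontal_face_cascade_filename
            xml_path = lbp_frontal_face_cascade_filename()
        self._cascade = Cascade(xml_path)
        self.min_size = min_size
        self.scale_factor = scale_factor

    def __call__(self, frame: np.ndarray) -> Optional[BoxT]:
        h, w = frame.shape[:2]
        detections = self._cascade.detect_multi_scale(
            img=frame, scale_factor=self.scale_factor, step_ratio=1,
            min_size=self.min_size, max_size=(h, w))
        if not detections:
            return None
        best = max(detections, key=lambda d: d["width"] * d["height"])
        x0, y0 = best["c"], best["r"]
        return (x0, y0, x0 + best["width"], y0 + best["height"])


def detect_face(frame: np.ndarray,
                detector: Optional[FaceDetectorT] = None) -> Optional[BoxT]:
    """Detect the (largest) face in an 8-bit RGB frame.

    ``detector`` is any callable returning a half-open box or ``None``;
    when omitted a pretrained cascade is instantiated lazily.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise InputError(f"frame must be (h, w, 3), got {frame.shape}")
    if detector is None:
        detector = _default_detector()
    return detector(frame)


_DEFAULT_DETECTOR: Optional[CascadeFaceDetector] = None


def _default_detector() -> CascadeFaceDetector:
    global _DEFAULT_DETECTOR
    if _DEFAULT_DETECTOR is None:
        _DEFAULT_DETECTOR = CascadeFaceDetector()
    return _DEFAULT_DETECTOR


#: Fractional cheek geometry within the face box: the left cheek spans
#: [0.15, 0.35] of the box width and [0.45, 0.70] of its height (below the
#: eyes, beside the nose); the right cheek is its mirror image.
CHEEK_X_FRACTIONS = (0.15, 0.35)
CHEEK_Y_FRACTIONS = (0.45, 0.70)


def extract_cheek_rois(face_box: BoxT,
                       frame_dims: Tuple[int, int],
                       x_frac: Tuple[float, float] = CHEEK_X_FRACTIONS,
                       y_frac: Tuple[float, float] = CHEEK_Y_FRACTIONS,
                       ) -> CheekROIPair:
    """Cheek rectangles at fixed fractional offsets of a face box.

    ``frame_dims`` is (height, width); both rectangles are clipped to the
    frame and are mirror images about the face box's vertical midline.
    """
    x0, y0, x1, y1 = face_box
    w, h = x1 - x0, y1 - y0
    if w <= 0 or h <= 0:
        raise InputError(f"face box has zero area: {face_box}")
    fh, fw = frame_dims
    ya = y0 + y_frac[0] * h
    yb = y0 + y_frac[1] * h
    lxa = x0 + x_frac[0] * w
    lxb = x0 + x_frac[1] * w
    # mirror about the midline: right cheek x in [1 - xb, 1 - xa] fractions
    rxa = x0 + (1.0 - x_frac[1]) * w
    rxb = x0 + (1.0 - x_frac[0]) * w

    def clip(xa: float, xb: float) -> BoxT:
        cx0 = int(np.clip(round(xa), 0, fw))
        cx1 = int(np.clip(round(xb), 0, fw))
        cy0 = int(np.clip(round(ya), 0, fh))
        cy1 = int(np.clip(round(yb), 0, fh))
        if cx1 <= cx0 or cy1 <= cy0:
            raise InputError("cheek ROI clipped to empty; face box "
                             f"{face_box} outside frame {frame_dims}")
        return (cx0, cy0, cx1, cy1)

    return CheekROIPair(left=clip(lxa, lxb), right=clip(rxa, rxb))


def mean_rgb(frame: np.ndarray, roi: BoxT) -> Tuple[float, float, float]:
    """Spatial mean of each colour channel over a rectangular ROI."""
    x0, y0, x1, y1 = roi
    if x1 <= x0 or y1 <= y0:
        raise InputError(f"empty ROI {roi}")
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise InputError(f"frame must be (h, w, 3), got {frame.shape}")
    if y1 > frame.shape[0] or x1 > frame.shape[1] or x0 < 0 or y0 < 0:
        raise InputError(f"ROI {roi} outside frame {frame.shape[:2]}")
    patch = frame[y0:y1, x0:x1].astype(float)
    means = patch.mean(axis=(0, 1))
    return (float(means[0]), float(means[1]), float(means[2]))


# ---------------------------------------------------------------------------
# CHROM signal chain
# ---------------------------------------------------------------------------

def normalize_segment(trace: np.ndarray) -> np.ndarray:
    """Divide each colour channel by its own temporal mean over the segment.

    ``trace`` has shape (n, 3).  Output channels have mean exactly 1, which
    removes the (multiplicative) dependence on illumination intensity and
    mean skin tone.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 3:
        raise InputError(f"trace must be (n, 3), got {trace.shape}")
    means = trace.mean(axis=0)
    if np.any(means <= 0):
        raise DegenerateSignalError(
            f"non-positive channel mean {means}; cannot normalize")
    return trace / means


def chrom_transform(Rn: np.ndarray, Gn: np.ndarray, Bn: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Project normalized RGB onto the two chrominance axes.

    Xs = 3 Rn - 2 Gn;  Ys = 1.5 Rn + Gn - 1.5 Bn.
    """
    Rn, Gn, Bn = (np.asarray(c, dtype=float) for c in (Rn, Gn, Bn))
    if not (Rn.shape == Gn.shape == Bn.shape):
        raise InputError("channel length mismatch: "
                         f"{Rn.shape}, {Gn.shape}, {Bn.shape}")
    Xs = 3.0 * Rn - 2.0 * Gn
    Ys = 1.5 * Rn + Gn - 1.5 * Bn
    return Xs, Ys


def design_bandpass(fps: float, numtaps: Optional[int] = None) -> np.ndarray:
    """Linear-phase least-squares FIR band-pass for the 0.67-3.67 Hz band.

    Length defaults to 31 taps at 30 fps, scaled linearly with fps (always
    odd, so the filter is symmetric / zero-phase when centred).  Transition
    bands 0.3->0.67 Hz and 3.67->4.2 Hz; a least-squares design keeps the
    pass band usefully flat even at this short length, which a windowed-sinc
    design of the same length does not.
    """
    if fps <= 2 * BAND_HZ[1]:
        raise InputError(f"fps {fps} too low for band edge {BAND_HZ[1]} Hz")
    if numtaps is None:
        numtaps = int(round(FIR_TAPS_AT_30FPS * fps / 30.0))
    if numtaps % 2 == 0:
        numtaps += 1
    nyq = fps / 2.0
    hi_stop = min(BAND_HZ[1] + 0.53, 0.98 * nyq)
    bands = [0.0, max(0.05, BAND_HZ[0] - 0.37), BAND_HZ[0],
             BAND_HZ[1], hi_stop, nyq]
    desired = [0, 0, 1, 1, 0, 0]
    return firls(numtaps, bands, desired, fs=fps)


def bandpass(signal: np.ndarray, fps: float,
             numtaps: Optional[int] = None) -> np.ndarray:
    """Zero-phase band-pass to [0.67, 3.67] Hz with explicit DC removal.

    The mean is subtracted first (so constant inputs map to exactly zero),
    then the symmetric FIR kernel is applied once via reflection-padded
    convolution: symmetry makes the single pass zero-phase.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise InputError(f"signal must be 1-D, got shape {x.shape}")
    taps = design_bandpass(fps, numtaps)
    if x.size < taps.size:
        raise InputError(
            f"signal length {x.size} shorter than filter length {taps.size}")
    x = x - x.mean()
    half = taps.size // 2
    xp = np.pad(x, half, mode="reflect")
    return np.convolve(xp, taps, mode="valid")


def alpha_combine(Xf: np.ndarray, Yf: np.ndarray
                  ) -> Tuple[float, np.ndarray]:
    """Combine filtered chrominance signals: Sf = Xf - alpha * Yf.

    alpha = std(Xf) / std(Yf) equalizes the two amplitudes so that the
    common (illumination) component cancels.
    """
    Xf = np.asarray(Xf, dtype=float)
    Yf = np.asarray(Yf, dtype=float)
    if Xf.shape != Yf.shape:
        raise InputError(f"length mismatch: {Xf.shape} vs {Yf.shape}")
    sy = float(np.std(Yf))
    if sy == 0.0:
        raise DegenerateSignalError("std(Yf) = 0; alpha undefined")
    alpha = float(np.std(Xf)) / sy
    return alpha, Xf - alpha * Yf


def overlap_add_pulse(window_trace: np.ndarray, fps: float,
                      sub_len: int = SUBSEGMENT_FRAMES,
                      overlap: float = SUBSEGMENT_OVERLAP) -> np.ndarray:
    """Full CHROM pulse signal for one analysis window.

    The (n, 3) RGB trace is cut into ``sub_len``-frame sub-segments with the
    given fractional overlap; each sub-segment is independently normalized,
    chrominance-transformed, band-pass filtered and alpha-combined, then
    Hann-weighted and summed into a length-n pulse signal.  Sub-segments
    with degenerate statistics contribute zeros.
    """
    trace = np.asarray(window_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 3:
        raise InputError(f"window trace must be (n, 3), got {trace.shape}")
    n = trace.shape[0]
    expected = window_length_frames(fps)
    if n != expected:
        raise InputError(f"window trace must hold {expected} frames "
                         f"at {fps} fps, got {n}")
    sub_len = min(sub_len, n)
    hop = max(1, int(round(sub_len * (1.0 - overlap))))
    starts = list(range(0, n - sub_len + 1, hop))
    if starts[-1] + sub_len < n:          # cover the tail
        starts.append(n - sub_len)
    win = hann(sub_len, sym=True)
    out = np.zeros(n)
    for s in starts:
        seg = trace[s:s + sub_len]
        try:
            norm = normalize_segment(seg)
            Xs, Ys = chrom_transform(norm[:, 0], norm[:, 1], norm[:, 2])
            Xf = bandpass(Xs, fps)
            Yf = bandpass(Ys, fps)
            _, sf = alpha_combine(Xf, Yf)
        except DegenerateSignalError:
            continue                      # zero-fill this sub-segment
        out[s:s + sub_len] += win * sf
    return out


def hr_from_spectrum(Sf: np.ndarray, fps: float,
                     nfft: int = 1024,
                     power_eps: float = 1e-12) -> float:
    """HR in bpm from the highest spectral peak inside the pass band.

    The pulse signal is zero-padded to ``nfft`` points and the in-band
    magnitude maximum refined by parabolic interpolation on the three bins
    around the peak (a 3.3 s window has ~18 bpm native resolution; the
    refinement recovers bpm-level estimates).  Returns the sentinel 0.0
    when the total in-band power falls below ``power_eps``.
    """
    x = np.asarray(Sf, dtype=float)
    if x.ndim != 1:
        raise InputError(f"Sf must be 1-D, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise InputError("Sf contains non-finite values")
    nfft = max(nfft, x.size)
    spec = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fps)
    band = (freqs >= BAND_HZ[0]) & (freqs <= BAND_HZ[1])
    if not band.any() or float(np.sum(spec[band] ** 2)) < power_eps:
        return 0.0
    idx = np.nonzero(band)[0]
    k = idx[int(np.argmax(spec[idx]))]
    # parabolic refinement around the peak bin
    if 0 < k < spec.size - 1:
        a, b, c = spec[k - 1], spec[k], spec[k + 1]
        denom = a - 2 * b + c
        delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    f_hat = (k + delta) * fps / nfft
    bpm = float(np.clip(f_hat * 60.0, 40.0, 220.0))
    return bpm


# ---------------------------------------------------------------------------
# Video driver
# ---------------------------------------------------------------------------

@dataclass
class ArrayVideo:
    """In-memory video: an (n, h, w, 3) uint8 array plus its frame rate."""

    frames: np.ndarray
    fps: float

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def read_video(path: str) -> ArrayVideo:
    """Decode a video file into memory.

    Supports NPZ frame bundles written by this package (arrays ``frames``
    and ``fps``) and, where an imageio plugin is available, standard
    containers such as MP4/AVI.
    """
    import os
    if str(path).endswith(".npz"):
        with np.load(path) as z:
            return ArrayVideo(frames=z["frames"], fps=float(z["fps"]))
    if not os.path.exists(path):
        raise VideoIOError(f"no such video: {path}")
    try:
        import imageio.v3 as iio
        meta = iio.immeta(path)
        fps = float(meta.get("fps", 0.0))
        frames = np.stack(list(iio.imiter(path)))
    except Exception as exc:                     # pragma: no cover - backend
        raise VideoIOError(f"cannot decode {path}: {exc}") from exc
    if fps <= 0:
        raise VideoIOError(f"cannot determine frame rate of {path}")
    return ArrayVideo(frames=frames, fps=fps)


def iter_windows(video: Iterable[np.ndarray], fps: float
                 ) -> Iterator[FrameWindow]:
    """Cut a frame stream into consecutive non-overlapping 3.3 s windows."""
    nw = window_length_frames(fps)
    buf: list = []
    start = 0
    count = 0
    for frame in video:
        buf.append(np.asarray(frame))
        if len(buf) == nw:
            yield FrameWindow(frames=np.stack(buf), fps=fps,
                              start_index=start)
            count += 1
            start += nw
            buf = []
    if buf:
        logger.warning("discarding %d trailing frames (< one %.1f s window)",
                       len(buf), WINDOW_SECONDS)
    if count == 0:
        logger.warning("video shorter than one %.1f s window: no HR values",
                       WINDOW_SECONDS)


def process_window(window: FrameWindow,
                   detector: Optional[FaceDetectorT] = None,
                   roi_pair: Optional[CheekROIPair] = None
                   ) -> Tuple[float, float]:
    """One (left, right) HR pair from a single window.

    Face detection runs on the first frame only (subjects sit still within
    3.3 s) and the ROI is held fixed; a window without a detectable face
    yields the sentinel pair (0, 0).  ``roi_pair`` bypasses detection.
    """
    frames = window.frames
    if roi_pair is None:
        box = detect_face(frames[0], detector)
        if box is None:
            return 0.0, 0.0
        try:
            roi_pair = extract_cheek_rois(box, frames.shape[1:3])
        except InputError:
            return 0.0, 0.0
    hrs = []
    for roi in (roi_pair.left, roi_pair.right):
        trace = np.array([mean_rgb(f, roi) for f in frames])
        try:
            sf = overlap_add_pulse(trace, window.fps)
        except DegenerateSignalError:
            hrs.append(0.0)
            continue
        hrs.append(hr_from_spectrum(sf, window.fps))
    return hrs[0], hrs[1]


def process_video(video, detector: Optional[FaceDetectorT] = None,
                  fps: Optional[float] = None,
                  roi_pair: Optional[CheekROIPair] = None
                  ) -> Tuple[HRSeries, HRSeries]:
    """Per-cheek HR series for a whole video.

    ``video`` is any frame iterable with an ``fps`` attribute (or pass
    ``fps`` explicitly).  The video is cut into consecutive non-overlapping
    3.3 s windows; the number of output values per cheek is exactly
    floor(duration / 3.3).
    """
    if fps is None:
        fps = getattr(video, "fps", None)
    if fps is None:
        raise InputError("frame rate unknown: pass fps or a video "
                         "object with an fps attribute")
    if fps < 20:
        raise InputError(f"fps must be >= 20, got {fps}")
    left, right = [], []
    for window in iter_windows(video, fps):
        hl, hr = process_window(window, detector=detector, roi_pair=roi_pair)
        left.append(hl)
        right.append(hr)
    logger.info("processed %d windows (%.1f s each)", len(left),
                WINDOW_SECONDS)
    return (HRSeries(np.array(left), source="left"),
            HRSeries(np.array(right), source="right"))
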