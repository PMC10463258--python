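"""Mixture decomposition of Sanger chromatograms at an insertion junction.

An RT-PCR product amplified from a template pool that contains two species
identical up to a short insertion produces a *mixed* electropherogram: up to
the insertion point the two reads agree, and downstream every scan position
superimposes the signal of two frame-shifted sequences.  At read positions
where the two species predict different bases ("informative sites") the
relative channel amplitudes carry the mixing fraction.

Two estimators are provided:

``estimate_fraction_amplitude``
    The peak-height ratio method: at each informative site the fraction of
    the insertion-bearing species is estimated as
    ``a(+base) / (a(+base) + a(-base))`` and site estimates are averaged.

``estimate_fraction_lsq``
    A least-squares generalization fitting a single mixing fraction to all
    peaks in a window around the junction, using sum-normalized channel
    amplitudes so that per-peak signal decay cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

CHANNELS = "ACGT"
_CHANNEL_INDEX = {b: i for i, b in enumerate(CHANNELS)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_sequence(seq: str, name: str) -> None:
    bad = set(seq) - set(CHANNELS)
    if bad:
        raise ValueError(f"{name} contains non-ACGT characters: {sorted(bad)}")


@dataclass(frozen=True)
class ChromatogramTrace:
    """Four-channel electropherogram with called peak positions.

    ``channels`` has shape ``(n_scans, 4)`` with columns ordered A, C, G, T;
    amplitudes are non-negative.  ``peak_positions`` holds one scan index per
    called base, strictly increasing.  ``base_calls`` is optional and, when
    present, has one character per peak.
    """

    channels: np.ndarray
    peak_positions: np.ndarray
    base_calls: str | None = None

    def __post_init__(self):
        channels = np.asarray(self.channels, dtype=float)
        peaks = np.asarray(self.peak_positions, dtype=int)
        if channels.ndim != 2 or channels.shape[1] != 4:
            raise ValueError("channels must be an (n_scans, 4) array")
        if np.any(channels < 0):
            raise ValueError("channel amplitudes must be non-negative")
        if peaks.ndim != 1:
            raise ValueError("peak_positions must be one-dimensional")
        if peaks.size and (peaks.min() < 0 or peaks.max() >= channels.shape[0]):
            raise ValueError("peak positions outside scan range")
        if np.any(np.diff(peaks) <= 0):
            raise ValueError("peak_positions must be strictly increasing")
        if self.base_calls is not None and len(self.base_calls) != peaks.size:
            raise ValueError("base_calls length must match peak count")
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "peak_positions", peaks)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_positions.size)

    @property
    def n_scans(self) -> int:
        return int(self.channels.shape[0])


@dataclass(frozen=True)
class ReferencePair:
    """The two co-amplified species around an insertion junction.

    ``short_seq`` is the read without the insertion; the insertion-bearing
    read equals ``short_seq[:insert_offset] + insert_seq +
    short_seq[insert_offset:]``.  ``insert_offset`` is a 0-based base index
    in the short read; the insert is placed before that base (half-open
    convention).
    """

    short_seq: str
    insert_seq: str
    insert_offset: int

    def __post_init__(self):
        _validate_sequence(self.short_seq, "short_seq")
        _validate_sequence(self.insert_seq, "insert_seq")
        if len(self.insert_seq) < 1:
            raise ValueError("insert_seq must have length >= 1")
        if not 0 <= self.insert_offset <= len(self.short_seq):
            raise ValueError(
                f"insert_offset {self.insert_offset} outside "
                f"[0, {len(self.short_seq)}]"
            )

    @property
    def long_seq(self) -> str:
        off = self.insert_offset
        return self.short_seq[:off] + self.insert_seq + self.short_seq[off:]

    def reverse_complemented(self) -> "ReferencePair":
        """The same junction as seen by a reverse-primer read."""
        return ReferencePair(
            short_seq=reverse_complement(self.short_seq),
            insert_seq=reverse_complement(self.insert_seq),
            insert_offset=len(self.short_seq) - self.insert_offset,
        )


@dataclass(frozen=True)
class InformativeSite:
    """A read position where the two species predict different bases."""

    peak_index: int
    base_plus: str
    base_minus: str

    def __post_init__(self):
        if self.base_plus == self.base_minus:
            raise ValueError("informative site requires base_plus != base_minus")
        for b in (self.base_plus, self.base_minus):
            if b not in _CHANNEL_INDEX:
                raise ValueError(f"invalid base {b!r}")
        if self.peak_index < 0:
            raise ValueError("peak_index must be non-negative")


@dataclass(frozen=True)
class MixtureEstimate:
    """Estimated fraction of the insertion-bearing species."""

    fraction: float
    per_site_fractions: tuple = ()
    sd: float = 0.0
    n_sites: int = 0
    method: str = "amplitude_ratio"

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        object.__setattr__(
            self, "per_site_fractions", tuple(float(v) for v in self.per_site_fractions)
        )


def detect_peaks(channel_data: np.ndarray, expected_spacing: float) -> np.ndarray:
    """Locate base peaks in the summed four-channel signal.

    Strict local maxima of the channel sum are thinned greedily from left to
    right so that consecutive peaks are at least ``0.6 * expected_spacing``
    scans apart; when two maxima are closer, the lower scan index wins.
    A flat (or all-zero) signal yields an empty array.
    """
    channel_data = np.asarray(channel_data, dtype=float)
    if expected_spacing <= 0:
        raise ValueError("expected_spacing must be positive")
    if channel_data.shape[0] < 2 * expected_spacing:
        raise ValueError("signal shorter than two expected spacings")
    total = channel_data.sum(axis=1)
    interior = np.arange(1, total.size - 1)
    is_max = (total[interior] > total[interior - 1]) & (
        total[interior] >= total[interior + 1]
    )
    candidates = interior[is_max & (total[interior] > 0)]
    min_dist = 0.6 * expected_spacing
    kept: list[int] = []
    for pos in candidates:
        if not kept or pos - kept[-1] >= min_dist:
            kept.append(int(pos))
    return np.asarray(kept, dtype=int)


def extract_peak_amplitudes(
    trace: ChromatogramTrace, smooth_sigma: float = 1.0
) -> np.ndarray:
    """Per-peak channel amplitudes as an ``(n_peaks, 4)`` table.

    The amplitude of a channel at a called peak is the channel's value at
    the peak apex after light Gaussian smoothing (``smooth_sigma`` scans;
    0 disables).  Reading the smoothed apex emulates how a peak height is
    read off a sequencing profile while suppressing scan-level noise;
    smoothing attenuates all channels by the same factor, so amplitude
    *ratios* are unaffected.
    """
    if trace.n_peaks == 0:
        raise ValueError("trace has no peaks")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be non-negative")
    channels = trace.channels
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter1d

        channels = gaussian_filter1d(channels, smooth_sigma, axis=0, mode="nearest")
    return channels[trace.peak_positions].copy()


def find_informative_sites(
    refs: ReferencePair, n_sites: int = 3, window: int | None = None
) -> list[InformativeSite]:
    """First ``n_sites`` read positions downstream of the junction where the
    insertion-bearing and insertion-free reads disagree.

    Positions ``insert_offset .. insert_offset + window - 1`` of the two
    reads are compared base by base.  ``n_sites`` defaults to 3, the number
    of nucleotide amplitudes conventionally read off a mixed profile.  The
    comparison is truncated (with a warning) where the shorter read ends.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    long_seq, short_seq = refs.long_seq, refs.short_seq
    if window is None:
        window = len(short_seq) - refs.insert_offset
    if window < n_sites:
        raise ValueError("window must be >= n_sites")
    stop = refs.insert_offset + window
    limit = min(len(short_seq), len(long_seq))
    if stop > limit:
        warnings.warn(
            "comparison window extends past the shorter read; truncating",
            stacklevel=2,
        )
        stop = limit
    sites = []
    for i in range(refs.insert_offset, stop):
        if long_seq[i] != short_seq[i]:
            sites.append(
                InformativeSite(peak_index=i, base_plus=long_seq[i], base_minus=short_seq[i])
            )
            if len(sites) == n_sites:
                break
    return sites


def estimate_fraction_amplitude(
    peak_table: np.ndarray, sites: list[InformativeSite]
) -> MixtureEstimate:
    """Peak-height ratio estimate of the insertion-bearing fraction.

    At each informative site the fraction is the amplitude of the
    +insertion base channel over the summed amplitudes of the two predicted
    channels; the reported fraction is the mean over sites with the sample
    SD as dispersion.  Sites where both predicted channels read zero are
    dropped with a warning.
    """
    peak_table = np.asarray(peak_table, dtype=float)
    if not sites:
        raise ValueError("at least one informative site required")
    per_site = []
    for site in sites:
        if site.peak_index >= peak_table.shape[0]:
            raise ValueError(
                f"site peak index {site.peak_index} outside peak table "
                f"({peak_table.shape[0]} peaks)"
            )
        a_plus = peak_table[site.peak_index, _CHANNEL_INDEX[site.base_plus]]
        a_minus = peak_table[site.peak_index, _CHANNEL_INDEX[site.base_minus]]
        denom = a_plus + a_minus
        if denom <= 0:
            warnings.warn(
                f"site at peak {site.peak_index} has zero signal in both "
                "predicted channels; dropped",
                stacklevel=2,
            )
            continue
        per_site.append(min(1.0, max(0.0, a_plus / denom)))
    if not per_site:
        raise ValueError("all informative sites had zero signal")
    fraction = float(np.mean(per_site))
    sd = float(np.std(per_site, ddof=1)) if len(per_site) > 1 else 0.0
    return MixtureEstimate(
        fraction=min(1.0, max(0.0, fraction)),
        per_site_fractions=tuple(per_site),
        sd=sd,
        n_sites=len(per_site),
        method="amplitude_ratio",
    )


def lsq_design(
    trace: ChromatogramTrace, refs: ReferencePair, window: int | None = None
):
    """Observed and template peak rows for the least-squares estimator.

    Returns ``(obs, e_plus, e_minus)``: sum-normalized observed channel rows
    and one-hot expected rows under the +insertion and -insertion species,
    restricted to peaks in ``[insert_offset, insert_offset + window)`` that
    both reads cover.  Channel values are read at the called peak scan
    (where the peak model is exact); normalizing each row by its channel
    sum absorbs the per-peak signal scale (amplitude decay), so a single
    mixing fraction is the only free parameter left.
    """
    long_seq, short_seq = refs.long_seq, refs.short_seq
    if window is None:
        window = len(short_seq) - refs.insert_offset
    if trace.n_peaks == 0:
        raise ValueError("trace has no peaks")
    table = trace.channels[trace.peak_positions]
    start = refs.insert_offset
    stop = min(start + window, len(short_seq), len(long_seq), table.shape[0])
    if stop <= start:
        raise ValueError("window covers no peaks shared by both reads")
    rows, e_plus, e_minus = [], [], []
    for i in range(start, stop):
        s = table[i].sum()
        if s <= 0:
            continue
        rows.append(table[i] / s)
        ep = np.zeros(4)
        ep[_CHANNEL_INDEX[long_seq[i]]] = 1.0
        em = np.zeros(4)
        em[_CHANNEL_INDEX[short_seq[i]]] = 1.0
        e_plus.append(ep)
        e_minus.append(em)
    if not rows:
        raise ValueError("no usable peaks in window")
    return np.array(rows), np.array(e_plus), np.array(e_minus)


def mixture_sse(f: float, obs: np.ndarray, e_plus: np.ndarray, e_minus: np.ndarray) -> float:
    """Sum of squared residuals of the mixture model at fraction ``f``."""
    resid = obs - (f * e_plus + (1.0 - f) * e_minus)
    return float(np.sum(resid * resid))


def estimate_fraction_lsq(
    trace: ChromatogramTrace, refs: ReferencePair, window: int | None = None
) -> MixtureEstimate:
    """Least-squares estimate of the insertion-bearing fraction.

    Minimizes ``sum_i ||obs_i - f*E+_i - (1-f)*E-_i||^2`` over ``f`` in
    [0, 1], where ``obs_i`` are sum-normalized observed channel amplitudes
    at peak ``i`` and ``E±`` the expected channel patterns of the two
    species.  The unconstrained minimizer is closed form (a projection onto
    the template difference) and is clamped to [0, 1].

    Raises ``ValueError("unidentifiable")`` when the two species predict
    identical bases at every peak in the window.
    """
    obs, e_plus, e_minus = lsq_design(trace, refs, window)
    diff = e_plus - e_minus
    denom = float(np.sum(diff * diff))
    if denom == 0.0:
        raise ValueError("unidentifiable: species agree at every peak in window")
    f = float(np.sum((obs - e_minus) * diff) / denom)
    f = min(1.0, max(0.0, f))
    informative = np.any(diff != 0, axis=1)
    per_site = []
    for o, ep, em in zip(obs[informative], e_plus[informative], e_minus[informative]):
        p, m = float(o[ep > 0][0]), float(o[em > 0][0])
        if p + m > 0:
            per_site.append(min(1.0, max(0.0, p / (p + m))))
    sd = float(np.std(per_site, ddof=1)) if len(per_site) > 1 else 0.0
    return MixtureEstimate(
        fraction=f,
        per_site_fractions=tuple(per_site),
        sd=sd,
        n_sites=int(informative.sum()),
        method="least_squares",
    )
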