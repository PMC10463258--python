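"""Synthetic chromatograms, gel lanes, and replicate bundles with known truth.

The generator emulates the measurement chain used to profile the four
SorCS2 splice variants: an RT-PCR of the receptor's intracellular-domain
coding region yields a *long* and a *short* fragment (differing by a 42-nt
acidic-cluster insertion) that are separated on an agarose gel; each band is
Sanger-sequenced and is itself a mixture of transcripts with and without a
3-nt serine-codon insertion.  Three quantities therefore define a sample:

``f_long``
    molar fraction of the long (acidic-cluster) fragment, read from the gel;
``s_long`` / ``s_short``
    serine-insertion fraction within the long / short band, read from the
    mixed chromatogram of that band.

The four isoform fractions follow as A=(1-f_long)(1-s_short),
C=(1-f_long)s_short, B=f_long(1-s_long), D=f_long*s_long.

Forward models are deliberately simple: Gaussian base peaks on a uniform
scan grid with exponential amplitude decay and optional channel crosstalk;
Gaussian gel bands positioned by a log-length migration law.  All noise is
seeded and every derived seed is deterministic, so identical inputs
reproduce byte-identical serialized bundles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .gels import LaneProfile
from .traces import CHANNELS, _CHANNEL_INDEX, ChromatogramTrace, ReferencePair

#: Serine codon used for the 3-nt insertion event.  The study's junction
#: nucleotides are not published, so this (like the sequences below) is a
#: configurable placeholder, never baked into the estimators.
DEFAULT_SERINE_INSERT = "AGC"

#: 42-nt stand-in for the acidic-cluster insertion: fourteen Asp/Glu codons.
DEFAULT_ACIDIC_INSERT = "GATGAAGAGGACGATGAGGAAGACGATGAAGAGGACGATGAG"

#: Synthetic sequencing window around the serine junction (40 nt, junction
#: after base 20).
DEFAULT_JUNCTION_SHORT = "GCTCACCAGGTAGCTGTGACCATCGTGAGCTTGTACCTGA"
DEFAULT_JUNCTION_OFFSET = 20

#: Fragment lengths (nt) of the two RT-PCR products and the GAPDH loading
#: control: the long fragment carries the 42-nt insertion.
DEFAULT_FRAGMENT_LENGTHS = {"short": 500, "long": 542, "reference": 450}


def default_reference_pair() -> ReferencePair:
    return ReferencePair(
        short_seq=DEFAULT_JUNCTION_SHORT,
        insert_seq=DEFAULT_SERINE_INSERT,
        insert_offset=DEFAULT_JUNCTION_OFFSET,
    )


@dataclass(frozen=True)
class TraceParams:
    """Forward-model parameters for a simulated electropherogram.

    peak_spacing : scan points per base.
    peak_sigma : Gaussian peak width in scan points; must be smaller than
        ``peak_spacing`` so neighbouring peaks stay resolvable.
    base_amplitude : peak amplitude of the first base, arbitrary units.
    decay_rate : per-base exponential amplitude decay.
    noise_sd : SD of additive Gaussian scan noise (truncated at zero).
    crosstalk : fraction of each peak's amplitude leaking (evenly) into the
        other three channels; in [0, 0.2].
    """

    peak_spacing: float = 12.0
    peak_sigma: float = 1.8
    base_amplitude: float = 1000.0
    decay_rate: float = 0.005
    noise_sd: float = 50.0
    crosstalk: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.peak_spacing <= 0 or self.peak_sigma <= 0 or self.base_amplitude <= 0:
            raise ValueError("scale parameters must be strictly positive")
        if self.peak_sigma >= self.peak_spacing:
            raise ValueError("peak_sigma must be < peak_spacing (peaks resolvable)")
        if self.decay_rate < 0 or self.noise_sd < 0:
            raise ValueError("decay_rate and noise_sd must be non-negative")
        if not 0.0 <= self.crosstalk <= 0.2:
            raise ValueError("crosstalk must lie in [0, 0.2]")


@dataclass(frozen=True)
class GelParams:
    """Forward-model parameters for a simulated 1-D gel lane.

    Band centers follow ``position = migration_intercept -
    migration_slope * ln(length)`` (strictly decreasing in length), matching
    the near-log mobility of DNA in agarose.  ``stain_mode`` controls
    whether band volume is proportional to molar abundance (``molar``) or to
    abundance times fragment length (``mass``, as for intercalating dyes).
    """

    migration_intercept: float = 1700.0
    migration_slope: float = 250.0
    lane_length: int = 400
    band_sigma: float = 2.0
    stain_mode: str = "molar"
    background_level: float = 20.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.band_sigma <= 0:
            raise ValueError("band_sigma must be positive")
        if self.migration_slope <= 0:
            raise ValueError("migration_slope must be positive")
        if self.stain_mode not in ("molar", "mass"):
            raise ValueError("stain_mode must be 'molar' or 'mass'")
        if self.lane_length < 10:
            raise ValueError("lane_length too short")
        if self.background_level < 0 or self.noise_sd < 0:
            raise ValueError("background_level and noise_sd must be non-negative")

    def migrate(self, length: float) -> float:
        """Lane position (pixels) of a fragment of the given length (nt)."""
        if length <= 0:
            raise ValueError("fragment length must be positive")
        return self.migration_intercept - self.migration_slope * math.log(length)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth isoform composition of a simulated sample.

    ``fractions`` holds the four isoform fractions (A, B, C, D) in order;
    they must be non-negative and sum to 1.  The band-level quantities
    ``f_long``, ``s_short`` and ``s_long`` are derived and always consistent
    with the fractions.
    """

    fractions: tuple
    replicate_count: int = 3
    seed: int = 0

    def __post_init__(self):
        fr = tuple(float(v) for v in self.fractions)
        if len(fr) != 4:
            raise ValueError("fractions must have four entries (A, B, C, D)")
        if any(v < 0 for v in fr):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        object.__setattr__(self, "fractions", fr)

    @classmethod
    def from_band_fractions(
        cls,
        f_long: float,
        s_short: float,
        s_long: float,
        replicate_count: int = 3,
        seed: int = 0,
    ) -> "SyntheticTruth":
        for name, v in (("f_long", f_long), ("s_short", s_short), ("s_long", s_long)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        a = (1.0 - f_long) * (1.0 - s_short)
        c = (1.0 - f_long) * s_short
        b = f_long * (1.0 - s_long)
        d = f_long * s_long
        return cls((a, b, c, d), replicate_count=replicate_count, seed=seed)

    @property
    def f_long(self) -> float:
        return self.fractions[1] + self.fractions[3]

    @property
    def s_short(self) -> float:
        a, c = self.fractions[0], self.fractions[2]
        return c / (a + c) if a + c > 0 else 0.0

    @property
    def s_long(self) -> float:
        b, d = self.fractions[1], self.fractions[3]
        return d / (b + d) if b + d > 0 else 0.0


def simulate_trace(
    f_insert: float, refs: ReferencePair, params: TraceParams
) -> ChromatogramTrace:
    """Simulate a mixed electropherogram of the two junction species.

    The trace is the superposition ``f_insert * T(+ins) + (1 - f_insert) *
    T(-ins)`` where ``T(s)`` places, for base ``i`` of sequence ``s``, a
    Gaussian peak of width ``peak_sigma`` at scan ``margin + i *
    peak_spacing`` in that base's channel, scaled by ``base_amplitude *
    exp(-decay_rate * i)``.  Crosstalk then leaks a fraction of each
    channel evenly into the other three (channel sums are conserved), and
    i.i.d. Gaussian noise truncated at zero is added.
    """
    if not 0.0 <= f_insert <= 1.0:
        raise ValueError("f_insert must lie in [0, 1]")
    long_seq, short_seq = refs.long_seq, refs.short_seq
    n_peaks = len(long_seq)
    margin = int(math.ceil(4 * params.peak_sigma))
    positions = margin + params.peak_spacing * np.arange(n_peaks)
    n_scans = int(math.ceil(positions[-1])) + margin + 1
    x = np.arange(n_scans, dtype=float)
    channels = np.zeros((n_scans, 4))
    for seq, weight in ((long_seq, f_insert), (short_seq, 1.0 - f_insert)):
        if weight == 0.0:
            continue
        for i, base in enumerate(seq):
            amp = weight * params.base_amplitude * math.exp(-params.decay_rate * i)
            channels[:, _CHANNEL_INDEX[base]] += amp * np.exp(
                -0.5 * ((x - positions[i]) / params.peak_sigma) ** 2
            )
    if params.crosstalk > 0:
        ct = params.crosstalk
        total = channels.sum(axis=1, keepdims=True)
        channels = (1.0 - ct) * channels + (ct / 3.0) * (total - channels)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        channels = channels + rng.normal(0.0, params.noise_sd, channels.shape)
    np.clip(channels, 0.0, None, out=channels)
    peak_positions = np.rint(positions).astype(int)
    base_calls = "".join(CHANNELS[j] for j in channels[peak_positions].argmax(axis=1))
    return ChromatogramTrace(
        channels=channels, peak_positions=peak_positions, base_calls=base_calls
    )


@dataclass(frozen=True)
class SimulatedLane:
    """A simulated lane profile together with its ground truth."""

    profile: LaneProfile
    true_volumes: dict
    centers: dict
    collisions: tuple = ()


def simulate_lane(
    abundances: dict, lengths: dict, params: GelParams
) -> SimulatedLane:
    """Simulate a 1-D gel lane with one Gaussian band per species.

    Band volume is the species abundance (``molar`` staining) or abundance
    times fragment length (``mass``); the profile adds a constant
    background and truncated Gaussian pixel noise.  Species whose fragment
    lengths migrate to the same position are allowed but flagged in
    ``collisions``.
    """
    if not abundances or all(v <= 0 for v in abundances.values()):
        raise ValueError("at least one species must have positive abundance")
    missing = set(abundances) - set(lengths)
    if missing:
        raise ValueError(f"no fragment length for species: {sorted(missing)}")
    positions = np.arange(params.lane_length, dtype=float)
    intensities = np.full(params.lane_length, float(params.background_level))
    volumes, centers = {}, {}
    for label, abundance in abundances.items():
        if abundance < 0:
            raise ValueError("abundances must be non-negative")
        volume = abundance * (lengths[label] if params.stain_mode == "mass" else 1.0)
        center = params.migrate(lengths[label])
        volumes[label] = float(volume)
        centers[label] = float(center)
        if volume > 0:
            intensities += (
                volume
                / (params.band_sigma * math.sqrt(2.0 * math.pi))
                * np.exp(-0.5 * ((positions - center) / params.band_sigma) ** 2)
            )
    labels = sorted(centers)
    collisions = tuple(
        (a, b)
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
        if abs(centers[a] - centers[b]) < 1e-9
    )
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        intensities = intensities + rng.normal(0.0, params.noise_sd, intensities.shape)
    np.clip(intensities, 0.0, None, out=intensities)
    return SimulatedLane(
        profile=LaneProfile(positions=positions, intensities=intensities),
        true_volumes=volumes,
        centers=centers,
        collisions=collisions,
    )


@dataclass(frozen=True)
class ReplicateBundle:
    """One technical replicate: two band chromatograms plus the gel lane."""

    index: int
    trace_long: ChromatogramTrace
    trace_short: ChromatogramTrace
    lane: SimulatedLane


@dataclass(frozen=True)
class SyntheticDataset:
    truth: SyntheticTruth
    refs: ReferencePair
    lengths: dict
    trace_params: TraceParams
    gel_params: GelParams
    replicates: tuple


def _derive_seed(base: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence((int(base),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


#: Total lane signal (arbitrary units) shared by the long and short bands;
#: the loading-control band gets a fixed comparable volume.
_LANE_TOTAL = 5000.0
_REFERENCE_VOLUME = 4000.0


def generate_dataset(
    truth: SyntheticTruth,
    trace_params: TraceParams | None = None,
    gel_params: GelParams | None = None,
    refs: ReferencePair | None = None,
    lengths: dict | None = None,
) -> SyntheticDataset:
    """Generate a replicate bundle for one sample with known truth.

    Each technical replicate draws an independent, deterministically derived
    seed (base seed plus replicate index) and consists of a chromatogram of
    the long band (serine mixture at ``s_long``), a chromatogram of the
    short band (mixture at ``s_short``), and a gel lane whose long/short
    band abundances realize ``f_long`` alongside a loading-control band.
    """
    trace_params = trace_params if trace_params is not None else TraceParams()
    gel_params = gel_params if gel_params is not None else GelParams()
    refs = refs if refs is not None else default_reference_pair()
    lengths = dict(lengths) if lengths is not None else dict(DEFAULT_FRAGMENT_LENGTHS)
    replicates = []
    for r in range(truth.replicate_count):
        rep_seed = truth.seed + r
        trace_long = simulate_trace(
            truth.s_long, refs, replace(trace_params, seed=_derive_seed(rep_seed, 1))
        )
        trace_short = simulate_trace(
            truth.s_short, refs, replace(trace_params, seed=_derive_seed(rep_seed, 2))
        )
        lane = simulate_lane(
            abundances={
                "long": truth.f_long * _LANE_TOTAL,
                "short": (1.0 - truth.f_long) * _LANE_TOTAL,
                "reference": _REFERENCE_VOLUME,
            },
            lengths=lengths,
            params=replace(gel_params, seed=_derive_seed(rep_seed, 3)),
        )
        replicates.append(
            ReplicateBundle(
                index=r, trace_long=trace_long, trace_short=trace_short, lane=lane
            )
        )
    return SyntheticDataset(
        truth=truth,
        refs=refs,
        lengths=lengths,
        trace_params=trace_params,
        gel_params=gel_params,
        replicates=tuple(replicates),
    )
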