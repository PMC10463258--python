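"""Four-isoform profiles from band and within-band splice fractions.

The two alternative splice events are measured separately — the gel gives
the long-fragment (acidic-cluster) fraction ``f_long``, and the mixed
chromatogram of each band gives the serine-insertion fraction within that
band (``s_short``, ``s_long``).  Because each band is sequenced on its own,
the only available estimator of the four isoform fractions multiplies the
band fraction with its within-band serine split:

    A = (1 - f_long) (1 - s_short)      C = (1 - f_long) s_short
    B = f_long (1 - s_long)             D = f_long s_long

This map is a bijection between (f_long, s_short, s_long) in (0,1)^3 and
interior profiles; ``band_fractions`` is its inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

ISOFORMS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class IsoformProfile:
    """Fractions of isoforms A-D (sum to 1) with replicate SDs."""

    fractions: dict
    sds: dict | None = None
    n_replicates: int = 1

    def __post_init__(self):
        fractions = {k: float(self.fractions[k]) for k in ISOFORMS}
        sds = {k: float((self.sds or {}).get(k, 0.0)) for k in ISOFORMS}
        for k, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {k}={v} outside [0, 1]")
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1 within 1e-9")
        if any(v < 0 for v in sds.values()):
            raise ValueError("sds must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        object.__setattr__(self, "fractions", fractions)
        object.__setattr__(self, "sds", sds)

    def as_array(self) -> np.ndarray:
        return np.array([self.fractions[k] for k in ISOFORMS])


def combine_isoform_fractions(
    f_long: float, s_short: float, s_long: float
) -> IsoformProfile:
    """Combine band and within-band fractions into a four-isoform profile.

    The complements are computed by subtraction so the four fractions sum
    to 1 exactly.  When ``f_long`` is 0 or 1 the serine fraction of the
    absent band is unused (and not validated against the data).
    """
    for name, v in (("f_long", f_long), ("s_short", s_short), ("s_long", s_long)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    c = (1.0 - f_long) * s_short
    a = (1.0 - f_long) - c
    d = f_long * s_long
    b = f_long - d
    return IsoformProfile(fractions={"A": a, "B": b, "C": c, "D": d})


def band_fractions(profile: IsoformProfile) -> tuple:
    """Inverse of :func:`combine_isoform_fractions` for interior profiles.

    Returns ``(f_long, s_short, s_long)``; a serine fraction whose band has
    zero abundance is reported as 0.
    """
    fr = profile.fractions
    f_long = fr["B"] + fr["D"]
    short_total = fr["A"] + fr["C"]
    s_short = fr["C"] / short_total if short_total > 0 else 0.0
    s_long = fr["D"] / f_long if f_long > 0 else 0.0
    return f_long, s_short, s_long


def mouse_two_isoform_profile(s_fraction: float) -> IsoformProfile:
    """Two-transcript profile for species lacking the acidic-cluster event.

    Mouse brain expresses only the A/C analogues (no acidic-cluster
    insertion), so the profile is ``combine_isoform_fractions(0,
    s_fraction, 0)``: A = 1 - s, C = s, B = D = 0.
    """
    return combine_isoform_fractions(0.0, s_fraction, 0.0)


def aggregate_replicates(profiles: list) -> IsoformProfile:
    """Mean ± sample SD of technical replicates, renormalized to sum 1.

    Each input must be a single-replicate profile.  Means are averaged per
    isoform and renormalized so the aggregate sums to 1; SDs are the sample
    SD (ddof=1) of the raw per-replicate fractions, 0 for a single
    replicate.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    for p in profiles:
        if p.n_replicates != 1:
            raise ValueError("aggregate_replicates expects single-replicate profiles")
    stacked = np.array([p.as_array() for p in profiles])
    means = stacked.mean(axis=0)
    means = means / means.sum()
    if len(profiles) > 1:
        sds = stacked.std(axis=0, ddof=1)
    else:
        sds = np.zeros(4)
    return IsoformProfile(
        fractions=dict(zip(ISOFORMS, means)),
        sds=dict(zip(ISOFORMS, sds)),
        n_replicates=len(profiles),
    )


def quantify_dataset(dataset, n_sites: int = 3, method: str = "amplitude"):
    """Run the full quantification on a synthetic replicate bundle.

    For every technical replicate the gel lane is background-subtracted and
    band volumes integrated to give ``f_long``; the long- and short-band
    chromatograms are decomposed at the serine junction to give ``s_long``
    and ``s_short``; the three fractions are combined into an isoform
    profile.  Per-replicate profiles are then aggregated to mean ± SD.
    Mass-mode staining is corrected to molar fractions using the known
    fragment lengths.
    """
    from .gels import long_fraction, quantify_bands, subtract_background
    from .traces import (
        estimate_fraction_amplitude,
        estimate_fraction_lsq,
        extract_peak_amplitudes,
        find_informative_sites,
    )

    if method not in ("amplitude", "lsq"):
        raise ValueError("method must be 'amplitude' or 'lsq'")
    refs = dataset.refs
    sites = find_informative_sites(refs, n_sites=n_sites)
    centers = {
        label: dataset.gel_params.migrate(length)
        for label, length in dataset.lengths.items()
        if label in ("long", "short")
    }
    correction = (
        {k: dataset.lengths[k] for k in ("long", "short")}
        if dataset.gel_params.stain_mode == "mass"
        else None
    )
    profiles = []
    for rep in dataset.replicates:
        lane = subtract_background(rep.lane.profile, method="linear")
        bands = quantify_bands(lane, centers)
        f_long = long_fraction(bands, length_correction=correction)
        estimates = {}
        for key, trace in (("s_long", rep.trace_long), ("s_short", rep.trace_short)):
            if method == "amplitude":
                table = extract_peak_amplitudes(trace)
                estimates[key] = estimate_fraction_amplitude(table, sites).fraction
            else:
                estimates[key] = estimate_fraction_lsq(trace, refs).fraction
        profiles.append(
            combine_isoform_fractions(f_long, estimates["s_short"], estimates["s_long"])
        )
    return aggregate_replicates(profiles)
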