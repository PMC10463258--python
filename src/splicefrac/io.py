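"""Readers and writers: ABIF/AB1 and TSV traces, FASTA, lane TSV, reports.

Trace TSV format (``# splicefrac trace v1``): comment header lines carry the
peak-index table (``# peak_positions``) and optional base calls, followed by
a ``scan  A  C  G  T`` table.  Lane profiles are two-column TSV
(``position``, ``intensity``).  All coordinates are 0-based, half-open.

ABIF reading uses the analyzed channel tags DATA9-DATA12 (ordered by the
file's FWO_ record), peak locations from PLOC and called bases from PBAS;
files carrying only raw DATA1-4 channels are rejected because amplitude
ratios assume processed traces.
"""

from __future__ import annotations

import dataclasses
import json
import struct
from pathlib import Path

import numpy as np

from . import __version__
from .gels import LaneProfile
from .isoforms import ISOFORMS, IsoformProfile
from .synth import (
    GelParams,
    ReplicateBundle,
    SimulatedLane,
    SyntheticDataset,
    SyntheticTruth,
    TraceParams,
)
from .traces import CHANNELS, ChromatogramTrace, ReferencePair

_TRACE_MAGIC = "# splicefrac trace v1"


class FormatError(ValueError):
    """Raised for malformed or unsupported input files."""


# ---------------------------------------------------------------------------
# chromatogram traces


def write_trace_tsv(trace: ChromatogramTrace, path) -> None:
    path = Path(path)
    lines = [_TRACE_MAGIC]
    lines.append(
        "# peak_positions: " + ",".join(str(int(p)) for p in trace.peak_positions)
    )
    if trace.base_calls is not None:
        lines.append("# base_calls: " + trace.base_calls)
    lines.append("scan\tA\tC\tG\tT")
    # repr-exact floats so a written trace reads back bit-identical
    for i, row in enumerate(trace.channels):
        lines.append(
            f"{i}\t" + "\t".join(format(v, ".17g") for v in row)
        )
    path.write_text("\n".join(lines) + "\n")


def _read_trace_tsv(path: Path) -> ChromatogramTrace:
    peak_positions = None
    base_calls = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("# peak_positions:"):
                    text = line.split(":", 1)[1].strip()
                    peak_positions = (
                        [int(v) for v in text.split(",")] if text else []
                    )
                elif line.startswith("# base_calls:"):
                    base_calls = line.split(":", 1)[1].strip()
                continue
            if line.startswith("scan\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}: malformed trace row {line!r}")
            rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise FormatError(f"{path}: no scan data")
    channels = np.asarray(rows, dtype=float)
    if peak_positions is None:
        from .traces import detect_peaks

        peak_positions = detect_peaks(channels, expected_spacing=12.0)
        base_calls = None
    return ChromatogramTrace(
        channels=channels,
        peak_positions=np.asarray(peak_positions, dtype=int),
        base_calls=base_calls,
    )


def _read_abif(path: Path) -> ChromatogramTrace:
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except Exception as exc:  # Biopython raises bare exceptions on truncation
        raise FormatError(f"{path}: cannot parse ABIF file ({exc})") from exc
    raw = record.annotations.get("abif_raw", {})
    if not all(f"DATA{i}" in raw for i in range(9, 13)):
        present_raw = [k for k in raw if k.startswith("DATA")]
        raise FormatError(
            f"{path}: analyzed channels DATA9-DATA12 missing "
            f"(found {present_raw or 'none'}); raw DATA1-4 traces are not "
            "supported — amplitude ratios require processed traces"
        )
    fwo = raw.get("FWO_1")
    if fwo is None:
        raise FormatError(f"{path}: missing FWO_ channel-order record")
    order = fwo.decode() if isinstance(fwo, bytes) else str(fwo)
    if sorted(order) != sorted(CHANNELS):
        raise FormatError(f"{path}: invalid FWO_ record {order!r}")
    columns = {}
    for i, base in enumerate(order):
        data = np.asarray(raw[f"DATA{9 + i}"], dtype=float)
        columns[base] = data
    channels = np.column_stack([columns[b] for b in CHANNELS])
    ploc = raw.get("PLOC2", raw.get("PLOC1"))
    if ploc is None:
        from .traces import detect_peaks

        peaks = detect_peaks(channels, expected_spacing=12.0)
        base_calls = None
    else:
        peaks = np.atleast_1d(np.asarray(ploc, dtype=int))
        pbas = raw.get("PBAS2", raw.get("PBAS1"))
        base_calls = (
            pbas.decode() if isinstance(pbas, bytes) else pbas
        ) if pbas is not None else None
    return ChromatogramTrace(
        channels=np.clip(channels, 0.0, None),
        peak_positions=peaks,
        base_calls=base_calls,
    )


def read_trace(path) -> ChromatogramTrace:
    """Read a chromatogram from ABIF/AB1 (magic bytes ``ABIF``) or trace TSV."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic == b"ABIF":
        return _read_abif(path)
    if not magic:
        raise FormatError(f"{path}: empty file")
    return _read_trace_tsv(path)


def write_abif(trace: ChromatogramTrace, path, channel_order: str = "GATC") -> None:
    """Write a minimal ABIF-compatible trace file.

    Only the records needed for quantification are emitted: analyzed
    channels DATA9-DATA12 in ``channel_order`` (FWO_), peak locations
    (PLOC2) and called bases (PBAS2).  Amplitudes are rounded to int16.
    """
    path = Path(path)
    if sorted(channel_order) != sorted(CHANNELS):
        raise ValueError(f"invalid channel_order {channel_order!r}")
    base_calls = trace.base_calls or "N" * trace.n_peaks
    items = []
    for i, base in enumerate(channel_order):
        col = np.clip(np.rint(trace.channels[:, CHANNELS.index(base)]), 0, 32767)
        data = b"".join(struct.pack(">h", int(v)) for v in col)
        items.append((b"DATA", 9 + i, 4, 2, len(col), data))
    items.append(
        (
            b"PLOC",
            2,
            4,
            2,
            trace.n_peaks,
            b"".join(struct.pack(">h", int(p)) for p in trace.peak_positions),
        )
    )
    items.append((b"PBAS", 2, 2, 1, len(base_calls), base_calls.encode()))
    items.append((b"FWO_", 1, 2, 1, 4, channel_order.encode()))
    body = b""
    offset = 128
    dirents = []
    for name, num, etype, esize, nelem, data in items:
        dsize = esize * nelem
        if dsize <= 4:
            packed = data + b"\x00" * (4 - dsize)
            dirents.append(
                struct.pack(">4sihhii4si", name, num, etype, esize, nelem, dsize, packed, 0)
            )
        else:
            dirents.append(
                struct.pack(">4sihhiiii", name, num, etype, esize, nelem, dsize, offset, 0)
            )
            body += data
            offset += dsize
    tdir = struct.pack(
        ">4sihhiiii", b"tdir", 1, 1023, 28, len(items), 28 * len(items), offset, 0
    )
    header = b"ABIF" + struct.pack(">h", 101) + tdir
    header += b"\x00" * (128 - len(header))
    path.write_bytes(header + body + b"".join(dirents))


# ---------------------------------------------------------------------------
# lane profiles


def write_lane_tsv(profile: LaneProfile, path) -> None:
    lines = ["position\tintensity"]
    for p, v in zip(profile.positions, profile.intensities):
        lines.append(f"{format(p, 'g')}\t{format(v, '.4f')}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lane_tsv(path) -> LaneProfile:
    path = Path(path)
    positions, intensities = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("position"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}: malformed lane row {line!r}")
            positions.append(float(parts[0]))
            intensities.append(float(parts[1]))
    if not positions:
        raise FormatError(f"{path}: no lane data")
    return LaneProfile(
        positions=np.asarray(positions), intensities=np.asarray(intensities)
    )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict:
    """Read a (possibly wrapped, multi-record) FASTA into an id -> sequence map.

    Sequences are upper-cased; characters outside A, C, G, T, N and
    duplicate record ids are rejected.
    """
    from Bio import SeqIO

    path = Path(path)
    records = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise FormatError(f"{path}: duplicate record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{path}: record {record.id!r} has invalid characters {sorted(bad)}"
            )
        records[record.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict, path, width: int = 60) -> None:
    lines = []
    for name in records:
        lines.append(f">{name}")
        seq = records[name]
        for i in range(0, len(seq), width):
            lines.append(seq[i : i + width])
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth / params JSON


def _params_to_dict(params) -> dict:
    return dataclasses.asdict(params)


def write_truth_json(truth: SyntheticTruth, path) -> None:
    payload = {
        "isoform_fractions": dict(zip(ISOFORMS, truth.fractions)),
        "f_long": truth.f_long,
        "s_short": truth.s_short,
        "s_long": truth.s_long,
        "replicate_count": truth.replicate_count,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth_json(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    if "isoform_fractions" in payload:
        fr = payload["isoform_fractions"]
        fractions = tuple(float(fr[k]) for k in ISOFORMS)
        return SyntheticTruth(
            fractions,
            replicate_count=int(payload.get("replicate_count", 3)),
            seed=int(payload.get("seed", 0)),
        )
    return SyntheticTruth.from_band_fractions(
        float(payload["f_long"]),
        float(payload["s_short"]),
        float(payload["s_long"]),
        replicate_count=int(payload.get("replicate_count", 3)),
        seed=int(payload.get("seed", 0)),
    )


def read_params_json(path, cls):
    """Load :class:`TraceParams` or :class:`GelParams` from a JSON object."""
    payload = json.loads(Path(path).read_text())
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise FormatError(f"{path}: unknown fields {sorted(unknown)}")
    return cls(**payload)


# ---------------------------------------------------------------------------
# dataset bundles


def write_dataset(dataset: SyntheticDataset, outdir) -> list:
    """Serialize a synthetic bundle to a directory; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    def _write(name, writer, *args):
        p = outdir / name
        writer(*args, p)
        paths.append(p)

    _write("truth.json", write_truth_json, dataset.truth)
    refs = dataset.refs
    _write(
        "references.fa",
        write_fasta,
        {"short_junction": refs.short_seq, "long_junction": refs.long_seq},
    )
    meta = {
        "insert_seq": refs.insert_seq,
        "insert_offset": refs.insert_offset,
        "fragment_lengths": dataset.lengths,
        "trace_params": _params_to_dict(dataset.trace_params),
        "gel_params": _params_to_dict(dataset.gel_params),
        "version": __version__,
    }
    p = outdir / "run_meta.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths.append(p)
    for rep in dataset.replicates:
        _write(f"rep{rep.index}_long.trace.tsv", write_trace_tsv, rep.trace_long)
        _write(f"rep{rep.index}_short.trace.tsv", write_trace_tsv, rep.trace_short)
        _write(f"rep{rep.index}_lane.tsv", write_lane_tsv, rep.lane.profile)
    return paths


def load_dataset(rundir) -> SyntheticDataset:
    """Load a bundle written by :func:`write_dataset`."""
    rundir = Path(rundir)
    truth = read_truth_json(rundir / "truth.json")
    meta = json.loads((rundir / "run_meta.json").read_text())
    refs_fa = read_fasta(rundir / "references.fa")
    refs = ReferencePair(
        short_seq=refs_fa["short_junction"],
        insert_seq=meta["insert_seq"],
        insert_offset=int(meta["insert_offset"]),
    )
    trace_params = TraceParams(**meta["trace_params"])
    gel_params = GelParams(**meta["gel_params"])
    replicates = []
    for r in range(truth.replicate_count):
        trace_long = read_trace(rundir / f"rep{r}_long.trace.tsv")
        trace_short = read_trace(rundir / f"rep{r}_short.trace.tsv")
        profile = read_lane_tsv(rundir / f"rep{r}_lane.tsv")
        replicates.append(
            ReplicateBundle(
                index=r,
                trace_long=trace_long,
                trace_short=trace_short,
                lane=SimulatedLane(profile=profile, true_volumes={}, centers={}),
            )
        )
    return SyntheticDataset(
        truth=truth,
        refs=refs,
        lengths={k: int(v) for k, v in meta["fragment_lengths"].items()},
        trace_params=trace_params,
        gel_params=gel_params,
        replicates=tuple(replicates),
    )


# ---------------------------------------------------------------------------
# reports


def write_report(profiles: dict, path, seed: int | None = None) -> None:
    """Write a sample x isoform report as TSV (mean ± SD per isoform).

    ``profiles`` maps a sample/tissue name to an :class:`IsoformProfile`.
    Rows are ordered by sample name then isoform; coordinates in all
    splicefrac outputs are 0-based, half-open.  Output is deterministic:
    identical inputs produce byte-identical files.
    """
    lines = [
        f"# splicefrac report v{__version__}",
        "# coordinates: 0-based, half-open",
    ]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    lines.append("sample\tisoform\tfraction\tsd\tn_replicates")
    for sample in sorted(profiles):
        prof = profiles[sample]
        for iso in ISOFORMS:
            lines.append(
                f"{sample}\t{iso}\t{prof.fractions[iso]:.6f}"
                f"\t{prof.sds[iso]:.6f}\t{prof.n_replicates}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
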