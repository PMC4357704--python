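"""Readers and writers for the text formats the pipeline touches.

bedGraph (0-based half-open) carries timing profiles and coverage tracks;
fibers travel as a flat TSV (fiber_id, length_kb, label, start_kb, end_kb);
Ct tables as CSV.  Every writer's output round-trips through its reader.
A run manifest (JSON: parameters, package version, input checksums) makes a
result reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from collections import OrderedDict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .synth import Fiber, FiberSegment, FiberSet
from .timing import CoverageTrack, TimingProfile

logger = logging.getLogger(__name__)

__all__ = [
    "read_bedgraph",
    "read_timing_profile",
    "read_coverage",
    "write_bedgraph",
    "read_fibers",
    "write_fibers",
    "read_ct_table",
    "write_ct_table",
    "load_config",
    "save_config",
    "write_manifest",
    "sha256_file",
]

_SKIP_PREFIXES = ("#", "track", "browser")


def read_bedgraph(path) -> pd.DataFrame:
    """Parse a 4-column bedGraph into a (chrom, start, end, value) frame.

    Track/comment lines are skipped.  Overlapping intervals raise an error
    naming the first offending pair; a non-numeric value names its line.
    """
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
    if not chroms:
        logger.warning("read_bedgraph: %s is empty", path)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends,
                       "value": values})
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    same = (df["chrom"].values[1:] == df["chrom"].values[:-1])
    overlap = same & (df["start"].values[1:] < df["end"].values[:-1])
    if overlap.any():
        k = int(np.argmax(overlap))
        a = df.iloc[k]
        b = df.iloc[k + 1]
        raise ValueError(
            f"{path}: overlapping intervals "
            f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
        )
    return df


def read_timing_profile(path) -> TimingProfile:
    df = read_bedgraph(path)
    return TimingProfile(
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(),
        ends=df["end"].to_numpy(),
        values=df["value"].to_numpy(),
    )


def read_coverage(path, library_size: int | None = None) -> CoverageTrack:
    """Read per-interval counts; library size defaults to the in-interval sum."""
    df = read_bedgraph(path)
    counts = df["value"].to_numpy()
    if np.any(counts != np.round(counts)):
        raise ValueError(f"{path}: coverage values must be integer counts")
    counts = counts.astype(np.int64)
    if library_size is None:
        library_size = int(counts.sum())
    return CoverageTrack(
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(),
        ends=df["end"].to_numpy(),
        counts=counts, library_size=library_size,
    )


def write_bedgraph(obj, path) -> None:
    """Write a TimingProfile or CoverageTrack as 4-column bedGraph."""
    if isinstance(obj, TimingProfile):
        values = obj.values
        fmt = "%.10g"
    elif isinstance(obj, CoverageTrack):
        values = obj.counts
        fmt = "%d"
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as bedGraph")
    with open(path, "w") as fh:
        for c, s, e, v in zip(obj.chroms, obj.starts, obj.ends, values):
            fh.write(f"{c}\t{s}\t{e}\t{fmt % v}\n")


# ---------------------------------------------------------------------------
# fibers
# ---------------------------------------------------------------------------

_FIBER_COLUMNS = ("fiber_id", "length_kb", "label", "start_kb", "end_kb")
_NO_SEGMENT = "none"    # sentinel row for fibers without visible segments


def write_fibers(fibers: FiberSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_FIBER_COLUMNS) + "\n")
        for fiber in fibers:
            if not fiber.segments:
                fh.write(f"{fiber.fiber_id}\t{fiber.length:.17g}\t"
                         f"{_NO_SEGMENT}\t0\t0\n")
                continue
            for seg in fiber.segments:
                fh.write(
                    f"{fiber.fiber_id}\t{fiber.length:.17g}\t{seg.label}\t"
                    f"{seg.start:.17g}\t{seg.end:.17g}\n"
                )


def read_fibers(path, condition: str = "",
                pulse1_minutes: float = 15.0,
                pulse2_minutes: float = 30.0) -> FiberSet:
    """Read a fiber TSV; duplicate fiber_ids with disjoint segments merge."""
    valid = {"IdU", "CldU", "unlabeled", _NO_SEGMENT}
    per_fiber: "OrderedDict[str, dict]" = OrderedDict()
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != _FIBER_COLUMNS:
            raise ValueError(f"{path}: unexpected fiber TSV header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            fid, length_s, label, start_s, end_s = fields
            if label not in valid:
                raise ValueError(f"{path}:{lineno}: invalid label {label!r}")
            try:
                length = float(length_s)
                start, end = float(start_s), float(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})")
            rec = per_fiber.setdefault(fid, {"length": length, "segments": []})
            if abs(rec["length"] - length) > 1e-9:
                raise ValueError(
                    f"{path}:{lineno}: conflicting lengths for fiber {fid!r}"
                )
            if label != _NO_SEGMENT:
                rec["segments"].append((label, start, end))
    fibers = []
    for fid, rec in per_fiber.items():
        segs = sorted(rec["segments"], key=lambda s: (s[1], s[2]))
        fibers.append(Fiber(
            fiber_id=fid, length=rec["length"],
            segments=tuple(FiberSegment(*s) for s in segs),
        ))
    return FiberSet(fibers=tuple(fibers), condition=condition,
                    pulse1_minutes=pulse1_minutes,
                    pulse2_minutes=pulse2_minutes)


# ---------------------------------------------------------------------------
# Ct tables, config, manifest
# ---------------------------------------------------------------------------

def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"amplicon", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing Ct table columns {sorted(missing)}")
    return df


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, parameters: dict, inputs: list | None = None) -> str:
    """Write a machine-readable run manifest next to the results."""
    manifest = {
        "tool": "oritime",
        "version": __version__,
        "parameters": parameters,
        "inputs": {
            os.path.basename(str(p)): sha256_file(p) for p in (inputs or [])
        },
    }
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
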