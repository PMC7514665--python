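"""Reading and writing multichannel recordings and analysis artifacts.

The reference on-disk format is human-inspectable delimited text: one
tab-separated file per recording with one column per channel, accompanied by
a sidecar JSON file (``<name>.meta.json``) declaring each channel's sampling
rate, units, start time and sample count. Channels with different rates
simply have columns of different lengths; shorter columns are padded with
empty fields. Segmentations are exported as three-column interval tables
(start s, end s, label) and c_max grids as long-format CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .segmentation import BreathSegmentation, Phase
from .signals import SampledSignal
from .simulate import SubjectRecord

__all__ = [
    "write_recording",
    "read_recording",
    "write_segmentation",
    "read_segmentation",
    "write_subject",
    "read_subject",
    "write_table",
]

# 17 significant digits guarantee exact float64 round-tripping
_FLOAT_FMT = "%.17g"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_recording(path: str | Path, signals: Sequence[SampledSignal]) -> None:
    """Write channels as a wide TSV plus a sidecar metadata JSON."""
    path = Path(path)
    labels = [s.label for s in signals]
    if len(set(labels)) != len(labels):
        raise ValueError("channel labels must be unique")
    meta = {
        "format": "fsampen-recording",
        "channels": [
            {
                "label": s.label,
                "fs": s.fs,
                "units": s.units,
                "t0": s.t0,
                "n_samples": s.n,
            }
            for s in signals
        ],
    }
    n_rows = max(s.n for s in signals)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(labels)
        cols = [s.samples for s in signals]
        for i in range(n_rows):
            writer.writerow(
                [(_FLOAT_FMT % c[i]) if i < c.size else "" for c in cols]
            )
    with open(_meta_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_recording(path: str | Path) -> dict[str, SampledSignal]:
    """Read a recording written by :func:`write_recording`.

    Every channel must be declared in the sidecar metadata with a sampling
    rate and units; undeclared columns, missing declarations and ragged rows
    are rejected.
    """
    path = Path(path)
    meta_file = _meta_path(path)
    if not meta_file.exists():
        raise FileNotFoundError(f"missing sidecar metadata {meta_file}")
    with open(meta_file) as fh:
        meta = json.load(fh)
    decls = {c["label"]: c for c in meta.get("channels", [])}
    for lbl, c in decls.items():
        if "fs" not in c:
            raise ValueError(f"channel {lbl!r}: sampling rate not declared")
        if "units" not in c:
            raise ValueError(f"channel {lbl!r}: units not declared")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        rows = list(reader)
    n_fields = len(header)
    for i, row in enumerate(rows):
        if len(row) != n_fields:
            raise ValueError(f"ragged row {i + 2} in {path}: "
                             f"{len(row)} fields, expected {n_fields}")
    unknown = [h for h in header if h not in decls]
    if unknown:
        raise ValueError(f"undeclared channels in {path}: {unknown}")
    out: dict[str, SampledSignal] = {}
    for j, lbl in enumerate(header):
        c = decls[lbl]
        vals = [row[j] for row in rows if row[j] != ""]
        n = c.get("n_samples", len(vals))
        if len(vals) != n:
            raise ValueError(
                f"channel {lbl!r}: {len(vals)} samples on disk, {n} declared"
            )
        out[lbl] = SampledSignal(
            np.array(vals, dtype=np.float64),
            fs=float(c["fs"]),
            label=lbl,
            units=str(c["units"]),
            t0=float(c.get("t0", 0.0)),
        )
    return out


def write_segmentation(path: str | Path, seg: BreathSegmentation) -> None:
    """Interval table: start (s), end (s), phase label."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["start_s", "end_s", "label"])
        for p in seg.phases:
            writer.writerow([_FLOAT_FMT % p.start, _FLOAT_FMT % p.end, p.label])


def read_segmentation(path: str | Path, min_duration_s: float = 0.5) -> BreathSegmentation:
    df = pd.read_csv(path, sep="\t")
    phases = tuple(
        Phase(float(r.start_s), float(r.end_s), str(r.label))
        for r in df.itertuples()
    )
    return BreathSegmentation(phases, min_duration_s=min_duration_s)


def write_table(path: str | Path, rows: Iterable[Mapping], params: Mapping | None = None) -> None:
    """Write records as CSV with the effective parameter set as a sidecar.

    Every exported table carries its provenance: the full parameter set used
    to produce it is stored alongside in ``<name>.params.json``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(list(rows)).to_csv(path, index=False, float_format="%.10g")
    if params is not None:
        with open(path.with_name(path.name + ".params.json"), "w") as fh:
            json.dump(params, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")


def write_subject(dirpath: str | Path, record: SubjectRecord) -> None:
    """Write a synthetic subject as one recording file per condition."""
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subject_id": record.subject_id,
        "montage": record.montage,
        "conditions": list(record.conditions),
        "groups": {g: list(m) for g, m in record.groups.items()},
        "seed": record.seed,
    }
    with open(dirpath / "subject.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    for cond in record.conditions:
        signals = [record.channels[lbl][cond] for lbl in record.channels]
        signals += [record.pressures[p][cond] for p in record.pressures]
        signals.append(record.envelopes[cond])
        write_recording(dirpath / f"{cond}.tsv", signals)


def read_subject(dirpath: str | Path) -> SubjectRecord:
    """Read a subject directory back into a :class:`SubjectRecord`."""
    dirpath = Path(dirpath)
    with open(dirpath / "subject.json") as fh:
        manifest = json.load(fh)
    conditions = tuple(manifest["conditions"])
    channels: dict[str, dict[str, SampledSignal]] = {}
    pressures: dict[str, dict[str, SampledSignal]] = {}
    envelopes: dict[str, SampledSignal] = {}
    pressure_labels = {"Pmo", "Pga", "Poes"}
    for cond in conditions:
        rec = read_recording(dirpath / f"{cond}.tsv")
        for lbl, sig in rec.items():
            if lbl == "envelope":
                envelopes[cond] = sig
            elif lbl in pressure_labels:
                pressures.setdefault(lbl, {})[cond] = sig
            else:
                channels.setdefault(lbl, {})[cond] = sig
    return SubjectRecord(
        subject_id=manifest["subject_id"],
        montage=manifest["montage"],
        conditions=conditions,
        channels=channels,
        pressures=pressures,
        envelopes=envelopes,
        groups={g: tuple(m) for g, m in manifest["groups"].items()},
        seed=int(manifest.get("seed", 0)),
    )
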