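"""Consensus transmembrane topology from multiple per-residue predictor tracks.

Each predictor contributes a binary per-residue mark (TM / non-TM). The
consensus is a vote: residues whose TM vote fraction reaches a threshold form
runs, nearby runs are bridged across short non-qualifying gaps, and runs
shorter than a minimum helix span are discarded. This automates the common
manual step of reconciling SOSUI/HMMTop/JPRED/PSIPRED-style predictions.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TopologyTrack",
    "ConsensusTopology",
    "TrackFormatError",
    "read_tracks",
    "write_tracks",
    "consensus",
    "write_segments_tsv",
    "write_consensus_json",
]


class TrackFormatError(ValueError):
    """Raised for non-binary or inconsistent predictor tracks."""


@dataclass
class TopologyTrack:
    predictor_name: str
    labels: np.ndarray  # boolean, one entry per residue

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise TrackFormatError("track labels must be a non-empty 1-D vector")


@dataclass
class ConsensusTopology:
    """Sorted, non-overlapping 1-based inclusive TM segments plus the vote."""

    segments: list[tuple[int, int]]
    vote_fraction: np.ndarray
    threshold: float

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def membership(self) -> np.ndarray:
        """Boolean per-residue vector of consensus TM membership."""
        out = np.zeros(len(self.vote_fraction), dtype=bool)
        for s, e in self.segments:
            out[s - 1 : e] = True
        return out


def read_tracks(path: str | Path) -> list[TopologyTrack]:
    """Read a TSV with one row per residue and one 0/1 column per predictor."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[0] == 0:
        raise TrackFormatError(f"{path}: no residue rows")
    if df.shape[1] == 0:
        raise TrackFormatError(f"{path}: no predictor columns")
    if "residue" in df.columns:  # optional index column
        df = df.drop(columns=["residue"])
    tracks = []
    for name in df.columns:
        vals = df[name].to_numpy()
        if not np.isin(vals, [0, 1]).all():
            bad = sorted(set(vals) - {0, 1})
            raise TrackFormatError(
                f"{path}: predictor {name!r} has non-binary entries {bad}"
            )
        tracks.append(TopologyTrack(predictor_name=str(name), labels=vals.astype(bool)))
    return tracks


def write_tracks(tracks: list[TopologyTrack], path: str | Path) -> None:
    df = pd.DataFrame(
        {t.predictor_name: t.labels.astype(int) for t in tracks}
    )
    df.insert(0, "residue", np.arange(1, len(df) + 1))
    df.to_csv(path, sep="\t", index=False)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as 1-based inclusive (start, end)."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    return [(int(s) + 1, int(e) + 1) for s, e in zip(starts, ends)]


def consensus(
    tracks: list[TopologyTrack],
    threshold: float = 0.5,
    min_len: int = 15,
    max_gap: int = 3,
    expected_count: int | None = None,
) -> ConsensusTopology:
    """Majority-vote consensus of binary TM tracks.

    Residues with vote fraction >= ``threshold`` (ties count as TM) form
    runs; runs separated by at most ``max_gap`` non-qualifying residues are
    merged, then merged runs shorter than ``min_len`` are dropped. If
    ``expected_count`` is given (e.g. the 12 helices of an MFS fold) a
    mismatch is reported as a warning, never enforced.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_len < 1 or max_gap < 0:
        raise ValueError("min_len must be >= 1 and max_gap >= 0")
    lengths = {t.labels.size for t in tracks}
    if len(lengths) != 1:
        raise TrackFormatError(f"tracks have differing lengths: {sorted(lengths)}")

    votes = np.mean([t.labels for t in tracks], axis=0)
    qualifying = votes >= threshold

    merged: list[tuple[int, int]] = []
    for s, e in _runs(qualifying):
        if merged and s - merged[-1][1] - 1 <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    segments = [(s, e) for s, e in merged if e - s + 1 >= min_len]

    if expected_count is not None and len(segments) != expected_count:
        warnings.warn(
            f"consensus found {len(segments)} TM segments, expected "
            f"{expected_count}",
            stacklevel=2,
        )
    return ConsensusTopology(segments=segments, vote_fraction=votes, threshold=threshold)


def write_segments_tsv(topo: ConsensusTopology, path: str | Path, name: str = "TM") -> None:
    """BED-like 1-based inclusive segment table (name, start, end)."""
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\n")
        for i, (s, e) in enumerate(topo.segments, start=1):
            fh.write(f"{name}{i}\t{s}\t{e}\n")


def write_consensus_json(topo: ConsensusTopology, path: str | Path) -> None:
    payload = {
        "threshold": topo.threshold,
        "segments": [[s, e] for s, e in topo.segments],
        "vote_fraction": [round(float(v), 10) for v in topo.vote_fraction],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
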