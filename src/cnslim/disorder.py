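"""Per-residue disorder tracks, IDR segmentation, and disorder filtering of hits.

CN-docking SLiMs are functional only inside intrinsically disordered regions
(IDRs), so motif hits are filtered against a per-residue disorder score
track (IUPred long-format style: position, residue, score in [0,1]) with a
default calling threshold of 0.4.

The IUPred algorithm itself is not reimplemented here: tracks are consumed
as data.  A clearly labelled toy scorer (sliding-window fraction of
disorder-promoting residues) is provided for tests and synthetic data only
— it is NOT IUPred and must not be mistaken for a real predictor.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Optional, TextIO, Union

import numpy as np

from .motifs import MotifHit, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.4

#: residues over-represented in disordered segments (toy scorer only)
DISORDER_PROMOTING = frozenset("ARGQSPEK")


class DisorderFormatError(ValueError):
    """Malformed disorder TSV; message carries the offending line number."""


@dataclass(frozen=True)
class IdrSegment:
    """A maximal run of residues at or above the calling threshold."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("segment start must be <= end")

    def __len__(self) -> int:
        return self.end - self.start + 1


class DisorderTrack:
    """Disorder scores aligned to a numbered sequence.

    Residue numbers must be strictly increasing and contiguous; scores lie
    in [0, 1].
    """

    def __init__(self, protein_id: str, positions, residues, scores):
        positions = np.asarray(positions, dtype=int)
        scores = np.asarray(scores, dtype=float)
        residues = list(residues)
        if not (len(positions) == len(scores) == len(residues)):
            raise ValueError("positions, residues and scores must align")
        if len(positions) == 0:
            raise ValueError("empty disorder track")
        if not np.all(np.diff(positions) == 1):
            raise ValueError("residue numbers must be contiguous and increasing")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ValueError("scores must lie in [0, 1]")
        self.protein_id = protein_id
        self.positions = positions
        self.residues = residues
        self.scores = scores

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def start(self) -> int:
        return int(self.positions[0])

    @property
    def end(self) -> int:
        return int(self.positions[-1])

    def covers(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def score_at(self, residue_number: int) -> float:
        if not self.start <= residue_number <= self.end:
            raise KeyError(f"residue {residue_number} outside track range")
        return float(self.scores[residue_number - self.start])

    def scores_in(self, start: int, end: int) -> np.ndarray:
        if not self.covers(start, end):
            raise KeyError(f"span {start}-{end} outside track range")
        return self.scores[start - self.start : end - self.start + 1]

    def check_sequence(self, record: ProteinRecord) -> None:
        """Raise if the track's residue letters disagree with the record."""
        for pos, res in zip(self.positions, self.residues):
            if record.start_number <= pos <= record.end_number:
                expected = record.sequence[pos - record.start_number]
                if res != expected and res != "X" and expected != "X":
                    raise ValueError(
                        f"track residue {res} at {pos} disagrees with "
                        f"sequence residue {expected}"
                    )


def read_disorder_track(
    source: Union[str, TextIO], protein_id: Optional[str] = None
) -> DisorderTrack:
    """Parse an IUPred long-format TSV (position, residue, score).

    ``#``-prefixed comment lines and blank lines are skipped.  Non-monotone
    or gapped positions and out-of-range scores raise
    :class:`DisorderFormatError` with the offending line number.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return read_disorder_track(fh, protein_id=protein_id or source)
    positions, residues, scores = [], [], []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise DisorderFormatError(
                f"line {lineno}: expected 3 columns (position, residue, score)"
            )
        try:
            pos = int(fields[0])
            score = float(fields[2])
        except ValueError as exc:
            raise DisorderFormatError(f"line {lineno}: {exc}") from exc
        if positions and pos != positions[-1] + 1:
            raise DisorderFormatError(
                f"line {lineno}: position {pos} not contiguous with {positions[-1]}"
            )
        if not 0.0 <= score <= 1.0:
            raise DisorderFormatError(f"line {lineno}: score {score} outside [0, 1]")
        positions.append(pos)
        residues.append(fields[1].upper())
        scores.append(score)
    if not positions:
        raise DisorderFormatError("no data lines in disorder track")
    return DisorderTrack(protein_id or "unknown", positions, residues, scores)


def write_disorder_track(track: DisorderTrack, dest: Union[str, TextIO]) -> None:
    if isinstance(dest, str):
        with open(dest, "w") as fh:
            write_disorder_track(track, fh)
        return
    dest.write(f"# disorder track for {track.protein_id}\n")
    dest.write("# position\tresidue\tscore\n")
    for pos, res, score in zip(track.positions, track.residues, track.scores):
        dest.write(f"{pos}\t{res}\t{score:.4f}\n")


def segment_idrs(
    track: DisorderTrack,
    threshold: float = DEFAULT_THRESHOLD,
    min_length: int = 1,
) -> list:
    """Maximal runs of consecutive residues with score >= threshold.

    Runs shorter than ``min_length`` are discarded.  Returned segments are
    disjoint and non-adjacent by construction.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    above = track.scores >= threshold
    segments = []
    run_start = None
    for i, flag in enumerate(above):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_length:
                segments.append(
                    IdrSegment(int(track.positions[run_start]), int(track.positions[i - 1]))
                )
            run_start = None
    if run_start is not None and len(above) - run_start >= min_length:
        segments.append(
            IdrSegment(int(track.positions[run_start]), int(track.positions[-1]))
        )
    return segments


def filter_hits_by_disorder(
    hits: Iterable[MotifHit],
    track: DisorderTrack,
    threshold: float = DEFAULT_THRESHOLD,
    rule: str = "all_residues",
) -> list:
    """Keep hits that lie in disordered sequence.

    ``rule='all_residues'``: every residue of the span must score >=
    threshold (strictest reading of "the SLiM is in an IDR").
    ``rule='anchor_only'``: only the anchor residue must.  Hits outside the
    track's numbered range are dropped with a logged warning.
    """
    if rule not in ("all_residues", "anchor_only"):
        raise ValueError(f"unknown rule {rule!r}")
    kept = []
    for hit in hits:
        if not track.covers(hit.start, hit.end):
            logger.warning(
                "hit %s %d-%d outside disorder track range %d-%d; dropped",
                hit.protein_id, hit.start, hit.end, track.start, track.end,
            )
            continue
        if rule == "all_residues":
            ok = bool(np.all(track.scores_in(hit.start, hit.end) >= threshold))
        else:
            ok = track.score_at(hit.anchor) >= threshold
        if ok:
            kept.append(hit)
    return kept


def toy_disorder_scores(sequence: str, window: int = 11) -> np.ndarray:
    """Sliding-window fraction of disorder-promoting residues {A,R,G,Q,S,P,E,K}.

    A deliberately simple stand-alone scorer for tests and synthetic data;
    it is NOT IUPred and approximates no published predictor.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    flags = np.array([c in DISORDER_PROMOTING for c in sequence], dtype=float)
    half = window // 2
    scores = np.empty(len(sequence))
    for i in range(len(sequence)):
        lo = max(0, i - half)
        hi = min(len(sequence), i + half + 1)
        scores[i] = flags[lo:hi].mean()
    return scores


def track_from_record(
    record: ProteinRecord, scores=None, window: int = 11
) -> DisorderTrack:
    """Build a track aligned to ``record``; toy-scored unless scores given."""
    if scores is None:
        scores = toy_disorder_scores(record.sequence, window=window)
    positions = [record.residue_number(i + 1) for i in range(len(record.sequence))]
    return DisorderTrack(record.id, positions, list(record.sequence), scores)
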