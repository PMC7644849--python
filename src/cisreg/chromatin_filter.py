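"""Chromatin-state and binding-evidence filtering of motif hits.

Two exclusion rules are applied: (1) a hit must sit near activating histone
marks (H3K4me3 / H3K36me3 / H3K27ac) and away from repressive H3K27me3;
(2) it must be supported by a TF ChIP-seq cluster scoring at least
``min_evidence_score`` out of 1000.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence, TextIO

from .promoter_scan import MotifHit

ACTIVATING_MARKS = ("H3K4me3", "H3K36me3", "H3K27ac")
REPRESSIVE_MARK = "H3K27me3"
HISTONE_LABELS = frozenset(ACTIVATING_MARKS) | {REPRESSIVE_MARK}

TrackKind = Literal["histone", "tf_cluster"]


@dataclass(frozen=True)
class TrackInterval:
    chrom: str
    start: int
    end: int
    label: str
    score: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")


@dataclass(frozen=True)
class AnnotatedTrack:
    """BED-like interval set: histone marks, or TF clusters with 0-1000 scores."""

    track_kind: TrackKind
    intervals: tuple[TrackInterval, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        if self.track_kind == "histone":
            for iv in self.intervals:
                if iv.label not in HISTONE_LABELS:
                    raise ValueError(f"unknown histone mark label {iv.label!r}")
        else:
            for iv in self.intervals:
                if not 0 <= iv.score <= 1000:
                    raise ValueError(
                        f"cluster score {iv.score} outside [0, 1000] "
                        f"({iv.chrom}:{iv.start}-{iv.end} {iv.label})"
                    )

    def overlapping(self, chrom: str, start: int, end: int) -> list[TrackInterval]:
        return [
            iv for iv in self.intervals
            if iv.chrom == chrom and iv.start < end and iv.end > start
        ]


@dataclass(frozen=True)
class ChromatinConfig:
    """Knobs for both filters; defaults are the documented assumptions."""

    window: int = 1000  # bp flank defining "near"
    activating_rule: Literal["any-of", "all-of"] = "any-of"
    min_evidence_score: int = 500
    missing_cluster_policy: Literal["exclude", "keep"] = "exclude"
    tf_name_matching: Literal["exact", "ignore"] = "exact"

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if not 0 <= self.min_evidence_score <= 1000:
            raise ValueError("min_evidence_score must lie in [0, 1000]")


def active_chromatin_filter(
    hits: Sequence[MotifHit],
    histone_track: AnnotatedTrack,
    cfg: ChromatinConfig = ChromatinConfig(),
) -> list[MotifHit]:
    """Set ``chromatin_active`` per hit.

    A hit passes iff the activating rule is satisfied by marks intersecting
    the hit's interval expanded by ``cfg.window`` on each side, and no
    repressive mark intersects that expanded interval.
    """
    if histone_track.track_kind != "histone":
        raise ValueError("active_chromatin_filter needs a histone track")
    out = []
    for hit in hits:
        lo, hi = hit.g_start - cfg.window, hit.g_end + cfg.window
        labels = {iv.label for iv in histone_track.overlapping(hit.chrom, lo, hi)}
        if REPRESSIVE_MARK in labels:
            ok = False
        elif cfg.activating_rule == "any-of":
            ok = any(m in labels for m in ACTIVATING_MARKS)
        else:
            ok = all(m in labels for m in ACTIVATING_MARKS)
        out.append(replace(hit, chromatin_active="pass" if ok else "fail"))
    return out


def encode_evidence_filter(
    hits: Sequence[MotifHit],
    tf_cluster_track: AnnotatedTrack,
    cfg: ChromatinConfig = ChromatinConfig(),
) -> list[MotifHit]:
    """Set ``evidence_pass`` per hit from ChIP-seq cluster scores.

    A hit passes iff the maximum score among intersecting clusters (for the
    hit's TF when ``tf_name_matching="exact"``) is >= ``min_evidence_score``.
    Hits with no intersecting cluster follow ``missing_cluster_policy``.
    """
    if tf_cluster_track.track_kind != "tf_cluster":
        raise ValueError("encode_evidence_filter needs a tf_cluster track")
    out = []
    for hit in hits:
        clusters = tf_cluster_track.overlapping(hit.chrom, hit.g_start, hit.g_end)
        if cfg.tf_name_matching == "exact":
            clusters = [c for c in clusters if c.label.lower() == hit.tf_name.lower()]
        if clusters:
            ok = max(c.score for c in clusters) >= cfg.min_evidence_score
        else:
            ok = cfg.missing_cluster_policy == "keep"
        out.append(replace(hit, evidence_pass="pass" if ok else "fail"))
    return out


def surviving_hits(hits: Iterable[MotifHit]) -> list[MotifHit]:
    """Hits passing both filters, order preserved."""
    return [h for h in hits if h.chromatin_active == "pass" and h.evidence_pass == "pass"]


def read_bed_track(path: str | Path, track_kind: TrackKind) -> AnnotatedTrack:
    """Read a BED track: columns chrom, start, end, label[, score]."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: need >=4 BED columns")
            score = int(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else 0
            intervals.append(
                TrackInterval(parts[0], int(parts[1]), int(parts[2]), parts[3], score)
            )
    return AnnotatedTrack(track_kind, tuple(intervals))


def write_bed_track(track: AnnotatedTrack, stream: TextIO) -> None:
    for iv in track.intervals:
        stream.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{iv.score}\n")
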