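"""Promoter extraction and base-pair-by-base-pair PWM scanning.

Promoters are the 10 kb immediately 5' of the annotated start codon on the
gene's strand.  Coordinates are 0-based half-open on the reference (+)
strand externally (BED convention); promoter-local offsets are 0-based on
the gene's strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence, TextIO

import numpy as np

from .motif_model import BASE_INDEX, BASES, PositionWeightMatrix

Flag = Literal["untested", "pass", "fail"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_WINDOW = 10_000
DEFAULT_THRESHOLD = 0.89


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnchor:
    """Start-codon anchor: position of the codon's first base on the gene strand."""

    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    start_codon_pos: int


@dataclass(frozen=True)
class PromoterRegion:
    gene_id: str
    chrom: str
    strand: Literal["+", "-"]
    start: int  # genomic, 0-based half-open on reference strand
    end: int
    sequence: str  # 5'->3' on the gene's strand
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if len(self.sequence) != self.length:
            raise ValueError("sequence length does not match genomic interval")


@dataclass(frozen=True)
class MotifHit:
    """One candidate binding site above the relative-score threshold."""

    matrix_id: str
    tf_name: str
    gene_id: str
    local_offset: int  # 0-based, 5'-most base in promoter coordinates
    chrom: str
    g_start: int  # reference-strand half-open interval; -1 until mapped
    g_end: int
    hit_strand: Literal["+", "-"]  # relative to the promoter sequence
    kmer: str
    score: float
    relative_score: float
    efficiency: float
    chromatin_active: Flag = "untested"
    evidence_pass: Flag = "untested"


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice ``genome[chrom][start:end]`` from a dict of strings or a pyfaidx.Fasta."""
    if chrom not in genome:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    return str(genome[chrom][start:end]).upper()


def _chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


def extract_promoter(
    genome, anchor: GeneAnchor, window: int = DEFAULT_WINDOW
) -> PromoterRegion:
    """Return the ``window`` bases immediately 5' of the start codon.

    The window never includes the start codon base itself.  It is truncated
    (and flagged) at chromosome edges; an empty window is an error.
    """
    if anchor.chrom not in genome:
        raise KeyError(f"chromosome {anchor.chrom!r} not in genome")
    clen = _chrom_length(genome, anchor.chrom)
    if not 0 <= anchor.start_codon_pos < clen:
        raise ValueError(
            f"start codon {anchor.start_codon_pos} outside chromosome "
            f"{anchor.chrom!r} of length {clen}"
        )
    if anchor.strand == "+":
        end = anchor.start_codon_pos
        start = max(0, end - window)
    else:
        start = anchor.start_codon_pos + 1
        end = min(clen, start + window)
    if end <= start:
        raise ValueError(f"empty promoter window for gene {anchor.gene_id!r}")
    seq = _fetch(genome, anchor.chrom, start, end)
    if anchor.strand == "-":
        seq = reverse_complement(seq)
    return PromoterRegion(
        gene_id=anchor.gene_id,
        chrom=anchor.chrom,
        strand=anchor.strand,
        start=start,
        end=end,
        sequence=seq,
        truncated=(end - start) < window,
    )


def _window_scores(pwm: PositionWeightMatrix, encoded: np.ndarray) -> np.ndarray:
    """Log-odds score at every offset; NaN where the window has an ambiguous base."""
    L = pwm.length
    n = encoded.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    safe = np.where(encoded < 0, 0, encoded)
    for j in range(L):
        col = encoded[j : j + n]
        valid &= col >= 0
        scores += pwm.logodds[safe[j : j + n], j]
    scores[~valid] = np.nan
    return scores


def scan_promoter(
    pwms: Sequence[PositionWeightMatrix],
    promoter: PromoterRegion,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[MotifHit]:
    """Scan every offset of the promoter on both strands.

    A hit is emitted iff its relative score is strictly above ``threshold``.
    Windows containing an ambiguous base are skipped.  Hits are sorted by
    (gene_id, local_offset, matrix_id, strand) with genomic coordinates
    already mapped.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    fwd = np.fromiter(
        (BASE_INDEX.get(b, -1) for b in promoter.sequence),
        dtype=np.int64,
        count=promoter.length,
    )
    # reverse-strand k-mer at offset i is revcomp(seq[i:i+L]); scoring the
    # complemented, reversed index array at mirrored offsets gives all of them
    rev = (3 - fwd)[::-1]
    rev[rev > 3] = -1  # ambiguous bases stay ambiguous after complement
    hits: list[MotifHit] = []
    for pwm in pwms:
        L = pwm.length
        span = pwm.s_max - pwm.s_min
        eff_denom = 1.0 if span == 0 else None
        for strand, encoded in (("+", fwd), ("-", rev)):
            scores = _window_scores(pwm, encoded)
            if span == 0:
                rel = np.where(np.isnan(scores), np.nan, 1.0)
            else:
                rel = (scores - pwm.s_min) / span
            for i in np.flatnonzero(rel > threshold):
                offset = int(i) if strand == "+" else promoter.length - L - int(i)
                kmer = promoter.sequence[offset : offset + L]
                if strand == "-":
                    kmer = reverse_complement(kmer)
                hits.append(
                    MotifHit(
                        matrix_id=pwm.matrix_id,
                        tf_name=pwm.tf_name,
                        gene_id=promoter.gene_id,
                        local_offset=offset,
                        chrom=promoter.chrom,
                        g_start=-1,
                        g_end=-1,
                        hit_strand=strand,  # type: ignore[arg-type]
                        kmer=kmer,
                        score=float(scores[i]),
                        relative_score=float(rel[i]),
                        efficiency=float(rel[i]) if eff_denom is None else 1.0,
                    )
                )
    hits.sort(key=lambda h: (h.gene_id, h.local_offset, h.matrix_id, h.hit_strand))
    return [map_to_genomic(h, promoter) for h in hits]


def map_to_genomic(hit: MotifHit, promoter: PromoterRegion) -> MotifHit:
    """Fill the reference-strand genomic interval from the local offset."""
    L = len(hit.kmer)
    if not 0 <= hit.local_offset <= promoter.length - L:
        raise ValueError(
            f"offset {hit.local_offset} outside promoter of length {promoter.length}"
        )
    if promoter.strand == "+":
        g_start = promoter.start + hit.local_offset
    else:
        g_start = promoter.end - hit.local_offset - L
    return replace(hit, chrom=promoter.chrom, g_start=g_start, g_end=g_start + L)


def genomic_to_local(g_start: int, g_end: int, promoter: PromoterRegion) -> int:
    """Inverse of :func:`map_to_genomic`: recover the promoter-local offset."""
    if promoter.strand == "+":
        offset = g_start - promoter.start
    else:
        offset = promoter.end - g_end
    if not 0 <= offset <= promoter.length - (g_end - g_start):
        raise ValueError("genomic interval outside promoter")
    return offset


# ---------------------------------------------------------------------------
# anchors and hit tables on disk

HIT_COLUMNS = [
    "gene_id", "matrix_id", "tf_name", "local_offset", "chrom", "g_start",
    "g_end", "hit_strand", "kmer", "score", "relative_score", "efficiency",
    "chromatin_active", "evidence_pass",
]


def read_anchors(path: str | Path) -> list[GeneAnchor]:
    """Read gene anchors from 4-column TSV (gene_id, chrom, strand, pos) or BED6.

    In BED6 the start-codon base is taken as ``start`` for + strand genes and
    ``end - 1`` for - strand genes (the 5'-most base of the feature on its
    own strand).
    """
    anchors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) >= 6 and parts[5] in "+-":  # BED6
                chrom, start, end, name, _score, strand = parts[:6]
                pos = int(start) if strand == "+" else int(end) - 1
                anchors.append(GeneAnchor(name, chrom, strand, pos))  # type: ignore[arg-type]
            elif len(parts) == 4 and parts[2] in "+-":
                gene_id, chrom, strand, pos = parts
                anchors.append(GeneAnchor(gene_id, chrom, strand, int(pos)))  # type: ignore[arg-type]
            else:
                raise ValueError(f"{path}:{lineno}: unrecognised anchor line {line!r}")
    return anchors


def write_anchors(anchors: Iterable[GeneAnchor], stream: TextIO) -> None:
    for a in anchors:
        stream.write(f"{a.gene_id}\t{a.chrom}\t{a.strand}\t{a.start_codon_pos}\n")


def write_hits_tsv(hits: Iterable[MotifHit], stream: TextIO) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(HIT_COLUMNS)
    for h in hits:
        writer.writerow([
            h.gene_id, h.matrix_id, h.tf_name, h.local_offset, h.chrom,
            h.g_start, h.g_end, h.hit_strand, h.kmer,
            f"{h.score:.6f}", f"{h.relative_score:.9f}", f"{h.efficiency:.9f}",
            h.chromatin_active, h.evidence_pass,
        ])


def read_hits_tsv(path: str | Path) -> list[MotifHit]:
    hits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            hits.append(MotifHit(
                matrix_id=row["matrix_id"], tf_name=row["tf_name"],
                gene_id=row["gene_id"], local_offset=int(row["local_offset"]),
                chrom=row["chrom"], g_start=int(row["g_start"]),
                g_end=int(row["g_end"]), hit_strand=row["hit_strand"],  # type: ignore[arg-type]
                kmer=row["kmer"], score=float(row["score"]),
                relative_score=float(row["relative_score"]),
                efficiency=float(row["efficiency"]),
                chromatin_active=row["chromatin_active"],  # type: ignore[arg-type]
                evidence_pass=row["evidence_pass"],  # type: ignore[arg-type]
            ))
    return hits


def write_hits_bed(hits: Iterable[MotifHit], stream: TextIO) -> None:
    """BED6 with score = round(1000 * relative_score)."""
    for h in hits:
        stream.write(
            f"{h.chrom}\t{h.g_start}\t{h.g_end}\t{h.tf_name}\t"
            f"{round(1000 * h.relative_score)}\t{h.hit_strand}\n"
        )
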