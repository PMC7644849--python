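"""Position frequency/weight matrix models and JASPAR-format I/O.

The scoring statistics exposed here are the ones promoter scanning is
defined on: the log2-odds site score, its min--max normalised *relative
score* (a "percent match" in [0, 1]), the per-column consensus sequence,
and the consensus-relative *binding efficiency*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

AmbigPolicy = Literal["reject", "background"]

UNIFORM_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


class JasparParseError(ValueError):
    """Raised on malformed JASPAR PFM input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Base counts per motif column, rows ordered A, C, G, T."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (4, L), non-negative

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
            raise ValueError(f"counts must be 4xL with L >= 1, got {counts.shape}")
        if np.any(counts < 0):
            raise ValueError("negative count in PFM")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("PFM column with no positive count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds motif model with its achievable score range and consensus."""

    matrix_id: str
    tf_name: str
    logodds: np.ndarray  # shape (4, L)
    background: np.ndarray  # shape (4,), sums to 1
    pseudocount: float
    s_min: float = field(init=False)
    s_max: float = field(init=False)
    consensus: str = field(init=False)

    def __post_init__(self) -> None:
        logodds = np.asarray(self.logodds, dtype=float)
        background = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "logodds", logodds)
        object.__setattr__(self, "background", background)
        if logodds.ndim != 2 or logodds.shape[0] != 4:
            raise ValueError("logodds must be a 4xL table")
        object.__setattr__(self, "s_min", float(logodds.min(axis=0).sum()))
        object.__setattr__(self, "s_max", float(logodds.max(axis=0).sum()))
        # argmax on axis 0 returns the first maximal row: alphabetical tie-break
        cons = "".join(BASES[i] for i in logodds.argmax(axis=0))
        object.__setattr__(self, "consensus", cons)

    @property
    def length(self) -> int:
        return self.logodds.shape[1]

    @classmethod
    def from_logodds(
        cls,
        matrix_id: str,
        tf_name: str,
        logodds: np.ndarray,
        background: Sequence[float] = UNIFORM_BACKGROUND,
        pseudocount: float = 1.0,
    ) -> "PositionWeightMatrix":
        return cls(matrix_id, tf_name, np.asarray(logodds, float),
                   np.asarray(background, float), pseudocount)


_HEADER_RE = re.compile(r"^>\s*(\S+)(?:\s+(.*\S))?\s*$")
_ROW_RE = re.compile(r"^\s*(?:([ACGTacgt])\s*)?\[?\s*([0-9eE+.\-\s]*?)\s*\]?\s*$")


def read_jaspar(stream: TextIO | Iterable[str]) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR PFM records (bracketed or plain 4-row dialect).

    Each record is a ``>ID NAME`` header followed by four count rows.  Rows
    may carry a leading base letter (``A [ 1 2 3 ]`` / ``A 1 2 3``) or be
    bare number rows in A, C, G, T order.  Row order is normalised to
    A, C, G, T in the returned matrices.
    """
    pfms: list[PositionFrequencyMatrix] = []
    header: tuple[str, str] | None = None
    header_line = 0
    rows: list[tuple[str | None, list[float], int]] = []

    def flush(at_line: int) -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise JasparParseError(
                f"record '{header[0]}' has {len(rows)} count rows, expected 4",
                at_line,
            )
        letters = [r[0] for r in rows]
        counts = np.zeros((4, len(rows[0][1])), dtype=float)
        if all(l is not None for l in letters):
            if sorted(letters) != list(BASES):  # type: ignore[arg-type]
                raise JasparParseError(
                    f"record '{header[0]}' rows labelled {letters}, expected one "
                    "each of A,C,G,T",
                    at_line,
                )
        elif any(l is not None for l in letters):
            raise JasparParseError(
                f"record '{header[0]}' mixes labelled and bare rows", at_line
            )
        for i, (letter, values, lineno) in enumerate(rows):
            if len(values) != counts.shape[1]:
                raise JasparParseError(
                    f"ragged row: {len(values)} values, expected {counts.shape[1]}",
                    lineno,
                )
            if any(v < 0 for v in values):
                raise JasparParseError("negative count", lineno)
            counts[BASE_INDEX[letter.upper()] if letter else i] = values
        pfms.append(PositionFrequencyMatrix(header[0], header[1], counts))
        header, rows = None, []

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush(lineno)
            m = _HEADER_RE.match(line)
            if m is None:
                raise JasparParseError(f"malformed header {line!r}", lineno)
            header = (m.group(1), m.group(2) or "")
            header_line = lineno
            continue
        if header is None:
            raise JasparParseError("count row before any header", lineno)
        m = _ROW_RE.match(line)
        if m is None or not m.group(2).strip():
            raise JasparParseError(f"unparseable count row {line!r}", lineno)
        try:
            values = [float(tok) for tok in m.group(2).split()]
        except ValueError as exc:
            raise JasparParseError(str(exc), lineno) from None
        if len(rows) == 4:
            raise JasparParseError(
                f"record '{header[0]}' has more than 4 count rows", lineno
            )
        rows.append((m.group(1), values, lineno))
    flush(lineno + 1 if header is not None else lineno)
    return pfms


def _fmt_count(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(float(value))


def write_jaspar(pfms: Iterable[PositionFrequencyMatrix], stream: TextIO) -> None:
    """Write PFMs in the plain labelled 4-row dialect; counts round-trip exactly."""
    for pfm in pfms:
        name = f" {pfm.tf_name}" if pfm.tf_name else ""
        stream.write(f">{pfm.matrix_id}{name}\n")
        for i, base in enumerate(BASES):
            stream.write(f"{base} " + " ".join(_fmt_count(c) for c in pfm.counts[i]) + "\n")


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    background: Sequence[float] = UNIFORM_BACKGROUND,
    pseudocount: float = 1.0,
) -> PositionWeightMatrix:
    """Convert counts to a log2-odds PWM against ``background``.

    ``logodds[b, i] = log2((counts[b, i] + pc*bg[b]) / (N_i + pc) / bg[b])``
    with ``N_i`` the column count sum and ``pc`` the pseudocount.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    n = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (n + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PositionWeightMatrix(pfm.matrix_id, pfm.tf_name, logodds, bg, pseudocount)


def _encode(kmer: str) -> np.ndarray:
    return np.fromiter((BASE_INDEX.get(b, -1) for b in kmer.upper()), dtype=np.int64,
                       count=len(kmer))


def score_site(
    pwm: PositionWeightMatrix, kmer: str, ambig: AmbigPolicy = "reject"
) -> float:
    """Log2-odds score of ``kmer``: the sum of per-position logodds entries.

    Ambiguous bases (anything outside A/C/G/T) raise by default; with
    ``ambig="background"`` they contribute the background-expected column
    value instead.
    """
    if len(kmer) != pwm.length:
        raise ValueError(f"k-mer length {len(kmer)} != motif length {pwm.length}")
    idx = _encode(kmer)
    bad = idx < 0
    if not bad.any():
        return float(pwm.logodds[idx, np.arange(pwm.length)].sum())
    if ambig == "reject":
        raise ValueError(f"ambiguous base in k-mer {kmer!r}")
    cols = np.arange(pwm.length)
    expected = (pwm.background[:, None] * pwm.logodds).sum(axis=0)
    per_pos = np.where(bad, expected, pwm.logodds[np.where(bad, 0, idx), cols])
    return float(per_pos.sum())


def relative_score(
    pwm: PositionWeightMatrix, kmer: str, ambig: AmbigPolicy = "reject"
) -> float:
    """Min--max normalised score in [0, 1]; 1.0 by convention for flat motifs."""
    span = pwm.s_max - pwm.s_min
    if span == 0:
        return 1.0
    return (score_site(pwm, kmer, ambig) - pwm.s_min) / span


def binding_efficiency(
    pwm: PositionWeightMatrix, kmer: str, ambig: AmbigPolicy = "reject"
) -> float:
    """Relative score of ``kmer`` rescaled to the consensus k-mer's relative score."""
    denom = relative_score(pwm, pwm.consensus)
    if denom == 0:
        raise ValueError("consensus has zero relative score; efficiency undefined")
    return relative_score(pwm, kmer, ambig) / denom
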