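"""Quantification arithmetic: comparative-Ct expression, expression-morphology
correlation, dual-luciferase fold change, and peroxisome morphology calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_REFERENCE_GENE = "18S"
TUBULAR_MIN_UM = 2.0  # strictly greater => tubular
PARTICLE_MIN_UM = 0.3  # smaller particles are not counted as peroxisomes
DEFAULT_CORRELATION_THRESHOLD = 0.7

CT_COLUMNS = ["gene", "time_h", "replicate", "ct"]
LUMINESCENCE_COLUMNS = [
    "construct", "treatment", "replicate", "fluc1", "fluc2", "fluc3", "rluc",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """Relative mRNA amounts (2^-ddCt) across ordered time points; calibrator = 1."""

    gene: str
    times: tuple[float, ...]
    relative_amounts: tuple[float, ...]
    calibrator_time: float

    def __post_init__(self) -> None:
        if len(self.times) != len(self.relative_amounts):
            raise ValueError("times and amounts differ in length")
        if any(a <= 0 for a in self.relative_amounts):
            raise ValueError("relative amounts must be positive")

    def amount_at(self, time_h: float) -> float:
        return self.relative_amounts[self.times.index(time_h)]


@dataclass(frozen=True)
class MorphologyRecord:
    cell_id: str
    condition: str
    particle_lengths: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.particle_lengths):
            raise ValueError("particle lengths must be positive")


@dataclass(frozen=True)
class LuminescenceRecord:
    construct: str
    treatment: str
    replicate: int
    fluc_reads: tuple[float, float, float]  # each reaction measured three times
    rluc: float

    def __post_init__(self) -> None:
        if len(self.fluc_reads) != 3:
            raise ValueError("each reaction carries exactly 3 firefly reads")
        if self.rluc <= 0:
            raise ValueError("rluc must be positive")


def _validate_ct(ct_table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct_table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns {missing}")
    bad = ct_table[(ct_table.ct <= 0) | (ct_table.ct > 45)]
    if len(bad):
        raise ValueError(f"Ct values outside (0, 45]: {bad.ct.tolist()}")
    return ct_table


def relative_expression(
    ct_table: pd.DataFrame,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    calibrator_time: float | None = None,
) -> dict[str, ExpressionProfile]:
    """Comparative threshold cycle (ddCt) quantification.

    Replicate Ct values are averaged per (gene, time); dCt(t) is the gene
    mean minus the reference-gene mean at the same time point; ddCt(t)
    subtracts dCt at the calibrator time (earliest by default); the relative
    amount is ``2**-ddCt``, exactly 1 at the calibrator.
    """
    ct_table = _validate_ct(ct_table)
    means = ct_table.groupby(["gene", "time_h"], sort=True)["ct"].mean()
    if reference_gene not in means.index.get_level_values("gene"):
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    ref = means[reference_gene]
    profiles: dict[str, ExpressionProfile] = {}
    for gene in means.index.get_level_values("gene").unique():
        if gene == reference_gene:
            continue
        gmeans = means[gene]
        times = sorted(gmeans.index)
        missing_ref = [t for t in times if t not in ref.index]
        if missing_ref:
            raise ValueError(
                f"reference gene {reference_gene!r} not measured at "
                f"time points {missing_ref}"
            )
        cal = min(times) if calibrator_time is None else calibrator_time
        if cal not in times:
            raise ValueError(f"calibrator time {cal} absent for gene {gene!r}")
        dct = {t: gmeans[t] - ref[t] for t in times}
        ddct = {t: dct[t] - dct[cal] for t in times}
        amounts = tuple(2.0 ** -ddct[t] for t in times)
        profiles[gene] = ExpressionProfile(gene, tuple(times), amounts, cal)
    return profiles


def correlate_profiles(
    expr: ExpressionProfile,
    morph: Mapping[float, float],
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> tuple[float, str]:
    """Pearson r between expression and a per-time % tubular morphology course.

    Returns ``(r, classification)``; r is NaN with classification
    ``"undefined"`` when either profile is constant.  Needs >= 3 matched
    time points.
    """
    times = [t for t in expr.times if t in morph]
    if len(times) < 3:
        raise ValueError(f"need >=3 matched time points, got {len(times)}")
    x = np.array([expr.amount_at(t) for t in times], dtype=float)
    y = np.array([morph[t] for t in times], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, "undefined"
    r = float(np.corrcoef(x, y)[0, 1])
    return r, ("proliferation-correlated" if r >= threshold else "uncorrelated")


def classify_cell(record: MorphologyRecord) -> tuple[Literal["tubular", "spherical"], int]:
    """Categorise one cell and count its peroxisomes.

    Particles shorter than 0.3 um are discarded; the cell is tubular iff any
    remaining particle exceeds 2 um (strictly), spherical otherwise.
    """
    kept = [l for l in record.particle_lengths if l >= PARTICLE_MIN_UM]
    label: Literal["tubular", "spherical"] = (
        "tubular" if any(l > TUBULAR_MIN_UM for l in kept) else "spherical"
    )
    return label, len(kept)


def percent_tubular(records: Iterable[MorphologyRecord]) -> float:
    """100 * (#tubular cells) / (#cells)."""
    records = list(records)
    if not records:
        raise ValueError("no cells to classify")
    n_tub = sum(1 for r in records if classify_cell(r)[0] == "tubular")
    return 100.0 * n_tub / len(records)


def luciferase_fold(
    records: Iterable[LuminescenceRecord],
    treated: str = "TGFb",
    untreated: str = "untreated",
) -> dict[str, float]:
    """Per-construct fold response of firefly/renilla ratios to treatment.

    Each reaction's ratio is mean(firefly reads) / renilla; ratios are
    averaged over replicates per (construct, treatment); the fold is the
    treated mean divided by the untreated mean.
    """
    ratios: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        ratios.setdefault((rec.construct, rec.treatment), []).append(
            sum(rec.fluc_reads) / 3.0 / rec.rluc
        )
    constructs = sorted({c for c, t in ratios if t == treated})
    folds: dict[str, float] = {}
    for construct in constructs:
        if (construct, untreated) not in ratios:
            raise ValueError(f"construct {construct!r} lacks an untreated arm")
        t_mean = float(np.mean(ratios[(construct, treated)]))
        u_mean = float(np.mean(ratios[(construct, untreated)]))
        folds[construct] = t_mean / u_mean
    return folds


# ---------------------------------------------------------------------------
# tabular I/O

def read_ct_table(path) -> pd.DataFrame:
    return _validate_ct(pd.read_csv(path, sep="\t"))


def read_luminescence_table(path) -> list[LuminescenceRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in LUMINESCENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"luminescence table missing columns {missing}")
    return [
        LuminescenceRecord(
            construct=row.construct, treatment=row.treatment,
            replicate=int(row.replicate),
            fluc_reads=(float(row.fluc1), float(row.fluc2), float(row.fluc3)),
            rluc=float(row.rluc),
        )
        for row in df.itertuples()
    ]


def read_morphology_table(path) -> list[MorphologyRecord]:
    """TSV columns: cell_id, condition, particle_lengths (comma-separated um)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str})
    records = []
    for row in df.itertuples():
        lengths = tuple(
            float(tok) for tok in str(row.particle_lengths).split(",") if tok.strip()
        )
        records.append(MorphologyRecord(row.cell_id, row.condition, lengths))
    return records


def profiles_to_frame(profiles: Mapping[str, ExpressionProfile]) -> pd.DataFrame:
    rows = [
        {"gene": p.gene, "time_h": t, "relative_amount": a,
         "calibrator_time": p.calibrator_time}
        for p in profiles.values() for t, a in zip(p.times, p.relative_amounts)
    ]
    return pd.DataFrame(rows, columns=["gene", "time_h", "relative_amount",
                                       "calibrator_time"])
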