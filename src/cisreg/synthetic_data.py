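"""Ground-truth fixture generation for the whole pipeline.

Everything the scanner and filters consume can be generated here with known
truth: promoters with motif instances planted at controlled relative
scores, matched histone/TF-cluster tracks encoding active or silent status,
the three-promoter shared-site fixture, the wild-type/mutant reporter
construct pair, and programmed Ct / luminescence tables.

All randomness flows through a single ``numpy.random.Generator``; fixtures
with the same seed are byte-identical on disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif_model import (
    BASES,
    PositionFrequencyMatrix,
    PositionWeightMatrix,
    pfm_to_pwm,
    relative_score,
    write_jaspar,
)
from .promoter_scan import (
    GeneAnchor,
    MotifHit,
    PromoterRegion,
    extract_promoter,
    reverse_complement,
    scan_promoter,
    write_anchors,
)
from .chromatin_filter import ACTIVATING_MARKS, AnnotatedTrack, TrackInterval, write_bed_track

WT_CONSTRUCT_LENGTH = 1302
SMAD_CORE_LENGTH = 6

_PANEL = [
    # (matrix_id, tf_name, consensus) -- SMAD core is 6 bp so the reporter
    # construct loses exactly 6 bp when the site is deleted
    ("MA0513.1", "SMAD2/3", "CAGACA"),
    ("MA0833.1", "ATF4", "TGATGCAA"),
    ("MA0442.2", "SOX10", "AACAATGG"),
    ("MA0066.1", "PPARG", "AGGTCAAAGG"),
    ("MA1148.1", "PPARA", "TGACCTATGC"),
    ("MA0506.1", "NRF1", "CGCCTGCGCA"),
    ("MA0114.2", "HNF4A", "CAAAGTCCAT"),
    ("MA0102.3", "CEBPA", "TTGCGCAATA"),
]

# per-column count pattern: dominant base 85, one secondary 9, two minors 3;
# the secondary step gives k-mers a usable ladder of relative scores
_DOMINANT, _SECONDARY, _MINOR = 85, 9, 3


def demo_pfms() -> list[PositionFrequencyMatrix]:
    """Deterministic 8-motif panel with strong, non-palindromic consensuses."""
    pfms = []
    for matrix_id, tf_name, consensus in _PANEL:
        counts = np.full((4, len(consensus)), _MINOR, dtype=float)
        for i, base in enumerate(consensus):
            bi = BASES.index(base)
            counts[bi, i] = _DOMINANT
            counts[(bi + 1) % 4, i] = _SECONDARY
        pfms.append(PositionFrequencyMatrix(matrix_id, tf_name, counts))
    return pfms


def demo_pwms() -> list[PositionWeightMatrix]:
    return [pfm_to_pwm(p) for p in demo_pfms()]


@dataclass(frozen=True)
class PlantSpec:
    """Request to plant ``n_sites`` instances of one motif in one promoter."""

    gene_id: str
    tf_name: str
    matrix_id: str
    n_sites: int = 1
    relative_score_band: tuple[float, float] = (0.92, 1.0)
    chromatin_status: Literal["active", "silent"] = "active"
    evidence_score: int = 900

    def __post_init__(self) -> None:
        lo, hi = self.relative_score_band
        if not 0 <= lo <= hi <= 1:
            raise ValueError(f"bad relative-score band [{lo}, {hi}]")
        if not 0 <= self.evidence_score <= 1000:
            raise ValueError("evidence_score outside [0, 1000]")


@dataclass(frozen=True)
class TruthRecord:
    gene_id: str
    matrix_id: str
    tf_name: str
    local_offset: int
    strand: str
    kmer: str
    relative_score: float
    chromatin_status: str
    evidence_score: int

    @property
    def expected_surviving(self) -> bool:
        return self.chromatin_status == "active" and self.evidence_score >= 500


@dataclass
class PromoterFixture:
    """In-memory fixture bundle plus writers for its on-disk formats."""

    genome: dict[str, str]
    anchors: list[GeneAnchor]
    histone_track: AnnotatedTrack
    cluster_track: AnnotatedTrack
    truth: list[TruthRecord]
    pwms: list[PositionWeightMatrix]
    pfms: list[PositionFrequencyMatrix] = field(default_factory=list)

    def promoter(self, gene_id: str, window: int = 10_000) -> PromoterRegion:
        anchor = next(a for a in self.anchors if a.gene_id == gene_id)
        return extract_promoter(self.genome, anchor, window=window)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "anchors": outdir / "anchors.tsv",
            "histone": outdir / "histone.bed",
            "clusters": outdir / "clusters.bed",
            "motifs": outdir / "motifs.jaspar",
            "truth": outdir / "truth.tsv",
        }
        with open(paths["genome"], "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        with open(paths["anchors"], "w") as fh:
            write_anchors(self.anchors, fh)
        with open(paths["histone"], "w") as fh:
            write_bed_track(self.histone_track, fh)
        with open(paths["clusters"], "w") as fh:
            write_bed_track(self.cluster_track, fh)
        with open(paths["motifs"], "w") as fh:
            write_jaspar(self.pfms or [], fh)
        with open(paths["truth"], "w") as fh:
            fh.write("gene_id\tmatrix_id\ttf_name\tlocal_offset\tstrand\tkmer\t"
                     "relative_score\tchromatin_status\tevidence_score\n")
            for t in self.truth:
                fh.write(f"{t.gene_id}\t{t.matrix_id}\t{t.tf_name}\t"
                         f"{t.local_offset}\t{t.strand}\t{t.kmer}\t"
                         f"{t.relative_score:.9f}\t{t.chromatin_status}\t"
                         f"{t.evidence_score}\n")
        return paths


def _enumerate_scores(pwm: PositionWeightMatrix) -> np.ndarray:
    """Relative score of every k-mer, indexed by base-4 code (A=0..T=3)."""
    scores = pwm.logodds[:, 0]
    for i in range(1, pwm.length):
        scores = (scores[:, None] + pwm.logodds[:, i][None, :]).ravel()
    span = pwm.s_max - pwm.s_min
    return np.ones_like(scores) if span == 0 else (scores - pwm.s_min) / span


def _decode(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        code, digit = divmod(code, 4)
        out.append(BASES[digit])
    return "".join(reversed(out))


def sample_site(
    pwm: PositionWeightMatrix,
    band: tuple[float, float],
    rng: np.random.Generator,
    max_iter: int = 2000,
) -> str:
    """Draw a k-mer whose relative score lies in ``band``; seeded, deterministic.

    A random walk starts from the consensus and mutates single bases,
    accepting proposals that move the score toward the band midpoint.  If the
    walk fails and the motif is short enough to enumerate (L <= 10), the band
    is resolved exhaustively; an empty band is reported as infeasible.
    """
    lo, hi = band
    if not 0 <= lo <= hi <= 1:
        raise ValueError(f"bad band [{lo}, {hi}]")
    if lo <= relative_score(pwm, pwm.consensus) <= hi:
        return pwm.consensus
    mid = (lo + hi) / 2
    current = list(pwm.consensus)
    cur_rel = relative_score(pwm, pwm.consensus)
    for step in range(max_iter):
        if step and step % 100 == 0:  # periodic restart avoids dead ends
            current = list(pwm.consensus)
            cur_rel = relative_score(pwm, pwm.consensus)
        pos = int(rng.integers(pwm.length))
        base = BASES[int(rng.integers(4))]
        if base == current[pos]:
            continue
        proposal = current.copy()
        proposal[pos] = base
        rel = relative_score(pwm, "".join(proposal))
        if lo <= rel <= hi:
            return "".join(proposal)
        if abs(rel - mid) < abs(cur_rel - mid):
            current, cur_rel = proposal, rel
    if pwm.length <= 10:
        rel_all = _enumerate_scores(pwm)
        in_band = np.flatnonzero((rel_all >= lo) & (rel_all <= hi))
        if in_band.size == 0:
            raise ValueError(
                f"band [{lo}, {hi}] infeasible for motif {pwm.matrix_id} "
                f"(no k-mer attains it)"
            )
        return _decode(int(rng.choice(in_band)), pwm.length)
    raise ValueError(
        f"could not sample a k-mer in band [{lo}, {hi}] for motif "
        f"{pwm.matrix_id} (L={pwm.length} too long to enumerate)"
    )


def _random_sequence(
    rng: np.random.Generator, length: int, composition: Sequence[float]
) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(composition, float))


def build_promoter_fixture(
    specs: Sequence[PlantSpec],
    length: int = 10_000,
    composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    pwms: Sequence[PositionWeightMatrix] | None = None,
    threshold: float = 0.89,
    max_redraws: int = 200,
) -> PromoterFixture:
    """Build a genome + tracks fixture realising ``specs`` exactly.

    Each gene gets its own chromosome (promoter occupying ``[0, length)``
    followed by an ATG start codon, + strand anchor).  Background windows
    that happen to score above ``threshold`` for any panel motif are
    redrawn; planted k-mers whose neighbourhood creates extra hits are
    resampled, so the scan result equals the truth table exactly.
    """
    rng = np.random.default_rng(seed)
    panel_pfms = demo_pfms() if pwms is None else []
    pwms = list(pwms) if pwms is not None else [pfm_to_pwm(p) for p in panel_pfms]
    by_id = {p.matrix_id: p for p in pwms}
    max_l = max(p.length for p in pwms)

    genes: dict[str, list[PlantSpec]] = {}
    for spec in specs:
        if spec.matrix_id not in by_id:
            raise KeyError(f"matrix {spec.matrix_id!r} not in the motif panel")
        genes.setdefault(spec.gene_id, []).append(spec)

    genome: dict[str, str] = {}
    anchors: list[GeneAnchor] = []
    histones: list[TrackInterval] = []
    clusters: list[TrackInterval] = []
    truth: list[TruthRecord] = []

    for gene_id in sorted(genes):
        gene_specs = genes[gene_id]
        n_sites = sum(s.n_sites for s in gene_specs)
        slot_pitch = max_l + 20
        n_slots = (length - slot_pitch) // slot_pitch
        if n_sites > n_slots:
            raise ValueError(
                f"{n_sites} sites do not fit a {length} bp promoter for {gene_id!r}"
            )
        slots = rng.choice(n_slots, size=n_sites, replace=False)
        offsets = sorted(int(s) * slot_pitch + 10 for s in slots)

        seq = _random_sequence(rng, length, composition)
        chrom = f"chr_{gene_id}"
        plants: list[dict] = []
        site_iter = iter(offsets)
        for spec in gene_specs:
            for _ in range(spec.n_sites):
                offset = next(site_iter)
                pwm = by_id[spec.matrix_id]
                plants.append({"spec": spec, "pwm": pwm, "offset": offset})

        def replant(plant: dict) -> None:
            pwm = plant["pwm"]
            kmer = sample_site(pwm, plant["spec"].relative_score_band, rng)
            strand = "+" if rng.integers(2) == 0 else "-"
            placed = kmer if strand == "+" else reverse_complement(kmer)
            o = plant["offset"]
            seq[o : o + pwm.length] = [BASES.index(b) for b in placed]
            plant.update(kmer=kmer, strand=strand,
                         rel=relative_score(pwm, kmer))

        for plant in plants:
            replant(plant)

        truth_keys = lambda: {
            (p["pwm"].matrix_id, p["offset"], p["strand"]) for p in plants
        }
        promoter = None
        for _ in range(max_redraws):
            seq_str = "".join(BASES[i] for i in seq)
            promoter = PromoterRegion(gene_id, chrom, "+", 0, length, seq_str)
            spurious = [
                h for h in scan_promoter(pwms, promoter, threshold)
                if (h.matrix_id, h.local_offset, h.hit_strand) not in truth_keys()
            ]
            if not spurious:
                break
            for h in spurious:
                overlapped = [
                    p for p in plants
                    if p["offset"] < h.local_offset + len(h.kmer)
                    and h.local_offset < p["offset"] + p["pwm"].length
                ]
                if overlapped:
                    for p in overlapped:
                        replant(p)
                else:
                    lo, hi = h.local_offset, h.local_offset + len(h.kmer)
                    seq[lo:hi] = _random_sequence(rng, hi - lo, composition)
        else:
            raise RuntimeError(
                f"spurious hits persist in {gene_id!r} after {max_redraws} redraws"
            )

        genome[chrom] = "".join(BASES[i] for i in seq) + "ATG" + "".join(
            BASES[i] for i in _random_sequence(rng, 7, composition)
        )
        anchors.append(GeneAnchor(gene_id, chrom, "+", length))

        for plant in sorted(plants, key=lambda p: p["offset"]):
            spec, pwm = plant["spec"], plant["pwm"]
            o, L = plant["offset"], pwm.length
            mark = ACTIVATING_MARKS[int(rng.integers(len(ACTIVATING_MARKS)))]
            histones.append(TrackInterval(chrom, max(0, o - 150), o + L + 150, mark))
            if spec.chromatin_status == "silent":
                histones.append(
                    TrackInterval(chrom, max(0, o - 100), o + L + 100, "H3K27me3")
                )
            clusters.append(
                TrackInterval(chrom, max(0, o - 50), o + L + 50, spec.tf_name,
                              spec.evidence_score)
            )
            truth.append(TruthRecord(
                gene_id=gene_id, matrix_id=pwm.matrix_id, tf_name=spec.tf_name,
                local_offset=o, strand=plant["strand"], kmer=plant["kmer"],
                relative_score=plant["rel"],
                chromatin_status=spec.chromatin_status,
                evidence_score=spec.evidence_score,
            ))

    return PromoterFixture(
        genome=genome,
        anchors=anchors,
        histone_track=AnnotatedTrack("histone", tuple(histones)),
        cluster_track=AnnotatedTrack("tf_cluster", tuple(clusters)),
        truth=truth,
        pwms=list(pwms),
        pfms=panel_pfms,
    )


def three_promoter_fixture(seed: int = 42) -> PromoterFixture:
    """Three-promoter fixture whose surviving TF sets partition as 4 / 0 / 1.

    The beta and gamma promoters share SMAD2/3, ATF4, SOX10 and PPARG; alpha
    and gamma share only PPARA; alpha and beta share nothing; each gene also
    carries one private TF.
    """
    def plant(gene: str, tf: str, mid: str, n: int = 1) -> PlantSpec:
        return PlantSpec(gene_id=gene, tf_name=tf, matrix_id=mid, n_sites=n)

    specs = [
        plant("PEX11A", "PPARA", "MA1148.1"),
        plant("PEX11A", "CEBPA", "MA0102.3"),
        plant("PEX11B", "SMAD2/3", "MA0513.1", n=2),
        plant("PEX11B", "ATF4", "MA0833.1"),
        plant("PEX11B", "SOX10", "MA0442.2"),
        plant("PEX11B", "PPARG", "MA0066.1"),
        plant("PEX11B", "NRF1", "MA0506.1"),
        plant("PEX11G", "SMAD2/3", "MA0513.1"),
        plant("PEX11G", "ATF4", "MA0833.1"),
        plant("PEX11G", "SOX10", "MA0442.2"),
        plant("PEX11G", "PPARG", "MA0066.1"),
        plant("PEX11G", "PPARA", "MA1148.1"),
        plant("PEX11G", "HNF4A", "MA0114.2"),
    ]
    return build_promoter_fixture(specs, seed=seed)


@dataclass(frozen=True)
class ConstructFixture:
    """Wild-type reporter promoter with its single SMAD2/3 core site."""

    wt_sequence: str
    site_start: int  # 0-based, half-open span of the 6 bp core
    site_end: int
    pwm: PositionWeightMatrix


def delete_motif(sequence: str, site_start: int, site_end: int) -> str:
    """Remove the motif span, yielding the mutant construct sequence."""
    if not 0 <= site_start < site_end <= len(sequence):
        raise ValueError("site span outside sequence")
    return sequence[:site_start] + sequence[site_end:]


def construct_fixture(
    seed: int = 0, length: int = WT_CONSTRUCT_LENGTH, threshold: float = 0.89
) -> ConstructFixture:
    """1302 bp wild-type promoter with exactly one above-threshold SMAD site.

    The sequence is rebuilt until both the wild type has exactly one
    SMAD2/3 hit (the planted 6 bp core) and the deletion mutant, 6 bp
    shorter, has none (a deletion junction could otherwise recreate a site).
    """
    rng = np.random.default_rng(seed)
    pwm = next(p for p in demo_pwms() if p.matrix_id == "MA0513.1")
    L = pwm.length

    def n_hits(seq: str) -> int:
        region = PromoterRegion("construct", "construct", "+", 0, len(seq), seq)
        return len(scan_promoter([pwm], region, threshold))

    for _ in range(200):
        site_start = int(rng.integers(50, length - 50 - L))
        seq = _random_sequence(rng, length, (0.25,) * 4)
        seq[site_start : site_start + L] = [BASES.index(b) for b in pwm.consensus]
        wt = "".join(BASES[i] for i in seq)
        mutant = delete_motif(wt, site_start, site_start + L)
        if n_hits(wt) == 1 and n_hits(mutant) == 0:
            return ConstructFixture(wt, site_start, site_start + L, pwm)
    raise RuntimeError("could not build a clean construct fixture")


def make_ct_table(
    fold_schedule: Mapping[str, Mapping[float, float]],
    control_gene: str = "18S",
    base_ct: float = 25.0,
    control_ct: float = 12.0,
    noise_sd: float = 0.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Programmed Ct table: ``Ct(t) = base_ct - log2(fold(t)) + noise``.

    The control gene is flat (plus noise) at every time point appearing in
    any schedule.  Recovering the programmed folds with the comparative-Ct
    method requires fold = 1 at the calibrator (earliest) time point.
    """
    rng = np.random.default_rng(seed)
    times = sorted({t for sched in fold_schedule.values() for t in sched})
    rows = []
    for gene in sorted(fold_schedule):
        for t in sorted(fold_schedule[gene]):
            fold = fold_schedule[gene][t]
            if fold <= 0:
                raise ValueError("fold inductions must be positive")
            for rep in range(1, n_replicates + 1):
                ct = base_ct - np.log2(fold) + noise_sd * rng.standard_normal()
                rows.append({"gene": gene, "time_h": t, "replicate": rep,
                             "ct": float(ct)})
    for t in times:
        for rep in range(1, n_replicates + 1):
            ct = control_ct + noise_sd * rng.standard_normal()
            rows.append({"gene": control_gene, "time_h": t, "replicate": rep,
                         "ct": float(ct)})
    return pd.DataFrame(rows, columns=["gene", "time_h", "replicate", "ct"])


def make_luciferase_plate(
    construct_folds: Mapping[str, float],
    base_ratio: float = 3.0,
    noise: float = 0.0,
    n_replicates: int = 3,
    rluc: float = 1000.0,
    seed: int = 0,
    treated: str = "TGFb",
    include_promoterless: bool = True,
) -> pd.DataFrame:
    """Programmed dual-luciferase plate with untreated and treated arms.

    ``noise`` is the fractional standard deviation applied per firefly read.
    The promoterless negative control emits ~1% of ``base_ratio``.
    """
    rng = np.random.default_rng(seed)
    folds = dict(construct_folds)
    ratios = {c: base_ratio for c in folds}
    if include_promoterless and "promoterless" not in folds:
        folds["promoterless"] = 1.0
        ratios["promoterless"] = base_ratio * 0.01
    rows = []
    for construct in sorted(folds):
        for treatment, scale in (("untreated", 1.0), (treated, folds[construct])):
            for rep in range(1, n_replicates + 1):
                target = ratios[construct] * scale * rluc
                reads = [
                    max(1e-9, target * (1.0 + noise * rng.standard_normal()))
                    for _ in range(3)
                ]
                rows.append({
                    "construct": construct, "treatment": treatment,
                    "replicate": rep, "fluc1": reads[0], "fluc2": reads[1],
                    "fluc3": reads[2], "rluc": rluc,
                })
    return pd.DataFrame(rows, columns=["construct", "treatment", "replicate",
                                       "fluc1", "fluc2", "fluc3", "rluc"])


def expected_surviving_truth(
    truth: Sequence[TruthRecord], threshold: float = 0.89
) -> set[tuple]:
    """Projection of the truth table onto the surviving-hit key space.

    A planted site is expected to survive iff it scores above the scan
    threshold, sits in active chromatin, and has evidence >= 500.
    """
    return {
        (t.gene_id, t.matrix_id, t.local_offset, t.strand)
        for t in truth
        if t.expected_surviving and t.relative_score > threshold
    }
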