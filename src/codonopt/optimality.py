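"""Per-codon relative adaptiveness (CAI and etAI) and per-transcript scores.

CAI weights follow the Sharp–Li convention: pooled codon counts in a
highly-expressed reference set, each weight scaled to the most frequent
synonymous codon, so 0 < w ≤ 1 and every transcript CAI lies in (0, 1].

etAI weights are measured tRNA anticodon read proportions assigned through
the decoding map — a wobble-decoded codon inherits its family's full
proportion — and are deliberately NOT rescaled to a maximum, because the
most abundant family can change between conditions.  etAI therefore scales
linearly with the profile and is not bounded by 1.

Per-transcript scores (CAI, etAI, decoding rate) are geometric means of the
per-codon values over the counted codons, computed in log domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import TrnaAbundanceProfile
from .genetic_code import (
    STANDARD_CODE,
    CodingSequence,
    CodonDecodingMap,
    GeneticCode,
    count_codons,
)
from .stats import rank_tests


@dataclass(frozen=True)
class AdaptivenessWeights:
    """Per-codon weights of one flavor (CAI or etAI)."""

    flavor: str
    w: Mapping[str, float]
    reference_label: str = ""

    def __post_init__(self) -> None:
        if self.flavor not in ("CAI", "etAI"):
            raise ValueError(f"unknown flavor {self.flavor!r}")
        if self.flavor == "CAI":
            vals = list(self.w.values())
            if any(v <= 0 or v > 1 + 1e-12 for v in vals):
                raise ValueError("CAI weights must lie in (0, 1]")
        elif any(v < 0 for v in self.w.values()):
            raise ValueError("etAI weights must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.w.items()), columns=["codon", "weight"]
        ).assign(flavor=self.flavor)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def cai_weights(
    cds_set: Sequence[CodingSequence],
    tpm: Mapping[str, float],
    top_fraction: float = 0.05,
    code: GeneticCode = STANDARD_CODE,
    reference_label: str = "",
) -> AdaptivenessWeights:
    """CAI relative adaptiveness from the top expressed reference set.

    The reference holds the ceiling(top_fraction · N) transcripts by mean
    TPM (ties broken lexicographically by transcript id); codon counts are
    pooled over the reference, zero counts replaced by a 0.5
    pseudo-occurrence, and each weight is count / max count among synonyms.
    """
    by_id = {c.transcript_id: c for c in cds_set if c.valid}
    expressed = [(tid, expr) for tid, expr in tpm.items() if tid in by_id]
    if len(expressed) < 20:
        raise ValueError("need at least 20 expressed transcripts for a CAI reference")
    n_ref = math.ceil(top_fraction * len(expressed))
    if n_ref == 0:
        raise ValueError("empty CAI reference set")
    ranked = sorted(expressed, key=lambda t: (-t[1], t[0]))
    reference = [by_id[tid] for tid, _ in ranked[:n_ref]]

    pooled: dict[str, float] = {c: 0.0 for c in code.sense_codons}
    for cds in reference:
        for codon, n in count_codons(cds).items():
            pooled[codon] += n
    for codon in pooled:
        if pooled[codon] == 0:
            pooled[codon] = 0.5

    by_aa: dict[str, list[str]] = {}
    for codon in code.sense_codons:
        by_aa.setdefault(code.amino_acid(codon), []).append(codon)
    w: dict[str, float] = {}
    for codons in by_aa.values():
        m = max(pooled[c] for c in codons)
        for c in codons:
            w[c] = pooled[c] / m
    return AdaptivenessWeights("CAI", w, reference_label or f"top{top_fraction:g}")


def etai_weights(
    profile: TrnaAbundanceProfile,
    dmap: CodonDecodingMap,
    zero_floor: float | str | None = None,
) -> AdaptivenessWeights:
    """etAI weights: each sense codon's weight is its family's read proportion.

    Zero proportions are kept as zeros by default (they abort downstream
    geometric means, flagging an input problem).  ``zero_floor`` may be a
    positive float or ``'half-min'`` (half the smallest nonzero proportion)
    to floor zeros for sparse inputs.
    """
    missing = sorted(
        {fam for fam, _ in dmap.assignments.values()} - set(profile.proportions)
    )
    if missing:
        raise ValueError(f"profile {profile.label!r} lacks families: {', '.join(missing)}")
    w = {codon: profile[fam] for codon, (fam, _) in dmap.assignments.items()}
    if zero_floor is not None and any(v == 0 for v in w.values()):
        if zero_floor == "half-min":
            nonzero = [v for v in w.values() if v > 0]
            if not nonzero:
                raise ValueError("all etAI weights are zero; no floor derivable")
            floor = min(nonzero) / 2
        else:
            floor = float(zero_floor)
            if floor <= 0:
                raise ValueError("zero_floor must be positive")
        w = {c: (v if v > 0 else floor) for c, v in w.items()}
    return AdaptivenessWeights("etAI", w, profile.label)


def transcript_score(
    cds: CodingSequence,
    per_codon: Mapping[str, float],
    exclude_start: bool = True,
    exclude_stop: bool = True,
) -> float:
    """Geometric mean of per-codon values over the transcript's counted codons.

    Codons enter with multiplicity; the mean is taken in log domain for
    numerical stability on long CDS.  A missing or non-positive value raises
    rather than being silently floored.
    """
    counts = count_codons(cds, exclude_start=exclude_start, exclude_stop=exclude_stop)
    log_sum = 0.0
    n = 0
    for codon, count in counts.items():
        v = per_codon.get(codon)
        if v is None:
            raise ValueError(f"no per-codon value for {codon} in {cds.transcript_id!r}")
        if v <= 0:
            raise ValueError(
                f"non-positive per-codon value {v!r} for {codon} in {cds.transcript_id!r}"
            )
        log_sum += count * math.log(v)
        n += count
    if n == 0:
        raise ValueError(f"CDS {cds.transcript_id!r} has no counted codons")
    return math.exp(log_sum / n)


@dataclass(frozen=True)
class DwellTimeTable:
    """Relative A-site dwell times per codon for one stage."""

    label: str
    dt: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [c for c, v in self.dt.items() if not v > 0]
        if bad:
            raise ValueError(f"non-positive dwell times for: {', '.join(sorted(bad))}")

    @classmethod
    def from_tsv(cls, path: str | Path, label: str = "") -> "DwellTimeTable":
        df = pd.read_csv(path, sep="\t")
        return cls(label or str(path), dict(zip(df.iloc[:, 0], df.iloc[:, 1].astype(float))))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.dt.items()), columns=["codon", "dt"]).to_csv(
            path, sep="\t", index=False
        )


def decoding_rates(dt_table: DwellTimeTable) -> dict[str, float]:
    """Per-codon decoding rates, the inverse of relative dwell times (1/DT)."""
    return {codon: 1.0 / dt for codon, dt in dt_table.dt.items()}


def wobble_vs_wc_dt(
    dt_table: DwellTimeTable,
    dmap: CodonDecodingMap,
) -> tuple[pd.DataFrame, float, float]:
    """Compare dwell times of Watson-Crick vs wobble codons of shared families.

    Returns the paired per-family listing and the two-sided Wilcoxon
    rank-sum statistic and p-value over the two dwell-time groups.
    """
    rows = []
    for family, wc_codon, wobble_codon in dmap.wobble_pairs:
        for c in (wc_codon, wobble_codon):
            if c not in dt_table.dt:
                raise ValueError(f"dwell time missing for codon {c}")
        rows.append((family, wc_codon, wobble_codon,
                     dt_table.dt[wc_codon], dt_table.dt[wobble_codon]))
    pairs = pd.DataFrame(
        rows, columns=["family", "codon_wc", "codon_wobble", "dt_wc", "dt_wobble"]
    )
    stat, p = rank_tests(
        pairs["dt_wc"].tolist(), pairs["dt_wobble"].tolist(), kind="wilcoxon_ranksum"
    )
    return pairs, stat, p


def score_transcripts(
    cds_set: Sequence[CodingSequence],
    cai: AdaptivenessWeights,
    etai: AdaptivenessWeights,
    rates: Mapping[str, float],
) -> pd.DataFrame:
    """CAI, etAI and decoding-rate geometric means for every valid CDS."""
    rows = []
    for cds in cds_set:
        if not cds.valid:
            continue
        n = sum(count_codons(cds).values())
        rows.append((
            cds.transcript_id,
            transcript_score(cds, cai.w),
            transcript_score(cds, etai.w),
            transcript_score(cds, rates),
            n,
        ))
    return pd.DataFrame(rows, columns=["transcript_id", "cai", "etai", "decoding_rate", "n_codons"])
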