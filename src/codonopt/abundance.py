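"""tRNA anticodon proportions, TPM-weighted codon usage, and demand vs supply.

Anticodon "supply" is the proportion of tRNA-mapped reads per family; codon
"demand" is transcriptome-wide proportional codon usage with each transcript's
codon frequencies weighted by its expression (TPM).  Wobble-decoded codons
inherit the full proportion of their assigned family (abundance duplication).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import CodingSequence, CodonDecodingMap, codon_frequencies

logger = logging.getLogger(__name__)

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class TrnaAbundanceProfile:
    """Per-family proportions of tRNA-mapped reads for one stage/condition."""

    label: str
    proportions: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = list(self.proportions.values())
        if any(v < 0 for v in vals):
            raise ValueError("proportions must be non-negative")
        if vals and abs(sum(vals) - 1.0) > _PROP_TOL:
            raise ValueError(f"proportions must sum to 1 (got {sum(vals)!r})")

    def __getitem__(self, family: str) -> float:
        return self.proportions[family]

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.proportions), name=self.label)


def trna_proportions(
    counts: Mapping[str, float],
    include: Iterable[str] | None = None,
    label: str = "",
) -> TrnaAbundanceProfile:
    """Normalize raw per-family read counts to proportions.

    ``include`` restricts the denominator to a family subset (the default
    usage excludes mitochondrial families by passing only cytosolic ones).
    """
    if include is not None:
        include = set(include)
        counts = {f: c for f, c in counts.items() if f in include}
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative read count")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all-zero counts: cannot form proportions")
    return TrnaAbundanceProfile(label, {f: c / total for f, c in counts.items()})


@dataclass(frozen=True)
class ExpressionTable:
    """Transcript × sample TPM matrix with replicate averaging."""

    tpm: pd.DataFrame  # index: transcript_id, columns: sample labels

    def __post_init__(self) -> None:
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def mean_tpm(self, samples: Sequence[str] | None = None) -> dict[str, float]:
        """Arithmetic mean TPM per transcript over the given replicate columns."""
        sub = self.tpm if samples is None else self.tpm[list(samples)]
        return sub.mean(axis=1).to_dict()


@dataclass(frozen=True)
class CodonUsageProfile:
    """Proportional sense-codon usage for one stage."""

    label: str
    usage: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.usage.values())
        if self.usage and abs(total - 1.0) > _PROP_TOL:
            raise ValueError(f"codon usage must sum to 1 (got {total!r})")

    def to_series(self) -> pd.Series:
        return pd.Series(dict(self.usage), name=self.label)


def weighted_codon_usage(
    cds_set: Sequence[CodingSequence],
    tpm: Mapping[str, float],
    stage: str = "",
    mode: str = "frequency",
) -> CodonUsageProfile:
    """Expression-weighted proportional codon usage.

    Per transcript, codon frequency (count / counted codons, start and stop
    excluded) is multiplied by the transcript's TPM; contributions are summed
    across transcripts and renormalized to proportions.  ``mode='count'``
    uses raw codon counts instead of frequencies (sensitivity mode).
    Transcripts expressed but absent from ``cds_set`` are skipped with a
    logged warning.
    """
    if mode not in ("frequency", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = {c.transcript_id: c for c in cds_set if c.valid}
    totals: dict[str, float] = {}
    n_skipped = 0
    for tid, expr in tpm.items():
        cds = by_id.get(tid)
        if cds is None:
            n_skipped += 1
            continue
        if expr == 0:
            continue
        freqs = codon_frequencies(cds)
        if mode == "count":
            n = sum(1 for _ in cds.codons) - 2
            freqs = {c: f * n for c, f in freqs.items()}
        for codon, f in freqs.items():
            totals[codon] = totals.get(codon, 0.0) + f * expr
    if n_skipped:
        logger.warning("weighted_codon_usage: skipped %d expressed transcripts "
                       "missing from the CDS set", n_skipped)
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("no expressed transcripts with valid CDS")
    return CodonUsageProfile(stage, {c: v / grand for c, v in totals.items()})


def demand_supply(
    usage: CodonUsageProfile,
    profile: TrnaAbundanceProfile,
    dmap: CodonDecodingMap,
) -> pd.DataFrame:
    """Per-codon demand (usage), tRNA supply, and demand/supply ratio.

    Supply is the assigned family's proportion, duplicated for wobble-decoded
    codons.  Ratios with zero supply are NaN with ``defined=False``.
    """
    rows = []
    for codon, demand in sorted(usage.usage.items()):
        if codon not in dmap.assignments:
            raise ValueError(f"codon {codon} has no family in the decoding map")
        family, pairing = dmap.assignments[codon]
        if family not in profile.proportions:
            raise ValueError(f"family {family} missing from profile {profile.label!r}")
        supply = profile[family]
        if supply > 0:
            ratio, defined = demand / supply, True
        else:
            ratio, defined = math.nan, False
        rows.append((codon, family, pairing, demand, supply, ratio, defined))
    return pd.DataFrame(
        rows, columns=["codon", "family", "pairing", "demand", "supply", "ratio", "defined"]
    )


def cross_stage_cv(values_per_stage: Mapping[str, Mapping[str, float]]) -> dict[str, float]:
    """Coefficient of variation (percent) per codon across ≥2 stages.

    CV = 100 · sample standard deviation (n−1) / mean; NaN when the mean is 0.
    """
    if len(values_per_stage) < 2:
        raise ValueError("need at least two stages for a coefficient of variation")
    stages = list(values_per_stage)
    codons = set().union(*(values_per_stage[s].keys() for s in stages))
    out: dict[str, float] = {}
    for codon in sorted(codons):
        vals = np.array([values_per_stage[s].get(codon, 0.0) for s in stages], dtype=float)
        mean = vals.mean()
        out[codon] = math.nan if mean == 0 else 100.0 * vals.std(ddof=1) / mean
    return out


def read_trna_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV of anticodon-family read counts (family, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    return df.set_index(first)
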