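"""mRNA half-life estimation and codon stabilization coefficients (CSC).

Half-lives come from first-order decay: log2(TPM) is regressed on time with
the slope bounded at zero from above, so k = −slope·ln2 and t½ = ln2/k =
−1/slope.  Transcripts are filtered, in order, for low starting expression,
a non-decreasing trend (bounded slope of 0), and a poor linear fit.

The CSC of a codon is the Pearson correlation, across retained transcripts,
between the codon's per-transcript occurrence and the transcript half-life:
significantly positive → stabilizing, significantly negative → destabilizing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genetic_code import CodingSequence, codon_frequencies, count_codons
from .stats import benjamini_hochberg, rank_tests

logger = logging.getLogger(__name__)

LN2 = math.log(2)

STATUS_RETAINED = "retained"
STATUS_LOW_T0 = "filtered_low_t0"
STATUS_NONDECREASING = "filtered_nondecreasing"
STATUS_POOR_FIT = "filtered_poor_fit"


@dataclass(frozen=True)
class TimeCourse:
    """TPM of one transcript on a strictly increasing hour grid."""

    transcript_id: str
    times: tuple[float, ...]
    tpm: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.tpm):
            raise ValueError("times and tpm must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("time grid must be strictly increasing")
        if any(v < 0 for v in self.tpm):
            raise ValueError("TPM must be non-negative")


@dataclass(frozen=True)
class HalfLifeResult:
    """Decay fit for one transcript (NaN fields when not retained)."""

    transcript_id: str
    slope: float        # log2(TPM) per hour, constrained ≤ 0
    k: float            # 1/h; −slope·ln2
    half_life: float    # h; ln2/k
    fit_p: float        # slope p-value of the unconstrained regression
    status: str


def fit_half_life(
    tc: TimeCourse,
    t0_min_tpm: float = 10.0,
    alpha: float = 0.05,
) -> HalfLifeResult:
    """Fit log2(TPM) vs time and classify the transcript.

    Zero TPM values truncate the time-course at the first zero (log2
    undefined beyond it).  The slope is constrained to (−∞, 0]: for a simple
    linear fit the bounded least-squares solution is min(OLS slope, 0).
    ``fit_p`` is the two-sided slope p-value of the unconstrained regression.
    """
    if len(tc.times) < 3:
        raise ValueError(f"transcript {tc.transcript_id!r}: need ≥ 3 time points")
    times = np.asarray(tc.times, dtype=float)
    tpm = np.asarray(tc.tpm, dtype=float)
    zeros = np.nonzero(tpm == 0)[0]
    if zeros.size:
        cut = zeros[0]
        logger.info("fit_half_life: %s truncated at first zero TPM (t=%g h)",
                    tc.transcript_id, times[cut])
        times, tpm = times[:cut], tpm[:cut]
    if times.size < 3:
        raise ValueError(
            f"transcript {tc.transcript_id!r}: fewer than 3 positive time points"
        )

    fit = sps.linregress(times, np.log2(tpm))
    slope = min(fit.slope, 0.0)
    fit_p = float(fit.pvalue)

    if tc.tpm[0] <= t0_min_tpm:
        status = STATUS_LOW_T0
    elif slope == 0.0:
        status = STATUS_NONDECREASING
    elif fit_p >= alpha:
        status = STATUS_POOR_FIT
    else:
        status = STATUS_RETAINED

    if status == STATUS_RETAINED:
        k = -slope * LN2
        half_life = LN2 / k
    else:
        k = half_life = math.nan
    return HalfLifeResult(tc.transcript_id, slope, k, half_life, fit_p, status)


def fit_half_lives(
    courses: Sequence[TimeCourse],
    t0_min_tpm: float = 10.0,
    alpha: float = 0.05,
) -> list[HalfLifeResult]:
    return [fit_half_life(tc, t0_min_tpm, alpha) for tc in courses]


CLASS_STABILIZING = "stabilizing"
CLASS_NEUTRAL = "neutral"
CLASS_DESTABILIZING = "destabilizing"


@dataclass(frozen=True)
class CscTable:
    """Per-codon CSC values with classification."""

    table: pd.DataFrame  # columns: codon, csc, p, q, codon_class
    n_transcripts: int

    def codon_class(self, codon: str) -> str:
        row = self.table.loc[self.table["codon"] == codon]
        if row.empty:
            raise KeyError(codon)
        return str(row["codon_class"].iloc[0])

    @property
    def classes(self) -> dict[str, str]:
        return dict(zip(self.table["codon"], self.table["codon_class"]))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def compute_csc(
    codon_freqs: Mapping[str, Mapping[str, float]],
    half_lives: Sequence[HalfLifeResult],
    min_transcripts: int = 10,
    alpha: float = 0.05,
    adjust: bool = False,
) -> CscTable:
    """Codon stabilization coefficients across retained transcripts.

    ``codon_freqs`` maps transcript → (codon → occurrence); only retained
    half-life results enter.  Per codon, Pearson r and its two-sided p are
    computed across transcripts; codons with zero variance get NaN and class
    neutral.  ``adjust=True`` classifies on BH-adjusted q instead of raw p.
    """
    retained = [h for h in half_lives if h.status == STATUS_RETAINED]
    missing = [h.transcript_id for h in retained if h.transcript_id not in codon_freqs]
    if missing:
        raise ValueError(f"retained transcripts missing codon frequencies: {missing[:5]}")
    if len(retained) < min_transcripts:
        raise ValueError(
            f"only {len(retained)} retained transcripts; need ≥ {min_transcripts}"
        )
    hl = np.array([h.half_life for h in retained])
    codons = sorted({c for h in retained for c in codon_freqs[h.transcript_id]})
    rows = []
    for codon in codons:
        x = np.array([codon_freqs[h.transcript_id].get(codon, 0.0) for h in retained])
        if np.all(x == x[0]):
            rows.append((codon, math.nan, math.nan))
            continue
        r, p = sps.pearsonr(x, hl)
        rows.append((codon, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["codon", "csc", "p"])
    df["q"] = np.nan
    ok = df["p"].notna()
    if ok.any():
        df.loc[ok, "q"] = benjamini_hochberg(df.loc[ok, "p"].to_numpy())
    crit = df["q"] if adjust else df["p"]
    df["codon_class"] = CLASS_NEUTRAL
    df.loc[(df["csc"] > 0) & (crit < alpha), "codon_class"] = CLASS_STABILIZING
    df.loc[(df["csc"] < 0) & (crit < alpha), "codon_class"] = CLASS_DESTABILIZING
    return CscTable(df, len(retained))


def transcript_class_codon_content(
    cds_set: Sequence[CodingSequence],
    csc: CscTable,
    groups: Mapping[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript stabilizing/neutral/destabilizing codon proportions.

    Each transcript in ``groups`` (transcript → group label) gets the three
    class proportions (summing to 1); classes are then compared between each
    pair of group labels with two-sided Mann–Whitney U tests.
    """
    classes = csc.classes
    by_id = {c.transcript_id: c for c in cds_set if c.valid}
    unknown = sorted(set(groups) - set(by_id))
    if unknown:
        raise ValueError(f"unknown transcripts in groups: {unknown[:5]}")
    rows = []
    for tid, label in groups.items():
        counts = count_codons(by_id[tid])
        total = sum(counts.values())
        shares = {CLASS_STABILIZING: 0.0, CLASS_NEUTRAL: 0.0, CLASS_DESTABILIZING: 0.0}
        for codon, n in counts.items():
            if codon not in classes:
                raise ValueError(f"codon {codon} in {tid!r} is not classified")
            shares[classes[codon]] += n / total
        rows.append((tid, label, shares[CLASS_STABILIZING], shares[CLASS_NEUTRAL],
                     shares[CLASS_DESTABILIZING]))
    content = pd.DataFrame(
        rows, columns=["transcript_id", "group", "stabilizing", "neutral", "destabilizing"]
    )
    labels = sorted(content["group"].unique())
    tests = []
    for i, g1 in enumerate(labels):
        for g2 in labels[i + 1:]:
            for cls in (CLASS_STABILIZING, CLASS_NEUTRAL, CLASS_DESTABILIZING):
                x = content.loc[content["group"] == g1, cls].tolist()
                y = content.loc[content["group"] == g2, cls].tolist()
                u, p = rank_tests(x, y, kind="mann_whitney")
                tests.append((g1, g2, cls, u, p))
    test_df = pd.DataFrame(tests, columns=["group1", "group2", "codon_class", "U", "p"])
    return content, test_df


def transcript_codon_frequencies(
    cds_set: Sequence[CodingSequence],
    mode: str = "frequency",
) -> dict[str, dict[str, float]]:
    """Codon occurrences per transcript for the CSC: frequencies or raw counts."""
    if mode not in ("frequency", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    out: dict[str, dict[str, float]] = {}
    for cds in cds_set:
        if not cds.valid:
            continue
        if mode == "frequency":
            out[cds.transcript_id] = codon_frequencies(cds)
        else:
            out[cds.transcript_id] = {c: float(n) for c, n in count_codons(cds).items()}
    return out


def read_timecourse_tsv(path: str | Path) -> list[TimeCourse]:
    """TSV with transcript_id plus one column per time point (header = hours)."""
    df = pd.read_csv(path, sep="\t")
    times = tuple(float(c) for c in df.columns[1:])
    return [
        TimeCourse(str(row.iloc[0]), times, tuple(float(v) for v in row.iloc[1:]))
        for _, row in df.iterrows()
    ]


def write_timecourse_tsv(courses: Sequence[TimeCourse], path: str | Path) -> None:
    if not courses:
        raise ValueError("no time-courses to write")
    times = courses[0].times
    rows = []
    for tc in courses:
        if tc.times != times:
            raise ValueError("all time-courses must share one time grid")
        rows.append([tc.transcript_id, *tc.tpm])
    pd.DataFrame(rows, columns=["transcript_id", *[f"{t:g}" for t in times]]).to_csv(
        path, sep="\t", index=False
    )


def half_lives_to_frame(results: Sequence[HalfLifeResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.transcript_id, r.slope, r.k, r.half_life, r.fit_p, r.status) for r in results],
        columns=["transcript_id", "slope", "k", "half_life", "fit_p", "status"],
    )
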