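"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emit exactly the dialects the analysis consumes (validated
CDS sets, tRNA abundance profiles, dwell-time tables, expression
time-courses) with known ground truth:

* anticodon proportions are symmetric-Dirichlet draws over the repertoire;
* dwell times are a power law in tRNA supply, dt ∝ supply^(−β), with
  multiplicative lognormal noise, so log dt is anti-correlated with log
  supply by construction;
* CDS sets have per-transcript codon compositions drawn around a common
  bias (Dirichlet heterogeneity), mimicking the across-gene codon-usage
  spread of real transcriptomes;
* decay rates are additive in codon content, k = k0 + Σ_c w_c · freq_c,
  giving exponential TPM time-courses whose half-lives ln2/k are analytic.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import TrnaAbundanceProfile
from .decay import LN2, TimeCourse
from .genetic_code import (
    STANDARD_CODE,
    CodingSequence,
    CodonDecodingMap,
    GeneticCode,
    build_decoding_map,
    codon_frequencies,
    default_repertoire,
    validate_cds,
)
from .optimality import DwellTimeTable

DEFAULT_TIMES: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 7, 8)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of one synthetic decay dataset."""

    seed: int
    codon_decay_weights: Mapping[str, float] = field(default_factory=dict)
    k0: float = 0.2                      # baseline decay, 1/h
    tpm_noise_sigma: float = 0.1         # lognormal σ on TPM
    times: tuple[float, ...] = DEFAULT_TIMES
    beta: float = 1.0                    # supply–dwell-time coupling exponent
    dt_noise_sigma: float = 0.3          # lognormal σ on dwell times
    family_proportions: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.tpm_noise_sigma < 0 or self.dt_noise_sigma < 0 or self.beta < 0:
            raise ValueError("noise σ and β must be non-negative")


def gen_trna_profile(
    seed: int,
    n_families: int = 47,
    concentration: float = 2.0,
    labels: Sequence[str] | None = None,
) -> TrnaAbundanceProfile:
    """Draw anticodon-family proportions from a symmetric Dirichlet.

    By default the 47 labels of the built-in repertoire are used; for other
    family counts, generic labels F00… are generated unless given.
    ``concentration`` is the per-family Dirichlet parameter: large values
    approach uniform 1/n proportions, small values give skewed pools.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if labels is None:
        rep = default_repertoire()
        if n_families == len(rep.labels):
            labels = rep.labels
        else:
            labels = tuple(f"F{i:02d}" for i in range(n_families))
    if len(labels) != n_families:
        raise ValueError("labels must match n_families")
    rng = np.random.default_rng(seed)
    props = rng.dirichlet(np.full(n_families, concentration))
    # Dirichlet draws are strictly positive almost surely; guard degenerate
    # floating-point zeros anyway.
    props = np.clip(props, np.finfo(float).tiny, None)
    props = props / props.sum()
    return TrnaAbundanceProfile(f"synthetic-seed{seed}", dict(zip(labels, props)))


def gen_dwell_times(
    profile: TrnaAbundanceProfile,
    dmap: CodonDecodingMap,
    beta: float = 1.0,
    sigma: float = 0.3,
    seed: int = 0,
) -> DwellTimeTable:
    """Dwell times dt(codon) = supply^(−β) · lognormal(0, σ), geometric mean 1.

    Larger β couples slow decoding to scarce tRNAs more tightly; σ = 0 gives
    an exact log-linear supply–dwell-time relation.
    """
    if beta < 0 or sigma < 0:
        raise ValueError("beta and sigma must be non-negative")
    rng = np.random.default_rng(seed)
    codons = sorted(dmap.assignments)
    supply = np.array([profile[dmap.family(c)] for c in codons])
    if np.any(supply <= 0):
        raise ValueError("zero tRNA supply for some codon; cannot generate dwell times")
    log_dt = -beta * np.log(supply) + rng.normal(0.0, sigma, len(codons))
    log_dt -= log_dt.mean()  # normalize geometric mean to 1
    return DwellTimeTable(profile.label, dict(zip(codons, np.exp(log_dt))))


def gen_cds_set(
    seed: int,
    n_transcripts: int = 500,
    length_range: tuple[int, int] = (100, 400),
    codon_bias: Mapping[str, float] | None = None,
    heterogeneity: float = 150.0,
    code: GeneticCode = STANDARD_CODE,
) -> list[CodingSequence]:
    """Generate validated CDS records: ATG + biased sense codons + stop.

    ``length_range`` bounds the number of internal codons (inclusive).
    ``codon_bias`` gives mean sampling weights over sense codons (uniform by
    default); per-transcript codon distributions are drawn from a Dirichlet
    with total concentration ``heterogeneity`` around the bias, so codon
    composition varies between transcripts as it does between real genes.
    Stop codons never appear internally, so every record passes validation.
    """
    lo, hi = length_range
    if lo < 3 or hi < lo:
        raise ValueError("length_range must satisfy 3 ≤ lo ≤ hi (codons)")
    sense = list(code.sense_codons)
    if codon_bias is None:
        bias = np.full(len(sense), 1.0 / len(sense))
    else:
        bad = set(codon_bias) - set(sense)
        if bad:
            raise ValueError(f"codon_bias contains non-sense codons: {sorted(bad)}")
        bias = np.array([codon_bias.get(c, 0.0) for c in sense], dtype=float)
        if np.any(bias < 0) or bias.sum() <= 0:
            raise ValueError("degenerate codon bias weights")
        bias = bias / bias.sum()
    if heterogeneity <= 0:
        raise ValueError("heterogeneity must be positive")

    rng = np.random.default_rng(seed)
    stops = sorted(code.stop_set)
    alpha = heterogeneity * bias
    # Dirichlet requires strictly positive concentration parameters.
    alpha = np.where(bias > 0, np.clip(alpha, 1e-6, None), 0.0)
    records = []
    for i in range(n_transcripts):
        n_internal = int(rng.integers(lo, hi + 1))
        if np.all(alpha > 0):
            p = rng.dirichlet(alpha)
        else:  # zero-weight codons stay at exactly zero probability
            p = np.zeros_like(bias)
            pos = alpha > 0
            p[pos] = rng.dirichlet(alpha[pos])
        body = rng.choice(sense, size=n_internal, p=p)
        stop = stops[int(rng.integers(len(stops)))]
        seq = "ATG" + "".join(body) + stop
        cds = validate_cds(f"synth{i:05d}", seq, code)
        assert cds.valid
        records.append(cds)
    return records


def write_fasta(cds_set: Sequence[CodingSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for cds in cds_set:
            fh.write(f">{cds.transcript_id}\n")
            for i in range(0, len(cds.seq), width):
                fh.write(cds.seq[i : i + width] + "\n")


def decay_weights_from_supply(
    profile: TrnaAbundanceProfile,
    dmap: CodonDecodingMap,
    coupling: float,
    scale: float = 0.1,
) -> dict[str, float]:
    """Per-codon decay weights ∝ −log tRNA supply, scaled by ``coupling``.

    This couples slow decoding (scarce tRNA) to faster decay: stronger
    coupling makes transcript adaptation (etAI) a better predictor of
    half-life, the synthetic analogue of translation-driven sensitization.
    """
    if coupling < 0 or scale <= 0:
        raise ValueError("coupling must be ≥ 0 and scale > 0")
    return {
        codon: coupling * scale * (-math.log(profile[dmap.family(codon)]))
        for codon in dmap.assignments
    }


def gen_decay_dataset(
    cds_set: Sequence[CodingSequence],
    truth: SyntheticTruth,
    t0_log_mean: float = math.log(300.0),
    t0_log_sigma: float = 1.0,
) -> tuple[list[TimeCourse], pd.DataFrame]:
    """Exponential decay time-courses with codon-dependent rate constants.

    k_i = k0 + Σ_c w_c · freq_i(c); TPM_i(t) = TPM_i(0) · 2^(−t·k_i/ln2) with
    multiplicative lognormal noise of σ = ``tpm_noise_sigma`` at every point.
    Returns the time-courses and a ground-truth table with k and t½ = ln2/k.
    """
    if 0.0 not in truth.times:
        raise ValueError("time grid must include t = 0")
    rng = np.random.default_rng(truth.seed)
    times = np.asarray(truth.times, dtype=float)
    weights = dict(truth.codon_decay_weights)
    courses: list[TimeCourse] = []
    truth_rows = []
    for cds in cds_set:
        freqs = codon_frequencies(cds)
        k = truth.k0 + sum(weights.get(c, 0.0) * f for c, f in freqs.items())
        if k <= 0:
            raise ValueError(f"non-positive decay rate for transcript {cds.transcript_id!r}")
        tpm0 = float(rng.lognormal(t0_log_mean, t0_log_sigma))
        clean = tpm0 * np.exp(-k * times)
        noise = rng.lognormal(0.0, truth.tpm_noise_sigma, times.size) \
            if truth.tpm_noise_sigma > 0 else np.ones(times.size)
        courses.append(TimeCourse(cds.transcript_id, tuple(times), tuple(clean * noise)))
        truth_rows.append((cds.transcript_id, k, LN2 / k, tpm0))
    truth_df = pd.DataFrame(truth_rows, columns=["transcript_id", "k", "half_life", "tpm0"])
    return courses, truth_df


def simulate_fixture(
    outdir: str | Path,
    seed: int,
    n_transcripts: int = 500,
    concentration: float = 2.0,
    beta: float = 1.0,
    dt_sigma: float = 0.3,
    tpm_sigma: float = 0.1,
    coupling: float = 1.0,
    dmap: CodonDecodingMap | None = None,
) -> dict[str, Path]:
    """Materialize a complete fixture directory plus a truth manifest.

    Writes cds.fasta, trna_proportions.tsv, dwell_times.tsv, expression.tsv,
    timecourse.tsv and truth_half_lives.tsv, all in the dialects the
    analysis readers consume.  Sub-seeds are derived deterministically.
    """
    from .decay import write_timecourse_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_prof, s_dt, s_cds, s_decay = [int(s.generate_state(1)[0] % 2**31)
                                    for s in ss.spawn(4)]
    dmap = dmap or build_decoding_map()
    profile = gen_trna_profile(s_prof, concentration=concentration)
    dts = gen_dwell_times(profile, dmap, beta=beta, sigma=dt_sigma, seed=s_dt)
    cds = gen_cds_set(s_cds, n_transcripts=n_transcripts)
    weights = decay_weights_from_supply(profile, dmap, coupling)
    truth = SyntheticTruth(seed=s_decay, codon_decay_weights=weights,
                           tpm_noise_sigma=tpm_sigma, beta=beta,
                           dt_noise_sigma=dt_sigma,
                           family_proportions=profile.proportions)
    courses, truth_df = gen_decay_dataset(cds, truth)

    paths = {
        "fasta": outdir / "cds.fasta",
        "trna": outdir / "trna_proportions.tsv",
        "dwell": outdir / "dwell_times.tsv",
        "expression": outdir / "expression.tsv",
        "timecourse": outdir / "timecourse.tsv",
        "truth": outdir / "truth_half_lives.tsv",
    }
    write_fasta(cds, paths["fasta"])
    profile.to_series().rename_axis("family").reset_index(name="proportion").to_csv(
        paths["trna"], sep="\t", index=False
    )
    dts.to_tsv(paths["dwell"])
    expr = truth_df[["transcript_id", "tpm0"]].rename(columns={"tpm0": "tpm"})
    expr.to_csv(paths["expression"], sep="\t", index=False)
    write_timecourse_tsv(courses, paths["timecourse"])
    truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return paths
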