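"""Half-life fitting, CSC computation, and codon-class content comparisons."""

import math

import numpy as np
import pytest

from codonopt import (
    CscTable,
    TimeCourse,
    compute_csc,
    fit_half_life,
    fit_half_lives,
    gen_cds_set,
    transcript_class_codon_content,
    transcript_codon_frequencies,
    validate_cds,
)
from codonopt.decay import (
    STATUS_LOW_T0,
    STATUS_NONDECREASING,
    STATUS_POOR_FIT,
    STATUS_RETAINED,
)

TIMES = tuple(float(t) for t in range(9))


def _course(tid, tpm):
    return TimeCourse(tid, TIMES, tuple(tpm))


class TestFitHalfLife:
    def test_noiseless_two_hour_half_life(self):
        tpm = [100 * 2 ** (-t / 2) for t in TIMES]
        res = fit_half_life(_course("t", tpm))
        assert res.status == STATUS_RETAINED
        assert res.slope == pytest.approx(-0.5)
        assert res.k == pytest.approx(0.5 * math.log(2))
        assert res.half_life == pytest.approx(2.0, rel=1e-12)

    def test_growing_transcript_filtered_nondecreasing(self):
        tpm = [100 * 2 ** (t / 2) for t in TIMES]
        res = fit_half_life(_course("t", tpm))
        assert res.status == STATUS_NONDECREASING
        assert res.slope == 0.0
        assert math.isnan(res.half_life)

    def test_low_t0_filter_precedes_others(self):
        tpm = [5 * 2 ** (-t / 2) for t in TIMES]
        res = fit_half_life(_course("t", tpm))
        assert res.status == STATUS_LOW_T0

    def test_flat_noisy_course_filtered_poor_fit(self):
        rng = np.random.default_rng(0)
        tpm = 100 * np.exp(rng.normal(0, 0.01, len(TIMES)))
        tpm[1] = 99.0  # ensure a slightly negative slope, not exactly flat
        res = fit_half_life(_course("t", tpm))
        assert res.status in (STATUS_POOR_FIT, STATUS_NONDECREASING)

    def test_zero_tpm_truncates_course(self):
        tpm = [100 * 2 ** (-t / 2) for t in TIMES]
        tpm[6:] = [0.0, 0.0, 0.0]
        res = fit_half_life(_course("t", tpm))
        assert res.status == STATUS_RETAINED
        assert res.half_life == pytest.approx(2.0, rel=1e-9)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError, match="3 time points"):
            fit_half_life(TimeCourse("t", (0.0, 1.0), (100.0, 50.0)))

    def test_nonincreasing_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TimeCourse("t", (0.0, 1.0, 1.0), (100.0, 50.0, 25.0))

    def test_noisy_recovery_median_error_under_ten_percent(self):
        """Lognormal σ=0.1 on 9 points: median |Δt½|/t½ stays below 10%."""
        rng = np.random.default_rng(123)
        errors = []
        for _ in range(200):
            half_life = rng.uniform(1.0, 6.0)
            k = math.log(2) / half_life
            noise = rng.lognormal(0.0, 0.1, len(TIMES))
            tpm = 100 * np.exp(-k * np.asarray(TIMES)) * noise
            res = fit_half_life(_course("t", tpm))
            if res.status == STATUS_RETAINED:
                errors.append(abs(res.half_life - half_life) / half_life)
        assert len(errors) > 150
        assert np.median(errors) < 0.10


def _retained(transcripts, half_lives):
    return [
        fit_half_life(_course(t, [100 * 2 ** (-x / h) for x in TIMES]))
        for t, h in zip(transcripts, half_lives)
    ]


class TestComputeCsc:
    def test_perfect_correlation(self):
        tids = [f"t{i}" for i in range(12)]
        hl = np.linspace(1.0, 6.0, 12)
        results = _retained(tids, hl)
        freqs = {t: {"AAA": h / 10, "GGG": 1 - h / 10} for t, h in zip(tids, hl)}
        table = compute_csc(freqs, results).table.set_index("codon")
        assert table.loc["AAA", "csc"] == pytest.approx(1.0)
        assert table.loc["AAA", "codon_class"] == "stabilizing"
        assert table.loc["GGG", "csc"] == pytest.approx(-1.0)
        assert table.loc["GGG", "codon_class"] == "destabilizing"

    def test_zero_variance_codon_is_neutral_nan(self):
        tids = [f"t{i}" for i in range(12)]
        hl = np.linspace(1.0, 6.0, 12)
        results = _retained(tids, hl)
        freqs = {t: {"AAA": 0.5, "GGG": h / 10} for t, h in zip(tids, hl)}
        table = compute_csc(freqs, results).table.set_index("codon")
        assert math.isnan(table.loc["AAA", "csc"])
        assert table.loc["AAA", "codon_class"] == "neutral"

    def test_affine_invariance_of_csc(self):
        """Pearson correlation is unchanged by positive affine maps of t½."""
        rng = np.random.default_rng(5)
        tids = [f"t{i}" for i in range(15)]
        hl = rng.uniform(1, 6, 15)
        freqs = {t: {"AAA": float(rng.uniform(0, 1))} for t in tids}
        r1 = compute_csc(freqs, _retained(tids, hl)).table.set_index("codon")
        r2 = compute_csc(freqs, _retained(tids, 0.5 * hl + 0.2)).table.set_index("codon")
        assert r1.loc["AAA", "csc"] == pytest.approx(r2.loc["AAA", "csc"], rel=1e-6)

    def test_class_partition_is_consistent(self):
        cds = gen_cds_set(9, n_transcripts=60, length_range=(60, 120))
        hl = np.random.default_rng(9).uniform(1, 6, 60)
        results = _retained([c.transcript_id for c in cds], hl)
        freqs = transcript_codon_frequencies(cds)
        table = compute_csc(freqs, results).table
        counts = table["codon_class"].value_counts()
        assert counts.sum() == len(table)
        assert set(counts.index) <= {"stabilizing", "neutral", "destabilizing"}

    def test_missing_transcript_errors(self):
        results = _retained([f"t{i}" for i in range(12)], np.linspace(1, 6, 12))
        with pytest.raises(ValueError, match="missing codon frequencies"):
            compute_csc({"t0": {"AAA": 0.5}}, results)

    def test_too_few_retained_errors(self):
        results = _retained(["t0", "t1"], [2.0, 3.0])
        freqs = {"t0": {"AAA": 0.5}, "t1": {"AAA": 0.6}}
        with pytest.raises(ValueError, match="need ≥ 10"):
            compute_csc(freqs, results)


def _csc_table(classes):
    import pandas as pd
    df = pd.DataFrame(
        [(c, 0.5 if k == "stabilizing" else (-0.5 if k == "destabilizing" else 0.0),
          0.01 if k != "neutral" else 0.9, np.nan, k) for c, k in classes.items()],
        columns=["codon", "csc", "p", "q", "codon_class"],
    )
    return CscTable(df, n_transcripts=10)


class TestTranscriptClassContent:
    def test_pure_stabilizing_transcript(self):
        csc = _csc_table({"AAA": "stabilizing", "GGG": "destabilizing"})
        cds = [validate_cds("t1", "ATGAAAAAATAA")]
        content, _ = transcript_class_codon_content(cds, csc, {"t1": "g"})
        row = content.iloc[0]
        assert (row["stabilizing"], row["neutral"], row["destabilizing"]) == (1.0, 0.0, 0.0)

    def test_proportions_sum_to_one(self):
        csc = _csc_table({"AAA": "stabilizing", "GGG": "destabilizing", "CCC": "neutral"})
        cds = [validate_cds("t1", "ATGAAAGGGCCCTAA")]
        content, _ = transcript_class_codon_content(cds, csc, {"t1": "g"})
        row = content.iloc[0]
        assert row[["stabilizing", "neutral", "destabilizing"]].sum() == pytest.approx(1.0)

    def test_identical_groups_p_one(self):
        csc = _csc_table({"AAA": "stabilizing", "GGG": "destabilizing"})
        cds = [validate_cds(f"t{i}", "ATGAAAGGGTAA") for i in range(6)]
        groups = {f"t{i}": ("a" if i < 3 else "b") for i in range(6)}
        _, tests = transcript_class_codon_content(cds, csc, groups)
        assert np.allclose(tests["p"], 1.0)

    def test_unclassified_codon_errors(self):
        csc = _csc_table({"AAA": "stabilizing"})
        cds = [validate_cds("t1", "ATGGGGTAA")]
        with pytest.raises(ValueError, match="not classified"):
            transcript_class_codon_content(cds, csc, {"t1": "g"})

    def test_unknown_transcript_errors(self):
        csc = _csc_table({"AAA": "stabilizing"})
        with pytest.raises(ValueError, match="unknown transcripts"):
            transcript_class_codon_content([], csc, {"ghost": "g"})
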