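"""CAI/etAI weights, geometric-mean transcript scores, and decoding rates."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonopt import (
    DwellTimeTable,
    TrnaAbundanceProfile,
    cai_weights,
    decoding_rates,
    etai_weights,
    gen_cds_set,
    transcript_score,
    validate_cds,
    wobble_vs_wc_dt,
)


def _cds(tid, body):
    return validate_cds(tid, "ATG" + body + "TAA")


def _expressed_set(reference_body, n_fill=25):
    """A CDS set where one highly expressed transcript dominates the reference."""
    cds = [_cds("ref", reference_body)]
    tpm = {"ref": 1e6}
    for i in range(n_fill):
        tid = f"fill{i:02d}"
        cds.append(_cds(tid, "GGG"))
        tpm[tid] = 1.0
    return cds, tpm


class TestCaiWeights:
    def test_synonymous_ratio(self):
        # reference counts Phe {TTC: 90, TTT: 10} → w(TTC)=1, w(TTT)=1/9
        cds, tpm = _expressed_set("TTC" * 90 + "TTT" * 10)
        w = cai_weights(cds, tpm).w
        assert w["TTC"] == pytest.approx(1.0)
        assert w["TTT"] == pytest.approx(1 / 9)

    def test_equal_counts_all_one(self):
        cds, tpm = _expressed_set("TTC" * 10 + "TTT" * 10)
        w = cai_weights(cds, tpm).w
        assert w["TTC"] == w["TTT"] == pytest.approx(1.0)

    def test_pseudo_occurrence_for_absent_codon(self):
        cds, tpm = _expressed_set("TTC" * 40)
        w = cai_weights(cds, tpm).w
        assert w["TTT"] == pytest.approx(0.5 / 40)

    def test_weights_in_unit_interval(self):
        cds = gen_cds_set(5, n_transcripts=40, length_range=(50, 100))
        tpm = {c.transcript_id: float(i + 1) for i, c in enumerate(cds)}
        w = cai_weights(cds, tpm).w
        assert set(w) == set(__import__("codonopt").STANDARD_CODE.sense_codons)
        assert all(0 < v <= 1 for v in w.values())

    def test_reference_size_is_ceiling(self):
        # 21 transcripts → ceil(0.05·21) = 2: the two top-TPM transcripts set weights
        cds = [_cds("a", "TTC"), _cds("b", "TTT")] + [_cds(f"f{i}", "GGG") for i in range(19)]
        tpm = {"a": 100.0, "b": 99.0, **{f"f{i}": 1.0 for i in range(19)}}
        w = cai_weights(cds, tpm).w
        assert w["TTC"] == w["TTT"] == pytest.approx(1.0)  # both in reference

    def test_too_few_transcripts_error(self):
        cds, tpm = _expressed_set("TTC", n_fill=5)
        with pytest.raises(ValueError, match="at least 20"):
            cai_weights(cds, tpm)


class TestEtaiWeights:
    def test_wobble_codon_inherits_family_proportion(self, dmap, repertoire):
        rest = [f.label for f in repertoire.elongators if f.label != "Phe-GAA"]
        props = {"Phe-GAA": 0.04, **{lab: 0.96 / len(rest) for lab in rest}}
        w = etai_weights(TrnaAbundanceProfile("s", props), dmap).w
        assert w["TTC"] == w["TTT"] == pytest.approx(0.04)

    def test_uniform_elongator_profile(self, dmap, repertoire):
        prof = TrnaAbundanceProfile(
            "u", {f.label: 1 / 45 for f in repertoire.elongators})
        w = etai_weights(prof, dmap).w
        assert all(v == pytest.approx(1 / 45) for v in w.values())

    def test_watson_crick_weights_sum_to_one(self, dmap, repertoire):
        rng = np.random.default_rng(3)
        props = rng.dirichlet(np.ones(45))
        prof = TrnaAbundanceProfile(
            "d", dict(zip((f.label for f in repertoire.elongators), props)))
        w = etai_weights(prof, dmap)
        wc_sum = sum(w.w[c] for c, (_, p) in dmap.assignments.items()
                     if p == "watson_crick")
        assert wc_sum == pytest.approx(1.0)

    def test_no_rescaling_to_maximum(self, dmap, profile):
        w = etai_weights(profile, dmap).w
        assert max(w.values()) < 1.0  # proportions, not rescaled

    def test_scale_covariance(self, dmap, profile):
        """Scaling all proportions by c scales every transcript etAI by c."""
        w1 = etai_weights(profile, dmap).w
        cds = _cds("t", "TTCGAAAAACCC")
        s1 = transcript_score(cds, w1)
        s2 = transcript_score(cds, {k: 2.5 * v for k, v in w1.items()})
        assert s2 == pytest.approx(2.5 * s1)

    def test_missing_family_errors(self, dmap):
        prof = TrnaAbundanceProfile("s", {"Phe-GAA": 1.0})
        with pytest.raises(ValueError, match="lacks families"):
            etai_weights(prof, dmap)

    def test_half_min_floor(self, dmap, repertoire):
        props = {f.label: 0.0 for f in repertoire.elongators}
        props["Phe-GAA"] = 0.6
        props["His-GTG"] = 0.4
        prof = TrnaAbundanceProfile("s", props)
        w = etai_weights(prof, dmap, zero_floor="half-min").w
        assert min(w.values()) == pytest.approx(0.2)


def _brute_force_geometric_mean(values):
    """Product-then-root without logs, tracking the binary exponent."""
    mant, expo = 1.0, 0
    for v in values:
        m, e = math.frexp(v)
        mant *= m
        expo += e
        m2, e2 = math.frexp(mant)
        mant, expo = m2, expo + e2
    n = len(values)
    return mant ** (1 / n) * 2 ** (expo / n)


class TestTranscriptScore:
    def test_constant_values(self):
        assert transcript_score(_cds("t", "AAAAAA"), {"AAA": 0.04}) == pytest.approx(0.04)

    def test_two_codon_geometric_mean(self):
        score = transcript_score(_cds("t", "AAAGGG"), {"AAA": 1.0, "GGG": 0.25})
        assert score == pytest.approx(0.5)

    def test_order_invariance(self):
        vals = {"AAA": 0.3, "GGG": 0.7, "CCC": 0.11}
        s1 = transcript_score(_cds("t", "AAAGGGCCC"), vals)
        s2 = transcript_score(_cds("t", "CCCAAAGGG"), vals)
        assert s1 == pytest.approx(s2, rel=1e-15)

    def test_matches_brute_force_oracle_on_long_cds(self):
        rng = np.random.default_rng(42)
        cds = gen_cds_set(7, n_transcripts=20, length_range=(500, 1000))
        values = {c: float(v) for c, v in zip(
            __import__("codonopt").STANDARD_CODE.sense_codons,
            rng.uniform(0.001, 0.2, 61))}
        from codonopt import count_codons
        for rec in cds:
            per_codon = []
            for codon, n in count_codons(rec).items():
                per_codon.extend([values[codon]] * n)
            expected = _brute_force_geometric_mean(per_codon)
            assert transcript_score(rec, values) == pytest.approx(expected, rel=1e-12)

    def test_zero_value_errors_naming_codon(self):
        with pytest.raises(ValueError, match="GGG"):
            transcript_score(_cds("t", "AAAGGG"), {"AAA": 1.0, "GGG": 0.0})

    def test_missing_value_errors(self):
        with pytest.raises(ValueError, match="GGG"):
            transcript_score(_cds("t", "AAAGGG"), {"AAA": 1.0})


class TestDecodingRates:
    def test_inverse(self):
        table = DwellTimeTable("s", {"AAA": 2.0, "GGG": 1.0})
        assert decoding_rates(table) == pytest.approx({"AAA": 0.5, "GGG": 1.0})

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            DwellTimeTable("s", {"AAA": 0.0})


class TestWobbleVsWcDt:
    def test_identical_dwell_times_p_one(self, dmap):
        table = DwellTimeTable("s", {c: 1.0 for c in dmap.assignments})
        pairs, _, p = wobble_vs_wc_dt(table, dmap)
        assert p == pytest.approx(1.0)

    def test_sixteen_paired_rows(self, dmap, profile):
        from codonopt import gen_dwell_times
        table = gen_dwell_times(profile, dmap, beta=1.0, sigma=0.2, seed=4)
        pairs, stat, p = wobble_vs_wc_dt(table, dmap)
        assert len(pairs) == 16
        assert 0 <= p <= 1

    def test_missing_dwell_time_errors(self, dmap):
        table = DwellTimeTable("s", {"TTC": 1.0})
        with pytest.raises(ValueError, match="dwell time missing"):
            wobble_vs_wc_dt(table, dmap)
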