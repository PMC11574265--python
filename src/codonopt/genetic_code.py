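"""Genetic-code tables, CDS validation, and the wobble-aware codon-to-anticodon map.

The decoding map assigns each of the 61 sense codons to exactly one tRNA
anticodon family.  A codon whose third base reverse-complements the family's
anticodon position 34 is a Watson-Crick assignment; the two wobble rules used
here are the pairwise duplications found across eukaryotes:

* G34 families additionally read the U-ending synonymous codon (G:U wobble);
* A34 families (inosine at position 34 in vivo) additionally read the
  C-ending synonymous codon.

With the default 47-family cytosolic repertoire (45 elongator families plus
initiator Met and Sec) this yields 16 wobble pairs, 8 of them from inosine
families.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

NUCLEOTIDES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Amino-acid letter for each of the 64 codons in the standard nuclear code
#: (DNA alphabet, '*' marks stop).
STANDARD_CODE_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneticCode:
    """The codon → amino-acid table with its stop/sense partition."""

    codon_to_aa: Mapping[str, str]

    def __post_init__(self) -> None:
        codons = set(self.codon_to_aa)
        expected = {a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES}
        if codons != expected:
            raise ValueError("genetic code must cover all 64 trinucleotides exactly once")
        if len(self.stop_set) != 3 or len(self.sense_codons) != 61:
            raise ValueError("genetic code must have 61 sense codons and 3 stop codons")

    @property
    def stop_set(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_to_aa.items() if aa == "*")

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(c for c, aa in self.codon_to_aa.items() if aa != "*"))

    def amino_acid(self, codon: str) -> str:
        return self.codon_to_aa[codon]


STANDARD_CODE = GeneticCode(STANDARD_CODE_TABLE)

REJECT_REASONS = ("bad_length", "no_start", "no_stop", "ambiguous_base", "internal_stop", "none")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding nucleotide sequence with its validation verdict.

    ``reject_reason`` reports the first failing check in the fixed order
    bad_length → no_start → no_stop → ambiguous_base → internal_stop.
    ``codons`` is populated whenever the length is a multiple of three.
    """

    transcript_id: str
    seq: str
    codons: tuple[str, ...]
    valid: bool
    reject_reason: str

    def __len__(self) -> int:
        return len(self.seq)


def validate_cds(transcript_id: str, seq: str, code: GeneticCode = STANDARD_CODE) -> CodingSequence:
    """Validate one CDS against the four structural filters.

    The sequence is upper-cased and U is normalized to T; validation is
    idempotent.  A valid CDS starts with ATG, ends with a stop codon, has
    length divisible by three, contains only unambiguous bases, and has no
    stop codon before the final triplet.
    """
    if not seq:
        raise ValueError("empty sequence")
    norm = seq.upper().replace("U", "T")
    codons: tuple[str, ...] = ()
    if len(norm) % 3 == 0:
        codons = tuple(norm[i : i + 3] for i in range(0, len(norm), 3))

    reason = "none"
    if len(norm) % 3 != 0:
        reason = "bad_length"
    elif not norm.startswith("ATG"):
        reason = "no_start"
    elif codons[-1] not in code.stop_set:
        reason = "no_stop"
    elif any(b not in NUCLEOTIDES for b in norm):
        reason = "ambiguous_base"
    elif any(c in code.stop_set for c in codons[:-1]):
        reason = "internal_stop"

    return CodingSequence(
        transcript_id=transcript_id,
        seq=norm,
        codons=codons,
        valid=reason == "none",
        reject_reason=reason,
    )


def count_codons(
    cds: CodingSequence,
    exclude_start: bool = True,
    exclude_stop: bool = True,
) -> dict[str, int]:
    """Count sense codons in a valid CDS.

    Defaults drop the start ATG and the terminal stop so that per-transcript
    statistics pool only elongation events; internal ATGs are counted as Met.
    """
    if not cds.valid:
        raise ValueError(f"cannot count codons of invalid CDS {cds.transcript_id!r} "
                         f"({cds.reject_reason})")
    codons = list(cds.codons)
    if exclude_stop:
        codons = codons[:-1]
    if exclude_start:
        codons = codons[1:]
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return counts


def codon_frequencies(cds: CodingSequence, **kwargs) -> dict[str, float]:
    """Per-transcript codon proportions (counts / counted codons)."""
    counts = count_codons(cds, **kwargs)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"CDS {cds.transcript_id!r} has no counted codons")
    return {c: n / total for c, n in counts.items()}


def select_principal_isoform(
    candidates: Sequence[tuple[str, float, int]],
    seed: int,
) -> str:
    """Pick a principal isoform: best score, then longest, then a seeded draw.

    ``candidates`` are (transcript_id, score, length) triples.  The final
    random tie-break is reproducible for a fixed seed.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    best_score = max(c[1] for c in candidates)
    scored = [c for c in candidates if c[1] == best_score]
    best_len = max(c[2] for c in scored)
    longest = sorted(c[0] for c in scored if c[2] == best_len)
    if len(longest) == 1:
        return longest[0]
    return random.Random(seed).choice(longest)


@dataclass(frozen=True)
class AnticodonFamily:
    """One tRNA anticodon family (isoacceptor)."""

    amino_acid: str
    anticodon: str
    cls: str = "elongator"  # elongator | initiator | selenocysteine

    @property
    def label(self) -> str:
        if self.cls == "initiator":
            return f"i{self.amino_acid}-{self.anticodon}"
        return f"{self.amino_acid}-{self.anticodon}"


# Standard eukaryotic cytosolic repertoire: 45 elongator families plus
# initiator Met and Sec (47 total).  The set covers all 61 sense codons under
# the two wobble duplication rules and produces 16 wobble pairs.
_DEFAULT_FAMILIES: tuple[tuple[str, str, str], ...] = (
    ("Ala", "AGC", "elongator"),
    ("Ala", "CGC", "elongator"),
    ("Ala", "TGC", "elongator"),
    ("Arg", "ACG", "elongator"),
    ("Arg", "CCG", "elongator"),
    ("Arg", "TCG", "elongator"),
    ("Arg", "TCT", "elongator"),
    ("Arg", "CCT", "elongator"),
    ("Asn", "GTT", "elongator"),
    ("Asp", "GTC", "elongator"),
    ("Cys", "GCA", "elongator"),
    ("Gln", "TTG", "elongator"),
    ("Gln", "CTG", "elongator"),
    ("Glu", "TTC", "elongator"),
    ("Glu", "CTC", "elongator"),
    ("Gly", "GCC", "elongator"),
    ("Gly", "TCC", "elongator"),
    ("Gly", "CCC", "elongator"),
    ("His", "GTG", "elongator"),
    ("Ile", "AAT", "elongator"),
    ("Ile", "TAT", "elongator"),
    ("Leu", "TAA", "elongator"),
    ("Leu", "CAA", "elongator"),
    ("Leu", "AAG", "elongator"),
    ("Leu", "TAG", "elongator"),
    ("Leu", "CAG", "elongator"),
    ("Lys", "TTT", "elongator"),
    ("Lys", "CTT", "elongator"),
    ("Met", "CAT", "elongator"),
    ("Phe", "GAA", "elongator"),
    ("Pro", "AGG", "elongator"),
    ("Pro", "TGG", "elongator"),
    ("Pro", "CGG", "elongator"),
    ("Ser", "AGA", "elongator"),
    ("Ser", "TGA", "elongator"),
    ("Ser", "CGA", "elongator"),
    ("Ser", "GCT", "elongator"),
    ("Thr", "AGT", "elongator"),
    ("Thr", "TGT", "elongator"),
    ("Thr", "CGT", "elongator"),
    ("Trp", "CCA", "elongator"),
    ("Tyr", "GTA", "elongator"),
    ("Val", "AAC", "elongator"),
    ("Val", "TAC", "elongator"),
    ("Val", "CAC", "elongator"),
    ("Met", "CAT", "initiator"),
    ("Sec", "TCA", "selenocysteine"),
)

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Sec": "U",
}


@dataclass(frozen=True)
class AnticodonRepertoire:
    """A set of anticodon families for one organism/compartment."""

    families: tuple[AnticodonFamily, ...]
    source_label: str = "default"

    def __post_init__(self) -> None:
        keys = [(f.cls, f.amino_acid, f.anticodon) for f in self.families]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate anticodon family in repertoire")

    @property
    def elongators(self) -> tuple[AnticodonFamily, ...]:
        return tuple(f for f in self.families if f.cls == "elongator")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f.label for f in self.families)

    @classmethod
    def from_tsv(cls, path: str | Path, source_label: str | None = None) -> "AnticodonRepertoire":
        """Load a repertoire from a TSV with columns amino_acid, anticodon, class."""
        df = pd.read_csv(path, sep="\t")
        required = {"amino_acid", "anticodon", "class"}
        if not required.issubset(df.columns):
            raise ValueError(f"repertoire TSV needs columns {sorted(required)}")
        fams = tuple(
            AnticodonFamily(str(aa), str(ac).upper().replace("U", "T"), str(cls))
            for aa, ac, cls in zip(df["amino_acid"], df["anticodon"], df["class"])
        )
        return cls(fams, source_label or str(path))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(f.amino_acid, f.anticodon, f.cls) for f in self.families],
            columns=["amino_acid", "anticodon", "class"],
        ).to_csv(path, sep="\t", index=False)


def default_repertoire() -> AnticodonRepertoire:
    """The built-in 47-family cytosolic repertoire."""
    return AnticodonRepertoire(
        tuple(AnticodonFamily(aa, ac, cls) for aa, ac, cls in _DEFAULT_FAMILIES),
        source_label="builtin-cytosolic-47",
    )


WATSON_CRICK = "watson_crick"
WOBBLE = "wobble"


@dataclass(frozen=True)
class CodonDecodingMap:
    """Assignment of every sense codon to one anticodon family.

    ``assignments`` maps codon → (family label, pairing); ``wobble_pairs``
    lists (family label, watson_crick codon, wobble codon) triples of
    synonymous codons sharing a family.
    """

    assignments: Mapping[str, tuple[str, str]]
    wobble_pairs: tuple[tuple[str, str, str], ...]
    repertoire: AnticodonRepertoire = field(default_factory=default_repertoire)

    def family(self, codon: str) -> str:
        return self.assignments[codon][0]

    def pairing(self, codon: str) -> str:
        return self.assignments[codon][1]

    @property
    def inosine_pairs(self) -> tuple[tuple[str, str, str], ...]:
        """Wobble pairs whose family has A (inosine in vivo) at position 34."""
        return tuple(p for p in self.wobble_pairs if p[0].split("-")[1].startswith("A"))

    def to_frame(self, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
        rows = [
            (codon, code.amino_acid(codon), fam.split("-", 1)[1], fam, pairing)
            for codon, (fam, pairing) in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["codon", "amino_acid", "anticodon", "family", "pairing"])

    def to_tsv(self, path: str | Path, code: GeneticCode = STANDARD_CODE) -> None:
        self.to_frame(code).to_csv(path, sep="\t", index=False)


def build_decoding_map(
    repertoire: AnticodonRepertoire | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> CodonDecodingMap:
    """Assign each sense codon to a family by Watson-Crick or wobble pairing.

    Watson-Crick: the codon equals the reverse complement of the family's
    anticodon.  Wobble duplication: a G34 family also reads the T-ending
    synonym of its C-ending codon, an A34 family also reads the C-ending
    synonym of its T-ending codon.  Initiator Met and Sec never decode sense
    codons (elongator Met-CAT reads ATG).
    """
    repertoire = repertoire or default_repertoire()
    assignments: dict[str, tuple[str, str]] = {}
    wc_family_of: dict[str, AnticodonFamily] = {}

    for fam in repertoire.elongators:
        codon = reverse_complement(fam.anticodon)
        if codon in code.stop_set:
            raise ValueError(f"elongator family {fam.label} decodes a stop codon")
        expected = _AA3_TO_1.get(fam.amino_acid, fam.amino_acid)
        if code.amino_acid(codon) != expected:
            raise ValueError(f"family {fam.label} is not synonymous with codon {codon}")
        if codon in assignments:
            raise ValueError(f"codon {codon} claimed by two families")
        assignments[codon] = (fam.label, WATSON_CRICK)
        wc_family_of[codon] = fam

    wobble_pairs: list[tuple[str, str, str]] = []
    for codon in code.sense_codons:
        if codon in assignments:
            continue
        fam = None
        if codon.endswith("T"):
            partner = codon[:2] + "C"
            cand = wc_family_of.get(partner)
            if cand is not None and cand.anticodon.startswith("G"):
                fam, wc_codon = cand, partner
        elif codon.endswith("C"):
            partner = codon[:2] + "T"
            cand = wc_family_of.get(partner)
            if cand is not None and cand.anticodon.startswith("A"):
                fam, wc_codon = cand, partner
        if fam is None:
            continue
        if code.amino_acid(codon) != code.amino_acid(wc_codon):
            continue  # wobble partners must be synonymous
        assignments[codon] = (fam.label, WOBBLE)
        wobble_pairs.append((fam.label, wc_codon, codon))

    uncovered = sorted(set(code.sense_codons) - set(assignments))
    if uncovered:
        raise ValueError(f"repertoire leaves sense codons uncovered: {', '.join(uncovered)}")

    return CodonDecodingMap(assignments, tuple(sorted(wobble_pairs)), repertoire)


def classify_codon_gc(codon: str, code: GeneticCode = STANDARD_CODE) -> tuple[bool, float]:
    """Return (GC3 flag, GC fraction) for a sense codon."""
    if len(codon) != 3 or any(b not in NUCLEOTIDES for b in codon):
        raise ValueError(f"malformed codon {codon!r}")
    if codon in code.stop_set:
        raise ValueError(f"stop codon {codon} has no GC3 class here")
    gc3 = codon[2] in "GC"
    gc_percent = sum(b in "GC" for b in codon) / 3
    return gc3, gc_percent


def read_cds_fasta(path: str | Path, code: GeneticCode = STANDARD_CODE) -> list[CodingSequence]:
    """Read a multi-record FASTA; record ID up to first whitespace is the transcript id."""
    return [validate_cds(rec.id, str(rec.seq), code) for rec in SeqIO.parse(str(path), "fasta")]
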