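"""Upstream translation-initiation sites and N-terminally extended proteoforms.

Ribosomes can initiate translation at near-cognate codons (one substitution
away from ATG) in a transcript's 5' leader. An in-frame near-cognate start
upstream of the database-annotated translation initiation site (dbTIS), with
no in-frame stop codon in between, yields an N-terminally extended proteoform
whose extra mass explains higher-molecular-weight precursor bands on a gel.
This module enumerates such candidate uTIS, translates the extension (the
initiator codon is decoded as Met regardless of identity, per initiator-tRNA
behaviour), predicts average-mass deltas (gel-apparent masses are average,
not monoisotopic), and builds disruption mutants that silence a chosen start
codon.

The default near-cognate set is the nine single-substitution neighbours of
ATG. Observed starts can sit further away (e.g. a TGG start, two edits from
ATG), so every scan takes an explicit codon set and reports refer to the set
used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as _product

from Bio.Seq import Seq
from pyteomics import mass as _pymass

from .io import AA_ALPHABET

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: the nine single-substitution neighbours of ATG
NEAR_COGNATE_CODONS = frozenset(
    {"CTG", "GTG", "TTG", "ACG", "AAG", "AGG", "ATA", "ATC", "ATT"}
)

WATER_AVERAGE_DA = 18.02


@dataclass(frozen=True)
class MrnaRecord:
    """An mRNA with its annotated start-codon position (1-based, first nt of ATG)."""

    accession: str
    sequence: str
    dbtis_pos: int

    def __post_init__(self) -> None:
        seq = self.sequence
        if set(seq) - set("ACGT"):
            raise ValueError(f"{self.accession}: sequence must be uppercase A/C/G/T")
        if not 1 <= self.dbtis_pos or self.dbtis_pos + 2 > len(seq):
            raise ValueError(f"{self.accession}: dbtis_pos {self.dbtis_pos} out of range")
        if self.codon_at(self.dbtis_pos) != START_CODON:
            raise ValueError(
                f"{self.accession}: dbTIS codon is {self.codon_at(self.dbtis_pos)}, not ATG"
            )

    def codon_at(self, pos: int) -> str:
        return self.sequence[pos - 1 : pos + 2]


@dataclass(frozen=True)
class UtisCandidate:
    pos: int
    codon: str
    offset_codons: int
    extension_peptide: str


@dataclass(frozen=True)
class Proteoform:
    label: str
    sequence: str
    average_mass_da: float
    delta_mass_da: float


def find_upstream_tis(
    mrna: MrnaRecord, codon_set: frozenset[str] | set[str] = NEAR_COGNATE_CODONS
) -> list[UtisCandidate]:
    """In-frame upstream candidate starts with no intervening in-frame stop.

    Walks the dbTIS reading frame 5'-ward; a candidate's codon must belong
    to ``codon_set`` and no stop codon may sit in frame strictly between the
    candidate and the dbTIS. Returned sorted 5' to 3'.
    """
    if not codon_set:
        raise ValueError("codon_set must be non-empty")
    candidates = []
    for pos in range(mrna.dbtis_pos - 3, 0, -3):
        codon = mrna.codon_at(pos)
        if codon in codon_set and not _stop_between(mrna, pos):
            offset = (mrna.dbtis_pos - pos) // 3
            candidates.append(
                UtisCandidate(pos, codon, offset, extension_peptide_at(mrna, pos))
            )
    return sorted(candidates, key=lambda c: c.pos)


def _stop_between(mrna: MrnaRecord, pos: int) -> bool:
    return any(
        mrna.codon_at(p) in STOP_CODONS for p in range(pos + 3, mrna.dbtis_pos, 3)
    )


def extension_peptide_at(mrna: MrnaRecord, pos: int) -> str:
    """Translate codons from ``pos`` up to (not including) the dbTIS.

    The initiator codon is decoded as Met regardless of identity.
    """
    ext_nt = mrna.sequence[pos - 1 : mrna.dbtis_pos - 1]
    if len(ext_nt) % 3:
        raise ValueError(f"position {pos} is not in the dbTIS reading frame")
    aa = str(Seq(ext_nt).translate())
    if "*" in aa:
        raise AssertionError("in-frame stop inside a validated extension")
    return "M" + aa[1:]


def extension_peptide(mrna: MrnaRecord, utis: UtisCandidate) -> str:
    return extension_peptide_at(mrna, utis.pos)


def average_mass(peptide: str) -> float:
    """Average molecular mass of a peptide in daltons (residues + one water).

    Additive up to one water per peptide bond formed:
    mass(A + B) = mass(A) + mass(B) - 18.02.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - AA_ALPHABET
    if bad:
        raise ValueError(f"unknown residue letters: {sorted(bad)}")
    return float(_pymass.calculate_mass(sequence=peptide, average=True))


def enumerate_proteoforms(
    mrna: MrnaRecord,
    protein_seq: str,
    codon_set: frozenset[str] | set[str] = NEAR_COGNATE_CODONS,
) -> list[Proteoform]:
    """The dbTIS proteoform plus one N-terminally extended form per uTIS candidate.

    ``protein_seq`` is the dbTIS-initiated protein (caller-asserted, Met
    first). Each candidate contributes extension + protein (the dbTIS Met is
    retained; the extension abuts it). Sorted by descending extension
    length, dbTIS form last.
    """
    if not protein_seq.startswith("M"):
        raise ValueError("dbTIS-initiated protein sequence must start with Met")
    base_mass = average_mass(protein_seq)
    forms = [Proteoform("dbTIS", protein_seq, base_mass, 0.0)]
    for cand in find_upstream_tis(mrna, codon_set):
        seq = cand.extension_peptide + protein_seq
        m = average_mass(seq)
        forms.append(
            Proteoform(
                f"uTIS@{cand.pos}({cand.codon.lower()})", seq, m, m - base_mass
            )
        )
    return sorted(forms, key=lambda f: len(f.sequence), reverse=True)


def disrupt_tis(
    mrna: MrnaRecord,
    pos: int,
    codon_set: frozenset[str] | set[str] = NEAR_COGNATE_CODONS,
    allow_dbtis: bool = False,
) -> MrnaRecord:
    """Replace the codon at ``pos`` so it can no longer initiate translation.

    ``pos`` must host a current uTIS candidate — or the dbTIS itself, which
    is only mutable when ``allow_dbtis`` is set (mirrors deliberate
    initiator-Met knockouts; the record is then re-annotated to the next
    in-frame downstream ATG). The replacement codon is >= 2 substitutions
    from ATG, outside ``codon_set``, and not a stop codon (which would
    truncate upstream-initiated frames); candidates are tried in a fixed
    lexicographic order, so the result is deterministic.
    """
    is_dbtis = pos == mrna.dbtis_pos
    if is_dbtis and not allow_dbtis:
        raise ValueError("refusing to disrupt the annotated start codon (set allow_dbtis=True)")
    if not is_dbtis:
        current = {c.pos for c in find_upstream_tis(mrna, codon_set)}
        if pos not in current:
            raise ValueError(f"position {pos} hosts no current uTIS candidate")
    for repl in ("".join(c) for c in _product("ACGT", repeat=3)):
        hamming = sum(a != b for a, b in zip(repl, START_CODON))
        if hamming < 2 or repl in codon_set or repl in STOP_CODONS:
            continue
        seq = mrna.sequence[: pos - 1] + repl + mrna.sequence[pos + 2 :]
        new_dbtis = mrna.dbtis_pos
        if is_dbtis:
            downstream = [
                p
                for p in range(mrna.dbtis_pos + 3, len(seq) - 1, 3)
                if seq[p - 1 : p + 2] == START_CODON
            ]
            if not downstream:
                raise ValueError("dbTIS knockout leaves no in-frame downstream ATG")
            new_dbtis = downstream[0]
        try:
            return MrnaRecord(mrna.accession, seq, new_dbtis)
        except ValueError:
            continue
    raise ValueError(f"no admissible replacement codon at position {pos}")
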