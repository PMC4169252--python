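"""Cleavage-site annotation: Schechter–Berger windows, motif scanning,
murinization variants and protease-specific assignment.

Convention throughout: the observed neo-N-terminal peptide's first residue is
the P1' residue, so the cleavage site's P1 position is ``neo_start - 1``
(granzyme B cleaves C-terminal to Asp; e.g. cleavage after the P4–P1
tetrapeptide IEAD leaves Ile at P4 four residues upstream of the scissile
bond). Substrate residues N-terminal to the scissile bond are labelled
P1, P2, ... walking away from the bond; C-terminal residues are P1', P2', ...
Windows past a protein terminus are padded with ``'-'``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import AA_ALPHABET, ProteinRecord, _round_half_away


@dataclass(frozen=True)
class CleavageSite:
    """A scissile bond: P1 residue index (1-based) in a database protein."""

    protein_acc: str
    p1_pos: int

    def __post_init__(self) -> None:
        if self.p1_pos < 1:
            raise ValueError(f"p1_pos must be >= 1, got {self.p1_pos}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.protein_acc, self.p1_pos)


@dataclass(frozen=True)
class SiteWindow:
    """P_n..P1 and P1'..P_n' context strings, '-'-padded past the termini."""

    nonprime: str
    prime: str
    n: int = 10

    def __post_init__(self) -> None:
        if len(self.nonprime) != self.n or len(self.prime) != self.n:
            raise ValueError("window strings must both have length n")

    def core(self) -> str:
        """The padding-free protein substring spanning the window."""
        return self.nonprime.lstrip("-") + self.prime.rstrip("-")


@dataclass(frozen=True)
class PrimedSiteMutation:
    """A point substitution, e.g. the P1' murinization I29>T of human BNIP-2."""

    pos: int
    from_aa: str
    to_aa: str
    label: str = ""

    def __post_init__(self) -> None:
        if self.from_aa == self.to_aa:
            raise ValueError("from_aa and to_aa must differ")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    def inverse(self) -> "PrimedSiteMutation":
        return PrimedSiteMutation(self.pos, self.to_aa, self.from_aa, self.label)


def validate_site(protein: ProteinRecord, site: CleavageSite) -> None:
    if site.p1_pos >= len(protein):
        raise ValueError(
            f"{site.protein_acc}: P1 at {site.p1_pos} leaves no bond to cleave "
            f"(protein length {len(protein)})"
        )


def site_from_neo(protein: ProteinRecord, neo_start: int) -> CleavageSite:
    """Cleavage site implied by a neo-N-terminus starting at ``neo_start`` (its P1')."""
    if neo_start <= 1:
        raise ValueError(f"neo_start must be >= 2 (no bond upstream of residue {neo_start})")
    site = CleavageSite(protein.accession, neo_start - 1)
    validate_site(protein, site)
    return site


def site_window(protein: ProteinRecord, site: CleavageSite, n: int = 10) -> SiteWindow:
    """Extract the P_n–P_n' sequence context around the scissile bond."""
    validate_site(protein, site)
    seq, p1 = protein.sequence, site.p1_pos
    lo = max(p1 - n, 0)
    nonprime = seq[lo:p1].rjust(n, "-")
    prime = seq[p1 : p1 + n].ljust(n, "-")
    return SiteWindow(nonprime, prime, n)


def scan_tetrapeptide(protein: ProteinRecord, motif: str) -> list[CleavageSite]:
    """All cleavage sites whose P4–P1 equals ``motif`` (P1 = last motif residue).

    A site requires a bond C-terminal to P1, so a motif ending at the very
    last residue is not reported.
    """
    if len(motif) != 4 or set(motif) - AA_ALPHABET:
        raise ValueError(f"motif must be a 4-letter amino-acid string, got {motif!r}")
    sites = []
    start = protein.sequence.find(motif)
    while start != -1:
        p1 = start + 4  # 1-based index of the motif's last residue
        if p1 < len(protein):
            sites.append(CleavageSite(protein.accession, p1))
        start = protein.sequence.find(motif, start + 1)
    return sites


def primed_label(site: CleavageSite, pos: int) -> str:
    """Schechter–Berger label of residue ``pos`` relative to the site's P1."""
    if pos < 1:
        raise ValueError("pos must be >= 1")
    if pos <= site.p1_pos:
        return f"P{site.p1_pos - pos + 1}"
    return f"P{pos - site.p1_pos}′"


def apply_mutations(
    protein: ProteinRecord, muts: Sequence[PrimedSiteMutation]
) -> ProteinRecord:
    """Apply point substitutions, validating the observed residue at each position.

    A mismatch between ``from_aa`` and the residue found raises with the
    position and observed residue named, guarding against off-by-one
    numbering conventions. Applying the inverse list restores the original.
    """
    seq = list(protein.sequence)
    for m in muts:
        if m.pos > len(seq):
            raise ValueError(f"mutation position {m.pos} beyond protein length {len(seq)}")
        found = seq[m.pos - 1]
        if found != m.from_aa:
            raise ValueError(
                f"{protein.accession} position {m.pos}: expected {m.from_aa}, found {found}"
            )
        seq[m.pos - 1] = m.to_aa
    return ProteinRecord(protein.accession, protein.description, "".join(seq))


def assign_protease_specific(
    neo_sites: Iterable[CleavageSite], reference: Iterable[CleavageSite]
) -> dict[str, set[CleavageSite]]:
    """Split neo sites into protease-specific (present in a reference
    compilation of cleavage events) and unmatched, keyed on (accession, P1)."""
    neo = set(neo_sites)
    ref_keys = {s.key for s in reference}
    specific = {s for s in neo if s.key in ref_keys}
    return {"specific": specific, "unmatched": neo - specific}


def cleave_peptide(peptide: str, cut_after: int) -> tuple[str, str]:
    """Split a peptide at the scissile bond after residue ``cut_after``."""
    if not 1 <= cut_after < len(peptide):
        raise ValueError(
            f"cut_after must lie in [1, {len(peptide) - 1}], got {cut_after}"
        )
    return peptide[:cut_after], peptide[cut_after:]


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner

#: alignment scoring reported with every identity figure, since percent
#: identity depends on the alignment produced
ALIGNMENT_PARAMS = {
    "mode": "global",
    "substitution_matrix": "BLOSUM62",
    "open_gap_score": -10.0,
    "extend_gap_score": -0.5,
    "denominator": "alignment length",
}


def pairwise_identity(seq1: str, seq2: str) -> tuple[int, int]:
    """Percent identity and percent similarity under a global alignment.

    The alignment itself uses BLOSUM62 with affine gaps (open -10,
    extend -0.5). Identity = identical columns / alignment length x 100,
    rounded half-away-from-zero to an integer. Similarity additionally
    counts positive-scoring (BLOSUM62 > 0) substitutions. Both percentages
    use the full alignment length (gap columns included) as denominator.
    """
    if not seq1 or not seq2:
        raise ValueError("both sequences must be non-empty")
    aln = _global_aligner().align(seq1, seq2)[0]
    a, b = str(aln[0]), str(aln[1])
    matrix = substitution_matrices.load("BLOSUM62")
    n_cols = len(a)
    n_ident = sum(x == y and x != "-" for x, y in zip(a, b))
    n_similar = sum(
        x != "-" and y != "-" and matrix[x, y] > 0 for x, y in zip(a, b)
    )
    def pct(k: int) -> int:
        return _round_half_away(100.0 * k / n_cols)

    return pct(n_ident), pct(n_similar)
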