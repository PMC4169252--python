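"""Data model and I/O for SILAC N-terminome tables and protein databases.

A COFRADIC N-terminomics experiment yields one row per identified N-terminal
peptide: its sequence, the database protein it maps to, the 1-based start
position of its first residue in that protein, the chemical state of its
alpha-amine, and two log2 SILAC ratios encoding abundance changes across the
three protease-incubation time points. The triage rule sorts these peptides
into database-annotated protein starts, protease-generated neo-N-termini, and
putative alternative translation-initiation events, using only the start
position and the N-terminal modification:

* in-vivo acetyl or in-vitro trideuteroacetyl at position 1 or 2 -> the
  annotated protein start (initiator Met retained or removed);
* trideuteroacetyl at position > 2 -> a free alpha-amine existed in the
  lysate, i.e. a proteolytic neo-N-terminus;
* in-vivo acetyl at position > 2 -> co-translational acetylation of an
  internal start, i.e. alternative translation initiation.

A free (unmodified) alpha-amine cannot survive the COFRADIC chemistry, so it
is rejected as malformed input rather than triaged.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: exact TSV tokens for the N-terminal modification column
MOD_TOKENS = {"acetyl": "acetyl", "d3-acetyl": "trideuteroacetyl", "free": "free"}
MOD_TOKENS_INV = {v: k for k, v in MOD_TOKENS.items()}

PEPTIDE_COLUMNS = [
    "peptide_id",
    "sequence",
    "protein_acc",
    "start_pos",
    "nterm_mod",
    "log2_ratio_a",
    "log2_ratio_b",
]


class NTermMod(str, enum.Enum):
    """Alpha-amine state of an identified N-terminal peptide."""

    ACETYL = "acetyl"
    TRIDEUTEROACETYL = "trideuteroacetyl"
    FREE = "free"


class TriageCategory(str, enum.Enum):
    ANNOTATED_START = "annotated_start"
    PROTEOLYTIC_NEO = "proteolytic_neo"
    ALT_INITIATION = "alt_initiation"


@dataclass(frozen=True)
class NTermPeptide:
    """One identified N-terminal peptide.

    ``ratio_a`` is the log2 abundance ratio of the second vs first time point,
    ``ratio_b`` of the third vs second; ``None`` marks a ratio that could not
    be calculated (never silently 0).
    """

    peptide_id: str
    sequence: str
    protein_acc: str
    start_pos: int
    nterm_mod: NTermMod
    ratio_a: float | None = None
    ratio_b: float | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.peptide_id}: empty peptide sequence")
        if self.start_pos < 1:
            raise ValueError(
                f"{self.peptide_id}: start_pos must be >= 1, got {self.start_pos}"
            )
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.peptide_id}: non-standard residues {sorted(bad)}"
            )
        for name in ("ratio_a", "ratio_b"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise ValueError(f"{self.peptide_id}: non-finite {name}")

    @property
    def has_ratios(self) -> bool:
        return self.ratio_a is not None and self.ratio_b is not None


@dataclass(frozen=True)
class LabelingDesign:
    """Three-channel SILAC time-course design.

    Default: light / medium (13C6) / heavy (13C6 15N4) arginine channels
    encode 10, 30 and 60 min of protease incubation; the two ratio axes are
    time point 2 vs 1 and 3 vs 2.
    """

    time_points: tuple[float, float, float] = (10.0, 30.0, 60.0)
    channel_labels: tuple[str, str, str] = ("light", "medium", "heavy")
    ratio_axes: tuple[tuple[int, int], tuple[int, int]] = ((2, 1), (3, 2))

    def __post_init__(self) -> None:
        t = self.time_points
        if not (0 < t[0] < t[1] < t[2]):
            raise ValueError(f"time points must be positive and strictly increasing: {t}")
        for late, early in self.ratio_axes:
            if not {late, early} <= {1, 2, 3}:
                raise ValueError(f"ratio axis ({late}/{early}) references invalid time point")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein database entry (FASTA carrier)."""

    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty protein sequence")

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# triage

def triage_nterm(p: NTermPeptide) -> TriageCategory:
    """Classify one N-terminal peptide by start position and alpha-amine state.

    Raises ``ValueError`` for a free alpha-amine: the in-vitro
    trideuteroacetylation step labels every free amine, so an unlabeled
    N-terminus indicates malformed input.
    """
    if p.nterm_mod is NTermMod.FREE:
        raise ValueError(
            f"{p.peptide_id}: unlabeled alpha-amine (nterm_mod='free') — "
            "COFRADIC chemistry trideuteroacetylates all free amines in vitro"
        )
    if p.start_pos in (1, 2):
        return TriageCategory.ANNOTATED_START
    if p.nterm_mod is NTermMod.TRIDEUTEROACETYL:
        return TriageCategory.PROTEOLYTIC_NEO
    return TriageCategory.ALT_INITIATION


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class TriageSummary:
    counts: dict[TriageCategory, int]
    fractions: dict[TriageCategory, float]
    percentages: dict[TriageCategory, int]
    total: int
    n_missing_ratios: int = 0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "n_missing_ratios": self.n_missing_ratios,
            "categories": {
                c.value: {
                    "count": self.counts[c],
                    "fraction": self.fractions[c],
                    "percent": self.percentages[c],
                }
                for c in TriageCategory
            },
        }


def summarize_triage(table: Sequence[NTermPeptide]) -> TriageSummary:
    """Triage every peptide and tabulate counts, raw fractions and integer percentages.

    Percentages are rounded half-away-from-zero; the raw fraction is always
    retained alongside, since rounded percentages need not sum to 100.
    Peptides lacking either ratio are still triaged (ratios play no role in
    the rule) but their number is counted and logged, because they are
    excluded downstream from null fitting and efficiency classification.
    """
    if not table:
        raise ValueError("cannot summarize an empty peptide table")
    counts = {c: 0 for c in TriageCategory}
    n_missing = 0
    for p in table:
        counts[triage_nterm(p)] += 1
        if not p.has_ratios:
            n_missing += 1
    total = len(table)
    if n_missing:
        logger.info("%d of %d peptides lack a complete ratio pair", n_missing, total)
    fractions = {c: counts[c] / total for c in TriageCategory}
    percentages = {c: _round_half_away(100.0 * fractions[c]) for c in TriageCategory}
    return TriageSummary(counts, fractions, percentages, total, n_missing)


def locate_peptide(protein: ProteinRecord, peptide_seq: str) -> list[int]:
    """All 1-based start positions of ``peptide_seq`` in the protein (overlaps included)."""
    if not peptide_seq:
        return []
    hits: list[int] = []
    start = protein.sequence.find(peptide_seq)
    while start != -1:
        hits.append(start + 1)
        start = protein.sequence.find(peptide_seq, start + 1)
    return hits


def resolve_redundancy(candidate_descriptions: Iterable[str]) -> tuple[str, list[str]]:
    """Pick the reported protein entry among identically-matching candidates.

    The chosen description is the alphabetically first (case-insensitive,
    ties broken case-sensitively); the remainder is returned sorted, to be
    reported as isoforms.
    """
    cands = set(candidate_descriptions)
    if not cands:
        raise ValueError("no candidate descriptions to resolve")
    key = lambda s: (s.casefold(), s)
    chosen = min(cands, key=key)
    rest = sorted(cands - {chosen}, key=key)
    return chosen, rest


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in seen:
            raise ValueError(f"duplicate accession in FASTA: {acc}")
        seen.add(acc)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(ProteinRecord(acc, desc, str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# peptide tables

def peptides_to_frame(peptides: Sequence[NTermPeptide]) -> pd.DataFrame:
    rows = [
        {
            "peptide_id": p.peptide_id,
            "sequence": p.sequence,
            "protein_acc": p.protein_acc,
            "start_pos": p.start_pos,
            "nterm_mod": MOD_TOKENS_INV[p.nterm_mod.value],
            "log2_ratio_a": p.ratio_a,
            "log2_ratio_b": p.ratio_b,
        }
        for p in peptides
    ]
    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def frame_to_peptides(df: pd.DataFrame) -> list[NTermPeptide]:
    missing = set(PEPTIDE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    peptides = []
    for row in df.itertuples(index=False):
        tok = str(row.nterm_mod)
        if tok not in MOD_TOKENS:
            raise ValueError(
                f"{row.peptide_id}: unknown nterm_mod token {tok!r} "
                f"(expected one of {sorted(MOD_TOKENS)})"
            )
        ra = None if pd.isna(row.log2_ratio_a) else float(row.log2_ratio_a)
        rb = None if pd.isna(row.log2_ratio_b) else float(row.log2_ratio_b)
        peptides.append(
            NTermPeptide(
                peptide_id=str(row.peptide_id),
                sequence=str(row.sequence),
                protein_acc=str(row.protein_acc),
                start_pos=int(row.start_pos),
                nterm_mod=NTermMod(MOD_TOKENS[tok]),
                ratio_a=ra,
                ratio_b=rb,
            )
        )
    return peptides


def read_peptide_table(path: str | Path) -> list[NTermPeptide]:
    """Read a tab-separated peptide table (empty ratio cell = missing)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"peptide_id": str, "protein_acc": str},
        float_precision="round_trip",
    )
    return frame_to_peptides(df)


def write_peptide_table(peptides: Sequence[NTermPeptide], path: str | Path) -> None:
    df = peptides_to_frame(peptides)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_triage_report(summary: TriageSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
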