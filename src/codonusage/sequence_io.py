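"""Reading, validating and decomposing coding sequences from FASTA.

A coding sequence (CDS) is handled as an in-frame string over {A,C,G,T} whose
length is a multiple of three; RNA input (U) is accepted and mapped to T, and
case is normalized. The terminal stop codon, when present, stays in the
sequence: nucleotide-level statistics run on the whole coding sequence, while
codon-level statistics (RSCU, ENC, amino-acid frequencies) exclude stops
downstream.

Validation separates hard errors (empty record, length not a multiple of 3)
from warnings (non-ACGT characters, internal stop codons), because annotated
CDS pulled from genome databases occasionally carry either without being
useless for composition statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import GeneticCode, standard_code

logger = logging.getLogger(__name__)

ACGT = frozenset("ACGT")

Strictness = Literal["strict", "lenient"]

#: Issue codes, ordered by severity.
ERROR_CODES = frozenset({"EMPTY", "NOT_MULTIPLE_OF_3"})
WARNING_CODES = frozenset({"NON_ACGT", "INTERNAL_STOP"})


def normalize_sequence(raw: str) -> str:
    """Uppercase and map U to T (RNA input accepted)."""
    return raw.strip().upper().replace("U", "T")


@dataclass(frozen=True)
class CodingSequence:
    """One in-frame coding sequence with its codon decomposition.

    ``species`` is parsed from the FASTA description (text after the first
    whitespace) when available, else it equals ``id``.
    """

    id: str
    species: str
    sequence: str
    codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        if len(self.sequence) % 3 != 0:
            raise ValueError(
                f"{self.id}: length {len(self.sequence)} is not a multiple of 3"
            )
        object.__setattr__(
            self,
            "codons",
            tuple(
                self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)
            ),
        )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ValidationIssue:
    code: str
    message: str

    @property
    def is_warning(self) -> bool:
        return self.code in WARNING_CODES


@dataclass(frozen=True)
class ValidationReport:
    issues: tuple[ValidationIssue, ...]

    @property
    def ok(self) -> bool:
        """True when every issue is a warning (or there are none)."""
        return all(issue.is_warning for issue in self.issues)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(issue.code for issue in self.issues)


@dataclass(frozen=True)
class CodonCountTable:
    """Codon counts over all 64 codons for one gene.

    Codons containing any non-ACGT character are excluded from ``counts`` and
    tallied in ``n_ambiguous``; for clean input 3 x total_codons equals the
    sequence length.
    """

    counts: Mapping[str, int]
    n_ambiguous: int = 0

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())


def validate_raw(seq_id: str, sequence: str, code: GeneticCode | None = None) -> ValidationReport:
    """Validate an already-normalized sequence string."""
    code = code or standard_code()
    issues: list[ValidationIssue] = []
    if not sequence:
        issues.append(ValidationIssue("EMPTY", f"{seq_id}: empty sequence"))
        return ValidationReport(tuple(issues))
    if len(sequence) % 3 != 0:
        issues.append(
            ValidationIssue(
                "NOT_MULTIPLE_OF_3",
                f"{seq_id}: length {len(sequence)} is not a multiple of 3",
            )
        )
    bad = sorted(set(sequence) - ACGT)
    if bad:
        issues.append(
            ValidationIssue(
                "NON_ACGT", f"{seq_id}: non-ACGT characters {''.join(bad)}"
            )
        )
    # Internal stops are only assessable on a whole number of codons.
    if len(sequence) % 3 == 0:
        codons = [sequence[i : i + 3] for i in range(0, len(sequence), 3)]
        internal = [
            (i + 1, c) for i, c in enumerate(codons[:-1]) if code.is_stop(c)
        ]
        if internal:
            pos, codon = internal[0]
            issues.append(
                ValidationIssue(
                    "INTERNAL_STOP",
                    f"{seq_id}: internal stop codon {codon} at codon {pos} "
                    f"({len(internal)} total)",
                )
            )
    return ValidationReport(tuple(issues))


def validate_cds(seq: CodingSequence, code: GeneticCode | None = None) -> ValidationReport:
    """Validate a parsed coding sequence (reports, never raises)."""
    return validate_raw(seq.id, seq.sequence, code)


def read_cds_fasta(
    path: str | Path, strictness: Strictness = "lenient"
) -> list[CodingSequence]:
    """Read a multi-record FASTA of coding sequences.

    In lenient mode a trailing incomplete triplet is trimmed with a logged
    warning and non-ACGT characters are tolerated (downstream codon counting
    skips the affected codons). In strict mode either condition is an error
    naming the record and issue code.

    Raises
    ------
    ValueError
        On a strict-mode validation failure, or when no valid record remains.
    OSError
        When the file cannot be read.
    """
    if strictness not in ("strict", "lenient"):
        raise ValueError(f"unknown strictness {strictness!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    out: list[CodingSequence] = []
    for rec in records:
        seq = normalize_sequence(str(rec.seq))
        report = validate_raw(rec.id, seq)
        hard = [i for i in report.issues if not i.is_warning]
        if strictness == "strict":
            bad = hard or [i for i in report.issues if i.code == "NON_ACGT"]
            if bad:
                raise ValueError(f"record {rec.id!r}: {bad[0].code}: {bad[0].message}")
        else:
            if any(i.code == "NOT_MULTIPLE_OF_3" for i in hard):
                trimmed = len(seq) % 3
                logger.warning(
                    "record %s: trimming %d trailing nucleotide(s) to frame",
                    rec.id,
                    trimmed,
                )
                seq = seq[: len(seq) - trimmed]
            if not seq:
                logger.warning("record %s: empty after normalization, skipped", rec.id)
                continue
        species = species_from_description(rec.id, rec.description)
        out.append(CodingSequence(id=rec.id, species=species, sequence=seq))
    if not out:
        raise ValueError(f"{path}: no valid coding sequences found")
    return out


def species_from_description(rec_id: str, description: str) -> str:
    """NCBI-style defline convention: species = text after the first whitespace."""
    parts = description.split(None, 1)
    if len(parts) == 2 and parts[0] == rec_id:
        return parts[1].strip()
    return rec_id


def write_cds_fasta(seqs: Iterable[CodingSequence], path: str | Path) -> None:
    """Write coding sequences back to FASTA (id + species on the defline)."""
    records = []
    for s in seqs:
        desc = s.species if s.species != s.id else ""
        records.append(SeqRecord(Seq(s.sequence), id=s.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def count_codons(seq: CodingSequence) -> CodonCountTable:
    """Tally codons over all 64 ACGT triplets; ambiguous codons are set aside."""
    counts = {c: 0 for c in standard_code().sense_codons}
    for stop in standard_code().stop_codons:
        counts[stop] = 0
    ambiguous = 0
    for codon in seq.codons:
        if set(codon) <= ACGT:
            counts[codon] += 1
        else:
            ambiguous += 1
    return CodonCountTable(counts=counts, n_ambiguous=ambiguous)


def amino_acid_frequencies(
    seq_or_counts: CodingSequence | CodonCountTable, code: GeneticCode | None = None
) -> dict[str, float]:
    """Amino-acid usage frequencies over the 20 canonical amino acids.

    Stop codons are excluded; the result always has exactly 20 entries summing
    to 1 (absent amino acids get 0).

    Raises
    ------
    ValueError
        If the sequence contains no sense codon.
    """
    code = code or standard_code()
    counts = (
        seq_or_counts
        if isinstance(seq_or_counts, CodonCountTable)
        else count_codons(seq_or_counts)
    )
    aa_counts = {aa: 0 for aa in code.family_of}
    for codon, n in counts.counts.items():
        if not code.is_stop(codon):
            aa_counts[code.codon_to_aa[codon]] += n
    total = sum(aa_counts.values())
    if total == 0:
        raise ValueError("no sense codons: amino-acid frequencies undefined")
    return {aa: aa_counts[aa] / total for aa in sorted(aa_counts)}
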