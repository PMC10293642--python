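"""Reading, validating, and codon-splitting coding sequences.

A coding transcript is accepted when it has an in-frame reading frame:
length divisible by 3, ATG start, a terminal stop codon, and (under the
strict default policy) no internal stop. Transcripts are grouped by gene,
since all per-gene statistics are averages over a gene's transcripts.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .genetic_code import GeneticCode, STANDARD_CODE

logger = logging.getLogger(__name__)

_VALID_CHARS = re.compile(r"^[ACGT]+$")

#: default FASTA header convention: ``>gene|transcript_id ...``
DEFAULT_HEADER_RE = re.compile(r"^(?P<gene>[^|]+)\|(?P<transcript_id>\S+)")


@dataclass(frozen=True)
class CdsRecord:
    """One coding transcript: id, gene label, uppercase A/C/G/T sequence."""

    transcript_id: str
    gene: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ValidationResult:
    """Verdict of CDS validation with machine-readable reason codes."""

    valid: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.valid


@dataclass
class GeneSet:
    """Gene label → ordered list of transcripts.

    Transcript ids must be unique across the set and every gene must carry
    at least one transcript.
    """

    genes: dict[str, list[CdsRecord]] = field(default_factory=dict)

    def add(self, record: CdsRecord) -> None:
        if record.transcript_id in {r.transcript_id for r in self.all_records()}:
            raise ValueError(f"duplicate transcript id: {record.transcript_id}")
        self.genes.setdefault(record.gene, []).append(record)

    def all_records(self) -> Iterator[CdsRecord]:
        for recs in self.genes.values():
            yield from recs

    def __getitem__(self, gene: str) -> list[CdsRecord]:
        return self.genes[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(v) for v in self.genes.values())

    @classmethod
    def from_records(cls, records: Iterable[CdsRecord]) -> "GeneSet":
        gs = cls()
        for rec in records:
            gs.add(rec)
        if any(len(v) == 0 for v in gs.genes.values()):
            raise ValueError("every gene needs at least one transcript")
        return gs


def read_fasta(
    path: str | Path,
    header_re: re.Pattern | str = DEFAULT_HEADER_RE,
    tolerate_ambiguous: bool = False,
) -> list[CdsRecord]:
    """Read a multi-FASTA file into unvalidated :class:`CdsRecord` objects.

    Sequences are uppercased. The gene label and transcript id are parsed
    from the header with ``header_re`` (named groups ``gene`` and
    ``transcript_id``); headers that do not match use the full id as
    transcript id and gene label alike.

    Non-A/C/G/T characters raise :class:`ValueError` by default; with
    ``tolerate_ambiguous`` the offending record is dropped with a warning.
    """
    if isinstance(header_re, str):
        header_re = re.compile(header_re)
    records: list[CdsRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        m = header_re.match(entry.description)
        if m:
            gene = m.group("gene")
            tid = m.group("transcript_id")
        else:
            gene = tid = entry.id
        if not _VALID_CHARS.match(seq):
            if tolerate_ambiguous:
                logger.warning(
                    "dropping %s: non-ACGT characters in sequence", tid
                )
                continue
            raise ValueError(f"record {tid}: non-ACGT characters in sequence")
        records.append(CdsRecord(transcript_id=tid, gene=gene, sequence=seq))
    return records


def validate_cds(
    record: CdsRecord,
    code: GeneticCode = STANDARD_CODE,
    strict_internal_stop: bool = True,
) -> ValidationResult:
    """Check the reading-frame invariants of a coding transcript.

    Valid iff the sequence is ≥ 6 nt, length divisible by 3, starts with
    ATG, ends with a stop codon, and (if ``strict_internal_stop``) contains
    no internal stop codon.
    """
    seq = record.sequence
    reasons: list[str] = []
    if len(seq) % 3 != 0:
        reasons.append("length_not_multiple_of_3")
    if len(seq) < 6:
        reasons.append("too_short")
    if not reasons:
        codons = split_codons(record)
        if codons[0] != "ATG":
            reasons.append("no_ATG_start")
        if not code.is_stop(codons[-1]):
            reasons.append("no_terminal_stop")
        if strict_internal_stop and any(code.is_stop(c) for c in codons[:-1]):
            reasons.append("internal_stop")
    return ValidationResult(valid=not reasons, reasons=tuple(reasons))


def split_codons(record: CdsRecord) -> list[str]:
    """Split the sequence into its ordered codons (length must be a multiple of 3)."""
    seq = record.sequence
    if len(seq) % 3 != 0:
        raise ValueError(
            f"{record.transcript_id}: length {len(seq)} not divisible by 3"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def translate(
    record: CdsRecord,
    code: GeneticCode = STANDARD_CODE,
    strict_internal_stop: bool = True,
) -> str:
    """Translate a validated CDS, dropping the terminal stop codon."""
    codons = split_codons(record)
    if code.is_stop(codons[-1]):
        codons = codons[:-1]
    aas = []
    for i, c in enumerate(codons):
        if code.is_stop(c):
            if strict_internal_stop:
                raise ValueError(
                    f"{record.transcript_id}: internal stop at codon {i}"
                )
            break
        aas.append(code.codon_to_aa[c])
    return "".join(aas)


def read_manifest(
    manifest_path: str | Path,
    header_re: re.Pattern | str = DEFAULT_HEADER_RE,
) -> GeneSet:
    """Load a gene set from a TSV manifest (columns: gene, transcript_id, path).

    ``path`` is resolved relative to the manifest's directory; each FASTA is
    searched for the row's transcript id (matched against the parsed
    transcript id or the raw FASTA id).
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    cache: dict[Path, list[CdsRecord]] = {}
    gs = GeneSet()
    with open(manifest_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene", "transcript_id", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"manifest needs columns {sorted(required)}")
        for row in reader:
            fasta = (base / row["path"]).resolve()
            if fasta not in cache:
                cache[fasta] = read_fasta(fasta, header_re=header_re)
            matches = [
                r for r in cache[fasta] if r.transcript_id == row["transcript_id"]
            ]
            if not matches:
                raise ValueError(
                    f"transcript {row['transcript_id']} not found in {fasta}"
                )
            rec = matches[0]
            gs.add(
                CdsRecord(
                    transcript_id=rec.transcript_id,
                    gene=row["gene"],
                    sequence=rec.sequence,
                )
            )
    return gs


def write_gene_set(
    gene_set: GeneSet, fasta_path: str | Path, manifest_path: str | Path | None = None
) -> None:
    """Write a gene set as multi-FASTA (``>gene|transcript_id``) plus optional manifest."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        for gene in gene_set:
            for rec in gene_set[gene]:
                fh.write(f">{rec.gene}|{rec.transcript_id}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
    if manifest_path is not None:
        with open(manifest_path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene", "transcript_id", "path"])
            for gene in gene_set:
                for rec in gene_set[gene]:
                    writer.writerow([gene, rec.transcript_id, fasta_path.name])
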