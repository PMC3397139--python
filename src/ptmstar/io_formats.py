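"""Readers and writers for the file formats the predictor consumes and emits.

Supported formats:

* multi-record FASTA protein sequences (via Bio.SeqIO);
* AAindex1 flat files (``H``/``D``/``I`` records terminated by ``//``),
  the canonical distribution format for amino-acid physico-chemical scales;
* site-annotation tables (TSV: protein id, 1-based position, PTM type);
* prediction tables (TSV with vote sums, ensemble size, confidence and the
  n-star quality string).

Sequences are normalised to upper case over the 20 one-letter codes; any
other character (ambiguity codes such as B/Z/U, gaps, digits) is replaced by
``'X'`` and counted in a logged warning, so real proteomes pass through the
same code path as clean synthetic ones.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: canonical 20 one-letter amino-acid codes, alphabetical
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: alphabet accepted in ProteinRecord sequences ('X' = unknown/ambiguous)
ALPHABET = AMINO_ACIDS + "X"

# AAindex1 value rows follow the residue-pair key
# "A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V": first row of ten, then second.
AAINDEX_ROW1 = "ARNDCQEGHI"
AAINDEX_ROW2 = "LKMFPSTWYV"
AAINDEX_ORDER = AAINDEX_ROW1 + AAINDEX_ROW2


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier (FASTA header first token)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """One annotated PTM site: protein id, 1-based position, PTM type label."""

    protein_id: str
    position: int
    ptm_type: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"annotation {self.protein_id}:{self.position}: "
                "position must be >= 1 (1-based)"
            )


@dataclass(frozen=True)
class AminoAcidIndex:
    """A named physico-chemical scale: one real value per amino acid.

    ``values`` maps each of the 20 one-letter codes to a number.  The
    accession follows the 10-character AAindex convention (e.g. BLAM930101)
    but any non-empty token is accepted for synthetic collections.
    """

    accession: str
    description: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        extra = set(self.values) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"index {self.accession}: needs exactly the 20 residues "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def vector(self, order: str = AAINDEX_ORDER) -> list[float]:
        """Values as a list in the given residue order."""
        return [self.values[a] for a in order]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into ProteinRecords.

    Sequences are uppercased; characters outside the 20 amino-acid codes are
    replaced by 'X' (total replacements logged as one warning).  Raises
    ``ValueError`` for an empty file, an empty sequence, or duplicate ids.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        cleaned = []
        for ch in seq:
            if ch in ALPHABET:
                cleaned.append(ch)
            else:
                cleaned.append("X")
                n_replaced += 1
        records.append(ProteinRecord(id=rec.id, sequence="".join(cleaned)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if n_replaced:
        logger.warning(
            "read_fasta(%s): replaced %d non-standard residue(s) with 'X'",
            path, n_replaced,
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write ProteinRecords as FASTA (one record per protein)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# AAindex1 flat files


def read_aaindex1(
    path: str | Path, impute: bool = False
) -> list[AminoAcidIndex]:
    """Parse an AAindex1 flat file into AminoAcidIndex records.

    Records are delimited by ``//``; ``H`` carries the accession, ``D`` the
    description, and the ``I`` line is followed by two rows of ten values in
    the canonical A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V column order.

    ``NA`` entries raise ``ValueError`` naming the accession unless
    ``impute`` is set, in which case they are replaced by the mean of the
    index's defined values.
    """
    indices: list[AminoAcidIndex] = []
    accession = ""
    description_parts: list[str] = []
    tokens: list[str] = []
    in_values = False

    def finish() -> None:
        nonlocal accession, description_parts, tokens, in_values
        if not accession and not tokens:
            return
        if len(tokens) != 20:
            raise ValueError(
                f"AAindex record {accession or '<no accession>'}: "
                f"expected 20 values, found {len(tokens)}"
            )
        parsed: dict[str, float | None] = {}
        for residue, tok in zip(AAINDEX_ORDER, tokens):
            if tok.upper() == "NA":
                parsed[residue] = None
            else:
                try:
                    parsed[residue] = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"AAindex record {accession}: unparsable value "
                        f"{tok!r}"
                    ) from exc
        if any(v is None for v in parsed.values()):
            if not impute:
                raise ValueError(
                    f"AAindex record {accession}: contains NA values "
                    "(pass impute=True to mean-impute)"
                )
            defined = [v for v in parsed.values() if v is not None]
            if not defined:
                raise ValueError(
                    f"AAindex record {accession}: all values are NA"
                )
            fill = mean(defined)
            parsed = {k: (fill if v is None else v) for k, v in parsed.items()}
        indices.append(
            AminoAcidIndex(
                accession=accession,
                description=" ".join(description_parts),
                values={k: float(v) for k, v in parsed.items()},  # type: ignore[arg-type]
            )
        )
        accession = ""
        description_parts = []
        tokens = []
        in_values = False

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("//"):
                finish()
            elif line.startswith("H "):
                accession = line[2:].strip()
                in_values = False
            elif line.startswith("D "):
                description_parts.append(line[2:].strip())
                in_values = False
            elif line.startswith("I "):
                in_values = True  # next lines carry the two value rows
            elif in_values and line[:1] in (" ", "\t"):
                tokens.extend(line.split())
            elif line and not line[:1].isspace():
                in_values = False
    finish()  # tolerate a missing trailing //
    return indices


def write_aaindex1(
    indices: Iterable[AminoAcidIndex], path: str | Path
) -> None:
    """Write AminoAcidIndex records in AAindex1 flat-file format."""
    key_row = "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
    with open(path, "w") as fh:
        for idx in indices:
            fh.write(f"H {idx.accession}\n")
            fh.write(f"D {idx.description or idx.accession}\n")
            fh.write(key_row + "\n")
            row1 = "  ".join(f"{idx.values[a]:8.4f}" for a in AAINDEX_ROW1)
            row2 = "  ".join(f"{idx.values[a]:8.4f}" for a in AAINDEX_ROW2)
            fh.write(f"    {row1}\n    {row2}\n//\n")


# ---------------------------------------------------------------------------
# annotation tables


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a site-annotation TSV (protein_id, position, ptm_type).

    A header row is autodetected by a non-integer second column.  Positions
    are 1-based; a non-positive or non-integer position raises ``ValueError``
    with the offending line number.
    """
    annotations: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(row)}"
                )
            pid, pos_str, ptm = row[0].strip(), row[1].strip(), row[2].strip()
            if lineno == 1 and not _is_int(pos_str):
                continue  # header row
            if not _is_int(pos_str):
                raise ValueError(
                    f"{path}:{lineno}: position {pos_str!r} is not an integer"
                )
            position = int(pos_str)
            if position < 1:
                raise ValueError(
                    f"{path}:{lineno}: position {position} must be >= 1"
                )
            annotations.append(SiteAnnotation(pid, position, ptm))
    return annotations


def write_annotations(
    annotations: Iterable[SiteAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["protein_id", "position", "ptm_type"])
        for ann in annotations:
            writer.writerow([ann.protein_id, ann.position, ann.ptm_type])


def _is_int(token: str) -> bool:
    try:
        int(token)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# prediction output


def write_predictions(
    records: Sequence[tuple[str, int, str, int, int]], path: str | Path
) -> None:
    """Write consensus predictions as TSV.

    Each record is ``(protein_id, position, ptm_type, S_p, N)`` with
    ``S_p <= N``; the confidence column is the vote fraction S_p/N and the
    star column the quality string ``"{S_p}-star"``.  Rows are sorted by
    protein id then position for deterministic output.
    """
    rows = []
    for pid, pos, ptm, s_p, n_members in records:
        if s_p > n_members:
            raise ValueError(
                f"prediction {pid}:{pos}: S_p={s_p} exceeds N={n_members}"
            )
        rows.append((pid, pos, ptm, s_p, n_members))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["protein_id", "position", "ptm_type", "votes", "ensemble_size",
             "confidence", "star_quality"]
        )
        for pid, pos, ptm, s_p, n_members in rows:
            writer.writerow(
                [pid, pos, ptm, s_p, n_members,
                 f"{s_p / n_members:.6g}", f"{s_p}-star"]
            )
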