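"""Readers and writers for the external representations the tool touches.

Supported formats:

* FASTA sequence files (via Bio.SeqIO), canonicalized to RNA: ``T``/``t``
  mapped to ``U``, lowercase uppercased, whitespace inside sequence lines
  stripped.
* MEME minimal motif files carrying letter-probability or log-odds matrices.
* Vienna/RNAfold-style dot-bracket structure files (header, sequence,
  structure line with an optional trailing ``(energy)``).
* Tab-separated manifests (id, label) and prediction tables (id, score,
  label).

DNA-convention inputs work unchanged because ``T`` is mapped to ``U`` at
ingest; ambiguity codes (``N`` etc.) are retained here and handled at the
encoding layer.  PSSM columns are 1-based (``k = 1..m``); sequence windows
use 0-based offsets.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .exceptions import DomainError, ParseError, StructureError

#: Canonical RNA alphabet, in the fixed row order used by every matrix here.
BASES = ("A", "C", "G", "U")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: IUPAC nucleotide codes accepted at the I/O layer (post T->U mapping).
IUPAC_CODES = frozenset("ACGUNRYSWKMBDHV")


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA string b_1 b_2 ... b_n over {A,C,G,U} (+ ambiguity codes)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - IUPAC_CODES
        if bad:
            raise ParseError(
                f"sequence {self.id!r}: non-IUPAC residue(s) {sorted(bad)!r}"
            )

    @property
    def n(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguity(self) -> bool:
        """True when the sequence contains codes outside {A,C,G,U}."""
        return any(c not in _BASE_INDEX for c in self.residues)


@dataclass
class LabeledDataset:
    """Per-protein collection of (sequence, label) records, label in {+1, -1}."""

    protein: str
    records: list[tuple[RnaSequence, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [seq.id for seq, _ in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DomainError(f"duplicate sequence ids in dataset: {dup}")
        for _, label in self.records:
            if label not in (+1, -1):
                raise DomainError(f"label must be +1 or -1, got {label!r}")

    @property
    def sequences(self) -> list[RnaSequence]:
        return [seq for seq, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, lab in self.records], dtype=int)

    def positives(self) -> list[RnaSequence]:
        return [seq for seq, lab in self.records if lab == +1]

    def negatives(self) -> list[RnaSequence]:
        return [seq for seq, lab in self.records if lab == -1]


@dataclass
class Pssm:
    """An m-column position-specific scoring matrix pssm(b, k).

    ``values`` has shape (4, m) with rows in :data:`BASES` order and columns
    the 1-based motif positions ``k = 1..m``.  ``kind`` records whether the
    cells are letter probabilities or log-odds scores.
    """

    motif_id: str
    values: np.ndarray
    kind: str = "log-odds"  # "probability" | "log-odds"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 4:
            raise DomainError(
                f"PSSM {self.motif_id!r}: expected a 4 x m matrix, got shape "
                f"{self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise DomainError(f"PSSM {self.motif_id!r}: non-finite cell")
        if self.kind not in ("probability", "log-odds"):
            raise DomainError(f"unknown PSSM kind {self.kind!r}")

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def score(self, base: str, k: int) -> float:
        """Matrix value for base b at 1-based position k."""
        if not 1 <= k <= self.m:
            raise DomainError(f"position k={k} outside 1..{self.m}")
        return float(self.values[_BASE_INDEX[base], k - 1])

    def to_log_odds(
        self,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudofrac: float = 1e-4,
    ) -> "Pssm":
        """Convert a probability matrix to base-2 log-odds against *background*.

        A tiny probability floor avoids -inf cells for zero frequencies.
        Log-odds matrices are returned unchanged.
        """
        if self.kind == "log-odds":
            return self
        bg = np.asarray(background, dtype=float).reshape(4, 1)
        if not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
            raise DomainError("background composition must sum to 1")
        probs = np.clip(self.values, pseudofrac, None)
        probs = probs / probs.sum(axis=0, keepdims=True)
        return Pssm(self.motif_id, np.log2(probs / bg), kind="log-odds")


@dataclass
class StructureRecord:
    """Dot-bracket pairing state (plus optional RNAfold energy) for one sequence."""

    sequence_id: str
    dotbracket: str
    energy: float | None = None  # kcal/mol

    def __post_init__(self) -> None:
        validate_dotbracket(self.dotbracket, context=self.sequence_id)

    @property
    def n(self) -> int:
        return len(self.dotbracket)


def validate_dotbracket(db: str, context: str = "") -> None:
    """Stack-check a pseudoknot-free dot-bracket string; raise StructureError."""
    where = f" in record {context!r}" if context else ""
    depth = 0
    for i, c in enumerate(db):
        if c == "(":
            depth += 1
        elif c == ")":
            depth -= 1
            if depth < 0:
                raise StructureError(
                    f"unbalanced ')' at position {i}{where}"
                )
        elif c != ".":
            raise StructureError(
                f"character {c!r} at position {i}{where}: only '.', '(', ')' allowed"
            )
    if depth != 0:
        raise StructureError(f"{depth} unclosed '('{where}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def canonicalize_residues(raw: str) -> str:
    """Uppercase, strip whitespace, and map DNA T to RNA U."""
    return re.sub(r"\s+", "", raw).upper().replace("T", "U")


def read_fasta(path: str | Path) -> list[RnaSequence]:
    """Read a FASTA file into canonical :class:`RnaSequence` records.

    Ids are the header up to the first whitespace; record order is preserved.
    Sequences containing ambiguity codes load fine (the encoding layer skips
    their windows).
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ParseError(
                    f"{path.name}:{lineno}: expected FASTA header '>' "
                    f"but found {line.strip()[:30]!r}"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            records.append(RnaSequence(rec.id, canonicalize_residues(str(rec.seq))))
        except ParseError as exc:
            raise ParseError(f"{path.name}: {exc}") from exc
    return records


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, seq.n, width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

_MATRIX_HEADER = re.compile(
    r"^(letter-probability|log-odds) matrix:(?P<attrs>.*)$"
)


def read_meme_minimal(path: str | Path) -> list[Pssm]:
    """Parse a MEME minimal motif file into a list of :class:`Pssm`.

    Both ``letter-probability matrix`` and ``log-odds matrix`` blocks are
    accepted; the matrix kind is recorded on each Pssm.  DNA alphabets are
    mapped onto {A,U,C,G} by T->U.  Column order follows the file's ALPHABET
    line; rows are re-ordered to the package's fixed A,C,G,U convention.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    alphabet: list[str] | None = None
    pssms: list[Pssm] = []
    current_id: str | None = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            letters = line.split("=", 1)[-1].strip().replace(" ", "")
            alphabet = [("U" if c.upper() == "T" else c.upper()) for c in letters]
            if sorted(alphabet) != sorted(BASES):
                raise ParseError(
                    f"{path.name}:{i + 1}: unsupported alphabet {letters!r} "
                    "(need the 4 nucleotides)"
                )
        elif line.startswith("MOTIF"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path.name}:{i + 1}: MOTIF line without identifier")
            current_id = parts[1]
        else:
            match = _MATRIX_HEADER.match(line)
            if match:
                if current_id is None:
                    raise ParseError(
                        f"{path.name}:{i + 1}: matrix block before any MOTIF line"
                    )
                if alphabet is None:
                    raise ParseError(
                        f"{path.name}:{i + 1}: matrix block but no ALPHABET line seen"
                    )
                kind = (
                    "probability"
                    if match.group(1) == "letter-probability"
                    else "log-odds"
                )
                width = None
                wmatch = re.search(r"w=\s*(\d+)", match.group("attrs"))
                if wmatch:
                    width = int(wmatch.group(1))
                rows = []
                j = i + 1
                while j < len(lines):
                    row = lines[j].strip()
                    if not row or not re.match(r"^[-+0-9.eE\s]+$", row):
                        break
                    cells = row.split()
                    if len(cells) != 4:
                        raise ParseError(
                            f"{path.name}:{j + 1}: matrix row has {len(cells)} "
                            "columns, expected 4"
                        )
                    rows.append([float(c) for c in cells])
                    j += 1
                if width is not None and len(rows) != width:
                    raise ParseError(
                        f"{path.name}: motif {current_id!r} declares w={width} "
                        f"but has {len(rows)} rows"
                    )
                if not rows:
                    raise ParseError(
                        f"{path.name}: motif {current_id!r} has an empty matrix"
                    )
                # MEME stores one row per motif position, one column per letter
                # in ALPHABET order; transpose and re-order rows to A,C,G,U.
                mat = np.array(rows, dtype=float).T
                order = [alphabet.index(b) for b in BASES]
                pssms.append(Pssm(current_id, mat[order, :], kind=kind))
                current_id = None
                i = j
                continue
        i += 1
    return pssms


def write_meme_minimal(
    pssms: Iterable[Pssm],
    path: str | Path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write PSSMs as a MEME minimal file (RNA alphabet ACGU)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.6f}" for b, f in zip(BASES, background)) + "\n\n"
        )
        for pssm in pssms:
            fh.write(f"MOTIF {pssm.motif_id}\n")
            header = (
                "letter-probability" if pssm.kind == "probability" else "log-odds"
            )
            fh.write(f"{header} matrix: alength= 4 w= {pssm.m}\n")
            for k in range(pssm.m):
                fh.write(
                    " ".join(f"{pssm.values[b, k]:.6f}" for b in range(4)) + "\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Dot-bracket structure files
# ---------------------------------------------------------------------------

_ENERGY_RE = re.compile(r"^(?P<db>[.()]+)(?:\s+\(\s*(?P<e>[-+]?\d+(?:\.\d+)?)\s*\))?\s*$")


def read_dotbracket(path: str | Path) -> list[StructureRecord]:
    """Read RNAfold-dialect records: header line, sequence line, structure line.

    The structure line may carry a trailing ``(energy)`` in kcal/mol.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    records: list[StructureRecord] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise ParseError(
                f"{path.name}:{i + 1}: expected '>' header, found {lines[i][:30]!r}"
            )
        seq_id = lines[i][1:].split()[0] if lines[i][1:].split() else ""
        if i + 2 >= len(lines):
            raise ParseError(f"{path.name}: truncated record {seq_id!r}")
        seq_line = canonicalize_residues(lines[i + 1])
        struct_line = lines[i + 2].strip()
        match = _ENERGY_RE.match(struct_line)
        if not match:
            raise ParseError(
                f"{path.name}:{i + 3}: unparseable structure line for {seq_id!r}"
            )
        db = match.group("db")
        if len(db) != len(seq_line):
            raise StructureError(
                f"record {seq_id!r}: structure length {len(db)} != sequence "
                f"length {len(seq_line)}"
            )
        energy = float(match.group("e")) if match.group("e") is not None else None
        records.append(StructureRecord(seq_id, db, energy))
        i += 3
    return records


def write_dotbracket(
    records: Iterable[tuple[RnaSequence, StructureRecord]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for seq, rec in records:
            fh.write(f">{rec.sequence_id}\n{seq.residues}\n{rec.dotbracket}")
            if rec.energy is not None:
                fh.write(f" ({rec.energy:.2f})")
            fh.write("\n")


# ---------------------------------------------------------------------------
# TSV manifests and prediction tables
# ---------------------------------------------------------------------------

def write_predictions(
    records: Sequence[tuple[str, float, int]], path: str | Path
) -> None:
    """Write (id, score, label) triples as a TSV table, input order preserved."""
    for _, score, _ in records:
        if not 0.0 <= score <= 1.0:
            raise DomainError(f"prediction score {score} outside [0, 1]")
    with open(path, "w") as fh:
        fh.write("id\tscore\tlabel\n")
        for seq_id, score, label in records:
            fh.write(f"{seq_id}\t{score:.6f}\t{label:+d}\n")


def read_predictions(path: str | Path) -> list[tuple[str, float, int]]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["id", "score", "label"]:
        raise ParseError(f"{path.name}: missing prediction-table header")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"{path.name}:{lineno}: expected 3 columns")
        out.append((parts[0], float(parts[1]), int(parts[2])))
    return out


def write_manifest(ds: LabeledDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for seq, label in ds.records:
            fh.write(f"{seq.id}\t{label:+d}\n")


def read_manifest(path: str | Path) -> dict[str, int]:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].split("\t") != ["id", "label"]:
        raise ParseError(f"{path.name}: missing manifest header")
    out: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path.name}:{lineno}: expected 2 columns")
        out[parts[0]] = int(parts[1])
    return out
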