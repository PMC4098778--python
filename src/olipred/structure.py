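"""Secondary-structure feature derivation from dot-bracket strings.

Four quantities describe a predicted secondary structure:

1. folding energy (kcal/mol), taken from the input file or folding program —
   never recomputed here;
2. stem density, the proportion of paired positions;
3. number of stems, where a stem is a maximal helix: a maximal run of
   consecutive base pairs (i, j), (i+1, j-1), ...  (bulges break stems);
4. accessibility, the maximal runs of >= 4 consecutive single-stranded
   (unpaired) nucleotides.

Only the pseudoknot-free grammar '.', '(', ')' is accepted, matching the
minimum-free-energy output of RNAfold.  Thermodynamic folding itself is out
of scope; :func:`fold_external` is a thin adapter around an external program
such as RNAfold.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass

import numpy as np

from .exceptions import AdapterError, DomainError, FoldingUnavailableError
from .formats import RnaSequence, StructureRecord, validate_dotbracket

#: Minimum run of unpaired nucleotides counted as accessible.
MIN_ACCESSIBLE_RUN = 4

UNPAIRED = -1


@dataclass(frozen=True)
class StructureFeatures:
    """The four structure quantities for one sequence."""

    energy: float
    stem_density: float
    n_stems: int
    accessible_runs: tuple[tuple[int, int], ...]  # (start, length), 0-based


def parse_pairing(dotbracket: str) -> np.ndarray:
    """Stack-match a dot-bracket string into a partner table.

    Returns an int array ``partner`` of length n with ``partner[i]`` the
    0-based index of the base paired with i, or :data:`UNPAIRED`.
    """
    validate_dotbracket(dotbracket)
    partner = np.full(len(dotbracket), UNPAIRED, dtype=int)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            partner[i], partner[j] = j, i
    return partner


def count_stems(partner: np.ndarray) -> int:
    """Number of maximal helices (runs of stacked consecutive pairs)."""
    n = len(partner)
    stems = 0
    for i in range(n):
        j = partner[i]
        if j == UNPAIRED or j < i:
            continue  # count each pair once, from its 5' side
        # (i, j) starts a new stem unless (i-1, j+1) is also a pair.
        if i == 0 or j + 1 >= n or partner[i - 1] != j + 1:
            stems += 1
    return stems


def stem_density(partner: np.ndarray) -> float:
    """Fraction of positions that are paired."""
    n = len(partner)
    if n == 0:
        raise DomainError("stem density undefined for an empty structure")
    return float(np.count_nonzero(partner != UNPAIRED)) / n


def accessible_runs(partner: np.ndarray) -> list[tuple[int, int]]:
    """Maximal unpaired runs with length >= 4, left to right, as (start, length)."""
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(len(partner)):
        if partner[i] == UNPAIRED:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= MIN_ACCESSIBLE_RUN:
                runs.append((start, i - start))
            start = None
    if start is not None and len(partner) - start >= MIN_ACCESSIBLE_RUN:
        runs.append((start, len(partner) - start))
    return runs


def structure_features(record: StructureRecord) -> StructureFeatures:
    """Compute all four structure quantities for one record.

    Missing energy defaults to 0.0 kcal/mol (completely unpaired input is
    the typical case).
    """
    partner = parse_pairing(record.dotbracket)
    return StructureFeatures(
        energy=record.energy if record.energy is not None else 0.0,
        stem_density=stem_density(partner),
        n_stems=count_stems(partner),
        accessible_runs=tuple(accessible_runs(partner)),
    )


def fold_external(seq: RnaSequence, program: str = "RNAfold") -> StructureRecord:
    """Fold *seq* with an external program (RNAfold dialect) — adapter only.

    The program receives FASTA on standard input and must emit the sequence
    followed by a dot-bracket line with a trailing ``(energy)``.  No folding
    logic lives in this package.
    """
    exe = shutil.which(program)
    if exe is None:
        raise FoldingUnavailableError(
            f"folding program {program!r} not found on PATH; fold sequences "
            "externally and supply the dot-bracket file instead"
        )
    proc = subprocess.run(
        [exe, "--noPS"] if program.endswith("RNAfold") else [exe],
        input=f">{seq.id}\n{seq.residues}\n",
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise AdapterError(
            f"{program} exited with status {proc.returncode}: {proc.stderr.strip()}"
        )
    import re

    for line in proc.stdout.splitlines():
        match = re.match(
            r"^(?P<db>[.()]+)\s*\(\s*(?P<e>[-+]?\d+(?:\.\d+)?)\s*\)\s*$", line.strip()
        )
        if match:
            db = match.group("db")
            if len(db) != seq.n:
                raise AdapterError(
                    f"{program} returned a structure of length {len(db)} for a "
                    f"{seq.n}-mer"
                )
            return StructureRecord(seq.id, db, float(match.group("e")))
    raise AdapterError(f"no dot-bracket line found in {program} output")
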