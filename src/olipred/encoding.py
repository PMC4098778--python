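"""Feature vector construction for the three predictors.

* ``oli``     — 256 tetranucleotide counts (all 4^4 words, lexicographic
  over A, C, G, U).
* ``olimo``   — oli plus the 10 highest PSSM motif scores on the sequence.
* ``olimoss`` — olimo plus [folding energy, stem density, number of stems]
  and 256 binary tetranucleotide-accessibility features.

Tetranucleotide counts are unnormalized by default (normalizing did not
improve discrimination in practice; a flag keeps the normalized mode for
comparisons with frequency-based encoders).  Sliding windows that contain a
non-ACGU symbol are skipped rather than zero-scored, to avoid inventing
signal from ambiguity codes.

Motif scores follow the windowed PSSM sum: for a window starting at 0-based
offset i, ``score(i) = sum_{k=1..m} pssm(b_{i+k}, k)``.  The feature order is
frozen (and versioned) so persisted models stay valid.
"""

from __future__ import annotations

import hashlib
import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .formats import BASES, Pssm, RnaSequence
from .structure import MIN_ACCESSIBLE_RUN, StructureFeatures

#: All 256 tetranucleotides in lexicographic order (AAAA, AAAC, ..., UUUU).
TETRANUCLEOTIDES: tuple[str, ...] = tuple(
    "".join(w) for w in itertools.product(BASES, repeat=4)
)
_TETRA_INDEX = {t: i for i, t in enumerate(TETRANUCLEOTIDES)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

N_MOTIF_SCORES = 10

SCHEMA_NAMES = ("oli", "olimo", "olimoss")


@dataclass(frozen=True)
class FeatureSchema:
    """Named, ordered, versioned feature layout."""

    name: str
    feature_names: tuple[str, ...]

    @property
    def dim(self) -> int:
        return len(self.feature_names)

    @property
    def version(self) -> str:
        """Stable fingerprint of the schema's name and feature order."""
        h = hashlib.sha256()
        h.update(self.name.encode())
        for f in self.feature_names:
            h.update(b"\0" + f.encode())
        return h.hexdigest()[:12]


def get_schema(name: str) -> FeatureSchema:
    if name not in SCHEMA_NAMES:
        raise ConfigurationError(
            f"unknown schema {name!r}; expected one of {SCHEMA_NAMES}"
        )
    names: list[str] = list(TETRANUCLEOTIDES)
    if name in ("olimo", "olimoss"):
        names += [f"motif_score_{i + 1}" for i in range(N_MOTIF_SCORES)]
    if name == "olimoss":
        names += ["energy", "stem_density", "n_stems"]
        names += [f"access_{t}" for t in TETRANUCLEOTIDES]
    return FeatureSchema(name, tuple(names))


@dataclass(frozen=True)
class WindowScore:
    """PSSM score of the length-m window at 0-based offset i.

    ``score`` is NaN for windows containing a non-ACGU base; such windows are
    excluded from top-k selection.
    """

    offset: int
    score: float


def tetra_counts(seq: RnaSequence, normalize: bool = False) -> np.ndarray:
    """Count every tetranucleotide along the sequence (window width 4, step 1).

    Windows containing a non-ACGU symbol are skipped.  With ``normalize``,
    counts are divided by max(n - 3, 1).  Sequences shorter than 4 nt yield
    an all-zero vector (with a warning).
    """
    counts = np.zeros(len(TETRANUCLEOTIDES), dtype=float)
    n = seq.n
    if n < 4:
        warnings.warn(
            f"sequence {seq.id!r} shorter than 4 nt: all-zero tetranucleotide vector",
            stacklevel=2,
        )
        return counts
    residues = seq.residues
    for i in range(n - 3):
        idx = _TETRA_INDEX.get(residues[i : i + 4])
        if idx is not None:  # skip windows with ambiguity codes
            counts[idx] += 1.0
    if normalize:
        counts /= max(n - 3, 1)
    return counts


def _window_scores(seq: RnaSequence, pssm: Pssm) -> np.ndarray:
    """All n - m + 1 window scores as an array; NaN marks ambiguous windows."""
    n, m = seq.n, pssm.m
    if n < m:
        return np.empty(0)
    # integer-encode once; -1 marks ambiguity codes
    enc = np.fromiter(
        (_BASE_INDEX.get(c, -1) for c in seq.residues), dtype=np.int64, count=n
    )
    windows = np.lib.stride_tricks.sliding_window_view(enc, m)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n - m + 1, np.nan)
    if valid.any():
        scores[valid] = pssm.values[windows[valid], np.arange(m)].sum(axis=1)
    return scores


def scan_pssm(seq: RnaSequence, pssm: Pssm) -> list[WindowScore]:
    """Score every length-m window of *seq* with *pssm*.

    Returns exactly ``n - m + 1`` window scores (empty, with a warning, when
    the sequence is shorter than the motif).  Windows containing a non-ACGU
    base get score NaN.
    """
    if seq.n < pssm.m:
        warnings.warn(
            f"sequence {seq.id!r} (n={seq.n}) shorter than motif "
            f"{pssm.motif_id!r} (m={pssm.m}): no windows",
            stacklevel=2,
        )
        return []
    return [
        WindowScore(i, float(s)) for i, s in enumerate(_window_scores(seq, pssm))
    ]


def top_motif_scores(
    seq: RnaSequence,
    pssms: Sequence[Pssm],
    k: int = N_MOTIF_SCORES,
    per_motif: bool = False,
) -> np.ndarray:
    """The k highest motif scores on the sequence, descending.

    By default all defined window scores across every supplied PSSM are
    pooled before taking the top k.  With ``per_motif`` the top score of each
    PSSM is taken first (cycling through PSSMs by rank) — the alternative
    reading of "10 PSSM-based motif scores" when several motifs exist.

    Fewer than k defined windows: the output is padded by repeating the
    minimum observed score (0.0 when no window exists at all), keeping the
    feature scale bounded for the linear kernel.  Tie-break is deterministic
    by (PSSM order, offset).
    """
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if not pssms:
        warnings.warn("no PSSMs supplied: motif-score block is all zeros", stacklevel=2)
        return np.zeros(k)
    scores_l, pidx_l, offs_l = [], [], []
    for p_idx, pssm in enumerate(pssms):
        arr = _window_scores(seq, pssm)
        ok = ~np.isnan(arr)
        scores_l.append(arr[ok])
        pidx_l.append(np.full(int(ok.sum()), p_idx))
        offs_l.append(np.nonzero(ok)[0])
    scores = np.concatenate(scores_l)
    if scores.size == 0:
        return np.zeros(k)
    pidx = np.concatenate(pidx_l)
    offs = np.concatenate(offs_l)
    # sort descending by score, ties broken by PSSM order then offset
    order = np.lexsort((offs, pidx, -scores))
    if per_motif:
        by_motif = [scores[order][pidx[order] == p] for p in range(len(pssms))]
        interleaved: list[float] = []
        rank = 0
        while len(interleaved) < scores.size:
            for col in by_motif:
                if rank < len(col):
                    interleaved.append(float(col[rank]))
            rank += 1
        picked = interleaved[:k]
    else:
        picked = [float(s) for s in scores[order][:k]]
    if len(picked) < k:
        picked += [min(picked)] * (k - len(picked))
    return np.array(picked)


def accessibility_features(seq: RnaSequence, sf: StructureFeatures) -> np.ndarray:
    """256 binary features: tetranucleotide t is 1 iff some occurrence of t
    lies entirely inside an accessible (>= 4 nt unpaired) run."""
    bits = np.zeros(len(TETRANUCLEOTIDES), dtype=float)
    for start, length in sf.accessible_runs:
        if length < MIN_ACCESSIBLE_RUN:
            raise DomainError(
                f"accessible run ({start}, {length}) shorter than "
                f"{MIN_ACCESSIBLE_RUN}"
            )
        if start + length > seq.n:
            raise DomainError(
                f"accessible run ({start}, {length}) extends past sequence "
                f"{seq.id!r} of length {seq.n}"
            )
        segment = seq.residues[start : start + length]
        for i in range(length - 3):
            idx = _TETRA_INDEX.get(segment[i : i + 4])
            if idx is not None:
                bits[idx] = 1.0
    return bits


def encode(
    seq: RnaSequence,
    schema: FeatureSchema | str,
    pssms: Sequence[Pssm] | None = None,
    sf: StructureFeatures | None = None,
    normalize: bool = False,
    per_motif: bool = False,
) -> np.ndarray:
    """Build the feature vector for one sequence under the given schema.

    Order is fixed: 256 tetranucleotide counts, then (olimo/olimoss) the 10
    top motif scores, then (olimoss) energy, stem density, number of stems,
    and the 256 accessibility bits.
    """
    if isinstance(schema, str):
        schema = get_schema(schema)
    parts = [tetra_counts(seq, normalize=normalize)]
    if schema.name in ("olimo", "olimoss"):
        if pssms is None:
            raise ConfigurationError(
                f"schema {schema.name!r} requires PSSMs but none were supplied"
            )
        parts.append(top_motif_scores(seq, pssms, per_motif=per_motif))
    if schema.name == "olimoss":
        if sf is None:
            raise ConfigurationError(
                "schema 'olimoss' requires structure features but none were supplied"
            )
        parts.append(np.array([sf.energy, sf.stem_density, float(sf.n_stems)]))
        parts.append(accessibility_features(seq, sf))
    vec = np.concatenate(parts)
    assert vec.shape == (schema.dim,)
    return vec


def encode_dataset(
    seqs: Sequence[RnaSequence],
    schema: FeatureSchema | str,
    pssms: Sequence[Pssm] | None = None,
    structures: Mapping[str, StructureFeatures] | None = None,
    normalize: bool = False,
    per_motif: bool = False,
) -> pd.DataFrame:
    """Feature matrix for many sequences: rows = sequence ids, columns =
    schema feature names."""
    if isinstance(schema, str):
        schema = get_schema(schema)
    rows = []
    for seq in seqs:
        sf = None
        if schema.name == "olimoss":
            if structures is None or seq.id not in structures:
                raise ConfigurationError(
                    f"schema 'olimoss': no structure supplied for {seq.id!r}"
                )
            sf = structures[seq.id]
        rows.append(
            encode(seq, schema, pssms=pssms, sf=sf, normalize=normalize,
                   per_motif=per_motif)
        )
    return pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, schema.dim)),
        index=[s.id for s in seqs],
        columns=list(schema.feature_names),
    )


def write_features_tsv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index_label="id")


def read_features_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")


def write_features_svmlight(
    features: pd.DataFrame, labels: Sequence[int], path: str | Path
) -> None:
    """Sparse label/index interchange format (1-based feature indices)."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(features.to_numpy(), np.asarray(labels), str(path))
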