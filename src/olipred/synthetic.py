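"""Synthetic labeled datasets with planted motifs and toy structures.

The generator emulates the statistical shape of a CLIP-derived training set
for one RNA-binding protein: a positive set of 3'UTR-like sequences in which
most members carry one to a few (possibly mutated) instances of the
protein's binding motif, and a negative set of background sequences drawn
from the same base composition.  Defaults are PUM2-like: the UGUAUAUA
consensus, lengths 200-1500 nt, and an AU-rich background as in human
3'UTRs.

``structure_mode="hairpin-toy"`` additionally emits schematic dot-bracket
structures in which every planted motif sits inside an unpaired hairpin loop
(length >= 4), so accessibility features carry signal; these structures are
schematic, not thermodynamic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .evaluate import PssmSource
from .exceptions import DomainError
from .formats import (
    BASES,
    LabeledDataset,
    Pssm,
    RnaSequence,
    StructureRecord,
    write_dotbracket,
    write_fasta,
    write_manifest,
    write_meme_minimal,
)

#: Margin needed around a planted site for the toy hairpin arms.
_ARM = 5


@dataclass
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_pos: int = 400
    n_neg: int = 800
    length_range: tuple[int, int] = (200, 1500)
    motif: str = "UGUAUAUA"  # PUM2-family consensus
    plant_prob: float = 0.9  # fraction of positives carrying >= 1 instance
    mutation_rate: float = 0.05  # per planted base
    max_instances: int = 3  # planted positives carry 1..max_instances sites
    background: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # A,C,G,U
    structure_mode: str = "none"  # "none" | "hairpin-toy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise DomainError("n_pos and n_neg must be >= 1")
        if not 0.0 <= self.plant_prob <= 1.0 or not 0.0 <= self.mutation_rate <= 1.0:
            raise DomainError("plant_prob and mutation_rate must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise DomainError("background composition must sum to 1")
        if len(self.motif) + 2 * _ARM + 2 > self.length_range[0]:
            raise DomainError(
                f"motif of length {len(self.motif)} does not fit in the minimum "
                f"sequence length {self.length_range[0]}"
            )
        if self.structure_mode not in ("none", "hairpin-toy"):
            raise DomainError(f"unknown structure_mode {self.structure_mode!r}")


@dataclass
class GeneratedData:
    dataset: LabeledDataset
    plant_positions: dict[str, list[tuple[int, int]]]  # id -> [(start, length)]
    structures: dict[str, StructureRecord] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int, bg: Sequence[float]) -> list[str]:
    return list(rng.choice(list(BASES), size=length, p=list(bg)))


def _mutate(rng: np.random.Generator, site: str, rate: float) -> str:
    out = []
    for c in site:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != c]))
        else:
            out.append(c)
    return "".join(out)


def _pick_starts(
    rng: np.random.Generator, n_sites: int, length: int, site_len: int
) -> list[int]:
    """Non-overlapping site starts, with margin for hairpin arms (rejection
    sampling)."""
    lo, hi = _ARM + 1, length - site_len - _ARM - 1
    starts: list[int] = []
    for _ in range(200):
        if len(starts) == n_sites:
            break
        s = int(rng.integers(lo, hi + 1))
        if all(abs(s - t) >= site_len + 2 * _ARM + 2 for t in starts):
            starts.append(s)
    return sorted(starts)


def _nested_fill(length: int) -> str:
    """A maximally-paired nested segment whose unpaired runs are all < 4 nt."""
    if length <= 0:
        return ""
    if length < 4:
        return "." * length
    if length == 4:
        return "(..)"
    arms = (length - 3) // 2
    return "(" * arms + "..." + ")" * arms + "." * (length - 3 - 2 * arms)


def _toy_structure(
    rng: np.random.Generator, length: int, sites: list[tuple[int, int]]
) -> str:
    """Schematic dot-bracket: planted sites sit in accessible hairpin loops,
    one decoy accessible loop (8 nt) adds background accessibility, and the
    rest of the sequence folds into filler helices with < 4 nt loops."""
    loops = sorted(sites)
    decoy_len = 8
    for _ in range(100):
        s = int(rng.integers(_ARM + 1, length - decoy_len - _ARM))
        if all(abs(s - t) >= 30 for t, _ in loops):
            loops = sorted(loops + [(s, decoy_len)])
            break
    parts: list[str] = []
    pos = 0
    for start, slen in loops:
        parts.append(_nested_fill(start - _ARM - pos))
        parts.append("(" * _ARM + "." * slen + ")" * _ARM)
        pos = start + slen + _ARM
    parts.append(_nested_fill(length - pos))
    return "".join(parts)


def generate(spec: SyntheticSpec) -> GeneratedData:
    """Generate a labeled dataset under *spec*; reproducible under its seed."""
    rng = np.random.default_rng(spec.seed)
    motif = spec.motif.upper().replace("T", "U")
    records: list[tuple[RnaSequence, int]] = []
    plants: dict[str, list[tuple[int, int]]] = {}
    structures: dict[str, StructureRecord] = {}
    lo, hi = spec.length_range

    def finish(seq_id: str, chars: list[str], label: int,
               sites: list[tuple[int, int]]) -> None:
        seq = RnaSequence(seq_id, "".join(chars))
        records.append((seq, label))
        plants[seq_id] = sites
        if spec.structure_mode == "hairpin-toy":
            db = _toy_structure(rng, seq.n, sites)
            n_pairs = db.count("(")
            energy = round(-1.8 * n_pairs + float(rng.normal(0.0, 0.5)), 2)
            structures[seq_id] = StructureRecord(seq_id, db, energy)

    for i in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        chars = _random_seq(rng, length, spec.background)
        sites: list[tuple[int, int]] = []
        if rng.random() < spec.plant_prob:
            n_inst = int(rng.integers(1, spec.max_instances + 1))
            for start in _pick_starts(rng, n_inst, length, len(motif)):
                instance = _mutate(rng, motif, spec.mutation_rate)
                chars[start : start + len(motif)] = list(instance)
                sites.append((start, len(motif)))
        finish(f"pos_{i:04d}", chars, +1, sites)

    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        finish(f"neg_{i:04d}", _random_seq(rng, length, spec.background), -1, [])

    ds = LabeledDataset(protein="SYN", records=records)
    return GeneratedData(ds, plants, structures)


def pssm_from_sites(
    aligned_sites: Sequence[str],
    pseudocount: float = 0.5,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    kind: str = "log-odds",
) -> Pssm:
    """Build a PSSM from aligned, equal-length binding sites.

    Position-wise base frequencies with additive pseudocounts, optionally
    converted to base-2 log-odds against *background*.  A trivial stand-in
    for de novo motif discovery, adequate as the per-fold PSSM provider on
    synthetic data.
    """
    if not aligned_sites:
        raise DomainError("need at least one site")
    m = len(aligned_sites[0])
    if any(len(s) != m for s in aligned_sites):
        raise DomainError("sites must all have equal length")
    counts = np.zeros((4, m))
    idx = {b: i for i, b in enumerate(BASES)}
    for site in aligned_sites:
        for k, c in enumerate(site.upper().replace("T", "U")):
            if c in idx:
                counts[idx[c], k] += 1.0
    freqs = (counts + pseudocount) / (counts.sum(axis=0, keepdims=True)
                                      + 4.0 * pseudocount)
    prob = Pssm("sites", freqs, kind="probability")
    if kind == "probability":
        return prob
    return prob.to_log_odds(background)


def estimate_background(seqs: Sequence[RnaSequence]) -> tuple[float, ...]:
    """0-order background base composition of a sequence set (A,C,G,U)."""
    counts = np.zeros(4)
    idx = {b: i for i, b in enumerate(BASES)}
    for seq in seqs:
        for c in seq.residues:
            if c in idx:
                counts[idx[c]] += 1.0
    if counts.sum() == 0:
        raise DomainError("cannot estimate background from empty sequences")
    return tuple(counts / counts.sum())


def planted_sites_pssm_source(
    gen: GeneratedData,
    pseudocount: float = 0.5,
    background: Sequence[float] | None = None,
) -> PssmSource:
    """Per-fold PSSM provider reading planted ground-truth sites.

    The returned callable extracts the (possibly mutated) planted site
    substrings from the training positives it is given — and from no other
    sequence — then builds one log-odds PSSM from them.  The log-odds
    background defaults to the 0-order base composition of those same
    training positives (as motif-discovery tools estimate it); pass an
    explicit composition to override.
    """

    def source(train_pos_seqs: Sequence[RnaSequence]) -> list[Pssm]:
        sites = []
        for seq in train_pos_seqs:
            for start, length in gen.plant_positions.get(seq.id, []):
                sites.append(seq.residues[start : start + length])
        if not sites:
            return []
        bg = background if background is not None else estimate_background(train_pos_seqs)
        return [pssm_from_sites(sites, pseudocount, bg)]

    return source


def write_dataset(gen: GeneratedData, outdir: str | Path) -> dict[str, Path]:
    """Emit FASTA (pos/neg), manifest TSV, dot-bracket and MEME minimal files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = gen.dataset
    paths = {
        "pos_fasta": outdir / "positives.fasta",
        "neg_fasta": outdir / "negatives.fasta",
        "manifest": outdir / "manifest.tsv",
    }
    write_fasta(ds.positives(), paths["pos_fasta"])
    write_fasta(ds.negatives(), paths["neg_fasta"])
    write_manifest(ds, paths["manifest"])
    if gen.structures:
        paths["structures"] = outdir / "structures.db"
        by_id = {s.id: s for s in ds.sequences}
        write_dotbracket(
            [(by_id[i], rec) for i, rec in gen.structures.items()],
            paths["structures"],
        )
    all_sites = [
        seq.residues[start : start + length]
        for seq in ds.positives()
        for start, length in gen.plant_positions.get(seq.id, [])
    ]
    if all_sites:
        paths["meme"] = outdir / "motifs.meme"
        write_meme_minimal([pssm_from_sites(all_sites)], paths["meme"])
    return paths
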