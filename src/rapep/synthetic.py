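"""Seeded synthetic peptide datasets with the statistical structure the
classifier assumes: two classes of 9-20-mers with distinct residue
composition biases and a short class-level motif planted into a fraction
of the positives and rejection-excluded from the negatives.

Defaults emulate the target data shape: positives enriched in G/P/Y,
negatives in A/D/E/L (2x weight multipliers over a uniform background),
and the degenerate pattern ``tiny polar hydrophobic G hydrophobic``
(Betts-Russell classes) planted in 60% of positives.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datasets import AMINO_ACIDS, Peptide, PeptideDataset
from .motifs import MotifPattern, ResidueClassScheme, get_scheme, match_motif


class GenerationError(RuntimeError):
    """Rejection sampling could not satisfy the constraints."""


DEFAULT_POS_BIAS = {"G": 2.0, "P": 2.0, "Y": 2.0}
DEFAULT_NEG_BIAS = {"A": 2.0, "D": 2.0, "E": 2.0, "L": 2.0}
DEFAULT_PLANTED = MotifPattern(("tiny", "polar", "hydrophobic", "G", "hydrophobic"))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation settings (all randomness flows from ``seed``).

    ``pos_bias`` / ``neg_bias`` multiply uniform per-residue weights;
    ``planted_motifs`` are inserted (as sampled concrete instances) into a
    fraction ``q`` of positives and rejection-excluded from negatives.
    """

    n_pos: int = 291
    n_neg: int = 165
    length_range: tuple[int, int] = (9, 20)
    pos_bias: dict = field(default_factory=lambda: dict(DEFAULT_POS_BIAS))
    neg_bias: dict = field(default_factory=lambda: dict(DEFAULT_NEG_BIAS))
    planted_motifs: tuple[MotifPattern, ...] = (DEFAULT_PLANTED,)
    q: float = 0.6
    scheme: str = "betts_russell"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class sizes must be positive")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("q must be in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid length range")
        for bias in (self.pos_bias, self.neg_bias):
            if any(w <= 0 for w in bias.values()):
                raise ValueError("bias weights must be positive")


def _weights(bias: dict) -> np.ndarray:
    w = np.array([bias.get(r, 1.0) for r in AMINO_ACIDS], dtype=float)
    return w / w.sum()


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=probs)
    return "".join(AMINO_ACIDS[i] for i in idx)


def _instantiate(rng: np.random.Generator, motif: MotifPattern,
                 scheme: ResidueClassScheme, probs: np.ndarray) -> str:
    """Sample a concrete residue string matching the motif, weighting
    class members by the positive composition bias."""
    out = []
    for token in motif.tokens:
        if len(token) == 1 and token in AMINO_ACIDS:
            out.append(token)
        else:
            members = sorted(scheme.classes[token])
            w = np.array([probs[AMINO_ACIDS.index(r)] for r in members])
            out.append(rng.choice(members, p=w / w.sum()))
    return "".join(out)


def generate_dataset(spec: SyntheticSpec) -> PeptideDataset:
    """Generate a labelled dataset reproducibly from ``spec.seed``.

    Positives and negatives have unique sequences (within and across
    classes); planted-motif instances never match any negative.
    """
    rng = np.random.default_rng(spec.seed)
    scheme = get_scheme(spec.scheme)
    pos_probs, neg_probs = _weights(spec.pos_bias), _weights(spec.neg_bias)
    lo, hi = spec.length_range
    max_retries = 2000

    def violates(seq: str) -> bool:
        return any(match_motif(m, seq, scheme) for m in spec.planted_motifs)

    seen: set[str] = set()
    peptides: list[Peptide] = []

    n_plant = int(round(spec.q * spec.n_pos))
    plant_idx = set(rng.permutation(spec.n_pos)[:n_plant].tolist())
    for i in range(spec.n_pos):
        for attempt in range(max_retries):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, pos_probs)
            if i in plant_idx and spec.planted_motifs:
                motif = spec.planted_motifs[int(rng.integers(len(spec.planted_motifs)))]
                inst = _instantiate(rng, motif, scheme, pos_probs)
                if len(inst) > length:
                    continue
                start = int(rng.integers(0, length - len(inst) + 1))
                seq = seq[:start] + inst + seq[start + len(inst):]
            if seq not in seen:
                seen.add(seq)
                peptides.append(Peptide(f"P{i + 1:04d}", seq, "positive"))
                break
        else:
            raise GenerationError("could not generate a unique positive sequence")

    for i in range(spec.n_neg):
        for attempt in range(max_retries):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, neg_probs)
            if seq in seen or (spec.planted_motifs and violates(seq)):
                continue
            seen.add(seq)
            peptides.append(Peptide(f"N{i + 1:04d}", seq, "negative"))
            break
        else:
            raise GenerationError(
                "could not generate a motif-free unique negative sequence; "
                "the planted motif may be unavoidable under neg_bias"
            )

    return PeptideDataset(peptides, provenance=f"synthetic(seed={spec.seed})")


def save_dataset(dataset: PeptideDataset, spec: SyntheticSpec, directory: str | Path,
                 stem: str = "synthetic") -> None:
    """Write FASTA (labels in headers), a label sidecar CSV and the spec
    as JSON for full provenance."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.write_fasta(directory / f"{stem}.fasta")
    dataset.write_csv(directory / f"{stem}.csv")
    payload = dataclasses.asdict(spec)
    payload["planted_motifs"] = [str(m) for m in spec.planted_motifs]
    (directory / f"{stem}.spec.json").write_text(json.dumps(payload, indent=2))
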