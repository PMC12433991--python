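"""Discovery and matching of class-exclusive sequence motifs over literal
and degenerate (residue-class) alphabets.

A motif is an ordered list of tokens; each token is either a literal
residue (``G``) or the name of a residue class (``tiny``, ``hydrophobic``,
...). A motif with positive-sequence support >= ``fp`` and
negative-sequence support <= ``fn`` is reported; with ``fn = 0`` the motif
is strictly exclusive to the positive class. Support is sequence-level: a
sequence counts once no matter how many times a motif matches it.

Discovery enumerates token strings by suffix extension, which is exhaustive
because sequence-level support can never increase when a pattern is
extended; a best-first frontier with top-k support thresholding prunes the
search without changing the returned set.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import tables
from .datasets import AMINO_ACIDS, PeptideDataset


class MotifConfigurationError(ValueError):
    """Unknown residue class or unusable scheme."""


@dataclass(frozen=True)
class ResidueClassScheme:
    """A named set of (possibly overlapping) residue classes.

    Literal residues are always available as tokens in addition to the
    class names. The ``none`` scheme has no classes (literal-only motifs).
    """

    name: str
    classes: Mapping[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, residues in self.classes.items():
            if not residues:
                raise MotifConfigurationError(f"class {cls!r} is empty")

    def token_matches(self, token: str, residue: str) -> bool:
        if len(token) == 1 and token in AMINO_ACIDS:
            return residue == token
        try:
            return residue in self.classes[token]
        except KeyError:
            raise MotifConfigurationError(f"unknown token {token!r}") from None

    def tokens_for(self, residue: str) -> list[str]:
        """The literal residue plus every class containing it (sorted)."""
        return [residue] + sorted(c for c, s in self.classes.items() if residue in s)


def get_scheme(name: str | ResidueClassScheme, custom: Mapping | None = None) -> ResidueClassScheme:
    """Resolve a scheme by name: ``none``, ``betts_russell``,
    ``koolman_rohm`` or ``custom`` (with explicit class sets)."""
    if isinstance(name, ResidueClassScheme):
        return name
    if name == "none":
        return ResidueClassScheme("none", {})
    if name == "custom":
        if not custom:
            raise MotifConfigurationError("custom scheme requires class sets")
        return ResidueClassScheme("custom", {k: frozenset(v) for k, v in custom.items()})
    schemes = tables.residue_class_schemes()
    if name not in schemes:
        raise MotifConfigurationError(f"unknown scheme {name!r}")
    return ResidueClassScheme(name, schemes[name])


@dataclass(frozen=True)
class MotifPattern:
    """An ordered token pattern with its class support statistics."""

    tokens: tuple[str, ...]
    gaps_allowed: int = 0
    pos_support: int = 0
    neg_support: int = 0

    def __post_init__(self) -> None:
        if len(self.tokens) < 1:
            raise ValueError("motif needs at least one token")

    def __str__(self) -> str:
        return " ".join(self.tokens)

    @classmethod
    def from_string(cls, text: str, gaps_allowed: int = 0) -> "MotifPattern":
        return cls(tuple(text.split()), gaps_allowed=gaps_allowed)


@dataclass(frozen=True)
class MotifSearchParams:
    """Search settings: ``fp`` minimum positive support, ``fn`` maximum
    negative support, ``g`` total gap budget, ``k`` motifs returned,
    ``max_len`` maximum pattern length."""

    fp: int = 2
    fn: int = 0
    g: int = 0
    k: int = 20
    max_len: int = 5

    def __post_init__(self) -> None:
        if self.fp < 1 or self.fn < 0 or self.k < 1 or self.max_len < 1 or self.g < 0:
            raise ValueError("invalid motif search parameters")


def _match_from(seq: str, tokens: Sequence[str], scheme: ResidueClassScheme,
                i: int, j: int, gaps_left: int) -> bool:
    if j == len(tokens):
        return True
    for skip in range(0, (gaps_left if j > 0 else 0) + 1):
        pos = i + skip
        if pos >= len(seq):
            break
        if scheme.token_matches(tokens[j], seq[pos]):
            if _match_from(seq, tokens, scheme, pos + 1, j + 1, gaps_left - skip):
                return True
    return False


def match_motif(pattern: MotifPattern | Sequence[str], sequence: str,
                scheme: ResidueClassScheme | str = "none") -> list[int]:
    """1-based start positions at which the motif matches the sequence.

    With ``gaps_allowed = 0`` the match is contiguous; otherwise up to
    ``gaps_allowed`` residues in total may be skipped between tokens.
    """
    scheme = get_scheme(scheme)
    if not isinstance(pattern, MotifPattern):
        pattern = MotifPattern(tuple(pattern))
    for t in pattern.tokens:  # validate tokens up front
        scheme.token_matches(t, "A")
    starts = []
    for s in range(len(sequence)):
        if scheme.token_matches(pattern.tokens[0], sequence[s]) and _match_from(
            sequence, pattern.tokens, scheme, s + 1, 1, pattern.gaps_allowed
        ):
            starts.append(s + 1)
    return starts


def _sequences(data: PeptideDataset | Iterable) -> list[str]:
    return [getattr(p, "sequence", None) or str(p) for p in data]


# ------------------------------------------------------------------ discovery
def _extend_states(seqs: list[str], states: list[tuple[int, int, int]],
                   token: str, scheme: ResidueClassScheme, g: int):
    """Advance match states by one token. A state is (seq index, next
    position, gaps used)."""
    out = []
    for si, pos, used in states:
        seq = seqs[si]
        for skip in range(0, g - used + 1):
            p = pos + skip
            if p >= len(seq):
                break
            if scheme.token_matches(token, seq[p]):
                out.append((si, p + 1, used + skip))
    return out


def _support(states) -> int:
    return len({si for si, _, _ in states})


def discover_motifs(
    pos: PeptideDataset | Iterable,
    neg: PeptideDataset | Iterable,
    scheme: ResidueClassScheme | str = "betts_russell",
    params: MotifSearchParams | None = None,
) -> list[MotifPattern]:
    """Exhaustively enumerate motifs exclusive to the positive class.

    Returns at most ``params.k`` patterns with positive support >= ``fp``
    and negative support <= ``fn``, ordered by positive support
    (descending), then pattern length (ascending), then token order.
    Equivalent to brute-force enumeration of all token strings up to
    ``max_len``; the best-first frontier only prunes patterns that cannot
    reach the returned top-k.
    """
    scheme = get_scheme(scheme)
    params = params or MotifSearchParams()
    pos_seqs, neg_seqs = _sequences(pos), _sequences(neg)
    if not pos_seqs:
        raise MotifConfigurationError("positive class is empty")

    # initial single-token states
    def seed_states(seqs):
        by_token: dict[str, list] = {}
        for si, seq in enumerate(seqs):
            for p, r in enumerate(seq):
                for t in scheme.tokens_for(r):
                    by_token.setdefault(t, []).append((si, p + 1, 0))
        return by_token

    pos_seed = seed_states(pos_seqs)
    neg_seed = seed_states(neg_seqs)

    results: list[tuple[tuple, MotifPattern]] = []
    counter = 0
    heap: list = []

    def sort_key(support: int, tokens: tuple[str, ...]):
        return (-support, len(tokens), tokens)

    def kth_support() -> int:
        if len(results) < params.k:
            return params.fp
        supports = sorted((-key[0] for key, _ in results), reverse=True)
        return max(params.fp, supports[params.k - 1])

    for token, states in pos_seed.items():
        support = _support(states)
        if support >= params.fp:
            counter += 1
            heapq.heappush(
                heap,
                (sort_key(support, (token,)), counter, states, neg_seed.get(token, [])),
            )

    while heap:
        key, _, pstates, nstates = heapq.heappop(heap)
        support = -key[0]
        tokens = key[2]
        if support < kth_support():
            continue
        neg_support = _support(nstates)
        if neg_support <= params.fn:
            results.append(
                (key, MotifPattern(tokens, gaps_allowed=params.g,
                                   pos_support=support, neg_support=neg_support))
            )
        if len(tokens) >= params.max_len:
            continue
        # candidate next tokens from residues reachable from current states
        nxt: set[str] = set()
        for si, p, used in pstates:
            seq = pos_seqs[si]
            for skip in range(0, params.g - used + 1):
                if p + skip < len(seq):
                    nxt.update(scheme.tokens_for(seq[p + skip]))
        bound = kth_support()
        for token in sorted(nxt):
            child_p = _extend_states(pos_seqs, pstates, token, scheme, params.g)
            child_support = _support(child_p)
            if child_support >= max(params.fp, bound):
                child_n = _extend_states(neg_seqs, nstates, token, scheme, params.g)
                counter += 1
                heapq.heappush(
                    heap,
                    (sort_key(child_support, tokens + (token,)), counter, child_p, child_n),
                )

    results.sort(key=lambda item: item[0])
    return [m for _, m in results[: params.k]]


def motif_score(sequence: str, positive_motifs: Sequence[MotifPattern],
                scheme: ResidueClassScheme | str = "betts_russell") -> float:
    """+0.5 if any exclusive positive motif matches the sequence, else 0."""
    scheme = get_scheme(scheme)
    for m in positive_motifs:
        if match_motif(m, sequence, scheme):
            return 0.5
    return 0.0


def matched_motifs(sequence: str, motifs: Sequence[MotifPattern],
                   scheme: ResidueClassScheme | str = "betts_russell") -> list[MotifPattern]:
    scheme = get_scheme(scheme)
    return [m for m in motifs if match_motif(m, sequence, scheme)]


def write_motif_report(motifs: Sequence[MotifPattern], path) -> None:
    with open(path, "w") as fh:
        fh.write("motif\tpos_support\tneg_support\n")
        for m in motifs:
            fh.write(f"{m}\t{m.pos_support}\t{m.neg_support}\n")


def read_motif_report(path) -> list[MotifPattern]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            text, ps, ns = line.rstrip("\n").split("\t")
            out.append(MotifPattern(tuple(text.split()), pos_support=int(ps),
                                    neg_support=int(ns)))
    return out
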