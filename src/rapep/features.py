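"""Composition-based and binary-profile peptide feature families.

Implemented families
--------------------
AAC / DPC / TPC
    k-mer composition (k = 1, 2, 3): ``100 * count(m) / (L - k + 1)`` over
    all ``20**k`` k-mers, so each row sums to 100.
CeTD
    Composition / transition / distribution descriptors over seven 3-group
    physicochemical partitions of the alphabet (hydrophobicity, van der
    Waals volume, polarity, polarizability, charge, secondary structure,
    solvent accessibility); 21 values per property, all in [0, 1].
AABP
    Amino-acid binary profile of the fixed 18-mer built by concatenating
    the N-terminal and C-terminal 9-mers; 360 one-hot features.
BTC
    Bond composition: mean per-residue covalent bond counts
    (total / hydrogen / single / double) from a shipped, overridable table.
DDR
    Distance distribution of residues: per residue type, the sum of gaps
    between consecutive occurrences divided by L (0 with < 2 occurrences).
CTC
    Conjoint-triad composition over the 7-class alphabet, normalized by
    (L - 2).
PRI
    Physicochemical residue indices: fraction of residues in each
    documented property set (e.g. NE = {D, E}).
SER
    Shannon entropy of residues: per residue type, -f * log2(f) with
    f = count / L.
APAAC
    Amphiphilic pseudo-amino-acid composition with sequence-order factors
    of order ``lambda`` and weight ``w``.

``ALLCOMP`` concatenates every composition family above.
"""

from __future__ import annotations

import math
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import tables
from .datasets import AMINO_ACIDS, Peptide, PeptideDataset


class UndefinedFeatureError(ValueError):
    """A peptide violates a feature family's length precondition."""


def _seq(p) -> str:
    return p.sequence if isinstance(p, Peptide) else str(p)


# --------------------------------------------------------------------- k-mers
_KMER_FAMILY = {1: "AAC", 2: "DPC", 3: "TPC"}


def kmer_names(k: int) -> list[str]:
    fam = _KMER_FAMILY[k]
    return [f"{fam}_{''.join(m)}" for m in product(AMINO_ACIDS, repeat=k)]


def kmer_composition(p, k: int) -> dict[str, float]:
    """Percent composition of all ``20**k`` k-mers; values sum to 100."""
    if k not in _KMER_FAMILY:
        raise ValueError("k must be 1, 2 or 3")
    seq = _seq(p)
    n = len(seq) - k + 1
    if n < 1:
        raise UndefinedFeatureError(
            f"{_KMER_FAMILY[k]} requires length >= {k}, got {len(seq)}"
        )
    vec = dict.fromkeys(kmer_names(k), 0.0)
    fam = _KMER_FAMILY[k]
    counts: dict[str, int] = {}
    for i in range(n):
        counts[seq[i:i + k]] = counts.get(seq[i:i + k], 0) + 1
    for mer, c in counts.items():
        vec[f"{fam}_{mer}"] = 100.0 * c / n
    return vec


# ------------------------------------------------------------------------ CTD
_PERCENT_TAGS = (("0", 0.0), ("25", 0.25), ("50", 0.50), ("75", 0.75), ("100", 1.0))


def ctd_names(properties: Iterable[str] | None = None) -> list[str]:
    props = list(properties) if properties is not None else list(tables.ctd_property_groups())
    names = []
    for prop in props:
        names += [f"CeTD_c_{prop}{g}" for g in (1, 2, 3)]
        names += [f"CeTD_{i}{j}_{prop}" for i, j in ((1, 2), (1, 3), (2, 3))]
        for g in (1, 2, 3):
            names += [f"CeTD_{tag}_p_{prop}{g}" for tag, _ in _PERCENT_TAGS]
    return names


def ctd_features(p, property_groups: Mapping | None = None) -> dict[str, float]:
    """Composition/transition/distribution descriptors, all in [0, 1].

    Distribution percentiles report the 1-based sequence position (divided
    by L) of the occurrence at which the given fraction of a group's
    occurrences is first exceeded: occurrence index ``min(floor(q*m)+1, m)``.
    """
    seq = _seq(p)
    L = len(seq)
    if L < 2:
        raise UndefinedFeatureError("CeTD requires length >= 2")
    groups = dict(property_groups) if property_groups is not None else tables.ctd_property_groups()
    vec: dict[str, float] = {}
    for prop, gs in groups.items():
        tables.validate_partition(gs)
        idx = [next(gi for gi, g in enumerate(gs, 1) if r in g) for r in seq]
        for g in (1, 2, 3):
            vec[f"CeTD_c_{prop}{g}"] = idx.count(g) / L
        pairs = {(1, 2): 0, (1, 3): 0, (2, 3): 0}
        for a, b in zip(idx, idx[1:]):
            if a != b:
                pairs[(min(a, b), max(a, b))] += 1
        for (i, j), c in pairs.items():
            vec[f"CeTD_{i}{j}_{prop}"] = c / (L - 1)
        for g in (1, 2, 3):
            occ = [pos for pos, gi in enumerate(idx, 1) if gi == g]
            m = len(occ)
            for tag, q in _PERCENT_TAGS:
                name = f"CeTD_{tag}_p_{prop}{g}"
                vec[name] = occ[min(math.floor(q * m), m - 1)] / L if m else 0.0
    return vec


# ------------------------------------------------------- terminal binary profile
def terminal_18mer(p) -> str:
    """Concatenation of the N-terminal and C-terminal 9-mers."""
    seq = _seq(p)
    if len(seq) < 9:
        raise UndefinedFeatureError("terminal profile requires length >= 9")
    return seq[:9] + seq[-9:]


def aabp_names() -> list[str]:
    return [f"AABP_{pos:02d}_{r}" for pos in range(1, 19) for r in AMINO_ACIDS]


def terminal_binary_profile(p) -> dict[str, float]:
    """One-hot profile of the terminal 18-mer: 360 features summing to 18."""
    s18 = terminal_18mer(p)
    vec = dict.fromkeys(aabp_names(), 0.0)
    for pos, r in enumerate(s18, 1):
        vec[f"AABP_{pos:02d}_{r}"] = 1.0
    return vec


# -------------------------------------------------------------- misc families
def _btc(seq: str, bond_table: Mapping | None) -> dict[str, float]:
    table = dict(bond_table) if bond_table is not None else tables.bond_counts()
    out = {}
    for key, tag in (("total", "T"), ("hydrogen", "H"), ("single", "S"), ("double", "D")):
        vals = [table[r].get(key, 0.0) for r in seq if r in table]
        out[f"BTC_{tag}"] = float(np.mean(vals)) if vals else 0.0
    return out


def _ddr(seq: str) -> dict[str, float]:
    L = len(seq)
    out = {}
    for r in AMINO_ACIDS:
        occ = [i for i, c in enumerate(seq) if c == r]
        if len(occ) < 2:
            out[f"DDR_{r}"] = 0.0
        else:
            out[f"DDR_{r}"] = sum(b - a for a, b in zip(occ, occ[1:])) / L
    return out


def _ctc(seq: str) -> dict[str, float]:
    if len(seq) < 3:
        raise UndefinedFeatureError("CTC requires length >= 3")
    cls = {r: str(i) for i, grp in enumerate(tables.CONJOINT_TRIAD_CLASSES, 1) for r in grp}
    vec = {f"CTC_{''.join(t)}": 0.0 for t in product("1234567", repeat=3)}
    n = len(seq) - 2
    for i in range(n):
        triad = "".join(cls[c] for c in seq[i:i + 3])
        vec[f"CTC_{triad}"] += 1.0 / n
    return vec


def _pri(seq: str, pri_sets: Mapping | None) -> dict[str, float]:
    sets = dict(pri_sets) if pri_sets is not None else tables.PRI_SETS
    L = len(seq)
    return {f"PRI_{code}": sum(1 for c in seq if c in s) / L for code, s in sets.items()}


def _ser(seq: str) -> dict[str, float]:
    L = len(seq)
    out = {}
    for r in AMINO_ACIDS:
        f = seq.count(r) / L
        out[f"SER_{r}"] = -f * math.log2(f) if f > 0 else 0.0
    return out


def _apaac(seq: str, lam: int, weight: float) -> dict[str, float]:
    L = len(seq)
    if L <= lam:
        raise UndefinedFeatureError(f"APAAC requires length > lambda ({lam})")
    scales = tables.apaac_scales()
    std = {}
    for key, sc in scales.items():
        v = np.array([sc[r] for r in AMINO_ACIDS])
        std[key] = {r: (sc[r] - v.mean()) / v.std() for r in AMINO_ACIDS}
    taus: list[float] = []
    for j in range(1, lam + 1):
        for key in ("hydrophobicity", "hydrophilicity"):
            s = std[key]
            taus.append(sum(s[seq[i]] * s[seq[i + j]] for i in range(L - j)) / (L - j))
    denom = 1.0 + weight * sum(taus)
    vec = {f"APAAC_{r}": (seq.count(r) / L) / denom for r in AMINO_ACIDS}
    for t, tau in enumerate(taus, 1):
        vec[f"APAAC_tau{t}"] = weight * tau / denom
    return vec


def misc_family_features(p, family: str, **params) -> dict[str, float]:
    """Dispatch for the BTC / DDR / CTC / PRI / SER / APAAC families."""
    seq = _seq(p)
    if family == "BTC":
        return _btc(seq, params.get("bond_table"))
    if family == "DDR":
        return _ddr(seq)
    if family == "CTC":
        return _ctc(seq)
    if family == "PRI":
        return _pri(seq, params.get("pri_sets"))
    if family == "SER":
        return _ser(seq)
    if family == "APAAC":
        return _apaac(seq, params.get("lam", 8), params.get("weight", 0.05))
    raise ValueError(f"unknown feature family {family!r}")


# ------------------------------------------------------------------- registry
COMPOSITION_FAMILIES = ("AAC", "DPC", "TPC", "BTC", "DDR", "CTC", "PRI", "SER", "APAAC", "CeTD")
ALL_FAMILIES = COMPOSITION_FAMILIES + ("AABP",)


def _family_vector(seq: str, family: str, params: Mapping) -> dict[str, float]:
    if family == "AAC":
        return kmer_composition(seq, 1)
    if family == "DPC":
        return kmer_composition(seq, 2)
    if family == "TPC":
        return kmer_composition(seq, 3)
    if family == "CeTD":
        return ctd_features(seq, params.get("property_groups"))
    if family == "AABP":
        return terminal_binary_profile(seq)
    return misc_family_features(seq, family, **params)


def _expand_families(families: Sequence[str]) -> list[str]:
    out: list[str] = []
    for fam in families:
        if fam == "ALLCOMP":
            out.extend(f for f in COMPOSITION_FAMILIES if f not in out)
        elif fam in ALL_FAMILIES:
            if fam not in out:
                out.append(fam)
        else:
            raise ValueError(f"unknown feature family {fam!r}")
    return out


def build_feature_matrix(
    data: PeptideDataset | Sequence,
    families: Sequence[str] = ("CeTD",),
    params: Mapping[str, Mapping] | None = None,
) -> pd.DataFrame:
    """Peptides x features matrix with family-ordered column blocks.

    ``data`` may be a :class:`PeptideDataset` or any sequence of peptides /
    strings. The returned frame carries ``attrs['family_tags']`` (feature
    name -> family) and ``attrs['params']``.
    """
    params = dict(params or {})
    fams = _expand_families(families)
    items = list(data)
    ids = [p.id if isinstance(p, Peptide) else f"pep{i + 1}" for i, p in enumerate(items)]
    rows = []
    for p, pid in zip(items, ids):
        row: dict[str, float] = {}
        for fam in fams:
            try:
                row.update(_family_vector(_seq(p), fam, params.get(fam, {})))
            except UndefinedFeatureError as exc:
                raise UndefinedFeatureError(f"peptide {pid!r}, family {fam}: {exc}") from exc
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(ids, name="id"))
    tags = {}
    for col in df.columns:
        tags[col] = col.split("_", 1)[0].replace("CeTD", "CeTD")
    df.attrs["family_tags"] = tags
    df.attrs["families"] = fams
    df.attrs["params"] = params
    return df


def write_feature_matrix(m: pd.DataFrame, path) -> None:
    """Write a feature matrix as CSV with a sidecar JSON of family params."""
    import json
    from pathlib import Path

    path = Path(path)
    m.to_csv(path)
    sidecar = dict(families=m.attrs.get("families", []),
                   params=m.attrs.get("params", {}))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_feature_matrix(path) -> pd.DataFrame:
    import json
    from pathlib import Path

    path = Path(path)
    m = pd.read_csv(path, index_col=0)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        m.attrs["families"] = meta.get("families", [])
        m.attrs["params"] = meta.get("params", {})
        m.attrs["family_tags"] = {c: c.split("_", 1)[0] for c in m.columns}
    return m


class PeptideFeaturizer(TransformerMixin, BaseEstimator):
    """Sklearn transformer mapping peptide sequences to numeric features.

    Parameters
    ----------
    families : sequence of str
        Feature families to concatenate (``"ALLCOMP"`` expands to every
        composition family).
    params : mapping, optional
        Per-family parameter overrides, e.g. ``{"APAAC": {"lam": 4}}``.
    """

    def __init__(self, families: Sequence[str] = ("CeTD",), params=None):
        self.families = families
        self.params = params

    def fit(self, X, y=None):
        X = list(X)
        if not X:
            raise ValueError("empty input")
        df = build_feature_matrix(X[:1], self.families, self.params)
        self.feature_names_ = list(df.columns)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> pd.DataFrame:
        df = build_feature_matrix(list(X), self.families, self.params)
        if hasattr(self, "feature_names_"):
            df = df.reindex(columns=self.feature_names_)
        return df

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
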