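"""Shipped residue tables: CTD partitions, bond counts, APAAC scales,
conjoint-triad classes and physicochemical residue-index sets.

All tables are packaged as plain-text data and can be overridden by passing
replacement mappings to the corresponding feature functions.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .datasets import AMINO_ACIDS


def _data_text(name: str) -> str:
    return resources.files("rapep.data").joinpath(name).read_text()


@lru_cache(maxsize=None)
def ctd_property_groups() -> dict[str, tuple[frozenset, frozenset, frozenset]]:
    """Seven 3-group partitions of the residue alphabet keyed by property code."""
    groups: dict[str, tuple[frozenset, frozenset, frozenset]] = {}
    for line in _data_text("ctd_groups.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("property"):
            continue
        prop, g1, g2, g3 = line.split("\t")
        groups[prop] = (frozenset(g1), frozenset(g2), frozenset(g3))
    return groups


def validate_partition(groups) -> None:
    """Check that the groups are disjoint and cover the 20-residue alphabet."""
    all_res = [r for g in groups for r in g]
    if len(all_res) != 20 or set(all_res) != set(AMINO_ACIDS):
        raise ValueError("groups must partition the 20-residue alphabet")


@lru_cache(maxsize=None)
def bond_counts() -> dict[str, dict[str, float]]:
    """Per-residue covalent bond counts (total/hydrogen/single/double)."""
    table: dict[str, dict[str, float]] = {}
    header: list[str] | None = None
    for line in _data_text("bond_counts.tsv").splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        table[parts[0]] = {k: float(v) for k, v in zip(header, parts[1:])}
    return table


@lru_cache(maxsize=None)
def apaac_scales() -> dict[str, dict[str, float]]:
    """Hydrophobicity/hydrophilicity scales (raw, not yet standardized)."""
    scales: dict[str, dict[str, float]] = {"hydrophobicity": {}, "hydrophilicity": {}}
    for line in _data_text("apaac_scales.tsv").splitlines():
        if not line or line.startswith("#") or line.startswith("residue"):
            continue
        res, h1, h2 = line.split("\t")
        scales["hydrophobicity"][res] = float(h1)
        scales["hydrophilicity"][res] = float(h2)
    return scales


@lru_cache(maxsize=None)
def residue_class_schemes() -> dict[str, dict[str, frozenset]]:
    """Named degenerate-alphabet schemes (overlapping residue classes)."""
    raw = json.loads(_data_text("residue_classes.json"))
    return {
        name: {cls: frozenset(res) for cls, res in classes.items()}
        for name, classes in raw.items()
    }


# Conjoint-triad classes: 7 groups by dipole and side-chain volume.
CONJOINT_TRIAD_CLASSES: tuple[str, ...] = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

# Physicochemical residue-index sets (fractions of residues in each set).
# PO positively charged, NE negatively charged, CH charged, PL polar,
# NP nonpolar, AL aliphatic, AR aromatic, TN tiny, SM small, HB hydrophobic.
PRI_SETS: dict[str, frozenset] = {
    "PO": frozenset("RHK"),
    "NE": frozenset("DE"),
    "CH": frozenset("DERHK"),
    "PL": frozenset("DEKNQRSTHY"),
    "NP": frozenset("ACFGILMPVW"),
    "AL": frozenset("ILV"),
    "AR": frozenset("FWYH"),
    "TN": frozenset("AGCS"),
    "SM": frozenset("AGCSPNDTV"),
    "HB": frozenset("ACFILMVWY"),
}
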