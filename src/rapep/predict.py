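"""Deployment logic: the hybrid motif+ML classifier, similarity-first
ensemble, protein scanning and single-residue analog design.

The hybrid rule adds a fixed +0.5 bonus to the classifier's positive-class
probability whenever any class-exclusive positive motif matches the
peptide; the label is decided by comparing the raw (uncapped) sum against
the decision threshold, while the reported combined score is capped at 1
for readability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datasets import AMINO_ACIDS, Peptide, PeptideDataset, from_sequences
from .features import UndefinedFeatureError, build_feature_matrix
from .models import ModelBundle, train_cv
from .motifs import (
    MotifPattern,
    MotifSearchParams,
    ResidueClassScheme,
    discover_motifs,
    get_scheme,
    matched_motifs,
    motif_score,
)
from .similarity import NO_HIT, top_hit_label


@dataclass
class HybridPrediction:
    peptide_id: str
    sequence: str
    ml_score: float
    motif_bonus: float
    combined: float  # capped at 1.0 for reporting
    label: str
    evidence: str = ""

    def as_row(self) -> dict:
        return dict(
            id=self.peptide_id, sequence=self.sequence,
            ml_score=round(self.ml_score, 6), motif_bonus=self.motif_bonus,
            combined=round(self.combined, 6), label=self.label,
            evidence=self.evidence,
        )


@dataclass
class ScanWindow:
    protein_id: str
    start: int  # 1-based inclusive
    end: int    # inclusive
    sequence: str
    prediction: HybridPrediction


def _as_peptide(p, default_id: str = "query") -> Peptide:
    if isinstance(p, Peptide):
        return p
    return Peptide(default_id, str(p).upper())


def hybrid_predict(
    p,
    bundle: ModelBundle,
    motifs: Sequence[MotifPattern] = (),
    scheme: ResidueClassScheme | str = "betts_russell",
    threshold: float = 0.5,
) -> HybridPrediction:
    """Score one peptide with the motif+ML hybrid rule."""
    pep = _as_peptide(p)
    if len(pep) < 9:
        raise UndefinedFeatureError("prediction requires peptides of length >= 9")
    m = build_feature_matrix([pep], bundle.families or ["CeTD"], bundle.family_params)
    ml = float(bundle.predict_proba(m)[0])
    bonus = motif_score(pep.sequence, motifs, scheme) if motifs else 0.0
    raw = ml + bonus
    hits = matched_motifs(pep.sequence, motifs, scheme) if bonus else []
    return HybridPrediction(
        peptide_id=pep.id,
        sequence=pep.sequence,
        ml_score=ml,
        motif_bonus=bonus,
        combined=min(raw, 1.0),
        label="positive" if raw >= threshold else "negative",
        evidence="; ".join(str(h) for h in hits),
    )


def blast_first_predict(
    p,
    reference: PeptideDataset,
    bundle: ModelBundle,
    evalue_cutoff: float = 10.0,
    threshold: float = 0.5,
) -> HybridPrediction:
    """Similarity-first ensemble: the top-hit label is final when a hit
    passes the e-value cutoff; otherwise fall back to the ML score."""
    pep = _as_peptide(p)
    label, hit = top_hit_label(pep, reference, evalue_cutoff)
    m = build_feature_matrix([pep], bundle.families or ["CeTD"], bundle.family_params)
    ml = float(bundle.predict_proba(m)[0])
    if label != NO_HIT:
        return HybridPrediction(
            peptide_id=pep.id, sequence=pep.sequence, ml_score=ml,
            motif_bonus=0.0, combined=1.0 if label == "positive" else 0.0,
            label=label,
            evidence=f"top_hit={hit.subject_id} evalue={hit.evalue:.3g}",
        )
    return HybridPrediction(
        peptide_id=pep.id, sequence=pep.sequence, ml_score=ml, motif_bonus=0.0,
        combined=ml, label="positive" if ml >= threshold else "negative",
        evidence="no_hit",
    )


def scan_protein(
    protein: str,
    bundle: ModelBundle,
    motifs: Sequence[MotifPattern] = (),
    scheme: ResidueClassScheme | str = "betts_russell",
    window: int = 15,
    step: int = 1,
    protein_id: str = "protein",
    threshold: float = 0.5,
) -> list[ScanWindow]:
    """Slide a fixed window along a protein and score every window.

    Windows are reported with 1-based inclusive coordinates; the number of
    windows is ``floor((L - window) / step) + 1``.
    """
    if not 9 <= window <= 20:
        raise ValueError("window must be within the trained length range [9, 20]")
    if step < 1:
        raise ValueError("step must be >= 1")
    protein = protein.upper()
    L = len(protein)
    if L < window:
        raise ValueError("protein shorter than the scan window")
    out = []
    for s0 in range(0, L - window + 1, step):
        sub = protein[s0:s0 + window]
        pred = hybrid_predict(
            Peptide(f"{protein_id}_{s0 + 1}_{s0 + window}", sub),
            bundle, motifs, scheme, threshold,
        )
        out.append(ScanWindow(protein_id, s0 + 1, s0 + window, sub, pred))
    return out


@dataclass
class AnalogResult:
    sequence: str
    is_original: bool
    prediction: HybridPrediction


def design_analogs(
    p,
    bundle: ModelBundle,
    motifs: Sequence[MotifPattern] = (),
    scheme: ResidueClassScheme | str = "betts_russell",
    threshold: float = 0.5,
) -> list[AnalogResult]:
    """Score every single-residue substitution analog of a peptide.

    Returns the original (flagged) followed by all ``19 * L`` analogs,
    each at Hamming distance 1 from the input.
    """
    pep = _as_peptide(p)
    results = [AnalogResult(pep.sequence, True,
                            hybrid_predict(pep, bundle, motifs, scheme, threshold))]
    for i, orig in enumerate(pep.sequence):
        for r in AMINO_ACIDS:
            if r == orig:
                continue
            seq = pep.sequence[:i] + r + pep.sequence[i + 1:]
            analog = Peptide(f"{pep.id}_{i + 1}{orig}>{r}", seq)
            results.append(
                AnalogResult(seq, False,
                             hybrid_predict(analog, bundle, motifs, scheme, threshold))
            )
    return results


# --------------------------------------------------------------- estimator API
class HybridClassifier(ClassifierMixin, BaseEstimator):
    """Motif + gradient-boosting hybrid peptide classifier.

    Fit on raw sequences: features are computed with the configured
    families, a grid-searched classifier is cross-validated and refit, and
    class-exclusive positive motifs are discovered on the training split.
    ``decision_scores`` returns ``P(positive) + 0.5 * [motif match]``; the
    predicted label compares that raw sum against ``threshold``.

    Parameters
    ----------
    families : sequence of str, default ``("CeTD",)``
        Feature families (the best-performing single family by default).
    algorithm : str, default ``"XGB"``
        Registry name of the underlying classifier.
    scheme : str, default ``"betts_russell"``
        Residue-class scheme for motif discovery.
    motif_params : MotifSearchParams, optional
        Exclusive-motif search settings (defaults: fp=2, fn=0, g=0, k=20).
    use_motifs : bool, default True
        Disable to obtain the pure ML model.
    threshold : float, default 0.5
        Decision threshold on the combined score.
    random_state : int, default 0
    """

    def __init__(self, families=("CeTD",), algorithm="XGB", grid=None,
                 scheme="betts_russell", motif_params=None, use_motifs=True,
                 threshold=0.5, family_params=None, random_state=0):
        self.families = families
        self.algorithm = algorithm
        self.grid = grid
        self.scheme = scheme
        self.motif_params = motif_params
        self.use_motifs = use_motifs
        self.threshold = threshold
        self.family_params = family_params
        self.random_state = random_state

    def _sequences(self, X) -> list[str]:
        return [p.sequence if isinstance(p, Peptide) else str(p).upper() for p in X]

    def fit(self, X, y):
        seqs = self._sequences(X)
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be binary (1 positive, 0 negative)")
        m = build_feature_matrix(seqs, self.families, self.family_params)
        self.bundle_, self.cv_report_ = train_cv(
            m, y, algorithm=self.algorithm, grid=self.grid,
            seed=self.random_state, threshold=self.threshold,
        )
        self.scheme_ = get_scheme(self.scheme)
        if self.use_motifs:
            params = self.motif_params or MotifSearchParams()
            pos = [s for s, lab in zip(seqs, y) if lab == 1]
            neg = [s for s, lab in zip(seqs, y) if lab == 0]
            self.motifs_ = discover_motifs(pos, neg, self.scheme_, params)
        else:
            self.motifs_ = []
        self.classes_ = np.array([0, 1])
        self.feature_names_ = list(m.columns)
        return self

    def _scores(self, X) -> tuple[np.ndarray, np.ndarray]:
        check_is_fitted(self, "bundle_")
        seqs = self._sequences(X)
        m = build_feature_matrix(seqs, self.families, self.family_params)
        ml = self.bundle_.predict_proba(m)
        bonus = np.array(
            [motif_score(s, self.motifs_, self.scheme_) if self.motifs_ else 0.0
             for s in seqs]
        )
        return ml, bonus

    def decision_scores(self, X) -> np.ndarray:
        """Raw combined scores (probability + motif bonus, uncapped)."""
        ml, bonus = self._scores(X)
        return ml + bonus

    def predict_proba(self, X) -> np.ndarray:
        combined = np.minimum(self.decision_scores(X), 1.0)
        return np.column_stack([1.0 - combined, combined])

    def predict(self, X) -> np.ndarray:
        return (self.decision_scores(X) >= self.threshold).astype(int)

    def predict_peptides(self, X) -> list[HybridPrediction]:
        """Full per-peptide reports (scores, labels, motif evidence)."""
        check_is_fitted(self, "bundle_")
        peps = [p if isinstance(p, Peptide) else Peptide(f"query{i + 1}", str(p).upper())
                for i, p in enumerate(X)]
        return [hybrid_predict(p, self.bundle_, self.motifs_, self.scheme_,
                               self.threshold) for p in peps]


# ----------------------------------------------------------------- persistence
_FORMAT_VERSION = 1


def save_model(path: str | Path, bundle: ModelBundle,
               motifs: Sequence[MotifPattern] = (),
               scheme: ResidueClassScheme | str = "betts_russell") -> None:
    """Serialize a fitted bundle plus its motifs to a single archive."""
    payload = dict(
        version=_FORMAT_VERSION,
        bundle=bundle,
        motifs=list(motifs),
        scheme=get_scheme(scheme),
    )
    joblib.dump(payload, path)


def load_model(path: str | Path):
    payload = joblib.load(path)
    if payload.get("version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version: {payload.get('version')}")
    return payload["bundle"], payload["motifs"], payload["scheme"]
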