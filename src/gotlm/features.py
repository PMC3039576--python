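"""The five feature channels.

Sequence channels are k-mer composition vectors (k=1 amino-acid, k=2
di-peptide), expressed as frequencies so the Gaussian kernel's length scale
is independent of sequence length. GO channels are binary indicator vectors
over per-aspect term vocabularies built from the training set only;
out-of-vocabulary terms on new proteins are dropped (and counted), never
retrained into the model.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from gotlm.io import ASPECTS, GoAnnotation, ProteinRecord

logger = logging.getLogger(__name__)

#: the 20 standard residues, fixed alphabetical order
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: all 400 dimers in row-major (first residue, second residue) order
DIPEPTIDES = tuple(a + b for a, b in itertools.product(AA_ALPHABET, repeat=2))
_DI_INDEX = {d: i for i, d in enumerate(DIPEPTIDES)}

#: channel names in canonical order
CHANNELS = ("AA", "diAA", "P", "F", "C")
SEQUENCE_CHANNELS = ("AA", "diAA")
GO_CHANNELS = ASPECTS  # ("P", "F", "C")


@dataclass(frozen=True)
class FeatureVocabulary:
    """Sorted unique GO accessions of one aspect, frozen from training data."""

    aspect: str
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise ValueError(f"aspect must be one of {ASPECTS}, got {self.aspect!r}")
        if list(self.terms) != sorted(set(self.terms)):
            raise ValueError("vocabulary terms must be unique and sorted")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class FeatureChannel:
    """One channel's feature matrix plus the vocabulary defining its columns."""

    name: str
    matrix: np.ndarray
    vocabulary: tuple[str, ...] | FeatureVocabulary

    def __post_init__(self) -> None:
        if self.name not in CHANNELS:
            raise ValueError(f"unknown channel {self.name!r}")


def aa_composition(sequence: str) -> np.ndarray:
    """Amino-acid composition: 20 relative frequencies in ACDEFGHIKLMNPQRSTVWY order.

    Ambiguity letters (B, Z, X, U, O, J) are excluded from both numerator and
    denominator. A sequence with no standard residue yields an all-zero
    vector with a warning.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must have length >= 1")
    counts = np.zeros(20)
    for ch in sequence:
        idx = _AA_INDEX.get(ch)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        warnings.warn(
            "sequence contains no standard amino-acid letters; "
            "amino-acid composition is all-zero",
            stacklevel=2,
        )
        return counts
    return counts / total


def diaa_composition(sequence: str) -> np.ndarray:
    """Di-peptide composition: 400 overlapping-dimer frequencies.

    Dimers containing an ambiguity letter are skipped; normalization is over
    retained dimers. Length-1 sequences (or ones with no valid dimer) yield
    an all-zero vector.
    """
    if len(sequence) < 1:
        raise ValueError("sequence must have length >= 1")
    counts = np.zeros(400)
    for i in range(len(sequence) - 1):
        idx = _DI_INDEX.get(sequence[i : i + 2])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def build_go_vocabulary(
    annotations: Iterable[GoAnnotation], aspect: str
) -> FeatureVocabulary:
    """Sorted unique terms of one aspect. Call on training annotations only.

    An aspect with no annotated terms yields an empty (legal) vocabulary; the
    corresponding kernel degenerates to all-ones and its weight collapses in
    the weighting step.
    """
    if aspect not in ASPECTS:
        raise ValueError(f"aspect must be one of {ASPECTS}, got {aspect!r}")
    terms = sorted({a.term for a in annotations if a.aspect == aspect})
    return FeatureVocabulary(aspect=aspect, terms=tuple(terms))


def go_binary_matrix(
    protein_ids: Sequence[str],
    annotations: Iterable[GoAnnotation],
    vocabulary: FeatureVocabulary,
) -> tuple[np.ndarray, int]:
    """Binary indicator matrix (n proteins x |vocabulary|) for one aspect.

    Entry (i, j) is 1 iff protein i carries vocabulary term j. Terms of the
    right aspect that are absent from the vocabulary (out-of-vocabulary test
    terms, the low-coverage situation) are silently dropped; the count of
    dropped (protein, term) pairs is returned and logged.
    """
    col = {t: j for j, t in enumerate(vocabulary.terms)}
    row = {pid: i for i, pid in enumerate(protein_ids)}
    matrix = np.zeros((len(protein_ids), len(vocabulary)))
    dropped = 0
    for ann in annotations:
        if ann.aspect != vocabulary.aspect or ann.protein_id not in row:
            continue
        j = col.get(ann.term)
        if j is None:
            dropped += 1
            continue
        matrix[row[ann.protein_id], j] = 1.0
    if dropped:
        logger.info(
            "aspect %s: dropped %d out-of-vocabulary (protein, term) pairs",
            vocabulary.aspect,
            dropped,
        )
    return matrix, dropped


def build_channels(
    records: Sequence[ProteinRecord],
    annotations: Iterable[GoAnnotation],
    vocabularies: Mapping[str, FeatureVocabulary] | None = None,
) -> dict[str, FeatureChannel]:
    """Build all five feature channels for a set of proteins.

    When ``vocabularies`` is None (training mode) the per-aspect GO
    vocabularies are built from ``annotations``; otherwise (test mode) the
    stored training vocabularies are used and out-of-vocabulary terms drop.
    """
    annotations = list(annotations)
    channels: dict[str, FeatureChannel] = {}
    ids = [r.id for r in records]
    aa = np.array([aa_composition(r.sequence) for r in records])
    di = np.array([diaa_composition(r.sequence) for r in records])
    channels["AA"] = FeatureChannel("AA", aa, tuple(AA_ALPHABET))
    channels["diAA"] = FeatureChannel("diAA", di, DIPEPTIDES)
    for aspect in GO_CHANNELS:
        vocab = (
            vocabularies[aspect]
            if vocabularies is not None
            else build_go_vocabulary(annotations, aspect)
        )
        matrix, _ = go_binary_matrix(ids, annotations, vocab)
        channels[aspect] = FeatureChannel(aspect, matrix, vocab)
    return channels
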