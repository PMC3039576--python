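"""Reading and writing the external formats: FASTA, annotation/label TSVs, model archives.

GO annotations are consumed as a minimal three-column TSV
(``protein_id<TAB>GO:NNNNNNN<TAB>aspect``) with aspect one of P/F/C — the
information content of an InterProScan ``--goterms`` run, without requiring
one. No ontology-graph reasoning is performed; terms are flat tokens.
"""

from __future__ import annotations

import hashlib
import logging
import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import joblib
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ASPECTS = ("P", "F", "C")

#: the 20 standard residues plus common ambiguity/rare letters
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXUOJ")

GO_PATTERN = re.compile(r"^GO:[0-9]{7}$")

MODEL_FORMAT = "gotlm-model"
MODEL_FORMAT_VERSION = 1


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ModelIOError(RuntimeError):
    """Unreadable, corrupted or incompatible model archive."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: identifier, amino-acid sequence, optional location label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise DataError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise DataError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )


@dataclass(frozen=True, order=True)
class GoAnnotation:
    """A (protein id, GO accession, aspect) triple — one transferred GO term."""

    protein_id: str
    term: str
    aspect: str

    def __post_init__(self) -> None:
        if self.aspect not in ASPECTS:
            raise DataError(
                f"annotation ({self.protein_id}, {self.term}): aspect must be one of "
                f"{ASPECTS}, got {self.aspect!r}"
            )
        if not GO_PATTERN.match(self.term):
            raise DataError(
                f"annotation for {self.protein_id!r}: malformed GO accession {self.term!r}"
            )


@dataclass
class Dataset:
    """Ordered protein records plus their GO annotations and the class list.

    ``classes`` is the sorted set of distinct labels present; empty when the
    dataset is unlabeled.
    """

    records: list[ProteinRecord]
    annotations: list[GoAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate protein ids in dataset: {dup}")
        known = set(ids)
        orphans = sorted({a.protein_id for a in self.annotations} - known)
        if orphans:
            raise DataError(
                f"annotations reference unknown protein ids: {orphans[:5]}"
                + ("..." if len(orphans) > 5 else "")
            )

    @property
    def classes(self) -> list[str]:
        return sorted({r.label for r in self.records if r.label is not None})

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """Row-subset by positional indices, keeping only matching annotations."""
        recs = [self.records[i] for i in indices]
        keep = {r.id for r in recs}
        anns = [a for a in self.annotations if a.protein_id in keep]
        return Dataset(records=recs, annotations=anns)

    @staticmethod
    def assemble(
        records: list[ProteinRecord],
        annotations: list[GoAnnotation],
        labels: Mapping[str, str] | None = None,
        strict: bool = True,
    ) -> "Dataset":
        """Join records, annotations and an optional label map into a Dataset.

        Annotations whose protein id is absent from ``records`` are rejected
        when ``strict`` (the default) and dropped with a warning otherwise.
        """
        known = {r.id for r in records}
        orphans = sorted({a.protein_id for a in annotations} - known)
        if orphans:
            if strict:
                raise DataError(
                    f"annotations reference unknown protein ids: {orphans[:5]}"
                    + ("..." if len(orphans) > 5 else "")
                )
            logger.warning(
                "dropping annotations for %d unknown protein ids", len(orphans)
            )
            annotations = [a for a in annotations if a.protein_id in known]
        if labels is not None:
            records = [
                ProteinRecord(r.id, r.sequence, labels.get(r.id, r.label))
                for r in records
            ]
        return Dataset(records=list(records), annotations=list(annotations))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records from a FASTA file.

    The record id is the first whitespace-delimited token of the header; the
    sequence is uppercased with ``*`` and gap characters (``-``, ``.``)
    stripped. Records that are empty after stripping, and duplicated ids,
    raise :class:`DataError`.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("*", "").replace("-", "").replace(".", "")
        if not seq:
            raise DataError(f"FASTA record {rec.id!r} in {path} has an empty sequence")
        if rec.id in seen:
            raise DataError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as plain FASTA (id-only headers)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(seq_records, str(Path(path)), "fasta-2line")


def read_go_annotations(path: str | Path) -> list[GoAnnotation]:
    """Read GO annotations from a 3+ column TSV: protein_id, term, aspect.

    Lines starting with ``#`` and blank lines are ignored; exact duplicate
    rows collapse to one annotation. Rows with an aspect outside {P, F, C} or
    a malformed GO accession raise :class:`DataError` naming the line.
    """
    path = Path(path)
    out: list[GoAnnotation] = []
    seen: set[GoAnnotation] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(parts)}"
                )
            try:
                ann = GoAnnotation(
                    protein_id=parts[0], term=parts[1], aspect=parts[2]
                )
            except DataError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            if ann not in seen:
                seen.add(ann)
                out.append(ann)
    return out


def write_go_annotations(annotations: Iterable[GoAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tterm\taspect\n")
        for a in annotations:
            fh.write(f"{a.protein_id}\t{a.term}\t{a.aspect}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping protein id to location name.

    Conflicting duplicate ids raise :class:`DataError`; repeating an identical
    row is harmless.
    """
    path = Path(path)
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            pid, label = parts[0], parts[1]
            if pid in labels and labels[pid] != label:
                raise DataError(
                    f"{path}:{lineno}: conflicting labels for {pid!r}: "
                    f"{labels[pid]!r} vs {label!r}"
                )
            labels[pid] = label
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#protein_id\tlocation\n")
        for pid, label in labels.items():
            fh.write(f"{pid}\t{label}\n")


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted model to a single-file archive with an integrity digest."""
    state = pickle.dumps(model, protocol=pickle.HIGHEST_PROTOCOL)
    archive = {
        "format": MODEL_FORMAT,
        "version": MODEL_FORMAT_VERSION,
        "sha256": hashlib.sha256(state).hexdigest(),
        "payload": state,
    }
    joblib.dump(archive, str(Path(path)))


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`.

    Raises :class:`ModelIOError` on a missing file, a foreign or truncated
    archive, a format-version mismatch, or a payload whose digest does not
    match (corruption).
    """
    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model archive not found: {path}")
    try:
        archive = joblib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - joblib raises many types here
        raise ModelIOError(f"unreadable model archive {path}: {exc}") from exc
    if not isinstance(archive, dict) or archive.get("format") != MODEL_FORMAT:
        raise ModelIOError(f"{path} is not a gotlm model archive")
    if archive.get("version") != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: archive version {archive.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    payload = archive.get("payload", b"")
    if hashlib.sha256(payload).hexdigest() != archive.get("sha256"):
        raise ModelIOError(f"{path}: integrity check failed (corrupted payload)")
    return pickle.loads(payload)
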