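"""Classifier objects and the classifier database.

The central object is :class:`CellClassifier`, which bundles the five
pieces of information needed to recognise one cell type: the cell-type
name, a trained binary linear model, the feature (gene) set the model was
trained on, a probability threshold, and an optional parent cell type.
Classifiers are collected in a :class:`ClassifierDatabase`, a named
mapping whose parent links form a forest: root classifiers see every
cell, child classifiers only see cells accepted by their parent.

Databases are persisted to a single ``.ctdb`` archive — a zip file with a
human-readable JSON manifest (names, parents, thresholds, feature names,
calibration constants) and one ``.npy`` member per numeric array so that
weights and scaling constants round-trip bit-exactly.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import (
    ArchiveParseError,
    NameCollisionError,
    NotFoundError,
    UnresolvedParentError,
    ValidityError,
    VersionError,
)

FORMAT_VERSION = "1.0"
_SUPPORTED_VERSIONS = {"1.0"}

__all__ = [
    "FORMAT_VERSION",
    "LinearBinaryModel",
    "CellClassifier",
    "ClassifierDatabase",
    "add_classifier",
    "remove_classifier",
    "validate_database",
    "save_database",
    "load_database",
]


@dataclass(frozen=True)
class LinearBinaryModel:
    """A probability-calibrated binary linear decision function.

    The decision value for a cell with standardized feature vector ``z``
    is ``f = w . z + b``; the calibrated probability is the Platt sigmoid
    ``p = 1 / (1 + exp(A f + B))``.  ``feature_means`` / ``feature_sds``
    are the training-set centering and scaling constants applied to the
    raw (normalized) expression values before the dot product.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_names", tuple(self.feature_names))
        for attr in ("weights", "feature_means", "feature_sds"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=np.float64))
        n = len(self.feature_names)
        if len(set(self.feature_names)) != n:
            raise ValidityError("feature_names must be unique")
        for attr in ("weights", "feature_means", "feature_sds"):
            arr = getattr(self, attr)
            if arr.ndim != 1 or arr.shape[0] != n:
                raise ValidityError(
                    f"{attr} has length {arr.shape}, expected ({n},) matching feature_names"
                )
        if not np.all(self.feature_sds > 0):
            raise ValidityError("all feature_sds must be > 0 (constant features are dropped before fitting)")

    def decision_values(self, z: np.ndarray) -> np.ndarray:
        """Return ``f = Z w + b`` for a cells x features standardized matrix."""
        z = np.asarray(z, dtype=np.float64)
        return z @ self.weights + self.intercept

    def equals(self, other: "LinearBinaryModel") -> bool:
        return (
            self.feature_names == other.feature_names
            and np.array_equal(self.weights, other.weights)
            and self.intercept == other.intercept
            and self.platt_a == other.platt_a
            and self.platt_b == other.platt_b
            and np.array_equal(self.feature_means, other.feature_means)
            and np.array_equal(self.feature_sds, other.feature_sds)
        )


@dataclass(frozen=True)
class CellClassifier:
    """One cell type's classifier: name, model, features, threshold, parent."""

    cell_type: str
    model: LinearBinaryModel
    threshold: float = 0.5
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.cell_type:
            raise ValidityError("cell_type must be a nonempty string")
        if not (0.0 < self.threshold < 1.0):
            raise ValidityError(f"threshold must lie in (0, 1), got {self.threshold!r}")

    @property
    def features(self) -> tuple[str, ...]:
        """Ordered gene symbols the model consumes (same as the model's)."""
        return self.model.feature_names

    def with_threshold(self, threshold: float) -> "CellClassifier":
        return replace(self, threshold=threshold)

    def equals(self, other: "CellClassifier") -> bool:
        return (
            self.cell_type == other.cell_type
            and self.threshold == other.threshold
            and self.parent == other.parent
            and self.model.equals(other.model)
        )


@dataclass
class ClassifierDatabase:
    """Named collection of classifiers whose parent links form a forest."""

    entries: dict[str, CellClassifier] = field(default_factory=dict)
    format_version: str = FORMAT_VERSION

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, cell_type: str) -> bool:
        return cell_type in self.entries

    def __iter__(self) -> Iterator[CellClassifier]:
        return iter(self.entries.values())

    def __getitem__(self, cell_type: str) -> CellClassifier:
        try:
            return self.entries[cell_type]
        except KeyError:
            raise NotFoundError(f"no classifier named {cell_type!r}") from None

    def copy(self) -> "ClassifierDatabase":
        return ClassifierDatabase(dict(self.entries), self.format_version)

    def roots(self) -> list[str]:
        return [name for name, c in self.entries.items() if c.parent is None]

    def children(self, cell_type: str) -> list[str]:
        return [name for name, c in self.entries.items() if c.parent == cell_type]

    def ancestors(self, cell_type: str) -> list[str]:
        """Parent chain of ``cell_type`` from its parent up to the root."""
        chain: list[str] = []
        node = self[cell_type].parent
        while node is not None:
            chain.append(node)
            node = self.entries[node].parent if node in self.entries else None
        return chain

    def descendants(self, cell_type: str) -> list[str]:
        out: list[str] = []
        frontier = self.children(cell_type)
        while frontier:
            node = frontier.pop()
            out.append(node)
            frontier.extend(self.children(node))
        return out

    def set_threshold(self, cell_type: str, new_threshold: float) -> "ClassifierDatabase":
        """Return a database where only this classifier's threshold changed."""
        current = self[cell_type]
        if not (0.0 < new_threshold < 1.0):
            raise ValidityError(f"threshold must lie in (0, 1), got {new_threshold!r}")
        out = self.copy()
        out.entries[cell_type] = current.with_threshold(new_threshold)
        return out

    def equals(self, other: "ClassifierDatabase") -> bool:
        return (
            self.format_version == other.format_version
            and list(self.entries) == list(other.entries)
            and all(c.equals(other.entries[name]) for name, c in self.entries.items())
        )


def add_classifier(db: ClassifierDatabase, c: CellClassifier) -> ClassifierDatabase:
    """Return a new database extended with ``c``.

    The name must be new, must not contain the ``/`` ambiguity separator,
    and a declared parent must already be present.
    """
    if "/" in c.cell_type:
        raise ValidityError(f"cell-type name must not contain '/': {c.cell_type!r}")
    if c.cell_type in db.entries:
        raise NameCollisionError(f"classifier {c.cell_type!r} already exists")
    if c.parent is not None and c.parent not in db.entries:
        raise UnresolvedParentError(
            f"parent {c.parent!r} of {c.cell_type!r} is not in the database"
        )
    out = db.copy()
    out.entries[c.cell_type] = c
    return out


def remove_classifier(db: ClassifierDatabase, cell_type: str) -> ClassifierDatabase:
    """Remove one classifier, re-rooting its children onto its parent.

    Children of the removed node inherit its parent (or become roots),
    so removal never silently discards a subtree.
    """
    removed = db[cell_type]
    out = ClassifierDatabase({}, db.format_version)
    for name, c in db.entries.items():
        if name == cell_type:
            continue
        if c.parent == cell_type:
            c = replace(c, parent=removed.parent)
        out.entries[name] = c
    return out


def validate_database(db: ClassifierDatabase) -> list[str]:
    """Return one human-readable description per invariant violation.

    Checks: mapping keys match each entry's own name, every parent
    resolves, and the parent relation is acyclic.  An empty list means
    the database is a valid forest.
    """
    violations: list[str] = []
    for key, c in db.entries.items():
        if key != c.cell_type:
            violations.append(
                f"key {key!r} does not match entry cell_type {c.cell_type!r}"
            )
        if c.parent is not None and c.parent not in db.entries:
            violations.append(f"parent {c.parent!r} of {key!r} is not in the database")

    # cycle detection over the resolvable parent links, reporting each cycle once
    seen_in_cycle: set[str] = set()
    for start in db.entries:
        if start in seen_in_cycle:
            continue
        visited: dict[str, int] = {}
        path: list[str] = []
        node: Optional[str] = start
        while node is not None and node in db.entries:
            if node in visited:
                cycle = path[visited[node]:]
                if not seen_in_cycle.intersection(cycle):
                    seen_in_cycle.update(cycle)
                    violations.append(
                        "cycle in parent relation: " + " -> ".join(cycle + [node])
                    )
                break
            visited[node] = len(path)
            path.append(node)
            node = db.entries[node].parent
    return violations


def _require_valid(db: ClassifierDatabase) -> None:
    from .errors import DatabaseValidationError

    violations = validate_database(db)
    if violations:
        raise DatabaseValidationError("; ".join(violations))


def save_database(db: ClassifierDatabase, path) -> None:
    """Write ``db`` to a single ``.ctdb`` zip archive at ``path``."""
    _require_valid(db)
    manifest = {
        "format_version": db.format_version,
        "classifiers": [
            {
                "cell_type": c.cell_type,
                "parent": c.parent,
                "threshold": c.threshold,
                "feature_names": list(c.model.feature_names),
                "intercept": c.model.intercept,
                "platt_a": c.model.platt_a,
                "platt_b": c.model.platt_b,
                "arrays": f"arrays/{i}",
            }
            for i, c in enumerate(db.entries.values())
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for i, c in enumerate(db.entries.values()):
            for part, arr in (
                ("weights", c.model.weights),
                ("means", c.model.feature_means),
                ("sds", c.model.feature_sds),
            ):
                buf = io.BytesIO()
                np.save(buf, arr, allow_pickle=False)
                zf.writestr(f"arrays/{i}/{part}.npy", buf.getvalue())


def _load_array(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    try:
        with zf.open(name) as fh:
            return np.load(io.BytesIO(fh.read()), allow_pickle=False)
    except KeyError:
        raise ArchiveParseError(f"archive is missing array member {name!r}") from None


def load_database(path) -> ClassifierDatabase:
    """Read a ``.ctdb`` archive written by :func:`save_database`."""
    try:
        zf = zipfile.ZipFile(path, "r")
    except zipfile.BadZipFile as exc:
        raise ArchiveParseError(f"not a classifier archive: {exc}") from exc
    with zf:
        try:
            manifest = json.loads(zf.read("manifest.json"))
        except KeyError:
            raise ArchiveParseError("archive is missing manifest.json") from None
        except json.JSONDecodeError as exc:
            raise ArchiveParseError(f"manifest.json is not valid JSON: {exc}") from exc
        version = manifest.get("format_version")
        if version not in _SUPPORTED_VERSIONS:
            raise VersionError(
                f"unsupported format_version {version!r}; supported: {sorted(_SUPPORTED_VERSIONS)}"
            )
        db = ClassifierDatabase({}, version)
        for rec in manifest.get("classifiers", []):
            for fld in ("cell_type", "threshold", "feature_names", "intercept",
                        "platt_a", "platt_b", "arrays"):
                if fld not in rec:
                    raise ArchiveParseError(
                        f"classifier record {rec.get('cell_type', '?')!r} is missing field {fld!r}"
                    )
            prefix = rec["arrays"]
            model = LinearBinaryModel(
                feature_names=tuple(rec["feature_names"]),
                weights=_load_array(zf, f"{prefix}/weights.npy"),
                intercept=float(rec["intercept"]),
                platt_a=float(rec["platt_a"]),
                platt_b=float(rec["platt_b"]),
                feature_means=_load_array(zf, f"{prefix}/means.npy"),
                feature_sds=_load_array(zf, f"{prefix}/sds.npy"),
            )
            c = CellClassifier(
                cell_type=rec["cell_type"],
                model=model,
                threshold=float(rec["threshold"]),
                parent=rec.get("parent"),
            )
            if c.cell_type in db.entries:
                raise ArchiveParseError(f"duplicate classifier {c.cell_type!r} in archive")
            db.entries[c.cell_type] = c
    _require_valid(db)
    return db
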