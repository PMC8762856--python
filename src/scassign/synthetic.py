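"""Seeded generator of hierarchically structured scRNA-seq counts.

Counts are negative-binomial: gene g in a cell of type t has mean
``s_c * baseline_mean * F``, where ``s_c`` is a per-cell log-normal
library-size factor (mean 1) and ``F`` is the planted fold change when g
is a marker of t or of one of t's ancestors, else 1.  Variance follows
the standard mean-dispersion form ``mu + mu^2 / dispersion``.  Ancestor
markers are inherited by descendant types, so a parent classifier has
signal covering all of its children.

Types listed in ``unknown_types`` are simulated like any other but held
out of training, providing ground truth for the rejection ("unknown
population") metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import SimulationSpecError, StratificationError, ValidityError
from .preprocess import ExpressionMatrix

__all__ = [
    "gene_names",
    "TypeSpec",
    "SimulationSpec",
    "default_spec",
    "simulate_dataset",
    "split_train_test",
    "training_hierarchy",
]


@dataclass(frozen=True)
class TypeSpec:
    """One simulated population: name, parent, size, planted markers."""

    name: str
    parent: Optional[str]
    n_cells: int
    marker_genes: tuple[str, ...]
    fold_change: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_genes", tuple(self.marker_genes))
        if self.n_cells < 1:
            raise SimulationSpecError(f"type {self.name!r} needs n_cells >= 1")
        if self.fold_change < 1.0:
            raise SimulationSpecError(f"type {self.name!r} needs fold_change >= 1")


def gene_names(n_genes: int) -> list[str]:
    """Synthetic gene symbols g0000, g0001, ... for an n-gene universe."""
    width = max(4, len(str(max(n_genes - 1, 1))))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


@dataclass(frozen=True)
class SimulationSpec:
    types: tuple[TypeSpec, ...]
    n_genes: int
    baseline_mean: float = 0.5
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.3
    unknown_types: frozenset[str] = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "types", tuple(self.types))
        object.__setattr__(self, "unknown_types", frozenset(self.unknown_types))
        names = [t.name for t in self.types]
        if len(set(names)) != len(names):
            raise SimulationSpecError("type names must be unique")
        by_name = {t.name: t for t in self.types}
        for t in self.types:
            if t.parent is not None and t.parent not in by_name:
                raise SimulationSpecError(f"parent {t.parent!r} of {t.name!r} is undefined")
        for u in self.unknown_types:
            if u not in by_name:
                raise SimulationSpecError(f"unknown_types entry {u!r} is not a simulated type")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0 or self.libsize_sigma < 0:
            raise SimulationSpecError("baseline_mean/nb_dispersion must be > 0, libsize_sigma >= 0")
        # sibling marker sets must be disjoint
        from collections import defaultdict

        siblings = defaultdict(list)
        for t in self.types:
            siblings[t.parent].append(t)
        for group in siblings.values():
            seen: dict[str, str] = {}
            for t in group:
                for g in t.marker_genes:
                    if g in seen:
                        raise SimulationSpecError(
                            f"marker {g!r} shared by sibling types {seen[g]!r} and {t.name!r}"
                        )
                    seen[g] = t.name
        gene_universe = set(self.gene_names())
        for t in self.types:
            bad = set(t.marker_genes) - gene_universe
            if bad:
                raise SimulationSpecError(
                    f"markers of {t.name!r} outside the {self.n_genes}-gene universe: {sorted(bad)}"
                )

    def gene_names(self) -> list[str]:
        return gene_names(self.n_genes)

    def ancestors(self, name: str) -> list[str]:
        by_name = {t.name: t for t in self.types}
        out: list[str] = []
        node = by_name[name].parent
        while node is not None:
            out.append(node)
            node = by_name[node].parent
        return out


def default_spec(
    seed: int = 0,
    n_cells_per_type: int = 500,
    fold_change: float = 4.0,
    n_markers: int = 30,
    n_genes: int = 1000,
) -> SimulationSpec:
    """The reference scenario: three root populations, one subtype of the
    first, and one extra root population held out of training.

    TypeA/TypeB/TypeC are well-separated roots; TypeA_sub refines TypeA
    (it inherits TypeA's markers and adds its own); TypeU is simulated
    but never trained on, standing in for a population missing from the
    reference.
    """
    genes = gene_names(n_genes)

    def block(i: int) -> tuple[str, ...]:
        return tuple(genes[i * n_markers : (i + 1) * n_markers])

    types = (
        TypeSpec("TypeA", None, n_cells_per_type, block(0), fold_change),
        TypeSpec("TypeB", None, n_cells_per_type, block(1), fold_change),
        TypeSpec("TypeC", None, n_cells_per_type, block(2), fold_change),
        TypeSpec("TypeA_sub", "TypeA", n_cells_per_type, block(3), fold_change),
        TypeSpec("TypeU", None, n_cells_per_type, block(4), fold_change),
    )
    return SimulationSpec(
        types=types,
        n_genes=n_genes,
        unknown_types=frozenset({"TypeU"}),
        seed=seed,
    )


_CHUNK = 4096  # cells simulated per block to bound dense scratch memory


def simulate_dataset(spec: SimulationSpec) -> tuple[ExpressionMatrix, np.ndarray]:
    """Draw one dataset: sparse counts plus per-cell truth labels.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_names()
    gene_index = {g: j for j, g in enumerate(genes)}
    by_name = {t.name: t for t in spec.types}

    blocks: list[sp.csr_matrix] = []
    labels: list[str] = []
    cell_ids: list[str] = []
    counter = 0
    r = spec.nb_dispersion
    for t in spec.types:
        mean = np.full(spec.n_genes, spec.baseline_mean)
        for owner in [t.name, *spec.ancestors(t.name)]:
            ot = by_name[owner]
            cols = [gene_index[g] for g in ot.marker_genes]
            mean[cols] = spec.baseline_mean * ot.fold_change
        done = 0
        while done < t.n_cells:
            n = min(_CHUNK, t.n_cells - done)
            if spec.libsize_sigma > 0:
                s = np.exp(
                    rng.normal(-0.5 * spec.libsize_sigma**2, spec.libsize_sigma, size=n)
                )
            else:
                s = np.ones(n)
            mu = s[:, None] * mean[None, :]
            lam = rng.gamma(shape=r, scale=mu / r)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))
            done += n
        labels.extend([t.name] * t.n_cells)
        cell_ids.extend(f"cell_{counter + i:06d}" for i in range(t.n_cells))
        counter += t.n_cells

    values = sp.csr_matrix(sp.vstack(blocks))
    m = ExpressionMatrix(
        values,
        np.array(cell_ids, dtype=object),
        np.array(genes, dtype=object),
        is_normalized=False,
    )
    return m, np.array(labels, dtype=object)


def split_train_test(
    m: ExpressionMatrix,
    labels: Sequence[str],
    test_fraction: float,
    seed: int,
) -> tuple[tuple[ExpressionMatrix, np.ndarray], tuple[ExpressionMatrix, np.ndarray]]:
    """Seeded stratified split into (train, test) pairs, disjoint and exhaustive."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != m.n_cells:
        raise ValidityError(f"{len(labels)} labels for {m.n_cells} cells")
    if not (0.0 < test_fraction < 1.0):
        raise ValidityError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for lab in sorted(set(labels)):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            raise StratificationError(f"class {lab!r} has {len(idx)} cell(s); need >= 2 to split")
        n_test = int(round(len(idx) * test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(m.n_cells), test)
    return (
        (m.subset_cells(train), labels[train]),
        (m.subset_cells(test), labels[test]),
    )


def training_hierarchy(
    spec: SimulationSpec, shared_panel: bool = True
) -> tuple[dict[str, Optional[str]], dict[str, tuple[str, ...]]]:
    """Hierarchy and per-type feature lists for the trainable (non-held-out) types.

    With ``shared_panel`` (the default) every classifier consumes the
    union of all trainable types' markers: a one-vs-rest model benefits
    from negative evidence — high expression of another type's markers
    argues against the type at hand.  With ``shared_panel=False`` each
    classifier sees only its own planted markers.
    """
    trainable = [t for t in spec.types if t.name not in spec.unknown_types]
    panel = tuple(sorted({g for t in trainable for g in t.marker_genes}))
    hierarchy: dict[str, Optional[str]] = {}
    features: dict[str, tuple[str, ...]] = {}
    for t in trainable:
        parent = t.parent if (t.parent is not None and t.parent not in spec.unknown_types) else None
        hierarchy[t.name] = parent
        features[t.name] = panel if shared_panel else t.marker_genes
    return hierarchy, features
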