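"""Loading, validation and summary of drug sets, signed DDI edge lists and
binary side-effect feature matrices.

A comprehensive drug-drug interaction (DDI) network is a signed graph over a
fixed set of drugs: an edge labeled +1 is *enhancive* (the interaction
increases the drugs' pharmacological behaviour, e.g. serum concentration) and
an edge labeled -1 is *degressive* (decreases it).  The network lives in a
symmetric m x m adjacency matrix with entries in {-1, 0, +1} and a zero
diagonal.  Each drug additionally carries a binary feature vector over p
side-effect vocabulary entries; vectors stack into an m x p matrix.

On-disk formats
---------------
* Edge list: TSV with header ``drug_a<TAB>drug_b<TAB>type`` where ``type`` is
  ``enhancive``/``degressive`` or ``+1``/``-1``.
* Feature matrix: MatrixMarket coordinate file plus sidecar ``features.txt``
  and ``drugs.txt`` (one label per line, order defines columns/rows).  A dense
  delimited table is also accepted for small inputs.
* Network statistics serialize to JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "DrugSet",
    "InteractionMatrix",
    "FeatureMatrix",
    "NetworkStats",
    "load_drug_list",
    "load_interactions",
    "save_interactions",
    "load_features",
    "save_features",
    "binarize",
    "network_stats",
]

_TYPE_ALIASES = {
    "enhancive": 1,
    "degressive": -1,
    "+1": 1,
    "1": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
}


@dataclass(frozen=True)
class DrugSet:
    """Ordered set of unique drug identifiers with a 0-based index."""

    ids: tuple[str, ...]
    index: Mapping[str, int] = field(compare=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = tuple(str(d) for d in self.ids)
        if not ids:
            raise ValueError("drug set must be non-empty")
        if any(d == "" for d in ids):
            raise ValueError("drug identifiers must be non-empty strings")
        index = {d: i for i, d in enumerate(ids)}
        if len(index) != len(ids):
            dupes = sorted({d for d in ids if ids.count(d) > 1})
            raise ValueError(f"duplicate drug identifiers: {dupes}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "index", index)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, drug: str) -> bool:
        return drug in self.index

    def position(self, drug: str) -> int:
        try:
            return self.index[drug]
        except KeyError:
            raise KeyError(f"unknown drug id: {drug!r}") from None


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric signed adjacency of a comprehensive DDI network.

    ``values[i, j]`` is +1 for an enhancive interaction between drugs i and j,
    -1 for a degressive one and 0 for no known interaction.  The diagonal is
    zero: drugs do not interact with themselves.
    """

    values: np.ndarray
    drugs: DrugSet

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"interaction matrix must be square, got {v.shape}")
        if v.shape[0] != len(self.drugs):
            raise ValueError(
                f"matrix size {v.shape[0]} != number of drugs {len(self.drugs)}"
            )
        if not np.isin(v, (-1, 0, 1)).all():
            raise ValueError("interaction entries must be in {-1, 0, +1}")
        if not np.array_equal(v, v.T):
            raise ValueError("interaction matrix must be symmetric")
        if np.any(np.diagonal(v) != 0):
            raise ValueError("interaction matrix must have a zero diagonal (no self-loops)")
        object.__setattr__(self, "values", v.astype(np.int8))

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary drugs-by-side-effects occurrence matrix with named columns."""

    values: np.ndarray
    drugs: DrugSet
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if v.shape[0] != len(self.drugs):
            raise ValueError(
                f"feature matrix has {v.shape[0]} rows for {len(self.drugs)} drugs"
            )
        names = tuple(str(f) for f in self.feature_names)
        if len(names) != v.shape[1]:
            raise ValueError(
                f"{len(names)} feature names for {v.shape[1]} columns"
            )
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("feature entries must be binary (0/1)")
        object.__setattr__(self, "values", v.astype(np.int8))
        object.__setattr__(self, "feature_names", names)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive statistics of a comprehensive DDI network."""

    n_drugs: int
    n_interactions: int
    n_enhancive: int
    n_degressive: int
    degree_summary: dict[str, float]
    enhancive_degree_summary: dict[str, float]
    degressive_degree_summary: dict[str, float]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def load_drug_list(path: str | Path) -> DrugSet:
    """Read a one-id-per-line drug list (``drugs.txt``)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    return DrugSet(tuple(ln for ln in lines if ln))


def _parse_sign(raw: str) -> int:
    key = str(raw).strip().lower()
    if key not in _TYPE_ALIASES:
        raise ValueError(
            f"unrecognized interaction type {raw!r}; expected enhancive/degressive or +1/-1"
        )
    return _TYPE_ALIASES[key]


def load_interactions(edge_list_path: str | Path, drugs: DrugSet) -> InteractionMatrix:
    """Load a signed edge list into a symmetric adjacency matrix.

    Duplicate identical edges are tolerated (with a warning) and deduplicated;
    the same pair listed with conflicting signs is a hard error, as are
    self-loops and unknown drug ids.
    """
    df = pd.read_csv(edge_list_path, sep="\t", dtype=str)
    expected = ["drug_a", "drug_b", "type"]
    if list(df.columns[:3]) != expected:
        raise ValueError(
            f"edge list must have header {expected}, got {list(df.columns)}"
        )
    m = len(drugs)
    values = np.zeros((m, m), dtype=np.int8)
    seen: dict[tuple[int, int], int] = {}
    n_dupes = 0
    for row in df.itertuples(index=False):
        a, b = drugs.position(row.drug_a), drugs.position(row.drug_b)
        if a == b:
            raise ValueError(f"self-loop on drug {row.drug_a!r} is not allowed")
        sign = _parse_sign(row.type)
        key = (min(a, b), max(a, b))
        if key in seen:
            if seen[key] != sign:
                raise ValueError(
                    f"conflicting duplicate edge ({row.drug_a}, {row.drug_b}): "
                    f"{seen[key]:+d} vs {sign:+d}"
                )
            n_dupes += 1
            continue
        seen[key] = sign
        values[a, b] = values[b, a] = sign
    if n_dupes:
        warnings.warn(f"deduplicated {n_dupes} repeated identical edge(s)", stacklevel=2)
    return InteractionMatrix(values, drugs)


def save_interactions(A: InteractionMatrix, edge_list_path: str | Path) -> None:
    """Write the upper-triangle edges back to the TSV edge-list format."""
    rows = []
    i_idx, j_idx = np.nonzero(np.triu(A.values, k=1))
    for i, j in zip(i_idx, j_idx):
        kind = "enhancive" if A.values[i, j] > 0 else "degressive"
        rows.append((A.drugs.ids[i], A.drugs.ids[j], kind))
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "type"]).to_csv(
        edge_list_path, sep="\t", index=False
    )


def load_features(
    matrix_path: str | Path,
    features_path: str | Path,
    drugs: DrugSet | None = None,
    drugs_path: str | Path | None = None,
) -> FeatureMatrix:
    """Load a binary feature matrix.

    ``matrix_path`` may be a MatrixMarket coordinate file (``.mtx``) or a dense
    delimited table.  Feature names come one-per-line from ``features_path``;
    the drug order comes from ``drugs`` or from a ``drugs.txt`` sidecar.
    All-zero side-effect columns are kept but reported in a warning.
    """
    if drugs is None:
        if drugs_path is None:
            raise ValueError("provide either a DrugSet or a drugs_path sidecar")
        drugs = load_drug_list(drugs_path)
    names = [ln.strip() for ln in Path(features_path).read_text().splitlines() if ln.strip()]
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        mat = scipy.io.mmread(matrix_path)
        values = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat
        )
    else:
        values = pd.read_csv(matrix_path, sep="\t", header=None).to_numpy()
    fm = FeatureMatrix(values, drugs, tuple(names))
    empty = np.flatnonzero(fm.values.sum(axis=0) == 0)
    if empty.size:
        warnings.warn(
            f"{empty.size} all-zero feature column(s), e.g. "
            f"{[names[k] for k in empty[:5]]}",
            stacklevel=2,
        )
    return fm


def save_features(F: FeatureMatrix, out_dir: str | Path) -> None:
    """Write ``F.mtx`` + ``features.txt`` + ``drugs.txt`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "F.mtx", scipy.sparse.coo_matrix(F.values))
    (out / "features.txt").write_text("\n".join(F.feature_names) + "\n")
    (out / "drugs.txt").write_text("\n".join(F.drugs.ids) + "\n")


def binarize(A: InteractionMatrix) -> InteractionMatrix:
    """Collapse the signed network to the conventional binary one.

    Every nonzero entry (enhancive or degressive) becomes +1; the binary
    adjacency is the special case of the comprehensive one.
    """
    return InteractionMatrix(np.abs(A.values), A.drugs)


def _summary(degrees: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(degrees)),
        "median": float(np.median(degrees)),
        "max": float(np.max(degrees)),
        "min": float(np.min(degrees)),
    }


def network_stats(A: InteractionMatrix) -> NetworkStats:
    """Counts and per-drug degree summaries of the signed DDI network.

    Interactions are counted as unordered pairs; each drug's total degree is
    the sum of its enhancive and degressive degrees.
    """
    v = A.values
    enh = (v > 0).sum(axis=1)
    deg = (v < 0).sum(axis=1)
    return NetworkStats(
        n_drugs=A.n_drugs,
        n_interactions=int((v != 0).sum() // 2),
        n_enhancive=int((v > 0).sum() // 2),
        n_degressive=int((v < 0).sum() // 2),
        degree_summary=_summary(enh + deg),
        enhancive_degree_summary=_summary(enh),
        degressive_degree_summary=_summary(deg),
    )
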