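"""Readers and writers for intensity matrices, labels and reconstructed networks.

The central container is :class:`SpectraDataset`: a subjects x measurements
matrix of (digitized) spectral intensities plus a binary class label per
subject.  Two on-disk dialects are supported: the dense whitespace-separated
``.data`` / ``.labels`` pair used by the ARCENE feature-selection benchmark,
and generic delimited text (CSV/TSV) with a header row.  Per-subject networks
are exported as TSV edge lists or GraphML.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

CONTROL = "control"
PATIENT = "patient"
LABELS = (CONTROL, PATIENT)


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected dialect."""


@dataclass
class SpectraDataset:
    """Subjects x measurements intensity matrix with binary class labels.

    Parameters
    ----------
    intensities : (n_subjects, n_features) float array
        Non-negative spectral intensities in arbitrary units.  Negative
        values are rejected unless ``allow_negative`` is set (mass spectra
        are non-negative, but synthetic or transformed data may not be).
    labels : sequence of str
        Per-subject class tag, ``"control"`` or ``"patient"``.
    feature_ids : sequence
        Ordered, unique measurement identifiers (integer index or m/z label).
    subject_ids : sequence
        Ordered subject identifiers.
    """

    intensities: np.ndarray
    labels: np.ndarray
    feature_ids: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D subjects x features matrix")
        self.labels = np.asarray(self.labels, dtype=object)
        n_subj, n_feat = self.intensities.shape
        if not self.feature_ids:
            self.feature_ids = list(range(n_feat))
        if not self.subject_ids:
            self.subject_ids = [f"S{i}" for i in range(n_subj)]
        self.feature_ids = list(self.feature_ids)
        self.subject_ids = list(self.subject_ids)
        if len(self.labels) != n_subj:
            raise ValueError(
                f"{len(self.labels)} labels for {n_subj} subjects"
            )
        if len(self.feature_ids) != n_feat:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {n_feat} columns"
            )
        if len(set(self.feature_ids)) != n_feat:
            raise ValueError("feature_ids must be unique")
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length mismatch")
        bad = sorted({l for l in self.labels} - set(LABELS))
        if bad:
            raise ValueError(f"unknown label values: {bad}; allowed: {LABELS}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.allow_negative and np.any(self.intensities < 0):
            raise ValueError(
                "negative intensities found; pass allow_negative=True to accept"
            )

    @property
    def n_subjects(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def class_rows(self, label: str) -> np.ndarray:
        """Row indices of subjects with the given class label."""
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return np.flatnonzero(self.labels == label)

    def class_counts(self) -> dict:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def subset(self, rows: Sequence[int]) -> "SpectraDataset":
        """Dataset restricted to the given subject rows (order preserved)."""
        rows = np.asarray(rows, dtype=int)
        return SpectraDataset(
            intensities=self.intensities[rows],
            labels=self.labels[rows],
            feature_ids=list(self.feature_ids),
            subject_ids=[self.subject_ids[i] for i in rows],
            allow_negative=self.allow_negative,
        )


def read_arcene(
    data_path,
    labels_path,
    positive_label: int = 1,
    allow_negative: bool = False,
) -> SpectraDataset:
    """Read a dense whitespace-separated matrix plus a +1/-1 labels file.

    This is the dialect of the ARCENE benchmark (NIPS 2003 feature-selection
    challenge): one subject per row, whitespace-separated intensities, and a
    separate file with one numeric label per line.  By challenge convention
    the positive class (+1) is the disease class; ``positive_label=-1``
    flips the mapping.
    """
    if positive_label not in (1, -1):
        raise ValueError("positive_label must be +1 or -1")
    rows: list[list[float]] = []
    with open(data_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            values = []
            for col, tok in enumerate(tokens, start=1):
                try:
                    values.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"{data_path}: non-numeric token {tok!r} "
                        f"at line {lineno}, column {col}"
                    ) from None
            if rows and len(values) != len(rows[0]):
                raise FormatError(
                    f"{data_path}: row {len(rows) + 1} has {len(values)} values, "
                    f"expected {len(rows[0])}"
                )
            rows.append(values)
    if not rows:
        raise FormatError(f"{data_path}: empty data file")

    labels: list[str] = []
    with open(labels_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                val = int(float(tok))
            except ValueError:
                raise FormatError(
                    f"{labels_path}: non-numeric label {tok!r} at line {lineno}"
                ) from None
            if val not in (1, -1):
                raise FormatError(
                    f"{labels_path}: label must be +1 or -1, got {val} "
                    f"at line {lineno}"
                )
            labels.append(PATIENT if val == positive_label else CONTROL)
    if not labels:
        raise FormatError(f"{labels_path}: empty labels file")
    if len(labels) != len(rows):
        raise FormatError(
            f"{len(labels)} labels for {len(rows)} data rows"
        )
    return SpectraDataset(
        intensities=np.asarray(rows, dtype=float),
        labels=np.asarray(labels, dtype=object),
        feature_ids=list(range(len(rows[0]))),
        subject_ids=[f"S{i}" for i in range(len(rows))],
        allow_negative=allow_negative,
    )


def read_delimited(
    path,
    label_column: str = "label",
    id_column: str | None = None,
    allow_negative: bool = False,
) -> SpectraDataset:
    """Read a delimited (CSV/TSV, sniffed) matrix with a header row.

    One column holds the class labels (``control`` / ``patient``); a subject
    identifier column named ``subject_id`` is used automatically when present.
    All remaining columns become features in header order.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if label_column not in df.columns:
        raise FormatError(
            f"{path}: label column {label_column!r} not found "
            f"(columns: {list(df.columns)})"
        )
    if id_column is None and "subject_id" in df.columns:
        id_column = "subject_id"
    if id_column is not None:
        if id_column not in df.columns:
            raise FormatError(f"{path}: id column {id_column!r} not found")
        subject_ids = [str(s) for s in df[id_column]]
    else:
        subject_ids = [f"S{i}" for i in range(len(df))]
    labels = [str(l) for l in df[label_column]]
    for sid, lab in zip(subject_ids, labels):
        if lab not in LABELS:
            raise FormatError(
                f"{path}: subject {sid!r} has unknown label {lab!r}; "
                f"allowed: {LABELS}"
            )
    feature_cols = [
        c for c in df.columns if c != label_column and c != id_column
    ]
    mat = df[feature_cols].to_numpy(dtype=float)
    return SpectraDataset(
        intensities=mat,
        labels=np.asarray(labels, dtype=object),
        feature_ids=[str(c) for c in feature_cols],
        subject_ids=subject_ids,
        allow_negative=allow_negative,
    )


def write_delimited(dataset: SpectraDataset, path, delimiter: str = ",") -> None:
    """Write a dataset as delimited text; round-trips bit-for-bit.

    Floats are printed with ``repr`` precision so that
    ``read_delimited(write_delimited(x))`` reproduces the intensity matrix
    exactly.
    """
    df = pd.DataFrame(
        dataset.intensities, columns=[str(f) for f in dataset.feature_ids]
    )
    df.insert(0, "label", list(dataset.labels))
    df.insert(0, "subject_id", [str(s) for s in dataset.subject_ids])
    # %.17g guarantees the written decimal parses back to the same double
    df.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def write_network(net, path, format: str = "edge_list") -> None:
    """Write a subject network as a TSV edge list or GraphML.

    Edge-list lines are ``node_i<TAB>node_j<TAB>weight`` with ``i < j`` in
    node order; weights are printed with 17 significant digits so the round
    trip is exact to double precision.
    """
    if format == "edge_list":
        lines = []
        for (i, j), w in net.iter_edges():
            lines.append(f"{i}\t{j}\t{w:.17g}")
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "graphml":
        import networkx as nx

        nx.write_graphml(net.to_networkx(), path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network_edge_list(path, subject_id=None):
    """Read a TSV edge list written by :func:`write_network` back into a
    :class:`~specnet.network_model.SubjectNetwork`.

    Nodes are inferred from edge endpoints (integer feature indices), so an
    edgeless file cannot be reconstructed this way.
    """
    from .network_model import SubjectNetwork

    pairs = []
    weights = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: malformed edge at line {lineno}")
        i, j, w = int(parts[0]), int(parts[1]), float(parts[2])
        pairs.append((i, j))
        weights.append(w)
    if not pairs:
        raise FormatError(f"{path}: no edges; node set cannot be inferred")
    nodes = sorted({n for p in pairs for n in p})
    pos = {n: idx for idx, n in enumerate(nodes)}
    k = len(nodes)
    wmat = np.zeros((k, k))
    for (i, j), w in zip(pairs, weights):
        wmat[pos[i], pos[j]] = w
        wmat[pos[j], pos[i]] = w
    ii, jj = np.triu_indices(k, 1)
    return SubjectNetwork(
        subject_id=subject_id,
        nodes=np.asarray(nodes),
        weights=wmat[ii, jj],
    )
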