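"""The samples x features data container shared by every stage.

A :class:`FeatureMatrix` holds the numeric matrix E (element ``e_sv`` is
feature v of sample s — presence 0/1 for variant data, or the variant
allele FREQ percentage), the sample and feature identifiers, and the
paired class-indicator vectors c^p and c^n. Each sample belongs to
exactly one of the two classes, so ``c_neg = 1 - c_pos`` always.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class FeatureMatrix:
    X: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    c_pos: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.c_pos = np.asarray(self.c_pos, dtype=int)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        s, v = self.X.shape
        if len(self.sample_ids) != s:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {s} rows")
        if len(self.feature_ids) != v:
            raise ValueError(f"{len(self.feature_ids)} feature ids for {v} columns")
        if self.c_pos.shape != (s,):
            raise ValueError("c_pos must have one entry per sample")
        if not np.isin(self.c_pos, (0, 1)).all():
            raise ValueError("c_pos must be a 0/1 indicator vector")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample ids")
        if len(set(self.feature_ids)) != v:
            raise ValueError("duplicate feature ids")

    @property
    def c_neg(self) -> np.ndarray:
        return 1 - self.c_pos

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def y(self) -> np.ndarray:
        """Binary labels: 1 for the positive class, 0 for the negative."""
        return self.c_pos.copy()

    def subset_features(self, indices) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            X=self.X[:, indices],
            sample_ids=list(self.sample_ids),
            feature_ids=[self.feature_ids[i] for i in indices],
            c_pos=self.c_pos,
        )

    # ---- TSV round-trip --------------------------------------------------

    def to_tsv(self, matrix_path, labels_path=None) -> None:
        """Write the matrix (header = feature ids, first column = sample id)
        and, optionally, a two-column sample/class label file."""
        df = pd.DataFrame(self.X, columns=self.feature_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(matrix_path, sep="\t", index=False)
        if labels_path is not None:
            lab = pd.DataFrame(
                {
                    "sample_id": self.sample_ids,
                    "class": [POSITIVE if c else NEGATIVE for c in self.c_pos],
                }
            )
            lab.to_csv(labels_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, labels_path) -> "FeatureMatrix":
        df = pd.read_csv(matrix_path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in df.columns:
            raise ValueError(f"{matrix_path}: expected a 'sample_id' first column")
        sample_ids = df["sample_id"].tolist()
        feature_ids = [c for c in df.columns if c != "sample_id"]
        labels = read_labels(labels_path)
        missing = [s for s in sample_ids if s not in labels]
        if missing:
            raise ValueError(f"samples missing from label file: {missing}")
        c_pos = np.array([1 if labels[s] == POSITIVE else 0 for s in sample_ids])
        return cls(
            X=df[feature_ids].to_numpy(dtype=float),
            sample_ids=sample_ids,
            feature_ids=feature_ids,
            c_pos=c_pos,
        )


def normalize_class_label(value) -> str:
    """Map common encodings of the two classes onto 'positive'/'negative'."""
    text = str(value).strip().lower()
    if text in {POSITIVE, "pos", "1", "true", "case"}:
        return POSITIVE
    if text in {NEGATIVE, "neg", "0", "false", "control"}:
        return NEGATIVE
    raise ValueError(f"unrecognized class label {value!r}")


def read_labels(path) -> dict[str, str]:
    """Read a two-column (sample_id, class) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class)")
    sid, cls = cols[0], cols[1]
    out: dict[str, str] = {}
    for s, c in zip(df[sid], df[cls]):
        s = str(s)
        if s in out:
            raise ValueError(f"duplicate sample id in label file: {s}")
        out[s] = normalize_class_label(c)
    return out


__all__ = ["FeatureMatrix", "read_labels", "normalize_class_label", "POSITIVE", "NEGATIVE"]
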