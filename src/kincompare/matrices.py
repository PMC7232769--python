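"""Square id-labeled matrices: kinship, relatedness and their estimates.

A :class:`LabeledMatrix` is the lingua franca between the pedigree,
estimator, pairing and statistics layers: a symmetric square array with a
stable individual-id index.  Kinship matrices carry kinship coefficients
``f`` with ``0.5 * (1 + F)`` on the diagonal; relatedness matrices carry
``R`` (diagonal ``1 + F``, or exactly 1 after scaling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["LabeledMatrix", "KinshipMatrix", "RelatednessMatrix"]


@dataclass
class LabeledMatrix:
    ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        self._index = {i: k for k, i in enumerate(self.ids)}
        if len(self._index) != n:
            raise ValueError("duplicate ids in matrix index")

    # -- access ----------------------------------------------------------
    def loc(self, a: str, b: str) -> float:
        return float(self.values[self._index[str(a)], self._index[str(b)]])

    def index_of(self, a: str) -> int:
        return self._index[str(a)]

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.values).copy()

    def reindex(self, ids: Sequence[str]) -> "LabeledMatrix":
        idx = [self._index[str(i)] for i in ids]
        return LabeledMatrix(list(ids), self.values[np.ix_(idx, idx)], dict(self.meta))

    def offdiag(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries, row-major order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=tol, equal_nan=True))

    # -- io ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in self.meta.items():
                fh.write(f"# {key}: {val}\n")
            fh.write("id," + ",".join(self.ids) + "\n")
            for i, row in zip(self.ids, self.values):
                cells = [("." if np.isnan(v) else repr(float(v))) for v in row]
                fh.write(i + "," + ",".join(cells) + "\n")

    @classmethod
    def from_csv(cls, path) -> "LabeledMatrix":
        meta: dict = {}
        rows: list[list[float]] = []
        ids: list[str] = []
        header: list[str] | None = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n").rstrip("\r")
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if ":" in body:
                        k, v = body.split(":", 1)
                        meta[k.strip()] = v.strip()
                    continue
                cells = line.split(",")
                if header is None:
                    header = cells[1:]
                    continue
                ids.append(cells[0])
                rows.append(
                    [np.nan if c == "." else float(c) for c in cells[1:]]
                )
        if header is None:
            raise ValueError(f"empty matrix file: {path}")
        if ids != header:
            raise ValueError("matrix row ids do not match header ids")
        return cls(ids, np.array(rows, dtype=float), meta)


# The pedigree and estimator layers produce the same container; the aliases
# exist to make signatures self-describing.
KinshipMatrix = LabeledMatrix
RelatednessMatrix = LabeledMatrix
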