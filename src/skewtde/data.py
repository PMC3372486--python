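"""Expression data container and the log2 normalization step."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionDataSet", "log2_transform"]


@dataclass
class ExpressionDataSet:
    """A probes x arrays log2 expression matrix with a two-group design.

    Parameters
    ----------
    values:
        ``(m, n)`` float array of (log2) expression; NaN marks a missing
        cell (dropped from the observation vector when the design is built).
    probe_ids, array_ids:
        Unique, non-empty identifiers for the m probes and n arrays.
    group:
        Per-array treatment label coded 1 or 2; both groups must be
        non-empty. Group 1 is the reference; the differential-expression
        effect d_k is the group-2 minus group-1 contrast within probe k.
    """

    values: np.ndarray
    probe_ids: list = field(default_factory=list)
    array_ids: list = field(default_factory=list)
    group: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D probes x arrays matrix")
        m, n = self.values.shape
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.array_ids = [str(a) for a in self.array_ids]
        if len(self.probe_ids) != m:
            raise ValueError(f"{len(self.probe_ids)} probe_ids for {m} rows")
        if len(self.array_ids) != n:
            raise ValueError(f"{len(self.array_ids)} array_ids for {n} columns")
        for name, ids in (("probe", self.probe_ids), ("array", self.array_ids)):
            if any(not i for i in ids):
                raise ValueError(f"missing (empty) {name} identifier")
            dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
            if dupes:
                raise ValueError(f"duplicated {name} identifiers: {dupes}")
        self.group = np.asarray(self.group, dtype=int)
        if self.group.shape != (n,):
            raise ValueError(f"group must have one label per array ({n})")
        labels = set(np.unique(self.group).tolist())
        if labels != {1, 2}:
            raise ValueError(
                f"exactly two treatment groups labeled 1 and 2 required, got {sorted(labels)}"
            )

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_arrays(self) -> int:
        return self.values.shape[1]

    @property
    def group_sizes(self) -> tuple[int, int]:
        return int(np.sum(self.group == 1)), int(np.sum(self.group == 2))

    def to_frame(self) -> pd.DataFrame:
        """Expression values as a probes x arrays DataFrame."""
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.array_ids)


def log2_transform(values: np.ndarray) -> np.ndarray:
    """Elementwise base-2 logarithm of a raw (linear-scale) expression matrix.

    Raises on non-positive entries, listing the offending cells.
    """
    values = np.asarray(values, dtype=float)
    bad = ~(values > 0)
    if np.any(bad):
        cells = list(zip(*np.nonzero(bad)))
        shown = ", ".join(f"(row {r}, col {c})" for r, c in cells[:10])
        more = "" if len(cells) <= 10 else f" and {len(cells) - 10} more"
        raise ValueError(
            f"log2 transform requires strictly positive values; "
            f"non-positive entries at {shown}{more}"
        )
    return np.log2(values)
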