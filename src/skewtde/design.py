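"""Design-matrix construction for the mixed model y = Xa + Z1 p + Z2 d + e.

X, Z1 and Z2 are 0/1 incidence matrices: each observation (one expression
value, probe k on array i) points at its array effect a_i, its probe effect
p_k and — for group-2 observations only — the within-probe differential
effect d_k. Observations are ordered probe-major (all arrays of probe 1,
then probe 2, ...); missing (NaN) cells are dropped.

The sampler does not multiply these (potentially large) sparse matrices;
it works on the equivalent probes x arrays grid stored alongside them
(``Y``, ``mask``, ``group2``). Both views are built here so they cannot
drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .data import ExpressionDataSet

__all__ = ["DesignMatrices", "build_design", "fitted_values"]


@dataclass
class DesignMatrices:
    """Incidence matrices and observation vector for one dataset.

    ``X`` (obs x arrays), ``Z1`` (obs x probes) and ``Z2`` (obs x probes)
    are CSR 0/1 matrices; a row of ``Z2`` is nonzero iff the observation
    belongs to treatment group 2. ``Y``/``mask``/``group2`` are the dense
    grid view used by the sampler: ``Y`` is the m x n value matrix with
    missing cells zeroed, ``mask`` flags observed cells, ``group2`` flags
    group-2 arrays. ``obs_probe``/``obs_array`` map observations back to
    grid coordinates.
    """

    X: sparse.csr_matrix
    Z1: sparse.csr_matrix
    Z2: sparse.csr_matrix
    y: np.ndarray
    probe_ids: list
    array_ids: list
    Y: np.ndarray
    mask: np.ndarray
    group2: np.ndarray
    obs_probe: np.ndarray
    obs_array: np.ndarray

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_probes(self) -> int:
        return self.Z1.shape[1]

    @property
    def n_arrays(self) -> int:
        return self.X.shape[1]


def build_design(ds: ExpressionDataSet) -> DesignMatrices:
    """Build the incidence matrices for a validated two-group dataset.

    Column order of Z1/Z2 follows ``ds.probe_ids``; column order of X
    follows ``ds.array_ids``. Raises if either treatment group is empty or
    an array has no observed value.
    """
    m, n = ds.values.shape
    mask = np.isfinite(ds.values)
    n1, n2 = ds.group_sizes
    if n1 == 0 or n2 == 0:
        raise ValueError("both treatment groups must be non-empty")
    dead = [ds.array_ids[i] for i in range(n) if not mask[:, i].any()]
    if dead:
        raise ValueError(f"arrays with no observed values: {dead}")
    dead_probes = [ds.probe_ids[k] for k in range(m) if not mask[k].any()]
    if dead_probes:
        raise ValueError(f"probes with no observed values: {dead_probes}")

    obs_probe, obs_array = np.nonzero(mask)  # probe-major order
    y = ds.values[obs_probe, obs_array]
    n_obs = y.size
    rows = np.arange(n_obs)
    ones = np.ones(n_obs)
    X = sparse.csr_matrix((ones, (rows, obs_array)), shape=(n_obs, n))
    Z1 = sparse.csr_matrix((ones, (rows, obs_probe)), shape=(n_obs, m))
    group2 = ds.group == 2
    in_g2 = group2[obs_array]
    Z2 = sparse.csr_matrix(
        (ones[in_g2], (rows[in_g2], obs_probe[in_g2])), shape=(n_obs, m)
    )
    Y = np.where(mask, ds.values, 0.0)
    return DesignMatrices(
        X=X,
        Z1=Z1,
        Z2=Z2,
        y=y,
        probe_ids=list(ds.probe_ids),
        array_ids=list(ds.array_ids),
        Y=Y,
        mask=mask,
        group2=group2,
        obs_probe=obs_probe,
        obs_array=obs_array,
    )


def fitted_values(state, design: DesignMatrices) -> np.ndarray:
    """Fitted observation vector X a + Z1 p + Z2 d.

    ``state`` is anything with ``a``, ``p`` and ``d`` vectors (a
    :class:`~skewtde.sampler.ChainState` in practice). The fitted value for
    observation (array i, probe k) is ``a_i + p_k + d_k * [group(i)=2]``.
    """
    a = np.asarray(state.a, dtype=float)
    p = np.asarray(state.p, dtype=float)
    d = np.asarray(state.d, dtype=float)
    if a.shape != (design.n_arrays,):
        raise ValueError(f"a has shape {a.shape}, expected ({design.n_arrays},)")
    if p.shape != (design.n_probes,) or d.shape != (design.n_probes,):
        raise ValueError("p and d must have one entry per probe")
    out = a[design.obs_array] + p[design.obs_probe]
    g2 = design.group2[design.obs_array]
    out[g2] += d[design.obs_probe[g2]]
    return out
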