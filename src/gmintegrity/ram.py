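"""Compilation of model specifications to RAM matrices.

The reticular-action-model form collects every variable (observed first,
then latent) into one vector with a directed-coefficient matrix ``A``
(``A[i, j]`` is the path ``j -> i``), a symmetric matrix ``S`` of variances
and covariances, a mean vector ``M`` and an implicit filter selecting the
observed variables.  Implied moments follow the standard algebra

``Sigma = F (I-A)^{-1} S (I-A)^{-T} F'``,  ``mu = F (I-A)^{-1} M``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .modelspec import ModelSpec

A_MAT, S_MAT, M_VEC = 0, 1, 2


@dataclass
class RAMMatrices:
    """Compiled numeric form of a :class:`ModelSpec`."""

    var_names: list[str]
    n_observed: int
    A0: np.ndarray  # fixed baseline of A
    S0: np.ndarray
    M0: np.ndarray
    #: free-parameter cells: label -> list of (matrix code, i, j)
    free: dict = field(default_factory=dict)
    param_names: list[str] = field(default_factory=list)
    start: np.ndarray | None = None
    mean_param_names: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    @property
    def observed_idx(self) -> np.ndarray:
        return np.arange(self.n_observed)

    def materialize(self, theta: np.ndarray):
        """Fill A, S, M with the fixed baseline plus free values."""
        A = self.A0.copy()
        S = self.S0.copy()
        M = self.M0.copy()
        for k, label in enumerate(self.param_names):
            for mat, i, j in self.free[label]:
                if mat == A_MAT:
                    A[i, j] = theta[k]
                elif mat == S_MAT:
                    S[i, j] = theta[k]
                    S[j, i] = theta[k]
                else:
                    M[i] = theta[k]
        return A, S, M

    def index_of(self, label: str) -> int:
        return self.param_names.index(label)


def compile_ram(spec: ModelSpec) -> RAMMatrices:
    """Deterministically map a validated spec onto RAM matrices."""
    spec.validate()
    names = spec.variables
    idx = {v: i for i, v in enumerate(names)}
    m = len(names)
    A0 = np.zeros((m, m))
    S0 = np.zeros((m, m))
    M0 = np.zeros(m)
    free: dict[str, list] = {}
    starts: dict[str, float] = {}

    def register(label, cell, start=None):
        free.setdefault(label, []).append(cell)
        if start is not None and label not in starts:
            starts[label] = start

    for p in spec.paths:
        i, j = idx[p.dst], idx[p.src]
        if p.value is not None:
            A0[i, j] = p.value
        else:
            register(p.label, (A_MAT, i, j), p.start)
    for c in spec.covs:
        i, j = idx[c.a], idx[c.b]
        if c.value is not None:
            S0[i, j] = S0[j, i] = c.value
        else:
            register(c.label, (S_MAT, i, j), c.start)
    mean_labels = []
    for v in names:
        term = spec.mean_term(v)
        if isinstance(term, str):
            register(term, (M_VEC, idx[v], idx[v]))
            mean_labels.append(term)
        else:
            M0[idx[v]] = float(term)

    param_names = list(free.keys())
    ram = RAMMatrices(var_names=names, n_observed=len(spec.observed),
                      A0=A0, S0=S0, M0=M0, free=free, param_names=param_names,
                      mean_param_names=mean_labels)
    # default starts; data-aware refinement happens in fit()
    th0 = np.zeros(ram.n_params)
    for k, label in enumerate(param_names):
        mat, i, j = free[label][0]
        if label in starts:
            th0[k] = starts[label]
        elif mat == A_MAT:
            th0[k] = 1.0
        elif mat == S_MAT:
            th0[k] = 0.5 if i == j else 0.0
    ram.start = th0
    return ram


def implied_moments(ram: RAMMatrices, theta: np.ndarray):
    """Model-implied mean vector and covariance of the observed variables."""
    A, S, M = ram.materialize(np.asarray(theta, dtype=float))
    m = A.shape[0]
    ImA = np.eye(m) - A
    try:
        E = np.linalg.inv(ImA)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular (I - A): check directed paths") from err
    full_cov = E @ S @ E.T
    full_mean = E @ M
    obs = ram.observed_idx
    return full_mean[obs], full_cov[np.ix_(obs, obs)]


def model_df(spec: ModelSpec, observed_count: int | None = None) -> int:
    """Degrees of freedom with a saturated mean structure.

    Counts covariance moments only: ``p(p+1)/2`` minus the number of unique
    free covariance-structure parameters (labels shared between cells count
    once).  Raises if the model is over-parameterized.
    """
    p = observed_count if observed_count is not None else len(spec.observed)
    df = p * (p + 1) // 2 - len(spec.free_structure_labels())
    if df < 0:
        raise ValueError(f"negative degrees of freedom ({df}): over-parameterized model")
    return df
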