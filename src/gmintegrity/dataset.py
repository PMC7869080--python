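"""Rectangular numeric tables with missing cells and column roles.

A :class:`Dataset` is a thin wrapper around a :class:`pandas.DataFrame` that
carries, for every column, a *role*: ``indicator`` (a variable entering a
measurement or structural model), ``covariate`` (age, sex, education, ICV),
``id`` or ``group``.  Missing cells are ``NaN`` in memory and empty strings
on disk (``NA`` is also accepted when reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = ("indicator", "covariate", "id", "group")


@dataclass
class Dataset:
    """A numeric table plus column roles.

    Parameters
    ----------
    frame
        The data; numeric columns except possibly an id/group column.
    roles
        Mapping column name -> role, one of ``indicator``, ``covariate``,
        ``id``, ``group``.  Columns absent from the mapping default to
        ``indicator``.
    """

    frame: pd.DataFrame
    roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col, role in self.roles.items():
            if role not in VALID_ROLES:
                raise ValueError(f"unknown role {role!r} for column {col!r}")
            if col not in self.frame.columns:
                raise ValueError(f"role given for absent column {col!r}")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def role_of(self, col: str) -> str:
        return self.roles.get(col, "indicator")

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c in self.frame.columns if self.role_of(c) == role]

    @property
    def indicators(self) -> list[str]:
        return self.columns_with_role("indicator")

    @property
    def covariates(self) -> list[str]:
        return self.columns_with_role("covariate")

    def numeric_columns(self) -> list[str]:
        return [c for c in self.frame.columns if self.role_of(c) not in ("id", "group")]

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        """Numeric matrix (float, NaN for missing) for the given columns."""
        cols = columns if columns is not None else self.numeric_columns()
        return self.frame[cols].to_numpy(dtype=float)

    # -- validation --------------------------------------------------------
    def validate(self, analysis_columns: list[str] | None = None) -> None:
        """Check the dataset invariants.

        Every non-missing cell must be finite, and no column of the analysis
        subset may be entirely missing.
        """
        cols = analysis_columns if analysis_columns is not None else self.numeric_columns()
        x = self.matrix(cols)
        observed = ~np.isnan(x)
        if not np.isfinite(x[observed]).all():
            raise ValueError("non-missing cells must be finite")
        empty = ~observed.any(axis=0)
        if empty.any():
            bad = [c for c, e in zip(cols, empty) if e]
            raise ValueError(f"all-missing analysis columns: {bad}")

    def copy(self) -> "Dataset":
        return Dataset(self.frame.copy(), dict(self.roles))

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the table; missing cells are empty strings."""
        self.frame.to_csv(path, index=False, na_rep="")

    @classmethod
    def read_csv(cls, path, roles: dict[str, str] | None = None) -> "Dataset":
        """Read a CSV with header; empty cells and ``NA`` are missing."""
        frame = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
        return cls(frame, roles or {})
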