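"""Dose-effect tables.

A :class:`DoseResponseTable` holds one record per administration: a dose
vector (one entry per compound, zero meaning "not given") and the observed
effect as a fraction in [0, 1].  Rows naturally fall into *groups* sharing
the same support (the set of compounds with nonzero dose): single-drug
series, binary mixture rays, ternary mixtures, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["DoseResponseTable"]


@dataclass
class DoseResponseTable:
    """Tabular dose-effect data for an n-compound study.

    Parameters
    ----------
    compounds
        Compound names, one per dose column.
    doses
        Array of shape (rows, n_compounds); nonnegative, finite.
    effects
        Observed effect fractions in [0, 1], shape (rows,).
    units
        Free-text dose units (e.g. ``"mg/kg"``).
    """

    compounds: list[str]
    doses: np.ndarray
    effects: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.compounds = list(self.compounds)
        self.doses = np.asarray(self.doses, dtype=float)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.doses.ndim != 2 or self.doses.shape[1] != len(self.compounds):
            raise ValueError(
                f"dose array shape {self.doses.shape} does not match "
                f"{len(self.compounds)} compounds"
            )
        if self.effects.shape != (self.doses.shape[0],):
            raise ValueError("effects length does not match number of rows")
        if len(self.effects) < 1:
            raise ValueError("table must contain at least one row")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            bad = np.where(~np.isfinite(self.doses) | (self.doses < 0))[0]
            raise ValueError(f"negative or non-finite dose in row(s) {bad.tolist()}")
        if np.any((self.effects < 0) | (self.effects > 1) | ~np.isfinite(self.effects)):
            bad = np.where((self.effects < 0) | (self.effects > 1))[0]
            raise ValueError(f"effect outside [0, 1] in row(s) {bad.tolist()}")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return self.doses.shape[0]

    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    # -- row classification ------------------------------------------------
    def support(self) -> np.ndarray:
        """Boolean (rows, n) array: which compounds are dosed in each row."""
        return self.doses > 0

    def support_key(self, row: int) -> tuple[str, ...]:
        """Names of the compounds dosed in ``row`` (table order)."""
        mask = self.doses[row] > 0
        return tuple(c for c, m in zip(self.compounds, mask) if m)

    def pure_rows(self, compound: str | None = None) -> np.ndarray:
        """Mask of single-drug rows, optionally for one compound."""
        supp = self.support()
        mask = supp.sum(axis=1) == 1
        if compound is not None:
            j = self.compounds.index(compound)
            mask &= supp[:, j]
        return mask

    def mixture_rows(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Mask of rows with >= 2 compounds dosed.

        With ``names`` given, only rows whose support is exactly that set.
        """
        supp = self.support()
        mask = supp.sum(axis=1) >= 2
        if names is not None:
            want = np.array([c in set(names) for c in self.compounds])
            mask &= (supp == want).all(axis=1)
        return mask

    def groups(self) -> dict[tuple[str, ...], np.ndarray]:
        """Row masks keyed by support set, mixture groups only."""
        out: dict[tuple[str, ...], np.ndarray] = {}
        for i in range(len(self)):
            key = self.support_key(i)
            if len(key) >= 2 and key not in out:
                out[key] = np.array(
                    [self.support_key(r) == key for r in range(len(self))]
                )
        return out

    # -- derived tables ----------------------------------------------------
    def select(self, mask: np.ndarray) -> "DoseResponseTable":
        return DoseResponseTable(
            self.compounds, self.doses[mask], self.effects[mask], self.units
        )

    def restrict(self, names: Sequence[str]) -> "DoseResponseTable":
        """Sub-table over ``names``: rows dosing only those compounds.

        Keeps single-drug rows of each named compound and mixture rows whose
        support is a subset of ``names``; drops the other dose columns.
        """
        idx = [self.compounds.index(c) for c in names]
        others = [j for j in range(self.n_compounds) if j not in idx]
        keep = (self.doses[:, others] == 0).all(axis=1) if others else np.ones(
            len(self), bool
        )
        keep &= self.doses[:, idx].sum(axis=1) > 0
        return DoseResponseTable(
            [self.compounds[j] for j in idx],
            self.doses[np.ix_(keep.nonzero()[0], idx)],
            self.effects[keep],
            self.units,
        )

    def dose_range(self, compound: str) -> tuple[float, float]:
        """(lowest nonzero, highest) dose of ``compound`` anywhere in the table."""
        j = self.compounds.index(compound)
        col = self.doses[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"compound {compound!r} is never dosed")
        return float(nz.min()), float(nz.max())

    # -- interchange -------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.doses, columns=self.compounds)
        df["effect"] = self.effects
        return df

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        compounds: Iterable[str],
        effect_column: str = "effect",
        units: str = "",
    ) -> "DoseResponseTable":
        compounds = list(compounds)
        missing = [c for c in compounds + [effect_column] if c not in df.columns]
        if missing:
            raise ValueError(f"missing column(s): {missing}")
        return cls(
            compounds,
            df[compounds].to_numpy(dtype=float),
            df[effect_column].to_numpy(dtype=float),
            units,
        )
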