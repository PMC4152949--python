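"""Dinucleotide structural-property tables.

A :class:`PropertyTable` holds per-dinucleotide values of structural
descriptors of the DNA double helix — by default the six base-pair step
parameters: the angular twist, tilt and roll and the translational shift,
slide and rise.  Before entering the pseudo dinucleotide composition each
property is standardized (z-scored) across the 16 dinucleotides, so the
encoder is invariant to the units and offsets of the raw table.

The packaged default table (``data/dinucleotide_properties.tsv``) carries
consensus B-DNA crystallographic averages; any table in the same TSV dialect
can be substituted.

TSV dialect: a header row ``dinucleotide<TAB>twist<TAB>...`` followed by 16
data rows, one per dinucleotide; ``#`` lines are comments; the pragma line
``#standardized=true`` marks a table whose values are already z-scores.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegeneratePropertyError, DhspredError

#: the 16 dinucleotides in fixed lexicographic order (column order everywhere)
DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in "ACGT" for b in "ACGT")

DEFAULT_PROPERTIES: tuple[str, ...] = ("twist", "tilt", "roll", "shift", "slide", "rise")

_STANDARDIZED_PRAGMA = "#standardized=true"


class PropertyTable:
    """mu structural properties x 16 dinucleotides, raw or standardized.

    Parameters
    ----------
    values
        DataFrame with property names as the index and the 16 dinucleotides
        (lexicographic order) as columns.
    standardized
        Whether ``values`` are already z-scores per property.
    """

    def __init__(self, values: pd.DataFrame, standardized: bool = False):
        missing = [d for d in DINUCLEOTIDES if d not in values.columns]
        if missing:
            raise DhspredError(f"property table missing dinucleotides: {missing}")
        extra = [c for c in values.columns if c not in DINUCLEOTIDES]
        if extra:
            raise DhspredError(f"property table has unknown columns: {extra}")
        self.values = values.loc[:, list(DINUCLEOTIDES)].astype(float)
        self.standardized = bool(standardized)
        if self.values.isna().any().any():
            raise DhspredError("property table contains missing values")

    @property
    def property_names(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def n_properties(self) -> int:
        return len(self.values.index)

    def value(self, prop: str, dinucleotide: str) -> float:
        if dinucleotide not in DINUCLEOTIDES:
            raise DhspredError(f"unknown dinucleotide {dinucleotide!r}")
        return float(self.values.at[prop, dinucleotide])

    def standardize(self) -> "PropertyTable":
        """z-score each property across the 16 dinucleotides.

        Uses the population standard deviation (divide by 16).  A property
        with zero variance cannot be standardized and raises
        :class:`~dhspred.exceptions.DegeneratePropertyError`.  Applied to an
        already-standardized table this is a no-op up to floating error.
        """
        if self.standardized:
            return self
        arr = self.values.to_numpy()
        mean = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, keepdims=True)  # population sd
        zero = np.flatnonzero(sd.ravel() == 0.0)
        if zero.size:
            names = [self.values.index[i] for i in zero]
            raise DegeneratePropertyError(
                f"zero variance across dinucleotides for propert"
                f"{'y' if len(names) == 1 else 'ies'}: {', '.join(map(str, names))}"
            )
        out = pd.DataFrame(
            (arr - mean) / sd, index=self.values.index, columns=self.values.columns
        )
        return PropertyTable(out, standardized=True)

    def theta_matrix(self) -> np.ndarray:
        """16x16 matrix of pairwise structural correlation distances.

        ``Theta(x, y) = (1/mu) * sum_xi (P_xi(x) - P_xi(y))**2`` over the
        standardized property values; symmetric with a zero diagonal.
        """
        std = self.standardize()
        arr = std.values.to_numpy()  # mu x 16
        diff = arr[:, :, None] - arr[:, None, :]
        return (diff**2).mean(axis=0)

    def checksum(self) -> str:
        """sha256 of the canonical table content, for model provenance."""
        payload = self.values.round(12).to_csv(sep="\t").encode()
        payload += b"standardized=%d" % int(self.standardized)
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PropertyTable":
        path = Path(path)
        standardized = False
        rows: list[str] = []
        with open(path) as fh:
            for line in fh:
                stripped = line.strip()
                if stripped.replace(" ", "").lower() == _STANDARDIZED_PRAGMA:
                    standardized = True
                    continue
                if stripped.startswith("#") or not stripped:
                    continue
                rows.append(line)
        if not rows:
            raise DhspredError(f"{path}: empty property table")
        from io import StringIO

        df = pd.read_csv(StringIO("".join(rows)), sep="\t")
        if df.columns[0] != "dinucleotide":
            raise DhspredError(f"{path}: first column must be 'dinucleotide'")
        df = df.set_index("dinucleotide")
        if len(df) != 16:
            raise DhspredError(f"{path}: expected 16 dinucleotide rows, got {len(df)}")
        # dialect stores dinucleotides as rows; internal layout is properties x dinucleotides
        return cls(df.T, standardized=standardized)

    def to_tsv(self, path: str | Path) -> None:
        df = self.values.T.reset_index().rename(columns={"index": "dinucleotide"})
        with open(path, "w") as fh:
            if self.standardized:
                fh.write(_STANDARDIZED_PRAGMA + "\n")
            df.to_csv(fh, sep="\t", index=False)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, PropertyTable)
            and self.standardized == other.standardized
            and self.values.equals(other.values)
        )


_default_table: PropertyTable | None = None


def default_table() -> PropertyTable:
    """The packaged six-property B-DNA step-parameter table (raw values)."""
    global _default_table
    if _default_table is None:
        ref = resources.files("dhspred.data").joinpath("dinucleotide_properties.tsv")
        with resources.as_file(ref) as path:
            _default_table = PropertyTable.from_tsv(path)
    return _default_table
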