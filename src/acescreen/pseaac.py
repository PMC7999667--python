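"""Type-II (amphiphilic) pseudo amino acid composition encoding.

A peptide of length ``L`` is represented by ``20 + i*lambda`` features:
the 20 residue frequencies ``f_u`` followed by ``i*lambda`` sequence-order
correlation factors built from ``i`` standardized physicochemical property
scales. For property ``p`` and lag ``m``,

    tau_{p,m} = (1/(L-m)) * sum_{j=1..L-m} H_p(R_j) * H_p(R_{j+m})

where ``H_p`` is the property standardized to zero mean and unit
population SD over the 20 residues. Composition and correlation blocks
are blended with a weight ``omega``:

    x_u      = f_u / (1 + omega * sum(tau))            for u = 1..20
    x_{20+j} = omega * tau_j / (1 + omega * sum(tau))  for j = 1..i*lambda

so the full vector sums to exactly 1 by construction. At the defaults
used throughout this package (six properties, lambda=1, omega=0.05) the
vector has 26 dimensions. The product form of tau (rather than the
squared-difference form of type-I PseAAC) is what makes this the type-II,
amphiphilic variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from acescreen.seqio import CANONICAL_AA, Peptide

DEFAULT_PROPERTY_NAMES = ("hydrophobicity", "hydrophilicity", "mass", "pK1", "pK2", "pI")


class PeptideTooShortError(ValueError):
    """Peptide length does not exceed the requested correlation lag."""


class DegenerateEncodingError(ValueError):
    """The blending denominator 1 + omega*sum(tau) is numerically zero."""


@dataclass(frozen=True)
class PropertyTable:
    """Physicochemical scales over the 20 residues, raw and standardized.

    ``raw`` and ``standardized`` are ``(n_properties, 20)`` arrays with
    columns in alphabetical one-letter residue order. Each standardized
    row has zero mean and unit population standard deviation.
    """

    names: tuple[str, ...]
    raw: np.ndarray
    standardized: np.ndarray
    provenance: tuple[str, ...] = ()

    @property
    def n_properties(self) -> int:
        return len(self.names)

    def row(self, name: str) -> np.ndarray:
        """Standardized 20-vector for one property."""
        return self.standardized[self.names.index(name)]

    def residue_values(self, name: str) -> dict[str, float]:
        row = self.row(name)
        return {aa: float(row[i]) for i, aa in enumerate(CANONICAL_AA)}


@dataclass(frozen=True)
class PseAACParams:
    """Encoding parameters: correlation depth, order weight, property count."""

    lambda_: int = 1
    omega: float = 0.05
    n_properties: int = 6

    def __post_init__(self) -> None:
        if self.lambda_ < 1:
            raise ValueError(f"lambda_ must be a positive integer, got {self.lambda_}")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        if self.n_properties < 1:
            raise ValueError(f"n_properties must be positive, got {self.n_properties}")

    @property
    def dimension(self) -> int:
        return 20 + self.n_properties * self.lambda_


@dataclass(frozen=True)
class PseAACVector:
    values: np.ndarray
    params: PseAACParams
    peptide_id: str = ""

    def __post_init__(self) -> None:
        if len(self.values) != self.params.dimension:
            raise ValueError(
                f"vector length {len(self.values)} != 20 + i*lambda = {self.params.dimension}"
            )


def standardize_properties(
    raw: np.ndarray,
    names: Sequence[str] = DEFAULT_PROPERTY_NAMES,
    provenance: Sequence[str] = (),
) -> PropertyTable:
    """Standardize each property row to mean 0 and population SD 1.

    Uses the divide-by-n (population) standard deviation over the 20
    residues, the convention under which PseAAC correlation factors are
    defined. A constant row has no scale information and is rejected.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 20:
        raise ValueError(f"raw table must be (n_properties, 20), got {raw.shape}")
    if raw.shape[0] != len(names):
        raise ValueError("number of names must match number of rows")
    means = raw.mean(axis=1, keepdims=True)
    sds = raw.std(axis=1, ddof=0, keepdims=True)
    for i, sd in enumerate(sds.ravel()):
        if sd == 0:
            raise ValueError(f"property {names[i]!r} is constant (zero variance)")
    standardized = (raw - means) / sds
    return PropertyTable(
        names=tuple(names),
        raw=raw,
        standardized=standardized,
        provenance=tuple(provenance),
    )


def load_property_table(path: Union[str, Path]) -> PropertyTable:
    """Load a property-scale TSV (rows=properties, columns=residues A..Y)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    missing = [aa for aa in CANONICAL_AA if aa not in df.columns]
    if missing:
        raise ValueError(f"property table missing residue columns: {missing}")
    raw = df[list(CANONICAL_AA)].to_numpy(dtype=float)
    return standardize_properties(raw, names=tuple(df.index), provenance=(str(path),))


def load_default_property_table() -> PropertyTable:
    """The six shipped scales: hydrophobicity, hydrophilicity, mass, pK1, pK2, pI."""
    ref = resources.files("acescreen.data") / "property_scales.tsv"
    with resources.as_file(ref) as path:
        table = load_property_table(path)
    if table.names != DEFAULT_PROPERTY_NAMES:
        raise RuntimeError("shipped property table is corrupted")
    return table


def correlation_factor(peptide: Peptide, property_row: np.ndarray, lag: int) -> float:
    """Mean product of standardized property values at residue pairs ``lag`` apart."""
    seq = peptide.sequence
    L = len(seq)
    if lag < 1:
        raise ValueError(f"lag must be a positive integer, got {lag}")
    if L <= lag:
        raise PeptideTooShortError(
            f"peptide {peptide.id!r} (length {L}) cannot be encoded at lag {lag}"
        )
    idx = np.fromiter((CANONICAL_AA.index(ch) for ch in seq), dtype=int, count=L)
    h = np.asarray(property_row, dtype=float)[idx]
    return float(np.mean(h[:-lag] * h[lag:]))


def encode(
    peptide: Peptide,
    table: Optional[PropertyTable] = None,
    params: PseAACParams = PseAACParams(),
) -> PseAACVector:
    """Encode one peptide as a type-II PseAAC vector.

    The correlation block is ordered lag-major, property-minor: all
    properties at lag 1, then all at lag 2, and so on (irrelevant at the
    default lambda=1, but pinned for larger depths). Requires peptide
    length >= lambda + 1 so every lag is computable.
    """
    if table is None:
        table = load_default_property_table()
    if table.n_properties != params.n_properties:
        raise ValueError(
            f"table has {table.n_properties} properties but params expect {params.n_properties}"
        )
    seq = peptide.sequence
    L = len(seq)
    if L < params.lambda_ + 1:
        raise PeptideTooShortError(
            f"peptide {peptide.id!r} (length {L}) is shorter than lambda+1 = {params.lambda_ + 1}"
        )
    idx = np.fromiter((CANONICAL_AA.index(ch) for ch in seq), dtype=int, count=L)
    freqs = np.bincount(idx, minlength=20).astype(float) / L
    taus = np.empty(params.n_properties * params.lambda_)
    for m in range(1, params.lambda_ + 1):
        for p in range(params.n_properties):
            h = table.standardized[p][idx]
            taus[(m - 1) * params.n_properties + p] = np.mean(h[:-m] * h[m:])
    denom = 1.0 + params.omega * taus.sum()
    if abs(denom) <= 1e-8:
        raise DegenerateEncodingError(
            f"peptide {peptide.id!r}: blending denominator {denom:.3e} is numerically zero"
        )
    values = np.concatenate([freqs, params.omega * taus]) / denom
    return PseAACVector(values=values, params=params, peptide_id=peptide.id)


def encode_batch(
    peptides: Sequence[Peptide],
    table: Optional[PropertyTable] = None,
    params: PseAACParams = PseAACParams(),
) -> tuple[np.ndarray, list[str], list[tuple[str, str]]]:
    """Encode many peptides into an ``(n, 20 + i*lambda)`` feature matrix.

    Returns ``(matrix, ids, skipped)`` where ``skipped`` lists
    ``(peptide_id, reason)`` for peptides that could not be encoded
    (too short for the requested lag). Row order follows input order.
    Raises if no peptide is encodable.
    """
    if table is None:
        table = load_default_property_table()
    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped: list[tuple[str, str]] = []
    for pep in peptides:
        try:
            vec = encode(pep, table, params)
        except (PeptideTooShortError, DegenerateEncodingError) as exc:
            skipped.append((pep.id, str(exc)))
            continue
        rows.append(vec.values)
        ids.append(pep.id)
    if not rows:
        raise ValueError(f"no encodable peptides among {len(peptides)} input(s)")
    return np.vstack(rows), ids, skipped
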