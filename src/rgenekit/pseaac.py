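"""Pseudo amino acid composition (Pse-AAC, type I).

Augments the 20 normalized residue frequencies with lambda sequence-order
correlation factors, yielding a (20 + lambda)-dimensional vector that sums
to 1:

    p_u = f_u / (sum_i f_i + w * sum_j e_j)          for u = 1..20
    p_{20+j} = w * e_j / (sum_i f_i + w * sum_j e_j)  for j = 1..lambda

where f_i is the occurrence count of residue i, w the weight factor, and
e_j the rank-j correlation factor

    e_j = (1 / (L - j)) * sum_{i=1..L-j} Theta(r_i, r_{i+j}),

Theta being the mean, over a set of per-residue numeric property scales
standardized to zero mean / unit variance across the 20 residues, of the
squared differences between the two residues' standardized values.

Defaults: lambda = 10, w = 0.05, scales = hydrophobicity, hydrophilicity and
side-chain mass, giving the 30-dimensional descriptor used throughout the
pipeline. With lambda = 0 the vector reduces exactly to normalized
amino-acid composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from rgenekit.sequence_io import Alphabet, ProteinRecord

DEFAULT_SCALES = ("hydrophobicity", "hydrophilicity", "side_chain_mass")


def _load_scale_table() -> pd.DataFrame:
    source = resources.files("rgenekit").joinpath("data/pseaac_scales.tsv")
    table = pd.read_csv(source.open(), sep="\t").set_index("residue")
    return table.loc[list(Alphabet.RESIDUES)]


def standardized_scales(names: tuple[str, ...] = DEFAULT_SCALES) -> np.ndarray:
    """Per-residue property values, standardized over the 20 residues.

    Returns an array of shape (n_scales, 20) in alphabet order, each row with
    zero mean and unit (population) variance, so Theta is unit-free.
    """
    table = _load_scale_table()
    rows = []
    for name in names:
        if name not in table.columns:
            raise KeyError(f"unknown property scale {name!r}; available: {list(table.columns)}")
        v = table[name].to_numpy(dtype=float)
        rows.append((v - v.mean()) / v.std())  # population std, ddof=0
    return np.vstack(rows)


@dataclass(frozen=True)
class PseaacConfig:
    """Pse-AAC parameters: correlation rank, weight factor and property scales."""

    lam: int = 10
    omega: float = 0.05
    scales: tuple[str, ...] = DEFAULT_SCALES
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.omega <= 0:
            raise ValueError("weight factor omega must be > 0")
        object.__setattr__(self, "_matrix", standardized_scales(self.scales))

    @property
    def dimension(self) -> int:
        return Alphabet.SIZE + self.lam

    def theta(self, a: str, b: str) -> float:
        """Correlation function: mean squared difference of standardized scale values."""
        ia, ib = Alphabet.INDEX[a], Alphabet.INDEX[b]
        diff = self._matrix[:, ia] - self._matrix[:, ib]
        return float(np.mean(diff**2))


def _indices(record: ProteinRecord) -> np.ndarray:
    """Alphabet indices per position; -1 for wildcards."""
    return np.fromiter(
        (Alphabet.INDEX.get(c, -1) for c in record.sequence),
        dtype=np.int64,
        count=record.length,
    )


def correlation_factor(record: ProteinRecord, j: int, config: PseaacConfig) -> float:
    """Rank-j sequence-order correlation factor e_j.

    Averages Theta over all position pairs (i, i+j). Pairs containing a
    wildcard carry no property information and are skipped; the mean is taken
    over the remaining pairs (0 if none remain).
    """
    if j < 1:
        raise ValueError("lag j must be >= 1")
    if record.length <= j:
        raise ValueError(
            f"record {record.id!r}: sequence shorter than lag (L={record.length}, j={j})"
        )
    idx = _indices(record)
    left, right = idx[:-j], idx[j:]
    valid = (left >= 0) & (right >= 0)
    if not valid.any():
        return 0.0
    m = config._matrix
    diff = m[:, left[valid]] - m[:, right[valid]]
    return float(np.mean(np.mean(diff**2, axis=0)))


def extract_pseaac(record: ProteinRecord, config: PseaacConfig | None = None) -> np.ndarray:
    """The (20 + lambda)-dimensional Pse-AAC vector for one record."""
    config = config or PseaacConfig()
    if record.length <= config.lam:
        raise ValueError(
            f"record {record.id!r}: length {record.length} must exceed lambda={config.lam}"
        )
    idx = _indices(record)
    canonical = idx[idx >= 0]
    if canonical.size == 0:
        raise ValueError(f"record {record.id!r}: all-wildcard sequence has no composition")

    freqs = np.bincount(canonical, minlength=Alphabet.SIZE).astype(float)
    e = np.array([correlation_factor(record, j, config) for j in range(1, config.lam + 1)])

    denom = freqs.sum() + config.omega * e.sum()
    return np.concatenate([freqs, config.omega * e]) / denom


def feature_names_pseaac(config: PseaacConfig | None = None) -> list[str]:
    config = config or PseaacConfig()
    return [f"pseaac_{aa}" for aa in Alphabet.RESIDUES] + [
        f"pseaac_lambda{j}" for j in range(1, config.lam + 1)
    ]


def extract_pseaac_batch(
    records: list[ProteinRecord], config: PseaacConfig | None = None
) -> pd.DataFrame:
    """Pse-AAC matrix: one row per record, 20 + lambda named columns."""
    config = config or PseaacConfig()
    names = feature_names_pseaac(config)
    if not records:
        return pd.DataFrame(columns=names, dtype=float)
    data = np.vstack([extract_pseaac(r, config) for r in records])
    return pd.DataFrame(data, index=[r.id for r in records], columns=names)
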