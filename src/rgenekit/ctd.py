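"""188-dimensional physicochemical sequence descriptor.

The vector concatenates 20 amino-acid-composition (AAC) percentages with, for
each of 8 physicochemical properties, a 21-component block of
composition/transition/distribution (CTD) features:

* Composition (3): percentage of residues falling in each of the property's
  three groups.
* Transition (3): percentage of adjacent residue pairs whose members lie in
  two different groups, for the unordered pairs (1,2), (1,3), (2,3),
  denominator L - 1.
* Distribution (15): for each group, the positions (as a percentage of L) of
  the first, 25%, 50%, 75% and last occurrence of that group's residues.

Total: 20 + 8 x 21 = 188 components, all on the percent scale. Each property
partitions the 20 amino acids into three groups; the partition tables are the
canonical ones from the CTD descriptor literature, shipped as a packaged TSV
so alternates can be swapped in and validated.

Wildcard residues ('X') belong to no group: they contribute to no count, but
composition denominators keep the full sequence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd

from rgenekit.sequence_io import Alphabet, ProteinRecord

logger = logging.getLogger(__name__)

N_FEATURES = 188  # 20 AAC + 8 properties x (3 C + 3 T + 15 D)

#: Registry order of the 8 properties; fixed, defines block order.
PROPERTY_ORDER = (
    "hydrophobicity",
    "normalized_vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "surface_tension",
    "secondary_structure",
    "solvent_accessibility",
)

_TRANSITION_PAIRS = ((1, 2), (1, 3), (2, 3))
_DIST_FRACTIONS = (0.0, 0.25, 0.5, 0.75, 1.0)
_DIST_TAGS = ("first", "25", "50", "75", "100")


@dataclass(frozen=True)
class PropertyPartition:
    """A named 3-group partition of the 20 amino acids."""

    name: str
    groups: tuple[frozenset[str], frozenset[str], frozenset[str]]

    def __post_init__(self) -> None:
        union = set().union(*self.groups)
        total = sum(len(g) for g in self.groups)
        if union != set(Alphabet.RESIDUES) or total != Alphabet.SIZE:
            raise ValueError(
                f"partition {self.name!r}: groups must disjointly cover the 20-letter alphabet"
            )

    def group_of(self, residue: str) -> int:
        """1-based group index; 0 for the wildcard."""
        for idx, group in enumerate(self.groups, start=1):
            if residue in group:
                return idx
        return 0


def load_partitions(path: str | Path | None = None) -> dict[str, PropertyPartition]:
    """Load the property partition registry from a TSV (property, group_index, residues)."""
    if path is None:
        source = resources.files("rgenekit").joinpath("data/ctd_partitions.tsv")
        table = pd.read_csv(source.open(), sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)

    partitions: dict[str, PropertyPartition] = {}
    for name, block in table.groupby("property", sort=False):
        block = block.sort_values("group_index")
        groups = tuple(frozenset(res) for res in block["residues"])
        if len(groups) != 3:
            raise ValueError(f"partition {name!r}: expected 3 groups, got {len(groups)}")
        partitions[name] = PropertyPartition(name=name, groups=groups)  # type: ignore[arg-type]

    missing = set(PROPERTY_ORDER) - partitions.keys()
    if missing:
        raise ValueError(f"partition table missing properties: {sorted(missing)}")
    return partitions


_PARTITIONS: dict[str, PropertyPartition] | None = None


def partitions() -> dict[str, PropertyPartition]:
    """The packaged partition registry (loaded once)."""
    global _PARTITIONS
    if _PARTITIONS is None:
        _PARTITIONS = load_partitions()
    return _PARTITIONS


def aac(record: ProteinRecord) -> np.ndarray:
    """Amino-acid composition: 20 percentages in alphabet order.

    Component i is 100 * count(residue_i) / L; wildcards add to no numerator
    but L stays the full length, so the vector sums to 100 only when the
    sequence is wildcard-free.
    """
    counts = np.zeros(Alphabet.SIZE)
    for c in record.sequence:
        idx = Alphabet.INDEX.get(c)
        if idx is not None:
            counts[idx] += 1
    return 100.0 * counts / record.length


def encode_groups(record: ProteinRecord, partition: PropertyPartition) -> np.ndarray:
    """Position-wise group indices in {1,2,3}; wildcards map to 0."""
    lookup = {aa: partition.group_of(aa) for aa in Alphabet.RESIDUES}
    lookup[Alphabet.WILDCARD] = 0
    return np.fromiter((lookup[c] for c in record.sequence), dtype=np.int8, count=record.length)


def ctd_composition(record: ProteinRecord, partition: PropertyPartition) -> np.ndarray:
    """Percentage of residues in each of the partition's three groups."""
    codes = encode_groups(record, partition)
    return np.array([100.0 * np.count_nonzero(codes == g) / record.length for g in (1, 2, 3)])


def ctd_transition(record: ProteinRecord, partition: PropertyPartition) -> np.ndarray:
    """Cross-group adjacent-pair frequencies for pairs (1,2), (1,3), (2,3).

    T_jk = 100 * (N_jk + N_kj) / (L - 1) where N_jk counts adjacent positions
    with group j followed by group k. A length-1 sequence has no adjacent
    pairs; all transitions are 0 by convention (logged).
    """
    if record.length < 2:
        logger.warning("transition on length-1 sequence %r: all zeros by convention", record.id)
        return np.zeros(3)
    codes = encode_groups(record, partition)
    left, right = codes[:-1], codes[1:]
    out = np.empty(3)
    for i, (j, k) in enumerate(_TRANSITION_PAIRS):
        crossings = np.count_nonzero((left == j) & (right == k)) + np.count_nonzero(
            (left == k) & (right == j)
        )
        out[i] = 100.0 * crossings / (record.length - 1)
    return out


def ctd_distribution(record: ProteinRecord, partition: PropertyPartition) -> np.ndarray:
    """First/25%/50%/75%/100% occurrence positions per group, as % of L.

    For group j with n_j occurrences, the value at fraction f is
    100 * pos(q) / L with q = max(1, ceil(f * n_j)) and pos() the 1-based
    sequence index of the q-th occurrence. An empty group yields five zeros.
    """
    codes = encode_groups(record, partition)
    out = np.zeros(15)
    for gi, g in enumerate((1, 2, 3)):
        positions = np.flatnonzero(codes == g) + 1  # 1-based
        n = positions.size
        if n == 0:
            continue
        for fi, f in enumerate(_DIST_FRACTIONS):
            q = max(1, ceil(f * n))
            out[gi * 5 + fi] = 100.0 * positions[q - 1] / record.length
    return out


def extract_188(record: ProteinRecord) -> np.ndarray:
    """The full 188-D descriptor: AAC then per-property C/T/D blocks."""
    reg = partitions()
    parts = [aac(record)]
    for name in PROPERTY_ORDER:
        p = reg[name]
        parts.extend((ctd_composition(record, p), ctd_transition(record, p), ctd_distribution(record, p)))
    vec = np.concatenate(parts)
    assert vec.size == N_FEATURES
    return vec


def feature_names_188() -> list[str]:
    """Stable column names for the 188-D descriptor."""
    names = [f"aac_{aa}" for aa in Alphabet.RESIDUES]
    for prop in PROPERTY_ORDER:
        names.extend(f"{prop}_C{g}" for g in (1, 2, 3))
        names.extend(f"{prop}_T{j}{k}" for j, k in _TRANSITION_PAIRS)
        for g in (1, 2, 3):
            names.extend(f"{prop}_D{g}_{tag}" for tag in _DIST_TAGS)
    assert len(names) == N_FEATURES
    return names


def extract_188_batch(records: list[ProteinRecord]) -> pd.DataFrame:
    """Descriptor matrix: one row per record (in input order), 188 named columns."""
    names = feature_names_188()
    if not records:
        return pd.DataFrame(columns=names, dtype=float)
    data = np.vstack([extract_188(r) for r in records])
    return pd.DataFrame(data, index=[r.id for r in records], columns=names)
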