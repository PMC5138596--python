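"""Synthetic two-class protein sequence generator.

Stands in for a curated positive/negative protein corpus so every pipeline
stage can be exercised end-to-end with known ground truth. Sequences are
drawn i.i.d. from residue emission distributions; the two classes differ by a
controllable compositional signal:

* negatives emit from a base distribution (uniform by default);
* positives emit from the base shifted toward a designated residue subset,
  with the shift sized so the total-variation distance between the two
  emission distributions equals ``effect`` exactly (mass ``effect`` is
  removed proportionally from residues outside the subset and added
  proportionally inside it).

``effect = 0`` gives identical distributions (a no-signal null);
``effect = 1`` requires a base with no mass on the subset, i.e. disjoint
class alphabets. Lengths are log-normal, clipped to a plausible protein
range. i.i.d. emission carries no positional motifs, so the signal is
visible to composition descriptors; a separate family generator produces
redundant mutated copies for exercising the clustering stage.

Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from rgenekit.sequence_io import (
    Alphabet,
    LabelTable,
    NEGATIVE_LABEL,
    POSITIVE_LABEL,
    ProteinRecord,
)

#: Default enriched subset for the positive class: the charged residues plus
#: histidine, evoking the charge-rich character of many defense peptides.
DEFAULT_SUBSET = "DEHKR"


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 200
    n_neg: int = 200
    effect: float = 0.0  # total-variation distance between class emissions
    enriched_subset: str = DEFAULT_SUBSET
    base_dist: np.ndarray | None = None  # length-20, alphabet order; uniform if None
    length_log_mean: float = float(np.log(250.0))
    length_log_sigma: float = 0.4
    length_range: tuple[int, int] = (50, 1000)
    # family-redundancy settings (generate_redundant_families)
    n_families: int = 10
    copies_per_family: int = 5
    mutation_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect <= 1.0:
            raise ValueError("effect must lie in [0, 1]")
        if not set(self.enriched_subset) <= set(Alphabet.RESIDUES):
            raise ValueError("enriched subset must use canonical residues")
        if self.base_dist is None:
            self.base_dist = np.full(Alphabet.SIZE, 1.0 / Alphabet.SIZE)
        else:
            self.base_dist = np.asarray(self.base_dist, dtype=float)
            if self.base_dist.shape != (Alphabet.SIZE,) or (self.base_dist < 0).any():
                raise ValueError("base_dist must be 20 non-negative probabilities")
            if not np.isclose(self.base_dist.sum(), 1.0):
                raise ValueError("base_dist must sum to 1")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must lie in [0, 1]")


def class_distributions(config: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    """(positive, negative) emission distributions with TV distance = effect."""
    base = config.base_dist
    in_subset = np.array([aa in config.enriched_subset for aa in Alphabet.RESIDUES])
    mass_out = base[~in_subset].sum()
    if config.effect > mass_out + 1e-12:
        raise ValueError(
            f"effect {config.effect} exceeds base mass outside the enriched subset "
            f"({mass_out:.4f}); use a base distribution with less subset mass"
        )
    pos = base.copy()
    if config.effect > 0:
        pos[~in_subset] -= config.effect * base[~in_subset] / mass_out
        mass_in = base[in_subset].sum()
        if mass_in > 0:
            pos[in_subset] += config.effect * base[in_subset] / mass_in
        else:
            pos[in_subset] += config.effect / in_subset.sum()
        pos = np.clip(pos, 0.0, None)
        pos /= pos.sum()
    return pos, base.copy()


def _draw_lengths(n: int, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    lengths = rng.lognormal(config.length_log_mean, config.length_log_sigma, size=n)
    return np.clip(np.rint(lengths), *config.length_range).astype(int)


def _draw_sequence(length: int, dist: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(Alphabet.SIZE, size=length, p=dist)
    return "".join(Alphabet.RESIDUES[i] for i in idx)


def generate_dataset(config: GeneratorConfig) -> tuple[list[ProteinRecord], LabelTable]:
    """Draw the labeled two-class dataset defined by ``config``."""
    rng = np.random.default_rng(config.seed)
    pos_dist, neg_dist = class_distributions(config)

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    for prefix, n, dist, label in (
        ("pos", config.n_pos, pos_dist, POSITIVE_LABEL),
        ("neg", config.n_neg, neg_dist, NEGATIVE_LABEL),
    ):
        lengths = _draw_lengths(n, config, rng)
        for i, L in enumerate(lengths):
            rid = f"{prefix}_{i:05d}"
            records.append(
                ProteinRecord(
                    id=rid,
                    sequence=_draw_sequence(L, dist, rng),
                    description=f"synthetic {label} effect={config.effect}",
                )
            )
            labels[rid] = label
    return records, LabelTable(labels)


def _mutate(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability ``rate`` to a different residue."""
    chars = list(sequence)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for pos in hits:
        current = Alphabet.INDEX[chars[pos]]
        new = rng.integers(Alphabet.SIZE - 1)
        if new >= current:
            new += 1
        chars[pos] = Alphabet.RESIDUES[new]
    return "".join(chars)


def generate_redundant_families(config: GeneratorConfig) -> list[ProteinRecord]:
    """Families of near-duplicate sequences for the clustering stage.

    Each family is one ancestor drawn from the base distribution plus
    ``copies_per_family - 1`` copies mutated at the per-site rate, so the
    expected copy-to-ancestor identity is about 1 - mutation_rate.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ProteinRecord] = []
    lengths = _draw_lengths(config.n_families, config, rng)
    for f in range(config.n_families):
        ancestor = _draw_sequence(lengths[f], config.base_dist, rng)
        records.append(
            ProteinRecord(id=f"fam{f:03d}_copy00", sequence=ancestor, description="family ancestor")
        )
        for c in range(1, config.copies_per_family):
            records.append(
                ProteinRecord(
                    id=f"fam{f:03d}_copy{c:02d}",
                    sequence=_mutate(ancestor, config.mutation_rate, rng),
                    description=f"mutated copy rate={config.mutation_rate}",
                )
            )
    return records
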