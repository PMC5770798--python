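"""Synthetic protein benchmarks with planted gapped-pair signal.

Each class is described by a :class:`FamilyProfile`: a base amino-acid
distribution, a length range, and a set of biased gapped residue pairs.
Sequences are drawn i.i.d. from the base distribution and a number of
positions proportional to the enrichment multiplier is rewritten to plant
(a, gap G, b) occurrences, so the intended pair enrichment is guaranteed
at any length. The default benchmark mirrors the heavily imbalanced
class sizes of the curated HSP training corpus (354 HSP20, 1,257 HSP40,
159 HSP60, 278 HSP70, 52 HSP90, 81 HSP100) plus a signal-free non-HSP
class; DnaJ sub-type defaults are 63/53/1107/22 for Types I-IV.

This is not a biological sequence simulator: there is no phylogeny and no
domain/motif structure beyond the planted pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import AMINO_ACIDS, LabeledDataset, ProteinSequence

FAMILY_COUNTS = {
    "HSP20": 354,
    "HSP40": 1257,
    "HSP60": 159,
    "HSP70": 278,
    "HSP90": 52,
    "HSP100": 81,
}
DNAJ_COUNTS = {"Type-I": 63, "Type-II": 53, "Type-III": 1107, "Type-IV": 22}
NEGATIVE_LABEL = "non-HSP"

#: planted gapped pairs per class, chosen to be pairwise distinct descriptors
FAMILY_PAIRS = {
    "HSP20": (("A", "C", 0), ("D", "E", 1), ("F", "G", 2), ("H", "I", 3)),
    "HSP40": (("K", "L", 0), ("M", "N", 1), ("P", "Q", 2), ("R", "S", 3)),
    "HSP60": (("T", "V", 0), ("W", "Y", 1), ("A", "D", 2), ("C", "E", 3)),
    "HSP70": (("F", "H", 0), ("G", "I", 1), ("K", "M", 2), ("L", "N", 3)),
    "HSP90": (("P", "R", 0), ("Q", "S", 1), ("T", "W", 2), ("V", "Y", 3)),
    "HSP100": (("A", "E", 0), ("C", "D", 1), ("F", "I", 2), ("G", "H", 3)),
}
DNAJ_PAIRS = {
    "Type-I": (("A", "K", 0), ("C", "L", 1), ("D", "M", 2), ("E", "N", 3)),
    "Type-II": (("F", "P", 0), ("G", "Q", 1), ("H", "R", 2), ("I", "S", 3)),
    "Type-III": (("K", "T", 0), ("L", "V", 1), ("M", "W", 2), ("N", "Y", 3)),
    "Type-IV": (("P", "A", 0), ("Q", "C", 1), ("R", "D", 2), ("S", "E", 3)),
}

#: enrichment multiplier of the "strong bias" study condition
STRONG_MULTIPLIER = 10.0
DEFAULT_LENGTH_RANGE = (80, 600)


@dataclass(frozen=True)
class FamilyProfile:
    """Generative description of one sequence class."""

    name: str
    base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(20, 0.05)
    )
    biased_pairs: tuple = ()  # (residue a, residue b, gap G, multiplier > 1)
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE

    def __post_init__(self) -> None:
        freqs = np.asarray(self.base_frequencies, dtype=float)
        object.__setattr__(self, "base_frequencies", freqs)
        if freqs.shape != (20,) or abs(freqs.sum() - 1.0) > 1e-9 or (freqs < 0).any():
            raise ValueError(
                f"profile {self.name!r}: base_frequencies must be 20 "
                f"non-negative probabilities summing to 1"
            )
        pairs = tuple(self.biased_pairs)
        object.__setattr__(self, "biased_pairs", pairs)
        max_gap = max((p[2] for p in pairs), default=0)
        lo, hi = self.length_range
        if lo < max_gap + 2 or hi < lo:
            raise ValueError(
                f"profile {self.name!r}: minimum length must be >= max gap + 2"
            )
        for a, b, gap, *rest in pairs:
            mult = rest[0] if rest else STRONG_MULTIPLIER
            if a not in AMINO_ACIDS or b not in AMINO_ACIDS or gap < 0 or mult <= 1:
                raise ValueError(f"profile {self.name!r}: invalid biased pair {(a, b, gap)}")

    def pair_descriptors(self) -> list[str]:
        """Feature names of the planted pairs in GPC naming."""
        return [f"g{gap}_{a}{b}" for a, b, gap, *_ in self.biased_pairs]


def generate_sequence(
    profile: FamilyProfile, rng: np.random.Generator, seq_id: str | None = None
) -> ProteinSequence:
    """Draw one sequence: i.i.d. residues from the base distribution, then
    planted occurrences of each biased pair.

    The number of planted (a, gap, b) occurrences is
    ``round((multiplier - 1) * (N - G - 1) * p_a * p_b)`` — the expected
    excess over the i.i.d. pair count at the requested enrichment.
    Raises if a pair would require more plants than there are pair slots.
    """
    lo, hi = profile.length_range
    n = int(rng.integers(lo, hi + 1))
    codes = rng.choice(20, size=n, p=profile.base_frequencies)
    residues = np.array(list(AMINO_ACIDS))[codes]
    for a, b, gap, *rest in profile.biased_pairs:
        mult = rest[0] if rest else STRONG_MULTIPLIER
        slots = n - gap - 1
        p_a = profile.base_frequencies[AMINO_ACIDS.index(a)]
        p_b = profile.base_frequencies[AMINO_ACIDS.index(b)]
        n_plant = int(round((mult - 1.0) * slots * p_a * p_b))
        if n_plant > slots:
            raise ValueError(
                f"profile {profile.name!r}: cannot plant {n_plant} "
                f"({a},{b},gap={gap}) pairs into {slots} slots of a "
                f"length-{n} sequence"
            )
        if n_plant:
            starts = rng.integers(0, slots, size=n_plant)
            residues[starts] = a
            residues[starts + gap + 1] = b
    return ProteinSequence(
        id=seq_id or f"{profile.name}_seq", residues="".join(residues)
    )


@dataclass(frozen=True)
class BenchmarkSpec:
    """Profiles, per-class counts and the seed of one benchmark draw."""

    profiles: tuple[FamilyProfile, ...]
    counts: dict[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "profiles", tuple(self.profiles))
        object.__setattr__(self, "counts", dict(self.counts))
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError("duplicate profile names")
        if set(self.counts) != set(names):
            raise ValueError("counts must cover exactly the profile names")
        if min(self.counts.values()) < 1:
            raise ValueError("all class counts must be >= 1")


def generate_benchmark(spec: BenchmarkSpec) -> LabeledDataset:
    """Deterministically draw a labeled dataset with exact class counts."""
    rng = np.random.default_rng(spec.seed)
    sequences, labels = [], []
    for profile in spec.profiles:
        for i in range(spec.counts[profile.name]):
            sequences.append(
                generate_sequence(profile, rng, seq_id=f"{profile.name}_{i + 1:05d}")
            )
            labels.append(profile.name)
    return LabeledDataset(sequences, labels)


def _scaled(counts: dict[str, int], scale: float) -> dict[str, int]:
    return {k: max(2, int(round(v * scale))) for k, v in counts.items()}


def strong_benchmark_spec(
    seed: int = 0,
    scale: float = 1.0,
    n_negative: int | None = None,
    multiplier: float = STRONG_MULTIPLIER,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> BenchmarkSpec:
    """Six HSP families with strong planted pair signal plus a signal-free
    non-HSP class. Counts default to the curated-corpus imbalance, scaled
    by ``scale``; negatives default to the total positive count."""
    counts = _scaled(FAMILY_COUNTS, scale)
    if n_negative is None:
        n_negative = sum(counts.values())
    profiles = [
        FamilyProfile(
            name=fam,
            biased_pairs=tuple((a, b, g, multiplier) for a, b, g in FAMILY_PAIRS[fam]),
            length_range=length_range,
        )
        for fam in FAMILY_COUNTS
    ]
    profiles.append(FamilyProfile(name=NEGATIVE_LABEL, length_range=length_range))
    counts[NEGATIVE_LABEL] = n_negative
    return BenchmarkSpec(profiles=tuple(profiles), counts=counts, seed=seed)


def null_benchmark_spec(
    seed: int = 0, n_per_class: int = 300,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> BenchmarkSpec:
    """Two identical signal-free classes — the no-signal calibration."""
    profiles = (
        FamilyProfile(name="HSP", length_range=length_range),
        FamilyProfile(name=NEGATIVE_LABEL, length_range=length_range),
    )
    return BenchmarkSpec(
        profiles=profiles,
        counts={"HSP": n_per_class, NEGATIVE_LABEL: n_per_class},
        seed=seed,
    )


def dnaj_benchmark_spec(
    seed: int = 0,
    scale: float = 1.0,
    multiplier: float = STRONG_MULTIPLIER,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
) -> BenchmarkSpec:
    """Four DnaJ sub-type classes with strong planted pair signal."""
    profiles = tuple(
        FamilyProfile(
            name=t,
            biased_pairs=tuple((a, b, g, multiplier) for a, b, g in DNAJ_PAIRS[t]),
            length_range=length_range,
        )
        for t in DNAJ_COUNTS
    )
    return BenchmarkSpec(
        profiles=profiles, counts=_scaled(DNAJ_COUNTS, scale), seed=seed
    )
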