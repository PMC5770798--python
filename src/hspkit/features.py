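"""Compositional feature encoders for protein sequences.

Four descriptor families are implemented:

GPC
    *g*-spaced amino-acid pair composition. For a gap ``G`` the descriptor
    for the ordered pair (a, b) is the number of positions ``p`` with
    residue ``a`` at ``p`` and ``b`` at ``p + G + 1``, divided by
    ``N - G - 1`` (the number of such pairs in a length-``N`` sequence).
    ``G = 0`` is the classical dipeptide composition; each gap contributes
    400 descriptors that sum to one.

PAAC
    Pseudo amino-acid composition: the 20 residue occurrence counts
    augmented with *d* sequence-order correlation factors
    ``rho_j = mean_i (Theta(s_i) - Theta(s_{i+j}))**2`` computed from a
    residue property standardized to zero mean and unit root-mean-square
    deviation over the 20 amino acids. All 20 + d entries share the
    denominator ``sum(f) + w * sum(rho)``, so they sum to one.

CTD
    Composition / transition / distribution descriptors over three-group
    physicochemical partitions of the alphabet (7 attributes by default,
    21 descriptors each).

ACF
    Autocorrelation features: for each property table and lag ``j`` the
    mean lagged product of standardized property values along the sequence.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, LabeledDataset, ProteinSequence, SequenceError

__all__ = [
    "FeatureVector",
    "AAPropertyTable",
    "PAACConfig",
    "CTDAttribute",
    "CTDScheme",
    "gpc",
    "gpc_combined",
    "paac",
    "ctd",
    "acf",
    "encode_dataset",
    "make_encoder",
    "load_property_tables",
    "default_property_tables",
    "default_paac_table",
    "load_ctd_scheme",
    "default_ctd_scheme",
]

_LUT = np.full(128, -1, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _LUT[ord(_a)] = _i


def residue_indices(seq: ProteinSequence) -> np.ndarray:
    """Map residues to integer codes 0..19 in alphabet order."""
    codes = _LUT[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    return codes


class SequenceTooShortError(SequenceError):
    """Sequence shorter than an encoder's minimum length."""


class ZeroVarianceError(ValueError):
    """A property table is constant and cannot be standardized."""


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named real-valued descriptors."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names and values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.names)

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.names))


@dataclass(frozen=True)
class AAPropertyTable:
    """One real property value per standard amino acid (AAindex style)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != set(AMINO_ACIDS):
            raise ValueError(
                f"property table {self.name!r} must cover exactly the 20 "
                f"standard amino acids (missing {sorted(set(AMINO_ACIDS) - keys)}, "
                f"extra {sorted(keys - set(AMINO_ACIDS))})"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    def standardized(self) -> np.ndarray:
        """Center to zero mean, scale by root-mean-square deviation over
        the 20 amino acids."""
        v = self.as_array()
        centered = v - v.mean()
        rms = np.sqrt(np.mean(centered**2))
        if rms == 0.0:
            raise ZeroVarianceError(
                f"property table {self.name!r} is constant; cannot standardize"
            )
        return centered / rms


# ---------------------------------------------------------------------------
# GPC — g-spaced amino-acid pair composition
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def gpc_names(G: int) -> tuple[str, ...]:
    """Descriptor names for gap G, row-major alphabetical pair order."""
    return tuple(f"g{G}_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS)


def gpc(seq: ProteinSequence, G: int = 0) -> FeatureVector:
    """400 pair-composition descriptors at gap ``G`` (skipped residues)."""
    if G < 0:
        raise ValueError(f"gap must be non-negative, got {G}")
    n = len(seq)
    if n < G + 2:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} too short for gap G={G}: length N={n} < G+2"
        )
    idx = residue_indices(seq)
    first = idx[: n - G - 1]
    second = idx[G + 1 :]
    counts = np.zeros((20, 20), dtype=float)
    np.add.at(counts, (first, second), 1.0)
    return FeatureVector(gpc_names(G), counts.ravel() / (n - G - 1))


def gpc_combined(seq: ProteinSequence, gaps=(0, 1, 2, 3)) -> FeatureVector:
    """Concatenated GPC blocks for each gap in ascending order."""
    gaps = sorted(set(int(g) for g in gaps))
    if not gaps:
        raise ValueError("at least one gap is required")
    names: list[str] = []
    blocks: list[np.ndarray] = []
    for g in gaps:
        fv = gpc(seq, g)
        names.extend(fv.names)
        blocks.append(fv.values)
    return FeatureVector(tuple(names), np.concatenate(blocks))


# ---------------------------------------------------------------------------
# PAAC — pseudo amino-acid composition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PAACConfig:
    """Tier count ``d``, sequence-order weight ``w`` and the residue
    property used for the correlation factors.

    Defaults: first-tier correlation only (d=1) with weight w=0.05 on the
    classical hydrophobicity scale.
    """

    d: int = 1
    w: float = 0.05
    property_table: AAPropertyTable | None = None

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"d must be a positive integer, got {self.d}")
        if not self.w > 0:
            raise ValueError(f"w must be positive, got {self.w}")

    def table(self) -> AAPropertyTable:
        return self.property_table if self.property_table is not None else default_paac_table()


def paac(seq: ProteinSequence, config: PAACConfig | None = None) -> FeatureVector:
    """(20 + d)-dimensional pseudo amino-acid composition.

    The first 20 entries are ``f_x / (sum f + w * sum rho)`` with ``f_x``
    the raw occurrence count of amino acid ``x``; the last ``d`` entries are
    ``w * rho_j`` over the same denominator, so the vector sums to one.
    """
    config = config or PAACConfig()
    L = len(seq)
    if L <= config.d:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} of length L={L} too short for d={config.d} "
            f"correlation tiers (requires L > d)"
        )
    theta = config.table().standardized()
    idx = residue_indices(seq)
    prop = theta[idx]
    rho = np.array(
        [np.mean((prop[: L - j] - prop[j:]) ** 2) for j in range(1, config.d + 1)]
    )
    f = np.bincount(idx, minlength=20).astype(float)
    denom = f.sum() + config.w * rho.sum()
    values = np.concatenate([f / denom, config.w * rho / denom])
    names = tuple(f"paac_{a}" for a in AMINO_ACIDS) + tuple(
        f"paac_rho{j}" for j in range(1, config.d + 1)
    )
    return FeatureVector(names, values)


# ---------------------------------------------------------------------------
# CTD — composition / transition / distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CTDAttribute:
    """A named partition of the 20 amino acids into three disjoint groups."""

    name: str
    groups: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self) -> None:
        groups = tuple(frozenset(g) for g in self.groups)
        object.__setattr__(self, "groups", groups)
        union = set().union(*groups)
        if union != set(AMINO_ACIDS) or sum(len(g) for g in groups) != 20:
            raise ValueError(
                f"attribute {self.name!r}: groups must be disjoint and cover "
                f"all 20 amino acids"
            )

    def group_codes(self) -> np.ndarray:
        codes = np.empty(20, dtype=np.int64)
        for gi, grp in enumerate(self.groups):
            for a in grp:
                codes[AMINO_ACIDS.index(a)] = gi
        return codes


@dataclass(frozen=True)
class CTDScheme:
    attributes: tuple[CTDAttribute, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "attributes", tuple(self.attributes))

    @property
    def length(self) -> int:
        return 21 * len(self.attributes)


_D_POINTS = ("first", "25", "50", "75", "100")


def ctd(seq: ProteinSequence, scheme: CTDScheme | None = None) -> FeatureVector:
    """21 descriptors per attribute: 3 composition, 3 transition, 15
    distribution values.

    Distribution reports, per group, the 1-based positions of the first
    occurrence and of the ceil(q * count)-th occurrence for q = 25/50/75%,
    and the last occurrence, each divided by sequence length; a group
    absent from the sequence contributes five zeros.
    """
    scheme = scheme or default_ctd_scheme()
    n = len(seq)
    if n < 2:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} of length {n} too short for transition "
            f"descriptors (requires N >= 2)"
        )
    idx = residue_indices(seq)
    names: list[str] = []
    values: list[float] = []
    for attr in scheme.attributes:
        gidx = attr.group_codes()[idx]
        comp = np.bincount(gidx, minlength=3) / n
        names.extend(f"ctd_{attr.name}_C{g + 1}" for g in range(3))
        values.extend(comp)
        a, b = gidx[:-1], gidx[1:]
        for g1, g2 in ((0, 1), (0, 2), (1, 2)):
            t = np.sum(((a == g1) & (b == g2)) | ((a == g2) & (b == g1)))
            names.append(f"ctd_{attr.name}_T{g1 + 1}{g2 + 1}")
            values.append(t / (n - 1))
        for g in range(3):
            pos = np.flatnonzero(gidx == g) + 1  # 1-based
            names.extend(f"ctd_{attr.name}_D{g + 1}_{p}" for p in _D_POINTS)
            if pos.size == 0:
                values.extend([0.0] * 5)
            else:
                m = pos.size
                quart = [pos[int(np.ceil(q * m)) - 1] for q in (0.25, 0.5, 0.75)]
                values.extend(p / n for p in [pos[0], *quart, pos[-1]])
    return FeatureVector(tuple(names), np.array(values))


# ---------------------------------------------------------------------------
# ACF — autocorrelation features
# ---------------------------------------------------------------------------

def acf(
    seq: ProteinSequence,
    tables: list[AAPropertyTable] | None = None,
    order: int = 2,
) -> FeatureVector:
    """Mean lagged products of standardized property values.

    For each property table ``u`` and lag ``j = 1..order`` the descriptor is
    ``(1 / (N - j)) * sum_i u(s_i) * u(s_{i+j})``; output length is
    ``len(tables) * order``.
    """
    if order < 1:
        raise ValueError(f"order must be a positive integer, got {order}")
    tables = tables if tables is not None else default_property_tables()
    n = len(seq)
    if n <= order:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} of length N={n} too short for order {order} "
            f"autocorrelation (requires N > order)"
        )
    idx = residue_indices(seq)
    names: list[str] = []
    values: list[float] = []
    for table in tables:
        u = table.standardized()[idx]
        for j in range(1, order + 1):
            names.append(f"acf_{table.name}_lag{j}")
            values.append(float(np.mean(u[: n - j] * u[j:])))
    return FeatureVector(tuple(names), np.array(values))


# ---------------------------------------------------------------------------
# Bundled data
# ---------------------------------------------------------------------------

def _data_path(filename: str):
    return resources.files("hspkit").joinpath("data", filename)


def load_property_tables(path=None) -> list[AAPropertyTable]:
    """Load property tables from a TSV (first column ``aa``, one column per
    property). Defaults to the bundled classical tables."""
    source = path if path is not None else _data_path("aa_properties.tsv")
    df = pd.read_csv(source, sep="\t", index_col="aa")
    return [
        AAPropertyTable(name=col, values=df[col].to_dict()) for col in df.columns
    ]


@lru_cache(maxsize=1)
def default_property_tables() -> list[AAPropertyTable]:
    return load_property_tables()


def default_paac_table() -> AAPropertyTable:
    return default_property_tables()[0]  # hydrophobicity


def load_ctd_scheme(path=None) -> CTDScheme:
    """Load a 3-group attribute scheme from TSV columns
    (attribute, group, residues)."""
    source = path if path is not None else _data_path("ctd_groups.tsv")
    df = pd.read_csv(source, sep="\t", dtype={"group": int})
    attributes = []
    for name, sub in df.groupby("attribute", sort=False):
        sub = sub.sort_values("group")
        if list(sub["group"]) != [1, 2, 3]:
            raise ValueError(f"attribute {name!r} must define groups 1, 2, 3")
        attributes.append(
            CTDAttribute(name=name, groups=tuple(frozenset(r) for r in sub["residues"]))
        )
    return CTDScheme(tuple(attributes))


@lru_cache(maxsize=1)
def default_ctd_scheme() -> CTDScheme:
    return load_ctd_scheme()


# ---------------------------------------------------------------------------
# Dataset-level encoding
# ---------------------------------------------------------------------------

class EncodingError(SequenceError):
    """One or more sequences failed an encoder precondition."""

    def __init__(self, failures: dict[str, str]):
        self.failures = failures
        lines = "; ".join(f"{k}: {v}" for k, v in list(failures.items())[:10])
        more = "" if len(failures) <= 10 else f" (+{len(failures) - 10} more)"
        super().__init__(f"{len(failures)} sequence(s) failed encoding: {lines}{more}")


def make_encoder(spec: dict):
    """Build (feature_names, encode_fn) from an encoder spec.

    Spec is a mapping with key ``name`` in {gpc, gpc_combined, paac, ctd,
    acf} plus encoder parameters (``G``/``gaps``, ``d``/``w``, ``order``).
    """
    spec = dict(spec)
    name = spec.pop("name", None)
    if name == "gpc":
        G = int(spec.pop("G", 0))
        fn = lambda s: gpc(s, G)
        names = gpc_names(G)
    elif name == "gpc_combined":
        gaps = tuple(sorted(set(int(g) for g in spec.pop("gaps", (0, 1, 2, 3)))))
        fn = lambda s: gpc_combined(s, gaps)
        names = tuple(n for g in gaps for n in gpc_names(g))
    elif name == "paac":
        config = PAACConfig(
            d=int(spec.pop("d", 1)),
            w=float(spec.pop("w", 0.05)),
            property_table=spec.pop("property_table", None),
        )
        fn = lambda s: paac(s, config)
        names = tuple(f"paac_{a}" for a in AMINO_ACIDS) + tuple(
            f"paac_rho{j}" for j in range(1, config.d + 1)
        )
    elif name == "ctd":
        scheme = spec.pop("scheme", None) or default_ctd_scheme()
        fn = lambda s: ctd(s, scheme)
        names = None  # derived lazily below
    elif name == "acf":
        order = int(spec.pop("order", 2))
        tables = spec.pop("tables", None)
        tables = tables if tables is not None else default_property_tables()
        fn = lambda s: acf(s, tables, order)
        names = tuple(
            f"acf_{t.name}_lag{j}" for t in tables for j in range(1, order + 1)
        )
    else:
        raise ValueError(f"unknown encoder {name!r}")
    if spec:
        raise ValueError(f"unknown encoder parameter(s) for {name!r}: {sorted(spec)}")
    if names is None:
        # CTD names depend only on the scheme; derive from a probe sequence
        probe = ProteinSequence(id="_probe", residues=AMINO_ACIDS)
        names = fn(probe).names
    return names, fn


def encode_dataset(data, spec: dict) -> pd.DataFrame:
    """Encode every sequence of a dataset (or a list of sequences) into a
    feature matrix, one row per sequence in input order.

    All failing sequences are collected and reported together in an
    :class:`EncodingError`.
    """
    sequences = data.sequences if isinstance(data, LabeledDataset) else list(data)
    names, fn = make_encoder(spec)
    rows = np.empty((len(sequences), len(names)), dtype=float)
    failures: dict[str, str] = {}
    for i, seq in enumerate(sequences):
        try:
            rows[i] = fn(seq).values
        except SequenceError as exc:
            failures[seq.id] = str(exc)
    if failures:
        raise EncodingError(failures)
    return pd.DataFrame(rows, index=pd.Index([s.id for s in sequences], name="id"),
                        columns=list(names))
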