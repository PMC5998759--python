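"""Protein primary-structure descriptors (1287 dimensions).

Eight descriptor blocks are concatenated in a fixed order:

======================  ====  ==========================================
block                   dims  content
======================  ====  ==========================================
AAC                       20  amino-acid composition
DPC                      400  dipeptide composition
NMBroto                  240  normalized Moreau-Broto autocorrelation
Moran                    240  Moran autocorrelation
Geary                    240  Geary autocorrelation
CTD-C                     21  composition over 3-group discretizations
CTD-T                     21  group-transition frequencies
CTD-D                    105  group-occurrence distribution percentiles
======================  ====  ==========================================

Autocorrelations use 8 physicochemical property scales x 30 lags = 240
values per family. The scales (hydrophobicity, flexibility, polarizability,
free energy of solution, accessible surface area, residue volume, steric
parameter, relative mutability) and the 7 three-group CTD attributes are
bundled as TSV data files and can be swapped for any AAindex-style table.
Property scales are standardized to zero mean and unit standard deviation
over the 20 canonical residues before autocorrelation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AMINO_ACIDS",
    "PropertyScale",
    "CTDAttribute",
    "ProteinDescriptor",
    "load_property_scales",
    "load_ctd_groups",
    "sanitize_sequence",
    "aac",
    "dpc",
    "autocorrelation",
    "ctd_composition",
    "ctd_transition",
    "ctd_distribution",
    "ctd",
    "protein_descriptor",
    "descriptor_matrix",
    "descriptor_feature_names",
    "DESCRIPTOR_LENGTH",
    "BLOCK_LENGTHS",
]

#: canonical residues in fixed alphabetical (one-letter) order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NONCANONICAL = set("BJOUXZ*")

DEFAULT_MAXLAG = 30
BLOCK_LENGTHS = {
    "aac": 20,
    "dpc": 400,
    "nmbroto": 240,
    "moran": 240,
    "geary": 240,
    "ctd_c": 21,
    "ctd_t": 21,
    "ctd_d": 105,
}
DESCRIPTOR_LENGTH = sum(BLOCK_LENGTHS.values())  # 1287


@dataclass(frozen=True)
class PropertyScale:
    """A per-residue physicochemical property (20 values)."""

    name: str
    values: Mapping[str, float]
    standardized: bool = False

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(
                f"scale {self.name!r} must define exactly the 20 canonical "
                f"amino acids"
            )

    def standardize(self) -> "PropertyScale":
        """Zero mean, unit (population) standard deviation over the 20 residues."""
        if self.standardized:
            return self
        arr = np.array([self.values[a] for a in AMINO_ACIDS])
        sd = arr.std()
        if sd == 0:
            raise ValueError(f"scale {self.name!r} is constant; cannot standardize")
        std = (arr - arr.mean()) / sd
        return PropertyScale(
            self.name, dict(zip(AMINO_ACIDS, std.tolist())), standardized=True
        )

    def encode(self, seq: str) -> np.ndarray:
        return np.array([self.values[a] for a in seq])


@dataclass(frozen=True)
class CTDAttribute:
    """A 3-group residue discretization (e.g. polar / neutral / hydrophobic)."""

    name: str
    groups: tuple[str, str, str]
    _lookup: Mapping[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        joined = "".join(self.groups)
        if sorted(joined) != sorted(AMINO_ACIDS):
            raise ValueError(
                f"CTD attribute {self.name!r}: groups must partition the "
                f"20 canonical amino acids"
            )
        lookup = {}
        for g, letters in enumerate(self.groups, start=1):
            for a in letters:
                lookup[a] = g
        object.__setattr__(self, "_lookup", lookup)

    def encode(self, seq: str) -> np.ndarray:
        """Map a sequence to its group labels (1, 2 or 3)."""
        return np.array([self._lookup[a] for a in seq], dtype=int)


def load_property_scales(path: str | None = None) -> list[PropertyScale]:
    """Load autocorrelation property scales (default: the bundled 8)."""
    if path is None:
        src = resources.files("rwrdti.data") / "property_scales.tsv"
        frame = pd.read_csv(src.open(), sep="\t", index_col=0)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    scales = []
    for name, row in frame.iterrows():
        scales.append(PropertyScale(str(name), {a: float(row[a]) for a in AMINO_ACIDS}))
    return scales


def load_ctd_groups(path: str | None = None) -> list[CTDAttribute]:
    """Load the 3-group CTD attributes (default: the bundled 7)."""
    if path is None:
        src = resources.files("rwrdti.data") / "ctd_groups.tsv"
        frame = pd.read_csv(src.open(), sep="\t", index_col=0)
    else:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    return [
        CTDAttribute(str(name), (row["group1"], row["group2"], row["group3"]))
        for name, row in frame.iterrows()
    ]


def sanitize_sequence(
    seq: str, on_noncanonical: Literal["warn", "error", "silent"] = "warn"
) -> str:
    """Uppercase and strip non-canonical residues (B, J, O, U, X, Z, ``*``)."""
    seq = seq.upper().strip()
    unknown = {a for a in seq if a not in _AA_INDEX and a not in _NONCANONICAL}
    if unknown:
        raise ValueError(f"unrecognized residue letters: {sorted(unknown)}")
    removed = [a for a in seq if a in _NONCANONICAL]
    if removed:
        if on_noncanonical == "error":
            raise ValueError(
                f"sequence contains non-canonical residues: {sorted(set(removed))}"
            )
        if on_noncanonical == "warn":
            logger.warning(
                "removed %d non-canonical residue(s) %s before descriptor "
                "computation", len(removed), sorted(set(removed)),
            )
        seq = "".join(a for a in seq if a not in _NONCANONICAL)
    return seq


# -- composition blocks ----------------------------------------------------


def aac(seq: str) -> np.ndarray:
    """Amino-acid composition: frequency of each residue (sums to 1)."""
    if len(seq) == 0:
        raise ValueError("cannot compute composition of an empty sequence")
    counts = np.zeros(20)
    for a in seq:
        counts[_AA_INDEX[a]] += 1
    return counts / len(seq)


def dpc(seq: str) -> np.ndarray:
    """Dipeptide composition over the L-1 overlapping pairs (sums to 1)."""
    if len(seq) < 2:
        raise ValueError("dipeptide composition needs a sequence of length >= 2")
    counts = np.zeros(400)
    for a, b in zip(seq, seq[1:]):
        counts[_AA_INDEX[a] * 20 + _AA_INDEX[b]] += 1
    return counts / (len(seq) - 1)


# -- autocorrelation block -------------------------------------------------


def autocorrelation(
    seq: str,
    scale: PropertyScale,
    maxlag: int = DEFAULT_MAXLAG,
    kind: Literal["moreau-broto", "moran", "geary"] = "moreau-broto",
) -> np.ndarray:
    """Lagged autocorrelation of a property profile along the sequence.

    For lag ``d`` in ``1..maxlag`` over the standardized property ``P``:

    * normalized Moreau-Broto:  ``(1/(L-d)) * sum_i P_i P_{i+d}``
    * Moran:  ``[(1/(L-d)) sum (P_i - Pbar)(P_{i+d} - Pbar)] /
      [(1/L) sum (P_i - Pbar)^2]``
    * Geary:  ``[(1/(2(L-d))) sum (P_i - P_{i+d})^2] /
      [(1/(L-1)) sum (P_i - Pbar)^2]``

    where ``Pbar`` is the sequence mean of the property. Zero-variance
    sequences (homopolymers under the scale) yield 0 for Moran and Geary so
    that downstream feature matrices stay finite.
    """
    L = len(seq)
    if L <= maxlag:
        raise ValueError(
            f"sequence length {L} must exceed maxlag={maxlag}; lower maxlag "
            f"or drop the sequence"
        )
    if not scale.standardized:
        scale = scale.standardize()
    p = scale.encode(seq)
    pbar = p.mean()
    centered = p - pbar
    ss = float(centered @ centered)
    # constant profiles: rounding can leave ss marginally above zero
    if ss <= 1e-12 * max(1.0, float(p @ p)):
        ss = 0.0
    out = np.empty(maxlag)
    for d in range(1, maxlag + 1):
        head, tail = p[:-d], p[d:]
        if kind == "moreau-broto":
            out[d - 1] = float(head @ tail) / (L - d)
        elif kind == "moran":
            if ss == 0:
                out[d - 1] = 0.0
            else:
                num = float(centered[:-d] @ centered[d:]) / (L - d)
                out[d - 1] = num / (ss / L)
        elif kind == "geary":
            if ss == 0:
                out[d - 1] = 0.0
            else:
                num = float(((head - tail) ** 2).sum()) / (2 * (L - d))
                out[d - 1] = num / (ss / (L - 1))
        else:
            raise ValueError(f"unknown autocorrelation kind {kind!r}")
    return out


# -- CTD block -------------------------------------------------------------


def ctd_composition(groups: np.ndarray) -> np.ndarray:
    """Fraction of residues in each of the 3 groups (sums to 1)."""
    L = len(groups)
    return np.array([(groups == g).sum() / L for g in (1, 2, 3)])


def ctd_transition(groups: np.ndarray) -> np.ndarray:
    """Adjacent-residue group-change frequencies for unordered pairs
    (1,2), (1,3), (2,3), each divided by L-1."""
    L = len(groups)
    if L < 2:
        raise ValueError("transition needs a sequence of length >= 2")
    a, b = groups[:-1], groups[1:]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = np.zeros(3)
    for i, (r, s) in enumerate(((1, 2), (1, 3), (2, 3))):
        out[i] = ((lo == r) & (hi == s)).sum() / (L - 1)
    return out


def ctd_distribution(groups: np.ndarray) -> np.ndarray:
    """Positions (percent of L, 1-based) of the first, 25%, 50%, 75% and
    last occurrence of each group; 5 zeros for an absent group."""
    L = len(groups)
    out = np.zeros(15)
    for g in (1, 2, 3):
        positions = np.flatnonzero(groups == g) + 1  # 1-based
        n = len(positions)
        if n == 0:
            continue
        picks = [
            positions[0],
            positions[max(math.ceil(0.25 * n), 1) - 1],
            positions[max(math.ceil(0.50 * n), 1) - 1],
            positions[max(math.ceil(0.75 * n), 1) - 1],
            positions[-1],
        ]
        out[(g - 1) * 5 : g * 5] = [100.0 * p / L for p in picks]
    return out


def ctd(seq: str, attributes: Sequence[CTDAttribute] | None = None) -> np.ndarray:
    """Full Composition/Transition/Distribution vector (21 + 21 + 105)."""
    if len(seq) < 2:
        raise ValueError("CTD needs a sequence of length >= 2")
    if attributes is None:
        attributes = load_ctd_groups()
    comp, trans, dist = [], [], []
    for attr in attributes:
        g = attr.encode(seq)
        comp.append(ctd_composition(g))
        trans.append(ctd_transition(g))
        dist.append(ctd_distribution(g))
    return np.concatenate(comp + trans + dist)


# -- assembled descriptor --------------------------------------------------


@dataclass
class ProteinDescriptor:
    """Named descriptor blocks and their 1287-dim concatenation."""

    blocks: dict[str, np.ndarray]

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.blocks[k] for k in BLOCK_LENGTHS])

    def __len__(self) -> int:
        return sum(len(v) for v in self.blocks.values())


def protein_descriptor(
    seq: str,
    scales: Sequence[PropertyScale] | None = None,
    attributes: Sequence[CTDAttribute] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
    on_noncanonical: Literal["warn", "error", "silent"] = "warn",
) -> ProteinDescriptor:
    """Compute all descriptor blocks for one sequence.

    The sequence is sanitized first; its (sanitized) length must exceed
    ``maxlag``. A pure function of the sequence: identical sequences yield
    identical vectors.
    """
    seq = sanitize_sequence(seq, on_noncanonical=on_noncanonical)
    if scales is None:
        scales = load_property_scales()
    scales = [s.standardize() for s in scales]
    if attributes is None:
        attributes = load_ctd_groups()
    blocks: dict[str, np.ndarray] = {
        "aac": aac(seq),
        "dpc": dpc(seq),
    }
    for kind, key in (("moreau-broto", "nmbroto"), ("moran", "moran"), ("geary", "geary")):
        blocks[key] = np.concatenate(
            [autocorrelation(seq, s, maxlag=maxlag, kind=kind) for s in scales]
        )
    ctd_all = ctd(seq, attributes)
    n_attr = len(attributes)
    blocks["ctd_c"] = ctd_all[: 3 * n_attr]
    blocks["ctd_t"] = ctd_all[3 * n_attr : 6 * n_attr]
    blocks["ctd_d"] = ctd_all[6 * n_attr :]
    return ProteinDescriptor(blocks)


def descriptor_feature_names(
    scales: Sequence[PropertyScale] | None = None,
    attributes: Sequence[CTDAttribute] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
) -> list[str]:
    if scales is None:
        scales = load_property_scales()
    if attributes is None:
        attributes = load_ctd_groups()
    names = [f"aac_{a}" for a in AMINO_ACIDS]
    names += [f"dpc_{a}{b}" for a in AMINO_ACIDS for b in AMINO_ACIDS]
    for fam in ("nmbroto", "moran", "geary"):
        for s in scales:
            names += [f"{fam}_{s.name}_lag{d}" for d in range(1, maxlag + 1)]
    names += [f"ctdc_{t.name}_g{g}" for t in attributes for g in (1, 2, 3)]
    names += [
        f"ctdt_{t.name}_{r}{s}" for t in attributes for r, s in ((1, 2), (1, 3), (2, 3))
    ]
    names += [
        f"ctdd_{t.name}_g{g}_{p}"
        for t in attributes
        for g in (1, 2, 3)
        for p in ("first", "p25", "p50", "p75", "last")
    ]
    return names


def descriptor_matrix(
    sequences: Mapping[str, str],
    scales: Sequence[PropertyScale] | None = None,
    attributes: Sequence[CTDAttribute] | None = None,
    maxlag: int = DEFAULT_MAXLAG,
    on_noncanonical: Literal["warn", "error", "silent"] = "warn",
) -> FeatureMatrix:
    """Descriptor vectors for a set of proteins as a :class:`FeatureMatrix`."""
    if scales is None:
        scales = load_property_scales()
    scales = [s.standardize() for s in scales]
    if attributes is None:
        attributes = load_ctd_groups()
    ids = list(sequences)
    rows = [
        protein_descriptor(
            sequences[i], scales, attributes, maxlag, on_noncanonical
        ).vector
        for i in ids
    ]
    return FeatureMatrix(
        ids, np.vstack(rows), descriptor_feature_names(scales, attributes, maxlag)
    )
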