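"""Readers and writers for the pipeline's file formats.

Input dialects are deliberately plain:

* PPI edge list — TSV with at least three columns ``idA idB score``
  (HIPPIE-style confidence scores; either the 0-1000 or the 0-1 scale,
  the threshold is up to the caller).
* DTI pair list — TSV with two columns ``drug_id protein_id``.
* Fingerprints — CSV/TSV with a header row, first column the drug id,
  remaining columns binary substructure bits.
* Protein sequences — multi-record FASTA.

All identifiers are opaque strings; no namespace mapping is attempted.
"""

from __future__ import annotations

import itertools
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import BipartiteDTI, FeatureMatrix, InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "read_ppi",
    "read_dti",
    "build_ddi_shared_target",
    "read_fingerprints",
    "read_fasta",
    "write_network",
    "write_dti",
    "write_fingerprints",
    "write_fasta",
]

_DTI_HEADER_TOKENS = {"drug", "drug_id", "protein", "protein_id", "target", "target_id"}


def read_ppi(path: str | Path, min_confidence: float = 800.0) -> InteractionNetwork:
    """Read a weighted PPI edge list, keeping edges with score > ``min_confidence``.

    The comparison is strict, matching the convention of keeping only
    interactions whose confidence exceeds the cut-off. Duplicate edges keep
    the maximum score; self-loops are dropped. Nodes are the endpoints of
    the surviving edges.
    """
    if min_confidence < 0:
        raise ValueError("min_confidence must be >= 0")
    path = Path(path)
    best: dict[tuple[str, str], float] = {}
    order: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns "
                    f"(idA, idB, score), got {len(fields)}"
                )
            a, b, raw_score = fields[0].strip(), fields[1].strip(), fields[2].strip()
            try:
                score = float(raw_score)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric confidence score {raw_score!r}"
                ) from exc
            if a == b:
                logger.debug("%s:%d: dropping self-loop on %s", path, lineno, a)
                continue
            if score <= min_confidence:
                continue
            key = (a, b) if a <= b else (b, a)
            if key not in best:
                order.append(key)
                best[key] = score
            else:
                best[key] = max(best[key], score)
    nodes: list[str] = []
    seen: set[str] = set()
    for a, b in order:
        for n in (a, b):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
    net = InteractionNetwork(nodes, [(a, b, best[(a, b)]) for a, b in order])
    logger.info(
        "read PPI %s: %d proteins, %d interactions (score > %g)",
        path, net.n_nodes, net.n_edges, min_confidence,
    )
    return net


def read_dti(path: str | Path) -> BipartiteDTI:
    """Read a two-column drug/protein pair list into a :class:`BipartiteDTI`.

    A leading header row with recognizable column names is tolerated and
    skipped. An empty (or header-only) file is an error.
    """
    path = Path(path)
    pairs: set[tuple[str, str]] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns "
                    f"(drug_id, protein_id)"
                )
            d, p = fields[0].strip(), fields[1].strip()
            if lineno == 1 and d.lower() in _DTI_HEADER_TOKENS:
                continue
            pairs.add((d, p))
    if not pairs:
        raise ValueError(f"{path}: no drug-target pairs found")
    dti = BipartiteDTI(pairs)
    logger.info(
        "read DTI %s: %d pairs over %d drugs and %d proteins",
        path, dti.n_pairs, len(dti.drug_ids), len(dti.protein_ids),
    )
    return dti


def build_ddi_shared_target(dti: BipartiteDTI) -> InteractionNetwork:
    """Drug-drug network with an edge between every pair sharing >= 1 target.

    Edges are unweighted (weight 1.0). Every drug that appears in the DTI
    set is a node, including drugs that share no target with any other
    (they remain isolated so each keeps a feature row and an RWR row).
    """
    if dti.n_pairs == 0:
        raise ValueError("cannot build a DDI network from an empty DTI set")
    by_target: dict[str, list[str]] = {}
    for d, p in dti.sorted_pairs():
        by_target.setdefault(p, []).append(d)
    edges: set[tuple[str, str]] = set()
    for drugs in by_target.values():
        for a, b in itertools.combinations(sorted(drugs), 2):
            edges.add((a, b))
    return InteractionNetwork(
        dti.drug_ids, [(a, b, 1.0) for a, b in sorted(edges)]
    )


def read_fingerprints(path: str | Path) -> FeatureMatrix:
    """Read a drug fingerprint table (header row; first column drug id).

    Every bit column must be strictly binary; a non-binary cell is reported
    with its row and column. All-zero fingerprints are accepted with a
    warning (such drugs carry no substructure information).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, dtype={0: str})
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed fingerprint table: {exc}") from exc
    if frame.shape[1] == 0:
        raise ValueError(f"{path}: no fingerprint bit columns found")
    values = frame.to_numpy()
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric fingerprint value: {exc}") from exc
    bad = np.argwhere(~np.isin(values, (0.0, 1.0)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-binary value {values[r, c]!r} at drug "
            f"{frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    for r in zero_rows:
        logger.warning("%s: drug %s has an all-zero fingerprint", path, frame.index[r])
    return FeatureMatrix(
        [str(i) for i in frame.index], values, [str(c) for c in frame.columns]
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> sequence mapping."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


# -- writers (round-trip partners of the readers) --------------------------


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    """Write an edge list TSV (idA, idB, weight). Isolated nodes are listed
    in a trailing comment so a round-trip can restore them."""
    path = Path(path)
    with path.open("w") as fh:
        for a, b, w in net.edges():
            fh.write(f"{a}\t{b}\t{w!r}\n")
        isolated = [n for n in net.node_ids if net.graph.degree(n) == 0]
        if isolated:
            fh.write("#isolated\t" + "\t".join(isolated) + "\n")


def read_network(path: str | Path) -> InteractionNetwork:
    """Read an edge list written by :func:`write_network` (keeps all edges)."""
    path = Path(path)
    edges: list[tuple[str, str, float]] = []
    nodes: list[str] = []
    seen: set[str] = set()

    def add_node(n: str) -> None:
        if n not in seen:
            seen.add(n)
            nodes.append(n)

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#isolated\t"):
                for n in line.split("\t")[1:]:
                    add_node(n)
                continue
            if line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected idA, idB, weight")
            a, b, w = fields[0], fields[1], float(fields[2])
            add_node(a)
            add_node(b)
            edges.append((a, b, w))
    return InteractionNetwork(nodes, edges)


def write_dti(dti: BipartiteDTI, path: str | Path, header: bool = True) -> None:
    with Path(path).open("w") as fh:
        if header:
            fh.write("drug_id\tprotein_id\n")
        for d, p in dti.sorted_pairs():
            fh.write(f"{d}\t{p}\n")


def write_fingerprints(fp: FeatureMatrix, path: str | Path) -> None:
    frame = fp.to_frame()
    sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    frame.astype(int).to_csv(path, sep=sep, index_label="drug_id")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with Path(path).open("w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
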