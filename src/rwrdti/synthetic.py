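"""Synthetic interactomes, sequences, fingerprints and planted DTIs.

The generator builds a world with exactly the statistical structure the
weighting method exploits: a modular protein interactome (stochastic block
model — dense within a functional module, sparse across), drugs whose
targets all live inside one module (so drugs of a module share targets and
form drug-drug cliques), and module-templated fingerprints. Held-out test
interactions follow the same module rule but are excluded from training,
emulating an independent test set. Protein sequences are random over the
20-letter alphabet, so any protein-side signal a model finds must come
through the network, not the sequences.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np

from .containers import BipartiteDTI, FeatureMatrix, InteractionNetwork
from .io import (
    build_ddi_shared_target,
    write_dti,
    write_fasta,
    write_fingerprints,
    write_network,
)

__all__ = ["SyntheticWorld", "generate_world", "write_world", "PRESETS"]

#: named parameter presets for the CLI (``small`` runs in seconds)
PRESETS: dict[str, dict[str, Any]] = {
    "default": {},
    "small": {
        "n_modules": 3,
        "proteins_per_module": 10,
        "drugs_per_module": 3,
        "fp_bits": 64,
        "seq_len_range": (40, 80),
    },
}


@dataclass
class SyntheticWorld:
    """A complete generated input set for the pipeline."""

    ppi: InteractionNetwork
    ddi: InteractionNetwork
    dti: BipartiteDTI
    test_dti: BipartiteDTI
    sequences: dict[str, str]
    fingerprints: FeatureMatrix
    drug_modules: dict[str, int]
    protein_modules: dict[str, int]
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def rng_seed(self) -> int:
        return int(self.params["rng_seed"])


def generate_world(
    n_modules: int = 4,
    proteins_per_module: int = 25,
    drugs_per_module: int = 5,
    p_in: float = 0.3,
    p_out: float = 0.01,
    targets_per_drug: int = 3,
    test_targets_per_drug: int = 2,
    seq_len_range: tuple[int, int] = (120, 300),
    fp_bits: int = 1024,
    fp_density: float = 0.1,
    fp_noise: float = 0.05,
    confidence_range: tuple[float, float] = (801.0, 999.0),
    rng_seed: int = 0,
) -> SyntheticWorld:
    """Generate a modular world with planted drug-target interactions.

    Each module designates one hub protein that every drug of the module
    targets (guaranteeing the shared-target drug cliques the weighting
    relies on); the remaining training and held-out targets are sampled
    from the drug's module. Fingerprints are a per-module template bit
    pattern with independent per-bit flip noise.
    """
    if not p_in > p_out:
        raise ValueError("need p_in > p_out for modular structure")
    if fp_bits < 1:
        raise ValueError("fp_bits must be >= 1")
    n_targets = targets_per_drug + test_targets_per_drug
    if n_targets + 1 > proteins_per_module:
        raise ValueError(
            "proteins_per_module must exceed targets_per_drug + "
            "test_targets_per_drug"
        )
    if seq_len_range[0] < 31:
        raise ValueError(
            "minimum sequence length must be >= 31 (autocorrelation lags "
            "run to 30)"
        )
    rng = np.random.default_rng(rng_seed)

    proteins = [
        f"P{m:02d}_{i:03d}" for m in range(n_modules) for i in range(proteins_per_module)
    ]
    drugs = [f"D{m:02d}_{j:02d}" for m in range(n_modules) for j in range(drugs_per_module)]
    protein_modules = {p: int(p[1:3]) for p in proteins}
    drug_modules = {d: int(d[1:3]) for d in drugs}

    # modular PPI: stochastic block model with confidence-score weights
    sizes = [proteins_per_module] * n_modules
    probs = [
        [p_in if a == b else p_out for b in range(n_modules)] for a in range(n_modules)
    ]
    sbm_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.stochastic_block_model(sizes, probs, seed=sbm_seed)
    g = nx.relabel_nodes(g, dict(enumerate(proteins)))
    lo, hi = confidence_range
    edges = [
        (a, b, float(rng.uniform(lo, hi))) for a, b in sorted(g.edges())
    ]
    ppi = InteractionNetwork(proteins, edges)

    # planted DTIs: per module one shared hub target + per-drug extras
    module_proteins = {
        m: [p for p in proteins if protein_modules[p] == m] for m in range(n_modules)
    }
    hubs = {m: module_proteins[m][int(rng.integers(0, proteins_per_module))]
            for m in range(n_modules)}
    train_pairs: set[tuple[str, str]] = set()
    test_pairs: set[tuple[str, str]] = set()
    for d in drugs:
        m = drug_modules[d]
        pool = [p for p in module_proteins[m] if p != hubs[m]]
        picked = rng.choice(len(pool), size=n_targets - 1, replace=False)
        chosen = [hubs[m]] + [pool[i] for i in picked]
        for p in chosen[:targets_per_drug]:
            train_pairs.add((d, p))
        for p in chosen[targets_per_drug:]:
            test_pairs.add((d, p))
    dti = BipartiteDTI(train_pairs)
    test_dti = BipartiteDTI(test_pairs)
    ddi = build_ddi_shared_target(dti)

    # fingerprints: module template bits + per-drug flip noise
    templates = {
        m: (rng.random(fp_bits) < fp_density).astype(float) for m in range(n_modules)
    }
    fp_rows = []
    for d in drugs:
        t = templates[drug_modules[d]].copy()
        flips = rng.random(fp_bits) < fp_noise
        t[flips] = 1.0 - t[flips]
        fp_rows.append(t)
    fingerprints = FeatureMatrix(
        drugs, np.vstack(fp_rows), [f"bit{i}" for i in range(fp_bits)]
    )

    # random sequences — no module signal on the sequence side
    from .descriptors import AMINO_ACIDS

    aa = np.array(list(AMINO_ACIDS))
    sequences = {}
    for p in proteins:
        L = int(rng.integers(seq_len_range[0], seq_len_range[1] + 1))
        sequences[p] = "".join(aa[rng.integers(0, 20, size=L)])

    params = dict(
        n_modules=n_modules,
        proteins_per_module=proteins_per_module,
        drugs_per_module=drugs_per_module,
        p_in=p_in,
        p_out=p_out,
        targets_per_drug=targets_per_drug,
        test_targets_per_drug=test_targets_per_drug,
        seq_len_range=list(seq_len_range),
        fp_bits=fp_bits,
        fp_density=fp_density,
        fp_noise=fp_noise,
        confidence_range=list(confidence_range),
        rng_seed=rng_seed,
    )
    return SyntheticWorld(
        ppi=ppi,
        ddi=ddi,
        dti=dti,
        test_dti=test_dti,
        sequences=sequences,
        fingerprints=fingerprints,
        drug_modules=drug_modules,
        protein_modules=protein_modules,
        params=params,
    )


def write_world(world: SyntheticWorld, out_dir: str | Path) -> dict[str, Path]:
    """Write a world in exactly the formats the readers consume.

    Emits ``ppi.tsv``, ``ddi.tsv``, ``dti_train.tsv``, ``dti_test.tsv``,
    ``fingerprints.csv``, ``proteins.fasta`` (60-column wrapped) and
    ``params.json``; returns the path of each artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": out / "ppi.tsv",
        "ddi": out / "ddi.tsv",
        "dti_train": out / "dti_train.tsv",
        "dti_test": out / "dti_test.tsv",
        "fingerprints": out / "fingerprints.csv",
        "fasta": out / "proteins.fasta",
        "params": out / "params.json",
    }
    write_network(world.ppi, paths["ppi"])
    write_network(world.ddi, paths["ddi"])
    write_dti(world.dti, paths["dti_train"])
    write_dti(world.test_dti, paths["dti_test"])
    write_fingerprints(world.fingerprints, paths["fingerprints"])
    write_fasta(world.sequences, paths["fasta"], width=60)
    paths["params"].write_text(json.dumps(world.params, indent=2) + "\n")
    return paths
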