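"""Synthetic genomes with controlled compositional structure.

Chromosomes are sampled from order-m Markov chains over {A, C, G, T} whose
transition rows are drawn from a symmetric Dirichlet; each synthetic genus
gets its own chain, so genomes carry distinct, reproducible k-mer
signatures. Compositional *amelioration* of a plasmid toward its hosts is
modeled as convex mixing of transition matrices: with strength ``alpha``
the plasmid chain is ``(1 - alpha) * own + alpha * mixture-of-host``
rowwise. ``build_scenario`` assembles a truth-labeled screen at toy scale:
Transconjugant hosts (toward whose mixture the plasmid is ameliorated),
Other hosts, and a metadata table, all reproducible byte-for-byte from one
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .records import GenomeRecord, write_fasta

__all__ = [
    "MarkovModel",
    "ScenarioBundle",
    "make_markov_model",
    "generate_sequence",
    "ameliorate",
    "build_scenario",
    "scenario_group_comparison",
]

_ROWSUM_TOL = 1e-12


def _sample_chain_py(cum, u, mod, ctx):
    out = np.empty(u.shape[0], dtype=np.int64)
    for i in range(u.shape[0]):
        row = cum[ctx]
        ui = u[i]
        b = 0
        while b < 3 and ui > row[b]:
            b += 1
        out[i] = b
        ctx = (ctx * 4 + b) % mod
    return out


try:  # jit-compile the inner sampling loop; pure-Python fallback otherwise
    from numba import njit

    _sample_chain = njit(cache=False)(_sample_chain_py)
except Exception:  # pragma: no cover
    _sample_chain = _sample_chain_py


@dataclass(frozen=True)
class MarkovModel:
    """Order-m Markov chain over ACGT.

    ``transitions`` has one row per 4^order context (lexicographic by
    context string) and four next-base probabilities per row;
    ``initial_distribution`` is over the 4^order starting contexts.
    """

    order: int
    initial_distribution: np.ndarray
    transitions: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        n_ctx = 4**self.order
        if self.transitions.shape != (n_ctx, 4):
            raise ValueError(
                f"transitions must be ({n_ctx}, 4), got {self.transitions.shape}"
            )
        if self.initial_distribution.shape != (n_ctx,):
            raise ValueError("initial_distribution must have 4^order entries")
        if (self.transitions < 0).any() or (self.initial_distribution < 0).any():
            raise ValueError("probabilities must be non-negative")
        if np.abs(self.transitions.sum(axis=1) - 1).max() > _ROWSUM_TOL:
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial_distribution.sum() - 1) > _ROWSUM_TOL:
            raise ValueError("initial_distribution must sum to 1")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.int64(self.order).tobytes())
        h.update(np.ascontiguousarray(self.initial_distribution).tobytes())
        h.update(np.ascontiguousarray(self.transitions).tobytes())
        return h.hexdigest()[:16]


def _renormalize(rows: np.ndarray) -> np.ndarray:
    return rows / rows.sum(axis=-1, keepdims=True)


def make_markov_model(
    seed: int, order: int = 2, concentration: float = 1.0, label: str = ""
) -> MarkovModel:
    """Random chain: transition rows ~ symmetric Dirichlet(concentration).

    Deterministic per seed. Large concentration pushes all rows toward the
    uniform distribution; small concentration gives strongly biased,
    signature-rich chains.
    """
    if order not in (0, 1, 2):
        raise ValueError(f"order must be in {{0, 1, 2}}, got {order}")
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    n_ctx = 4**order
    transitions = _renormalize(rng.dirichlet([concentration] * 4, size=n_ctx))
    initial = _renormalize(rng.dirichlet([concentration] * n_ctx))
    return MarkovModel(
        order=order, initial_distribution=initial, transitions=transitions,
        label=label,
    )


def generate_sequence(model: MarkovModel, length: int, seed: int) -> str:
    """Sample a nucleotide string of the given length from the chain."""
    if length < model.order + 1:
        raise ValueError(
            f"length must be >= order + 1 = {model.order + 1}, got {length}"
        )
    rng = np.random.default_rng(seed)
    n_ctx = 4**model.order
    ctx = int(rng.choice(n_ctx, p=model.initial_distribution))
    # emit the starting context's bases, then run the chain
    prefix = []
    c = ctx
    for j in range(model.order - 1, -1, -1):
        prefix.append((c // 4**j) % 4)
        c %= 4**j
    n_rest = length - model.order
    cum = np.cumsum(model.transitions, axis=1)
    u = rng.random(n_rest)
    rest = _sample_chain(cum, u, n_ctx, ctx)
    codes = np.concatenate([np.array(prefix, dtype=np.int64), rest])
    return np.frombuffer(b"ACGT", dtype=np.uint8)[codes].tobytes().decode("ascii")


def ameliorate(
    plasmid_model: MarkovModel, host_model: MarkovModel, alpha: float
) -> MarkovModel:
    """Convex mixing of the plasmid chain toward a host chain.

    alpha = 0 returns the plasmid model, alpha = 1 the host model; rows are
    renormalized to machine precision.
    """
    if plasmid_model.order != host_model.order:
        raise ValueError(
            f"order mismatch: {plasmid_model.order} vs {host_model.order}"
        )
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    mix = _renormalize(
        (1 - alpha) * plasmid_model.transitions + alpha * host_model.transitions
    )
    init = _renormalize(
        (1 - alpha) * plasmid_model.initial_distribution
        + alpha * host_model.initial_distribution
    )
    return MarkovModel(
        order=plasmid_model.order, initial_distribution=init, transitions=mix,
        label=f"({plasmid_model.label})+{alpha}*({host_model.label})",
    )


def _mixture(models: List[MarkovModel], label: str) -> MarkovModel:
    trans = _renormalize(np.mean([m.transitions for m in models], axis=0))
    init = _renormalize(np.mean([m.initial_distribution for m in models], axis=0))
    return MarkovModel(
        order=models[0].order, initial_distribution=init, transitions=trans,
        label=label,
    )


@dataclass
class ScenarioBundle:
    """Truth-labeled synthetic screen: hosts, plasmid, metadata, seed."""

    host_records: List[GenomeRecord]
    plasmid_record: GenomeRecord
    metadata: pd.DataFrame
    alpha: float
    seed: int
    host_models: List[MarkovModel] = field(default_factory=list)
    plasmid_model: Optional[MarkovModel] = None

    @property
    def transconjugant_genera(self) -> set:
        return set(
            self.metadata.loc[self.metadata["group"] == "Transconjugants", "genus"]
        )

    def write(self, outdir) -> dict:
        """Emit hosts.fasta, plasmid.fasta, metadata.tsv and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts_fasta": outdir / "hosts.fasta",
            "plasmid_fasta": outdir / "plasmid.fasta",
            "metadata": outdir / "metadata.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.host_records, paths["hosts_fasta"])
        write_fasta([self.plasmid_record], paths["plasmid_fasta"])
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        manifest = {
            "seed": self.seed,
            "alpha": self.alpha,
            "n_hosts": len(self.host_records),
            "plasmid_length": len(self.plasmid_record),
            "model_hashes": {
                m.label: m.content_hash() for m in self.host_models
            },
            "plasmid_model_hash": (
                self.plasmid_model.content_hash() if self.plasmid_model else None
            ),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def build_scenario(
    n_transconjugant_hosts: int = 10,
    n_other_hosts: int = 10,
    chrom_length: int = 500_000,
    plasmid_length: int = 50_000,
    alpha: float = 0.9,
    seed: int = 0,
    order: int = 2,
    concentration: float = 2.0,
    window_bp: int = 5000,
) -> ScenarioBundle:
    """Build a toy screen with known ground truth.

    Each host genus gets its own Dirichlet-sampled chain; the plasmid chain
    is its own draw ameliorated (strength ``alpha``) toward the equal
    mixture of the Transconjugant-host chains. Fully reproducible from
    ``seed``.
    """
    if n_transconjugant_hosts < 1 or n_other_hosts < 0:
        raise ValueError("need >= 1 Transconjugant host and >= 0 Other hosts")
    if chrom_length < (4**2 + 2) * window_bp:
        raise ValueError(
            f"chrom_length must be >= {(4**2 + 2) * window_bp} so that the "
            f"k=2 segment model is available (n > 16 segments)"
        )
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    n_hosts = n_transconjugant_hosts + n_other_hosts
    ss = np.random.SeedSequence(seed)
    # one child seed per host model, per host sequence, plus plasmid model+seq
    children = ss.spawn(2 * n_hosts + 2)
    child_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]

    host_models: List[MarkovModel] = []
    host_records: List[GenomeRecord] = []
    meta_rows = []
    for i in range(n_hosts):
        genus = f"Genus{i:03d}"
        group = "Transconjugants" if i < n_transconjugant_hosts else "Others"
        model = make_markov_model(
            child_seeds[2 * i], order=order, concentration=concentration,
            label=genus,
        )
        seq = generate_sequence(model, chrom_length, child_seeds[2 * i + 1])
        acc = f"SYN{i:04d}"
        host_models.append(model)
        host_records.append(
            GenomeRecord(
                id=acc, sequence=seq,
                description=f"synthetic chromosome {genus}", role="chromosome",
            )
        )
        meta_rows.append(
            {
                "accession": acc, "genus": genus, "family": f"Family{i % 5:02d}",
                "order": "Synthetales", "class": "Synthetia",
                "phylum": "Synthetica", "group": group,
            }
        )
    plasmid_base = make_markov_model(
        child_seeds[-2], order=order, concentration=concentration,
        label="plasmid-base",
    )
    host_mixture = _mixture(
        host_models[:n_transconjugant_hosts], label="transconjugant-mixture"
    )
    plasmid_model = ameliorate(plasmid_base, host_mixture, alpha)
    plasmid_seq = generate_sequence(plasmid_model, plasmid_length, child_seeds[-1])
    plasmid_record = GenomeRecord(
        id="pSYN0001", sequence=plasmid_seq,
        description=f"synthetic plasmid alpha={alpha}", role="plasmid",
    )
    metadata = pd.DataFrame(meta_rows)
    return ScenarioBundle(
        host_records=host_records,
        plasmid_record=plasmid_record,
        metadata=metadata,
        alpha=alpha,
        seed=seed,
        host_models=host_models,
        plasmid_model=plasmid_model,
    )


def scenario_group_comparison(alpha: float, seed: int, k: int = 3, **scenario_kwargs):
    """Run one synthetic scenario end-to-end and compare the two groups.

    Builds the truth-labeled bundle, screens the plasmid against every host
    chromosome at one k, and returns the Transconjugants-vs-Others
    :class:`~plasmidhost.stats.GroupComparison`. The workhorse of power and
    null-calibration simulations.
    """
    from .screen import PlasmidHostScreen

    bundle = build_scenario(alpha=alpha, seed=seed, **scenario_kwargs)
    screen = PlasmidHostScreen(
        bundle.plasmid_record,
        bundle.host_records,
        bundle.metadata.set_index("accession", drop=False),
        ks=(k,),
    )
    return screen.fit().compare_groups(k)
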