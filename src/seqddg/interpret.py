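"""Attention-weight extraction and residue-interaction reports.

The dual cross-attention weights say, for every antibody residue, how
strongly it attends to each antigen residue (and vice versa).  Focusing on a
mutated position, the most-attended partner residues nominate candidate
interaction partners -- the style of analysis that, on real complexes,
recovers hydrogen-bond-network neighbours of a mutation site.

Per-head matrices are retained; summaries use the arithmetic mean over heads
(the mean of row-stochastic matrices is row-stochastic).  Only numeric
exports are produced here; colour rendering is presentation, not computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import ComplexRecord, Mutation
from .embedding import EmbedderSpec
from .model_core import AttentionConfig, AttentionState, ModelParameters, forward


class CapabilityError(RuntimeError):
    """The forward pass did not capture attention weights."""


def residue_labels(chains) -> list[str]:
    """``chain:positionAA`` labels for a serialized multi-chain side."""
    labels = []
    for chain in chains:
        for i, aa in enumerate(chain.residues, 1):
            labels.append(f"{chain.chain_id}:{i}{aa}")
    return labels


@dataclass
class AttentionMap:
    """Cross-attention weights for one direction and one variant (wt/mt)."""

    direction: str  # "ab2ag" | "ag2ab"
    variant: str  # "wt" | "mt"
    per_head: np.ndarray  # (n_heads, L_query, L_key)
    query_labels: list[str]
    key_labels: list[str]

    def __post_init__(self):
        self.per_head = np.asarray(self.per_head, dtype=float)
        if self.per_head.ndim != 3:
            raise ValueError("per-head weights must be (n_heads, Lq, Lk)")
        if self.per_head.shape[1] != len(self.query_labels):
            raise ValueError("query labels do not match the weight matrix")
        if self.per_head.shape[2] != len(self.key_labels):
            raise ValueError("key labels do not match the weight matrix")

    @property
    def head_avg(self) -> np.ndarray:
        return self.per_head.mean(axis=0)

    def row(self, query_index: int) -> np.ndarray:
        if not 0 <= query_index < self.per_head.shape[1]:
            raise IndexError(
                f"query index {query_index} outside 0..{self.per_head.shape[1] - 1}"
            )
        return self.head_avg[query_index]


@dataclass
class InteractionReport:
    """Ranked partner residues for one focal (usually mutated) position."""

    focal_label: str
    direction: str
    variant: str
    partners: list[dict] = field(default_factory=list)  # rank-ordered

    def to_json(self) -> str:
        return json.dumps(
            {
                "focal": self.focal_label,
                "direction": self.direction,
                "variant": self.variant,
                "partners": self.partners,
            },
            indent=2,
        )


def extract_attention(
    params: ModelParameters,
    record: ComplexRecord,
    spec: EmbedderSpec,
    config: AttentionConfig | None = None,
    cache=None,
) -> dict[tuple[str, str], AttentionMap]:
    """Run the model on one record and return the four annotated maps.

    Keys are (direction, variant) tuples; shapes are (L_ab x L_ag) for
    ab2ag and transposed for ag2ab.
    """
    _, state = forward(record, spec, params, config, cache=cache, capture=True)
    return attention_maps_from_state(state, record)


def attention_maps_from_state(
    state: AttentionState | None, record: ComplexRecord
) -> dict[tuple[str, str], AttentionMap]:
    if state is None or not state.attention:
        raise CapabilityError(
            "no attention weights captured (was the model run with "
            "capture=True and the full variant?)"
        )
    from .embedding import serialized_sequences

    seqs = serialized_sequences(record)
    from .data_io import ProteinSequence

    def labels(side: str, variant: str) -> list[str]:
        chains = (
            record.antibody_chains if side == "ab" else record.antigen_chains
        )
        if variant == "mt":
            serial = seqs[f"{side}_mt"].residues
            # relabel with mutant residues, preserving chain boundaries
            out, offset = [], 0
            for chain in chains:
                for i in range(len(chain)):
                    out.append(f"{chain.chain_id}:{i + 1}{serial[offset + i]}")
                offset += len(chain)
            return out
        return residue_labels(chains)

    maps = {}
    for (direction, variant), weights in state.attention.items():
        q_side, k_side = ("ab", "ag") if direction == "ab2ag" else ("ag", "ab")
        maps[(direction, variant)] = AttentionMap(
            direction=direction,
            variant=variant,
            per_head=weights,
            query_labels=labels(q_side, variant),
            key_labels=labels(k_side, variant),
        )
    return maps


def locate_query(map_: AttentionMap, mutation: Mutation) -> int:
    """Index of a mutation's position on the map's query axis."""
    prefix = f"{mutation.chain_id}:{mutation.position}"
    for i, label in enumerate(map_.query_labels):
        if label.startswith(prefix) and label[len(prefix):] in (
            mutation.wt_aa, mutation.mut_aa,
        ):
            return i
    raise IndexError(f"mutation {mutation} not on the query axis of this map")


def top_interactions(
    map_: AttentionMap,
    focal: int | Mutation,
    k: int = 5,
    baseline: AttentionMap | None = None,
) -> InteractionReport:
    """The k partner residues most attended from the focal query row.

    Scores are head-averaged attention weights; when a `baseline` map (the
    other variant) is supplied, each partner also carries the mt - wt delta.
    `k` larger than the key axis returns all partners.  Ties rank by key
    index for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    idx = focal if isinstance(focal, int) else locate_query(map_, focal)
    row = map_.row(idx)
    base_row = None
    if baseline is not None:
        base_idx = focal if isinstance(focal, int) else locate_query(baseline, focal)
        base_row = baseline.row(base_idx)
    order = sorted(range(row.size), key=lambda j: (-row[j], j))[: min(k, row.size)]
    partners = []
    for rank, j in enumerate(order, 1):
        entry = {
            "rank": rank,
            "residue": map_.key_labels[j],
            "score": float(row[j]),
        }
        if base_row is not None:
            entry["delta"] = float(row[j] - base_row[j])
        partners.append(entry)
    return InteractionReport(
        focal_label=map_.query_labels[idx],
        direction=map_.direction,
        variant=map_.variant,
        partners=partners,
    )


def export_heatmap_table(map_: AttentionMap, path: str | Path) -> None:
    """Write the head-averaged map as a TSV with residue annotations."""
    df = pd.DataFrame(
        map_.head_avg, index=map_.query_labels, columns=map_.key_labels
    )
    df.index.name = "query\\key"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_heatmap_table(path: str | Path) -> AttentionMap:
    """Read back an exported TSV (single pseudo-head; lossless to ~1e-10)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AttentionMap(
        direction="ab2ag",
        variant="wt",
        per_head=df.to_numpy()[None, :, :],
        query_labels=[str(x) for x in df.index],
        key_labels=[str(c) for c in df.columns],
    )
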