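"""Synthetic antibody-antigen mutation datasets with known ground truth.

The generator emulates the *shape* of curated ddG benchmarks (a few dozen
complexes, a handful to a couple hundred variants each, 1-7 substitutions per
variant) while giving every label a known decomposition:

    label = sum_m s(wt_m, mut_m) + sum_{m at interface} b * coupling(m) + noise

* ``s`` is a frozen per-(wt, mut) substitution effect table (a seeded uniform
  draw in [-2, 2] kcal/mol, shipped with the package so tests are stable).
* Each complex designates a small *interface*: antibody positions paired with
  the antigen residue at the same sequence index (a diagonal paratope-epitope
  contact geometry).  A mutation at an interface position earns the bonus
  ``b`` only when its partner residue (in the mutant antigen) is hydrophobic
  -- a genuine cross-sequence, position-aligned dependency that a model
  unable to relate specific residue pairs across the two sequences cannot
  fully capture.
* Mutant residues are alanine-biased (alanine-scanning-style panels dominate
  curated antibody data), which also keeps the substitution-pair vocabulary
  shared between any train/test split of realistic size.

Positive labels destabilize binding (dG_mut > dG_wild).  Everything is a pure
function of the seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .data_io import AMINO_ACIDS, ComplexRecord, Mutation, ProteinSequence

HYDROPHOBIC = set("FLIVW")  # interface trigger letters


class SynthesisError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the package's standard study conditions."""

    n_complexes: int = 32
    records_per_complex: tuple[int, int] = (7, 24)
    antibody_length: tuple[int, int] = (20, 30)
    antigen_length: tuple[int, int] = (20, 30)
    #: probability of each mutation depth (support within 1..7)
    depth_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    n_interface: int = 5
    interaction_bonus: float = 1.5
    #: probability an antibody-side mutation is drawn from the interface set
    interface_bias: float = 0.5
    #: probability a mutation falls on the antibody (vs antigen) side
    antibody_side_prob: float = 0.85
    #: probability the mutant residue is alanine (when the wild type is not)
    alanine_bias: float = 0.6
    noise_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.antibody_length) < 5 or min(self.antigen_length) < 5:
            raise SynthesisError("chain lengths must be at least 5")
        if not self.depth_dist or not set(self.depth_dist) <= set(range(1, 8)):
            raise SynthesisError("depth distribution support must lie in 1..7")
        if abs(sum(self.depth_dist.values()) - 1.0) > 1e-9:
            raise SynthesisError("depth distribution must sum to 1")
        if self.noise_sd < 0:
            raise SynthesisError("noise_sd must be non-negative")
        if max(self.depth_dist) > min(self.antibody_length):
            raise SynthesisError("maximum depth exceeds the shortest chain")


@dataclass
class SynthTruth:
    """Noise-free labels and their decomposition, reproducible from the seed."""

    noise_free: list[float] = field(default_factory=list)
    noise: list[float] = field(default_factory=list)
    terms: list[list[dict]] = field(default_factory=list)
    interfaces: dict[str, list[dict]] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "noise_free": self.noise_free,
                "noise": self.noise,
                "terms": self.terms,
                "interfaces": self.interfaces,
            }
        )


def _effect_table_path() -> Path:
    return Path(resources.files("seqddg") / "data" / "effect_table.csv")


def load_effect_table() -> dict[tuple[str, str], float]:
    """The frozen substitution-effect table s(wt, mut), kcal/mol."""
    table: dict[tuple[str, str], float] = {}
    with open(_effect_table_path(), newline="") as fh:
        for row in csv.DictReader(fh):
            table[(row["wt"], row["mut"])] = float(row["effect"])
    return table


def draw_effect_table(seed: int = 20240) -> dict[tuple[str, str], float]:
    """Seeded draw of the substitution-effect table, clipped to [-2, 2].

    s(w, m) = u(m) - u(w) + 0.3 * eps(w, m): a residue-intrinsic binding
    propensity difference (as in empirical substitution scales, where
    mutation effects track residue properties) plus a pair-specific
    residual.  Used once to create the shipped table; kept for provenance
    and tests.
    """
    rng = np.random.default_rng(seed)
    u = {a: rng.uniform(-1.0, 1.0) for a in AMINO_ACIDS}
    mu = float(np.mean(list(u.values())))
    table = {}
    for w in AMINO_ACIDS:
        for m in AMINO_ACIDS:
            if w != m:
                eff = (u[m] - mu) - (u[w] - mu) + 0.3 * rng.uniform(-1.0, 1.0)
                table[(w, m)] = float(np.clip(eff, -2.0, 2.0))
    return table


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _draw_depth(rng: np.random.Generator, dist: dict[int, float]) -> int:
    depths = sorted(dist)
    return int(rng.choice(depths, p=[dist[d] for d in depths]))


def _mutant_residue(rng: np.random.Generator, wt: str, alanine_bias: float) -> str:
    if wt != "A" and rng.random() < alanine_bias:
        return "A"
    choices = [a for a in AMINO_ACIDS if a != wt]
    return str(rng.choice(choices))


def record_truth(
    ab: str,
    ag_mut: str,
    mutations: list[Mutation],
    interface: dict[int, int],
    effects: dict[tuple[str, str], float],
    bonus: float,
) -> tuple[float, list[dict]]:
    """Noise-free label and decomposition for one variant (label convention:
    additive effects plus interface bonuses on the mutant antigen)."""
    total = 0.0
    terms = []
    for mut in mutations:
        s = effects[(mut.wt_aa, mut.mut_aa)]
        applied = 0.0
        if mut.chain_id == "H" and (mut.position - 1) in interface:
            partner = interface[mut.position - 1]
            if ag_mut[partner] in HYDROPHOBIC:
                applied = bonus
        total += s + applied
        terms.append({"mutation": str(mut), "additive": s, "bonus": applied})
    return total, terms


def generate(config: SynthConfig) -> tuple[list[ComplexRecord], SynthTruth]:
    """Draw a full labelled dataset plus its ground-truth decomposition.

    Antibody chains are named ``H``, antigen chains ``G``.  Labels are the
    decomposition sum plus Normal(0, noise_sd^2) noise.
    """
    rng = np.random.default_rng(config.rng_seed)
    effects = load_effect_table()
    records: list[ComplexRecord] = []
    truth = SynthTruth()
    lo, hi = config.records_per_complex
    for c in range(config.n_complexes):
        cid = f"SYN{c:03d}"
        ab = _random_sequence(rng, int(rng.integers(*config.antibody_length, endpoint=True)))
        ag = _random_sequence(rng, int(rng.integers(*config.antigen_length, endpoint=True)))
        interface = _aligned_interface(rng, ab, ag, config.n_interface)
        truth.interfaces[cid] = [
            {"antibody_pos": a + 1, "antigen_pos": g + 1}
            for a, g in sorted(interface.items())
        ]
        n_rec = int(rng.integers(lo, hi, endpoint=True))
        for _ in range(n_rec):
            depth = _draw_depth(rng, config.depth_dist)
            mutations = _draw_mutations(rng, ab, ag, interface, depth, config)
            ag_mut = list(ag)
            for mut in mutations:
                if mut.chain_id == "G":
                    ag_mut[mut.position - 1] = mut.mut_aa
            noise_free, terms = record_truth(
                ab, "".join(ag_mut), mutations, interface, effects,
                config.interaction_bonus,
            )
            eps = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
            records.append(
                ComplexRecord(
                    complex_id=cid,
                    antibody_chains=(ProteinSequence("H", ab),),
                    antigen_chains=(ProteinSequence("G", ag),),
                    mutations=tuple(mutations),
                    ddg_label=noise_free + eps,
                )
            )
            truth.noise_free.append(noise_free)
            truth.noise.append(eps)
            truth.terms.append(terms)
    return records, truth


def _aligned_interface(
    rng: np.random.Generator, ab: str, ag: str, n_interface: int
) -> dict[int, int]:
    """Interface map: antibody position -> same-index antigen position
    (diagonal contact geometry), drawn among the overlapping index range."""
    span = min(len(ab), len(ag))
    n_int = min(n_interface, span)
    picks = rng.choice(span, size=n_int, replace=False)
    return {int(p): int(p) for p in picks}


def _draw_mutations(
    rng: np.random.Generator,
    ab: str,
    ag: str,
    interface: dict[int, int],
    depth: int,
    config: SynthConfig,
) -> list[Mutation]:
    used_ab: set[int] = set()
    used_ag: set[int] = set()
    mutations: list[Mutation] = []
    for _ in range(depth):
        on_ab = rng.random() < config.antibody_side_prob
        if on_ab and len(used_ab) >= len(ab):
            on_ab = False
        if not on_ab and len(used_ag) >= len(ag):
            on_ab = True
        if on_ab:
            free_int = [p for p in interface if p not in used_ab]
            if free_int and rng.random() < config.interface_bias:
                pos = int(rng.choice(free_int))
            else:
                pos = int(rng.choice([p for p in range(len(ab)) if p not in used_ab]))
            used_ab.add(pos)
            wt = ab[pos]
            mutations.append(
                Mutation("H", wt, pos + 1, _mutant_residue(rng, wt, config.alanine_bias))
            )
        else:
            pos = int(rng.choice([p for p in range(len(ag)) if p not in used_ag]))
            used_ag.add(pos)
            wt = ag[pos]
            mutations.append(
                Mutation("G", wt, pos + 1, _mutant_residue(rng, wt, config.alanine_bias))
            )
    return mutations


def make_identity_clusters(
    config: SynthConfig,
    n_clusters: int,
    divergence: float,
    members_per_cluster: int = 4,
) -> tuple[list[ComplexRecord], SynthTruth]:
    """Dataset whose complexes form sequence-identity clusters.

    Each cluster starts from an independently drawn complex; other members
    copy it with at most `divergence` of positions substituted, so
    within-cluster identity is >= 1 - divergence while across clusters it
    sits near the ~5% background of unrelated sequences.  Records carry a
    ``cluster:<i>`` split tag for verification.
    """
    if n_clusters < 2:
        raise SynthesisError("need at least 2 clusters")
    if not 0.0 <= divergence < 1.0:
        raise SynthesisError("divergence must lie in [0, 1)")
    rng = np.random.default_rng(config.rng_seed)
    effects = load_effect_table()
    records: list[ComplexRecord] = []
    truth = SynthTruth()
    for ci in range(n_clusters):
        base_ab = _random_sequence(
            rng, int(rng.integers(*config.antibody_length, endpoint=True))
        )
        base_ag = _random_sequence(
            rng, int(rng.integers(*config.antigen_length, endpoint=True))
        )
        for mi in range(members_per_cluster):
            ab = _diverge(rng, base_ab, divergence if mi else 0.0)
            ag = _diverge(rng, base_ag, divergence if mi else 0.0)
            cid = f"CL{ci:02d}M{mi:02d}"
            interface = _aligned_interface(rng, ab, ag, config.n_interface)
            depth = _draw_depth(rng, config.depth_dist)
            mutations = _draw_mutations(rng, ab, ag, interface, depth, config)
            ag_mut = list(ag)
            for mut in mutations:
                if mut.chain_id == "G":
                    ag_mut[mut.position - 1] = mut.mut_aa
            noise_free, terms = record_truth(
                ab, "".join(ag_mut), mutations, interface, effects,
                config.interaction_bonus,
            )
            eps = float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
            records.append(
                ComplexRecord(
                    complex_id=cid,
                    antibody_chains=(ProteinSequence("H", ab),),
                    antigen_chains=(ProteinSequence("G", ag),),
                    mutations=tuple(mutations),
                    ddg_label=noise_free + eps,
                    split_tags=(f"cluster:{ci}",),
                )
            )
            truth.noise_free.append(noise_free)
            truth.noise.append(eps)
            truth.terms.append(terms)
    return records, truth


def _diverge(rng: np.random.Generator, seq: str, divergence: float) -> str:
    if divergence == 0.0:
        return seq
    out = list(seq)
    n_sub = int(round(divergence * len(seq)))
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        out[pos] = _mutant_residue(rng, seq[pos], 0.0)
    return "".join(out)
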