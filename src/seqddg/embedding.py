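"""Per-residue sequence embeddings behind a pluggable, frozen embedder contract.

For every record the model consumes four embedding matrices
``{H_ab_wt, H_ag_wt, H_ab_mt, H_ag_mt}`` -- wild-type and mutant antibody and
antigen, each an L x d real matrix with one row per residue.  Production
deployments plug in a pre-trained protein language model (ProtBert / ESM-style
backends) through :func:`register_embedder`; such backends are always run
frozen, with special tokens stripped so the row count equals the residue
count.

The shipped backend is a deterministic *mock* embedder: each row is a
pseudo-random vector keyed by (residue letter, position, seed).  It is a test
double, not a scientific claim -- it is non-contextual by construction so a
single-point mutation perturbs exactly one row, which makes the downstream
attention machinery sharply testable offline.  The residue-identity component
dominates (a per-letter base vector) with a small position-keyed jitter, so
residue identity remains decodable from any row.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ComplexRecord, ProteinSequence, apply_mutations, serialize_chains


class ConfigurationError(ValueError):
    """Unknown embedder kind or unresolvable model identifier."""


class SequenceLengthError(ValueError):
    """Sequence exceeds the backend's context limit (never silently truncated)."""


@dataclass(frozen=True)
class EmbeddingMatrix:
    """L x d per-residue representation of one sequence."""

    values: np.ndarray  # (L, d)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (L x d)")
        if not np.all(np.isfinite(v)):
            raise ValueError("embedding matrix contains non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EmbedderSpec:
    """Which embedder to use and its output width.

    `kind` selects a registered backend ("mock" ships with the package);
    `identifier` is a model name for pretrained backends or the seed salt for
    the mock; embedders are always frozen in this tool.
    """

    kind: str = "mock"
    identifier: str = "0"
    d: int = 32
    frozen: bool = True

    def __post_init__(self):
        if self.d < 2 or self.d % 2 != 0:
            raise ConfigurationError(
                f"embedding width d must be even and >= 2 (rotary pairs), got {self.d}"
            )
        if not self.frozen:
            raise ConfigurationError("the embedding module is always frozen")

    def digest(self) -> str:
        payload = f"{self.kind}|{self.identifier}|{self.d}".encode()
        return hashlib.sha256(payload).hexdigest()


def _hashed_rng(*parts) -> np.random.Generator:
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


class MockEmbedder:
    """Deterministic (letter, position, seed)-keyed pseudo-random embeddings.

    row(letter, pos) = base(letter) + jitter * noise(letter, pos), with both
    components drawn from hash-seeded generators, so embeddings are a pure
    function of (residues, spec) and stable across platforms.
    """

    max_length = 4096
    jitter = 0.1

    def __init__(self, spec: EmbedderSpec):
        self.spec = spec
        self.n_calls = 0
        self._base: dict[str, np.ndarray] = {}

    def _base_vector(self, letter: str) -> np.ndarray:
        if letter not in self._base:
            rng = _hashed_rng("base", self.spec.identifier, letter)
            self._base[letter] = rng.standard_normal(self.spec.d)
        return self._base[letter]

    def __call__(self, seq: ProteinSequence) -> EmbeddingMatrix:
        if len(seq) > self.max_length:
            raise SequenceLengthError(
                f"sequence of length {len(seq)} exceeds the mock context "
                f"limit {self.max_length}"
            )
        self.n_calls += 1
        rows = np.empty((len(seq), self.spec.d))
        for i, letter in enumerate(seq.residues):
            rng = _hashed_rng("pos", self.spec.identifier, letter, i)
            rows[i] = self._base_vector(letter) + self.jitter * rng.standard_normal(
                self.spec.d
            )
        return EmbeddingMatrix(rows)


_REGISTRY: dict[str, type] = {"mock": MockEmbedder}


def register_embedder(kind: str, factory: type) -> None:
    """Register a backend; `factory(spec)` must return a callable embedder."""
    _REGISTRY[kind] = factory


def make_embedder(spec: EmbedderSpec):
    try:
        factory = _REGISTRY[spec.kind]
    except KeyError:
        raise ConfigurationError(
            f"unknown embedder kind {spec.kind!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(spec)


def embed(
    seq: ProteinSequence, spec: EmbedderSpec, embedder=None
) -> EmbeddingMatrix:
    """Embed one sequence; rows = residues, columns = the spec's d."""
    embedder = embedder if embedder is not None else make_embedder(spec)
    out = embedder(seq)
    if out.L != len(seq):
        raise RuntimeError(
            f"embedder returned {out.L} rows for a {len(seq)}-residue sequence "
            "(special tokens must be stripped)"
        )
    return out


@dataclass
class ComplexEmbeddings:
    """The four matrices the attention module consumes."""

    ab_wt: EmbeddingMatrix
    ag_wt: EmbeddingMatrix
    ab_mt: EmbeddingMatrix
    ag_mt: EmbeddingMatrix

    def as_dict(self) -> dict[str, EmbeddingMatrix]:
        return {
            "ab_wt": self.ab_wt,
            "ag_wt": self.ag_wt,
            "ab_mt": self.ab_mt,
            "ag_mt": self.ag_mt,
        }


def serialized_sequences(
    record: ComplexRecord, separator: str = ""
) -> dict[str, ProteinSequence]:
    """Serialize each side's chains into one sequence, wild-type and mutant.

    Multi-chain sides are concatenated in listed order; an unmutated side's
    mutant sequence is the wild type itself.
    """
    mt_ab = apply_mutations(
        list(record.antibody_chains),
        [m for m in record.mutations if m.chain_id in
         {c.chain_id for c in record.antibody_chains}],
    )
    mt_ag = apply_mutations(
        list(record.antigen_chains),
        [m for m in record.mutations if m.chain_id in
         {c.chain_id for c in record.antigen_chains}],
    )
    out = {}
    for name, chains in (
        ("ab_wt", record.antibody_chains),
        ("ag_wt", record.antigen_chains),
        ("ab_mt", mt_ab),
        ("ag_mt", mt_ag),
    ):
        seq, _ = serialize_chains(chains, separator)
        out[name] = ProteinSequence("+".join(c.chain_id for c in chains), seq)
    return out


def embed_complex(
    record: ComplexRecord,
    spec: EmbedderSpec,
    cache: "EmbeddingCache | None" = None,
    embedder=None,
) -> ComplexEmbeddings:
    """Produce {H_ab_wt, H_ag_wt, H_ab_mt, H_ag_mt} for one record."""
    embedder = embedder if embedder is not None else make_embedder(spec)
    seqs = serialized_sequences(record)

    def one(seq):
        if cache is not None:
            return cache.get_or_compute(seq, spec, embedder)
        return embed(seq, spec, embedder)

    return ComplexEmbeddings(
        ab_wt=one(seqs["ab_wt"]),
        ag_wt=one(seqs["ag_wt"]),
        ab_mt=one(seqs["ab_mt"]),
        ag_mt=one(seqs["ag_mt"]),
    )


class EmbeddingCache:
    """Content-addressed embedding store (memory, optionally backed on disk).

    Keys are SHA-256 digests of (residue string, embedder spec); the frozen
    embedder makes entries permanently valid.  Disk entries are ``.npy``
    arrays with a JSON sidecar recording the sequence and spec; a corrupted
    entry is recomputed with a warning, never served.
    """

    def __init__(self, directory: str | Path | None = None):
        self.directory = Path(directory) if directory is not None else None
        if self.directory is not None:
            self.directory.mkdir(parents=True, exist_ok=True)
        self._memory: dict[str, EmbeddingMatrix] = {}

    @staticmethod
    def key(seq: ProteinSequence, spec: EmbedderSpec) -> str:
        return hashlib.sha256(
            f"{seq.residues}|{spec.digest()}".encode()
        ).hexdigest()

    def get_or_compute(
        self, seq: ProteinSequence, spec: EmbedderSpec, embedder
    ) -> EmbeddingMatrix:
        k = self.key(seq, spec)
        if k in self._memory:
            return self._memory[k]
        if self.directory is not None:
            hit = self._load(k, seq)
            if hit is not None:
                self._memory[k] = hit
                return hit
        out = embed(seq, spec, embedder)
        self._memory[k] = out
        if self.directory is not None:
            self._store(k, seq, spec, out)
        return out

    def clear(self) -> None:
        self._memory.clear()

    # -- disk backend ----------------------------------------------------
    def _paths(self, k: str) -> tuple[Path, Path]:
        return self.directory / f"{k}.npy", self.directory / f"{k}.json"

    def _store(self, k, seq, spec, matrix) -> None:
        npy, sidecar = self._paths(k)
        np.save(npy, matrix.values)
        sidecar.write_text(
            json.dumps({"length": len(seq), "spec": spec.digest(), "d": spec.d})
        )

    def _load(self, k: str, seq: ProteinSequence) -> EmbeddingMatrix | None:
        npy, sidecar = self._paths(k)
        if not (npy.exists() and sidecar.exists()):
            return None
        try:
            meta = json.loads(sidecar.read_text())
            values = np.load(npy)
            if values.shape[0] != meta["length"] or values.shape[0] != len(seq):
                raise ValueError("row count mismatch")
            return EmbeddingMatrix(values)
        except Exception as exc:  # corrupted entry: recompute
            warnings.warn(f"corrupted embedding cache entry {k[:12]}: {exc}")
            return None
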