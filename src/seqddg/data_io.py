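"""Mutation-dataset I/O and thermodynamic conversions.

The package consumes AB-bind/SKEMPI-style tables of antibody-antigen complex
variants: each row names a complex, gives the wild-type antibody and antigen
chain sequences, a list of point substitutions, and the measured change in
binding free energy (ddG, kcal/mol, positive = weakened binding).

Mutation codes use the ``CHAIN:WposM`` dialect (e.g. ``A:R53Q`` -- arginine 53
of chain A to glutamine), with ``;`` separating the sites of a multi-point
variant.  Positions are 1-based indices into the supplied chain sequence; PDB
author numbering with insertion codes is *not* resolved -- datasets must ship
positions aligned to the given sequences.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = set(AMINO_ACIDS) | {"X"}

#: Gas constant in kcal/(mol K) and lab-standard absolute temperature;
#: overridable when a dataset was measured under other conditions.
DEFAULT_R = 0.0019872
DEFAULT_T = 298.15


class MutationParseError(ValueError):
    """Malformed mutation code."""


class MutationValidationError(ValueError):
    """Mutation inconsistent with the wild-type sequences."""


class SchemaError(ValueError):
    """Dataset file missing required columns."""


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant R (kcal/mol/K) and absolute temperature T (K)."""

    R: float = DEFAULT_R
    T: float = DEFAULT_T

    def __post_init__(self):
        if self.R <= 0 or self.T <= 0:
            raise ValueError("R and T must be positive")


@dataclass(frozen=True)
class ProteinSequence:
    """One chain: a short identifier plus its residue string."""

    chain_id: str
    residues: str

    def __post_init__(self):
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.residues) - ALLOWED_LETTERS
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


_MUTATION_RE = re.compile(
    r"^(?P<chain>[A-Za-z0-9]+):(?P<wt>[A-Za-z])(?P<pos>\d+)(?P<mut>[A-Za-z])$"
)


@dataclass(frozen=True)
class Mutation:
    """A single substitution: wild-type residue -> mutant at a 1-based position."""

    chain_id: str
    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self):
        object.__setattr__(self, "wt_aa", self.wt_aa.upper())
        object.__setattr__(self, "mut_aa", self.mut_aa.upper())
        if self.wt_aa not in AMINO_ACIDS:
            raise MutationParseError(f"invalid wild-type residue {self.wt_aa!r}")
        if self.mut_aa not in AMINO_ACIDS:
            raise MutationParseError(f"invalid mutant residue {self.mut_aa!r}")
        if self.wt_aa == self.mut_aa:
            raise MutationParseError(
                f"wild-type and mutant residues identical ({self.wt_aa!r})"
            )
        if self.position < 1:
            raise MutationParseError(f"non-positive position {self.position}")

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.wt_aa}{self.position}{self.mut_aa}"


def parse_mutation_code(code: str) -> Mutation:
    """Parse one ``CHAIN:WposM`` code, e.g. ``A:R53Q``."""
    m = _MUTATION_RE.match(code.strip())
    if m is None:
        raise MutationParseError(f"malformed mutation code {code!r}")
    return Mutation(m["chain"], m["wt"], int(m["pos"]), m["mut"])


def format_mutation_code(mut: Mutation) -> str:
    return str(mut)


def parse_mutation_list(codes: str) -> list[Mutation]:
    """Parse a ``;``-separated multi-site mutation string."""
    return [parse_mutation_code(c) for c in codes.split(";") if c.strip()]


@dataclass(frozen=True)
class ComplexRecord:
    """One labelled data point: a complex, its mutations, and the ddG label."""

    complex_id: str
    antibody_chains: tuple[ProteinSequence, ...]
    antigen_chains: tuple[ProteinSequence, ...]
    mutations: tuple[Mutation, ...]
    ddg_label: float
    split_tags: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "antibody_chains", tuple(self.antibody_chains))
        object.__setattr__(self, "antigen_chains", tuple(self.antigen_chains))
        object.__setattr__(self, "mutations", tuple(self.mutations))
        object.__setattr__(self, "split_tags", tuple(self.split_tags))
        if len(self.mutations) < 1:
            raise MutationValidationError(
                f"{self.complex_id}: a record needs at least one mutation"
            )
        chains = {c.chain_id: c for c in self.antibody_chains + self.antigen_chains}
        if len(chains) != len(self.antibody_chains) + len(self.antigen_chains):
            raise MutationValidationError(f"{self.complex_id}: duplicate chain ids")
        for mut in self.mutations:
            validate_mutation(list(chains.values()), mut, context=self.complex_id)
        if not math.isfinite(self.ddg_label):
            raise MutationValidationError(f"{self.complex_id}: non-finite ddG label")

    @property
    def depth(self) -> int:
        """Number of simultaneously substituted residues (1 = single-point)."""
        return len(self.mutations)

    @property
    def mutated_chain_ids(self) -> set[str]:
        return {m.chain_id for m in self.mutations}

    def antibody_is_mutated(self) -> bool:
        ab = {c.chain_id for c in self.antibody_chains}
        return bool(self.mutated_chain_ids & ab)

    def antigen_is_mutated(self) -> bool:
        ag = {c.chain_id for c in self.antigen_chains}
        return bool(self.mutated_chain_ids & ag)


def validate_mutation(
    chains: list[ProteinSequence], mut: Mutation, context: str = ""
) -> ProteinSequence:
    """Check `mut` against the chain it names; return that chain."""
    prefix = f"{context}: " if context else ""
    matching = [c for c in chains if c.chain_id == mut.chain_id]
    if not matching:
        raise MutationValidationError(
            f"{prefix}mutation {mut} names unknown chain {mut.chain_id!r}"
        )
    chain = matching[0]
    if mut.position > len(chain):
        raise MutationValidationError(
            f"{prefix}mutation {mut}: position {mut.position} beyond chain "
            f"{chain.chain_id!r} of length {len(chain)}"
        )
    found = chain.residues[mut.position - 1]
    if found != mut.wt_aa:
        raise MutationValidationError(
            f"{prefix}wt mismatch for {mut}: chain {chain.chain_id!r} position "
            f"{mut.position} expected {mut.wt_aa!r}, found {found!r}"
        )
    return chain


def apply_mutations(
    wt_chains: list[ProteinSequence], mutations: list[Mutation]
) -> list[ProteinSequence]:
    """Return copies of `wt_chains` with every substitution applied.

    Inputs are never modified; chains untouched by any mutation come back
    as the same objects.
    """
    residues = {c.chain_id: list(c.residues) for c in wt_chains}
    touched: set[str] = set()
    for mut in mutations:
        validate_mutation(wt_chains, mut)
        residues[mut.chain_id][mut.position - 1] = mut.mut_aa
        touched.add(mut.chain_id)
    return [
        replace(c, residues="".join(residues[c.chain_id]))
        if c.chain_id in touched
        else c
        for c in wt_chains
    ]


def serialize_chains(
    chains: tuple[ProteinSequence, ...] | list[ProteinSequence],
    separator: str = "",
) -> tuple[str, dict[str, int]]:
    """Concatenate chains in listed order into one sequence string.

    Returns the serialized sequence and a map from chain id to the 0-based
    offset of that chain's first residue, so per-chain 1-based mutation
    positions convert deterministically to serialized indices.
    """
    if separator and (len(separator) != 1 or separator not in ALLOWED_LETTERS):
        raise ValueError("separator must be a single allowed residue letter")
    offsets: dict[str, int] = {}
    parts: list[str] = []
    pos = 0
    for i, chain in enumerate(chains):
        if i > 0 and separator:
            pos += 1
        offsets[chain.chain_id] = pos
        parts.append(chain.residues)
        pos += len(chain)
    return separator.join(parts), offsets


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def delta_g(kd: float, const: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy dG = -R T ln(1/Kd) = R T ln(Kd), in kcal/mol.

    Lower dissociation constants (tighter binding) give more negative dG.
    """
    if kd <= 0:
        raise ValueError(f"dissociation constant must be positive, got {kd}")
    return const.R * const.T * math.log(kd)


def ddg(dg_mut: float, dg_wild: float) -> float:
    """ddG_bind = dG_mut - dG_wild (kcal/mol); positive = destabilized binding."""
    return dg_mut - dg_wild


# ---------------------------------------------------------------------------
# dataset reading / writing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FormatSpec:
    """Column mapping for the CSV dialect.

    Antibody/antigen columns hold ``ID=SEQ`` entries joined by ``|`` (one per
    chain); the mutation column holds ``;``-separated ``CHAIN:WposM`` codes.
    """

    complex_id: str = "complex_id"
    antibody: str = "antibody"
    antigen: str = "antigen"
    mutations: str = "mutations"
    ddg: str = "ddg"


@dataclass
class Rejection:
    row: int
    complex_id: str
    reason: str


@dataclass
class ReadResult:
    records: list[ComplexRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)

    def rejection_report(self) -> str:
        """JSON report of every rejected row and why."""
        return json.dumps(
            [
                {"row": r.row, "complex_id": r.complex_id, "reason": r.reason}
                for r in self.rejections
            ],
            indent=2,
        )


def _parse_chain_field(text: str) -> list[ProteinSequence]:
    chains = []
    for entry in str(text).split("|"):
        if "=" not in entry:
            raise ValueError(f"chain entry {entry!r} is not 'ID=SEQ'")
        cid, seq = entry.split("=", 1)
        chains.append(ProteinSequence(cid.strip(), seq.strip()))
    return chains


def _format_chain_field(chains: tuple[ProteinSequence, ...]) -> str:
    return "|".join(f"{c.chain_id}={c.residues}" for c in chains)


def read_dataset(path, format_spec: FormatSpec = FormatSpec()) -> ReadResult:
    """Read a mutation dataset CSV; invalid rows go to the rejection report.

    Raises :class:`SchemaError` if a required column is absent; row-level
    problems (unparseable ddG, wt mismatches, malformed codes) never abort
    the read.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        format_spec.complex_id,
        format_spec.antibody,
        format_spec.antigen,
        format_spec.mutations,
        format_spec.ddg,
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    result = ReadResult()
    for i, row in df.iterrows():
        cid = str(row[format_spec.complex_id])
        try:
            label = float(row[format_spec.ddg])
        except ValueError:
            result.rejections.append(
                Rejection(int(i), cid, f"unreadable ddG {row[format_spec.ddg]!r}")
            )
            continue
        try:
            record = ComplexRecord(
                complex_id=cid,
                antibody_chains=tuple(_parse_chain_field(row[format_spec.antibody])),
                antigen_chains=tuple(_parse_chain_field(row[format_spec.antigen])),
                mutations=tuple(parse_mutation_list(row[format_spec.mutations])),
                ddg_label=label,
            )
        except (ValueError, MutationParseError, MutationValidationError) as exc:
            reason = str(exc)
            if "wt mismatch" in reason:
                reason = "wt mismatch: " + reason
            result.rejections.append(Rejection(int(i), cid, reason))
            continue
        result.records.append(record)
    return result


def write_dataset(
    records: list[ComplexRecord], path, format_spec: FormatSpec = FormatSpec()
) -> None:
    """Write records in the CSV dialect `read_dataset` consumes (round-trips)."""
    rows = [
        {
            format_spec.complex_id: r.complex_id,
            format_spec.antibody: _format_chain_field(r.antibody_chains),
            format_spec.antigen: _format_chain_field(r.antigen_chains),
            format_spec.mutations: ";".join(str(m) for m in r.mutations),
            format_spec.ddg: repr(r.ddg_label),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_fasta(path) -> list[ProteinSequence]:
    """Read chains from a FASTA file (record id becomes the chain id)."""
    from Bio import SeqIO

    return [
        ProteinSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(chains: list[ProteinSequence], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(c.residues), id=c.chain_id, description="") for c in chains],
        path,
        "fasta",
    )


def records_to_dataframe(records: list[ComplexRecord]) -> pd.DataFrame:
    """Flat view of a record list for analysis (one row per record)."""
    return pd.DataFrame(
        {
            "complex_id": [r.complex_id for r in records],
            "depth": [r.depth for r in records],
            "mutations": [";".join(str(m) for m in r.mutations) for r in records],
            "ddg": [r.ddg_label for r in records],
        }
    )
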