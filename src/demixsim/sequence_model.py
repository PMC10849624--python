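"""Protein chains, domain maps, variant constructs and coarse-grained bead parameters.

A chain is a one-letter amino-acid sequence with 1-based, inclusive domain
annotations (the convention used throughout condensate biology figures).
Variants are ordered edit lists (substitutions + deletions) expressed in the
coordinates of the *original* sequence; applying a variant re-indexes domain
annotations and reactive-cysteine flags across deletions.

Coarse-graining maps each residue onto a single bead carrying a diameter
``sigma`` (nm), a hydropathy "stickiness" ``lam`` (the λ of hydropathy-scale
condensate models, dimensionless), a net ``charge`` (e) and a ``mass`` (amu).
The bundled default table is an HPS-style hydropathy-scale parameter set
shipped as data (``demixsim/data/hps_params.tsv``); alternative tables with
the same columns can be supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AMINO_ACIDS",
    "CGBeadParams",
    "Deletion",
    "DomainAnnotation",
    "DomainMapError",
    "ParameterizationError",
    "ProteinChainSpec",
    "Substitution",
    "VariantError",
    "VariantSpec",
    "annotate_tdp43_domains",
    "apply_variant",
    "default_cg_table",
    "load_cg_table",
    "load_domains",
    "load_variant",
    "save_domains",
    "save_variant",
    "parameterize",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

TDP43_LENGTH = 414
#: Canonical TDP-43 domain intervals (1-based inclusive).
TDP43_DOMAINS = (
    ("NTD", 1, 80),
    ("RRM1", 106, 176),
    ("RRM2", 191, 262),
    ("CTD", 263, 414),
    ("G", 274, 314),
    ("HP", 318, 343),
    ("Q/N", 344, 365),
    ("S", 370, 402),
)
#: RRM1 cysteines whose solvent exposure enables intermolecular disulfides.
TDP43_REACTIVE_CYSTEINES = (173, 175)


class DomainMapError(ValueError):
    """Chain length does not match the canonical domain map."""


class VariantError(ValueError):
    """Variant edit inconsistent with the chain sequence."""


class ParameterizationError(KeyError):
    """A residue is missing from the CG parameter table."""


@dataclass(frozen=True)
class DomainAnnotation:
    """A labelled 1-based inclusive interval on a chain."""

    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain interval {self.label}: {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Substitution:
    """Point substitution at a 1-based position; ``from_res`` must match."""

    position: int
    from_res: str
    to_res: str


@dataclass(frozen=True)
class Deletion:
    """Deletion of a 1-based inclusive interval."""

    start: int
    end: int


Edit = Union[Substitution, Deletion]


@dataclass(frozen=True)
class VariantSpec:
    """An ordered list of edits, all in original-sequence coordinates.

    Substitutions are applied first (in list order), then deletions are
    applied from the C-terminal end so earlier intervals stay valid.
    Deletion intervals must not overlap.
    """

    edits: tuple[Edit, ...] = ()

    @property
    def deletions(self) -> tuple[Deletion, ...]:
        return tuple(e for e in self.edits if isinstance(e, Deletion))

    @property
    def substitutions(self) -> tuple[Substitution, ...]:
        return tuple(e for e in self.edits if isinstance(e, Substitution))


@dataclass(frozen=True)
class CGBeadParams:
    """Per-bead coarse-grained parameters (one bead per residue)."""

    sigma: float  # bead diameter, nm
    lam: float  # hydropathy stickiness λ
    charge: float  # net charge, e
    mass: float  # amu
    reactive: bool = False  # reactive-cysteine flag (disulfide candidate)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.mass <= 0:
            raise ValueError("mass must be positive")


@dataclass
class ProteinChainSpec:
    """A named chain with domains and reactive-cysteine positions."""

    name: str
    residues: str
    domains: tuple[DomainAnnotation, ...] = ()
    reactive_cysteines: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("residues must be non-empty")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residue codes: {sorted(bad)}")
        self.domains = tuple(self.domains)
        labels = [d.label for d in self.domains]
        if len(labels) != len(set(labels)):
            raise ValueError("domain labels must be unique per chain")
        for d in self.domains:
            if d.end > len(self.residues):
                raise ValueError(f"domain {d.label} exceeds chain length {len(self.residues)}")
        self.reactive_cysteines = frozenset(int(i) for i in self.reactive_cysteines)
        for i in self.reactive_cysteines:
            if not (1 <= i <= len(self.residues)):
                raise ValueError(f"reactive cysteine index {i} out of range")
            if self.residues[i - 1] != "C":
                raise ValueError(f"residue {i} is {self.residues[i - 1]}, not C")

    def __len__(self) -> int:
        return len(self.residues)

    def domain(self, label: str) -> DomainAnnotation:
        for d in self.domains:
            if d.label == label:
                return d
        raise KeyError(label)


def annotate_tdp43_domains(length: int) -> list[DomainAnnotation]:
    """Canonical TDP-43 domain map for the full-length 414-residue protein.

    Returns the eight labelled intervals: NTD 1-80, RRM1 106-176,
    RRM2 191-262, CTD 263-414, and the CTD sub-regions G 274-314,
    HP 318-343 (hydrophobic patch), Q/N 344-365, S 370-402.
    """
    if length != TDP43_LENGTH:
        raise DomainMapError(
            f"canonical TDP-43 domain map requires length {TDP43_LENGTH}, got {length}"
        )
    return [DomainAnnotation(lbl, s, e) for lbl, s, e in TDP43_DOMAINS]


def _check_substitution(residues: str, sub: Substitution) -> None:
    if not (1 <= sub.position <= len(residues)):
        raise VariantError(f"substitution position {sub.position} out of range 1-{len(residues)}")
    actual = residues[sub.position - 1]
    if actual != sub.from_res:
        raise VariantError(
            f"substitution at {sub.position}: sequence has {actual}, variant expects {sub.from_res}"
        )
    if sub.to_res not in AMINO_ACIDS:
        raise VariantError(f"substitution target {sub.to_res!r} is not a canonical residue")


def apply_variant(chain: ProteinChainSpec, variant: VariantSpec) -> ProteinChainSpec:
    """Apply a variant to a chain, re-indexing annotations across deletions.

    Substitutions are checked against the original sequence. Domain
    annotations falling entirely inside a deleted interval are dropped;
    partially overlapping annotations are truncated. Reactive-cysteine flags
    survive only if the flagged position still carries a cysteine.
    """
    dels = sorted(variant.deletions, key=lambda d: d.start)
    for d in dels:
        if not (1 <= d.start <= d.end <= len(chain.residues)):
            raise VariantError(f"deletion {d.start}-{d.end} out of range")
    for a, b in zip(dels, dels[1:]):
        if b.start <= a.end:
            raise VariantError(f"overlapping deletions {a} and {b}")

    seq = list(chain.residues)
    for sub in variant.substitutions:
        _check_substitution(chain.residues, sub)
        seq[sub.position - 1] = sub.to_res

    # keep[i] True if original 1-based position i+1 survives
    keep = [True] * len(seq)
    for d in dels:
        for i in range(d.start - 1, d.end):
            keep[i] = False
    # new_index[i] = 1-based position after deletions, or None
    new_index: list[int | None] = []
    pos = 0
    for k in keep:
        if k:
            pos += 1
            new_index.append(pos)
        else:
            new_index.append(None)

    new_seq = "".join(s for s, k in zip(seq, keep) if k)
    if not new_seq:
        raise VariantError("variant deletes the entire chain")

    new_domains = []
    for dom in chain.domains:
        surv = [new_index[i] for i in range(dom.start - 1, dom.end) if keep[i]]
        if surv:
            new_domains.append(DomainAnnotation(dom.label, surv[0], surv[-1]))

    new_reactive = set()
    for rc in chain.reactive_cysteines:
        ni = new_index[rc - 1]
        if ni is not None and new_seq[ni - 1] == "C":
            new_reactive.add(ni)

    return ProteinChainSpec(
        name=chain.name,
        residues=new_seq,
        domains=tuple(new_domains),
        reactive_cysteines=frozenset(new_reactive),
    )


# ---------------------------------------------------------------------------
# CG parameter tables


def load_cg_table(path: str | Path) -> dict[str, CGBeadParams]:
    """Read a per-residue CG parameter table.

    TSV columns: ``residue``, ``sigma_nm``, ``lambda``, ``charge``, ``mass``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"residue", "sigma_nm", "lambda", "charge", "mass"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterizationError(f"table missing columns: {sorted(missing)}")
    table = {}
    for rec in df.to_dict("records"):
        table[str(rec["residue"])] = CGBeadParams(
            sigma=float(rec["sigma_nm"]),
            lam=float(rec["lambda"]),
            charge=float(rec["charge"]),
            mass=float(rec["mass"]),
        )
    return table


def default_cg_table() -> dict[str, CGBeadParams]:
    """The bundled HPS-style hydropathy-scale table (all 20 residues)."""
    with resources.as_file(resources.files("demixsim") / "data" / "hps_params.tsv") as p:
        return load_cg_table(p)


def parameterize(
    chain: ProteinChainSpec, table: dict[str, CGBeadParams]
) -> list[CGBeadParams]:
    """One CG bead per residue; reactive flags set on ``reactive_cysteines``."""
    beads = []
    for i, res in enumerate(chain.residues, start=1):
        if res not in table:
            raise ParameterizationError(f"residue {res!r} absent from CG table")
        base = table[res]
        beads.append(replace(base, reactive=(i in chain.reactive_cysteines)))
    return beads


# ---------------------------------------------------------------------------
# Annotation / variant serialisation (YAML; JSON is a YAML subset)


def save_domains(domains: Sequence[DomainAnnotation], path: str | Path) -> None:
    import yaml

    payload = [{"label": d.label, "start": d.start, "end": d.end} for d in domains]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_domains(path: str | Path) -> list[DomainAnnotation]:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh) or []
    return [DomainAnnotation(d["label"], int(d["start"]), int(d["end"])) for d in payload]


def save_variant(variant: VariantSpec, path: str | Path) -> None:
    import yaml

    edits = []
    for e in variant.edits:
        if isinstance(e, Substitution):
            edits.append({"type": "substitution", "position": e.position,
                          "from": e.from_res, "to": e.to_res})
        else:
            edits.append({"type": "deletion", "start": e.start, "end": e.end})
    with open(path, "w") as fh:
        yaml.safe_dump({"edits": edits}, fh, sort_keys=False)


def load_variant(path: str | Path) -> VariantSpec:
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    edits: list[Edit] = []
    for e in payload.get("edits", []):
        kind = e.get("type")
        if kind == "substitution":
            edits.append(Substitution(int(e["position"]), e["from"], e["to"]))
        elif kind == "deletion":
            edits.append(Deletion(int(e["start"]), int(e["end"])))
        else:
            raise ValueError(f"unknown edit type {kind!r}")
    return VariantSpec(tuple(edits))


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path: str | Path) -> list[ProteinChainSpec]:
    """Read chains from FASTA (no annotations; sequence + name only)."""
    chains = []
    for rec in SeqIO.parse(str(path), "fasta"):
        chains.append(ProteinChainSpec(name=rec.id, residues=str(rec.seq)))
    return chains


def write_fasta(chains: Iterable[ProteinChainSpec], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.residues), id=c.name, description="") for c in chains
    ]
    SeqIO.write(records, str(path), "fasta")
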