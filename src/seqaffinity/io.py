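"""Domain types and file I/O: chains, complexes, PSSM profiles, datasets.

Formats are deliberately plain text: multi-record FASTA for chains, a small
comma-delimited table for complexes (``complex_id, ligand_chains,
receptor_chains, delta_g, kd`` with ``;``-separated chain ids), and the ASCII
PSSM layout produced by ``psiblast -out_ascii_pssm``.  All writers are
byte-stable given identical inputs.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, sanitize_sequence
from .thermo import STANDARD_TEMPERATURE, delta_g_to_kd

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its expected layout."""


class ChainReferenceError(KeyError):
    """Raised when a complex table references an unknown chain id."""


@dataclass(frozen=True)
class ProteinChain:
    """One amino-acid sequence with an identifier.

    The sequence must already be sanitized: non-empty, upper-case, and drawn
    from the canonical 20-letter alphabet (see :func:`sanitize_sequence`).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("chain id must be non-empty")
        if not self.sequence:
            raise ValueError(f"chain {self.id!r}: sequence must be non-empty")
        bad = set(self.sequence) - set(AA_INDEX)
        if bad:
            raise ValueError(
                f"chain {self.id!r}: non-canonical residues {sorted(bad)}; "
                "sanitize sequences before constructing ProteinChain"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_raw(cls, id: str, sequence: str) -> "ProteinChain":
        """Build a chain from raw input, sanitizing the sequence."""
        return cls(id=id, sequence=sanitize_sequence(sequence, context=f"chain {id!r}"))


@dataclass(frozen=True)
class ProteinComplex:
    """A ligand/receptor pair of (possibly multi-chain) proteins.

    ``delta_g`` is the binding free energy in kcal/mol, ``kd`` the dissociation
    constant in molar; both labels are optional.  When both are present they
    are checked against ``dG = R*T*ln(Kd)`` at standard temperature and a
    warning is logged if they disagree by more than 1% (relative, on Kd).
    """

    id: str
    ligand: tuple[ProteinChain, ...]
    receptor: tuple[ProteinChain, ...]
    delta_g: float | None = None
    kd: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand", tuple(self.ligand))
        object.__setattr__(self, "receptor", tuple(self.receptor))
        if not self.id:
            raise ValueError("complex id must be non-empty")
        if not self.ligand or not self.receptor:
            raise ValueError(f"complex {self.id!r}: ligand and receptor each need >=1 chain")
        if self.delta_g is not None and not math.isfinite(self.delta_g):
            raise ValueError(f"complex {self.id!r}: delta_g must be finite")
        if self.kd is not None and (not math.isfinite(self.kd) or self.kd <= 0):
            raise ValueError(f"complex {self.id!r}: kd must be finite and positive")
        if self.delta_g is not None and self.kd is not None:
            implied = delta_g_to_kd(self.delta_g, STANDARD_TEMPERATURE)
            if abs(implied - self.kd) > 0.01 * self.kd:
                logger.warning(
                    "complex %r: delta_g=%.4g kcal/mol implies Kd=%.4g M at %.2f K "
                    "but table gives Kd=%.4g M (>1%% apart)",
                    self.id, self.delta_g, implied, STANDARD_TEMPERATURE, self.kd,
                )

    @property
    def chains(self) -> tuple[ProteinChain, ...]:
        """All chains of the complex, ligand first."""
        return self.ligand + self.receptor


@dataclass(frozen=True)
class PSSMProfile:
    """Per-residue log-odds profile (PSI-BLAST position-specific scores)."""

    chain_id: str
    rows: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.chain_id!r}: expected (L, 20) rows, got {rows.shape}"
            )
        object.__setattr__(self, "rows", rows)

    def __len__(self) -> int:
        return self.rows.shape[0]


@dataclass
class ComplexDataset:
    """A labelled collection of protein complexes."""

    complexes: list[ProteinComplex]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.complexes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FormatError(f"duplicate complex ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.complexes]

    @property
    def y(self) -> np.ndarray:
        """Affinity labels (kcal/mol); NaN where unlabelled."""
        return np.array(
            [c.delta_g if c.delta_g is not None else np.nan for c in self.complexes]
        )

    def unique_chains(self) -> list[ProteinChain]:
        """Distinct chains across all complexes, in first-appearance order."""
        seen: dict[str, ProteinChain] = {}
        for c in self.complexes:
            for ch in c.chains:
                if ch.id not in seen:
                    seen[ch.id] = ch
                elif seen[ch.id].sequence != ch.sequence:
                    raise FormatError(f"chain id {ch.id!r} used with differing sequences")
        return list(seen.values())

    def require_cv_ready(self, min_n: int = 2) -> None:
        if len(self) < min_n:
            raise ValueError(
                f"dataset has {len(self)} complexes; >= {min_n} required for cross-validation"
            )
        missing = [c.id for c in self.complexes if c.delta_g is None]
        if missing:
            raise ValueError(f"complexes without delta_g labels: {missing}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read protein chains from a FASTA file, sanitizing sequences."""
    from Bio import SeqIO

    path = Path(path)
    chains = [
        ProteinChain.from_raw(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not chains:
        raise FormatError(f"{path}: no FASTA records found")
    return chains


def write_fasta(chains: list[ProteinChain], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for ch in chains:
            fh.write(f">{ch.id}\n")
            for i in range(0, len(ch.sequence), width):
                fh.write(ch.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Complex table

_TABLE_COLUMNS = ["complex_id", "ligand_chains", "receptor_chains", "delta_g", "kd"]


def read_complex_table(path: str | Path, chains: list[ProteinChain]) -> ComplexDataset:
    """Read the complex table and resolve chain ids against ``chains``."""
    path = Path(path)
    by_id = {ch.id: ch for ch in chains}
    complexes: list[ProteinComplex] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _TABLE_COLUMNS:
            raise FormatError(
                f"{path}: header must be {','.join(_TABLE_COLUMNS)}, got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            cid = (row["complex_id"] or "").strip()
            if not cid:
                raise FormatError(f"{path}:{lineno}: empty complex_id")

            def resolve(which: str) -> list[ProteinChain]:
                ids = [s.strip() for s in (row[which] or "").split(";") if s.strip()]
                missing = [i for i in ids if i not in by_id]
                if missing:
                    raise ChainReferenceError(
                        f"{path}:{lineno}: complex {cid!r} references unknown "
                        f"{which.split('_')[0]} chain id(s) {missing}"
                    )
                return [by_id[i] for i in ids]

            dg = row["delta_g"].strip() if row["delta_g"] else ""
            kd = row["kd"].strip() if row["kd"] else ""
            complexes.append(
                ProteinComplex(
                    id=cid,
                    ligand=tuple(resolve("ligand_chains")),
                    receptor=tuple(resolve("receptor_chains")),
                    delta_g=float(dg) if dg else None,
                    kd=float(kd) if kd else None,
                )
            )
    return ComplexDataset(complexes=complexes, provenance=str(path))


def write_complex_table(dataset: ComplexDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_COLUMNS)
        for c in dataset:
            writer.writerow(
                [
                    c.id,
                    ";".join(ch.id for ch in c.ligand),
                    ";".join(ch.id for ch in c.receptor),
                    "" if c.delta_g is None else repr(float(c.delta_g)),
                    "" if c.kd is None else repr(float(c.kd)),
                ]
            )


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

def read_pssm_ascii(path: str | Path, chain_id: str | None = None) -> PSSMProfile:
    """Parse a ``psiblast -out_ascii_pssm`` file into a per-residue profile.

    Score rows start with a position index and a residue letter followed by 20
    integer log-odds columns (the trailing 20 weighted-percentage columns and
    the two information columns, if present, are ignored).  Header and footer
    lines are skipped.  Columns are reordered from the file's residue order
    (the PSI-BLAST default ``ARNDCQEGHILKMFPSTWYV`` when no column-header line
    is present) to the package's alphabetical convention so PSSM features
    align with the other 20-dimensional descriptors.
    """
    path = Path(path)
    rows: list[list[float]] = []
    column_order = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST default
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) >= 20 and all(tok in AA_INDEX for tok in parts[:20]):
                column_order = "".join(parts[:20])  # column-header line
                continue
            if len(parts) < 2 or not parts[0].isdigit() or parts[1] not in AA_INDEX:
                continue  # header/footer/blank
            values = []
            for tok in parts[2:]:
                try:
                    values.append(float(tok))
                except ValueError:
                    break
            if len(values) < 20:
                raise FormatError(
                    f"{path}:{lineno}: PSSM row has {len(values)} score columns, expected 20"
                )
            rows.append(values[:20])
    if not rows:
        raise FormatError(f"{path}: no PSSM score rows found")
    if len(set(column_order)) != 20:
        raise FormatError(f"{path}: malformed residue column header {column_order!r}")
    order = [column_order.index(aa) for aa in sorted(AA_INDEX)]
    return PSSMProfile(chain_id=chain_id or path.stem, rows=np.array(rows)[:, order])


def associate_pssm(chain: ProteinChain, profile: PSSMProfile) -> PSSMProfile:
    """Validate that a profile matches a chain's length before use."""
    if len(profile) != len(chain):
        raise ValueError(
            f"PSSM for chain {chain.id!r} has {len(profile)} rows but the chain "
            f"has {len(chain)} residues"
        )
    return profile
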