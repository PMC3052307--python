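"""Reading and writing of sequences, site annotations and per-residue profiles.

Every candidate site is a lysine (K).  Coordinates are 1-based inclusive
(UniProt convention); a window of half-width ``n`` covers offsets −n…+n
around the site, with positions falling outside the protein represented by
the terminal marker ``-``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

#: Fixed amino-acid order used for every vector/matrix column in the package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Residues accepted in sequences; X marks an unknown residue.
VALID_RESIDUES = frozenset(AA_ORDER) | {"X"}

#: Marker for window positions beyond the protein termini.
TERMINAL = "-"

SS_SYMBOLS = frozenset("HEC")


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        for offset, ch in enumerate(self.sequence):
            if ch not in VALID_RESIDUES:
                raise FormatError(
                    f"protein {self.id!r}: illegal residue {ch!r} at offset {offset}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside protein {self.id!r} (length {self.length})"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class SiteAnnotation:
    """A labelled candidate lysine site on a protein."""

    protein_id: str
    position: int  # 1-based
    label: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.position < 1:
            raise ValueError(f"position must be ≥ 1, got {self.position}")


@dataclass(frozen=True)
class Fragment:
    """A (2n+1)-residue window centred on a candidate lysine.

    ``residues[i]`` is the protein residue at position ``center − n + i``,
    or the terminal marker when that position lies outside the protein.
    """

    protein_id: str
    center: int
    n: int
    residues: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.residues) != 2 * self.n + 1:
            raise ValueError(
                f"window length {len(self.residues)} != 2n+1 = {2 * self.n + 1}"
            )
        if self.residues[self.n] != "K":
            raise ValueError("window centre must be a lysine (K)")

    @property
    def has_unknown(self) -> bool:
        """True when the window contains an unknown residue (X)."""
        return "X" in self.residues

    def offsets(self) -> range:
        return range(-self.n, self.n + 1)


@dataclass
class ResidueProfiles:
    """Optional per-residue profiles attached to a protein.

    pssm : L×20 position-specific scores, columns in :data:`AA_ORDER` order.
    asa  : per-residue percent solvent accessibility in [0, 100].
    ss   : per-residue secondary-structure state over {H, E, C}.
    """

    pssm: Optional[np.ndarray] = None
    asa: Optional[np.ndarray] = None
    ss: Optional[str] = None

    def validate_against(self, protein: ProteinRecord) -> None:
        L = protein.length
        if self.pssm is not None and self.pssm.shape != (L, 20):
            raise FormatError(
                f"PSSM shape {self.pssm.shape} does not match protein "
                f"{protein.id!r} length {L}"
            )
        if self.asa is not None and len(self.asa) != L:
            raise FormatError(
                f"ASA length {len(self.asa)} does not match protein "
                f"{protein.id!r} length {L}"
            )
        if self.ss is not None and len(self.ss) != L:
            raise FormatError(
                f"SS length {len(self.ss)} does not match protein "
                f"{protein.id!r} length {L}"
            )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects, order preserved."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# Site annotations (TSV: protein_id <TAB> position <TAB> label)

def read_site_annotations(
    path: str | Path, proteins: Sequence[ProteinRecord]
) -> list[SiteAnnotation]:
    """Read the site TSV, cross-checking every row against its protein."""
    by_id = {p.id: p for p in proteins}
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, pos_s, label = parts
            try:
                pos = int(pos_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if pid not in by_id:
                raise FormatError(f"{path}:{lineno}: unknown protein id {pid!r}")
            protein = by_id[pid]
            if not 1 <= pos <= protein.length:
                raise FormatError(
                    f"{path}:{lineno}: position {pos} outside protein "
                    f"{pid!r} (length {protein.length})"
                )
            if protein.residue(pos) != "K":
                raise FormatError(
                    f"{path}:{lineno}: residue at {pid}:{pos} is "
                    f"{protein.residue(pos)!r}, expected K"
                )
            sites.append(SiteAnnotation(protein_id=pid, position=pos, label=label))
    return sites


def write_site_annotations(sites: Iterable[SiteAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def enumerate_negative_sites(
    protein: ProteinRecord, positives: Iterable[SiteAnnotation]
) -> list[SiteAnnotation]:
    """Every lysine of the protein not annotated positive, labelled negative."""
    pos_positions = set()
    for p in positives:
        if p.protein_id != protein.id:
            raise ValueError(f"positive site on {p.protein_id!r} passed with {protein.id!r}")
        if protein.residue(p.position) != "K":
            raise ValueError(f"positive at {protein.id}:{p.position} is not K")
        pos_positions.add(p.position)
    return [
        SiteAnnotation(protein_id=protein.id, position=i + 1, label="negative")
        for i, ch in enumerate(protein.sequence)
        if ch == "K" and (i + 1) not in pos_positions
    ]


def extract_fragment(
    protein: ProteinRecord, position: int, n: int = 20, label: Optional[str] = None
) -> Fragment:
    """Window of half-width ``n`` centred on the lysine at ``position``."""
    if protein.residue(position) != "K":
        raise ValueError(
            f"residue at {protein.id}:{position} is {protein.residue(position)!r}, "
            "fragments are centred on K"
        )
    chars = []
    for off in range(-n, n + 1):
        p = position + off
        chars.append(protein.sequence[p - 1] if 1 <= p <= protein.length else TERMINAL)
    return Fragment(
        protein_id=protein.id, center=position, n=n, residues="".join(chars), label=label
    )


# ---------------------------------------------------------------------------
# PSSM profiles

def read_pssm_profile(
    path: str | Path,
    dialect: str = "tsv",
    protein: Optional[ProteinRecord] = None,
) -> np.ndarray:
    """Read an L×20 PSSM with columns in :data:`AA_ORDER` order.

    dialect "tsv": one whitespace-separated row of 20 scores per residue.
    dialect "psiblast_ascii": the PSI-BLAST ASCII matrix dump; the first 20
    score columns are used and reordered to :data:`AA_ORDER` if needed.
    """
    if dialect == "tsv":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                vals = line.split()
                if len(vals) != 20:
                    raise FormatError(f"{path}:{lineno}: expected 20 columns, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric PSSM value")
        mat = np.asarray(rows, dtype=float)
    elif dialect == "psiblast_ascii":
        mat = _read_psiblast_ascii(path)
    else:
        raise ValueError(f"unknown PSSM dialect {dialect!r}")
    if mat.ndim != 2 or mat.shape[0] == 0:
        raise FormatError(f"{path}: empty PSSM")
    if protein is not None and mat.shape[0] != protein.length:
        raise FormatError(
            f"{path}: {mat.shape[0]} PSSM rows for protein {protein.id!r} "
            f"of length {protein.length}"
        )
    return mat


def _read_psiblast_ascii(path: str | Path) -> np.ndarray:
    """Parse the 44-column PSI-BLAST ASCII PSSM; keep the 20 score columns."""
    with open(path) as fh:
        lines = fh.readlines()
    header_order = None
    rows = []
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if header_order is None:
            # column-letter header: ≥20 single amino-acid letters
            if len(parts) >= 20 and all(len(p) == 1 and p in AA_INDEX for p in parts[:20]):
                header_order = parts[:20]
            continue
        if not parts:
            if rows:
                break  # blank line before footer statistics
            continue
        if not parts[0].isdigit():
            break
        if len(parts) < 22:
            raise FormatError(f"{path}:{lineno}: truncated PSSM row")
        try:
            scores = [float(v) for v in parts[2:22]]
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric PSSM score")
        rows.append(scores)
    if header_order is None or not rows:
        raise FormatError(f"{path}: not a PSI-BLAST ASCII PSSM")
    mat = np.asarray(rows, dtype=float)
    perm = [header_order.index(aa) for aa in AA_ORDER]
    return mat[:, perm]


def write_pssm_profile(matrix: np.ndarray, path: str | Path) -> None:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[1] != 20:
        raise ValueError(f"PSSM must be L×20, got {matrix.shape}")
    with open(path, "w") as fh:
        for row in matrix:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# ASA / secondary-structure profiles

def read_asa_profile(
    path: str | Path, protein: Optional[ProteinRecord] = None
) -> np.ndarray:
    """Per-residue percent accessibility, one or more values per line."""
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            for tok in line.split():
                try:
                    v = float(tok)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric ASA value {tok!r}")
                if not np.isfinite(v) or not 0.0 <= v <= 100.0:
                    raise FormatError(f"{path}:{lineno}: ASA {v} outside [0, 100]")
                values.append(v)
    if not values:
        raise FormatError(f"{path}: empty ASA profile")
    asa = np.asarray(values, dtype=float)
    if protein is not None and len(asa) != protein.length:
        raise FormatError(
            f"{path}: {len(asa)} ASA values for protein {protein.id!r} "
            f"of length {protein.length}"
        )
    return asa


def write_asa_profile(asa: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for v in np.asarray(asa, dtype=float):
            fh.write(f"{float(v)!r}\n")


def read_ss_profile(
    path: str | Path, protein: Optional[ProteinRecord] = None
) -> str:
    """Secondary-structure string over {H,E,C}.

    Accepts a bare string (one line, or one symbol per line) or the PSIPRED
    .ss2 layout, where the state letter is the third column.
    """
    chars = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) >= 3 and parts[0].isdigit():  # .ss2 row
                sym = parts[2]
            else:
                sym = stripped
            for ch in sym:
                if ch not in SS_SYMBOLS:
                    raise FormatError(
                        f"{path}:{lineno}: illegal secondary-structure symbol {ch!r}"
                    )
                chars.append(ch)
    if not chars:
        raise FormatError(f"{path}: empty secondary-structure profile")
    ss = "".join(chars)
    if protein is not None and len(ss) != protein.length:
        raise FormatError(
            f"{path}: {len(ss)} SS states for protein {protein.id!r} "
            f"of length {protein.length}"
        )
    return ss


def write_ss_profile(ss: str, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(ss + "\n")
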