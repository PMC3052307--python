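"""Feature encoders for candidate lysine windows.

Six block encoders are provided, concatenated in the fixed order
AAC, AAPC, BLOSUM, PSSM400, ASA, SS:

AAC      20    amino-acid composition of the window
AAPC     400   adjacent amino-acid-pair composition
BLOSUM   21·(2n+1)  per-position min–max-normalised BLOSUM62 row + terminal flag
PSSM400  400   window PSSM rows pooled by residue type into a 20×20 map,
               scaled by the window length and squashed with the logistic
PSSM is the evolutionary-information block; ASA and SS carry the predicted
structural context:
ASA      2n+1  percent solvent accessibility / 100 per position
SS       3·(2n+1)  one-hot secondary structure (H=100, E=010, C=001)

Unknown residues (X) contribute nothing to composition counts or to the
PSSM pooling; a terminal-marker position is encoded as the dedicated 21st
BLOSUM channel and as zeros elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import (
    AA_INDEX,
    AA_ORDER,
    TERMINAL,
    Fragment,
    ProteinRecord,
    ResidueProfiles,
)

BLOCK_ORDER = ("AAC", "AAPC", "BLOSUM", "PSSM400", "ASA", "SS")

_SS_INDEX = {"H": 0, "E": 1, "C": 2}


def _normalized_blosum62() -> np.ndarray:
    """20×20 BLOSUM62 in AA_ORDER, min–max scaled to [0, 1] globally."""
    mat = substitution_matrices.load("BLOSUM62")
    sub = np.array(
        [[mat[a, b] for b in AA_ORDER] for a in AA_ORDER], dtype=float
    )
    lo, hi = sub.min(), sub.max()
    return (sub - lo) / (hi - lo)


_BLOSUM_NORM = _normalized_blosum62()


@dataclass(frozen=True)
class EncoderConfig:
    """Which blocks to compute and at what window geometry.

    n : half-window; the fragment covers offsets −n…+n (default 20, 41-mer).
    blocks : subset of :data:`BLOCK_ORDER`; output order is always canonical.
    m : PSSM pooling window length (odd); defaults to the fragment length 2n+1.
    whole_protein_composition : compute AAC/AAPC over the full protein
        instead of the window.
    """

    n: int = 20
    blocks: Tuple[str, ...] = ("AAC", "PSSM400")
    m: Optional[int] = None
    whole_protein_composition: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("half-window n must be ≥ 1")
        unknown = set(self.blocks) - set(BLOCK_ORDER)
        if unknown:
            raise ValueError(f"unknown blocks: {sorted(unknown)}")
        if not self.blocks:
            raise ValueError("at least one block must be enabled")
        if self.m is not None and self.m % 2 == 0:
            raise ValueError("PSSM window length m must be odd")

    @property
    def pssm_window(self) -> int:
        return self.m if self.m is not None else 2 * self.n + 1

    def ordered_blocks(self) -> Tuple[str, ...]:
        return tuple(b for b in BLOCK_ORDER if b in self.blocks)

    def block_length(self, block: str) -> int:
        w = 2 * self.n + 1
        return {
            "AAC": 20,
            "AAPC": 400,
            "BLOSUM": 21 * w,
            "PSSM400": 400,
            "ASA": w,
            "SS": 3 * w,
        }[block]


@dataclass(frozen=True)
class FeatureVector:
    """A block-structured numeric feature vector with provenance."""

    values: np.ndarray
    blocks: Tuple[Tuple[str, int, int], ...]  # (name, offset, length)
    provenance: str = ""

    def __post_init__(self) -> None:
        if sum(length for _, _, length in self.blocks) != len(self.values):
            raise ValueError("block lengths do not sum to vector length")

    def block(self, name: str) -> np.ndarray:
        for bname, offset, length in self.blocks:
            if bname == name:
                return self.values[offset : offset + length]
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Block encoders

def _effective(residues: str) -> str:
    return "".join(ch for ch in residues if ch in AA_INDEX)


def encode_aac(residues: str) -> np.ndarray:
    """Amino-acid composition: count(a) / effective length.

    Terminal markers and X are excluded from both counts and denominator.
    """
    eff = _effective(residues)
    if not eff:
        raise ValueError("no effective residues (all markers/unknown)")
    vec = np.zeros(20)
    for ch in eff:
        vec[AA_INDEX[ch]] += 1.0
    return vec / len(eff)


def encode_aapc(residues: str) -> np.ndarray:
    """Adjacent-pair composition: count(ab) / effective length.

    Pairs spanning a terminal marker or X are skipped; the denominator is
    the effective residue count (so the vector sums to (pairs)/(L_eff)).
    """
    eff_len = len(_effective(residues))
    if eff_len < 2:
        raise ValueError("pair composition needs ≥ 2 effective residues")
    vec = np.zeros(400)
    for a, b in zip(residues, residues[1:]):
        if a in AA_INDEX and b in AA_INDEX:
            vec[AA_INDEX[a] * 20 + AA_INDEX[b]] += 1.0
    return vec / eff_len


def encode_blosum(fragment: Fragment) -> np.ndarray:
    """Per-position 21-channel encoding from the normalised BLOSUM62 rows.

    Channels 0–19 are the residue's BLOSUM62 row scaled to [0, 1]; channel
    20 is the terminal flag, set (with the row zeroed) for positions beyond
    the protein ends.  Unknown residues get an all-zero row with flag 0.
    """
    w = 2 * fragment.n + 1
    out = np.zeros((w, 21))
    for i, ch in enumerate(fragment.residues):
        if ch == TERMINAL:
            out[i, 20] = 1.0
        elif ch in AA_INDEX:
            out[i, :20] = _BLOSUM_NORM[AA_INDEX[ch]]
    return out.ravel()


def encode_pssm400(
    pssm: np.ndarray, sequence: str, center: int, m: int
) -> np.ndarray:
    """Pool the m window rows of a PSSM by residue type into 400 features.

    The m rows centred on the 1-based ``center`` are taken (rows outside the
    protein are skipped); rows sharing the same sequence residue type t are
    summed into row t of a 20×20 matrix, every element is divided by m, and
    the result is squashed elementwise with the logistic 1/(1+e^−x) and
    flattened row-major.  Rows whose residue is X contribute to no type.
    """
    pssm = np.asarray(pssm, dtype=float)
    L = pssm.shape[0]
    if pssm.shape != (L, 20) or L == 0:
        raise ValueError(f"PSSM must be L×20, got {pssm.shape}")
    if len(sequence) != L:
        raise ValueError("sequence length does not match PSSM row count")
    if not 1 <= center <= L:
        raise ValueError(f"center {center} outside profile of length {L}")
    if m < 1 or m % 2 == 0:
        raise ValueError("window length m must be odd and ≥ 1")
    half = m // 2
    pooled = np.zeros((20, 20))
    for pos in range(center - half, center + half + 1):
        if 1 <= pos <= L:
            ch = sequence[pos - 1]
            if ch in AA_INDEX:
                pooled[AA_INDEX[ch]] += pssm[pos - 1]
    pooled /= m
    with np.errstate(over="ignore"):
        squashed = 1.0 / (1.0 + np.exp(-pooled))
    return squashed.ravel()


def encode_asa(asa: np.ndarray, center: int, n: int) -> np.ndarray:
    """Window of percent accessibilities scaled to [0, 1]; out-of-range → 0."""
    asa = np.asarray(asa, dtype=float)
    L = len(asa)
    out = np.zeros(2 * n + 1)
    for i, pos in enumerate(range(center - n, center + n + 1)):
        if 1 <= pos <= L:
            out[i] = asa[pos - 1] / 100.0
    return out


def encode_ss(ss: str, center: int, n: int) -> np.ndarray:
    """Per-position one-hot secondary structure (H=100, E=010, C=001)."""
    L = len(ss)
    out = np.zeros((2 * n + 1, 3))
    for i, pos in enumerate(range(center - n, center + n + 1)):
        if 1 <= pos <= L:
            out[i, _SS_INDEX[ss[pos - 1]]] = 1.0
    return out.ravel()


# ---------------------------------------------------------------------------
# Assembly

def assemble(
    fragment: Fragment,
    profiles: Optional[ResidueProfiles],
    config: EncoderConfig,
    protein: Optional[ProteinRecord] = None,
) -> FeatureVector:
    """Concatenate the enabled blocks for one fragment, canonical order."""
    parts: list[np.ndarray] = []
    table: list[Tuple[str, int, int]] = []
    offset = 0
    for block in config.ordered_blocks():
        if block == "AAC":
            src = _composition_source(fragment, protein, config)
            vec = encode_aac(src)
        elif block == "AAPC":
            src = _composition_source(fragment, protein, config)
            vec = encode_aapc(src)
        elif block == "BLOSUM":
            vec = encode_blosum(fragment)
        elif block == "PSSM400":
            if profiles is None or profiles.pssm is None:
                raise ValueError(
                    f"PSSM400 block enabled but no PSSM profile for {fragment.protein_id!r}"
                )
            if protein is None:
                raise ValueError("PSSM400 block requires the protein record")
            vec = encode_pssm400(
                profiles.pssm, protein.sequence, fragment.center, config.pssm_window
            )
        elif block == "ASA":
            if profiles is None or profiles.asa is None:
                raise ValueError(
                    f"ASA block enabled but no ASA profile for {fragment.protein_id!r}"
                )
            vec = encode_asa(profiles.asa, fragment.center, config.n)
        elif block == "SS":
            if profiles is None or profiles.ss is None:
                raise ValueError(
                    f"SS block enabled but no SS profile for {fragment.protein_id!r}"
                )
            vec = encode_ss(profiles.ss, fragment.center, config.n)
        parts.append(vec)
        table.append((block, offset, len(vec)))
        offset += len(vec)
    return FeatureVector(
        values=np.concatenate(parts),
        blocks=tuple(table),
        provenance=f"{fragment.protein_id}:{fragment.center}",
    )


def _composition_source(
    fragment: Fragment, protein: Optional[ProteinRecord], config: EncoderConfig
) -> str:
    if config.whole_protein_composition:
        if protein is None:
            raise ValueError("whole-protein composition requires the protein record")
        return protein.sequence
    return fragment.residues


def feature_names(config: EncoderConfig) -> list[str]:
    """Block-qualified column names matching :func:`assemble` output order."""
    names: list[str] = []
    w = 2 * config.n + 1
    offsets = [o for o in range(-config.n, config.n + 1)]
    for block in config.ordered_blocks():
        if block == "AAC":
            names += [f"AAC:{a}" for a in AA_ORDER]
        elif block == "AAPC":
            names += [f"AAPC:{a}{b}" for a in AA_ORDER for b in AA_ORDER]
        elif block == "BLOSUM":
            for o in offsets:
                names += [f"BLOSUM:{o:+d}:{a}" for a in AA_ORDER]
                names.append(f"BLOSUM:{o:+d}:term")
        elif block == "PSSM400":
            names += [f"PSSM400:{a}:{b}" for a in AA_ORDER for b in AA_ORDER]
        elif block == "ASA":
            names += [f"ASA:{o:+d}" for o in offsets]
        elif block == "SS":
            for o in offsets:
                names += [f"SS:{o:+d}:{s}" for s in "HEC"]
    return names


def build_feature_matrix(
    proteins: Sequence[ProteinRecord],
    sites,
    profiles: Optional[Dict[str, ResidueProfiles]],
    config: EncoderConfig,
):
    """Encode every annotated site into a dense matrix.

    Returns ``(X, labels, names, provenance)`` where X is (n_sites, d),
    labels is a list of site labels, and provenance lists "protein:pos".
    """
    from .seqio import extract_fragment

    by_id = {p.id: p for p in proteins}
    rows, labels, prov = [], [], []
    names = feature_names(config)
    for site in sites:
        protein = by_id[site.protein_id]
        frag = extract_fragment(protein, site.position, config.n, site.label)
        prof = profiles.get(site.protein_id) if profiles else None
        fv = assemble(frag, prof, config, protein)
        rows.append(fv.values)
        labels.append(site.label)
        prov.append(fv.provenance)
    if not rows:
        raise ValueError("no sites to encode")
    X = np.vstack(rows)
    assert X.shape[1] == len(names)
    return X, labels, names, prov
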