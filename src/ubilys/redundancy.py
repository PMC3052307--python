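"""Homology-aware redundancy reduction of training fragments.

Two proteins sharing more than 30% local-alignment identity are treated as
homologs; among homologs, window fragments with identical residue strings
are collapsed to a single representative (first occurrence wins).  The
positive and negative classes are reduced independently, so reduction never
mixes labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Sequence, Tuple

from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import Fragment, ProteinRecord


@dataclass(frozen=True)
class IdentityResult:
    """Fractional identity of the best local alignment of two sequences."""

    protein_a: str
    protein_b: str
    identity: float
    aligned_length: int


def _aligner() -> Align.PairwiseAligner:
    # BL2SEQ protein defaults: local, BLOSUM62, gap open 11, extend 1
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(
    seq_a: str | ProteinRecord, seq_b: str | ProteinRecord
) -> IdentityResult:
    """Identity = matches / aligned columns of the best local alignment.

    Sequences that produce no positive-scoring local alignment are treated
    as 0% identical.
    """
    id_a, s_a = _unpack(seq_a, "a")
    id_b, s_b = _unpack(seq_b, "b")
    if not s_a or not s_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    aligner = _aligner()
    try:
        alignments = aligner.align(s_a, s_b)
        best = alignments[0] if len(alignments) else None
    except (ValueError, OverflowError, IndexError):
        best = None
    if best is None or best.score <= 0:
        return IdentityResult(id_a, id_b, 0.0, 0)
    counts = best.counts()  # gaps, identities, mismatches
    aligned_length = counts.gaps + counts.identities + counts.mismatches
    identity = counts.identities / aligned_length if aligned_length else 0.0
    return IdentityResult(id_a, id_b, identity, aligned_length)


def _unpack(seq, default_id: str) -> Tuple[str, str]:
    if isinstance(seq, ProteinRecord):
        return seq.id, seq.sequence
    return default_id, str(seq)


def reduce_fragments(
    fragments: Sequence[Fragment],
    proteins: Sequence[ProteinRecord],
    threshold: float = 0.30,
    log: list | None = None,
) -> list[Fragment]:
    """Collapse duplicate fragments between homologous proteins.

    For every protein pair with full-sequence identity > ``threshold``, any
    pair of their fragments (same label class) with identical residue
    strings keeps only the first occurrence in input order.  Fragments of
    the same protein are never deduplicated against each other: distinct
    sites on one protein are distinct observations.
    """
    if not fragments:
        return []
    lengths = {f.n for f in fragments}
    if len(lengths) > 1:
        raise ValueError(f"fragments mix window half-widths: {sorted(lengths)}")
    by_id = {p.id: p for p in proteins}
    for f in fragments:
        if f.protein_id not in by_id:
            raise ValueError(f"fragment references unknown protein {f.protein_id!r}")

    identity_cache: Dict[Tuple[str, str], float] = {}

    def homologous(a: str, b: str) -> bool:
        if a == b:
            return False
        key = (a, b) if a <= b else (b, a)
        if key not in identity_cache:
            identity_cache[key] = pairwise_identity(by_id[key[0]], by_id[key[1]]).identity
        return identity_cache[key] > threshold

    kept: list[Fragment] = []
    # seen[(label, residues)] -> protein ids of kept fragments with that string
    seen: Dict[Tuple[str, str], list[str]] = {}
    for frag in fragments:
        key = (frag.label or "", frag.residues)
        duplicate_of = None
        for prior_pid in seen.get(key, ()):
            if homologous(frag.protein_id, prior_pid):
                duplicate_of = prior_pid
                break
        if duplicate_of is not None:
            if log is not None:
                log.append(
                    f"dropped {frag.protein_id}:{frag.center} "
                    f"(duplicate of homolog {duplicate_of})"
                )
            continue
        kept.append(frag)
        seen.setdefault(key, []).append(frag.protein_id)
    return kept
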