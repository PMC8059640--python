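"""Helix splitting, center-residue tethering, and full-length alignment.

Corresponding transmembrane helices of target and template are aligned by
anchoring ("tethering") their X.50 center residues opposite each other and
pairing outward by equal offset; no gaps are ever introduced inside a helix.
Loops and termini are joined by a deterministic centered-gap rule so the
assembled alignment is ready for downstream editing and model building.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .registry import N_HELICES, GPCRSequence, RegistryError


@dataclass(frozen=True)
class TetheredHelixAlignment:
    """Gapless pairing of one target/template helix pair around X.50.

    ``pairs`` holds absolute 1-based (target_index, template_index) tuples,
    strictly increasing with unit steps in both coordinates.  Overhangs count
    the unpaired positions of each sequence at the two helix ends.
    """

    helix_index: int
    pairs: tuple
    target_left_overhang: int
    target_right_overhang: int
    template_left_overhang: int
    template_right_overhang: int

    @property
    def n_paired(self) -> int:
        return len(self.pairs)

    @property
    def target_overhang(self) -> int:
        return self.target_left_overhang + self.target_right_overhang

    @property
    def template_overhang(self) -> int:
        return self.template_left_overhang + self.template_right_overhang

    @property
    def target_len(self) -> int:
        return self.n_paired + self.target_overhang

    @property
    def template_len(self) -> int:
        return self.n_paired + self.template_overhang


def split_tm(seq: GPCRSequence) -> list:
    """Return the seven annotated helices as (helix_index, start, end,
    subsequence) with absolute 1-based inclusive ranges."""
    out = []
    for k in range(1, N_HELICES + 1):
        s, e, _ = seq.tm.span(k)
        out.append((k, s, e, seq.sequence[s - 1:e]))
    return out


def tether_helices(
    helix_index: int, target_span: tuple, template_span: tuple
) -> TetheredHelixAlignment:
    """Tether two helices at their center residues.

    Spans are absolute (start, end, center) triples.  Positions at equal
    offset from the center pair up; the pair count is
    min(left arms) + min(right arms) + 1 and residues beyond the shorter arm
    on either side are overhangs.
    """
    ts, te, tc = target_span
    ps, pe, pc = template_span
    left = min(tc - ts, pc - ps)
    right = min(te - tc, pe - pc)
    pairs = tuple(
        (tc + off, pc + off_p)
        for off, off_p in zip(range(-left, right + 1), range(-left, right + 1))
    )
    return TetheredHelixAlignment(
        helix_index=helix_index,
        pairs=pairs,
        target_left_overhang=(tc - ts) - left,
        target_right_overhang=(te - tc) - right,
        template_left_overhang=(pc - ps) - left,
        template_right_overhang=(pe - pc) - right,
    )


def tether_all(target: GPCRSequence, template: GPCRSequence) -> list:
    """Tether all seven helix pairs, in order 1..7."""
    return [
        tether_helices(k, target.tm.span(k), template.tm.span(k))
        for k in range(1, N_HELICES + 1)
    ]


# ---------------------------------------------------------------------------
# Full-length alignment assembly
# ---------------------------------------------------------------------------

GAP = "-"


@dataclass(frozen=True)
class FullAlignment:
    """A two-row gapped alignment with per-column region annotations.

    Annotations are 'TM1'..'TM7' for helix columns (tethered pairs and
    gapped helix overhangs), 'loop' for inter-helix segments, and 'terminus'
    for the N- and C-terminal segments.
    """

    target_id: str
    template_id: str
    target_row: str
    template_row: str
    annotations: tuple

    def __post_init__(self) -> None:
        if not (len(self.target_row) == len(self.template_row)
                == len(self.annotations)):
            raise RegistryError("alignment rows/annotations length mismatch")

    def __len__(self) -> int:
        return len(self.target_row)

    def degapped(self) -> tuple:
        return (self.target_row.replace(GAP, ""),
                self.template_row.replace(GAP, ""))

    def match_line(self) -> str:
        return "".join(
            "|" if a == b and a != GAP else " "
            for a, b in zip(self.target_row, self.template_row)
        )

    def to_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            for name, row in ((self.target_id, self.target_row),
                              (self.template_id, self.template_row)):
                fh.write(f">{name}\n")
                for i in range(0, len(row), 60):
                    fh.write(row[i:i + 60] + "\n")

    def to_text_block(self, width: int = 60) -> str:
        """3-line annotated blocks: target row, match line, template row."""
        match = self.match_line()
        chunks = []
        for i in range(0, len(self), width):
            chunks.append(
                f"{self.target_row[i:i + width]}\n"
                f"{match[i:i + width]}\n"
                f"{self.template_row[i:i + width]}\n"
            )
        return "\n".join(chunks)


def read_alignment_fasta(path: Union[str, Path]) -> tuple:
    """Read a 2-record aligned FASTA back as ((id, row), (id, row))."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise RegistryError(f"{path}: expected 2 aligned records")
    return tuple((r.id, str(r.seq)) for r in records)


def _center_gapped(a: str, b: str) -> tuple:
    """Align two unequal segments by centering a gap block in the shorter.

    The first ceil(m/2) residues of the shorter segment stay left-anchored,
    the rest right-anchored, with the gap block between; equal lengths give a
    gap-free column block.
    """
    if len(a) == len(b):
        return a, b
    short, long_, short_is_a = (a, b, True) if len(a) < len(b) else (b, a, False)
    n_gap = len(long_) - len(short)
    first = (len(short) + 1) // 2
    padded = short[:first] + GAP * n_gap + short[first:]
    return (padded, long_) if short_is_a else (long_, padded)


def assemble_full_alignment(
    target: GPCRSequence,
    template: GPCRSequence,
    helix_alignments: Optional[Sequence[TetheredHelixAlignment]] = None,
) -> FullAlignment:
    """Assemble the complete target-template alignment.

    Helix blocks reproduce the tethered alignments with overhangs gapped
    against the partner; loops and termini use the centered-gap rule.
    Stripping gaps from either row recovers the input sequence exactly.
    """
    if helix_alignments is None:
        helix_alignments = tether_all(target, template)
    if len(helix_alignments) != N_HELICES:
        raise RegistryError("need exactly 7 helix alignments")

    t_seq, p_seq = target.sequence, template.sequence
    t_row, p_row, notes = [], [], []

    def add(tr: str, pr: str, tag: str) -> None:
        t_row.append(tr)
        p_row.append(pr)
        notes.extend([tag] * len(tr))

    t_pos, p_pos = 1, 1  # next unconsumed 1-based position in each sequence
    for k in range(1, N_HELICES + 1):
        ha = helix_alignments[k - 1]
        ts, te, _ = target.tm.span(k)
        ps, pe, _ = template.tm.span(k)
        # loop/terminus before this helix
        seg_t = t_seq[t_pos - 1:ts - 1]
        seg_p = p_seq[p_pos - 1:ps - 1]
        a, b = _center_gapped(seg_t, seg_p)
        add(a, b, "terminus" if k == 1 else "loop")
        # helix block: left overhangs, paired core, right overhangs
        tlo, plo = ha.target_left_overhang, ha.template_left_overhang
        tro, pro = ha.target_right_overhang, ha.template_right_overhang
        tag = f"TM{k}"
        if tlo:
            add(t_seq[ts - 1:ts - 1 + tlo], GAP * tlo, tag)
        if plo:
            add(GAP * plo, p_seq[ps - 1:ps - 1 + plo], tag)
        core_t = t_seq[ts - 1 + tlo:te - tro]
        core_p = p_seq[ps - 1 + plo:pe - pro]
        if len(core_t) != ha.n_paired or len(core_p) != ha.n_paired:
            raise RegistryError(
                f"TM{k}: helix alignment inconsistent with TM spans"
            )
        add(core_t, core_p, tag)
        if tro:
            add(t_seq[te - tro:te], GAP * tro, tag)
        if pro:
            add(GAP * pro, p_seq[pe - pro:pe], tag)
        t_pos, p_pos = te + 1, pe + 1
    # C-terminus
    a, b = _center_gapped(t_seq[t_pos - 1:], p_seq[p_pos - 1:])
    add(a, b, "terminus")

    return FullAlignment(
        target_id=target.id,
        template_id=template.id,
        target_row="".join(t_row),
        template_row="".join(p_row),
        annotations=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Sequence identity
# ---------------------------------------------------------------------------

def _make_global_aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def identity_global(a: str, b: str) -> float:
    """Percent identity over aligned (non-gap) columns of a global
    Needleman-Wunsch alignment (BLOSUM62, affine gaps open 11 / extend 1).

    Letters outside the BLOSUM62 alphabet are mapped to X for alignment
    purposes and never count as identical.
    """
    if not a or not b:
        raise RegistryError("identity_global: empty sequence")
    alphabet = "ARNDCQEGHILKMFPSTWYVBZX*"
    a_clean = "".join(c if c in alphabet else "X" for c in a.upper())
    b_clean = "".join(c if c in alphabet else "X" for c in b.upper())
    aligner = _make_global_aligner()
    aln = aligner.align(a_clean, b_clean)[0]
    matches = 0
    aligned_cols = 0
    for (ta, tb), (pa, pb) in zip(*aln.aligned):
        aligned_cols += tb - ta
        for i, j in zip(range(ta, tb), range(pa, pb)):
            if a_clean[i] == b_clean[j] and a_clean[i] != "X":
                matches += 1
    if aligned_cols == 0:
        return 0.0
    return 100.0 * matches / aligned_cols


def identity_per_tm(
    target: GPCRSequence,
    template: GPCRSequence,
    helix_alignments: Optional[Sequence[TetheredHelixAlignment]] = None,
) -> list:
    """Percent identity over the tethered pairs of each helix, in order 1..7."""
    if helix_alignments is None:
        helix_alignments = tether_all(target, template)
    out = []
    for ha in helix_alignments:
        matches = sum(
            1 for ti, pi in ha.pairs
            if target.residue(ti) == template.residue(pi)
        )
        out.append(100.0 * matches / ha.n_paired)
    return out
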