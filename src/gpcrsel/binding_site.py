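"""Orthosteric-hotspot extraction and binding-site residue similarity (BRS).

The 24 canonical class A orthosteric-pocket positions are resolved on each
sequence through Ballesteros-Weinstein numbering and the aligned residue
pairs are scored with a substitution matrix (ideally one derived from GPCR
transmembrane regions, e.g. GPCRtm supplied as a matrix file); the sum over
scored pairs is S_b, the BRS score.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .registry import (
    DEFAULT_HOTSPOT_LABELS,
    GPCRSequence,
    RegistryError,
    SubstitutionMatrix,
    bw_to_index,
    parse_bw_label,
)


def validate_hotspot_labels(labels: Sequence[str]) -> tuple:
    """Check uniqueness and parseability of a hotspot label set."""
    if len(set(labels)) != len(labels):
        raise RegistryError("hotspot labels must be unique")
    for lab in labels:
        parse_bw_label(lab)
    return tuple(labels)


def extract_hotspots(
    seq: GPCRSequence, labels: Sequence[str] = DEFAULT_HOTSPOT_LABELS
) -> dict:
    """Resolve each label to its residue on ``seq`` (None when the computed
    index falls outside the sequence).

    Labels outside the annotated helix span but inside the sequence still
    resolve: 7.31 commonly precedes the TM7 annotation.
    """
    labels = validate_hotspot_labels(labels)
    out = {}
    for lab in labels:
        idx = bw_to_index(seq.tm, lab, seq_length=len(seq))
        out[lab] = None if idx is None else seq.residue(idx)
    return out


@dataclass(frozen=True)
class HotspotComparison:
    """Per-label residue pairs and scores plus their sum S_b.

    ``entries`` maps label -> (target residue or None, template residue or
    None, pair score or None); pairs with a missing side are excluded from
    the sum, and n_scored reports how many positions actually contributed.
    """

    entries: Mapping[str, tuple]
    s_b: float
    n_scored: int


def brs_score(
    target_hotspots: Mapping[str, Optional[str]],
    template_hotspots: Mapping[str, Optional[str]],
    matrix: SubstitutionMatrix,
) -> HotspotComparison:
    """Score hotspot correspondence between target and template.

    Both maps must cover the same labels.  S_b is integral when the matrix
    is; an int is returned in that case.
    """
    if set(target_hotspots) != set(template_hotspots):
        raise RegistryError("hotspot label sets differ between sequences")
    entries = {}
    total = 0.0
    n_scored = 0
    for lab in target_hotspots:
        a, b = target_hotspots[lab], template_hotspots[lab]
        if a is None or b is None:
            entries[lab] = (a, b, None)
            continue
        sc = matrix.score(a, b)
        entries[lab] = (a, b, sc)
        total += sc
        n_scored += 1
    if total == int(total):
        total = int(total)
    return HotspotComparison(entries=entries, s_b=total, n_scored=n_scored)
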