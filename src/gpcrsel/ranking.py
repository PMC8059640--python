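"""Template scoring and ranking.

Each surviving target-template pair receives
    S_t    = S_h + S_b + S_r                (total score, integer scale)
    S_rank = S_hn + S_bn + S_r              (ranking score, in [0, 3])
where S_h is the HC score over the seven helices, S_b the hotspot BRS score,
S_r the resolution score (1 for structures at <= 2.5 Angstrom, else 0), and
S_hn/S_bn are min-max normalizations of S_h/S_b over the candidate set being
ranked.  Search mode filters and deduplicates to one best PDB entry per
receptor; browse mode scores every entry unfiltered.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import alignment, binding_site, hydropathy
from .registry import (
    DEFAULT_HOTSPOT_LABELS,
    GPCRSequence,
    HydrophobicityScale,
    N_HELICES,
    RegistryError,
    SubstitutionMatrix,
    TemplateRecord,
    filter_templates,
)

logger = logging.getLogger("gpcrsel")

#: Resolution cutoff (Angstrom, inclusive) granting S_r = 1.
RESOLUTION_CUTOFF = 2.5


def resolution_score(resolution: Optional[float]) -> int:
    """1 iff a resolution is reported and is <= 2.5 Angstrom (inclusive)."""
    return int(resolution is not None and resolution <= RESOLUTION_CUTOFF)


def total_score(s_h: int, s_b: float, s_r: int) -> float:
    """Total score S_t = S_h + S_b + S_r."""
    if s_r not in (0, 1):
        raise RegistryError(f"s_r must be 0 or 1, got {s_r}")
    return s_h + s_b + s_r


@dataclass
class PairScore:
    """All scoring components for one target-template pair."""

    template: TemplateRecord
    helices: tuple  # 7 HelixCorrespondence
    hotspots: binding_site.HotspotComparison
    s_h: int
    s_b: float
    s_r: int
    s_t: float
    identity_global: float
    identity_tm: tuple  # 7 percents
    s_hn: Optional[float] = None
    s_bn: Optional[float] = None
    s_rank: Optional[float] = None

    @property
    def pdb_id(self) -> str:
        return self.template.pdb_id


def score_pair(
    query: GPCRSequence,
    template: TemplateRecord,
    scale: HydrophobicityScale,
    matrix: SubstitutionMatrix,
    window: int = hydropathy.DEFAULT_WINDOW,
    edge_mode: str = "extend",
    ssd_divisor: str = "paired",
    hotspot_labels: Sequence[str] = DEFAULT_HOTSPOT_LABELS,
) -> PairScore:
    """Compute every component score for one pair (normalization comes
    later, over the candidate set)."""
    tethered = alignment.tether_all(query, template.receptor)
    q_prof = hydropathy.profile_for_correspondence(
        query, scale, window=window, edge_mode=edge_mode
    )
    t_prof = hydropathy.profile_for_correspondence(
        template.receptor, scale, window=window, edge_mode=edge_mode
    )
    helices = tuple(
        hydropathy.helix_correspondence(ha, q_prof, t_prof, divisor=ssd_divisor)
        for ha in tethered
    )
    s_h = hydropathy.hc_score(helices)
    comp = binding_site.brs_score(
        binding_site.extract_hotspots(query, hotspot_labels),
        binding_site.extract_hotspots(template.receptor, hotspot_labels),
        matrix,
    )
    s_r = resolution_score(template.resolution)
    return PairScore(
        template=template,
        helices=helices,
        hotspots=comp,
        s_h=s_h,
        s_b=comp.s_b,
        s_r=s_r,
        s_t=total_score(s_h, comp.s_b, s_r),
        identity_global=alignment.identity_global(
            query.sequence, template.receptor.sequence
        ),
        identity_tm=tuple(
            alignment.identity_per_tm(query, template.receptor, tethered)
        ),
    )


def normalize_scores(pairs: Sequence[PairScore]) -> Sequence[PairScore]:
    """Min-max normalize S_h and S_b over the candidate set and set S_rank.

    When max = min the normalized value is 1.0 for every candidate ("all
    equally best"), which keeps S_rank's additive structure.
    """
    if not pairs:
        raise RegistryError("normalize_scores: empty candidate set")

    def minmax(values):
        lo, hi = min(values), max(values)
        if hi == lo:
            return [1.0] * len(values), lo, hi
        return [(v - lo) / (hi - lo) for v in values], lo, hi

    hn, h_lo, h_hi = minmax([p.s_h for p in pairs])
    bn, b_lo, b_hi = minmax([p.s_b for p in pairs])
    logger.info(
        "normalization set: n=%d, s_h range [%s, %s], s_b range [%s, %s]",
        len(pairs), h_lo, h_hi, b_lo, b_hi,
    )
    for p, h, b in zip(pairs, hn, bn):
        p.s_hn, p.s_bn = h, b
        p.s_rank = h + b + p.s_r
    return pairs


def _sort_key(p: PairScore) -> tuple:
    res = p.template.resolution
    return (
        -p.s_rank,
        -p.s_b,
        math.inf if res is None else res,
        p.pdb_id,
    )


@dataclass
class RankedResults:
    """Scored and ordered candidate table for one query."""

    query_id: str
    filters: dict
    pairs: list  # PairScore, ordered
    top_k: int = 3

    @property
    def top(self) -> list:
        return self.pairs[: self.top_k]

    @property
    def empty(self) -> bool:
        return not self.pairs


def dedupe_by_receptor(records: Sequence[TemplateRecord]) -> list:
    """Keep one best PDB entry per receptor: lowest resolution (absent
    last), then highest coverage, then lexicographic pdb_id."""
    best = {}
    for rec in records:
        key = rec.receptor.id
        cand = (
            math.inf if rec.resolution is None else rec.resolution,
            -rec.coverage,
            rec.pdb_id,
        )
        if key not in best or cand < best[key][0]:
            best[key] = (cand, rec)
    # preserve original order of survivors
    keep = {rec.pdb_id for _, rec in best.values()}
    return [rec for rec in records if rec.pdb_id in keep]


def rank_templates(
    query: GPCRSequence,
    registry: Sequence[TemplateRecord],
    state: Optional[str] = None,
    max_resolution: Optional[float] = None,
    min_coverage: Optional[float] = None,
    k: int = 3,
    dedupe: bool = True,
    scale: Optional[HydrophobicityScale] = None,
    matrix: Optional[SubstitutionMatrix] = None,
    **scoring_opts,
) -> RankedResults:
    """Search mode: filter, deduplicate per receptor, score, normalize over
    the survivors, and rank.

    Ordering is by S_rank descending with the deterministic tie-break chain
    (S_b descending, resolution ascending with absent last, pdb_id
    lexicographic).  An empty survivor set yields an empty RankedResults.
    """
    from .registry import load_matrix, load_scale

    scale = scale if scale is not None else load_scale()
    matrix = matrix if matrix is not None else load_matrix()
    survivors = filter_templates(
        registry, state=state, max_resolution=max_resolution,
        min_coverage=min_coverage,
    )
    logger.info(
        "filters (state=%s, max_resolution=%s, min_coverage=%s): "
        "%d of %d entries survive",
        state, max_resolution, min_coverage, len(survivors), len(registry),
    )
    if dedupe:
        survivors = dedupe_by_receptor(survivors)
        logger.info("per-receptor dedup: %d representatives", len(survivors))
    filters = {
        "state": state,
        "max_resolution": max_resolution,
        "min_coverage": min_coverage,
        "dedupe": dedupe,
    }
    if not survivors:
        return RankedResults(query_id=query.id, filters=filters,
                             pairs=[], top_k=k)
    pairs = [
        score_pair(query, rec, scale, matrix, **scoring_opts)
        for rec in survivors
    ]
    normalize_scores(pairs)
    pairs.sort(key=_sort_key)
    return RankedResults(query_id=query.id, filters=filters,
                         pairs=pairs, top_k=k)


def browse_table(
    query: GPCRSequence,
    registry: Sequence[TemplateRecord],
    scale: Optional[HydrophobicityScale] = None,
    matrix: Optional[SubstitutionMatrix] = None,
    **scoring_opts,
) -> RankedResults:
    """Browse mode: score every PDB entry, unfiltered and without
    deduplication, normalized over the full registry."""
    return rank_templates(
        query, registry, state=None, max_resolution=None, min_coverage=None,
        k=len(registry) if registry else 1, dedupe=False,
        scale=scale, matrix=matrix, **scoring_opts,
    )


#: Fixed column order of exported result tables.
TABLE_COLUMNS = (
    ["rank", "receptor_id", "pdb_id", "resolution", "state", "coverage",
     "s_h", "s_b", "s_r", "s_t", "s_hn", "s_bn", "s_rank", "identity_global"]
    + [f"identity_tm{k}" for k in range(1, N_HELICES + 1)]
    + [f"ssd_per_residue_tm{k}" for k in range(1, N_HELICES + 1)]
)


def results_table(results: RankedResults, top_only: bool = False) -> pd.DataFrame:
    """Flatten RankedResults into the fixed-column result table."""
    rows = []
    pairs = results.top if top_only else results.pairs
    for rank, p in enumerate(pairs, start=1):
        row = {
            "rank": rank,
            "receptor_id": p.template.receptor.id,
            "pdb_id": p.pdb_id,
            "resolution": p.template.resolution,
            "state": p.template.state,
            "coverage": p.template.coverage,
            "s_h": p.s_h,
            "s_b": p.s_b,
            "s_r": p.s_r,
            "s_t": p.s_t,
            "s_hn": round(p.s_hn, 6),
            "s_bn": round(p.s_bn, 6),
            "s_rank": round(p.s_rank, 6),
            "identity_global": round(p.identity_global, 3),
        }
        for k in range(1, N_HELICES + 1):
            row[f"identity_tm{k}"] = round(p.identity_tm[k - 1], 3)
            row[f"ssd_per_residue_tm{k}"] = round(
                p.helices[k - 1].ssd_per_residue, 6
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
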