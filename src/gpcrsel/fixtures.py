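"""Synthetic GPCR-like fixtures with controllable hydropathy structure.

Sequences are built region by region (N-terminus, seven helices, six loops,
C-terminus) so that each region's windowed mean hydrophobicity sits within a
small tolerance of a piecewise-constant target level.  Residues are chosen
from the pair of scale-adjacent amino acids bracketing the target and
interleaved evenly (Bresenham-style, with a seeded random phase), followed by
a local swap-repair pass; the interleave keeps every interior window's mean
within ~gap/window of the target, comfortably inside the +/-0.05 guarantee for
the hydrophobicity ranges realistic GPCR regions occupy.

Registries plant a known-best template (same hydropathy targets and hotspot
residues as the query) among decoys whose helices and hotspots are
progressively degraded, with the intended score structure recorded in a
ground-truth table so ranking tests can assert planted recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .registry import (
    DEFAULT_HOTSPOT_LABELS,
    GPCRSequence,
    HydrophobicityScale,
    N_HELICES,
    RegistryError,
    TMDefinition,
    TemplateRecord,
    bw_to_index,
    load_scale,
    write_registry,
)

#: Window-mean tolerance the generator guarantees (scale units).
PROFILE_TOLERANCE = 0.05

#: Default hotspot residue per label for query and planted-best template:
#: hydrophobic-leaning residues cycled over the 24 canonical labels.
_HOTSPOT_CYCLE = "FLIVWYMA"

#: Hydrophobicity-conservative single mutations used to degrade decoy
#: hotspots without perturbing the hydropathy profile appreciably.
_HOTSPOT_MUTATION = {
    "F": "I", "L": "V", "I": "F", "V": "L",
    "W": "M", "Y": "C", "M": "A", "A": "M",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry, hydropathy targets, and metadata for one synthetic registry.

    Helix targets default to the 0.6-0.95 window-mean range typical of
    transmembrane spans on the Eisenberg scale, loops to a mildly
    hydrophilic -0.4.  ``seed`` fully determines the output.
    """

    n_templates: int = 5
    helix_lengths: tuple = (30, 27, 32, 25, 29, 33, 26)
    nterm_length: int = 20
    loop_lengths: tuple = (8, 6, 9, 7, 10, 6)
    cterm_length: int = 15
    helix_targets: tuple = (0.85, 0.70, 0.90, 0.60, 0.75, 0.95, 0.65)
    loop_target: float = -0.40
    hotspot_labels: tuple = DEFAULT_HOTSPOT_LABELS
    hotspot_residues: Optional[Mapping[str, str]] = None
    bad_helix_delta: float = -0.50
    resolutions: Optional[tuple] = None
    states: Optional[tuple] = None
    coverages: Optional[tuple] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.helix_lengths) != N_HELICES:
            raise RegistryError("need 7 helix lengths")
        if len(self.loop_lengths) != N_HELICES - 1:
            raise RegistryError("need 6 loop lengths")
        if len(self.helix_targets) != N_HELICES:
            raise RegistryError("need 7 helix targets")


def default_hotspot_residues(labels: Sequence[str] = DEFAULT_HOTSPOT_LABELS) -> dict:
    return {
        lab: _HOTSPOT_CYCLE[i % len(_HOTSPOT_CYCLE)]
        for i, lab in enumerate(labels)
    }


def _bracketing_pair(target: float, scale: HydrophobicityScale) -> tuple:
    """The two scale-adjacent residues whose values bracket ``target``."""
    if not scale.min <= target <= scale.max:
        raise RegistryError(
            f"target {target} outside achievable range "
            f"[{scale.min}, {scale.max}]"
        )
    ordered = sorted(scale.values.items(), key=lambda kv: kv[1])
    for (a, va), (b, vb) in zip(ordered, ordered[1:]):
        if va <= target <= vb:
            if target == va:
                return a, va, a, va
            return a, va, b, vb
    last, vlast = ordered[-1]
    return last, vlast, last, vlast


def _window_means(vals: np.ndarray, window: int) -> np.ndarray:
    """Means of every full window of length ``window`` inside ``vals``."""
    if len(vals) < window:
        return np.array([vals.mean()])
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    return (csum[window:] - csum[:-window]) / window


def _realize_region(
    n: int,
    target: float,
    scale: HydrophobicityScale,
    rng: np.random.Generator,
    window: int = 11,
    tol: float = PROFILE_TOLERANCE,
    max_repair: int = 400,
) -> str:
    """Build an ``n``-residue region whose full-window means sit within
    ``tol`` of ``target``."""
    a, va, b, vb = _bracketing_pair(target, scale)
    if a == b:
        return a * n
    frac = (target - va) / (vb - va)
    phase = float(rng.random())
    residues = [
        b if int(np.floor((j + 1) * frac + phase)) > int(np.floor(j * frac + phase))
        else a
        for j in range(n)
    ]
    vals = np.array([scale[r] for r in residues])
    w = min(window, n)
    for _ in range(max_repair):
        means = _window_means(vals, w)
        worst = int(np.argmax(np.abs(means - target)))
        err = means[worst] - target
        if abs(err) <= tol:
            break
        lo = worst if len(vals) >= w else 0
        window_idx = range(lo, lo + w)
        # flip one residue inside the worst window toward the target
        want_lower = err > 0
        swap_from, swap_to = (b, a) if want_lower else (a, b)
        cands = [j for j in window_idx if residues[j] == swap_from]
        if not cands:
            break
        j = cands[len(cands) // 2]
        residues[j] = swap_to
        vals[j] = scale[swap_to]
    return "".join(residues)


def _tm_definition(spec: FixtureSpec) -> TMDefinition:
    helices = []
    pos = spec.nterm_length + 1
    for k in range(1, N_HELICES + 1):
        length = spec.helix_lengths[k - 1]
        start, end = pos, pos + length - 1
        center = start + length // 2  # mid-helix anchor
        helices.append((start, end, center))
        pos = end + 1
        if k < N_HELICES:
            pos += spec.loop_lengths[k - 1]
    return TMDefinition(tuple(helices))


def make_sequence(
    spec: FixtureSpec,
    helix_targets: Optional[Sequence[float]] = None,
    hotspot_residues: Optional[Mapping[str, str]] = None,
    seq_id: str = "FIX",
    name: str = "synthetic receptor",
    gpcr_class: str = "A",
    rng: Optional[np.random.Generator] = None,
    scale: Optional[HydrophobicityScale] = None,
) -> GPCRSequence:
    """Generate one synthetic receptor with the spec's geometry.

    ``helix_targets`` overrides the spec's per-helix hydropathy levels;
    hotspot positions are overwritten with the demanded residues after
    profile realization.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    scale = scale if scale is not None else load_scale()
    targets = tuple(helix_targets) if helix_targets is not None \
        else spec.helix_targets
    if len(targets) != N_HELICES:
        raise RegistryError("need 7 helix targets")
    hotspots = dict(
        hotspot_residues if hotspot_residues is not None
        else (spec.hotspot_residues or default_hotspot_residues(spec.hotspot_labels))
    )

    parts = [_realize_region(spec.nterm_length, spec.loop_target, scale, rng)]
    for k in range(1, N_HELICES + 1):
        parts.append(
            _realize_region(spec.helix_lengths[k - 1], targets[k - 1], scale, rng)
        )
        if k < N_HELICES:
            parts.append(
                _realize_region(spec.loop_lengths[k - 1], spec.loop_target,
                                scale, rng)
            )
    parts.append(_realize_region(spec.cterm_length, spec.loop_target, scale, rng))
    seq = list("".join(parts))

    tm = _tm_definition(spec)
    for lab, res in hotspots.items():
        idx = bw_to_index(tm, lab, seq_length=len(seq))
        if idx is not None:
            seq[idx - 1] = res
    return GPCRSequence(
        id=seq_id, name=name, gpcr_class=gpcr_class,
        sequence="".join(seq), tm=tm,
    )


@dataclass(frozen=True)
class FixtureRegistry:
    """A generated query, its candidate templates, and the intended truth."""

    query: GPCRSequence
    records: tuple
    truth: pd.DataFrame


def make_registry(spec: FixtureSpec) -> FixtureRegistry:
    """Generate a registry with one planted-best template among decoys.

    Template 0 shares the query's hydropathy targets and hotspot residues
    (sequence still differs through the seeded phases) at 2.0 Angstrom;
    decoy i has i helices degraded by ``bad_helix_delta`` and 3*i hotspot
    residues mutated, so the intended HC score is 14 - 3*i and the intended
    identity-matrix BRS score is 24 - 3*i.  The truth table records both.
    """
    rng = np.random.default_rng(spec.seed)
    scale = load_scale()
    hotspots = dict(
        spec.hotspot_residues or default_hotspot_residues(spec.hotspot_labels)
    )
    query = make_sequence(
        spec, hotspot_residues=hotspots, seq_id="QUERY",
        name="synthetic query receptor", rng=rng, scale=scale,
    )
    n_labels = len(spec.hotspot_labels)

    default_res = [2.0, 2.3, 2.4, 2.8, 2.35, 2.1, 2.45, 2.9]
    default_cov = [95.0, 92.0, 88.0, 85.0, 90.0, 93.0, 87.0, 89.0]
    records = []
    truth_rows = []
    for i in range(spec.n_templates):
        n_bad = min(i, N_HELICES)
        targets = list(spec.helix_targets)
        for k in range(N_HELICES - n_bad, N_HELICES):
            targets[k] = targets[k] + spec.bad_helix_delta
        n_mut = min(3 * i, n_labels)
        t_hotspots = dict(hotspots)
        for lab in list(spec.hotspot_labels)[:n_mut]:
            t_hotspots[lab] = _HOTSPOT_MUTATION[hotspots[lab]]
        resolution = (spec.resolutions[i] if spec.resolutions
                      else default_res[i % len(default_res)])
        state = spec.states[i] if spec.states else "inactive"
        coverage = (spec.coverages[i] if spec.coverages
                    else default_cov[i % len(default_cov)])
        receptor = make_sequence(
            spec, helix_targets=targets, hotspot_residues=t_hotspots,
            seq_id=f"R{i:03d}", name=f"synthetic template receptor {i}",
            rng=rng, scale=scale,
        )
        pdb_id = f"9T{i:02d}"
        records.append(
            TemplateRecord(
                receptor=receptor, pdb_id=pdb_id, resolution=resolution,
                state=state, coverage=coverage,
            )
        )
        truth_rows.append({
            "pdb_id": pdb_id,
            "receptor_id": receptor.id,
            "n_bad_helices": n_bad,
            "expected_s_h": 14 - 3 * n_bad,
            "n_hotspot_mutations": n_mut,
            "expected_s_b_unit": n_labels - n_mut,
            "planted_best": i == 0,
        })
    return FixtureRegistry(
        query=query, records=tuple(records), truth=pd.DataFrame(truth_rows)
    )


def write_fixture(spec: FixtureSpec, outdir: Union[str, Path]) -> dict:
    """Write a loadable registry TSV, ground-truth TSV, and query
    FASTA + TM sidecar; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = make_registry(spec)
    paths = {
        "registry": outdir / "registry.tsv",
        "truth": outdir / "truth.tsv",
        "query_fasta": outdir / "query.fasta",
        "query_tm": outdir / "query.tm.tsv",
    }
    write_registry(fx.records, paths["registry"])
    fx.truth.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["query_fasta"], "w") as fh:
        fh.write(f">{fx.query.id} {fx.query.name}\n")
        for i in range(0, len(fx.query.sequence), 60):
            fh.write(fx.query.sequence[i:i + 60] + "\n")
    row = {}
    for k in range(1, N_HELICES + 1):
        s, e, c = fx.query.tm.span(k)
        row[f"tm{k}_start"], row[f"tm{k}_end"], row[f"tm{k}_center"] = s, e, c
    pd.DataFrame([row]).to_csv(paths["query_tm"], sep="\t", index=False)
    return paths
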