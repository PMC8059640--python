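"""Windowed hydropathy profiles, SSD helix correspondence, and moments.

The hydrophobicity correspondence (HC) between a pair of tethered helices is
the sum of squared differences (SSD) of their window-averaged hydropathy
profiles over the paired positions, normalized per residue.  Each helix then
contributes +2 (SSD per residue <= 0.1, in scale-units squared) or -1 to the
HC score S_h, which ranges from -7 to +14 in steps of 3.

Amphiphilicity is quantified by the hydrophobic moment: the magnitude of the
vector sum of residue hydrophobicities placed at 100 degree increments around
an ideal alpha-helix, maximized over sliding windows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .registry import GPCRSequence, HydrophobicityScale, N_HELICES, RegistryError
from .alignment import TetheredHelixAlignment

#: Window length (residues) for both the hydropathy profile and the moment;
#: 11 is the classic transmembrane-detection window.
DEFAULT_WINDOW = 11

#: Degrees of helical twist per residue for an ideal alpha-helix.
DEFAULT_DELTA_DEG = 100.0

#: SSD-per-residue boundary separating "good" (+2) from "poor" (-1) helix
#: correspondence; the boundary value itself scores +2.
SPR_GOOD_MAX = 0.1

EDGE_MODES = ("extend", "truncate")
SSD_DIVISORS = ("paired", "target", "template")


@dataclass(frozen=True)
class HydroProfile:
    """Window-averaged hydrophobicity per position (absolute 1-based)."""

    positions: np.ndarray
    H: np.ndarray

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.H):
            raise RegistryError("profile positions/H length mismatch")

    def lookup(self) -> dict:
        return dict(zip(self.positions.tolist(), self.H.tolist()))


def window_profile(
    seq: str, scale: HydrophobicityScale, window: int = DEFAULT_WINDOW
) -> HydroProfile:
    """Moving-window mean hydrophobicity at every position of ``seq``.

    The window is centered (odd length); positions within (window-1)/2 of an
    end use the truncated available window, divided by its actual size.
    """
    if not seq:
        raise RegistryError("window_profile: empty sequence")
    if window < 1 or window % 2 == 0:
        raise RegistryError(f"window must be odd and >= 1, got {window}")
    if window > len(seq):
        raise RegistryError(
            f"window {window} exceeds sequence length {len(seq)}"
        )
    vals = np.array([scale[r] for r in seq], dtype=float)
    half = (window - 1) // 2
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    n = len(vals)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    H = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return HydroProfile(positions=idx + 1, H=H)


def profile_for_correspondence(
    seq: GPCRSequence,
    scale: HydrophobicityScale,
    window: int = DEFAULT_WINDOW,
    edge_mode: str = "extend",
) -> dict:
    """Per-position profile values used for helix SSDs, as {abs index: H}.

    edge_mode 'extend' (default): the profile is computed on the full-length
    sequence and sliced to each helix, so helix-edge windows average over the
    genuine flanking loop residues.  'truncate': each helix is profiled in
    isolation and windows truncate at the helix boundaries.
    """
    if edge_mode not in EDGE_MODES:
        raise RegistryError(f"edge_mode must be one of {EDGE_MODES}")
    if edge_mode == "extend":
        return window_profile(seq.sequence, scale, window).lookup()
    lut = {}
    for k in range(1, N_HELICES + 1):
        s, e, _ = seq.tm.span(k)
        sub = seq.sequence[s - 1:e]
        w = min(window, len(sub) if len(sub) % 2 else len(sub) - 1)
        prof = window_profile(sub, scale, w)
        for pos, h in zip(prof.positions, prof.H):
            lut[s + int(pos) - 1] = float(h)
    return lut


@dataclass(frozen=True)
class HelixCorrespondence:
    """SSD summary and +2/-1 contribution for one tethered helix pair."""

    helix_index: int
    n_paired: int
    ssd: float
    ssd_per_residue: float
    s_i: int


def helix_correspondence(
    pair: TetheredHelixAlignment,
    target_profile: dict,
    template_profile: dict,
    divisor: str = "paired",
) -> HelixCorrespondence:
    """Score one helix pair: SSD over paired positions, per-residue value,
    and the +2/-1 contribution.

    divisor selects the SSD normalization population: 'paired' (default, the
    number of aligned positions), 'target' or 'template' (that sequence's
    full helix length including overhangs).
    """
    if pair.n_paired == 0:
        raise RegistryError(
            f"TM{pair.helix_index}: no paired positions to score"
        )
    if divisor not in SSD_DIVISORS:
        raise RegistryError(f"divisor must be one of {SSD_DIVISORS}")
    ssd = 0.0
    for ti, pi in pair.pairs:
        try:
            dh = template_profile[pi] - target_profile[ti]
        except KeyError as exc:
            raise RegistryError(
                f"TM{pair.helix_index}: profile missing position {exc}"
            ) from exc
        ssd += dh * dh
    n = {
        "paired": pair.n_paired,
        "target": pair.target_len,
        "template": pair.template_len,
    }[divisor]
    spr = ssd / n
    s_i = 2 if spr <= SPR_GOOD_MAX else -1
    return HelixCorrespondence(
        helix_index=pair.helix_index,
        n_paired=pair.n_paired,
        ssd=ssd,
        ssd_per_residue=spr,
        s_i=s_i,
    )


def hc_score(helix_scores: Sequence[HelixCorrespondence]) -> int:
    """Overall HC score S_h: the sum of the seven +2/-1 contributions."""
    if len(helix_scores) != N_HELICES:
        raise RegistryError(
            f"hc_score needs exactly {N_HELICES} helix scores, "
            f"got {len(helix_scores)}"
        )
    return sum(h.s_i for h in helix_scores)


# ---------------------------------------------------------------------------
# Hydrophobic moment / helical wheel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MomentResult:
    """Hydrophobic-moment summary for one helix.

    mu_max is the largest per-window moment (scale units); direction_deg the
    resultant-vector angle of that window; mu_whole the single moment of the
    entire helix; wheel lists (residue, angle_deg, hydrophobicity) per
    position at 100 degree increments.
    """

    helix_index: int
    mu_max: float
    direction_deg: float
    window_center: int
    mu_whole: float
    wheel: tuple


def _window_moment(vals: np.ndarray, delta_rad: float) -> tuple:
    """(mu, direction_deg) of one window: vector-sum magnitude / length."""
    j = np.arange(len(vals))
    s = float(np.sum(vals * np.sin(j * delta_rad)))
    c = float(np.sum(vals * np.cos(j * delta_rad)))
    mu = math.hypot(s, c) / len(vals)
    direction = math.degrees(math.atan2(s, c)) % 360.0
    return mu, direction


def hydrophobic_moment(
    helix: str,
    scale: HydrophobicityScale,
    window: int = DEFAULT_WINDOW,
    delta_deg: float = DEFAULT_DELTA_DEG,
    helix_index: int = 0,
    start: int = 1,
) -> MomentResult:
    """Sliding-window hydrophobic moment of one helix.

    For each full window of ``window`` residues (the whole helix when it is
    shorter), the moment is |sum_i h_i * (sin(i*delta), cos(i*delta))| / w.
    ``start`` is the absolute index of the first helix residue, so
    window_center is reported on the parent sequence.  Ties in the maximal
    window resolve to the leftmost.
    """
    if not helix:
        raise RegistryError("hydrophobic_moment: empty helix")
    vals = np.array([scale[r] for r in helix], dtype=float)
    delta_rad = math.radians(delta_deg)
    w = min(window, len(vals))
    best = (-1.0, 0.0, 0)  # (mu, direction, window start offset)
    for off in range(len(vals) - w + 1):
        mu, direction = _window_moment(vals[off:off + w], delta_rad)
        if mu > best[0]:
            best = (mu, direction, off)
    mu_whole, _ = _window_moment(vals, delta_rad)
    wheel = tuple(
        (res, (j * delta_deg) % 360.0, float(vals[j]))
        for j, res in enumerate(helix)
    )
    return MomentResult(
        helix_index=helix_index,
        mu_max=best[0],
        direction_deg=best[1],
        window_center=start + best[2] + (w - 1) // 2,
        mu_whole=mu_whole,
        wheel=wheel,
    )


def helix_moments(
    seq: GPCRSequence,
    scale: HydrophobicityScale,
    window: int = DEFAULT_WINDOW,
    delta_deg: float = DEFAULT_DELTA_DEG,
) -> list:
    """MomentResult for each of the seven annotated helices."""
    out = []
    for k in range(1, N_HELICES + 1):
        s, e, _ = seq.tm.span(k)
        out.append(
            hydrophobic_moment(
                seq.sequence[s - 1:e], scale, window=window,
                delta_deg=delta_deg, helix_index=k, start=s,
            )
        )
    return out
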