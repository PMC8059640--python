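"""Plain-text/Markdown report and TSV export for scored pairs.

Every number in a report is recomputed from the same inputs through the
library; the writer only formats.  Output is deterministic: identical inputs
give byte-identical files.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .alignment import FullAlignment
from .hydropathy import HydroProfile, MomentResult
from .ranking import PairScore, RankedResults, results_table
from .registry import N_HELICES


def _f(x: Optional[float]) -> str:
    return "NA" if x is None else f"{x:.3f}"


def write_report(
    path: Union[str, Path],
    pair: PairScore,
    alignment: FullAlignment,
    query_moments: Sequence[MomentResult],
    template_moments: Sequence[MomentResult],
    settings: Optional[dict] = None,
    normalization_note: str = "",
) -> None:
    """Write the per-pair Markdown report.

    Contains the settings echo, the score block (with a note on which
    candidate set the normalization ran over), the per-helix HC table, the
    hotspot table, moments for both sequences, the annotated alignment, and
    a FASTA block that parses back to the alignment.
    """
    lines = []
    add = lines.append
    add(f"# Template report: {alignment.target_id} vs "
        f"{pair.pdb_id} ({pair.template.receptor.id})")
    add("")
    add("## Settings")
    add("")
    for key in sorted(settings or {}):
        add(f"- {key}: {(settings or {})[key]}")
    add("")
    add("## Scores")
    add("")
    add(f"- S_h (HC score): {pair.s_h}")
    add(f"- S_b (BRS score): {pair.s_b} over {pair.hotspots.n_scored} "
        f"scored hotspot positions")
    add(f"- S_r (resolution score): {pair.s_r}")
    add(f"- S_t (total): {_f(float(pair.s_t))}")
    add(f"- S_hn: {_f(pair.s_hn)}  S_bn: {_f(pair.s_bn)}  "
        f"S_rank: {_f(pair.s_rank)}")
    if normalization_note:
        add(f"- normalization set: {normalization_note}")
    add(f"- global identity: {_f(pair.identity_global)}%")
    add("")
    add("## Helix correspondence")
    add("")
    add("| helix | n_paired | ssd | ssd_per_residue | s_i | identity_% |")
    add("|---|---|---|---|---|---|")
    for k in range(1, N_HELICES + 1):
        h = pair.helices[k - 1]
        add(f"| TM{k} | {h.n_paired} | {_f(h.ssd)} | "
            f"{_f(h.ssd_per_residue)} | {h.s_i:+d} | "
            f"{_f(pair.identity_tm[k - 1])} |")
    add("")
    add("## Hotspot comparison")
    add("")
    add("| label | target | template | score |")
    add("|---|---|---|---|")
    for lab, (a, b, sc) in pair.hotspots.entries.items():
        add(f"| {lab} | {a or '-'} | {b or '-'} | "
            f"{'-' if sc is None else _f(float(sc))} |")
    add("")
    add("## Hydrophobic moments")
    add("")
    add("| helix | sequence | mu_max | direction_deg | window_center "
        "| mu_whole |")
    add("|---|---|---|---|---|---|")
    for label, moments in ((alignment.target_id, query_moments),
                           (alignment.template_id, template_moments)):
        for m in moments:
            add(f"| TM{m.helix_index} | {label} | {_f(m.mu_max)} | "
                f"{_f(m.direction_deg)} | {m.window_center} | "
                f"{_f(m.mu_whole)} |")
    add("")
    add("## Full-length alignment")
    add("")
    add("```")
    add(alignment.to_text_block().rstrip("\n"))
    add("```")
    add("")
    add("## Alignment (FASTA)")
    add("")
    add("```")
    add(f">{alignment.target_id}")
    add(alignment.target_row)
    add(f">{alignment.template_id}")
    add(alignment.template_row)
    add("```")
    add("")
    Path(path).write_text("\n".join(lines))


def profile_frame(profile: HydroProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "position": profile.positions,
        "H": [round(h, 6) for h in profile.H],
    })


def wheel_frame(moments: Sequence[MomentResult]) -> pd.DataFrame:
    rows = []
    for m in moments:
        for j, (res, angle, h) in enumerate(m.wheel, start=1):
            rows.append({
                "helix": m.helix_index, "residue_index": j, "residue": res,
                "angle_deg": round(angle, 3), "h": round(h, 6),
            })
    return pd.DataFrame(rows,
                        columns=["helix", "residue_index", "residue",
                                 "angle_deg", "h"])


def hc_frame(pair: PairScore) -> pd.DataFrame:
    rows = [
        {
            "helix": h.helix_index,
            "n_paired": h.n_paired,
            "ssd": round(h.ssd, 6),
            "ssd_per_residue": round(h.ssd_per_residue, 6),
            "s_i": h.s_i,
        }
        for h in pair.helices
    ]
    return pd.DataFrame(rows,
                        columns=["helix", "n_paired", "ssd",
                                 "ssd_per_residue", "s_i"])


def hotspot_frame(pair: PairScore) -> pd.DataFrame:
    rows = [
        {
            "label": lab,
            "target_res": a or "",
            "template_res": b or "",
            "score": "" if sc is None else sc,
        }
        for lab, (a, b, sc) in pair.hotspots.entries.items()
    ]
    return pd.DataFrame(rows,
                        columns=["label", "target_res", "template_res",
                                 "score"])


def write_table(results: RankedResults, path: Union[str, Path],
                top_only: bool = False) -> None:
    results_table(results, top_only=top_only).to_csv(path, sep="\t",
                                                     index=False)


# ---------------------------------------------------------------------------
# Optional plots (headless-safe; behind a CLI flag)
# ---------------------------------------------------------------------------

def plot_helix_profiles(
    pair: PairScore, query, path: Union[str, Path],
    scale=None, window: int = 11,
) -> None:
    """Line plots of the windowed hydropathy of each tethered helix pair."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .hydropathy import profile_for_correspondence
    from .alignment import tether_all
    from .registry import load_scale

    scale = scale if scale is not None else load_scale()
    qp = profile_for_correspondence(query, scale, window=window)
    tp = profile_for_correspondence(pair.template.receptor, scale,
                                    window=window)
    tethered = tether_all(query, pair.template.receptor)
    fig, axes = plt.subplots(4, 2, figsize=(10, 12))
    for ha, ax in zip(tethered, axes.flat):
        offs = range(len(ha.pairs))
        ax.plot(list(offs), [qp[i] for i, _ in ha.pairs], label=query.id)
        ax.plot(list(offs), [tp[j] for _, j in ha.pairs],
                label=pair.pdb_id)
        ax.set_title(f"TM{ha.helix_index}")
        ax.set_xlabel("paired position")
        ax.set_ylabel("H")
    axes.flat[0].legend()
    axes.flat[-1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def plot_wheel(moment: MomentResult, path: Union[str, Path]) -> None:
    """Polar helical-wheel plot with the moment direction marked."""
    import math

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    for res, angle, h in moment.wheel:
        theta = math.radians(angle)
        ax.plot([theta], [1.0], "o", color="tab:blue" if h > 0 else "tab:red")
        ax.annotate(res, (theta, 1.08), ha="center", va="center")
    ax.annotate(
        "", xy=(math.radians(moment.direction_deg), 0.9), xytext=(0, 0),
        arrowprops=dict(arrowstyle="->", color="black"),
    )
    ax.set_rticks([])
    ax.set_title(f"TM{moment.helix_index}  mu_max={moment.mu_max:.3f}")
    fig.savefig(path, dpi=100)
    plt.close(fig)
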