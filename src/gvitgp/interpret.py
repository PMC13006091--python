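"""Attention-to-genome mapping and prediction-quality plots.

``attention_manhattan`` projects the [CLS] token's self-attention row of a
chosen encoder layer back onto physical genomic coordinates: each non-padding
patch becomes one point whose chromosome is the majority chromosome of its
member markers, whose position is the median member bp, and whose score is
the head-averaged, cohort-averaged [CLS]->patch attention weight. The
[CLS]->[CLS] weight is dropped without renormalizing, so patch scores plus
that weight sum to 1. The significance line defaults to mean + 3 sd of the
patch scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractError
from .genotype_io import MarkerMap
from .train_eval import FitResult, compute_metrics


@dataclass
class AttentionManhattan:
    patch_index: np.ndarray       # non-padding patch indices
    chromosome: np.ndarray        # majority chromosome per patch
    position_bp: np.ndarray       # median member position per patch
    score: np.ndarray             # mean [CLS]->patch attention
    cls_weight: float             # dropped [CLS]->[CLS] mass
    threshold: float
    members: list[list[str]]      # member marker ids per patch

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patch": self.patch_index,
            "chrom": self.chromosome,
            "pos_bp": self.position_bp,
            "score": self.score,
            "above_threshold": self.score > self.threshold,
            "members": [";".join(m) for m in self.members],
        })

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def attention_manhattan(
    fit: FitResult,
    mmap: MarkerMap,
    layer: int | str = "last",
    threshold_sd: float = 3.0,
) -> AttentionManhattan:
    """Map the chosen layer's [CLS] attention row to genomic coordinates.

    ``layer`` is an encoder-layer index or ``"last"`` (the final post-fusion
    self-attention layer). Requires attention records plus the patch plan and
    selection stored on the fit.
    """
    if not fit.attention:
        raise ContractError(
            "no attention recorded; rerun evaluation with record_attention=True"
        )
    if fit.plan is None or fit.selection is None:
        raise ContractError("fit lacks the patch plan / selection used at training")
    self_records = [rec for rec in fit.attention if rec.layer != "fusion"]
    if not self_records:
        raise ContractError("no self-attention layers recorded")
    if layer == "last":
        rec = self_records[-1]
    else:
        match = [r for r in self_records if r.layer == layer]
        if not match:
            raise ContractError(f"layer {layer!r} not recorded")
        rec = match[0]

    plan = fit.plan
    row = rec.cls_row                     # (N_p + 1,), sums to 1
    cls_weight = float(row[0])
    sel = np.asarray(fit.selection.selected)
    patch_idx, chroms, positions, scores, members = [], [], [], [], []
    for pi, (start, end) in enumerate(plan.patch_ranges):
        if end <= start:
            continue                      # all-padding trailing patch
        marker_ids = sel[start:end]
        chrom_labels = [mmap.chromosomes[i] for i in marker_ids]
        vals, counts = np.unique(chrom_labels, return_counts=True)
        chroms.append(vals[np.argmax(counts)])
        positions.append(int(np.median([mmap.positions[i] for i in marker_ids])))
        scores.append(float(row[pi + 1]))
        patch_idx.append(pi)
        members.append([str(mmap.ids[i]) for i in marker_ids])
    scores_arr = np.array(scores)
    threshold = float(scores_arr.mean() + threshold_sd * scores_arr.std())
    return AttentionManhattan(
        patch_index=np.array(patch_idx),
        chromosome=np.array(chroms, dtype=object),
        position_bp=np.array(positions),
        score=scores_arr,
        cls_weight=cls_weight,
        threshold=threshold,
        members=members,
    )


def plot_attention_manhattan(am: AttentionManhattan, out_path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    chrom_order = list(dict.fromkeys(am.chromosome))
    offset, ticks = 0.0, []
    for chrom in chrom_order:
        mask = am.chromosome == chrom
        x = am.position_bp[mask] + offset
        ax.scatter(x, am.score[mask], s=12,
                   color="tab:blue" if chrom_order.index(chrom) % 2 == 0 else "tab:cyan")
        ticks.append((offset + x.max()) / 2 if len(x) else offset)
        offset = x.max() + 1 if len(x) else offset
    ax.axhline(am.threshold, color="red", linestyle="--", linewidth=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(chrom_order, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("[CLS] attention")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def prediction_density(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    out_dir: str | Path,
    prefix: str = "prediction",
) -> dict[str, object]:
    """2-D KDE of predicted vs observed (y=x reference) plus an annotated
    scatter with the linear fit and Pearson r. Falls back to scatter only
    when fewer than 5 points make a KDE unstable. Returns the written paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ContractError("length mismatch")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, object] = {}

    m = compute_metrics(y_true, y_pred)
    slope, intercept = (np.polyfit(y_pred, y_true, 1)
                        if np.std(y_pred) > 0 else (0.0, float(np.mean(y_true))))

    if y_true.size >= 5 and np.std(y_pred) > 0:
        kde_path = out_dir / f"{prefix}_kde.png"
        fig, ax = plt.subplots(figsize=(4.2, 4))
        xy = np.vstack([y_pred, y_true])
        try:
            dens = gaussian_kde(xy)(xy)
        except np.linalg.LinAlgError:
            dens = np.ones(y_true.size)
        ax.scatter(y_pred, y_true, c=dens, s=14, cmap="viridis")
        lims = [min(y_pred.min(), y_true.min()), max(y_pred.max(), y_true.max())]
        ax.plot(lims, lims, "r--", linewidth=1)
        ax.set_xlabel("predicted")
        ax.set_ylabel("observed")
        fig.tight_layout()
        fig.savefig(kde_path, dpi=120)
        plt.close(fig)
        written["kde"] = kde_path

    scatter_path = out_dir / f"{prefix}_scatter.png"
    fig, ax = plt.subplots(figsize=(4.2, 4))
    ax.scatter(y_pred, y_true, s=14, alpha=0.7)
    xs = np.linspace(y_pred.min(), y_pred.max(), 50) if np.std(y_pred) > 0 else y_pred
    ax.plot(xs, slope * xs + intercept, color="tab:blue", linewidth=1.2)
    ax.annotate(f"r = {m.r:.4f}", xy=(0.05, 0.92), xycoords="axes fraction")
    ax.set_xlabel("predicted")
    ax.set_ylabel("observed")
    fig.tight_layout()
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)
    written["scatter"] = scatter_path
    written["fit"] = {"slope": float(slope), "intercept": float(intercept), "r": m.r}
    return written
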