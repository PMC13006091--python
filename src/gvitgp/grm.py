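"""VanRaden genomic relationship matrix with fold-aware, leakage-free features.

G = M* M*' / (2 * sum_j p_j (1 - p_j)), where M* is the dosage matrix centered
by twice the second-allele frequency p_j. Frequencies are always estimated on
an explicit reference cohort; evaluation individuals are represented only by
their relationship vectors against that cohort and never touch frequency
estimation. Missing dosages are filled with 2 p_j before centering so they
contribute exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DegeneratePanelError, LeakageError, UndefinedMarkerError, ValidationError
from .genotype_io import GenotypeMatrix


@dataclass
class AlleleFreqs:
    """Per-marker second-allele frequencies estimated on a named cohort."""

    p: np.ndarray               # (m,) in [0,1]
    n_used: np.ndarray          # (m,) non-missing count per marker
    source_cohort: list[str]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValidationError("allele frequency outside [0,1]")
        if np.any(self.n_used < 1):
            raise ValidationError("retained marker with zero observations")


@dataclass
class GRMFeatures:
    """Reference-cohort GRM plus the ingredients needed to score new samples."""

    G_ref: np.ndarray           # (n_ref, n_ref), symmetric
    ref_ids: list[str]
    freqs: AlleleFreqs
    denom: float                # 2 * sum_j p_j (1 - p_j)

    def __post_init__(self) -> None:
        if not np.allclose(self.G_ref, self.G_ref.T, atol=1e-10):
            raise ValidationError("G_ref not symmetric")
        if self.denom <= 0:
            raise ValidationError("non-positive VanRaden denominator")
        if self.freqs.source_cohort != self.ref_ids:
            raise ValidationError("freqs cohort differs from ref_ids")

    @property
    def n_ref(self) -> int:
        return len(self.ref_ids)


def estimate_freqs(g: GenotypeMatrix, cohort: Sequence[str]) -> AlleleFreqs:
    """Second-allele frequencies p_j over the non-missing entries of ``cohort``."""
    cohort = list(cohort)
    if not cohort:
        raise ValidationError("empty cohort")
    rows = g.row_index(cohort)
    X = g.dosages[rows]
    obs = np.isfinite(X)
    n_used = obs.sum(axis=0)
    dead = np.where(n_used == 0)[0]
    if dead.size:
        ids = list(np.asarray(g.markers.ids)[dead][:5])
        raise UndefinedMarkerError(
            f"{dead.size} marker(s) all-missing within cohort, e.g. {ids}"
        )
    p = np.where(obs, X, 0.0).sum(axis=0) / (2.0 * n_used)
    return AlleleFreqs(p=p, n_used=n_used, source_cohort=cohort)


def _centered(g: GenotypeMatrix, freqs: AlleleFreqs, ids: Sequence[str]) -> np.ndarray:
    """M* rows for ``ids``: missing filled with 2p then centered by 2p."""
    rows = g.row_index(list(ids))
    X = g.dosages[rows].copy()
    two_p = 2.0 * freqs.p
    nan_r, nan_c = np.where(~np.isfinite(X))
    X[nan_r, nan_c] = two_p[nan_c]
    return X - two_p


def vanraden_denom(freqs: AlleleFreqs) -> float:
    return float(2.0 * np.sum(freqs.p * (1.0 - freqs.p)))


def compute_grm(
    g: GenotypeMatrix,
    freqs: AlleleFreqs,
    rows: Sequence[str],
    cols: Sequence[str],
) -> np.ndarray:
    """|rows| x |cols| block of the VanRaden GRM under ``freqs``.

    With rows == cols == freqs.source_cohort this is the reference GRM;
    with rows an evaluation cohort it yields their relationship vectors.
    """
    denom = vanraden_denom(freqs)
    if denom <= 0:
        raise DegeneratePanelError(
            "all markers monomorphic in the reference cohort (denominator 0)"
        )
    A = _centered(g, freqs, rows)
    B = _centered(g, freqs, cols)
    return (A @ B.T) / denom


def fold_grm_features(
    g: GenotypeMatrix,
    train_ids: Sequence[str],
    eval_ids: Sequence[str],
) -> tuple[GRMFeatures, np.ndarray]:
    """Fold-aware GRM: frequencies and reference GRM from the training cohort
    only; evaluation individuals appear only as relationship vectors.

    Raises :class:`LeakageError` on any train/eval overlap.
    """
    train_ids, eval_ids = list(train_ids), list(eval_ids)
    overlap = set(train_ids) & set(eval_ids)
    if overlap:
        raise LeakageError(f"train/eval cohorts overlap: {sorted(overlap)[:5]}")
    freqs = estimate_freqs(g, train_ids)
    denom = vanraden_denom(freqs)
    if denom <= 0:
        raise DegeneratePanelError("reference panel monomorphic")
    M_train = _centered(g, freqs, train_ids)
    G_ref = (M_train @ M_train.T) / denom
    G_ref = (G_ref + G_ref.T) / 2.0  # exact symmetry
    feats = GRMFeatures(G_ref=G_ref, ref_ids=train_ids, freqs=freqs, denom=denom)
    if eval_ids:
        eval_vectors = (_centered(g, freqs, eval_ids) @ M_train.T) / denom
    else:
        eval_vectors = np.empty((0, len(train_ids)))
    return feats, eval_vectors


def write_grm_tsv(G: np.ndarray, row_ids: Iterable[str], col_ids: Iterable[str],
                  path: str | Path) -> None:
    pd.DataFrame(G, index=list(row_ids), columns=list(col_ids)).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_grm_tsv(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return frame.to_numpy(dtype=float), list(frame.index.astype(str)), list(
        frame.columns.astype(str)
    )
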