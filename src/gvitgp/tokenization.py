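"""SNP-sequence tokenization: SPE, FPE and SIE strategies.

A selected (or full) SNP sequence of length L is partitioned into a fixed
number of patches N_p with patch size P = ceil(L / N_p); the final patch is
zero-padded. Each patch is flattened and mapped to a D-dimensional token by
one shared linear projection, and a learnable [CLS] token is prepended. SIE
instead maps every selected marker's scalar dosage through a shared 1 -> D
projection (no patching).

Dosage preprocessing (mean-fill missing with the training fold's 2p_j, then
z-score per marker by training-fold statistics) lives here so that every
embedding strategy sees identically scaled inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .exceptions import ContractError
from .locus_selection import SelectionResult


@dataclass
class PatchPlan:
    """Bookkeeping for fixed-patch-count tokenization of an L-marker sequence."""

    L: int
    N_p: int
    P: int
    pad: int
    patch_ranges: list[tuple[int, int]]  # half-open [start, end) into the sequence

    def to_dict(self) -> dict:
        return {
            "L": self.L, "N_p": self.N_p, "P": self.P, "pad": self.pad,
            "patch_ranges": [list(r) for r in self.patch_ranges],
        }


def make_patch_plan(L: int, N_p: int = 400) -> PatchPlan:
    """P = ceil(L / N_p); pad = N_p * P - L; trailing patches may be all-pad.

    When L < N_p the plan degenerates to P = 1 with L - N_p empty trailing
    patches, kept so the token-sequence length is constant across folds.
    """
    if L < 1 or N_p < 1:
        raise ContractError("L and N_p must be >= 1")
    P = math.ceil(L / N_p)
    pad = N_p * P - L
    ranges = []
    for i in range(N_p):
        start = min(i * P, L)
        end = min((i + 1) * P, L)
        ranges.append((start, end))
    return PatchPlan(L=L, N_p=N_p, P=P, pad=pad, patch_ranges=ranges)


@dataclass
class TokenBatch:
    """[CLS] + patch/marker tokens for a batch; token 0 is always [CLS]."""

    tokens: Tensor               # (batch, S, D)
    plan: PatchPlan | None       # None for SIE
    marker_indices: np.ndarray   # selected marker indices in sequence order
    cls_index: int = 0

    @property
    def S(self) -> int:
        return self.tokens.shape[1]

    @property
    def D(self) -> int:
        return self.tokens.shape[2]


@dataclass
class DosageScaler:
    """Training-fold fill + standardization statistics for a marker subset."""

    fill: np.ndarray   # value used for missing entries (2 p_j)
    mean: np.ndarray   # post-fill mean per marker
    sd: np.ndarray     # post-fill sd per marker (0 -> 1 guard)

    @staticmethod
    def fit(X_train: np.ndarray, two_p: np.ndarray | None = None) -> "DosageScaler":
        X = X_train.copy()
        fill = two_p if two_p is not None else np.nanmean(X, axis=0)
        fill = np.where(np.isfinite(fill), fill, 0.0)
        nan_r, nan_c = np.where(~np.isfinite(X))
        X[nan_r, nan_c] = fill[nan_c]
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return DosageScaler(fill=fill, mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = X.copy()
        nan_r, nan_c = np.where(~np.isfinite(X))
        X[nan_r, nan_c] = self.fill[nan_c]
        return (X - self.mean) / self.sd


def _patch_tokens(rows: np.ndarray, plan: PatchPlan, W: Tensor, b: Tensor,
                  cls: Tensor) -> Tensor:
    n = rows.shape[0]
    if rows.shape[1] != plan.L:
        raise ContractError(
            f"sequence length {rows.shape[1]} != plan.L {plan.L}"
        )
    padded = np.zeros((n, plan.N_p * plan.P))
    padded[:, : plan.L] = rows
    patches = Tensor(padded.reshape(n * plan.N_p, plan.P))
    D = W.shape[1]
    tok = (patches @ W + b).reshape(n, plan.N_p, D)   # shared affine P -> D
    cls_tok = cls.reshape(1, 1, -1).expand((n, 1, cls.data.size))
    return concat([cls_tok, tok], axis=1)


def spe_tokenize(
    g_rows: np.ndarray,
    selection: SelectionResult,
    plan: PatchPlan,
    W: Tensor,
    b: Tensor,
    cls: Tensor,
) -> TokenBatch:
    """Selective Patch Embedding: gather selected markers, patch, project.

    ``g_rows`` must already be preprocessed (mean-filled + standardized with
    training-fold statistics) and hold the full marker panel; the selection's
    genomic-ordered indices pick the sequence.
    """
    if plan.L != selection.k:
        raise ContractError(f"plan.L={plan.L} != selection.k={selection.k}")
    seq = np.asarray(g_rows, dtype=float)[:, selection.selected]
    tokens = _patch_tokens(seq, plan, W, b, cls)
    return TokenBatch(tokens=tokens, plan=plan, marker_indices=selection.selected)


def fpe_tokenize(
    g_rows: np.ndarray,
    plan: PatchPlan,
    W: Tensor,
    b: Tensor,
    cls: Tensor,
) -> TokenBatch:
    """Full-sequence Patch Embedding: patch the entire post-QC panel."""
    rows = np.asarray(g_rows, dtype=float)
    tokens = _patch_tokens(rows, plan, W, b, cls)
    return TokenBatch(
        tokens=tokens, plan=plan, marker_indices=np.arange(rows.shape[1])
    )


def sie_tokenize(
    g_rows: np.ndarray,
    selection: SelectionResult,
    W: Tensor,
    b: Tensor,
    cls: Tensor,
) -> TokenBatch:
    """Selective Independent Embedding: one token per selected marker (1 -> D)."""
    seq = np.asarray(g_rows, dtype=float)[:, selection.selected]
    n, k = seq.shape
    x = Tensor(seq.reshape(n, k, 1))
    tok = x @ W + b                             # shared affine 1 -> D
    cls_tok = cls.reshape(1, 1, -1).expand((n, 1, cls.data.size))
    tokens = concat([cls_tok, tok], axis=1)
    return TokenBatch(tokens=tokens, plan=None, marker_indices=selection.selected)
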