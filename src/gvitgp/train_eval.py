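"""Leakage-free evaluation protocol: 80/20 hold-out, 5-fold nested CV,
fold-nested locus selection, fold-aware GRM features, AdamW/cosine training
with early stopping, and the ablation harnesses.

Every quantity that could leak — allele frequencies, dosage scalers,
phenotype standardization, locus selection — is estimated on the fold's
training partition only. Phenotypes are standardized to training-fold
z-scores and all metrics are reported on that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from . import grm as grm_mod
from . import locus_selection as sel_mod
from .autodiff import AdamW, clone_params, cosine_lr, load_params, mse_loss
from .exceptions import ConfigError, ContractError, DivergenceError, LeakageError
from .genotype_io import GenotypeMatrix, PhenotypeTable
from .model import AttentionRecord, GViTGP, ModelConfig
from .tokenization import (
    DosageScaler,
    PatchPlan,
    TokenBatch,
    fpe_tokenize,
    make_patch_plan,
    sie_tokenize,
    spe_tokenize,
)


# ---------------------------------------------------------------------------
# splits & metrics
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    train_val_ids: list[str]
    test_ids: list[str]
    folds: list[list[str]]      # disjoint validation partitions of train_val
    seed: int = 0

    def fold_train(self, f: int) -> list[str]:
        val = set(self.folds[f])
        return [s for s in self.train_val_ids if s not in val]


def make_split(ids: Sequence[str], seed: int = 0, n_folds: int = 5,
               test_frac: float = 0.2) -> SplitPlan:
    """Seeded 80/20 partition plus ``n_folds`` disjoint validation folds."""
    ids = list(ids)
    if len(ids) < 10:
        raise ConfigError("need >= 10 samples to split")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(round(test_frac * len(ids)))
    test_ids = sorted(perm[:n_test])
    train_val = perm[n_test:]
    if len(train_val) < n_folds:
        raise ConfigError(f"too few samples for {n_folds} folds")
    folds = [sorted(train_val[f::n_folds]) for f in range(n_folds)]
    return SplitPlan(train_val_ids=sorted(train_val), test_ids=test_ids,
                     folds=folds, seed=seed)


def split_report(plan: SplitPlan, pheno: PhenotypeTable, trait: str) -> dict:
    """Train/test distribution-consistency check (mean, sd, KS statistic)."""
    y_tr = pheno.values_for(plan.train_val_ids, trait)
    y_te = pheno.values_for(plan.test_ids, trait)
    ks = stats.ks_2samp(y_tr, y_te)
    return {
        "train_mean": float(np.mean(y_tr)), "train_sd": float(np.std(y_tr)),
        "test_mean": float(np.mean(y_te)), "test_sd": float(np.std(y_te)),
        "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
    }


@dataclass
class EvalMetrics:
    r: float
    R2: float
    mse: float
    constant_prediction: bool = False

    def as_dict(self) -> dict:
        return {"r": self.r, "R2": self.R2, "mse": self.mse}


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    """Pearson r (0 by convention if either side is constant),
    R2 = 1 - SS_res/SS_tot, and mean squared error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ContractError("y_true and y_pred must be equal-length 1-D")
    if y_true.size < 2:
        raise ContractError("need >= 2 observations")
    mse = float(np.mean((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    R2 = 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    const = np.std(y_true) == 0 or np.std(y_pred) == 0
    r = 0.0 if const else float(np.corrcoef(y_true, y_pred)[0, 1])
    return EvalMetrics(r=r, R2=R2, mse=mse, constant_prediction=bool(const))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 0.01
    batch_size: int = 64
    max_epochs: int = 300
    patience: int = 20
    t_max: int | None = None       # cosine period; defaults to max_epochs
    seed: int = 0

    def validate(self) -> None:
        if self.patience >= self.max_epochs:
            raise ConfigError("patience must be < max_epochs")


@dataclass
class FoldData:
    """Preprocessed inputs for one training/evaluation pair."""

    X_train: np.ndarray            # standardized full-panel rows (n_tr, m)
    y_train: np.ndarray            # standardized phenotype
    X_val: np.ndarray
    y_val: np.ndarray
    grm_train: np.ndarray | None   # (n_tr, n_ref)
    grm_val: np.ndarray | None
    selection: sel_mod.SelectionResult
    plan: PatchPlan | None
    embedding: str = "spe"         # spe | fpe | sie


@dataclass
class FitResult:
    model: GViTGP
    history: list[dict]
    best_epoch: int
    best_val_mse: float
    val_metrics: EvalMetrics
    attention: list[AttentionRecord] = field(default_factory=list)
    selection: sel_mod.SelectionResult | None = None
    plan: PatchPlan | None = None


def _tokenize(model: GViTGP, X: np.ndarray, fold: FoldData) -> TokenBatch | None:
    P = model.params
    if model.cfg.variant == "grm_mlp":
        return None
    if fold.embedding == "spe":
        return spe_tokenize(X, fold.selection, fold.plan,
                            P["embed.W"], P["embed.b"], P["embed.cls"])
    if fold.embedding == "fpe":
        return fpe_tokenize(X, fold.plan, P["embed.W"], P["embed.b"], P["embed.cls"])
    if fold.embedding == "sie":
        return sie_tokenize(X, fold.selection, P["embed.W"], P["embed.b"],
                            P["embed.cls"])
    raise ConfigError(f"unknown embedding {fold.embedding!r}")


def predict(model: GViTGP, X: np.ndarray, grm_vectors: np.ndarray | None,
            fold: FoldData, record_attention: bool = False
            ) -> tuple[np.ndarray, list[AttentionRecord]]:
    tokens = _tokenize(model, X, fold)
    out, records = model.forward(tokens, grm_vectors, training=False,
                                 record_attention=record_attention)
    return out.data.copy(), records


def build_model(cfg: ModelConfig, fold: FoldData, seed: int = 0) -> GViTGP:
    if fold.embedding == "sie":
        patch_in, S_max = 1, fold.selection.k + 1
    else:
        patch_in, S_max = fold.plan.P, fold.plan.N_p + 1
    return GViTGP(cfg, patch_in=patch_in, S_max=S_max, seed=seed)


def train_model(variant: str, fold: FoldData, model_cfg: ModelConfig,
                train_cfg: TrainConfig) -> FitResult:
    """Minimize MSE with AdamW + cosine annealing; early-stop on val MSE and
    restore the best-validation weights."""
    train_cfg.validate()
    cfg = replace(model_cfg, variant=variant)
    if cfg.variant != "gvit_base" and fold.grm_train is not None:
        cfg = replace(cfg, n_ref=fold.grm_train.shape[1])
    model = build_model(cfg, fold, seed=train_cfg.seed)
    opt = AdamW(model.params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed + 7)
    t_max = train_cfg.t_max or train_cfg.max_epochs

    n = fold.X_train.shape[0]
    needs_grm = cfg.variant in ("gvit_gp", "grm_mlp", "gvit_concat")
    best_state, best_val, best_epoch = clone_params(model.params), np.inf, -1
    history: list[dict] = []
    bad_epochs = 0
    for epoch in range(train_cfg.max_epochs):
        lr = cosine_lr(train_cfg.lr, epoch, t_max)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            Xb = fold.X_train[idx]
            gb = fold.grm_train[idx] if needs_grm else None
            tokens = _tokenize(model, Xb, fold)
            pred, _ = model.forward(tokens, gb, training=True, rng=rng)
            loss = mse_loss(pred, fold.y_train[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}, lr {lr:.3g}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            losses.append(float(loss.data))
        val_pred, _ = predict(model, fold.X_val,
                              fold.grm_val if needs_grm else None, fold)
        val_mse = float(np.mean((val_pred - fold.y_val) ** 2))
        history.append({"epoch": epoch, "lr": lr,
                        "train_mse": float(np.mean(losses)), "val_mse": val_mse})
        if val_mse < best_val - 1e-12:
            best_val, best_epoch = val_mse, epoch
            best_state = clone_params(model.params)
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > train_cfg.patience:
                break
    load_params(model.params, best_state)
    val_pred, att = predict(model, fold.X_val,
                            fold.grm_val if needs_grm else None, fold,
                            record_attention=True)
    return FitResult(
        model=model, history=history, best_epoch=best_epoch,
        best_val_mse=best_val, val_metrics=compute_metrics(fold.y_val, val_pred),
        attention=att, selection=fold.selection, plan=fold.plan,
    )


# ---------------------------------------------------------------------------
# fold assembly (nested selection + fold-aware GRM + scalers)
# ---------------------------------------------------------------------------


def _select(strategy: str, g_tr: GenotypeMatrix, y_tr: np.ndarray,
            allowed: list[str], seed: int,
            k_match: int | None) -> sel_mod.SelectionResult:
    if strategy == "gbdt":
        return sel_mod.select_gbdt(g_tr, y_tr, seed=seed, allowed_ids=allowed)
    if k_match is None:
        k_match = sel_mod.select_gbdt(g_tr, y_tr, seed=seed, allowed_ids=allowed).k
    if strategy == "linear_svr":
        return sel_mod.select_linear_svr(g_tr, y_tr, k=k_match, seed=seed,
                                         allowed_ids=allowed)
    if strategy == "gwas_ld":
        return sel_mod.select_gwas_ld(g_tr, y_tr, k=k_match, allowed_ids=allowed)
    raise ConfigError(f"unknown selection strategy {strategy!r}")


def build_fold(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    train_ids: list[str],
    eval_ids: list[str],
    strategy: str = "gbdt",
    embedding: str = "spe",
    N_p: int = 400,
    seed: int = 0,
    k_match: int | None = None,
    selection: sel_mod.SelectionResult | None = None,
) -> FoldData:
    """Assemble leakage-free fold inputs.

    Selection, allele frequencies, dosage scaling and phenotype
    standardization all come from ``train_ids`` only. A precomputed
    ``selection`` may be passed to share one selection across ablation arms;
    it must have been trained on exactly this cohort.
    """
    if set(train_ids) & set(eval_ids):
        raise LeakageError("train/eval overlap in fold construction")
    g_tr = g.subset_samples(train_ids)
    y_tr_raw = pheno.values_for(train_ids, trait)
    mu, sd = float(np.mean(y_tr_raw)), float(np.std(y_tr_raw))
    if sd == 0:
        raise ConfigError("constant training phenotype")
    y_tr = (y_tr_raw - mu) / sd
    y_ev = (pheno.values_for(eval_ids, trait) - mu) / sd if eval_ids else np.empty(0)

    if selection is None:
        selection = _select(strategy, g_tr, y_tr, list(train_ids), seed, k_match)
    elif set(selection.trained_on) - set(train_ids):
        raise LeakageError("shared selection was trained outside this fold")

    feats, eval_vecs = grm_mod.fold_grm_features(g, train_ids, eval_ids)
    scaler = DosageScaler.fit(g_tr.dosages, two_p=2.0 * feats.freqs.p)
    X_tr = scaler.transform(g_tr.dosages)
    X_ev = (scaler.transform(g.subset_samples(eval_ids).dosages)
            if eval_ids else np.empty((0, g.n_markers)))

    if embedding == "fpe":
        plan = make_patch_plan(g.n_markers, N_p)
    elif embedding == "sie":
        plan = None
    else:
        plan = make_patch_plan(selection.k, N_p)
    return FoldData(
        X_train=X_tr, y_train=y_tr, X_val=X_ev, y_val=y_ev,
        grm_train=feats.G_ref, grm_val=eval_vecs,
        selection=selection, plan=plan, embedding=embedding,
    )


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


def run_protocol(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    variant: str = "gvit_gp",
    strategy: str = "gbdt",
    embedding: str = "spe",
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    N_p: int = 400,
    seed: int = 0,
    cv_folds: int = 5,
) -> dict:
    """80/20 split with fold-nested selection and fold-aware GRM features.

    Per CV fold: select on the fold's training partition, build its GRM
    features and scalers, train, evaluate on the fold's validation partition.
    Afterwards the selector and model are refit on the full 80% split (early
    stopping monitored on the first fold's validation partition) and
    evaluated once on the untouched test set. ``cv_folds=0`` skips the fold
    loop and runs only the refit + single test evaluation.
    """
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    plan = make_split(g.sample_ids, seed=seed,
                      n_folds=max(cv_folds, 2) if cv_folds else 5)
    report: dict = {
        "split": plan,
        "distribution": split_report(plan, pheno, trait),
        "folds": [],
    }
    for f in range(cv_folds):
        fold = build_fold(g, pheno, trait, plan.fold_train(f), plan.folds[f],
                          strategy=strategy, embedding=embedding, N_p=N_p,
                          seed=seed)
        fit = train_model(variant, fold, model_cfg,
                          replace(train_cfg, seed=train_cfg.seed + f))
        report["folds"].append({
            "fold": f, "k": fold.selection.k,
            "metrics": fit.val_metrics, "best_epoch": fit.best_epoch,
        })

    # Refit on the 80% split (minus one carved-out validation fold that
    # monitors early stopping — the test set is never touched), then a single
    # test evaluation through preprocessing anchored to the refit cohort.
    refit_train = plan.fold_train(0)
    refit_fold = build_fold(g, pheno, trait, refit_train, plan.folds[0],
                            strategy=strategy, embedding=embedding, N_p=N_p,
                            seed=seed)
    fit = train_model(variant, refit_fold, model_cfg, train_cfg)
    test_fold = build_fold(g, pheno, trait, refit_train, plan.test_ids,
                           strategy=strategy, embedding=embedding, N_p=N_p,
                           seed=seed, selection=refit_fold.selection)
    needs_grm = variant in ("gvit_gp", "grm_mlp", "gvit_concat")
    test_pred, att = predict(fit.model, test_fold.X_val,
                             test_fold.grm_val if needs_grm else None,
                             test_fold, record_attention=True)
    report["test"] = {
        "k": refit_fold.selection.k,
        "metrics": compute_metrics(test_fold.y_val, test_pred),
        "y_true": test_fold.y_val,
        "y_pred": test_pred,
    }
    report["fit"] = fit
    report["test_attention"] = att
    return report


def permutation_pvalue(y_true: np.ndarray, y_pred: np.ndarray,
                       n_shuffles: int = 200, seed: int = 0) -> tuple[float, float]:
    """One-sided permutation test of Pearson r against a shuffled-phenotype
    null; returns (observed r, p-value with the +1 correction)."""
    rng = np.random.default_rng(seed)
    r_obs = compute_metrics(y_true, y_pred).r
    hits = 0
    for _ in range(n_shuffles):
        y_sh = y_true[rng.permutation(y_true.size)]
        if compute_metrics(y_sh, y_pred).r >= r_obs:
            hits += 1
    return r_obs, (hits + 1.0) / (n_shuffles + 1.0)


# ---------------------------------------------------------------------------
# baselines & ablations
# ---------------------------------------------------------------------------


def gblup_ridge_baseline(
    G_train: np.ndarray,
    y_train: np.ndarray,
    G_eval_train: np.ndarray,
    lambdas: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0),
    inner_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Kernel-ridge (GBLUP-style) predictor on the GRM.

    Solves (G + lambda I) alpha = y - ybar on the training cohort, with
    lambda chosen by inner CV, and predicts eval individuals through their
    relationship vectors: yhat = ybar + G_eval,train alpha.
    """
    y = np.asarray(y_train, dtype=float)
    n = y.size
    if G_train.shape != (n, n):
        raise ContractError("G_train shape mismatch with y_train")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    best_lam, best_err = None, np.inf
    for lam in lambdas:
        errs = []
        for f in range(inner_folds):
            val = perm[f::inner_folds]
            tr = np.setdiff1d(perm, val)
            ybar = y[tr].mean()
            try:
                alpha = np.linalg.solve(
                    G_train[np.ix_(tr, tr)] + lam * np.eye(tr.size), y[tr] - ybar
                )
            except np.linalg.LinAlgError as e:
                raise ConfigError(f"singular GBLUP system at lambda={lam}") from e
            pred = ybar + G_train[np.ix_(val, tr)] @ alpha
            errs.append(np.mean((pred - y[val]) ** 2))
        if np.mean(errs) < best_err:
            best_err, best_lam = float(np.mean(errs)), lam
    ybar = y.mean()
    alpha = np.linalg.solve(G_train + best_lam * np.eye(n), y - ybar)
    return ybar + np.asarray(G_eval_train) @ alpha


def run_ablation(
    which: str,
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    trait: str,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    N_p: int = 400,
    seeds: Sequence[int] = (0,),
) -> dict:
    """Compare arms under identical splits and seeds.

    ``which`` is ``embedding`` ({spe, sie, fpe} on the gvit_gp backbone),
    ``fusion`` ({gvit_base, grm_mlp, gvit_concat, gvit_gp} with SPE), or
    ``selection`` ({gbdt, linear_svr, gwas_ld} at the GBDT-matched k).
    Returns per-arm, per-seed test metrics and per-arm means.
    """
    if which == "embedding":
        arms = [("spe", "gvit_gp", "gbdt"), ("sie", "gvit_gp", "gbdt"),
                ("fpe", "gvit_gp", "gbdt")]
        labels = ["spe", "sie", "fpe"]
    elif which == "fusion":
        arms = [("spe", v, "gbdt")
                for v in ("gvit_base", "grm_mlp", "gvit_concat", "gvit_gp")]
        labels = ["gvit_base", "grm_mlp", "gvit_concat", "gvit_gp"]
    elif which == "selection":
        arms = [("spe", "gvit_gp", s) for s in ("gbdt", "linear_svr", "gwas_ld")]
        labels = ["gbdt", "linear_svr", "gwas_ld"]
    else:
        raise ConfigError(f"unknown ablation {which!r}")

    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    records: dict[str, list[dict]] = {lab: [] for lab in labels}
    for seed in seeds:
        plan = make_split(g.sample_ids, seed=seed)
        refit_train = plan.fold_train(0)
        # the GBDT fold selection is shared where arms must match on k
        gbdt_sel = None
        for (embedding, variant, strategy), lab in zip(arms, labels):
            k_match = None
            shared = None
            if strategy == "gbdt":
                if gbdt_sel is None:
                    g_tr = g.subset_samples(refit_train)
                    y_raw = pheno.values_for(refit_train, trait)
                    y_std = (y_raw - y_raw.mean()) / y_raw.std()
                    gbdt_sel = sel_mod.select_gbdt(
                        g_tr, y_std, seed=seed, allowed_ids=refit_train)
                shared = gbdt_sel
            elif gbdt_sel is not None:
                k_match = gbdt_sel.k
            fold = build_fold(g, pheno, trait, refit_train, plan.folds[0],
                              strategy=strategy, embedding=embedding, N_p=N_p,
                              seed=seed, k_match=k_match, selection=shared)
            fit = train_model(variant, fold,
                              replace(model_cfg, variant=variant),
                              replace(train_cfg, seed=seed))
            test_fold = build_fold(g, pheno, trait, refit_train, plan.test_ids,
                                   strategy=strategy, embedding=embedding,
                                   N_p=N_p, seed=seed, selection=fold.selection)
            needs_grm = variant in ("gvit_gp", "grm_mlp", "gvit_concat")
            pred, _ = predict(fit.model, test_fold.X_val,
                              test_fold.grm_val if needs_grm else None,
                              test_fold)
            m = compute_metrics(test_fold.y_val, pred)
            records[lab].append({
                "seed": seed, "k": fold.selection.k, "metrics": m,
            })
    if which == "selection":
        k_by_seed: dict[int, set[int]] = {}
        for lab in labels:
            for rec in records[lab]:
                k_by_seed.setdefault(rec["seed"], set()).add(rec["k"])
        bad = {s: ks for s, ks in k_by_seed.items() if len(ks) > 1}
        if bad:
            raise ContractError(f"mismatched k across selection arms: {bad}")
    means = {
        lab: {
            "r": float(np.mean([rec["metrics"].r for rec in records[lab]])),
            "R2": float(np.mean([rec["metrics"].R2 for rec in records[lab]])),
            "mse": float(np.mean([rec["metrics"].mse for rec in records[lab]])),
        }
        for lab in labels
    }
    return {"which": which, "records": records, "means": means}
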