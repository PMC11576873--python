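"""Cross-validated model selection and repeat-averaged final fitting.

The grid spans model class ('gmm', 'hmm', 'arhmm'), state count K and lag
L.  Videos (not frames) are partitioned into folds, optionally at the
participant level.  Per grid cell and fold the model is fit on the
training folds and scored by mean per-frame held-out log-likelihood and
by AIC on the held-out data.

Final fitting repeats EM from independent seeds and averages parameters
after resolving label switching with a Hungarian assignment between
per-state parameter blocks.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import arhmm
from .arhmm import ARHMMParams, FitResult
from .principal_movements import PMSeries

MODEL_CLASSES = ("gmm", "hmm", "arhmm")


def _class_settings(model_class: str, L: int) -> tuple[int, bool]:
    """(effective lag, tied_transitions) for a model class."""
    if model_class == "arhmm":
        if L < 1:
            raise ValueError("arhmm requires L >= 1")
        return L, False
    if model_class == "hmm":
        return 0, False
    if model_class == "gmm":
        return 0, True
    raise ValueError(f"unknown model class {model_class!r}")


def _as_arrays(videos) -> list[np.ndarray]:
    return [v.velocity if isinstance(v, PMSeries) else np.asarray(v, float) for v in videos]


def cv_grid_search(
    videos: list,
    grid: list[tuple[str, int, int]],
    folds: int = 5,
    seed: int = 0,
    participant_ids: list[str] | None = None,
    max_iter: int = 150,
    tol: float = 1e-6,
    mode: str = "full",
) -> pd.DataFrame:
    """Grid search with video-level K-fold cross-validation.

    ``grid`` holds (model_class, K, L) cells.  Returns a tidy table with
    one row per cell and fold: mean per-frame test log-likelihood and
    AIC evaluated on the held-out videos.
    """
    xs = _as_arrays(videos)
    n = len(xs)
    if n < folds:
        raise ValueError(f"need at least {folds} videos, have {n}")
    if not grid:
        raise ValueError("grid must be non-empty")
    rng = np.random.default_rng(seed)
    if participant_ids is not None:
        pids = np.asarray(participant_ids)
        if len(pids) != n:
            raise ValueError("participant_ids length mismatch")
        uniq = np.array(sorted(set(pids.tolist())))
        if len(uniq) < n:
            raise ValueError(
                "duplicate participants across videos: model selection expects "
                "one video per participant"
            )
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for rank, idx in enumerate(order):
        fold_of[idx] = rank % folds

    rows = []
    for model_class, K, L in grid:
        eff_L, tied = _class_settings(model_class, L)
        for f in range(folds):
            train = [xs[i] for i in range(n) if fold_of[i] != f]
            test = [xs[i] for i in range(n) if fold_of[i] == f]
            fit = arhmm.fit_em(
                train, K=K, L=eff_L, max_iter=max_iter, tol=tol,
                seed=int(seed + 1000 * f), mode=mode, tied_transitions=tied,
            )
            test_ll = arhmm.log_likelihood(fit.params, test)
            n_frames = sum(x.shape[0] - eff_L for x in test)
            rows.append(
                {
                    "model_class": model_class,
                    "K": K,
                    "L": L,
                    "fold": f,
                    "test_ll_per_frame": test_ll / n_frames,
                    "aic": arhmm.aic(fit, test),
                    "train_ll": float(fit.loglik_trace[-1]),
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame, rule: str = "test_ll") -> tuple[str, int, int]:
    """Pick the grid cell with the best fold-averaged criterion.

    ``rule='test_ll'`` maximises mean per-frame held-out log-likelihood;
    ``rule='aic'`` minimises fold-averaged AIC.  Ties break toward
    smaller K, then smaller L.
    """
    if table.empty:
        raise ValueError("selection table is empty")
    agg = (
        table.groupby(["model_class", "K", "L"], as_index=False)
        .agg(test_ll=("test_ll_per_frame", "mean"), aic=("aic", "mean"))
    )
    if rule == "test_ll":
        agg["score"] = agg["test_ll"]
    elif rule == "aic":
        agg["score"] = -agg["aic"]
    else:
        raise ValueError(f"unknown rule {rule!r}")
    agg = agg.sort_values(["score", "K", "L"], ascending=[False, True, True])
    best = agg.iloc[0]
    return str(best["model_class"]), int(best["K"]), int(best["L"])


# ---------------------------------------------------------------------------
# state alignment and parameter averaging

def _state_blocks(params: ARHMMParams) -> np.ndarray:
    """Per-state feature vector [vec(A_k), mu_k, vech(S_k)] for matching."""
    K, d = params.K, params.d
    iu = np.triu_indices(d)
    return np.stack(
        [
            np.concatenate(
                [params.A[k].ravel(), params.mu[k], params.Sigma[k][iu]]
            )
            for k in range(K)
        ]
    )


def align_params(ref: ARHMMParams, other: ARHMMParams) -> np.ndarray:
    """Permutation p such that state p[k] of ``other`` matches state k of ref."""
    cost = np.linalg.norm(
        _state_blocks(ref)[:, None, :] - _state_blocks(other)[None, :, :], axis=2
    )
    if np.ptp(cost) < 1e-12:
        import warnings

        warnings.warn("state alignment cost degenerate; using identity", RuntimeWarning)
        return np.arange(ref.K)
    _, cols = linear_sum_assignment(cost)
    return cols


def permute_states(params: ARHMMParams, perm: np.ndarray) -> ARHMMParams:
    """Relabel states so new state k is old state perm[k]."""
    perm = np.asarray(perm, int)
    return replace(
        params,
        A=params.A[perm],
        mu=params.mu[perm],
        Sigma=params.Sigma[perm],
        Phi=params.Phi[np.ix_(perm, perm)],
        pi0=params.pi0[perm],
    )


def best_label_permutation(
    true_labels: np.ndarray, pred_labels: np.ndarray, K: int
) -> np.ndarray:
    """Permutation mapping predicted labels onto true labels (max overlap)."""
    conf = np.zeros((K, K))
    np.add.at(conf, (np.asarray(true_labels), np.asarray(pred_labels)), 1.0)
    rows, cols = linear_sum_assignment(-conf)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return perm


def refit_and_average(
    videos: list,
    model_class: str,
    K: int,
    L: int,
    repeats: int = 25,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
    mode: str = "full",
) -> ARHMMParams:
    """Repeat the final fit from independent seeds and average parameters.

    Runs are aligned to the highest-likelihood run by Hungarian matching on
    per-state parameter blocks, then averaged element-wise; transition rows
    and pi0 are renormalised and covariances checked positive-definite.
    """
    xs = _as_arrays(videos)
    eff_L, tied = _class_settings(model_class, L)
    fits: list[FitResult] = [
        arhmm.fit_em(
            xs, K=K, L=eff_L, max_iter=max_iter, tol=tol,
            seed=int(seed + r), mode=mode, tied_transitions=tied,
        )
        for r in range(repeats)
    ]
    lls = [arhmm.log_likelihood(f.params, xs) for f in fits]
    ref = fits[int(np.argmax(lls))].params
    aligned = [permute_states(f.params, align_params(ref, f.params)) for f in fits]
    A = np.mean([p.A for p in aligned], axis=0)
    mu = np.mean([p.mu for p in aligned], axis=0)
    Sigma = np.mean([p.Sigma for p in aligned], axis=0)
    Phi = np.mean([p.Phi for p in aligned], axis=0)
    pi0 = np.mean([p.pi0 for p in aligned], axis=0)
    Phi = Phi / Phi.sum(axis=1, keepdims=True)
    pi0 = pi0 / pi0.sum()
    for k in range(K):
        np.linalg.cholesky(Sigma[k])  # raises if the average lost definiteness
    return replace(ref, A=A, mu=mu, Sigma=Sigma, Phi=Phi, pi0=pi0)
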