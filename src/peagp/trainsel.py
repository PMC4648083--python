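"""Training-set optimization by the mean generalized coefficient of
determination (CDmean) of prediction contrasts.

For a candidate training set (incidence Z over the panel) and variance
ratio lambda = sigma_e^2 / sigma_g^2, the generalized CD of a contrast c is

    CD(c) = c' (G - lambda (Z'MZ + lambda G^-1)^-1) c / (c' G c)

with M the projector orthogonal to the intercept on the training dimension.
CDmean averages CD over the contrasts between each target accession and the
panel mean (c_i = e_i - 1/N).  The optimizer starts from a random set and
iteratively proposes single in/out swaps, accepting strict improvements;
the inner inverse is maintained by low-rank (Woodbury) updates with
periodic full recomputes, and a naive re-solve path is kept for checking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import RelationshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CDConfig",
    "OptimizationTrace",
    "cd_of_contrast",
    "cdmean",
    "optimize_training_set",
]


@dataclass
class CDConfig:
    lam: float = 0.01  # variance ratio sigma_e^2 / sigma_g^2
    n_iter: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("lambda must be > 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class OptimizationTrace:
    best_cdmean: np.ndarray
    accepted: np.ndarray
    final_ids: np.ndarray
    initial_cdmean: float = field(default=np.nan)


def _as_matrix(G) -> np.ndarray:
    return G.values if isinstance(G, RelationshipMatrix) else np.asarray(G, dtype=float)


def _ids_to_idx(G, ids):
    if isinstance(G, RelationshipMatrix):
        lookup = {v: i for i, v in enumerate(G.individuals)}
        return np.array([lookup[i] for i in ids], dtype=int)
    return np.asarray(ids, dtype=int)


def _stable_inv(G: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    try:
        if np.linalg.eigvalsh(G)[0] <= 0:
            logger.warning("relationship matrix not PD; adding ridge %g", ridge)
            G = G + ridge * np.eye(len(G))
        return np.linalg.inv(G)
    except np.linalg.LinAlgError:
        return np.linalg.inv(G + ridge * np.eye(len(G)))


def _inner_inverse(G_inv: np.ndarray, train_idx: np.ndarray, lam: float) -> np.ndarray:
    n = len(train_idx)
    N = len(G_inv)
    ind = np.zeros(N)
    ind[train_idx] = 1.0
    A = np.diag(ind) - np.outer(ind, ind) / n + lam * G_inv
    return np.linalg.inv(A)


def cd_of_contrast(G, train_ids, c, lam: float) -> float:
    """Generalized CD of one contrast for a given training set."""
    Gm = _as_matrix(G)
    c = np.asarray(c, dtype=float)
    if abs(c.sum()) > 1e-8 * max(1.0, np.abs(c).sum()):
        raise ValueError("contrast must sum to zero")
    train_idx = _ids_to_idx(G, train_ids)
    if len(train_idx) == 0:
        raise ValueError("training set is empty")
    denom = float(c @ Gm @ c)
    if denom <= 0:
        raise ValueError("contrast has zero variance under G")
    Ainv = _inner_inverse(_stable_inv(Gm), train_idx, lam)
    num = float(c @ (Gm @ c) - lam * c @ (Ainv @ c))
    return num / denom


def _panel_mean_contrast_stats(Gm, Ainv, lam, target_idx):
    """CD of c_i = e_i - 1/N for every target i, vectorized."""
    N = len(Gm)
    T = Gm - lam * Ainv
    t1 = T @ np.ones(N)
    g1 = Gm @ np.ones(N)
    tg = t1.sum() / N**2
    gg = g1.sum() / N**2
    num = np.diag(T)[target_idx] - 2.0 * t1[target_idx] / N + tg
    den = np.diag(Gm)[target_idx] - 2.0 * g1[target_idx] / N + gg
    return num / den


def cdmean(G, train_ids, target_ids, lam: float) -> float:
    """Mean CD of panel-mean contrasts over the target accessions."""
    target_idx = _ids_to_idx(G, target_ids)
    train_idx = _ids_to_idx(G, train_ids)
    if len(target_idx) == 0:
        raise ValueError("target set is empty")
    if set(target_idx) & set(train_idx):
        raise ValueError("target and training sets overlap")
    Gm = _as_matrix(G)
    Ainv = _inner_inverse(_stable_inv(Gm), train_idx, lam)
    return float(np.mean(_panel_mean_contrast_stats(Gm, Ainv, lam, target_idx)))


class _CDState:
    """Incremental CDmean evaluation under single-swap proposals."""

    def __init__(self, Gm, G_inv, lam, train_idx):
        self.Gm = Gm
        self.G_inv = G_inv
        self.lam = lam
        self.N = len(Gm)
        self.n_train = len(train_idx)
        self.g_diag = np.diag(Gm).copy()
        g1 = Gm @ np.ones(self.N)
        self.g_row = g1 / self.N
        self.g_grand = g1.sum() / self.N**2
        self.in_set = np.zeros(self.N, dtype=bool)
        self.in_set[train_idx] = True
        self.recompute()

    def recompute(self):
        idx = np.flatnonzero(self.in_set)
        self.Ainv = _inner_inverse(self.G_inv, idx, self.lam)
        self.Ainv_diag = np.diag(self.Ainv).copy()
        self.Ainv_1 = self.Ainv @ np.ones(self.N)

    def _cdmean_from(self, a_diag, a_row_sum, a_grand, targets):
        lam = self.lam
        num = (
            self.g_diag[targets]
            - 2 * self.g_row[targets]
            + self.g_grand
            - lam * (a_diag[targets] - 2 * a_row_sum[targets] / self.N + a_grand)
        )
        den = self.g_diag[targets] - 2 * self.g_row[targets] + self.g_grand
        return float(np.mean(num / den))

    def cdmean(self, targets):
        return self._cdmean_from(
            self.Ainv_diag, self.Ainv_1, self.Ainv_1.sum() / self.N**2, targets
        )

    def _woodbury_parts(self, a, b):
        """Low-rank pieces of the inverse after swapping a (in) for b (out)."""
        N, n = self.N, self.n_train
        ind = self.in_set.astype(float)
        ind_new = ind.copy()
        ind_new[a], ind_new[b] = 0.0, 1.0
        m = ind + ind_new
        u = np.zeros(N)
        u[b], u[a] = 1.0, -1.0
        # Delta A = e_b e_b' - e_a e_a' - (u m' + m u') / (2 n)
        Ai = self.Ainv
        Ai_m = Ai @ m
        Ai_u = Ai[:, b] - Ai[:, a]
        AiU = np.column_stack([Ai[:, b], -Ai[:, a], -Ai_u / (2 * n), -Ai_m / (2 * n)])
        AiV = np.column_stack([Ai[:, b], Ai[:, a], Ai_m, Ai_u])
        V = np.column_stack([np.eye(N)[:, b], np.eye(N)[:, a], m, u])
        S4 = np.eye(4) + V.T @ AiU
        B = AiU @ np.linalg.inv(S4)
        return B, AiV

    def propose(self, a, b, targets):
        """CDmean after the swap, without committing it."""
        B, AiV = self._woodbury_parts(a, b)
        a_diag = self.Ainv_diag - np.sum(B * AiV, axis=1)
        corr1 = B @ (AiV.sum(axis=0))
        a_row = self.Ainv_1 - corr1
        a_grand = a_row.sum() / self.N**2
        return self._cdmean_from(a_diag, a_row, a_grand, targets), (B, AiV)

    def commit(self, a, b, parts):
        # proposals are a single Woodbury step off an exact inverse; commits
        # re-solve exactly so no low-rank drift accumulates across swaps
        del parts
        self.in_set[a], self.in_set[b] = False, True
        self.recompute()


def optimize_training_set(
    G,
    size: int,
    mode: str = "within_panel",
    cfg: CDConfig | None = None,
    test_ids=None,
    fast: bool = True,
    recompute_every: int = 50,
):
    """Exchange optimization of a training set maximizing CDmean.

    Modes
    -----
    ``within_panel`` : a test set is held out; the training set is sampled
        from the remaining accessions.  Targets are the accessions outside
        the training set when ``size`` saturates the eligible pool, and the
        accessions in neither the training nor the test set otherwise.
    ``cross_population`` : no held-out set; targets are all non-training
        accessions (the contrast with the external test population is not
        part of the criterion).

    Returns ``(selected_ids, OptimizationTrace)``.
    """
    cfg = cfg or CDConfig()
    Gm = _as_matrix(G)
    N = len(Gm)
    rng = np.random.default_rng(cfg.seed)
    ids = G.individuals if isinstance(G, RelationshipMatrix) else np.arange(N)

    if mode == "within_panel":
        if test_ids is None:
            raise ValueError("within_panel mode needs test_ids")
        test_idx = _ids_to_idx(G, test_ids)
        eligible = np.setdiff1d(np.arange(N), test_idx)
    elif mode == "cross_population":
        test_idx = np.array([], dtype=int)
        eligible = np.arange(N)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if size > len(eligible):
        raise ValueError(f"size {size} exceeds {len(eligible)} eligible accessions")

    train = rng.choice(eligible, size=size, replace=False)
    in_train = np.zeros(N, dtype=bool)
    in_train[train] = True

    def targets_of(in_train_mask):
        out = ~in_train_mask
        if mode == "within_panel" and size < len(eligible):
            out = out.copy()
            out[test_idx] = False
        return np.flatnonzero(out)

    if len(np.setdiff1d(eligible, train)) == 0:
        logger.warning("training set saturates the eligible pool; nothing to swap")
        tr = OptimizationTrace(
            best_cdmean=np.full(cfg.n_iter, np.nan),
            accepted=np.zeros(cfg.n_iter, dtype=bool),
            final_ids=ids[np.sort(train)],
        )
        return ids[np.sort(train)], tr

    G_inv = _stable_inv(Gm)
    state = _CDState(Gm, G_inv, cfg.lam, train)
    current = state.cdmean(targets_of(in_train))
    best_hist = np.empty(cfg.n_iter)
    accepted = np.zeros(cfg.n_iter, dtype=bool)
    initial = current
    best_value, best_mask = current, in_train.copy()
    # restart from a fresh random set when the greedy search stalls; the
    # returned set is the best over all iterations and restarts
    stall_limit = max(40, 2 * size)
    stall = 0

    for it in range(cfg.n_iter):
        inside = np.flatnonzero(in_train)
        outside = np.setdiff1d(eligible, inside)
        a = inside[rng.integers(len(inside))]
        b = outside[rng.integers(len(outside))]
        prop_mask = in_train.copy()
        prop_mask[a], prop_mask[b] = False, True
        tgt = targets_of(prop_mask)
        if fast:
            value, parts = state.propose(a, b, tgt)
        else:
            idx_new = np.flatnonzero(prop_mask)
            Ainv_new = _inner_inverse(G_inv, idx_new, cfg.lam)
            value = float(
                np.mean(_panel_mean_contrast_stats(Gm, Ainv_new, cfg.lam, tgt))
            )
        if value > current:
            current = value
            in_train = prop_mask
            accepted[it] = True
            stall = 0
            if fast:
                state.commit(a, b, parts)
            else:
                state = _CDState(Gm, G_inv, cfg.lam, np.flatnonzero(in_train))
            if current > best_value:
                best_value, best_mask = current, in_train.copy()
        else:
            stall += 1
            if stall >= stall_limit:
                stall = 0
                train = rng.choice(eligible, size=size, replace=False)
                in_train = np.zeros(N, dtype=bool)
                in_train[train] = True
                state = _CDState(Gm, G_inv, cfg.lam, train)
                current = state.cdmean(targets_of(in_train))
        best_hist[it] = best_value

    final = ids[np.sort(np.flatnonzero(best_mask))]
    trace = OptimizationTrace(
        best_cdmean=best_hist,
        accepted=accepted,
        final_ids=final,
        initial_cdmean=initial,
    )
    return final, trace
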