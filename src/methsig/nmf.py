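"""Methylation-signature extraction by nonnegative matrix factorization.

A probes x samples matrix V of beta values (or 1 - beta) is decomposed as
V ~ E H with E (probes x k) the signature weight matrix and H (k x samples)
the activity matrix, both nonnegative.  After normalization each E column
sums to one, so a signature is a convex weighting over its DMPs and H picks
up the scale.

The factorization uses multiplicative updates (Lee-Seung) under either the
generalized Kullback-Leibler divergence (default) or the squared Frobenius
norm, restarted ``n_runs`` times from random nonnegative initializations;
the run with the lowest objective wins.  The rank k is selected by consensus
clustering over runs: samples co-cluster when assigned to the same signature
by maximal activity, and the cophenetic correlation plus average silhouette
width of the consensus matrix measure the stability of each candidate rank.

Projection of fixed signatures onto a new cohort solves a nonnegative least
squares problem per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import silhouette_score
from sklearn.metrics.pairwise import cosine_similarity

_EPS = 1e-10


@dataclass
class SignatureModel:
    """Fitted factorization V ~ E H.

    E is probes x k (column-stochastic after :func:`normalize_model`); H is
    k x samples.  ``orientation`` records whether the input was beta or
    1 - beta.
    """

    E: pd.DataFrame
    H: pd.DataFrame
    k: int
    orientation: str = "beta"
    objective: str = "kl"
    n_runs: int = 1
    seed: int = 0
    reconstruction_error: float = float("nan")
    objective_trace: np.ndarray = field(
        default_factory=lambda: np.array([])
    )

    @property
    def probe_ids(self) -> pd.Index:
        return self.E.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.H.columns


@dataclass
class RankDiagnostics:
    """Consensus-stability diagnostics over candidate ranks."""

    k_values: np.ndarray
    cophenetic: np.ndarray
    silhouette: np.ndarray
    chosen_k: int | None = None


def _kl_constants(V):
    mask = V > 0
    Vm = V[mask]
    return {
        "mask": mask,
        "Vm": Vm,
        "Vsum": float(np.sum(V)),
        "VlogV": float(np.sum(Vm * np.log(Vm))),
    }


def _objective(V, W, H, objective, kl_const=None):
    WH = W @ H
    if objective == "frobenius":
        return 0.5 * float(np.sum((V - WH) ** 2))
    # generalized KL: sum(V log(V / WH) - V + WH), 0 log 0 = 0
    c = kl_const if kl_const is not None else _kl_constants(V)
    val = float(np.sum(WH)) - c["Vsum"] + c["VlogV"]
    val -= float(np.sum(c["Vm"] * np.log(np.maximum(WH[c["mask"]], _EPS))))
    return val


def _mu_run(V, k, rng, objective, max_iter, tol):
    p, n = V.shape
    scale = np.sqrt(max(V.mean(), _EPS) / k)
    W = rng.random((p, k)) * scale + _EPS
    H = rng.random((k, n)) * scale + _EPS
    kl_const = _kl_constants(V) if objective == "kl" else None
    trace = [_objective(V, W, H, objective, kl_const)]
    check_every = 20
    for it in range(1, max_iter + 1):
        if objective == "frobenius":
            H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
            W *= (V @ H.T) / np.maximum(W @ H @ H.T, _EPS)
        else:
            WH = np.maximum(W @ H, _EPS)
            H *= (W.T @ (V / WH)) / np.maximum(
                W.sum(axis=0)[:, None], _EPS
            )
            WH = np.maximum(W @ H, _EPS)
            W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if it % check_every == 0 or it == max_iter:
            obj = _objective(V, W, H, objective, kl_const)
            trace.append(obj)
            prev = trace[-2]
            denom = max(abs(trace[0]), _EPS)
            if abs(prev - obj) / denom < tol:
                break
    return W, H, np.array(trace)


def nmf_factorize(
    V,
    k: int,
    n_runs: int = 30,
    seed: int = 0,
    objective: str = "kl",
    max_iter: int = 200,
    tol: float = 1e-6,
    orientation: str = "beta",
) -> SignatureModel:
    """Best-of-``n_runs`` multiplicative-update NMF of a nonnegative matrix.

    Each run starts from its own random nonnegative initialization (run
    seeds derived from ``seed``); the run with the lowest objective is kept
    and column-normalized.  Deterministic given (seed, n_runs, k).
    """
    V_df = V if isinstance(V, pd.DataFrame) else pd.DataFrame(np.asarray(V))
    A = V_df.to_numpy(dtype=float)
    if np.any(A < 0):
        raise ValueError("input matrix must be nonnegative")
    if not np.any(A > 0):
        raise ValueError("input matrix is all zero")
    if k < 1:
        raise ValueError("rank k must be >= 1")
    if k > min(A.shape):
        raise ValueError(f"rank k={k} exceeds matrix dimensions {A.shape}")
    if objective not in ("kl", "frobenius"):
        raise ValueError("objective must be 'kl' or 'frobenius'")

    best = None
    for run in range(n_runs):
        rng = np.random.default_rng([seed % (2**31), run, k])
        W, H, trace = _mu_run(A, k, rng, objective, max_iter, tol)
        obj = trace[-1]
        if best is None or obj < best[3]:
            best = (W, H, trace, obj)
    W, H, trace, _ = best
    err = float(
        np.linalg.norm(A - W @ H) / max(np.linalg.norm(A), _EPS)
    )
    model = SignatureModel(
        E=pd.DataFrame(
            W, index=V_df.index, columns=[f"MS{i + 1}" for i in range(k)]
        ),
        H=pd.DataFrame(
            H, index=[f"MS{i + 1}" for i in range(k)], columns=V_df.columns
        ),
        k=k,
        orientation=orientation,
        objective=objective,
        n_runs=n_runs,
        seed=seed,
        reconstruction_error=err,
        objective_trace=trace,
    )
    return normalize_model(model)


def normalize_model(m: SignatureModel) -> SignatureModel:
    """Rescale so each E column sums to 1, moving the scale into H.

    The product E H is unchanged; idempotent.
    """
    sums = m.E.sum(axis=0).to_numpy()
    if np.any(sums <= 0):
        raise ValueError("cannot normalize an all-zero signature column")
    E = m.E / sums
    H = m.H.mul(sums, axis=0)
    return SignatureModel(
        E=E,
        H=H,
        k=m.k,
        orientation=m.orientation,
        objective=m.objective,
        n_runs=m.n_runs,
        seed=m.seed,
        reconstruction_error=m.reconstruction_error,
        objective_trace=m.objective_trace,
    )


def assign_dmps_and_samples(
    m: SignatureModel, top_n: int = 100
) -> tuple[pd.Series, pd.Series, dict[str, pd.Index]]:
    """Hard assignments by maximal weight / activity.

    Each probe goes to the signature with the largest E-row entry and each
    sample to the signature with the largest H-column entry (ties break
    toward the lowest signature index).  Also returns the ``top_n`` most
    highly weighted probes per signature (the signature's up-/down-DMPs,
    depending on orientation).
    """
    probe_assign = pd.Series(
        m.E.columns[m.E.to_numpy().argmax(axis=1)],
        index=m.E.index,
        name="signature",
    )
    sample_assign = pd.Series(
        m.H.index[m.H.to_numpy().argmax(axis=0)],
        index=m.H.columns,
        name="signature",
    )
    top = {
        sig: m.E[sig].nlargest(top_n).index for sig in m.E.columns
    }
    return probe_assign, sample_assign, top


def signature_similarity(
    E1: pd.DataFrame, E2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str, float]]]:
    """Cosine and Spearman similarity between two signature weight sets.

    Probe universes are intersected and row-aligned first.  Matching is
    greedy by descending cosine similarity, each signature used once.
    """
    common = E1.index.intersection(E2.index)
    if len(common) == 0:
        raise ValueError("signature sets share no probes")
    A = E1.loc[common].to_numpy().T
    B = E2.loc[common].to_numpy().T
    cos = pd.DataFrame(
        cosine_similarity(A, B), index=E1.columns, columns=E2.columns
    )
    rho = pd.DataFrame(
        [
            [float(spearmanr(a, b).statistic) for b in B]
            for a in A
        ],
        index=E1.columns,
        columns=E2.columns,
    )
    matching = []
    used1: set = set()
    used2: set = set()
    order = (
        cos.stack().sort_values(ascending=False).index.tolist()
    )
    for s1, s2 in order:
        if s1 in used1 or s2 in used2:
            continue
        matching.append((s1, s2, float(cos.loc[s1, s2])))
        used1.add(s1)
        used2.add(s2)
    return cos, rho, matching


def project_signatures(
    V_new, E, min_probe_overlap: float = 0.5
) -> pd.DataFrame:
    """Nonnegative least-squares projection of fixed signatures.

    Solves ``min_{h >= 0} ||E h - v||_2`` per sample column of ``V_new``,
    after intersecting the probe universe with E's probes.  Errors when
    fewer than ``min_probe_overlap`` of E's probes are present.
    """
    E_df = E if isinstance(E, pd.DataFrame) else pd.DataFrame(np.asarray(E))
    V_df = (
        V_new
        if isinstance(V_new, pd.DataFrame)
        else pd.DataFrame(np.asarray(V_new))
    )
    common = E_df.index.intersection(V_df.index)
    frac = len(common) / len(E_df.index)
    if frac < min_probe_overlap:
        raise ValueError(
            f"only {frac:.1%} of signature probes present in the new matrix "
            f"(floor {min_probe_overlap:.0%})"
        )
    A = E_df.loc[common].to_numpy(dtype=float)
    B = V_df.loc[common].to_numpy(dtype=float)
    H = np.column_stack([nnls(A, B[:, i])[0] for i in range(B.shape[1])])
    return pd.DataFrame(H, index=E_df.columns, columns=V_df.columns)


def _consensus_matrix(V, k, n_runs, seed, objective, max_iter, tol):
    n = V.shape[1]
    C = np.zeros((n, n))
    for run in range(n_runs):
        rng = np.random.default_rng([seed % (2**31), run, k, 7])
        _, H, _ = _mu_run(
            np.asarray(V, float), k, rng, objective, max_iter, tol
        )
        labels = H.argmax(axis=0)
        C += labels[:, None] == labels[None, :]
    return C / n_runs


def rank_survey(
    V,
    k_range=range(2, 9),
    n_runs: int = 30,
    seed: int = 0,
    objective: str = "kl",
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RankDiagnostics:
    """Consensus-clustering stability of each candidate rank.

    For each k, n_runs factorizations are run; the consensus matrix holds
    the fraction of runs in which two samples share an argmax-activity
    signature.  Cophenetic correlation compares consensus distances (1 - C)
    with the cophenetic distances of their average-linkage dendrogram; the
    silhouette is the average width of the k-cut of that dendrogram against
    consensus distances.  k = 1 records a missing silhouette and is excluded
    from selection.
    """
    if n_runs < 2:
        raise ValueError("consensus needs n_runs >= 2")
    ks = np.array(sorted(k_range))
    A = V.to_numpy(float) if isinstance(V, pd.DataFrame) else np.asarray(V, float)
    coph = np.full(len(ks), np.nan)
    sil = np.full(len(ks), np.nan)
    for i, k in enumerate(ks):
        if k < 1 or k > min(A.shape):
            raise ValueError(f"invalid rank {k} for shape {A.shape}")
        C = _consensus_matrix(A, k, n_runs, seed, objective, max_iter, tol)
        D = 1.0 - C
        dvec = squareform(D, checks=False)
        Z = sch.linkage(dvec, method="average")
        if np.ptp(dvec) < 1e-12:
            # all pairwise consensus distances equal: trivially ultrametric
            coph[i] = 1.0
        else:
            coph[i], _ = sch.cophenet(Z, dvec)
        if k >= 2:
            labels = sch.fcluster(Z, k, criterion="maxclust")
            if len(np.unique(labels)) >= 2:
                sil[i] = silhouette_score(D, labels, metric="precomputed")
    return RankDiagnostics(k_values=ks, cophenetic=coph, silhouette=sil)


def select_rank(
    d: RankDiagnostics,
    cophenetic_floor: float = 0.95,
    silhouette_floor: float = 0.80,
    drop_tol: float = 0.05,
) -> int:
    """Pick a rank from consensus diagnostics.

    Candidate ranks must exceed both stability floors (ranks with a missing
    silhouette, e.g. k = 1, are excluded).  If the cophenetic profile shows
    a sustained drop (a fall of more than ``drop_tol`` that never recovers),
    the largest candidate before the drop wins; with no drop, the candidate
    with the highest silhouette wins (consensus can stay cophenetically
    stable both below and above the true rank, where merges and splits are
    consistent across runs, but the silhouette peaks where the clusters are
    tightest).  Ties break toward the smaller rank.
    """
    ks, coph, sil = d.k_values, d.cophenetic, d.silhouette
    usable = ~np.isnan(sil) & ~np.isnan(coph)
    eligible = usable & (coph > cophenetic_floor) & (sil > silhouette_floor)
    if not eligible.any():
        warnings.warn(
            "no rank passes the stability floors; falling back to the "
            "cophenetic argmax",
            stacklevel=2,
        )
        pool = np.where(usable)[0]
        if pool.size == 0:
            pool = np.arange(len(ks))
        best = pool[np.argmax(np.nan_to_num(coph[pool], nan=-2.0))]
        d.chosen_k = int(ks[best])
        return d.chosen_k
    idx = np.where(usable)[0]
    drop_at = None
    for j in range(1, len(idx)):
        ref = coph[idx[j - 1]]
        if all(coph[idx[m]] < ref - drop_tol for m in range(j, len(idx))):
            drop_at = ks[idx[j]]
            break
    cand = [k for k, e in zip(ks, eligible) if e]
    if drop_at is not None:
        before = [k for k in cand if k < drop_at]
        chosen = max(before) if before else min(cand)
    else:
        cand_sil = {k: sil[list(ks).index(k)] for k in cand}
        best = max(cand_sil.values())
        chosen = min(k for k, s in cand_sil.items() if s >= best - 1e-12)
    d.chosen_k = int(chosen)
    return d.chosen_k


def compare_beta_orientation(
    V,
    k: int,
    n_runs: int = 10,
    seed: int = 0,
    objective: str = "kl",
    max_iter: int = 500,
) -> pd.DataFrame:
    """Factorize both beta and 1 - beta at the same rank and match signatures.

    Signatures are matched across orientations by the absolute Spearman
    correlation of their activity rows (raw-cosine matching is dominated by
    the shared activity offset and pairs signatures arbitrarily); the signed
    per-pair Spearman correlation is reported — complement-derived
    activities may mirror the originals with flipped sign.  A constant input
    is flagged and yields missing correlations.
    """
    V_df = V if isinstance(V, pd.DataFrame) else pd.DataFrame(np.asarray(V))
    arr = V_df.to_numpy(float)
    if np.ptp(arr) < 1e-12:
        warnings.warn("constant matrix; orientation comparison is degenerate",
                      stacklevel=2)
        return pd.DataFrame(
            {"beta_signature": [], "flipped_signature": [], "spearman": []}
        )
    m_beta = nmf_factorize(
        V_df, k, n_runs=n_runs, seed=seed, objective=objective,
        max_iter=max_iter, orientation="beta",
    )
    m_flip = nmf_factorize(
        1.0 - V_df, k, n_runs=n_runs, seed=seed, objective=objective,
        max_iter=max_iter, orientation="one_minus_beta",
    )
    S = np.array(
        [
            [
                float(spearmanr(m_beta.H.iloc[i], m_flip.H.iloc[j]).statistic)
                for j in range(k)
            ]
            for i in range(k)
        ]
    )
    order = np.dstack(
        np.unravel_index(np.argsort(-np.abs(S), axis=None), S.shape)
    )[0]
    used1: set = set()
    used2: set = set()
    rows = []
    for i, j in order:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        rows.append(
            (m_beta.H.index[int(i)], m_flip.H.index[int(j)], S[i, j])
        )
    return pd.DataFrame(
        rows, columns=["beta_signature", "flipped_signature", "spearman"]
    )


class SignatureNMF(BaseEstimator, TransformerMixin):
    """Sklearn-style methylation-signature extractor.

    Follows the sklearn convention: ``X`` is samples x probes.  ``fit``
    factorizes ``X.T`` (probes x samples) and stores the column-stochastic
    weight matrix; ``transform`` projects new samples onto the fitted
    signatures by nonnegative least squares.

    Parameters
    ----------
    n_components : int or "auto"
        Rank k; "auto" runs the consensus rank survey over ``k_range``.
    k_range : iterable of int
        Candidate ranks for automatic selection.
    n_runs : int
        Random restarts per factorization (best objective wins).
    objective : {"kl", "frobenius"}
    orientation : {"beta", "one_minus_beta"}
        Whether to factorize X or 1 - X.
    random_state : int

    Attributes
    ----------
    components_ : ndarray (k, n_probes), rows sum to 1.
    activities_ : ndarray (n_samples_fit, k).
    model_ : SignatureModel of the training factorization.
    rank_diagnostics_ : RankDiagnostics (only when n_components="auto").
    """

    def __init__(
        self,
        n_components="auto",
        k_range=(2, 3, 4, 5, 6),
        n_runs: int = 30,
        objective: str = "kl",
        orientation: str = "beta",
        max_iter: int = 200,
        tol: float = 1e-6,
        min_probe_overlap: float = 0.5,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.k_range = k_range
        self.n_runs = n_runs
        self.objective = objective
        self.orientation = orientation
        self.max_iter = max_iter
        self.tol = tol
        self.min_probe_overlap = min_probe_overlap
        self.random_state = random_state

    def _as_V(self, X) -> pd.DataFrame:
        X_df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        V = X_df.T
        if self.orientation == "one_minus_beta":
            V = 1.0 - V
        elif self.orientation != "beta":
            raise ValueError("orientation must be 'beta' or 'one_minus_beta'")
        return V

    def fit(self, X, y=None) -> "SignatureNMF":
        V = self._as_V(X)
        if self.n_components == "auto":
            self.rank_diagnostics_ = rank_survey(
                V,
                k_range=self.k_range,
                n_runs=self.n_runs,
                seed=self.random_state,
                objective=self.objective,
                max_iter=self.max_iter,
            )
            k = select_rank(self.rank_diagnostics_)
        else:
            k = int(self.n_components)
        self.model_ = nmf_factorize(
            V,
            k,
            n_runs=self.n_runs,
            seed=self.random_state,
            objective=self.objective,
            max_iter=self.max_iter,
            tol=self.tol,
            orientation=self.orientation,
        )
        self.n_components_ = k
        self.components_ = self.model_.E.to_numpy().T
        self.activities_ = self.model_.H.to_numpy().T
        self.reconstruction_err_ = self.model_.reconstruction_error
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("SignatureNMF is not fitted")
        V = self._as_V(X)
        H = project_signatures(
            V, self.model_.E, min_probe_overlap=self.min_probe_overlap
        )
        return H.to_numpy().T
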