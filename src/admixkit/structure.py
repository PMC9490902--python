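"""Ancestry inference: LD pruning, PCA with projection, Gaussian-mixture
clustering of leading PCs, binomial-likelihood admixture estimation with
cross-validation, and the ancestry-Q dendrogram.

The admixture model is the standard unsupervised one: genotype g_il is
Binomial(2, f_il) with f_il = sum_k q_ik p_kl, where Q (N x K) holds
individual ancestry proportions and P (K x L) ancestral allele frequencies;
both are estimated by EM ascent of the log-likelihood

    l(Q, P) = sum_il [ g_il ln f_il + (2 - g_il) ln (1 - f_il) ].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.mixture import GaussianMixture

from .core import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

P_CLAMP = 1e-6

#: sklearn covariance families spanning the spherical..full spectrum
GMM_FAMILIES = ("spherical", "diag", "tied", "full")


# ---------------------------------------------------------------- LD pruning

def _window_r2(X: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation between genotype columns,
    missing entries replaced by the column mean (0 correlation contribution).
    Monomorphic columns yield r² = 0 against everything."""
    X = X.astype(float)
    X[X == MISSING] = np.nan
    mu = np.nanmean(X, axis=0)
    Xc = np.where(np.isnan(X), 0.0, X - mu)
    denom = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (Xc.T @ Xc) / np.outer(denom, denom)
    C[~np.isfinite(C)] = 0.0
    np.fill_diagonal(C, 0.0)
    return C**2


def ld_prune(G: GenotypeMatrix, window_snps: int = 200, step_snps: int = 50,
             r2_max: float = 0.4) -> np.ndarray:
    """Greedy sliding-window LD pruning (the ``--indep-pairwise`` scheme).

    Within each window of ``window_snps`` variants advanced by ``step_snps``,
    one member of every pair with r² > ``r2_max`` is removed — the member
    with the lower minor-allele frequency (tie: the later position) — and
    passes repeat until no window changes.  Returns the keep mask.
    """
    keep = np.ones(G.n_variants, dtype=bool)
    freqs = G.allele_freqs()
    maf = np.minimum(freqs, 1 - freqs)
    for chrom, sub in G.variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        changed = True
        while changed:
            changed = False
            for start in range(0, max(1, len(idx) - 1), step_snps):
                win = idx[start:start + window_snps]
                win = win[keep[win]]
                if win.size < 2:
                    continue
                r2 = _window_r2(G.calls[:, win])
                local_keep = np.ones(win.size, dtype=bool)
                pairs = np.argwhere(np.triu(r2 > r2_max, k=1))
                for a, b in pairs:
                    if not (local_keep[a] and local_keep[b]):
                        continue
                    # drop lower MAF; tie -> later position (b)
                    drop = b if maf[win[b]] <= maf[win[a]] else a
                    local_keep[drop] = False
                    changed = True
                keep[win[~local_keep]] = False
                if start + window_snps >= len(idx):
                    break
    return keep


# ----------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    scores: np.ndarray            # N x m
    eigenvalues: np.ndarray       # m
    loadings: np.ndarray          # L x m (for projection)
    varexp: np.ndarray            # m, fraction of total variance
    freqs: np.ndarray             # per-site p-hat used for scaling
    variant_ids: np.ndarray
    samples: list[str] = field(default_factory=list)


def _patterson_scale(calls: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Centre by 2p and scale by sqrt(2p(1-p)); missing entries become 0
    (i.e. imputed at the mean)."""
    denom = np.sqrt(2 * p * (1 - p))
    X = (calls.astype(float) - 2 * p) / denom
    X[calls == MISSING] = 0.0
    return X


def pca(G: GenotypeMatrix, m: int = 10) -> PCAResult:
    """Principal components of Patterson-scaled genotypes.

    Monomorphic sites are excluded.  Eigenvalues are those of the sample
    covariance of the scaled genotypes; variance-explained fractions are
    relative to the total.  Scores are sign-arbitrary (documented).
    """
    if G.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    p = G.allele_freqs()
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    calls = G.calls[:, poly]
    if m > G.n_samples:
        logger.warning("m=%d > N=%d; truncating", m, G.n_samples)
        m = G.n_samples
    X = _patterson_scale(calls, p[poly])
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eigvals = S**2 / (G.n_samples - 1)
    total = eigvals.sum()
    m = min(m, S.size)
    return PCAResult(
        scores=U[:, :m] * S[:m],
        eigenvalues=eigvals[:m],
        loadings=Vt[:m].T,
        varexp=eigvals[:m] / total,
        freqs=p[poly],
        variant_ids=G.variants.loc[poly, "id"].to_numpy(),
        samples=list(G.samples),
    )


def project(pca_result: PCAResult, G_new: GenotypeMatrix) -> np.ndarray:
    """Project new samples onto stored loadings using the training-set
    frequencies and scaling; variants matched by id."""
    ids = G_new.variants["id"].to_numpy()
    lookup = {v: i for i, v in enumerate(ids)}
    try:
        order = np.array([lookup[v] for v in pca_result.variant_ids])
    except KeyError as exc:
        raise ValueError(f"projection data lack training variant {exc}") from exc
    X = _patterson_scale(G_new.calls[:, order], pca_result.freqs)
    return X @ pca_result.loadings


# ----------------------------------------------------- Gaussian-mixture step

@dataclass
class ClusterAssignment:
    labels: np.ndarray            # 1..K
    posterior: np.ndarray         # N x K, rows sum to 1
    K: int
    covariance_family: str
    bic_table: pd.DataFrame       # columns K, family, bic


def _degenerate_fit(gm: GaussianMixture, labels: np.ndarray, K: int) -> bool:
    """A mixture fit is degenerate when a component is empty or a singleton
    under hard assignment, or when a component variance has collapsed onto
    the regularization floor (the spurious-likelihood solutions of
    unconstrained EM)."""
    counts = np.bincount(labels, minlength=K)
    if counts.min() < 2:
        return True
    cov = gm.covariances_
    floor = 100 * gm.reg_covar
    if gm.covariance_type == "spherical":
        return bool(cov.min() <= floor)
    if gm.covariance_type == "diag":
        return bool(cov.min() <= floor)
    if gm.covariance_type == "tied":
        return bool(np.linalg.eigvalsh(cov).min() <= floor)
    return bool(min(np.linalg.eigvalsh(c).min() for c in cov) <= floor)


def gmm_cluster(scores: np.ndarray, n_pc: int = 6, K_range=range(1, 10),
                seed: int = 0, n_restarts: int = 20) -> ClusterAssignment:
    """Model-based Gaussian clustering of the leading principal components.

    Mixtures are EM-fitted over four covariance families (spherical,
    diagonal, shared-full, full) for each K; the (K, family) pair with
    minimal BIC wins, except that models leaving a component empty under
    hard assignment are never selected.  Deterministic given seed
    (k-means++ initialisation, ``n_restarts`` restarts).
    """
    X = np.asarray(scores, dtype=float)
    if n_pc > X.shape[1]:
        raise ValueError(f"n_pc={n_pc} exceeds available PCs ({X.shape[1]})")
    X = X[:, :n_pc]
    rows, fits = [], {}
    for K in K_range:
        for fam in GMM_FAMILIES:
            try:
                gm = GaussianMixture(
                    n_components=K, covariance_type=fam, n_init=n_restarts,
                    init_params="k-means++", reg_covar=1e-6,
                    random_state=seed, max_iter=500)
                gm.fit(X)
                bic = gm.bic(X)
            except Exception as exc:  # persistent EM degeneracy
                logger.warning("GMM K=%d family=%s failed: %s", K, fam, exc)
                continue
            labels = gm.predict(X)
            degenerate = _degenerate_fit(gm, labels, K)
            if degenerate:
                logger.info("GMM K=%d family=%s degenerate "
                            "(empty/singleton component or collapsed "
                            "covariance); excluded from selection", K, fam)
            rows.append((K, fam, bic, degenerate))
            if not degenerate:
                fits[(K, fam)] = gm
    bic_table = pd.DataFrame(rows, columns=["K", "family", "bic", "degenerate"])
    usable = bic_table[~bic_table["degenerate"]]
    if usable.empty:
        raise RuntimeError("no Gaussian mixture fit succeeded")
    best = usable.loc[usable["bic"].idxmin()]
    gm = fits[(int(best["K"]), best["family"])]
    post = gm.predict_proba(X)
    return ClusterAssignment(labels=gm.predict(X) + 1, posterior=post,
                             K=int(best["K"]), covariance_family=best["family"],
                             bic_table=bic_table)


# ------------------------------------------------------- admixture estimation

@dataclass
class AdmixtureModel:
    Q: np.ndarray                 # N x K, rows sum to 1
    P: np.ndarray                 # K x L, clamped to [1e-6, 1-1e-6]
    loglik_trace: np.ndarray
    cv_error: dict = field(default_factory=dict)


def _admixture_loglik(g: np.ndarray, obs: np.ndarray, Q: np.ndarray,
                      P: np.ndarray) -> float:
    f = np.clip(Q @ P, 1e-12, 1 - 1e-12)
    ll = np.where(obs, g * np.log(f) + (2 - g) * np.log(1 - f), 0.0)
    return float(ll.sum())


def admixture_em(G: GenotypeMatrix, K: int, seed: int = 0, tol: float = 1e-6,
                 max_iter: int = 2000) -> AdmixtureModel:
    """Unsupervised admixture estimation by EM under the binomial likelihood.

    Missing genotype entries are skipped per-entry (not imputed).  The
    log-likelihood is non-decreasing across iterations (up to the P clamp);
    iteration stops when the relative change drops below ``tol``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > G.n_samples:
        raise ValueError(f"K={K} exceeds sample count {G.n_samples}")
    g = G.calls.astype(float)
    obs = G.calls != MISSING
    g[~obs] = 0.0
    N, L = g.shape
    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=N)
    P = rng.uniform(0.05, 0.95, size=(K, L))
    if K == 1:
        Q = np.ones((N, 1))
    g2 = np.where(obs, 2.0 - g, 0.0)
    trace = []
    ll_old = -np.inf
    for it in range(max_iter):
        f = np.clip(Q @ P, 1e-12, 1 - 1e-12)
        A = g / f                      # N x L, zero where unobserved
        B = g2 / (1 - f)
        QtA = Q.T @ A                  # K x L
        QtB = Q.T @ B
        num = P * QtA
        P_new = num / np.clip(num + (1 - P) * QtB, 1e-300, None)
        Q_new = Q * ((A @ P.T) + (B @ (1 - P).T))
        denom = 2.0 * obs.sum(axis=1, keepdims=True)
        Q_new = Q_new / np.clip(denom, 1, None)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        P = np.clip(P_new, P_CLAMP, 1 - P_CLAMP)
        Q = Q_new
        ll = _admixture_loglik(g, obs, Q, P)
        trace.append(ll)
        if it > 0 and abs(ll - ll_old) / max(abs(ll_old), 1.0) < tol:
            break
        ll_old = ll
    return AdmixtureModel(Q=Q, P=P, loglik_trace=np.array(trace))


def admixture_cv(G: GenotypeMatrix, K_range, folds: int = 5,
                 mask_fraction: float = 0.1, seed: int = 0,
                 tol: float = 1e-5, max_iter: int = 500) -> dict[int, float]:
    """Cross-validated admixture model choice.

    Per fold, a random ``mask_fraction`` of the observed genotype entries is
    hidden, the model refitted, and the hidden entries scored by mean
    binomial deviance between g and the fitted dosage 2·(QP); the CV error
    for each K is the mean over folds.  Bit-reproducible given seed.
    """
    if mask_fraction <= 0 or mask_fraction >= 1:
        raise ValueError("mask_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(G.calls != MISSING)
    errors = {int(K): [] for K in K_range}
    for fold in range(folds):
        chosen = obs_idx[rng.random(len(obs_idx)) < mask_fraction]
        if chosen.size == 0:
            raise ValueError("mask produced no held-out entries")
        masked = GenotypeMatrix(G.calls.copy(), list(G.samples),
                                G.variants.copy(), G.phased)
        masked.calls[chosen[:, 0], chosen[:, 1]] = MISSING
        truth = G.calls[chosen[:, 0], chosen[:, 1]].astype(float)
        for K in errors:
            model = admixture_em(masked, K, seed=seed + 1000 * fold + K,
                                 tol=tol, max_iter=max_iter)
            f = np.clip(model.Q @ model.P, 1e-9, 1 - 1e-9)
            mu = f[chosen[:, 0], chosen[:, 1]]
            with np.errstate(divide="ignore", invalid="ignore"):
                t1 = np.where(truth > 0, truth * np.log(truth / (2 * mu)), 0.0)
                t2 = np.where(truth < 2,
                              (2 - truth) * np.log((2 - truth) / (2 * (1 - mu))),
                              0.0)
            errors[K].append(float(np.mean(2 * (t1 + t2))))
    return {K: float(np.mean(v)) for K, v in errors.items()}


def align_components(Q_est: np.ndarray, Q_true: np.ndarray) -> np.ndarray:
    """Permute estimated components to best match the truth (label switching
    is inherent to mixture models); greedy assignment on column correlation."""
    from scipy.optimize import linear_sum_assignment
    K = Q_true.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = np.mean(np.abs(Q_est[:, a] - Q_true[:, b]))
    row, col = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[col] = row
    return Q_est[:, perm]


# ---------------------------------------------------------------- dendrogram

def _linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    n = len(leaf_names)
    trees = {i: (leaf_names[i], 0.0) for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        (sa, ha), (sb, hb) = trees.pop(int(a)), trees.pop(int(b))
        node = f"({sa}:{h / 2 - ha / 2:.6g},{sb}:{h / 2 - hb / 2:.6g})"
        trees[n + k] = (node, h / 2)
    (s, _), = trees.values()
    return s + ";"


def q_dendrogram(Q: np.ndarray, samples: list[str] | None = None,
                 cluster_labels=None, roh_mb=None,
                 metric: str = "euclidean", method: str = "average"
                 ) -> tuple[str, list[int], np.ndarray]:
    """UPGMA dendrogram of individuals in ancestry space.

    Pairwise distances (default Euclidean) between Q rows are agglomerated
    with average linkage; leaves carry the sample name and, when provided,
    the cluster label and total ROH Mb.  Returns (newick, leaf order, Z).
    """
    Q = np.asarray(Q, dtype=float)
    if Q.shape[0] < 2:
        raise ValueError("dendrogram needs at least 2 samples")
    if samples is None:
        samples = [f"S{i:04d}" for i in range(Q.shape[0])]
    names = []
    for i, s in enumerate(samples):
        parts = [str(s)]
        if cluster_labels is not None:
            parts.append(f"c{cluster_labels[i]}")
        if roh_mb is not None:
            parts.append(f"roh{roh_mb[i]:.1f}")
        names.append("_".join(parts))
    Z = hierarchy.linkage(pdist(Q, metric=metric), method=method)
    order = hierarchy.leaves_list(Z).tolist()
    return _linkage_to_newick(Z, names), order, Z
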