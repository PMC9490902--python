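"""nSL selection scan, frequency-bin standardization, candidate calling and
the shared/private partition of signals across ancestry clusters.

nSL (number of segregating sites by length) compares mean pairwise
haplotype-identity tract lengths, measured in SNPs, between carriers of the
derived and the ancestral allele at a focal SNP; unusually long derived
tracts mark recent positive selection (including soft sweeps) and need no
genetic map.  Here the tract for a haplotype pair (i, j) at focal SNP x is
the number of SNPs in the maximal contiguous SNP interval containing x over
which i and j agree at every SNP — so L_ij >= 1 always, and intervals are
truncated at chromosome ends without penalty.

Raw scores, nsl_raw = ln(SL_A / SL_D), are standardized within
derived-allele-frequency bins; candidates must clear an absolute score
threshold, a genome-wide percentile, and carry a trait annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import HaplotypeSet

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["id", "chrom", "pos", "daf", "sl_a", "sl_d", "nsl_raw"]


def _pair_tract_lengths(hi: np.ndarray, hj: np.ndarray) -> np.ndarray:
    """L_ij(x) for every focal SNP x on one chromosome: size of the maximal
    identity interval around x, from the previous/next mismatch positions."""
    L = hi.size
    mism = hi != hj
    idx = np.arange(L)
    prev = np.where(mism, idx, -1)
    prev = np.maximum.accumulate(prev)                       # last mismatch <= x
    nxt = np.where(mism, idx, L)
    nxt = np.minimum.accumulate(nxt[::-1])[::-1]             # next mismatch >= x
    # at focal SNPs where the pair agrees, <=/>= equal strict versions
    return nxt - prev - 1


def nsl_scan(H: HaplotypeSet, maf_min: float = 0.05) -> pd.DataFrame:
    """Compute raw nSL for every scorable SNP.

    A SNP is skipped when its minor-allele frequency is below ``maf_min`` or
    when either carrier class holds fewer than two haplotypes.  Scores are
    invariant to haplotype order; flipping the derived/ancestral labels at
    the focal SNP negates nsl_raw.
    """
    rows = []
    for chrom in H.chroms():
        sub = H.for_chrom(chrom)
        hap = sub.haplotypes
        n, L = hap.shape
        sum_d = np.zeros(L)
        cnt_d = np.zeros(L, dtype=np.int64)
        sum_a = np.zeros(L)
        cnt_a = np.zeros(L, dtype=np.int64)
        hap_b = hap.astype(bool)
        for i in range(n):
            for j in range(i + 1, n):
                tl = _pair_tract_lengths(hap[i], hap[j])
                both_d = hap_b[i] & hap_b[j]
                both_a = ~hap_b[i] & ~hap_b[j]
                sum_d[both_d] += tl[both_d]
                cnt_d[both_d] += 1
                sum_a[both_a] += tl[both_a]
                cnt_a[both_a] += 1
        daf = hap.mean(axis=0)
        maf = np.minimum(daf, 1 - daf)
        ok = (maf >= maf_min) & (cnt_d > 0) & (cnt_a > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sl_d = sum_d / np.maximum(cnt_d, 1)
            sl_a = sum_a / np.maximum(cnt_a, 1)
            raw = np.log(sl_a / sl_d)
        v = sub.variants
        for x in np.flatnonzero(ok):
            rows.append((v.at[x, "id"], chrom, int(v.at[x, "pos"]),
                         float(daf[x]), float(sl_a[x]), float(sl_d[x]),
                         float(raw[x])))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def nsl_brute_force(H: HaplotypeSet, maf_min: float = 0.05) -> pd.DataFrame:
    """Independent O(n²L²) reference: expand left/right from each focal SNP
    for each haplotype pair.  For cross-checking ``nsl_scan`` on small
    instances only."""
    rows = []
    for chrom in H.chroms():
        sub = H.for_chrom(chrom)
        hap = sub.haplotypes
        n, L = hap.shape
        v = sub.variants
        for x in range(L):
            daf = float(hap[:, x].mean())
            if min(daf, 1 - daf) < maf_min:
                continue
            der = [i for i in range(n) if hap[i, x] == 1]
            anc = [i for i in range(n) if hap[i, x] == 0]
            if len(der) < 2 or len(anc) < 2:
                continue

            def mean_l(group):
                lengths = []
                for a in range(len(group)):
                    for b in range(a + 1, len(group)):
                        i, j = group[a], group[b]
                        lo = x
                        while lo - 1 >= 0 and hap[i, lo - 1] == hap[j, lo - 1]:
                            lo -= 1
                        hi = x
                        while hi + 1 < L and hap[i, hi + 1] == hap[j, hi + 1]:
                            hi += 1
                        lengths.append(hi - lo + 1)
                return sum(lengths) / len(lengths)

            sl_d = mean_l(der)
            sl_a = mean_l(anc)
            rows.append((v.at[x, "id"], chrom, int(v.at[x, "pos"]), daf,
                         sl_a, sl_d, float(np.log(sl_a / sl_d))))
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def normalize_nsl(scores: pd.DataFrame, n_bins: int = 50) -> pd.DataFrame:
    """Standardize nsl_raw within equal-width derived-allele-frequency bins.

    Bins with fewer than two variants are merged with their nearest occupied
    neighbour; a zero-variance bin after merging leaves its scores flagged
    (``flagged`` column) rather than silently dropped.
    """
    if len(scores) < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} scored variants, "
                         f"got {len(scores)}")
    out = scores.copy()
    daf = out["daf"].to_numpy()
    bin_idx = np.clip((daf * n_bins).astype(int), 0, n_bins - 1)
    # merge small bins into the nearest occupied neighbour (leftward first)
    counts = np.bincount(bin_idx, minlength=n_bins)
    mapping = np.arange(n_bins)
    for b in range(n_bins):
        if 0 < counts[b] < 2:
            neigh = [o for o in range(n_bins)
                     if o != b and counts[o] >= 2]
            if neigh:
                target = min(neigh, key=lambda o: (abs(o - b), o))
                mapping[b] = target
                counts[target] += counts[b]
                counts[b] = 0
    bin_idx = mapping[bin_idx]
    out["bin"] = bin_idx
    out["nsl_std"] = np.nan
    out["flagged"] = False
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        vals = out.loc[sel, "nsl_raw"].to_numpy()
        sd = vals.std()
        if sd == 0:
            out.loc[sel, "flagged"] = True
            logger.warning("zero-variance frequency bin %d (%d variants)",
                           b, sel.sum())
        else:
            out.loc[sel, "nsl_std"] = (vals - vals.mean()) / sd
    return out


@dataclass
class CandidateSet:
    cluster: str
    variants: set[str]
    traits: dict[str, str] = field(default_factory=dict)
    scores: pd.DataFrame | None = None


def call_candidates(scores: pd.DataFrame, annotations: pd.DataFrame,
                    cluster: str = "", abs_min: float = 2.0,
                    percentile: float = 99.0) -> CandidateSet:
    """Candidates under selection: |nsl_std| >= abs_min, |nsl_std| at or
    above the cluster's given percentile of |nsl_std|, and trait-annotated."""
    if "nsl_std" not in scores.columns:
        raise ValueError("scores must be normalized first")
    ann = annotations.set_index("id")
    traited = ann.index[(ann["traits"].astype(str) != "")]
    if len(traited) == 0:
        logger.warning("annotation table carries no trait labels; "
                       "candidate set will be empty")
    ok = scores.dropna(subset=["nsl_std"]).copy()
    a = ok["nsl_std"].abs()
    cut = np.percentile(a, percentile) if len(a) else np.inf
    hits = ok[(a >= abs_min) & (a >= cut) & ok["id"].isin(traited)]
    traits = {v: ann.at[v, "traits"] for v in hits["id"]}
    return CandidateSet(cluster=cluster, variants=set(hits["id"]),
                        traits=traits, scores=hits.reset_index(drop=True))


def shared_private_partition(candidate_sets: list[CandidateSet]
                             ) -> tuple[dict[frozenset, int], pd.DataFrame]:
    """Inclusion/exclusion lattice over >= 2 clusters.

    Every candidate falls in exactly one lattice cell (the set of clusters
    calling it); cell counts sum to the union size.  The shared-by-all table
    lists each fully shared variant with its per-cluster standardized score
    and trait, mirroring a shared-signals summary table.
    """
    if len(candidate_sets) < 2:
        raise ValueError("partition needs at least 2 clusters")
    union = set().union(*(cs.variants for cs in candidate_sets))
    cells: dict[frozenset, int] = {}
    membership: dict[str, frozenset] = {}
    for v in union:
        cell = frozenset(cs.cluster for cs in candidate_sets if v in cs.variants)
        membership[v] = cell
        cells[cell] = cells.get(cell, 0) + 1
    all_clusters = frozenset(cs.cluster for cs in candidate_sets)
    shared_rows = []
    for v in sorted(union):
        if membership[v] != all_clusters:
            continue
        row = {"id": v}
        for cs in candidate_sets:
            sc = cs.scores
            val = np.nan
            if sc is not None and (sc["id"] == v).any():
                val = float(sc.loc[sc["id"] == v, "nsl_std"].iloc[0])
            row[f"nsl_std_{cs.cluster}"] = val
            if v in cs.traits:
                row["traits"] = cs.traits[v]
        shared_rows.append(row)
    return cells, pd.DataFrame(shared_rows)


def private_by_trait(candidate_sets: list[CandidateSet]) -> pd.DataFrame:
    """Variants private to one cluster, grouped by associated trait."""
    rows = []
    for cs in candidate_sets:
        others = set().union(*(o.variants for o in candidate_sets if o is not cs))
        for v in sorted(cs.variants - others):
            rows.append((cs.cluster, cs.traits.get(v, ""), v))
    return pd.DataFrame(rows, columns=["cluster", "trait", "id"])
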