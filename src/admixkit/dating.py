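"""Two-reference weighted-LD admixture dating.

In a population formed by an admixture pulse g generations ago, linkage
disequilibrium between variant pairs — weighted by the allele-frequency
difference between the two source populations — decays with genetic
distance d (Morgans) as exp(-g·d).  Binning the weighted LD
D_lm · w_l · w_m by |cM_l - cM_m| and fitting a·exp(-g·d) + c therefore
dates the pulse; a two-exponential fit (accepted over one pulse only when
an F-test on residual variance passes) dates two events.  Standard errors
come from a leave-one-chromosome-out jackknife when at least two
chromosomes contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import HaplotypeSet

logger = logging.getLogger(__name__)


@dataclass
class WeightedLDCurve:
    bin_mid_cM: np.ndarray
    value: np.ndarray
    n_pairs: np.ndarray
    dmin_cM: float
    bin_width_cM: float
    # per-chromosome accumulators enabling the jackknife
    chrom_sums: dict = field(default_factory=dict)    # chrom -> (sum, count) arrays

    def drop_chrom(self, chrom) -> "WeightedLDCurve":
        sums = {c: v for c, v in self.chrom_sums.items() if c != chrom}
        return _combine(sums, self.bin_mid_cM, self.dmin_cM, self.bin_width_cM)


def _combine(chrom_sums: dict, mids: np.ndarray, dmin: float,
             width: float) -> WeightedLDCurve:
    total = np.zeros(mids.size)
    count = np.zeros(mids.size, dtype=np.int64)
    for s, c in chrom_sums.values():
        total += s
        count += c
    with np.errstate(invalid="ignore"):
        value = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return WeightedLDCurve(mids, value, count, dmin, width, chrom_sums)


def weighted_ld_curve(H_target: HaplotypeSet, ref1_freqs: np.ndarray,
                      ref2_freqs: np.ndarray, bin_width_cM: float = 0.1,
                      dmin_cM: float = 0.5, dmax_cM: float = 30.0
                      ) -> WeightedLDCurve:
    """Distance-binned weighted LD in the target cohort.

    Weights are w_l = ref1_l - ref2_l; for every same-chromosome variant pair
    with dmin <= |cM_l - cM_m| <= dmax, D_lm·w_l·w_m is accumulated into its
    distance bin, where D_lm is the haplotype-frequency covariance
    (frequency of the 1-1 allele pair minus the product of marginals) in the
    target.  Swapping the references flips every weight's sign, which
    cancels in the product, so the curve is reference-symmetric.
    """
    ref1_freqs = np.asarray(ref1_freqs, dtype=float)
    ref2_freqs = np.asarray(ref2_freqs, dtype=float)
    if ref1_freqs.size != len(H_target.variants) or ref2_freqs.size != ref1_freqs.size:
        raise ValueError("reference frequency vectors must align with the "
                         "target variant table")
    if "cM" not in H_target.variants.columns:
        raise ValueError("target variants need cM coordinates")
    n_bins = int(np.ceil((dmax_cM - dmin_cM) / bin_width_cM))
    mids = dmin_cM + (np.arange(n_bins) + 0.5) * bin_width_cM
    w_all = ref1_freqs - ref2_freqs
    chrom_sums = {}
    for chrom in H_target.chroms():
        mask = (H_target.variants["chrom"] == chrom).to_numpy()
        if mask.sum() < 2:
            raise ValueError(f"chromosome {chrom} has < 2 mapped variants")
        hap = H_target.haplotypes[:, mask].astype(float)
        cm = H_target.variants.loc[mask, "cM"].to_numpy(dtype=float)
        w = w_all[mask]
        n = hap.shape[0]
        p = hap.mean(axis=0)
        D = (hap.T @ hap) / n - np.outer(p, p)
        WW = np.outer(w, w)
        dist = np.abs(cm[:, None] - cm[None, :])
        iu, ju = np.triu_indices(cm.size, k=1)
        d = dist[iu, ju]
        ok = (d >= dmin_cM) & (d <= dmax_cM)
        b = np.minimum(((d[ok] - dmin_cM) / bin_width_cM).astype(int), n_bins - 1)
        vals = (D * WW)[iu, ju][ok]
        chrom_sums[chrom] = (np.bincount(b, weights=vals, minlength=n_bins),
                             np.bincount(b, minlength=n_bins).astype(np.int64))
    return _combine(chrom_sums, mids, dmin_cM, bin_width_cM)


@dataclass
class PulseFit:
    amplitudes: tuple
    g: tuple                     # generations, one per pulse, descending
    c: float
    n_pulses: int
    sse: float
    jackknife_se: tuple | None = None
    f_test_p: float | None = None
    converged: bool = True
    message: str = ""


def _model1(d, a, g, c):
    return a * np.exp(-g * d) + c


def _model2(d, a1, g2, dg, a2, c):
    # parametrized as g1 = g2 + dg with dg > 0 so the order is enforced
    return a1 * np.exp(-(g2 + dg) * d) + a2 * np.exp(-g2 * d) + c


def _fit_one(d, y, n_starts: int = 8):
    best = None
    a0 = y[0] - y[-1] if y.size > 1 else y[0]
    c0 = float(y[-1])
    for g0 in np.geomspace(1, 200, n_starts):
        try:
            popt, _ = optimize.curve_fit(
                _model1, d, y, p0=[a0, g0, c0],
                bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        sse = float(((y - _model1(d, *popt)) ** 2).sum())
        if best is None or sse < best[1]:
            best = (popt, sse)
    return best


def _fit_two(d, y, n_starts: int = 6):
    best = None
    a0 = (y[0] - y[-1]) / 2 if y.size > 1 else y[0]
    c0 = float(y[-1])
    for g_old in np.geomspace(10, 200, n_starts):
        for g_new in np.geomspace(1, 20, 4):
            if g_new >= g_old:
                continue
            try:
                popt, _ = optimize.curve_fit(
                    _model2, d, y, p0=[a0, g_new, g_old - g_new, a0, c0],
                    bounds=([-np.inf, 1e-3, 1e-3, -np.inf, -np.inf],
                            [np.inf, 1e4, 1e4, np.inf, np.inf]),
                    maxfev=40000)
            except RuntimeError:
                continue
            sse = float(((y - _model2(d, *popt)) ** 2).sum())
            if best is None or sse < best[1]:
                best = (popt, sse)
    return best


def fit_pulses(curve: WeightedLDCurve, n_pulses: int | str = 1) -> PulseFit:
    """Nonlinear least squares of the pulse-decay model to a weighted-LD
    curve.

    ``n_pulses`` 1 fits a single exponential; 2 or "auto" fits both models
    and keeps the two-pulse one only when the nested F-test on residual
    variance rejects at alpha = 0.05.  Rates are reported directly as
    generations since each pulse (distance in Morgans).
    """
    ok = (curve.n_pairs > 0) & np.isfinite(curve.value)
    d = curve.bin_mid_cM[ok] / 100.0     # Morgans
    y = curve.value[ok]
    if d.size < 5:
        raise ValueError("need at least 5 usable distance bins")
    one = _fit_one(d, y)
    if one is None:
        return PulseFit((), (), np.nan, 0, np.nan, converged=False,
                        message="single-pulse fit failed from every start")
    (a, g, c), sse1 = one
    fit = PulseFit((float(a),), (float(g),), float(c), 1, sse1)
    if n_pulses in (2, "auto"):
        two = _fit_two(d, y)
        if two is None and n_pulses == 2:
            fit.message = "two-pulse fit failed; single-pulse fit reported"
        elif two is not None:
            (a1, g2, dg, a2, c2), sse2 = two
            dof2 = d.size - 5
            if dof2 > 0 and sse2 < sse1:
                F = ((sse1 - sse2) / 2.0) / (sse2 / dof2)
                p = float(stats.f.sf(F, 2, dof2))
            else:
                p = 1.0
            fit.f_test_p = p
            if p < 0.05:
                fit = PulseFit((float(a1), float(a2)),
                               (float(g2 + dg), float(g2)), float(c2), 2,
                               sse2, f_test_p=p)
    elif n_pulses != 1:
        raise ValueError("n_pulses must be 1, 2 or 'auto'")
    if len(curve.chrom_sums) >= 2:
        fit.jackknife_se = _jackknife_se(curve, fit)
    return fit


def _jackknife_se(curve: WeightedLDCurve, fit: PulseFit) -> tuple:
    gs = []
    for chrom in curve.chrom_sums:
        sub = curve.drop_chrom(chrom)
        ok = (sub.n_pairs > 0) & np.isfinite(sub.value)
        d = sub.bin_mid_cM[ok] / 100.0
        y = sub.value[ok]
        try:
            if fit.n_pulses == 1:
                popt, _ = optimize.curve_fit(
                    _model1, d, y, p0=[fit.amplitudes[0], fit.g[0], fit.c],
                    bounds=([-np.inf, 1e-3, -np.inf], [np.inf, 1e4, np.inf]),
                    maxfev=20000)
                gs.append([popt[1]])
            else:
                g1, g2 = fit.g
                popt, _ = optimize.curve_fit(
                    _model2, d, y,
                    p0=[fit.amplitudes[0], g2, g1 - g2, fit.amplitudes[1], fit.c],
                    bounds=([-np.inf, 1e-3, 1e-3, -np.inf, -np.inf],
                            [np.inf, 1e4, 1e4, np.inf, np.inf]),
                    maxfev=40000)
                gs.append([popt[1] + popt[2], popt[1]])
        except RuntimeError:
            continue
    if len(gs) < 2:
        return tuple(np.nan for _ in fit.g)
    gs = np.array(gs)
    m = gs.shape[0]
    return tuple(float(np.sqrt((m - 1) / m * ((gs[:, k] - gs[:, k].mean()) ** 2).sum()))
                 for k in range(gs.shape[1]))


def generations_to_year(g: float, gen_time_years: float = 30.0,
                        ref_year: float = 2000.0) -> int:
    """Calendar year of an event g generations before ``ref_year``
    (rounded to an integer year; g = 32 with 30-year generations and a
    2000 CE baseline gives 1040 CE)."""
    if g < 0:
        raise ValueError("g must be non-negative")
    return int(round(ref_year - g * gen_time_years))


def curve_table(curve: WeightedLDCurve) -> pd.DataFrame:
    return pd.DataFrame({"bin_cM": curve.bin_mid_cM, "value": curve.value,
                         "n_pairs": curve.n_pairs})
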