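"""Negative-binomial differential expression between tissues.

A compact re-implementation of the count-model workflow the field's
standard package popularised: median-of-ratios size factors, a per-row
NB2 model (variance m + a*m^2) with a log link and a two-group design,
a moment dispersion estimate shrunk halfway toward an across-row
target, a Wald test on the log2 fold change referred to a moderated t
distribution, and Benjamini-Hochberg adjustment. Calls use padj < 0.01.
Validated by simulation properties (null calibration, FDR, power), not
bit-equality with any package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)
MIN_DISPERSION = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    s_j = median over rows of count_ij / geometric-mean_i, using rows
    positive in every library; if no such row exists, fall back to the
    per-library median over that library's positive rows (logged).
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_pos = np.isfinite(logs).all(axis=1)
    if all_pos.any():
        loggeo = logs[all_pos].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs[all_pos] - loggeo, axis=0))
    else:
        logger.warning("no row with all-positive counts; "
                       "falling back to positive-subset medians")
        loggeo = np.nanmean(np.where(np.isfinite(logs), logs, np.nan),
                            axis=1, keepdims=True)
        ratios = logs - loggeo
        sf = np.exp(np.nanmedian(np.where(np.isfinite(ratios), ratios, np.nan),
                                 axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _moment_dispersion(q: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-row method-of-moments NB dispersion pooled across groups."""
    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for idx in groups:
        sub = q[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / np.maximum(m, 1e-12) ** 2, 0.0)
        w = len(idx) - 1
        num += w * a
        den += w
    return num / np.maximum(den, 1)


def _fit_group_log_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray,
                        n_iter: int = 30):
    """Vectorised per-row Newton fit of the group log-mean (log link).

    Returns (beta, info): the MLE of beta_g with mu_ij = s_j*exp(beta)
    and the Fisher information sum_j mu/(1+alpha*mu) at the optimum.
    """
    q_mean = (y / s).mean(axis=1)
    beta = np.log(np.maximum(q_mean, 1e-8))
    for _ in range(n_iter):
        mu = s * np.exp(beta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        beta = np.clip(beta + np.clip(step, -5, 5), -30.0, 30.0)
    mu = s * np.exp(beta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return beta, np.maximum(info, 1e-12)


def nb_wald_test(counts: pd.DataFrame, sf: pd.Series,
                 group_a: list[str], group_b: list[str],
                 alpha_level: float = 0.01) -> pd.DataFrame:
    """Per-row NB Wald test of group B over group A.

    Dispersion per row: max(pooled moment estimate, 1e-8) shrunk 50/50
    toward the across-row median. Rows with zero counts everywhere are
    dropped. Returns baseMean, log2FC (B over A), SE, stat, p, padj and
    the call at padj < ``alpha_level``.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 libraries")
    libs = list(group_a) + list(group_b)
    y = counts[libs].to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    y = y[nonzero]
    ids = counts.index[nonzero]
    s = sf.reindex(libs).to_numpy(dtype=float)
    q = y / s
    ia = np.arange(len(group_a))
    ib = np.arange(len(group_a), len(libs))

    raw = _moment_dispersion(q, [ia, ib])
    # shrinkage target: outlier-clipped mean of the raw per-row moment
    # estimates (the raw median is biased low at these residual df)
    hi = np.quantile(raw, 0.99) if raw.size > 1 else np.inf
    target = float(np.mean(np.clip(raw, 0.0, hi))) if raw.size else 0.0
    disp = np.maximum(0.5 * raw + 0.5 * target, MIN_DISPERSION)

    beta_a, info_a = _fit_group_log_mean(y[:, ia], s[ia], disp)
    beta_b, info_b = _fit_group_log_mean(y[:, ib], s[ib], disp)

    delta = beta_b - beta_a
    se_nat = np.sqrt(1.0 / info_a + 1.0 / info_b)
    stat = delta / se_nat
    # t reference: the 50/50-shrunk dispersion carries w^2 = 1/4 of the
    # row-estimate variance, so Satterthwaite df = residual_df / w^2
    df = 4 * (len(ia) + len(ib) - 2)
    p = 2.0 * stats.t.sf(np.abs(stat), df=df)
    padj = bh_adjust(p)
    lfc = delta / LOG2
    call = np.where(padj < alpha_level, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame({
        "baseMean": q.mean(axis=1),
        "log2FC": lfc,
        "SE": se_nat / LOG2,
        "stat": stat,
        "p": p,
        "padj": padj,
        "call": call,
    }, index=ids)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class EnrichmentSets:
    """The derived tissue-enrichment sets.

    ``nc_enriched``: up in NC against neural AND ectoderm AND blastula.
    ``shared_nc_blastula``: up in both NC and blastula against neural
    AND ectoderm, excluding anything DE between NC and blastula.
    """
    nc_enriched: list[str]
    shared_nc_blastula: list[str]


def _calls(results: dict, a: str, b: str, alpha: float):
    """(up_in_a, up_in_b, de_any) id sets for the pair, either orientation."""
    if (a, b) in results:
        df, flip = results[(a, b)], False
    elif (b, a) in results:
        df, flip = results[(b, a)], True
    else:
        raise ValueError(f"missing comparison between {a!r} and {b!r}")
    sig = df["padj"] < alpha
    up_b = set(df.index[sig & (df["log2FC"] > 0)])
    down_b = set(df.index[sig & (df["log2FC"] < 0)])
    de = set(df.index[sig])
    if flip:
        up_b, down_b = down_b, up_b
    # results[(a, b)] tests b over a: positive lfc = up in b
    return down_b, up_b, de


def build_enrichment_sets(results: dict[tuple[str, str], pd.DataFrame],
                          alpha: float = 0.01,
                          tissues=("NC", "neural", "ectoderm", "blastula"),
                          ) -> EnrichmentSets:
    import itertools
    for a, b in itertools.combinations(tissues, 2):
        if (a, b) not in results and (b, a) not in results:
            raise ValueError(f"missing comparison between {a!r} and {b!r}")
    nc, neural, ecto, blast = tissues
    up_nc = {}
    for other in (neural, ecto, blast):
        up_a, _, _ = _calls(results, nc, other, alpha)
        up_nc[other] = up_a
    nc_enriched = sorted(up_nc[neural] & up_nc[ecto] & up_nc[blast])

    up_blast = {}
    for other in (neural, ecto):
        up_a, _, _ = _calls(results, blast, other, alpha)
        up_blast[other] = up_a
    _, _, de_nc_blast = _calls(results, nc, blast, alpha)
    shared = (up_nc[neural] & up_nc[ecto]
              & up_blast[neural] & up_blast[ecto]) - de_nc_blast
    return EnrichmentSets(nc_enriched=nc_enriched,
                          shared_nc_blastula=sorted(shared))
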